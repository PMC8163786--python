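# Methods

`invascreen` quantifies how well breast myoepithelial cells restrain tumour
cell invasion in 3-D co-culture, at the scale of an siRNA screen.  A well is
photographed in brightfield as a stitched montage; each tumour colony is
segmented, and its invasiveness is scored by the convexity of its outline:

    R = convex hull length / boundary perimeter length.

A smooth, rounded colony has `R = 1`; protrusions lengthen the perimeter
while barely changing the hull, driving `R` toward 0.  Per-well Hoechst
images of the 2-D transfection plate give a companion viability readout, so
that loss of tumour control can be separated from plain myoepithelial death.

## Segmentation

The colony mask is produced by a fixed filter chain on the stitched
brightfield image:

1. Sobel edge magnitude (3×3 kernels, replicate borders) — colonies are
   texture- and rim-rich, background is flat, so gradient energy separates
   them independently of absolute intensity;
2. unsharp mask, radius 4 px, weight 0.8 (`(I − 0.8·G₄(I)) / 0.2`, ImageJ
   semantics where the radius is the Gaussian σ);
3. Gaussian blur, σ = 4 px, to consolidate the edge-energy field for
   thresholding;
4. threshold: Otsu over a 256-bin histogram by default.  The original
   workflow adjusted thresholds by hand per well; that is unrecorded, so the
   package instead exposes a deterministic additive `threshold_offset` and a
   per-well `manual_threshold`;
5. hole filling, so the perimeter later measures only the outer contour;
6. size filter: only components with area **strictly greater than 5,000
   pixels** survive (smaller objects may have grown from a single cell and
   are treated as debris).  At the default calibration of 2.58 µm/px —
   derived from the printed pair 5,000 px ↔ 33,282 µm² — that is 33,282 µm²;
7. components touching the image border are excluded by default (a
   truncated colony biases `R`); a flag re-includes them.

Components use 8-connectivity throughout.

## Shape measurement and the digital length metric

The outer boundary of each colony is traced with Moore-neighbor tracing
(Jacob's stopping criterion) through pixel centers, and its length is the
8-connected chain code: 1 per orthogonal step, √2 per diagonal step.  The
convex hull is computed on the boundary pixel centers with Andrew's
monotone chain.

Chain codes systematically overestimate smooth Euclidean curves (~5% for a
circle, direction-dependent for straight edges).  If the hull polygon were
measured as a Euclidean polygon while the boundary is measured as a chain
code, a perfect disc would score `R ≈ 0.95` and the "smooth = 1"
calibration that the score's interpretation rests on would be lost.  The
package therefore measures **both** lengths in the same digital metric: the
hull polygon is rasterized back onto the pixel grid, its outline re-traced,
and measured with the same chain code.  The shared digitization bias
cancels; a rasterized disc of radius 100 px scores `R = 1.000` and star
polygons agree with the exact vertex-geometry ratio to within ~5%.  The
Euclidean hull length remains available (`hull_perimeter`) for comparison
with other software; chain-code perimeters are comparable to ImageJ's
traced perimeters only within a ~5–10% band for smooth shapes.

Ratios in `(1, 1.01]` — possible on near-convex shapes because of
rasterization — are clamped to exactly 1.  Measured colonies always satisfy
`H ≤ 1.01·P`.

## Nuclei counting

Viability fields are counted with a transparent smooth-and-peak-find
detector: Gaussian smoothing at the nucleus scale (σ = 3 px), then local
maxima at a minimum separation (5 px) above
`median + max(0.3·(max − median), 12·σ_smooth)`.  The noise floor
`σ_smooth` is the pixel-noise scale estimated from raw adjacent-pixel
differences (nuclei are smooth at the single-pixel scale, so the median
difference is noise-dominated even on dense fields) propagated through the
smoothing filter (`var/(4πσ²)`).  The floor makes a field with no nuclei
count zero — on a blank field the relative term alone would chase noise
maxima — while sitting two orders of magnitude below real smoothed nuclei.  Nuclei closer than the separation merge into one detection —
a deliberate, documented limitation shared by this whole class of counters.
The proprietary counter used for the original screen is not emulated, and
absolute agreement with it is not claimed; accuracy is defined against the
synthetic generator (exact recovery at ≥12 px spacing).

## Normalization, hit calling, classification

Per plate, every colony ratio is divided by the mean ratio of that plate's
non-targeting-control (siOTP-NT) colonies, and every well nuclei count by
the mean control well count.  Conditions screened on several plates are
reported per plate; nothing is pooled across runs.

Hypothesis tests run on **raw** ratios (normalization is a per-plate
positive scalar, so within-plate test decisions are unchanged either way —
a property the test suite asserts): one-way ANOVA across groups, then
Dunnett's two-sided many-to-one comparisons of each target against the
control at α = 0.05.  Individual colonies are the observations, mirroring
the screen design in which dots on the published graphs are single 3-D
structures; wells are not independent biological replicates, so p-values
carry that pseudo-replication caveat.

Dunnett p-values are computed from the central many-to-one multivariate t
distribution with one-factor correlation λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)), by
deterministic 2-D quadrature (96-node Gauss–Hermite over the shared normal
factor × 96-node Gauss–Legendre over the pooled-scale chi variable).  For
k = 1 this reduces to the pooled two-sided t-test (agreement ~1e-12); for
general k it matches `scipy.stats.dunnett` to the latter's own Monte-Carlo
accuracy, and the simulated family-wise error at k = 5, n = 30 is
0.05 ± 0.01.  Groups with fewer than 3 colonies (default) are flagged
untestable rather than dropped.  Whether a non-significant ANOVA should
suppress Dunnett calls is ambiguous in screen practice; by default Dunnett
is reported regardless and the omnibus p alongside (`require_omnibus`
enables the gate).

Target conditions are classified with the only viability threshold the
screen defines, 50% of control:

| class                 | ratio test              | viability |
|-----------------------|-------------------------|-----------|
| suppressor_candidate  | hit, decreased ratio    | ≥ 0.5     |
| viability_impaired    | hit, decreased ratio    | < 0.5     |
| promoter_candidate    | hit, increased ratio    | ≥ 0.5     |
| no_hit                | otherwise               | —         |

Control roles map to `control`; tumour-alone wells to `tumor_alone`.

## Synthetic data

Colonies are radial star polygons `r(θ) = R₀(1 + a·cos(kθ))` sampled at 256
vertices (optionally with small multiplicative radial jitter).  Radial
polygons are always simple, and the exact hull/perimeter ratio of the
generating polygon — computed with shapely, independently of the
measurement path — serves as ground truth.  The ratio is 1 at `a = 0` and
decreases monotonically in `a`.  Rendering: textured interior (strong
fine-grained speckle), a darker 1.5 px rim, flat background, additive
Gaussian noise (σ = 0.02 of full scale by default).  The texture constants
were chosen so the fixed segmentation chain localizes colony boundaries
tightly: ≥95% of random colonies are recovered with Jaccard ≥ 0.85 against
the rasterized generating polygon.

A synthetic plate mirrors the real plate design: one non-targeting control
and one mock well per 3-D plate, four tumour-alone wells, two lethal-control
wells (2-D only, ~99.5% kill), and one well per siRNA target.  Per-condition
effects are an additive shift of the mean spike amplitude (invasion
release) and a multiplicative viability factor (transfection lethality).
Desk-scale defaults, chosen once as realistic for the geometry rather than
matched to any dataset: 5×3 fields of 256×256 px per well montage (fields
are the real acquisition grid; the field size is scaled down), 6+Poisson(5)
colonies per well with base radii 45–60 px, baseline amplitude 0.08 ± 0.05,
tumour-alone amplitude 0.45, four 2-D fields per well with ~120 nuclei per
field at full viability and ≥10 px spacing.  All randomness derives from
one seed via spawned substreams; outputs are byte-identical across reruns.

What the generator does **not** emulate: optical vignetting and field
stitching seams, uneven illumination, out-of-focus colonies, Cultrex matrix
texture, overlapping or touching colonies, and nucleus size/intensity
heterogeneity beyond amplitude jitter.  Passing tests therefore demonstrate
correctness of the measurement and inference chain under controlled
conditions, not robustness to every artefact of real plates — on real data
the manual threshold override and edge-exclusion flags exist precisely
because those artefacts occur.

## Numerical choices and edge cases

* Otsu thresholding errors out on single-valued images with advice to use a
  manual threshold; pixels strictly above threshold are foreground.
* The trace of a one-pixel-wide protrusion visits pixels twice — correct
  for a perimeter (both sides count).
* Collinear point sets yield a degenerate 2-point hull measured as twice
  the segment length (cannot reach the measurement path, which requires
  areas > 5,000 px).
* Simulation sizes in the test suite (100 replicate screens, 2,000-replicate
  null calibration, 200 brute-force hull sets) are the package's chosen
  verification scale.

## Known limitations

* The original screen's per-well manual thresholds are unrecorded, so exact
  reproduction of its deposited masks and hit lists is out of scope by
  design; the pipeline reproduces the *method*, with calibration properties
  as the contract.
* Colonies are measured independently; merged/touching colonies are
  measured as one object.
* No flat-field or illumination correction, and no plate-position (edge
  effect) correction — per-plate normalization to in-plate controls is the
  only batch handling, as in the original design.
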
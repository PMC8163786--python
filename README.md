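# invascreen

Quantitative analysis of 3-D myoepithelial/tumour co-culture screens from
high-content well images.

In early breast cancer, the myoepithelial cell layer around ducts acts as a
physical and paracrine barrier to tumour cell invasion (the DCIS → IDC
transition).  One way to find the genes behind that barrier is an siRNA
screen: knock genes down in myoepithelial cells, co-culture them with
invasive tumour cells in 3-D matrix, photograph every well, and ask whether
the tumour colonies grew smooth (contained) or protrusive (invasive).

`invascreen` implements the full quantification chain for such a screen:

* **Segmentation** of tumour colonies from stitched brightfield well
  montages (Sobel edge filter → unsharp mask radius 4/weight 0.8 →
  Gaussian blur σ 4 → threshold → hole filling → size filter: area
  > 5,000 px ≙ 33,282 µm² at 2.58 µm/px).
* **Invasiveness scoring** of every colony by the perimeter-to-convex-hull
  ratio

  `R = convex hull length / boundary perimeter length`

  with both lengths measured in one digital chain-code metric, so a smooth
  convex colony scores exactly 1 and protrusive colonies fall toward 0.
* **Viability** from Hoechst-stained 2-D companion plates (nuclei counted
  per field by a transparent smooth-and-peak-find detector).
* **Per-plate normalization** of ratios and viability to the in-plate
  non-targeting control (siOTP-NT).
* **Hit calling** by one-way ANOVA followed by Dunnett's two-sided
  many-to-one comparisons against the control — computed on raw ratios,
  with a deterministic multivariate-t quadrature — and phenotype
  classification: `suppressor_candidate` (invasion released, viability
  intact), `viability_impaired` (invasion released but <50% viability),
  `promoter_candidate` (colonies smoother than control).
* A **synthetic plate generator** (star-polygon colonies with exact,
  analytically known ratios; Gaussian-spot nuclei fields) so that every
  stage is testable offline with ground truth.

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

Simulate a plate with one planted invasion effect (`siINV`), one lethal
knockdown (`siLETHAL`), and a null (`siNULL`), then push it through the
whole pipeline in memory:

```python
from invascreen import SyntheticPlateSpec, ConditionEffect
from invascreen.pipeline import run_synthetic_screen

spec = SyntheticPlateSpec(
    plate_id="R1",
    targets={"siINV":    ConditionEffect(amplitude_shift=0.3),
             "siLETHAL": ConditionEffect(amplitude_shift=0.3,
                                         viability_factor=0.15),
             "siNULL":   ConditionEffect()},
    seed=11)
res = run_synthetic_screen(spec)
print(res["summary"][["condition", "role", "n_colonies", "ratio_raw_mean",
                      "ratio_norm_mean", "viability", "p_value", "hit",
                      "phenotype_class"]].round(4).to_string(index=False))
```

prints

```
  condition        role  n_colonies  ratio_raw_mean  ratio_norm_mean  viability  p_value   hit      phenotype_class
      siINV      target          12          0.6749           0.7061     0.9284   0.0000  True suppressor_candidate
   siLETHAL      target          14          0.7246           0.7581     0.1537   0.0000  True   viability_impaired
     siNULL      target          12          0.9530           0.9971     0.9221   0.9996 False               no_hit
   siOTP-NT  control_nt           7          0.9558           1.0000     1.0000      NaN False              control
       mock        mock          10          0.9565           1.0007     1.0337      NaN False              control
tumor_alone tumor_alone          44          0.6708           0.7019        NaN      NaN False          tumor_alone
      siTOX control_tox           0             NaN              NaN     0.0063      NaN False              control
```

Reading the table: control colonies score a raw mean ratio ≈ 0.96 (smooth,
tumour contained) and normalize to 1 by construction.  `siINV` colonies
drop to 0.71 of control with intact viability — the knocked-down gene is a
candidate invasion suppressor.  `siLETHAL` also releases invasion but only
15% of myoepithelial cells survive transfection, so the call is flagged as
viability-impaired rather than a clean suppressor.  The null stays at 1.0
and is not a hit.  Tumour cells alone (no myoepithelial partner) grow
invasively (0.70), and the lethal transfection control retains <1% of
control nuclei, confirming transfection efficiency.

The same analysis runs from the shell against images on disk:

```
invascreen simulate --out plate --seed 11        # or your own TIFFs
invascreen run --config config.toml              # montage → segment →
                                                 # measure → count → screen
```

with stage subcommands (`montage`, `segment`, `measure`, `count-nuclei`,
`screen`) that compose to the same CSVs.  Inputs are grayscale TIFF/PNG
wells named `<plate>_<well>.tif` (stitched) or `<plate>_<well>_f<k>.tif`
(5×3 field tiles), plus a plate-map CSV with columns
`plate_id,well,condition,role`.

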
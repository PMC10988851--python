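# renodki

Diffusion kurtosis imaging (DKI) of the layered kidney: signal simulation,
voxelwise tensor estimation, parameter maps, and cohort statistics.

## The problem

Renal interstitial fibrosis — for example the fibrosis induced by
hyperuricemia — changes the microstructure of the outer medulla before
conventional blood markers (creatinine, urea nitrogen) move. DKI probes that
microstructure non-invasively: water diffusion in complex tissue deviates
from a Gaussian displacement profile, and the size of that deviation (the
kurtosis) rises with inflammation and fibrosis while diffusivity falls.

`renodki` implements the complete quantitative chain used in longitudinal
small-animal DKI studies of the kidney, for researchers who want to test,
calibrate, or reanalyze such pipelines on fully synthetic, ground-truth data:

1. **Acquisition** — multi-shell schemes (default b = 0, 400, 800 s/mm² with
   25 electrostatically dispersed encoding directions, 51 volumes).
2. **Signal model** — for diffusion weighting *b* along unit direction *n*,

   ln[S(n, b) / S₀] = −b Σᵢⱼ nᵢnⱼ Dᵢⱼ + (b²/6) · D̄² · Σᵢⱼₖₗ nᵢnⱼnₖnₗ Wᵢⱼₖₗ

   with diffusion tensor **D** (6 unique components, mm²/s), dimensionless
   kurtosis tensor **W** (15 unique components, scaled by the squared mean
   diffusivity D̄²), and the b = 0 amplitude S₀.
3. **Estimation** — voxelwise log-linear fitting (OLS, or WLS with squared
   predicted-signal weights) of all 22 parameters, linearized through the
   auxiliary products V = D̄²·W; a nonlinear signal-space fit serves as an
   independent oracle in the test suite.
4. **Metrics** — MD = tr(D)/3, FA from the eigenvalue dispersion of D, and
   MK: the directional apparent kurtosis K(n) = (D̄²/D(n)²)·W(n) averaged
   over the sphere with a Gauss–Legendre product quadrature.
5. **Synthetic data** — tensors calibrated in closed form + bisection to any
   target (MD, FA, MK) triple; three-layer kidney phantoms (cortex CO, outer
   stripe OS, inner stripe IS of the outer medulla) under Rician magnitude
   noise; a 4-group × 6-timepoint cohort generator (control, hyperuricemia,
   allopurinol, allopurinol + empagliflozin; n = 6 per cell) calibrated to
   published regional means ± SDs; two-rater remeasurements; and fibrosis
   scores (Masson-stain mean optical density) correlated with MK.
6. **Statistics** — layered-ROI means over central coronal slices, ICC(2,1)
   inter-rater reproducibility with F-based confidence intervals, per-timepoint
   one-way ANOVA with Fisher-LSD post-hoc tests, and Pearson correlations
   between DKI metrics and fibrosis scores.

## Worked example

Calibrate tensors to a published outer-stripe baseline triple, simulate a
noiseless 51-volume acquisition, fit, and recompute the metrics:

```python
import renodki as rk

scheme = rk.build_scheme(25, [0, 400, 800], seed=7)
d, w = rk.calibrate_tensors(rk.TissueParams(md_target=2.735, fa_target=0.444,
                                            mk_target=0.760, region="OS"))
signals = rk.forward_signal(d, w, 1000.0, scheme)
fit = rk.fit_voxel(signals, scheme, "WLS")
print(f"MD = {rk.md(fit.D) * 1e3:.3f} x10-3 mm2/s")
print(f"FA = {rk.fa(fit.D):.3f}")
print(f"MK = {rk.mean_kurtosis(fit.D, fit.W):.3f}")
```

prints

```
MD = 2.735 x10-3 mm2/s
FA = 0.444
MK = 0.760
```

i.e. the estimation chain inverts the forward model exactly in the noiseless
limit. The full pipeline runs from the shell:

```bash
renodki full-run --seed 1 --out demo_run
```

which simulates a noisy 20×20×10 phantom plus the longitudinal cohort, fits
the phantom, extracts layered-ROI means, runs the statistics, and writes a
SHA-256 manifest (`demo_run/manifest.json`) that is byte-identical on reruns
with the same seed. Typical statistical output (`demo_run/stats/`): inner- and
outer-stripe MK separate the hyperuricemic group from day 3–5 onward
(e.g. 9d MK_OS ANOVA F ≈ 18.4, P ≈ 7e-7), inter-rater ICCs exceed 0.98, and
MK correlates positively with the fibrosis score (r ≈ 0.65 in OS, 0.73 in IS,
n = 27) while MD_OS correlates negatively — the qualitative fingerprint of
hyperuricemic renal fibrosis.

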
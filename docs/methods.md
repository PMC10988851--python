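# Methods

## Signal model and conventions

The package models the diffusion-weighted magnitude signal as

ln[S(n, b) / S₀] = −b·D(n) + (b²/6)·D̄²·W(n)

with D(n) = Σ nᵢnⱼ Dᵢⱼ the apparent diffusivity along unit direction n,
W(n) = Σ nᵢnⱼnₖnₗ Wᵢⱼₖₗ the quartic kurtosis form, and D̄ = tr(D)/3. The
kurtosis tensor is dimensionless under the D̄² scaling (Jensen's convention),
so the directional apparent kurtosis is K(n) = (D̄²/D(n)²)·W(n). The
diffusion term carries the physically required minus sign (signal decays
with b).

Component ordering is fixed in `renodki.tensors` and used everywhere:
D = (xx, yy, zz, xy, xz, yz) in mm²/s; W = the 15 unique quartic components
in lexicographic index order. Contractions carry permutation multiplicities
(2 for D off-diagonals; 4!/(cx!·cy!·cz!) for W).

## Estimation

Fitting is log-linear in the 22 parameters (ln S₀, the 6 Dᵢⱼ, and the 15
auxiliary products Vᵢⱼₖₗ = D̄²·Wᵢⱼₖₗ); W is recovered by dividing the fitted
V by D̄² of the fitted D. This two-step linearization is the standard way to
avoid the nonlinearity of D̄ inside the model. Estimators:

* **OLS** — unweighted least squares on ln S.
* **WLS** (default) — one reweighting pass with weights equal to the squared
  OLS-predicted signals, the first-order correction for the
  heteroscedasticity introduced by the log transform. Further reweighting
  iterations change the estimates by < 0.1% at realistic noise levels and
  are omitted.
* **NLS oracle** — full nonlinear least squares on S itself
  (`scipy.optimize.least_squares`, initialized from the linearized fit).
  It exists to bound the linearized estimators in tests and is not part of
  the production path.

Numerical policies: signals ≤ 0 are clipped to 10⁻⁶ × the voxel's b0 signal
(the log demands positivity) and the voxel is flagged `clipped-signal`;
fitting is unconstrained, and non-physical outcomes set flags rather than
being silently repaired (`negative-eigenvalue`, directional kurtosis outside
[−3/7, 10] → `implausible-kurtosis`, D̄ ≤ 10⁻¹² or a singular system →
`rank-deficient` with a least-norm solution). Voxels flagged rank-deficient
or negative-eigenvalue become NaN sentinels in the metric maps and are
excluded (never zero-filled) from ROI statistics. Model exponents beyond
|50| raise an unphysical-parameters error rather than overflowing.

A scheme must contain at least one b = 0 volume and two distinct nonzero
shells (to separate the b and b² terms) and at least 15 directions (to span
the 15-dimensional quartic space); the default acquisition is one b0 plus
25 shared directions on b = 400 and 800 s/mm², i.e. 51 volumes. Direction
sets come from seeded electrostatic repulsion on the half-sphere with
antipodal interaction, the standard construction for diffusion encoding.

## Mean kurtosis quadrature

MK is the orientation average of K(n). Because K(n) is a rational function
of n (not a polynomial), finite direction sets integrate it only
approximately. The default quadrature is a Gauss–Legendre (polar cosine) ×
uniform (azimuth) product rule of order 20 — 800 directions, exact for
spherical polynomials up to degree 39 — whose measured error on
renal-regime tensors is below 10⁻⁷, making MK rotation invariant to well
under 10⁻⁵. A 250–500 point equal-weight repulsion set was evaluated first
and rejected: its MK error (2–5 × 10⁻⁵) moves with tensor orientation, which
is large enough to contaminate round-trip calibration checks at the 10⁻⁴
level. An acquisition-direction average (`quadrature="acquisition"`) mimics
workstations that average over the 25 measured directions only; it differs
from the dense average by < 2% for the reference tissue values. Tensor
calibration uses the same default quadrature, so calibrate → simulate → fit
→ metrics round trips close to < 10⁻⁶ relative.

## Synthetic data: what it emulates

The generators reproduce the statistical structure of a longitudinal
rodent hyperuricemia study with four arms (control CON, hyperuricemic HUA,
allopurinol AP, allopurinol + empagliflozin AP+EM), six imaging timepoints
(baseline, days 1/3/5/7/9), six imaged animals per cell, and three renal
layers (CO, OS, IS):

* **Tensor calibration.** D is axially symmetric (prolate, principal axis
  +z) with eigenvalues solved in closed form from (MD, FA):
  d = FA·MD/√(3 − 2·FA²), λ₁ = MD + 2d, λ₂,₃ = MD − d (valid for FA < 0.95).
  W is isotropic, w₀ × the unit tensor with W(n) ≡ 1, with w₀ bisected so the
  quadrature MK hits the target to 10⁻¹². Orientation and kurtosis
  anisotropy are immaterial here because the reported metrics are rotation
  invariant and only MK is analyzed.
* **Phantom.** Three nested in-plane rectangular rings (CO/OS/IS plus a
  background frame), constant along the coronal axis; every region ≥ 30
  voxels so ROI means are stable. Default grid 20×20×10, S₀ = 1000.
* **Noise.** Rician magnitude noise, √((S+σg₁)² + (σg₂)²) with independent
  standard normal g₁, g₂. σ is parameterized as S₀/SNR with default SNR 25,
  a typical 3T small-animal abdominal regime.
* **Cohort.** Regional metric values drawn per cell as Normal(mean, SD)
  using the embedded reference table of published regional means ± SDs —
  the minimal model consistent with mean ± SD reporting. No within-subject
  longitudinal correlation is modeled (the downstream tests are
  cross-sectional per timepoint).
* **Raters.** Each measurement duplicated for two raters with independent
  Normal noise of SD = fraction × the empirical between-subject SD of its
  cell (default fraction 0.2), giving an expected ICC of 1/(1+fraction²)
  within a cell.
* **Fibrosis scores.** Histology animals (3 per group × days 1/5/9, three
  treated groups → 27 subjects) receive a Masson mean-optical-density score
  drawn from the bivariate-normal conditional given their regional MK,
  with configurable true correlation (default 0.687), MOD marginal
  Normal(0.13, 0.01) truncated at zero.

What the generators do **not** emulate — and hence what passing tests do not
establish about real data: anatomically realistic kidney shapes, partial
volume at layer boundaries, perfusion/IVIM contamination (suppressed in the
emulated design by b ≥ 400 s/mm²), motion or eddy-current artifacts, spatial
noise correlation, within-animal longitudinal correlation, and any real
histology-imaging coupling beyond the imposed bivariate correlation.

## Statistics

* **ROI means** — arithmetic mean of non-sentinel voxels per region over
  the 3 central coronal slices (configurable axis/count), voxel counts
  reported.
* **ICC** — ICC(2,1): two-way random effects, absolute agreement, single
  measure, from the two-way mean squares; 95% CI by the standard F-based
  construction (cross-checked against pingouin's ICC(A,1) in tests). Chosen
  because inter-rater agreement of continuous measurements is the textbook
  ICC(2,1) use case; the study design this mirrors reported only "ICC".
* **ANOVA + LSD** — classical one-way between/within decomposition per
  (timepoint, region, metric) stratum; Fisher LSD pairwise t-tests on the
  pooled MSE with N−k df and no multiplicity adjustment (that is the LSD
  definition, and it mirrors per-timepoint reporting practice). No
  correction is applied across strata either, matching the emulated
  analysis; this inflates family-wise error and is a deliberate fidelity
  choice, not a recommendation.
* **Correlations** — Pearson r with the two-sided t-transform P, pooling
  subjects across groups and the histology timepoints (1d/5d/9d). The
  exact pooling rule in the emulated analysis is not documented; this rule
  reproduces its apparent n = 27 and is configurable.

## Noise-floor limitation

At the default SNR 25, the b = 800 signals along the principal axis of the
medullary tensors fall to roughly the noise floor (S/σ ≈ 1–3). In that
regime magnitude-MRI bias is unavoidable for any estimator: regional FA is
inflated (strongest in the low-FA cortex, ~17%) and MK deflated (~8% in
IS), while MD stays within ~6%. The bias falls rapidly with noise — at
SNR 50 all nine regional means are within 5% of truth and at SNR 100 within
~1% — so the estimator-bias property test is run at SNR 50, and the default
generator keeps SNR 25 as the realistic acquisition condition. Cohort-level
statistics are generated directly from the published means/SDs and are not
affected by this imaging-chain bias.

## Reproducibility

Every stochastic stage consumes a seed derived from the global seed as
SHA-256(seed:stage) mod 2³¹, so stages are decorrelated but individually
pinnable (e.g. the scheme seed can be held fixed while the noise seed
varies). NIfTI `.nii.gz` outputs are gzipped with a zeroed timestamp and
CSVs are written at 17 significant digits with round-trip parsing, so a
full pipeline run is byte-reproducible and the run manifest records a
SHA-256 checksum per artifact. Default problem sizes (20×20×10 phantom,
51 volumes, 6 subjects per cohort cell, 500/200-replicate stochastic
checks) were chosen so the whole analysis remains interactive on one CPU.
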
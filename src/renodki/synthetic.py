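"""Synthetic inputs: calibrated tensors, layered kidney phantoms, cohorts.

This module generates everything the pipeline consumes, with the
statistical structure of a longitudinal rodent hyperuricemia study:

* per-region (MD, FA, MK) targets inverted into (D, W) tensor pairs,
* a three-layer kidney phantom (cortex CO, outer stripe OS, inner stripe
  IS of the outer medulla) imaged with a multi-shell scheme under Rician
  magnitude noise,
* a 4-group (CON control, HUA hyperuricemia, AP allopurinol, AP+EM
  allopurinol + empagliflozin) x 6-timepoint cohort of regional metric
  values drawn per cell from Normal(mean, SD),
* two-rater remeasurements for reproducibility (ICC) analysis, and
* histology fibrosis scores (Masson-stain mean optical density, MOD)
  correlated with MK through a bivariate-normal conditional.

The default cell means/SDs in ``REFERENCE_CELLS`` are the study conditions
the generators emulate; MD is on the x10^-3 mm^2/s scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import GradientScheme
from .errors import CalibrationError, PhantomSpecError
from .fitting import forward_signal
from .io import REGION_LEGEND, DWIVolume, LabelMap, validate_roi_table
from .metrics import SphereQuadrature, default_quadrature, mean_kurtosis
from .tensors import DiffusionTensor, KurtosisTensor, isotropic_kurtosis

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "REGIONS",
    "METRICS",
    "REFERENCE_CELLS",
    "reference_cohort_params",
    "baseline_tissue_params",
    "TissueParams",
    "PhantomSpec",
    "CohortDesign",
    "calibrate_tensors",
    "layered_labels",
    "simulate_phantom",
    "add_rician_noise",
    "simulate_cohort",
    "simulate_rater_pair",
    "simulate_fibrosis_scores",
    "simulate_histology_cohort",
]

GROUPS = ("CON", "HUA", "AP", "AP+EM")
TIMEPOINTS = ("base", "1d", "3d", "5d", "7d", "9d")
REGIONS = ("CO", "OS", "IS")
METRICS = ("MK", "FA", "MD")

# (metric, region) -> timepoint -> ((mean, sd) per group, in GROUPS order)
REFERENCE_CELLS = {
    ("MK", "CO"): {
        "base": ((0.857, 0.018), (0.859, 0.020), (0.857, 0.036), (0.853, 0.020)),
        "1d": ((0.877, 0.015), (0.864, 0.018), (0.862, 0.012), (0.867, 0.008)),
        "3d": ((0.862, 0.012), (0.861, 0.010), (0.842, 0.030), (0.859, 0.007)),
        "5d": ((0.858, 0.032), (0.840, 0.026), (0.852, 0.022), (0.858, 0.019)),
        "7d": ((0.852, 0.039), (0.853, 0.033), (0.858, 0.017), (0.865, 0.023)),
        "9d": ((0.863, 0.025), (0.866, 0.011), (0.849, 0.016), (0.845, 0.025)),
    },
    ("MK", "OS"): {
        "base": ((0.760, 0.022), (0.754, 0.011), (0.769, 0.016), (0.767, 0.010)),
        "1d": ((0.763, 0.015), (0.758, 0.014), (0.758, 0.010), (0.753, 0.009)),
        "3d": ((0.763, 0.021), (0.789, 0.018), (0.775, 0.014), (0.770, 0.011)),
        "5d": ((0.773, 0.016), (0.820, 0.020), (0.788, 0.023), (0.778, 0.019)),
        "7d": ((0.776, 0.022), (0.821, 0.016), (0.788, 0.017), (0.785, 0.021)),
        "9d": ((0.773, 0.024), (0.820, 0.018), (0.787, 0.011), (0.780, 0.017)),
    },
    ("MK", "IS"): {
        "base": ((0.640, 0.035), (0.657, 0.023), (0.647, 0.021), (0.653, 0.019)),
        "1d": ((0.658, 0.028), (0.675, 0.023), (0.658, 0.008), (0.658, 0.019)),
        "3d": ((0.660, 0.021), (0.737, 0.040), (0.682, 0.024), (0.670, 0.013)),
        "5d": ((0.667, 0.029), (0.776, 0.027), (0.683, 0.019), (0.673, 0.016)),
        "7d": ((0.678, 0.025), (0.789, 0.026), (0.688, 0.012), (0.681, 0.013)),
        "9d": ((0.687, 0.029), (0.787, 0.030), (0.699, 0.009), (0.693, 0.013)),
    },
    ("FA", "CO"): {
        "base": ((0.263, 0.022), (0.272, 0.015), (0.270, 0.017), (0.273, 0.021)),
        "1d": ((0.269, 0.011), (0.264, 0.009), (0.264, 0.015), (0.264, 0.011)),
        "3d": ((0.283, 0.012), (0.273, 0.010), (0.275, 0.014), (0.280, 0.013)),
        "5d": ((0.278, 0.013), (0.270, 0.016), (0.268, 0.018), (0.272, 0.009)),
        "7d": ((0.280, 0.015), (0.280, 0.007), (0.275, 0.013), (0.275, 0.008)),
        "9d": ((0.278, 0.014), (0.266, 0.016), (0.269, 0.011), (0.264, 0.012)),
    },
    ("FA", "OS"): {
        "base": ((0.444, 0.015), (0.448, 0.021), (0.450, 0.039), (0.455, 0.033)),
        "1d": ((0.463, 0.021), (0.463, 0.034), (0.459, 0.024), (0.461, 0.022)),
        "3d": ((0.470, 0.014), (0.448, 0.029), (0.455, 0.024), (0.461, 0.017)),
        "5d": ((0.467, 0.030), (0.440, 0.024), (0.450, 0.033), (0.462, 0.028)),
        "7d": ((0.470, 0.013), (0.447, 0.041), (0.450, 0.030), (0.457, 0.031)),
        "9d": ((0.471, 0.006), (0.448, 0.043), (0.457, 0.028), (0.462, 0.022)),
    },
    ("FA", "IS"): {
        "base": ((0.748, 0.020), (0.733, 0.021), (0.733, 0.015), (0.730, 0.011)),
        "1d": ((0.757, 0.014), (0.740, 0.018), (0.745, 0.025), (0.739, 0.023)),
        "3d": ((0.751, 0.032), (0.698, 0.035), (0.723, 0.032), (0.740, 0.030)),
        "5d": ((0.760, 0.016), (0.669, 0.027), (0.732, 0.034), (0.740, 0.017)),
        "7d": ((0.763, 0.026), (0.643, 0.023), (0.750, 0.030), (0.755, 0.029)),
        "9d": ((0.763, 0.014), (0.644, 0.024), (0.752, 0.011), (0.757, 0.012)),
    },
    ("MD", "CO"): {
        "base": ((3.163, 0.118), (3.240, 0.404), (3.468, 0.258), (3.327, 0.371)),
        "1d": ((2.593, 0.247), (2.772, 0.302), (2.708, 0.309), (2.397, 0.378)),
        "3d": ((3.147, 0.422), (2.927, 0.289), (3.078, 0.594), (2.910, 0.358)),
        "5d": ((2.635, 0.315), (3.107, 0.452), (2.652, 0.531), (2.687, 0.377)),
        "7d": ((2.815, 0.685), (3.115, 0.485), (2.502, 0.097), (2.680, 0.687)),
        "9d": ((3.170, 0.447), (3.192, 0.281), (2.840, 0.329), (3.262, 0.416)),
    },
    ("MD", "OS"): {
        "base": ((2.735, 0.222), (2.608, 0.447), (2.751, 0.237), (2.666, 0.352)),
        "1d": ((2.766, 0.121), (2.811, 0.161), (2.784, 0.258), (2.760, 0.235)),
        "3d": ((2.723, 0.227), (2.239, 0.414), (2.637, 0.328), (2.661, 0.226)),
        "5d": ((2.770, 0.262), (1.970, 0.318), (2.428, 0.436), (2.503, 0.378)),
        "7d": ((2.781, 0.385), (1.859, 0.413), (2.362, 0.342), (2.517, 0.311)),
        "9d": ((2.790, 0.292), (1.849, 0.460), (2.349, 0.249), (2.463, 0.286)),
    },
    ("MD", "IS"): {
        "base": ((2.628, 0.183), (2.660, 0.213), (2.567, 0.296), (2.642, 0.624)),
        "1d": ((2.607, 0.121), (2.332, 0.401), (2.375, 0.173), (2.333, 0.196)),
        "3d": ((2.605, 0.463), (2.194, 0.306), (2.307, 0.330), (2.333, 0.658)),
        "5d": ((2.615, 0.229), (2.287, 0.401), (2.357, 0.266), (2.444, 0.315)),
        "7d": ((2.716, 0.132), (2.278, 0.421), (2.456, 0.684), (2.580, 0.370)),
        "9d": ((2.784, 0.194), (2.321, 0.341), (2.468, 0.427), (2.705, 0.650)),
    },
}


def reference_cohort_params() -> pd.DataFrame:
    """Tidy (metric, region, timepoint, group, mean, sd) reference table."""
    rows = []
    for (metric, region), by_tp in REFERENCE_CELLS.items():
        for tp, cells in by_tp.items():
            for group, (mean, sd) in zip(GROUPS, cells):
                rows.append((metric, region, tp, group, mean, sd))
    return pd.DataFrame(
        rows, columns=["metric", "region", "timepoint", "group", "mean", "sd"]
    )


@dataclass(frozen=True)
class TissueParams:
    """Regional metric targets; ``md`` on the x10^-3 mm^2/s scale."""

    md_target: float
    fa_target: float
    mk_target: float
    region: str = ""

    def __post_init__(self) -> None:
        if self.md_target <= 0:
            raise CalibrationError("md_target must be positive")
        if not (0 <= self.fa_target < 0.95):
            raise CalibrationError(
                "fa_target must lie in [0, 0.95) for the prolate closed form"
            )
        if self.mk_target < 0:
            raise CalibrationError("mk_target must be nonnegative")


def baseline_tissue_params(group: str = "CON", timepoint: str = "base") -> dict:
    """Per-region targets from the reference table for one (group, timepoint) cell."""
    gi = GROUPS.index(group)
    out = {}
    for region in REGIONS:
        md = REFERENCE_CELLS[("MD", region)][timepoint][gi][0]
        fa = REFERENCE_CELLS[("FA", region)][timepoint][gi][0]
        mk = REFERENCE_CELLS[("MK", region)][timepoint][gi][0]
        out[region] = TissueParams(md, fa, mk, region)
    return out


def calibrate_tensors(
    target: TissueParams, quadrature: SphereQuadrature | None = None
) -> tuple[DiffusionTensor, KurtosisTensor]:
    """Invert (MD, FA, MK) targets into a prolate D and isotropic W.

    The diffusion tensor is axially symmetric with principal axis +z and
    eigenvalues (l1, l2, l2) solved in closed form from (MD, FA); the
    kurtosis tensor is w0 times the isotropic unit tensor, with w0 found by
    bisection so the quadrature-averaged MK hits the target.
    """
    q = quadrature if quadrature is not None else default_quadrature()
    m = target.md_target * 1e-3  # mm^2/s
    f = target.fa_target
    # prolate split: l1 = m + 2d, l2 = l3 = m - d with FA = 3d/sqrt(3m^2+6d^2)
    d = f * m / np.sqrt(3.0 - 2.0 * f**2)
    lam1, lam2 = m + 2.0 * d, m - d
    if lam2 <= 0:
        raise CalibrationError("fa_target too large: radial eigenvalue <= 0")
    diffusion = DiffusionTensor(np.array([lam2, lam2, lam1, 0.0, 0.0, 0.0]))

    def mk_of(w0: float) -> float:
        return mean_kurtosis(diffusion, isotropic_kurtosis(w0), q)

    if target.mk_target == 0:
        return diffusion, isotropic_kurtosis(0.0)
    unit = mk_of(1.0)
    if unit <= 0:
        raise CalibrationError("quadrature-averaged kurtosis of the unit tensor is <= 0")
    lo, hi = 0.0, 1.5 * target.mk_target / unit
    for _ in range(200):
        if mk_of(hi) >= target.mk_target:
            break
        hi *= 2.0
    else:  # pragma: no cover
        raise CalibrationError("bisection bracket not found")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        err = mk_of(mid) - target.mk_target
        if abs(err) < 1e-12:
            lo = hi = mid
            break
        if err < 0:
            lo = mid
        else:
            hi = mid
    w0 = 0.5 * (lo + hi)
    return diffusion, isotropic_kurtosis(w0)


def layered_labels(
    shape: tuple[int, int, int],
    margins: tuple[int, int, int] = (1, 2, 1),
    region_boxes: dict | None = None,
) -> LabelMap:
    """Three nested in-plane (x, z) rings, constant along the coronal axis y.

    ``margins`` are the background frame, CO ring and OS ring thicknesses;
    the remaining core is IS.  Explicit ``region_boxes`` (region ->
    (x0, x1, y0, y1, z0, z1) half-open bounds) override the nesting and are
    checked for disjointness.
    """
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)
    code = {v: k for k, v in REGION_LEGEND.items()}
    if region_boxes is not None:
        occupied = np.zeros(shape, dtype=bool)
        for region, (x0, x1, y0, y1, z0, z1) in region_boxes.items():
            mask = np.zeros(shape, dtype=bool)
            mask[x0:x1, y0:y1, z0:z1] = True
            if (mask & occupied).any():
                raise PhantomSpecError(f"region {region} overlaps another region")
            occupied |= mask
            labels[mask] = code[region]
    else:
        bg, co, os_ = margins
        bounds = [bg, bg + co, bg + co + os_]
        for level, region in zip(bounds, ("CO", "OS", "IS")):
            if 2 * level >= min(nx, nz):
                raise PhantomSpecError("margins leave no room for the inner regions")
            labels[level : nx - level, :, level : nz - level] = code[region]
    for region in REGIONS:
        n_vox = int((labels == code[region]).sum())
        if n_vox < 30:
            raise PhantomSpecError(
                f"region {region} has only {n_vox} voxels (< 30, unstable ROI means)"
            )
    return LabelMap(labels)


@dataclass(frozen=True)
class PhantomSpec:
    """Layered kidney phantom specification."""

    shape: tuple[int, int, int] = (20, 20, 10)
    tissue: dict = field(default_factory=baseline_tissue_params)
    s0: float = 1000.0
    rician_sigma: float = 40.0  # s0 / SNR; default SNR 25
    seed: int = 0
    margins: tuple[int, int, int] = (1, 2, 1)
    region_boxes: dict | None = None
    voxel_size: tuple[float, float, float] = (0.625, 3.0, 0.417)

    def __post_init__(self) -> None:
        if self.rician_sigma < 0:
            raise PhantomSpecError("rician_sigma must be nonnegative")
        if set(self.tissue) != set(REGIONS):
            raise PhantomSpecError(f"tissue params must cover regions {REGIONS}")


def add_rician_noise(signals: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((S + sigma*g1)^2 + (sigma*g2)^2)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    signals = np.asarray(signals, dtype=float)
    if sigma == 0:
        return signals.copy()
    rng = np.random.default_rng(seed)
    g1 = rng.standard_normal(signals.shape)
    g2 = rng.standard_normal(signals.shape)
    return np.sqrt((signals + sigma * g1) ** 2 + (sigma * g2) ** 2)


def simulate_phantom(
    spec: PhantomSpec,
    scheme: GradientScheme,
    quadrature: SphereQuadrature | None = None,
) -> tuple[DWIVolume, LabelMap]:
    """Noisy multi-shell acquisition of the layered phantom."""
    affine = np.diag(list(spec.voxel_size) + [1.0])
    label_map = layered_labels(spec.shape, spec.margins, spec.region_boxes)
    label_map = LabelMap(label_map.labels, label_map.legend, affine)
    data = np.zeros(spec.shape + (scheme.n_volumes,))
    for region in REGIONS:
        d, w = calibrate_tensors(spec.tissue[region], quadrature)
        data[label_map.region_mask(region)] = forward_signal(d, w, spec.s0, scheme)
    data = add_rician_noise(data, spec.rician_sigma, spec.seed)
    return DWIVolume(data, scheme, affine), label_map


@dataclass(frozen=True)
class CohortDesign:
    """Longitudinal cohort: groups x timepoints, n subjects per cell."""

    groups: tuple = GROUPS
    timepoints: tuple = TIMEPOINTS
    regions: tuple = REGIONS
    metrics: tuple = METRICS
    n_subjects: int = 6
    cell_params: pd.DataFrame | None = None  # defaults to reference table
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need n_subjects >= 2")
        params = self.cell_params if self.cell_params is not None else reference_cohort_params()
        if (params["sd"] <= 0).any():
            raise ValueError("cell SDs must be positive")
        object.__setattr__(self, "cell_params", params)


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Per-cell Normal draws of regional metric values, seeded and tidy."""
    rng = np.random.default_rng(design.seed)
    lookup = design.cell_params.set_index(["metric", "region", "timepoint", "group"])
    rows = []
    for metric in design.metrics:
        for region in design.regions:
            for tp in design.timepoints:
                for group in design.groups:
                    mean, sd = lookup.loc[(metric, region, tp, group)]
                    values = rng.normal(mean, sd, size=design.n_subjects)
                    for i, v in enumerate(values):
                        rows.append(
                            (f"{group}-{i + 1:02d}", group, tp, region, metric, v)
                        )
    table = pd.DataFrame(
        rows, columns=["subject", "group", "timepoint", "region", "metric", "value"]
    )
    return validate_roi_table(table)


def simulate_rater_pair(
    table: pd.DataFrame, rater_sd_fraction: float, seed: int
) -> pd.DataFrame:
    """Duplicate each measurement for two raters with independent noise.

    The rater noise SD is ``rater_sd_fraction`` times the empirical
    between-subject SD of the measurement's (group, timepoint, region,
    metric) cell; single-subject cells fall back to the metric-wide SD.
    """
    if not 0 <= rater_sd_fraction < 1:
        raise ValueError("rater_sd_fraction must lie in [0, 1)")
    validate_roi_table(table)
    rng = np.random.default_rng(seed)
    cell_cols = ["group", "timepoint", "region", "metric"]
    cell_sd = table.groupby(cell_cols)["value"].transform("std")
    metric_sd = table.groupby("metric")["value"].transform("std")
    sd = cell_sd.fillna(metric_sd).fillna(0.0) * rater_sd_fraction
    parts = []
    for rater in (1, 2):
        part = table.copy()
        part["rater"] = rater
        part["value"] = part["value"] + rng.normal(0.0, 1.0, len(part)) * sd.to_numpy()
        parts.append(part)
    return validate_roi_table(pd.concat(parts, ignore_index=True))


def simulate_histology_cohort(
    seed: int,
    n_per_cell: int = 3,
    groups: tuple = ("HUA", "AP", "AP+EM"),
    timepoints: tuple = ("1d", "5d", "9d"),
    regions: tuple = REGIONS,
    metrics: tuple = METRICS,
) -> pd.DataFrame:
    """Distinct euthanized subjects per (group, timepoint) histology cell."""
    rng = np.random.default_rng(seed)
    lookup = reference_cohort_params().set_index(
        ["metric", "region", "timepoint", "group"]
    )
    rows = []
    for group in groups:
        for tp in timepoints:
            for i in range(n_per_cell):
                subject = f"{group}-{tp}-H{i + 1:02d}"
                for region in regions:
                    for metric in metrics:
                        mean, sd = lookup.loc[(metric, region, tp, group)]
                        rows.append(
                            (subject, group, tp, region, metric, rng.normal(mean, sd))
                        )
    table = pd.DataFrame(
        rows, columns=["subject", "group", "timepoint", "region", "metric", "value"]
    )
    return validate_roi_table(table)


def simulate_fibrosis_scores(
    table: pd.DataFrame,
    true_r: float,
    seed: int,
    metric: str = "MK",
    mod_mean: float = 0.13,
    mod_sd: float = 0.01,
) -> pd.DataFrame:
    """Fibrosis MOD scores conditionally correlated with a regional metric.

    For each subject's regional ``metric`` value the MOD score is drawn
    from the bivariate-normal conditional with correlation ``true_r``,
    standardizing the metric within each region against its pooled
    empirical moments; the MOD marginal is Normal(mod_mean, mod_sd)
    truncated at zero.
    """
    if not -1 < true_r < 1:
        raise ValueError("true_r must lie strictly inside (-1, 1)")
    validate_roi_table(table)
    rng = np.random.default_rng(seed)
    sub = table[table["metric"] == metric].copy()
    if sub.empty:
        raise ValueError(f"table holds no rows for metric {metric!r}")
    out_rows = []
    for region, part in sub.groupby("region", sort=False):
        v = part["value"].to_numpy()
        sd = v.std(ddof=1)
        z = (v - v.mean()) / (sd if sd > 0 else 1.0)
        eps = rng.standard_normal(len(part))
        mod = mod_mean + mod_sd * (true_r * z + np.sqrt(1.0 - true_r**2) * eps)
        mod = np.maximum(mod, np.finfo(float).tiny)
        for (_, row), m in zip(part.iterrows(), mod):
            out_rows.append(
                (row["subject"], row["group"], row["timepoint"], region, m)
            )
    return pd.DataFrame(
        out_rows, columns=["subject", "group", "timepoint", "region", "mod_value"]
    )
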
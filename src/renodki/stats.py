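"""Cohort statistics: ROI means, two-rater ICC, ANOVA + LSD, correlations.

The statistical layer mirrors a classical small-animal imaging analysis:

* regional means over a few central coronal slices of the metric maps,
* inter-rater reproducibility via the two-way random-effects,
  absolute-agreement, single-measure intraclass correlation ICC(2,1),
  with the F-based 95% confidence interval,
* per-timepoint one-way ANOVA across the four treatment groups followed by
  Fisher's least-significant-difference (LSD) pairwise tests (unadjusted,
  pooled ANOVA error term), and
* Pearson correlations between regional DKI metrics and fibrosis scores.

All formulas are computed from sums of squares directly so the pooled
error term is available to the post-hoc tests; tests cross-check them
against scipy and pingouin.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError
from .io import LabelMap, validate_roi_table
from .metrics import ParameterMaps

__all__ = [
    "AnovaResult",
    "IccResult",
    "StatsReport",
    "roi_means",
    "icc",
    "anova_oneway",
    "lsd_posthoc",
    "pearson",
    "summary_report",
]

HISTOLOGY_TIMEPOINTS = ("1d", "5d", "9d")


def roi_means(
    maps: ParameterMaps,
    labels: LabelMap,
    slice_axis: int = 1,
    n_slices: int = 3,
) -> pd.DataFrame:
    """Mean MK/FA/MD per region over central contiguous slices.

    Sentinel (NaN) voxels are excluded; the surviving voxel count is
    reported alongside each mean.  Raises if a region is empty within the
    selected slices.
    """
    if labels.labels.shape != maps.shape:
        raise StatsError(
            f"label grid {labels.labels.shape} does not match maps {maps.shape}"
        )
    length = maps.shape[slice_axis]
    if n_slices > length:
        warnings.warn(
            f"n_slices={n_slices} exceeds volume extent {length}; using all slices",
            stacklevel=2,
        )
        n_slices = length
    start = (length - n_slices) // 2
    sl = [slice(None)] * 3
    sl[slice_axis] = slice(start, start + n_slices)
    sl = tuple(sl)

    rows = []
    region_names = [name for code, name in sorted(labels.legend.items()) if code != 0]
    for region in region_names:
        region_mask = labels.region_mask(region)[sl]
        for metric, arr in (("MK", maps.mk), ("FA", maps.fa), ("MD", maps.md)):
            values = arr[sl][region_mask]
            values = values[np.isfinite(values)]
            if values.size == 0:
                raise StatsError(
                    f"region {region} has no defined voxels in the selected slices"
                )
            rows.append((region, metric, float(values.mean()), int(values.size)))
    return pd.DataFrame(rows, columns=["region", "metric", "value", "n_voxels"])


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    n_subjects: int
    n_raters: int


def icc(data: np.ndarray | pd.DataFrame, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``data`` is (subjects x raters); a DataFrame with subject/rater/value
    columns is pivoted first.  CI from the standard F-based construction.
    """
    if isinstance(data, pd.DataFrame):
        data = data.pivot(index="subject", columns="rater", values="value").to_numpy()
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise StatsError("ICC input must be a subjects x raters matrix")
    if np.isnan(x).any():
        raise StatsError("every subject must be measured by every rater")
    n, k = x.shape
    if n < 3:
        raise StatsError(f"need >= 3 subjects for ICC, got {n}")
    if k < 2:
        raise StatsError("need >= 2 raters")

    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise StatsError("degenerate ICC: no variance anywhere")
    est = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return IccResult(1.0, 1.0, 1.0, n, k)

    a = k * est / (n * (1.0 - est)) if est < 1 else np.inf
    b = 1.0 + k * est * (n - 1) / (n * (1.0 - est)) if est < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:  # est == 1 with rater bias zero handled above; protect the edge
        lower = upper = 1.0
    return IccResult(float(est), float(lower), float(upper), n, k)


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ms_error: float
    group_names: tuple
    group_means: tuple
    group_ns: tuple
    degenerate: bool = False


def anova_oneway(groups, names=None) -> AnovaResult:
    """Classical one-way between/within decomposition with an F test."""
    arrays = [np.asarray(g, dtype=float).reshape(-1) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise StatsError("every group needs >= 2 values")
    if names is None:
        names = tuple(f"g{i + 1}" for i in range(len(arrays)))
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    total_n = int(ns.sum())
    grand = np.concatenate(arrays).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b, df_w = len(arrays) - 1, total_n - len(arrays)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0:
        # zero within-group variance: either no signal at all or a perfect split
        f = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
        return AnovaResult(
            f, p, df_b, df_w, 0.0, tuple(names), tuple(means), tuple(ns), True
        )
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        float(f), p, df_b, df_w, float(ms_w), tuple(names), tuple(means), tuple(ns)
    )


def lsd_posthoc(anova: AnovaResult) -> pd.DataFrame:
    """Fisher LSD pairwise tests using the pooled ANOVA error term.

    t = (m_a - m_b) / sqrt(MSE (1/n_a + 1/n_b)) with N - k degrees of
    freedom and no multiplicity adjustment.
    """
    if anova.degenerate and anova.ms_error == 0:
        raise StatsError("LSD undefined: pooled error variance is zero")
    rows = []
    for ia, ib in itertools.combinations(range(len(anova.group_names)), 2):
        diff = anova.group_means[ia] - anova.group_means[ib]
        se = np.sqrt(anova.ms_error * (1.0 / anova.group_ns[ia] + 1.0 / anova.group_ns[ib]))
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), anova.df_within))
        rows.append(
            (anova.group_names[ia], anova.group_names[ib], float(diff), float(t), p)
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "t", "p"])


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-transform P value."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    if x.size < 3:
        raise StatsError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class StatsReport:
    """Assembled analysis tables (ICC, ANOVA, LSD, correlations, summary)."""

    icc_table: pd.DataFrame
    anova_table: pd.DataFrame
    posthoc_table: pd.DataFrame
    correlation_table: pd.DataFrame
    summary_table: pd.DataFrame
    alpha: float = 0.05

    def save(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("icc", "anova", "posthoc", "correlation", "summary"):
            df = getattr(self, f"{name}_table")
            path = directory / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.17g")
            paths[name] = path
        significant = (
            self.anova_table[self.anova_table["p"] < self.alpha]
            if not self.anova_table.empty
            else self.anova_table
        )
        summary = {
            "alpha": self.alpha,
            "n_significant_anova_strata": int(len(significant)),
            "significant_strata": significant[
                ["timepoint", "region", "metric", "p"]
            ].to_dict("records")
            if not self.anova_table.empty
            else [],
        }
        path = directory / "report.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        paths["report"] = path
        return paths


def _icc_table(raters: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (region, metric), part in raters.groupby(["region", "metric"], sort=False):
        wide = part.pivot_table(
            index=["subject", "timepoint"], columns="rater", values="value"
        ).dropna()
        res = icc(wide.to_numpy())
        rows.append(
            (region, metric, res.estimate, res.ci_lower, res.ci_upper, res.n_subjects)
        )
    return pd.DataFrame(
        rows, columns=["region", "metric", "icc", "ci_lower", "ci_upper", "n"]
    )


def summary_report(
    table: pd.DataFrame,
    raters: pd.DataFrame | None = None,
    fibrosis: pd.DataFrame | None = None,
    correlation_timepoints: tuple = HISTOLOGY_TIMEPOINTS,
    alpha: float = 0.05,
) -> StatsReport:
    """Run the full statistical layer on a tidy regional-metrics table.

    ANOVA + LSD run per (timepoint, region, metric) stratum across groups;
    correlations pool subjects across groups and the histology timepoints;
    ICC is computed from the optional two-rater table.
    """
    validate_roi_table(table)
    if table.empty:
        raise StatsError("ROI table is empty")

    anova_rows, posthoc_parts = [], []
    strata = table.groupby(["timepoint", "region", "metric"], sort=False)
    for (tp, region, metric), part in strata:
        named = [
            (g, sub["value"].to_numpy())
            for g, sub in part.groupby("group", sort=False)
        ]
        if len(named) < 2 or any(v.size < 2 for _, v in named):
            continue
        res = anova_oneway([v for _, v in named], names=[g for g, _ in named])
        anova_rows.append((tp, region, metric, res.f, res.p, res.df_between, res.df_within))
        if res.ms_error > 0:
            post = lsd_posthoc(res)
            post.insert(0, "metric", metric)
            post.insert(0, "region", region)
            post.insert(0, "timepoint", tp)
            posthoc_parts.append(post)
    anova_table = pd.DataFrame(
        anova_rows,
        columns=["timepoint", "region", "metric", "f", "p", "df_between", "df_within"],
    )
    posthoc_table = (
        pd.concat(posthoc_parts, ignore_index=True)
        if posthoc_parts
        else pd.DataFrame(
            columns=["timepoint", "region", "metric", "group_a", "group_b", "mean_diff", "t", "p"]
        )
    )

    agg = table.groupby(["metric", "region", "timepoint", "group"], sort=False)["value"]
    summary_table = agg.agg(["mean", "std", "count"]).reset_index()
    summary_table = summary_table.rename(columns={"std": "sd", "count": "n"})
    summary_table["formatted"] = [
        f"{m:.3f} ± {s:.3f}" for m, s in zip(summary_table["mean"], summary_table["sd"])
    ]

    corr_rows = []
    if fibrosis is not None and not fibrosis.empty:
        pool = table[table["timepoint"].isin(correlation_timepoints)]
        merge_keys = ["subject", "region"]
        if "timepoint" in fibrosis.columns:
            merge_keys.append("timepoint")
        merged = pool.merge(fibrosis, on=merge_keys, suffixes=("", "_fib"))
        for (metric, region), part in merged.groupby(["metric", "region"], sort=False):
            if len(part) < 3 or part["value"].std() == 0:
                continue
            r, p = pearson(part["value"], part["mod_value"])
            corr_rows.append((metric, region, r, p, len(part)))
    correlation_table = pd.DataFrame(
        corr_rows, columns=["metric", "region", "r", "p", "n"]
    )

    icc_table = (
        _icc_table(validate_roi_table(raters))
        if raters is not None and not raters.empty
        else pd.DataFrame(columns=["region", "metric", "icc", "ci_lower", "ci_upper", "n"])
    )
    return StatsReport(
        icc_table=icc_table,
        anova_table=anova_table,
        posthoc_table=posthoc_table,
        correlation_table=correlation_table,
        summary_table=summary_table,
        alpha=alpha,
    )
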
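"""Pipeline orchestration: simulate -> fit -> ROI -> stats, with a manifest.

Each stage is a plain function over the library modules; the CLI wraps
them.  A full run records every written artifact with its SHA-256 checksum
in ``manifest.json`` so reruns with the same configuration can be verified
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import io as rio
from .acquisition import build_scheme
from .config import RunConfig
from .errors import RenodkiError
from .fitting import fit_volume
from .metrics import acquisition_quadrature, default_quadrature, maps_from_fit
from .stats import roi_means, summary_report
from .synthetic import (
    PhantomSpec,
    simulate_cohort,
    simulate_fibrosis_scores,
    simulate_histology_cohort,
    simulate_phantom,
    simulate_rater_pair,
    CohortDesign,
)

__all__ = ["run_simulate", "run_fit", "run_roi", "run_stats", "run_full"]

log = logging.getLogger("renodki")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except RenodkiError as exc:
                raise RenodkiError(f"[{name}] {exc}") from exc
            log.info("stage=%s duration=%.2fs", name, time.perf_counter() - t0)
            return result

        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped

    return deco


def _quadrature_for(config: RunConfig, scheme):
    if config.quadrature == "acquisition":
        return acquisition_quadrature(scheme)
    return default_quadrature()


@_stage("simulate")
def run_simulate(config: RunConfig, out_dir) -> dict[str, Path]:
    """Write every synthetic input: phantom, gradient tables, cohort CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = build_scheme(
        config.n_directions, list(config.shells), config.seed_for("scheme")
    )
    spec = PhantomSpec(
        shape=tuple(config.phantom_shape),
        s0=config.s0,
        rician_sigma=config.rician_sigma,
        seed=config.seed_for("phantom"),
        margins=tuple(config.margins),
        region_boxes=config.region_boxes,
    )
    quad = _quadrature_for(config, scheme)
    dwi, labels = simulate_phantom(spec, scheme, quad)
    artifacts = {}
    rio.write_dwi(dwi, out / "dwi.nii.gz", out / "dwi.bval", out / "dwi.bvec")
    artifacts["dwi"] = out / "dwi.nii.gz"
    artifacts["bval"] = out / "dwi.bval"
    artifacts["bvec"] = out / "dwi.bvec"
    rio.write_labels(labels, out / "labels.nii.gz")
    artifacts["labels"] = out / "labels.nii.gz"

    cohort = simulate_cohort(
        CohortDesign(n_subjects=config.n_subjects, seed=config.seed_for("cohort"))
    )
    rio.write_roi_table(cohort, out / "cohort.csv")
    artifacts["cohort"] = out / "cohort.csv"

    raters = simulate_rater_pair(
        cohort[cohort["group"] == "HUA"],
        config.rater_sd_fraction,
        config.seed_for("raters"),
    )
    rio.write_roi_table(raters, out / "raters.csv")
    artifacts["raters"] = out / "raters.csv"

    histology = simulate_histology_cohort(config.seed_for("histology"))
    rio.write_roi_table(histology, out / "histology.csv")
    artifacts["histology"] = out / "histology.csv"
    fibrosis = simulate_fibrosis_scores(
        histology, config.fibrosis_r, config.seed_for("fibrosis")
    )
    fibrosis.to_csv(out / "fibrosis.csv", index=False, float_format="%.17g")
    artifacts["fibrosis"] = out / "fibrosis.csv"
    log.info("simulate: seeds %s", {s: config.seed_for(s) for s in
             ("scheme", "phantom", "cohort", "raters", "histology", "fibrosis")})
    return artifacts


@_stage("fit")
def run_fit(
    dwi_path, bval_path, bvec_path, out_dir, mask_path=None, estimator="wls",
    quadrature="sphere",
) -> dict[str, Path]:
    """Fit tensors voxelwise and write MK/FA/MD/S0 maps plus a fit log."""
    out = Path(out_dir)
    dwi = rio.read_dwi(dwi_path, bval_path, bvec_path)
    mask = rio.read_labels(mask_path) if mask_path else None
    fit = fit_volume(dwi, mask, estimator=estimator.upper())
    quad = (
        acquisition_quadrature(dwi.scheme)
        if quadrature == "acquisition"
        else default_quadrature()
    )
    maps = maps_from_fit(fit, affine=dwi.affine, quadrature=quad)
    artifacts = dict(rio.write_maps(maps, out))
    fit_log = {
        "estimator": fit.estimator_tag,
        "quadrature": quadrature,
        "n_fitted_voxels": int(fit.mask.sum()),
        "flag_counts": fit.flag_counts(),
    }
    path = out / "fit_log.json"
    path.write_text(json.dumps(fit_log, indent=2, sort_keys=True))
    artifacts["fit_log"] = path
    log.info("fit: %s", fit_log)
    return artifacts


@_stage("roi")
def run_roi(maps_dir, labels_path, out_path, slice_axis=1, n_slices=3) -> dict[str, Path]:
    """Extract per-region metric means from written maps."""
    maps = rio.read_maps(maps_dir)
    labels = rio.read_labels(labels_path)
    table = roi_means(maps, labels, slice_axis=slice_axis, n_slices=n_slices)
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False, float_format="%.17g")
    return {"roi_means": out}


@_stage("stats")
def run_stats(
    table_path, out_dir, raters_path=None, fibrosis_path=None, alpha=0.05
) -> dict[str, Path]:
    """Run ICC/ANOVA/LSD/correlation analyses and write the report files."""
    table = rio.read_roi_table(table_path)
    raters = rio.read_roi_table(raters_path) if raters_path else None
    fibrosis = pd.read_csv(fibrosis_path) if fibrosis_path else None
    report = summary_report(table, raters=raters, fibrosis=fibrosis, alpha=alpha)
    artifacts = report.save(out_dir)
    sig = report.anova_table[report.anova_table["p"] < alpha]
    for _, row in sig.iterrows():
        log.info(
            "significant: %s %s %s P=%.4g",
            row["timepoint"], row["region"], row["metric"], row["p"],
        )
    return artifacts


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> Path:
    """simulate -> fit -> roi -> stats; returns the manifest path."""
    out = Path(config.out_dir)
    artifacts: dict[str, Path] = {}
    artifacts.update(run_simulate(config, out))
    artifacts.update(
        run_fit(
            out / "dwi.nii.gz", out / "dwi.bval", out / "dwi.bvec",
            out / "maps", mask_path=out / "labels.nii.gz",
            estimator=config.estimator, quadrature=config.quadrature,
        )
    )
    artifacts.update(
        run_roi(
            out / "maps", out / "labels.nii.gz", out / "roi_means.csv",
            slice_axis=config.slice_axis, n_slices=config.n_slices,
        )
    )
    # the correlation arm uses the histology animals, so stats run on the
    # longitudinal cohort plus the euthanized histology subjects
    combined = pd.concat(
        [rio.read_roi_table(out / "cohort.csv"), rio.read_roi_table(out / "histology.csv")],
        ignore_index=True,
    )
    rio.write_roi_table(combined, out / "metrics_all.csv")
    artifacts["metrics_all"] = out / "metrics_all.csv"
    artifacts.update(
        run_stats(
            out / "metrics_all.csv", out / "stats",
            raters_path=out / "raters.csv", fibrosis_path=out / "fibrosis.csv",
        )
    )
    # normalize the output location so the serialized config (and hence the
    # manifest) is identical wherever the run directory lives
    config.override(out_dir=".").to_yaml(out / "config.yaml")
    artifacts["config"] = out / "config.yaml"
    manifest = {
        "seed": config.seed,
        "stage_seeds": {
            s: config.seed_for(s)
            for s in ("scheme", "phantom", "cohort", "raters", "histology", "fibrosis")
        },
        "artifacts": sorted(
            (
                {
                    "name": name,
                    "path": str(Path(p).relative_to(out)),
                    "sha256": _sha256(Path(p)),
                }
                for name, p in artifacts.items()
            ),
            key=lambda a: a["name"],
        ),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
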
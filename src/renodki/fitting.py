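"""Forward signal model and voxelwise tensor estimation.

The diffusion-kurtosis signal model used throughout is

    ln[S(n, b) / S0] = -b * D(n) + (b² / 6) * MD² * W(n)

with D(n) = Σ n_i n_j D_ij, W(n) = Σ n_i n_j n_k n_l W_ijkl and
MD = trace(D)/3.  The fit is linearized by estimating the auxiliary
products V_ijkl = MD² W_ijkl, which makes the 22-parameter system
(ln S0, 6 D components, 15 V components) linear in the log signal; W is
recovered afterwards by dividing the fitted V by MD² of the fitted D.

Estimators: OLS (unweighted log-linear), WLS (one reweighting pass with
weights equal to the squared OLS-predicted signals — the standard remedy
for the log transform's heteroscedasticity), and a nonlinear least-squares
fit in signal space that serves as an independent oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .acquisition import GradientScheme
from .errors import FitError
from .tensors import (
    D_MULTIPLICITY,
    W_MULTIPLICITY,
    DiffusionTensor,
    KurtosisTensor,
    d_monomials,
    w_monomials,
)

__all__ = [
    "FitResult",
    "FitMaps",
    "design_matrix",
    "forward_signal",
    "fit_voxel",
    "fit_volume",
    "nls_oracle_fit",
]

N_PARAMS = 22
_MAX_EXPONENT = 50.0
_MD_FLOOR = 1e-12
SIGNAL_FLOOR_FRACTION = 1e-6

FLAG_NEGATIVE_EIGENVALUE = "negative-eigenvalue"
FLAG_CLIPPED_SIGNAL = "clipped-signal"
FLAG_RANK_DEFICIENT = "rank-deficient"
FLAG_IMPLAUSIBLE_KURTOSIS = "implausible-kurtosis"
FLAG_NON_CONVERGED = "non-converged"

# physically admissible directional kurtosis range used only for flagging
KURTOSIS_RANGE = (-3.0 / 7.0, 10.0)


@dataclass(frozen=True)
class FitResult:
    """Single-voxel model solution with provenance flags."""

    D: DiffusionTensor
    W: KurtosisTensor
    s0: float
    residual_norm: float
    estimator_tag: str
    flags: frozenset = field(default_factory=frozenset)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(n_volumes, 22) matrix mapping (ln S0, D6, V15) onto ln S.

    Column 0 is the intercept; columns 1-6 are -b·n_i n_j with pair
    multiplicity; columns 7-21 are (b²/6)·n_i n_j n_k n_l with multinomial
    multiplicity, acting on V = MD²·W.
    """
    b = scheme.bvals[:, None]
    dm = d_monomials(scheme.bvecs) * D_MULTIPLICITY
    wm = w_monomials(scheme.bvecs) * W_MULTIPLICITY
    return np.hstack([np.ones((scheme.n_volumes, 1)), -b * dm, (b**2 / 6.0) * wm])


def forward_signal(
    d: DiffusionTensor, w: KurtosisTensor, s0: float, scheme: GradientScheme
) -> np.ndarray:
    """Noiseless signals S(n, b) for every volume of the scheme."""
    if s0 <= 0:
        raise FitError("s0 must be positive")
    md = d.mean_diffusivity
    beta = np.concatenate([[0.0], d.components, md**2 * w.components])
    exponent = design_matrix(scheme) @ beta
    if np.any(np.abs(exponent) > _MAX_EXPONENT):
        raise FitError(
            "unphysical parameters: |model exponent| exceeds "
            f"{_MAX_EXPONENT} for at least one volume"
        )
    return s0 * np.exp(exponent)


def _beta_to_result(
    beta: np.ndarray,
    residual_norm: float,
    tag: str,
    flags: set,
) -> FitResult:
    d = DiffusionTensor(beta[1:7])
    md = d.mean_diffusivity
    if md <= _MD_FLOOR:
        flags.add(FLAG_RANK_DEFICIENT)
        w = KurtosisTensor(np.zeros(15))
    else:
        w = KurtosisTensor(beta[7:] / md**2)
    if np.linalg.eigvalsh(d.as_matrix()).min() < 0:
        flags.add(FLAG_NEGATIVE_EIGENVALUE)
    return FitResult(
        D=d,
        W=w,
        s0=float(np.exp(beta[0])),
        residual_norm=float(residual_norm),
        estimator_tag=tag,
        flags=frozenset(flags),
    )


def _prepare_signals(signals: np.ndarray, scheme: GradientScheme) -> tuple[np.ndarray, bool]:
    s = np.asarray(signals, dtype=float).reshape(-1)
    if s.shape[0] != scheme.n_volumes:
        raise FitError(
            f"signal length {s.shape[0]} does not match scheme "
            f"({scheme.n_volumes} volumes)"
        )
    if not np.all(np.isfinite(s)):
        raise FitError("signals must be finite")
    b0 = s[scheme.b0_mask].mean()
    floor = SIGNAL_FLOOR_FRACTION * max(b0, np.finfo(float).tiny)
    clipped = bool(np.any(s < floor))
    return np.maximum(s, floor), clipped


def fit_voxel(
    signals: np.ndarray, scheme: GradientScheme, estimator: str = "WLS"
) -> FitResult:
    """Estimate (S0, D, W) for one voxel from the log-linearized model."""
    estimator = estimator.upper()
    if estimator not in ("OLS", "WLS"):
        raise FitError(f"unknown estimator {estimator!r}")
    scheme.validate_for_kurtosis()
    if scheme.n_volumes < N_PARAMS:
        raise FitError(f"need >= {N_PARAMS} volumes, got {scheme.n_volumes}")
    s, clipped = _prepare_signals(signals, scheme)
    x = design_matrix(scheme)
    logs = np.log(s)
    flags: set = {FLAG_CLIPPED_SIGNAL} if clipped else set()

    beta, _, rank, _ = np.linalg.lstsq(x, logs, rcond=None)
    if rank < N_PARAMS:
        flags.add(FLAG_RANK_DEFICIENT)
    if estimator == "WLS":
        weights = np.exp(x @ beta) ** 2
        sw = np.sqrt(weights)
        beta, _, rank, _ = np.linalg.lstsq(x * sw[:, None], logs * sw, rcond=None)
        if rank < N_PARAMS:
            flags.add(FLAG_RANK_DEFICIENT)
    residual = float(np.linalg.norm(logs - x @ beta))
    result = _beta_to_result(beta, residual, estimator, flags)
    _flag_kurtosis_range(result, scheme)
    return result


def _flag_kurtosis_range(result: FitResult, scheme: GradientScheme) -> FitResult:
    # directional kurtosis checked on the acquisition directions
    dirs = scheme.bvecs[~scheme.b0_mask]
    dn = result.D.along(dirs)
    valid = dn > 0
    if not np.any(valid):
        return result
    md = result.D.mean_diffusivity
    kapp = (md**2 / dn[valid] ** 2) * np.atleast_1d(result.W.along(dirs))[valid]
    lo, hi = KURTOSIS_RANGE
    if np.any(kapp < lo - 1e-12) or np.any(kapp > hi + 1e-12):
        object.__setattr__(result, "flags", result.flags | {FLAG_IMPLAUSIBLE_KURTOSIS})
    return result


def nls_oracle_fit(
    signals: np.ndarray, scheme: GradientScheme, init: FitResult
) -> FitResult:
    """Nonlinear least squares on the signal (not log-signal) model.

    Used in tests as the independent oracle bounding the linearized
    estimators; starts from a linearized fit and can only decrease the
    signal-space residual.
    """
    s, clipped = _prepare_signals(signals, scheme)
    x = design_matrix(scheme)
    md0 = init.D.mean_diffusivity
    beta0 = np.concatenate(
        [[np.log(init.s0)], init.D.components, md0**2 * init.W.components]
    )

    def residuals(beta: np.ndarray) -> np.ndarray:
        return np.exp(np.clip(x @ beta, -_MAX_EXPONENT, _MAX_EXPONENT)) - s

    sol = least_squares(residuals, beta0, method="trf", max_nfev=2000)
    flags: set = {FLAG_CLIPPED_SIGNAL} if clipped else set()
    if not sol.success:
        flags.add(FLAG_NON_CONVERGED)
    resid = float(np.linalg.norm(residuals(sol.x)))
    result = _beta_to_result(sol.x, resid, "NLS", flags)
    return result


@dataclass
class FitMaps:
    """Voxelwise fit output on the image grid.

    Background (unmasked) voxels hold NaN sentinels in every field.
    """

    d_components: np.ndarray  # (x, y, z, 6)
    w_components: np.ndarray  # (x, y, z, 15)
    s0: np.ndarray  # (x, y, z)
    residual_norm: np.ndarray  # (x, y, z)
    mask: np.ndarray  # bool (x, y, z)
    flags: dict  # flag name -> bool (x, y, z)
    estimator_tag: str

    def flag_counts(self) -> dict:
        return {name: int(arr.sum()) for name, arr in self.flags.items()}


def fit_volume(dwi, mask=None, estimator: str = "WLS") -> FitMaps:
    """Fit every in-mask voxel of a 4D volume (vectorized log-linear solve).

    ``mask`` may be a LabelMap (voxels with code > 0 are fitted), a boolean
    array, or None (all voxels fitted).
    """
    estimator = estimator.upper()
    if estimator not in ("OLS", "WLS"):
        raise FitError(f"unknown estimator {estimator!r}")
    scheme = dwi.scheme
    scheme.validate_for_kurtosis()
    data = np.asarray(dwi.data, dtype=float)
    shape = data.shape[:3]
    if mask is None:
        mask_arr = np.ones(shape, dtype=bool)
    else:
        labels = getattr(mask, "labels", mask)
        labels = np.asarray(labels)
        if labels.shape != shape:
            raise FitError(
                f"mask shape {labels.shape} does not match volume grid {shape}"
            )
        mask_arr = labels > 0

    sig = data[mask_arr]  # (v, n)
    n_vox = sig.shape[0]
    x = design_matrix(scheme)

    b0 = sig[:, scheme.b0_mask].mean(axis=1)
    floor = SIGNAL_FLOOR_FRACTION * np.maximum(b0, np.finfo(float).tiny)
    clipped_v = (sig < floor[:, None]).any(axis=1)
    logs = np.log(np.maximum(sig, floor[:, None]))

    beta = np.linalg.lstsq(x, logs.T, rcond=None)[0].T  # (v, 22)
    if estimator == "WLS":
        w = np.exp(np.clip(beta @ x.T, -_MAX_EXPONENT, _MAX_EXPONENT)) ** 2
        ata = np.einsum("vn,nj,nk->vjk", w, x, x)
        atb = np.einsum("vn,nj->vj", w * logs, x)
        try:
            beta = np.linalg.solve(ata, atb[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.stack(
                [np.linalg.lstsq(ata[i], atb[i], rcond=None)[0] for i in range(n_vox)]
            )
    resid_v = np.linalg.norm(logs - beta @ x.T, axis=1)

    d_v = beta[:, 1:7]
    md_v = d_v[:, :3].sum(axis=1) / 3.0
    rank_def_v = (md_v <= _MD_FLOOR) | ~np.isfinite(beta).all(axis=1)
    w_v = np.zeros((n_vox, 15))
    ok = ~rank_def_v
    w_v[ok] = beta[ok, 7:] / md_v[ok, None] ** 2

    from .tensors import _D_FULL_INDEX  # fixed component layout

    d_mats = d_v[:, _D_FULL_INDEX]
    eigmin = np.full(n_vox, np.nan)
    eigmin[ok] = np.linalg.eigvalsh(d_mats[ok])[:, 0]
    neg_v = ok & (eigmin < 0)

    def scatter(values, fill=np.nan):
        out = np.full(shape + values.shape[1:], fill, dtype=float)
        out[mask_arr] = values
        return out

    def scatter_bool(values):
        out = np.zeros(shape, dtype=bool)
        out[mask_arr] = values
        return out

    return FitMaps(
        d_components=scatter(d_v),
        w_components=scatter(w_v),
        s0=scatter(np.exp(beta[:, 0])),
        residual_norm=scatter(resid_v),
        mask=mask_arr,
        flags={
            FLAG_CLIPPED_SIGNAL: scatter_bool(clipped_v),
            FLAG_RANK_DEFICIENT: scatter_bool(rank_def_v),
            FLAG_NEGATIVE_EIGENVALUE: scatter_bool(neg_v),
        },
        estimator_tag=estimator,
    )
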
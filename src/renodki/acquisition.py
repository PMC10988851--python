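"""Multi-shell diffusion acquisition schemes and direction sets.

A diffusion acquisition is described by one b-value (s/mm²) and one unit
encoding direction per acquired volume.  Kurtosis estimation needs at least
two distinct nonzero shells (to separate the quadratic b² kurtosis term from
the linear diffusion term) plus an unweighted b = 0 anchor for S0.

Direction sets are produced by seeded electrostatic repulsion on the
half-sphere: antipodal directions are equivalent for diffusion encoding, so
point pairs interact through both ``p_i - p_j`` and ``p_i + p_j`` Coulomb
terms.  The same generator supplies the dense direction sets used for the
mean-kurtosis sphere quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDirectionsError, SchemeError, UnderdeterminedSchemeError

__all__ = [
    "GradientScheme",
    "build_scheme",
    "disperse_directions",
    "minimum_angle",
]

_UNIT_TOL = 1e-6

# 15 kurtosis + 6 diffusion + 1 intercept = 22 unknowns; with one b0 volume
# and two shells sharing directions, 15 directions is the minimum that can
# span the 15-dimensional quartic space.
MIN_DIRECTIONS = 15


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values (s/mm²) and unit encoding directions.

    ``bvecs`` rows for b = 0 volumes may be the zero vector; every nonzero-b
    row must be unit length within 1e-6.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).reshape(-1)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise SchemeError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise SchemeError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) "
                "describe different numbers of volumes"
            )
        if np.any(bvals < 0):
            raise SchemeError("b-values must be nonnegative")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > _UNIT_TOL):
            raise SchemeError("nonzero-b directions must be unit vectors (±1e-6)")
        bvals.setflags(write=False)
        bvecs.setflags(write=False)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def shells(self) -> np.ndarray:
        """Distinct nonzero b-values, ascending."""
        return np.unique(self.bvals[self.bvals > 0])

    def validate_for_kurtosis(self) -> None:
        """Raise unless the scheme can determine all 22 model parameters."""
        if not np.any(self.b0_mask):
            raise SchemeError("kurtosis fitting needs at least one b = 0 volume")
        if self.shells.size < 2:
            raise UnderdeterminedSchemeError(
                "kurtosis fitting needs at least two distinct nonzero shells"
            )


def disperse_directions(
    n: int, seed: int, n_iter: int = 400, step: float = 0.03
) -> np.ndarray:
    """Spread ``n`` unit vectors over the half-sphere by electrostatic repulsion.

    Deterministic for a fixed seed.  Returns an (n, 3) array with every
    vector canonicalized to the z >= 0 hemisphere.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    p = rng.normal(size=(n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    if n == 1:
        return _canonical_hemisphere(p)
    eye = np.arange(n)
    for it in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]
        summ = p[:, None, :] + p[None, :, :]
        d3 = np.linalg.norm(diff, axis=2) ** 3
        s3 = np.linalg.norm(summ, axis=2) ** 3
        d3[eye, eye] = np.inf
        s3[eye, eye] = np.inf
        force = (diff / d3[:, :, None]).sum(axis=1) + (summ / s3[:, :, None]).sum(axis=1)
        # tangential component only; radial motion is removed by renormalization
        force -= (force * p).sum(axis=1, keepdims=True) * p
        fmax = np.linalg.norm(force, axis=1).max()
        if fmax <= 0:
            break
        p = p + (step / (1.0 + 3.0 * it / n_iter)) * force / fmax
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return _canonical_hemisphere(p)


def _canonical_hemisphere(p: np.ndarray) -> np.ndarray:
    """Flip antipodal representatives into z > 0 (ties: y > 0, then x > 0)."""
    p = p.copy()
    flip = (p[:, 2] < 0) | ((p[:, 2] == 0) & (p[:, 1] < 0))
    flip |= (p[:, 2] == 0) & (p[:, 1] == 0) & (p[:, 0] < 0)
    p[flip] *= -1.0
    return p


def minimum_angle(directions: np.ndarray) -> float:
    """Smallest pairwise angular separation (radians), antipodally symmetric."""
    d = np.asarray(directions, dtype=float)
    cos = np.abs(np.clip(d @ d.T, -1.0, 1.0))
    np.fill_diagonal(cos, 0.0)
    return float(np.arccos(cos.max()))


def build_scheme(n_directions: int, shells: list[float], seed: int) -> GradientScheme:
    """Construct a multi-shell scheme: one b0 volume, then each nonzero
    shell traversed with the same seeded repulsion direction set.
    """
    shells_arr = np.asarray(list(shells), dtype=float)
    if np.any(shells_arr < 0):
        raise SchemeError("b-values must be nonnegative")
    nonzero = np.unique(shells_arr[shells_arr > 0])
    if 0 not in shells_arr:
        raise SchemeError("shells must contain b = 0")
    if nonzero.size < 2:
        raise UnderdeterminedSchemeError(
            "at least two distinct nonzero shells are required to separate "
            "diffusion from kurtosis"
        )
    if n_directions < MIN_DIRECTIONS:
        raise InsufficientDirectionsError(
            f"need >= {MIN_DIRECTIONS} directions to determine the 15 kurtosis "
            f"components, got {n_directions}"
        )
    dirs = disperse_directions(n_directions, seed)
    bvals = [0.0]
    bvecs = [np.zeros(3)]
    for b in nonzero:
        bvals.extend([b] * n_directions)
        bvecs.extend(dirs)
    return GradientScheme(np.asarray(bvals), np.asarray(bvecs))
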
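"""Diffusion (rank-2) and kurtosis (rank-4) tensor containers.

Component ordering conventions — fixed here and used everywhere else:

* Diffusion tensor ``D``: 6 unique components in the order
  ``(xx, yy, zz, xy, xz, yz)``, units mm²/s.
* Kurtosis tensor ``W``: 15 unique components in lexicographic index order
  ``(xxxx, xxxy, xxxz, xxyy, xxyz, xxzz, xyyy, xyyz, xyzz, xzzz,
  yyyy, yyyz, yyzz, yzzz, zzzz)``, dimensionless.  ``W`` follows the
  convention in which it enters the signal model scaled by the squared mean
  diffusivity, so its directional projection ``W(n)`` is the raw (unscaled)
  quartic form.

Contractions with a direction carry the permutation multiplicity of each
unique component (1/2 for D diagonal/off-diagonal; multinomial 4!/(cx!cy!cz!)
for W).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = [
    "DiffusionTensor",
    "KurtosisTensor",
    "D_COMPONENT_ORDER",
    "W_COMPONENT_ORDER",
    "d_monomials",
    "w_monomials",
    "isotropic_kurtosis",
    "rotate_diffusion",
    "rotate_kurtosis",
    "random_rotation",
]

D_COMPONENT_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")
_D_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
D_MULTIPLICITY = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

# exponent triples (cx, cy, cz) of the 15 unique quartic index multisets,
# lexicographic in the index string
W_COUNTS = (
    (4, 0, 0), (3, 1, 0), (3, 0, 1), (2, 2, 0), (2, 1, 1), (2, 0, 2),
    (1, 3, 0), (1, 2, 1), (1, 1, 2), (1, 0, 3),
    (0, 4, 0), (0, 3, 1), (0, 2, 2), (0, 1, 3), (0, 0, 4),
)
W_COMPONENT_ORDER = tuple(
    "".join("xyz"[a] * c for a, c in enumerate(counts)) for counts in W_COUNTS
)
W_MULTIPLICITY = np.array(
    [factorial(4) / (factorial(cx) * factorial(cy) * factorial(cz)) for cx, cy, cz in W_COUNTS]
)

_COUNTS_TO_POS = {c: i for i, c in enumerate(W_COUNTS)}


def _counts_of(idx: tuple[int, ...]) -> tuple[int, int, int]:
    return (idx.count(0), idx.count(1), idx.count(2))


# map every full (i,j,k,l) index onto its unique-component slot
_FULL_TO_UNIQUE = np.array(
    [_COUNTS_TO_POS[_counts_of(idx)] for idx in itertools.product(range(3), repeat=4)],
    dtype=np.intp,
).reshape(3, 3, 3, 3)

# one representative full index per unique component
_UNIQUE_REPRESENTATIVE = []
for counts in W_COUNTS:
    rep = (0,) * counts[0] + (1,) * counts[1] + (2,) * counts[2]
    _UNIQUE_REPRESENTATIVE.append(rep)
_UNIQUE_REPRESENTATIVE = np.array(_UNIQUE_REPRESENTATIVE, dtype=np.intp)

_D_FULL_INDEX = np.array([[0, 3, 4], [3, 1, 5], [4, 5, 2]], dtype=np.intp)


def d_monomials(directions: np.ndarray) -> np.ndarray:
    """Quadratic direction monomials (n, 6) in D component order (no multiplicity)."""
    n = np.atleast_2d(np.asarray(directions, dtype=float))
    x, y, z = n[:, 0], n[:, 1], n[:, 2]
    return np.stack([x * x, y * y, z * z, x * y, x * z, y * z], axis=1)


def w_monomials(directions: np.ndarray) -> np.ndarray:
    """Quartic direction monomials (n, 15) in W component order (no multiplicity)."""
    n = np.atleast_2d(np.asarray(directions, dtype=float))
    cols = [
        n[:, 0] ** cx * n[:, 1] ** cy * n[:, 2] ** cz for cx, cy, cz in W_COUNTS
    ]
    return np.stack(cols, axis=1)


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric rank-2 diffusion tensor, 6 unique components (mm²/s)."""

    components: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float).reshape(6)
        c.setflags(write=False)
        object.__setattr__(self, "components", c)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "DiffusionTensor":
        m = np.asarray(m, dtype=float)
        return cls(np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]]))

    def as_matrix(self) -> np.ndarray:
        return self.components[_D_FULL_INDEX]

    def along(self, directions: np.ndarray) -> np.ndarray:
        """Apparent diffusivity D(n) = Σ n_i n_j D_ij for unit direction(s)."""
        vals = d_monomials(directions) @ (D_MULTIPLICITY * self.components)
        return vals if vals.size > 1 else float(vals[0])

    @property
    def mean_diffusivity(self) -> float:
        return float(self.components[:3].sum() / 3.0)


@dataclass(frozen=True)
class KurtosisTensor:
    """Fully symmetric rank-4 kurtosis tensor, 15 unique components."""

    components: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float).reshape(15)
        c.setflags(write=False)
        object.__setattr__(self, "components", c)

    @classmethod
    def from_full(cls, full: np.ndarray) -> "KurtosisTensor":
        full = np.asarray(full, dtype=float)
        idx = _UNIQUE_REPRESENTATIVE
        return cls(full[idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]])

    def as_full(self) -> np.ndarray:
        """Expand to the full symmetric (3, 3, 3, 3) array."""
        return self.components[_FULL_TO_UNIQUE]

    def along(self, directions: np.ndarray) -> np.ndarray:
        """Quartic form W(n) = Σ n_i n_j n_k n_l W_ijkl for unit direction(s)."""
        vals = w_monomials(directions) @ (W_MULTIPLICITY * self.components)
        return vals if vals.size > 1 else float(vals[0])


def isotropic_kurtosis(w0: float = 1.0) -> KurtosisTensor:
    """Isotropic fully symmetric rank-4 tensor normalized so W(n) = w0 for all n.

    Components: quartic diagonals = w0, paired squares (xxyy, xxzz, yyzz)
    = w0/3, all others zero.
    """
    c = np.zeros(15)
    c[W_COMPONENT_ORDER.index("xxxx")] = w0
    c[W_COMPONENT_ORDER.index("yyyy")] = w0
    c[W_COMPONENT_ORDER.index("zzzz")] = w0
    c[W_COMPONENT_ORDER.index("xxyy")] = w0 / 3.0
    c[W_COMPONENT_ORDER.index("xxzz")] = w0 / 3.0
    c[W_COMPONENT_ORDER.index("yyzz")] = w0 / 3.0
    return KurtosisTensor(c)


def rotate_diffusion(d: DiffusionTensor, rotation: np.ndarray) -> DiffusionTensor:
    r = np.asarray(rotation, dtype=float)
    return DiffusionTensor.from_matrix(r @ d.as_matrix() @ r.T)


def rotate_kurtosis(w: KurtosisTensor, rotation: np.ndarray) -> KurtosisTensor:
    r = np.asarray(rotation, dtype=float)
    full = np.einsum("ai,bj,ck,dl,ijkl->abcd", r, r, r, r, w.as_full())
    return KurtosisTensor.from_full(full)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR with sign fixing."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q
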
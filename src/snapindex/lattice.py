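"""Unit-cell algebra: reciprocal basis, reflection lists, lattice symmetry.

The crystal-frame convention is the standard Busing–Levy setting with a*
along +x and b* in the xy-plane, so that the reciprocal basis matrix B
(columns a*, b*, c*, in Å⁻¹) is upper triangular.  An orientation matrix
R then maps crystal-frame reciprocal vectors B·h into the laboratory
frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

CENTERINGS = ("P", "A", "B", "C", "I", "F")


class CellError(ValueError):
    """Invalid or degenerate unit cell."""


class ReflectionCapError(RuntimeError):
    """Reflection list would exceed the configured cap.

    The pair table cost grows quadratically with the number of
    reflections, so an oversized list is converted into an explicit
    configuration decision (raise d_min or the cap) instead of a silent
    memory blow-up.
    """


@dataclass(frozen=True)
class UnitCell:
    """Direct-space lattice parameters (Å, degrees) plus centering."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    centering: str = "P"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise CellError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise CellError(f"cell angle {name} must be in (0, 180) deg, got {v}")
        if self.centering not in CENTERINGS:
            raise CellError(f"unknown centering {self.centering!r}; expected one of {CENTERINGS}")
        ca, cb, cg = (np.cos(np.radians(getattr(self, n))) for n in ("alpha", "beta", "gamma"))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if not arg > 0:
            raise CellError("degenerate metric: cell volume is not real and positive")

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        ca, cb, cg = (np.cos(np.radians(getattr(self, n))) for n in ("alpha", "beta", "gamma"))
        return self.a * self.b * self.c * np.sqrt(
            1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        )

    def with_lengths(self, a: float, b: float, c: float) -> "UnitCell":
        return UnitCell(a, b, c, self.alpha, self.beta, self.gamma, self.centering)


def reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Reciprocal basis matrix B (Å⁻¹), columns a*, b*, c* (Busing–Levy).

    Satisfies the duality B^T·A = I with A the direct basis from
    :func:`direct_matrix`, and det B = 1/V.  For orthorhombic cells B is
    diag(1/a, 1/b, 1/c).
    """
    al, be, ga = (np.radians(getattr(cell, n)) for n in ("alpha", "beta", "gamma"))
    ca, cb, cg = np.cos([al, be, ga])
    sa = np.sin(al)
    V = cell.volume
    # reciprocal parameters
    ar = cell.b * cell.c * sa / V
    br = cell.a * cell.c * np.sin(be) / V
    cr = cell.a * cell.b * np.sin(ga) / V
    cos_ar = (cb * cg - ca) / (np.sin(be) * np.sin(ga))
    cos_br = (ca * cg - cb) / (sa * np.sin(ga))
    sin_br = np.sqrt(max(1.0 - cos_br * cos_br, 0.0))
    cos_gr = (ca * cb - cg) / (sa * np.sin(be))
    sin_gr = np.sqrt(max(1.0 - cos_gr * cos_gr, 0.0))
    B = np.array(
        [
            [ar, br * cos_gr, cr * cos_br],
            [0.0, br * sin_gr, -cr * sin_br * ca],
            [0.0, 0.0, 1.0 / cell.c],
        ]
    )
    return B


def direct_matrix(cell: UnitCell) -> np.ndarray:
    """Direct basis matrix A (Å), columns a, b, c, dual to B."""
    return np.linalg.inv(reciprocal_basis(cell)).T


def centering_mask(hkl: np.ndarray, centering: str) -> np.ndarray:
    """Boolean mask of reflections allowed by the centering extinction rule."""
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    if centering == "P":
        return np.ones(len(hkl), dtype=bool)
    if centering == "A":
        return (k + l) % 2 == 0
    if centering == "B":
        return (h + l) % 2 == 0
    if centering == "C":
        return (h + k) % 2 == 0
    if centering == "I":
        return (h + k + l) % 2 == 0
    if centering == "F":
        return (h % 2 == k % 2) & (k % 2 == l % 2)
    raise CellError(f"unknown centering {centering!r}")


def generate_reflections(
    cell: UnitCell, d_min: float, cap: int = 200_000
) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate non-zero reflections with d >= d_min.

    Returns ``(hkl, q_length)``: an (N, 3) integer array (Friedel mates
    listed separately) and the (N,) array of |B·h| in Å⁻¹.  Reflections
    extinct under the cell's centering are excluded.

    Raises :class:`ReflectionCapError` when more than ``cap`` reflections
    would be produced.
    """
    if not d_min > 0:
        raise CellError(f"d_min must be > 0, got {d_min}")
    B = reciprocal_basis(cell)
    q_max = 1.0 / d_min
    # h = a·q, so |h| <= |a| * q_max exactly bounds the search box.
    A = direct_matrix(cell)
    lim = np.floor(np.linalg.norm(A, axis=0) * q_max).astype(int)
    # guard the enumeration box itself before allocating it
    box = np.prod(2 * lim.astype(np.int64) + 1)
    if box > 50 * max(cap, 1):
        raise ReflectionCapError(
            f"enumeration box of {box} candidate indices for d_min={d_min} Å; "
            f"raise d_min or the cap (cap={cap})"
        )
    axes = [np.arange(-m, m + 1) for m in lim]
    hkl = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    q = hkl @ B.T
    q_len = np.linalg.norm(q, axis=1)
    keep = (q_len > 0) & (q_len <= q_max) & centering_mask(hkl, cell.centering)
    hkl, q_len = hkl[keep], q_len[keep]
    if len(hkl) > cap:
        raise ReflectionCapError(
            f"{len(hkl)} reflections to d_min={d_min} Å exceeds cap={cap}; "
            "raise d_min or the cap (pair-table cost grows as N^2)"
        )
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0], q_len))
    return hkl[order], q_len[order]


def shortest_reciprocal_vector(cell: UnitCell) -> float:
    """Length (Å⁻¹) of the shortest non-zero reciprocal-lattice vector.

    Used for the "half-nearest" peak-match threshold: half this length
    is the largest radius for which nearest-node assignment is
    unambiguous.  Searched over a small index box, which is sufficient
    for any non-pathological cell.
    """
    B = reciprocal_basis(cell)
    hkl = np.array([h for h in product(range(-2, 3), repeat=3) if h != (0, 0, 0)])
    hkl = hkl[centering_mask(hkl, cell.centering)]
    return float(np.min(np.linalg.norm(hkl @ B.T, axis=1)))


def lattice_rotations(cell: UnitCell, tol: float = 1e-6) -> list[tuple[np.ndarray, np.ndarray]]:
    """Proper rotational symmetries of the lattice (its point group ∩ SO(3)).

    Returns a list of ``(M, R)`` with M an integer re-indexing matrix
    (h → M·h), det M = +1, such that ``R = B·M·B⁻¹`` is a rotation.
    These are the exact indexing ambiguities of a reference-based
    indexer: two orientations related by such an R predict identical
    peak positions.  The identity is always included; an orthorhombic
    lattice has 4 ops (identity plus the three 2-folds).
    """
    B = reciprocal_basis(cell)
    Binv = np.linalg.inv(B)
    ops = []
    for entries in product((-1, 0, 1), repeat=9):
        M = np.array(entries).reshape(3, 3)
        if round(np.linalg.det(M)) != 1:
            continue
        R = B @ M @ Binv
        if np.allclose(R.T @ R, np.eye(3), atol=tol):
            ops.append((M, R))
    return ops
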
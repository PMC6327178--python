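"""Rotation-invariant reference table of reciprocal-vector pairs.

For a guiding cell, every unordered pair of distinct reflections within
the resolution limit is characterized by three rotation invariants: the
two vector lengths (sorted, len_1 <= len_2), their ratio and the
inter-vector angle.  Observed peak pairs are matched against this table
to produce candidate Miller assignments; the table is built once per
guiding cell and queried by bisection on the angle axis.

Equivalent to matching against "a large set of discretized crystal
orientations", but exact: pair invariants do not depend on orientation,
and the orientation is recovered afterwards from each matched
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lattice import UnitCell, generate_reflections, reciprocal_basis


@dataclass(frozen=True)
class PairEntry:
    """One reference pair: Miller indices plus the three invariants."""

    hkl_1: tuple[int, int, int]
    hkl_2: tuple[int, int, int]
    len_1: float  # Å⁻¹, len_1 <= len_2
    len_2: float
    ratio: float  # len_1/len_2 in (0, 1]
    angle: float  # degrees in (0, 180)


@dataclass
class ReferenceTable:
    """Columnar pair table, sorted by angle (ascending) for bisection.

    Attributes are parallel arrays of length ``n_entries``; ``hkl_1``
    holds the shorter vector of each pair.
    """

    cell: UnitCell
    d_min: float
    angle_min: float
    hkl_1: np.ndarray  # (M, 3) int16
    hkl_2: np.ndarray
    len_1: np.ndarray  # (M,) float64
    len_2: np.ndarray
    ratio: np.ndarray
    angle: np.ndarray  # degrees, sorted ascending

    @property
    def n_entries(self) -> int:
        return len(self.angle)

    def entry(self, i: int) -> PairEntry:
        return PairEntry(
            tuple(int(x) for x in self.hkl_1[i]),
            tuple(int(x) for x in self.hkl_2[i]),
            float(self.len_1[i]),
            float(self.len_2[i]),
            float(self.ratio[i]),
            float(self.angle[i]),
        )

    def save(self, path) -> None:
        """Serialize to a single .npz file with a cell/limits header."""
        c = self.cell
        np.savez_compressed(
            path,
            header=np.array(
                [c.a, c.b, c.c, c.alpha, c.beta, c.gamma, self.d_min, self.angle_min]
            ),
            centering=np.array([c.centering]),
            hkl_1=self.hkl_1,
            hkl_2=self.hkl_2,
            len_1=self.len_1,
            len_2=self.len_2,
            ratio=self.ratio,
            angle=self.angle,
        )

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        with np.load(Path(path), allow_pickle=False) as f:
            h = f["header"]
            cell = UnitCell(*h[:6], centering=str(f["centering"][0]))
            return cls(
                cell=cell,
                d_min=float(h[6]),
                angle_min=float(h[7]),
                hkl_1=f["hkl_1"],
                hkl_2=f["hkl_2"],
                len_1=f["len_1"],
                len_2=f["len_2"],
                ratio=f["ratio"],
                angle=f["angle"],
            )


def build_reference_table(
    cell: UnitCell,
    d_min: float,
    angle_min: float = 10.0,
    cap: int = 200_000,
) -> ReferenceTable:
    """Build the pair table for a guiding cell down to d_min (Å).

    Friedel mates count as distinct reflections, so each unordered pair
    of lattice vectors appears once; pairs closer than ``angle_min``
    degrees to collinearity (angle < angle_min or > 180 - angle_min) are
    excluded because they cannot constrain an orientation.
    """
    hkl, q_len = generate_reflections(cell, d_min, cap=cap)
    B = reciprocal_basis(cell)
    v = hkl @ B.T  # (N, 3) crystal-frame reciprocal vectors
    n = len(hkl)
    # cos(angle) from the reciprocal metric, all pairs at once
    dots = v @ v.T
    cosang = dots / np.outer(q_len, q_len)
    iu, ju = np.triu_indices(n, k=1)
    cosang = np.clip(cosang[iu, ju], -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    keep = (angle >= angle_min) & (angle <= 180.0 - angle_min)
    iu, ju, angle = iu[keep], ju[keep], angle[keep]
    li, lj = q_len[iu], q_len[ju]
    # order each pair so that hkl_1 is the shorter vector
    swap = li > lj
    i1 = np.where(swap, ju, iu)
    i2 = np.where(swap, iu, ju)
    len_1, len_2 = q_len[i1], q_len[i2]
    order = np.argsort(angle, kind="stable")
    return ReferenceTable(
        cell=cell,
        d_min=float(d_min),
        angle_min=float(angle_min),
        hkl_1=hkl[i1][order].astype(np.int16),
        hkl_2=hkl[i2][order].astype(np.int16),
        len_1=len_1[order],
        len_2=len_2[order],
        ratio=(len_1 / len_2)[order],
        angle=angle[order],
    )


def query_matches(
    table: ReferenceTable,
    obs_len_1: float,
    obs_len_2: float,
    obs_angle: float,
    tol_len: float = 3e-3,
    tol_angle: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Find table entries compatible with an observed pair.

    Matches require the angle within ``tol_angle`` degrees and both
    lengths within ``tol_len`` (Å⁻¹, absolute) under either assignment
    of the two observed vectors to (hkl_1, hkl_2); both orderings are
    returned when both fit (relevant for near-equal lengths).

    Returns ``(hkl_for_obs1, hkl_for_obs2, entry_idx)`` where the first
    two are (m, 3) integer arrays giving the Miller assignment of the
    observed vectors *in the argument order given*, and ``entry_idx``
    indexes the underlying table rows.  An empty result is valid.
    """
    if not (obs_len_1 > 0 and obs_len_2 > 0):
        raise ValueError("observed pair lengths must be > 0")
    if not (tol_len > 0 and tol_angle > 0):
        raise ValueError("tolerances must be > 0")
    lo = np.searchsorted(table.angle, obs_angle - tol_angle, side="left")
    hi = np.searchsorted(table.angle, obs_angle + tol_angle, side="right")
    if hi <= lo:
        empty = np.empty((0, 3), dtype=np.int16)
        return empty, empty, np.empty(0, dtype=np.intp)
    l1 = table.len_1[lo:hi]
    l2 = table.len_2[lo:hi]
    # assignment A: obs_1 -> hkl_1, obs_2 -> hkl_2
    mask_a = (np.abs(l1 - obs_len_1) <= tol_len) & (np.abs(l2 - obs_len_2) <= tol_len)
    # assignment B: obs_1 -> hkl_2, obs_2 -> hkl_1
    mask_b = (np.abs(l2 - obs_len_1) <= tol_len) & (np.abs(l1 - obs_len_2) <= tol_len)
    idx_a = lo + np.nonzero(mask_a)[0]
    idx_b = lo + np.nonzero(mask_b)[0]
    hkl_for_obs1 = np.concatenate([table.hkl_1[idx_a], table.hkl_2[idx_b]])
    hkl_for_obs2 = np.concatenate([table.hkl_2[idx_a], table.hkl_1[idx_b]])
    entry_idx = np.concatenate([idx_a, idx_b])
    return hkl_for_obs1, hkl_for_obs2, entry_idx
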
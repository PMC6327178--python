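"""Sparse-pattern auto-indexing core.

Pipeline per pattern: select the best few peaks, form all peak pairs,
match each pair's rotation invariants against the reference table, fit a
candidate orientation for every matched Miller assignment (closed-form
two-vector triad fit), intersect the per-pair solution pools by
misorientation clustering, then predict peaks from the surviving
orientations and accept or reject the pattern.

For a single-lattice pattern the true orientation must appear in every
pair's solution pool, which is the constraint that eliminates spurious
candidates.  Orientations related by a proper rotational symmetry of the
lattice predict identical patterns and are genuinely indistinguishable;
the indexer returns one representative, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import ReciprocalPeak
from .lattice import (
    centering_mask,
    lattice_rotations,
    reciprocal_basis,
    shortest_reciprocal_vector,
)
from .table import ReferenceTable, query_matches

# rejection reasons (typed, stable strings)
TOO_FEW_PEAKS = "too-few-peaks"
NO_TABLE_MATCH = "no-table-match"
NO_CONSENSUS = "no-consensus"
FAILED_MATCH_GATE = "failed-match-gate"


class DegeneratePairError(ValueError):
    """Collinear (or zero) vectors cannot constrain an orientation."""


@dataclass(frozen=True)
class IndexingParams:
    """Tunable parameters of the indexing pipeline.

    Defaults follow the tool's standard operating point: five indexing
    peaks (ten pairs), pair-search tolerances of 3e-3 Å⁻¹ (= 3e7 m⁻¹)
    on vector lengths and 3° on angles, and a peak-match threshold of
    half the shortest reciprocal-lattice vector ("half-nearest").
    """

    n_index_peaks: int = 5
    peak_selection: str = "snr"  # intensity | snr | resolution
    tol_len: float = 3e-3  # Å⁻¹
    tol_angle: float = 3.0  # deg
    pool_merge_tol: float = 1.0  # deg, single-linkage merge radius
    #: "auto": all non-empty pools in sparse mode, ceil(half) in general
    #: mode; "all": always all non-empty pools; or an integer count.
    min_pool_support: int | str = "auto"
    match_threshold: float | str = "half-nearest"  # Å⁻¹ or "half-nearest"
    sparse_cutoff: int = 6  # <= this many peaks -> sparse (all-matched) rule
    #: sparse mode: reject when a second fully-supported, fully-matching
    #: orientation exists that is not a lattice-symmetry copy of the best
    require_unique_consensus: bool = True
    #: the competing orientation only vetoes acceptance when its match
    #: quality is comparable: rms_dq within this factor of the best's
    ambiguity_rms_factor: float = 2.0
    #: (max_n_peaks, min_match_fraction) gate rows for general mode,
    #: evaluated in order; a higher fraction is demanded when few peaks.
    match_fraction_gates: tuple[tuple[float, float], ...] = ((6, 1.0), (15, 0.8), (np.inf, 0.6))
    d_min_table: float | None = None  # resolution limit used for the table

    def __post_init__(self) -> None:
        if self.n_index_peaks < 3:
            raise ValueError("n_index_peaks must be >= 3 (at least two pairs sharing a peak)")
        if self.peak_selection not in ("intensity", "snr", "resolution"):
            raise ValueError(f"unknown peak_selection {self.peak_selection!r}")

    def min_match_fraction(self, n_peaks: int) -> float:
        for max_n, frac in self.match_fraction_gates:
            if n_peaks <= max_n:
                return frac
        return self.match_fraction_gates[-1][1]


@dataclass
class SolutionPool:
    """Orientation candidates generated by one observed peak pair."""

    pair_id: tuple[int, int]
    orientations: np.ndarray  # (m, 3, 3)
    residuals: np.ndarray  # (m,) two-vector fit residuals, Å⁻¹
    entry_idx: np.ndarray  # (m,) reference-table rows that produced them
    n_degenerate: int = 0  # assignments dropped as degenerate fits

    def __len__(self) -> int:
        return len(self.residuals)


@dataclass
class IndexingSolution:
    """Result record for one pattern (accepted or rejected)."""

    accepted: bool
    reason: str | None = None  # rejection reason when not accepted
    orientation: np.ndarray | None = None  # R, lab <- crystal
    oriented_basis: np.ndarray | None = None  # R·B, Å⁻¹
    hkl: np.ndarray | None = None  # (n_peaks, 3) nearest-node indices
    matched: np.ndarray | None = None  # (n_peaks,) bool
    match_dist: np.ndarray | None = None  # (n_peaks,) |q - R·B·h| in Å⁻¹
    n_matched: int = 0
    match_fraction: float = 0.0
    rms_dq: float = np.inf
    pool_support: int = 0
    n_pools: int = 0
    fit_residual: float = np.inf
    match_threshold: float = np.nan
    params: IndexingParams | None = field(default=None, repr=False)


def misorientation(R1: np.ndarray, R2: np.ndarray) -> float:
    """Minimal rotation angle (deg) relating two orientations.

    arccos((trace(R1ᵀ·R2) − 1)/2), symmetric in its arguments.
    """
    t = np.trace(np.asarray(R1).T @ np.asarray(R2))
    return float(np.degrees(np.arccos(np.clip((t - 1.0) / 2.0, -1.0, 1.0))))


def _quats(R: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_matrix(R).as_quat()


def _cluster_rotations(Rs: np.ndarray, tol_deg: float) -> np.ndarray:
    """Single-linkage component labels under misorientation <= tol_deg.

    Rotations are embedded as unit quaternions; misorientation θ
    corresponds to chord distance 2·sin(θ/4), so neighbor pairs come
    from a KD-tree radius query.  Both quaternion signs are inserted to
    handle the q ↔ −q double cover (orientations near 180° rotations
    would otherwise split across the sign boundary).
    """
    from scipy.spatial import cKDTree

    q = _quats(Rs)
    m = len(q)
    pts = np.vstack([q, -q])
    tree = cKDTree(pts)
    radius = 2.0 * np.sin(np.radians(tol_deg) / 4.0)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        pairs = pairs % m
        adj = csr_matrix(
            (np.ones(len(pairs), dtype=bool), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
    else:
        adj = csr_matrix((m, m), dtype=bool)
    _, labels = connected_components(adj, directed=False)
    return labels


def select_peaks(
    peaks: Sequence[ReciprocalPeak], params: IndexingParams
) -> list[ReciprocalPeak]:
    """Pick the best ``n_index_peaks`` peaks by the configured criterion.

    Intensity and SNR rank descending, resolution ranks by ascending
    |q| (lowest-resolution-shell peaks first).  Ties break
    deterministically by intensity then detector position.  The 000
    reflection (q = 0) is never selectable.
    """
    usable = [p for p in peaks if p.q_length > 0]

    def tiebreak(p: ReciprocalPeak):
        src = p.source_peak
        inten = src.intensity if src is not None else 0.0
        pos = (src.fast, src.slow) if src is not None else (0.0, 0.0)
        return (-inten, pos[0], pos[1])

    if params.peak_selection == "intensity":
        key = lambda p: (-(p.source_peak.intensity if p.source_peak else 0.0),) + tiebreak(p)
    elif params.peak_selection == "snr":
        key = lambda p: (-(p.source_peak.snr if p.source_peak else 0.0),) + tiebreak(p)
    else:  # resolution: smallest q_length first
        key = lambda p: (p.q_length,) + tiebreak(p)
    return sorted(usable, key=key)[: params.n_index_peaks]


def enumerate_pairs(n_or_peaks) -> list[tuple[int, int]]:
    """All N(N−1)/2 unordered index pairs of the selected peaks."""
    n = n_or_peaks if isinstance(n_or_peaks, int) else len(n_or_peaks)
    return list(combinations(range(n), 2))


def pair_geometry(q1: np.ndarray, q2: np.ndarray) -> tuple[float, float, float, float]:
    """(len_1, len_2, ratio, angle°) for an observed pair, lengths sorted."""
    n1, n2 = float(np.linalg.norm(q1)), float(np.linalg.norm(q2))
    if n1 <= 0 or n2 <= 0:
        raise DegeneratePairError("zero-length reciprocal vector in pair")
    cosang = np.clip(np.dot(q1, q2) / (n1 * n2), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    lo, hi = sorted((n1, n2))
    return lo, hi, lo / hi, angle


def _triad(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal triad (columns) from two vectors."""
    t1 = v1 / np.linalg.norm(v1)
    c = np.cross(v1, v2)
    nc = np.linalg.norm(c)
    if nc <= 1e-12 * np.linalg.norm(v1) * np.linalg.norm(v2):
        raise DegeneratePairError("collinear vectors")
    t3 = c / nc
    t2 = np.cross(t3, t1)
    return np.column_stack([t1, t2, t3])


def orientation_from_assignment(
    q_obs_1: np.ndarray,
    q_obs_2: np.ndarray,
    hkl_1,
    hkl_2,
    B: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Closed-form two-vector orientation fit (Wahba via triads).

    Builds right-handed orthonormal triads from the observed pair and
    from the reference vectors r_i = B·h_i and returns
    ``R = T_obs · T_refᵀ`` together with the post-fit residual
    ``sqrt(Σ|q_i − R·r_i|²)`` in Å⁻¹.
    """
    r1 = B @ np.asarray(hkl_1, dtype=float)
    r2 = B @ np.asarray(hkl_2, dtype=float)
    T_obs = _triad(np.asarray(q_obs_1, float), np.asarray(q_obs_2, float))
    T_ref = _triad(r1, r2)
    R = T_obs @ T_ref.T
    resid = float(np.sqrt(np.sum((q_obs_1 - R @ r1) ** 2) + np.sum((q_obs_2 - R @ r2) ** 2)))
    return R, resid


def _fit_orientations_batch(
    q1: np.ndarray, q2: np.ndarray, r1s: np.ndarray, r2s: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized triad fit of one observed pair against m reference pairs.

    Returns (R (m,3,3), residual (m,), ok (m,)); degenerate reference
    pairs are flagged not-ok.
    """
    T_obs = _triad(q1, q2)
    n1 = np.linalg.norm(r1s, axis=1)
    n2 = np.linalg.norm(r2s, axis=1)
    c = np.cross(r1s, r2s)
    nc = np.linalg.norm(c, axis=1)
    ok = nc > 1e-12 * n1 * n2
    nc_safe = np.where(ok, nc, 1.0)
    t1 = r1s / np.where(n1 > 0, n1, 1.0)[:, None]
    t3 = c / nc_safe[:, None]
    t2 = np.cross(t3, t1)
    T_ref = np.stack([t1, t2, t3], axis=-1)  # (m, 3, 3), columns
    R = np.einsum("ab,mcb->mac", T_obs, T_ref)
    d1 = q1[None, :] - np.einsum("mab,mb->ma", R, r1s)
    d2 = q2[None, :] - np.einsum("mab,mb->ma", R, r2s)
    resid = np.sqrt(np.sum(d1 * d1, axis=1) + np.sum(d2 * d2, axis=1))
    return R, resid, ok


def build_solution_pools(
    q_vectors: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    table: ReferenceTable,
    params: IndexingParams,
    B: np.ndarray | None = None,
) -> list[SolutionPool]:
    """One solution pool per observed peak pair.

    Each pool holds a candidate orientation for every reference-table
    assignment compatible with the pair's invariants; degenerate fits
    are dropped and counted.  Empty pools are allowed.

    Observed pairs inside the table's collinearity exclusion band
    (angle < angle_min or > 180° − angle_min) are skipped entirely
    rather than reported as empty: the table holds no entries there by
    construction, and a near-collinear pair cannot constrain an
    orientation, so it carries no evidence for or against a solution.
    """
    if B is None:
        B = reciprocal_basis(table.cell)
    pools = []
    for i, j in pairs:
        l1, l2, _, ang = pair_geometry(q_vectors[i], q_vectors[j])
        if ang < table.angle_min or ang > 180.0 - table.angle_min:
            continue
        h_i, h_j, entry_idx = query_matches(
            table,
            float(np.linalg.norm(q_vectors[i])),
            float(np.linalg.norm(q_vectors[j])),
            ang,
            tol_len=params.tol_len,
            tol_angle=params.tol_angle,
        )
        if len(entry_idx) == 0:
            pools.append(
                SolutionPool(
                    pair_id=(i, j),
                    orientations=np.empty((0, 3, 3)),
                    residuals=np.empty(0),
                    entry_idx=np.empty(0, dtype=np.intp),
                )
            )
            continue
        r1s = h_i.astype(float) @ B.T
        r2s = h_j.astype(float) @ B.T
        R, resid, ok = _fit_orientations_batch(q_vectors[i], q_vectors[j], r1s, r2s)
        pools.append(
            SolutionPool(
                pair_id=(i, j),
                orientations=R[ok],
                residuals=resid[ok],
                entry_idx=entry_idx[ok],
                n_degenerate=int(np.sum(~ok)),
            )
        )
    return pools


@dataclass
class ConsensusCandidate:
    orientation: np.ndarray  # smallest-residual member
    fit_residual: float
    pool_support: int
    cluster_size: int
    member_orientations: np.ndarray = field(default=None, repr=False)  # (m, 3, 3)
    member_residuals: np.ndarray = field(default=None, repr=False)
    member_pool_ids: np.ndarray = field(default=None, repr=False)
    required_support: int = 0


def intersect_pools(
    pools: Sequence[SolutionPool],
    params: IndexingParams,
    sparse_mode: bool = True,
) -> list[ConsensusCandidate]:
    """Merge candidates across pools and keep well-supported clusters.

    Single-linkage clustering under misorientation <= pool_merge_tol;
    each cluster is represented by its smallest-residual member and its
    pool support is the number of distinct pools represented.  Clusters
    below the required support are discarded.

    In sparse mode with the default ("auto"/"all") support policy, a
    single-lattice pattern must explain *every* peak pair, so the
    required support is the total number of pools — an empty pool
    (a pair the guiding lattice cannot produce) vetoes the pattern.
    """
    n_nonempty = sum(1 for p in pools if len(p) > 0)
    if n_nonempty == 0:
        return []
    Rs = np.concatenate([p.orientations for p in pools if len(p) > 0])
    residuals = np.concatenate([p.residuals for p in pools if len(p) > 0])
    pool_ids = np.concatenate(
        [np.full(len(p), k) for k, p in enumerate(pools) if len(p) > 0]
    )
    if params.min_pool_support in ("auto", "all"):
        required = len(pools) if sparse_mode else int(np.ceil(n_nonempty / 2))
    else:
        required = int(params.min_pool_support)

    labels = _cluster_rotations(Rs, params.pool_merge_tol)
    out = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        support = len(np.unique(pool_ids[members]))
        if support < required:
            continue
        best = members[np.argmin(residuals[members])]
        out.append(
            ConsensusCandidate(
                orientation=Rs[best],
                fit_residual=float(residuals[best]),
                pool_support=support,
                cluster_size=len(members),
                member_orientations=Rs[members],
                member_residuals=residuals[members],
                member_pool_ids=pool_ids[members],
                required_support=required,
            )
        )
    # deterministic order: strongest support, then best residual
    out.sort(key=lambda c: (-c.pool_support, c.fit_residual))
    return out


@lru_cache(maxsize=8)
def _lattice_ops(cell) -> tuple:
    """Cached proper rotational symmetries of the guiding lattice."""
    return tuple(R for _, R in lattice_rotations(cell))


def _symmetry_equivalent(R1: np.ndarray, R2: np.ndarray, ops, tol: float) -> bool:
    """True when two orientations differ by a lattice rotation (± tol deg)."""
    return any(misorientation(R1 @ S, R2) <= tol for S in ops)


def resolve_match_threshold(params: IndexingParams, cell) -> float:
    """Numeric peak-match threshold in Å⁻¹ ("half-nearest" resolved)."""
    if params.match_threshold == "half-nearest":
        return 0.5 * shortest_reciprocal_vector(cell)
    return float(params.match_threshold)


def predict_and_match(
    orientation: np.ndarray,
    B: np.ndarray,
    q_vectors: np.ndarray,
    match_threshold: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Nearest-node prediction and matching in 3-D reciprocal space.

    For each observed q the nearest lattice node ``h* = round((R·B)⁻¹·q)``
    is computed; the peak is matched iff ``|q − R·B·h*|`` is within the
    threshold.  Returns (hkl (n,3), dist (n,), matched (n,), rms_dq).
    """
    RB = orientation @ B
    h = np.rint(q_vectors @ np.linalg.inv(RB).T).astype(int)
    dq = q_vectors - h @ RB.T
    dist = np.linalg.norm(dq, axis=1)
    matched = dist <= match_threshold
    # the 000 node is not a Bragg match
    matched &= np.any(h != 0, axis=1)
    rms = float(np.sqrt(np.mean(dist[matched] ** 2))) if np.any(matched) else np.inf
    return h, dist, matched, rms


def _match_stats_batch(
    Rs: np.ndarray, B: np.ndarray, q_vectors: np.ndarray, match_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """(n_matched, rms_dq) of nearest-node matching for many orientations."""
    Binv = np.linalg.inv(B)
    invRB = np.einsum("ab,mcb->mac", Binv, Rs)  # (RB)^-1 = B^-1 R^T
    h = np.rint(np.einsum("mab,nb->mna", invRB, q_vectors))
    RB = np.einsum("mab,bc->mac", Rs, B)
    dq = q_vectors[None, :, :] - np.einsum("mab,mnb->mna", RB, h)
    dist = np.linalg.norm(dq, axis=2)  # (m, n)
    matched = (dist <= match_threshold) & np.any(h != 0, axis=2)
    n_matched = matched.sum(axis=1)
    sq = np.where(matched, dist * dist, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        rms = np.where(n_matched > 0, np.sqrt(sq / np.maximum(n_matched, 1)), np.inf)
    return n_matched, rms


def index_pattern(
    peaks: Sequence[ReciprocalPeak],
    table: ReferenceTable,
    params: IndexingParams = IndexingParams(),
    B: np.ndarray | None = None,
) -> IndexingSolution:
    """Index one pattern against a guiding-cell reference table.

    Sparse rule (<= ``sparse_cutoff`` usable peaks): a consensus
    orientation must exist and its prediction must match *all* observed
    peaks, otherwise the pattern is rejected.  General rule: all
    consensus candidates are scored on all observed peaks by
    (centering consistency, n_matched, match_fraction, −rms_dq) and the
    best must pass the peak-count-dependent match-fraction gate.
    """
    if B is None:
        B = reciprocal_basis(table.cell)
    usable = [p for p in peaks if p.q_length > 0]
    if len(usable) < 3:
        return IndexingSolution(accepted=False, reason=TOO_FEW_PEAKS, params=params)
    q_all = np.array([p.q for p in usable])
    selected = select_peaks(usable, params)
    # positions of selected peaks within the usable list
    q_sel = np.array([p.q for p in selected])
    pairs = enumerate_pairs(len(selected))
    pools = build_solution_pools(q_sel, pairs, table, params, B=B)
    n_pools = len(pools)
    if all(len(p) == 0 for p in pools):
        return IndexingSolution(accepted=False, reason=NO_TABLE_MATCH, n_pools=n_pools, params=params)
    sparse_mode = len(usable) <= params.sparse_cutoff
    candidates = intersect_pools(pools, params, sparse_mode=sparse_mode)
    if not candidates:
        return IndexingSolution(accepted=False, reason=NO_CONSENSUS, n_pools=n_pools, params=params)
    threshold = resolve_match_threshold(params, table.cell)

    scored = []
    for k, cand in enumerate(candidates):
        # the all-peak rms, not the two-vector fit residual, decides the
        # best orientation within a cluster
        n_match_m, rms_m = _match_stats_batch(cand.member_orientations, B, q_all, threshold)
        order = np.lexsort(
            (np.arange(len(rms_m)), cand.member_residuals, rms_m, -n_match_m)
        )
        # star support: the chosen orientation must be corroborated by
        # every required pool *directly* (within the merge tolerance),
        # not merely through a single-linkage chain — chains of
        # independent coincidences masquerade as consensus otherwise.
        # Members are tried best-rms first; the first star-supported one
        # represents the cluster.
        qm = _quats(cand.member_orientations)
        cos_half = np.cos(np.radians(params.pool_merge_tol) / 2.0)
        best_m = -1
        for m in order[:200]:
            close = np.abs(qm @ qm[m]) >= cos_half
            support = int(len(np.unique(cand.member_pool_ids[close])))
            if support >= cand.required_support:
                best_m, cand.pool_support = int(m), support
                break
        if best_m < 0:
            continue
        cand.orientation = cand.member_orientations[best_m]
        cand.fit_residual = float(cand.member_residuals[best_m])
        h, dist, matched, rms = predict_and_match(cand.orientation, B, q_all, threshold)
        n_matched = int(np.sum(matched))
        frac = n_matched / len(usable)
        centering_ok = (
            bool(np.all(centering_mask(h[matched], table.cell.centering)))
            if n_matched
            else False
        )
        score = (centering_ok, n_matched, frac, -rms if np.isfinite(rms) else -np.inf, -cand.fit_residual, -k)
        scored.append((score, cand, h, dist, matched, n_matched, frac, rms))
    if not scored:
        return IndexingSolution(accepted=False, reason=NO_CONSENSUS, n_pools=n_pools, params=params)
    scored.sort(key=lambda t: t[0], reverse=True)
    _, cand, h, dist, matched, n_matched, frac, rms = scored[0]

    required_frac = 1.0 if sparse_mode else params.min_match_fraction(len(usable))
    centering_ok = scored[0][0][0]
    if frac < required_frac or not centering_ok:
        return IndexingSolution(
            accepted=False,
            reason=FAILED_MATCH_GATE,
            orientation=cand.orientation,
            n_matched=n_matched,
            match_fraction=frac,
            rms_dq=rms,
            pool_support=cand.pool_support,
            n_pools=n_pools,
            fit_residual=cand.fit_residual,
            match_threshold=threshold,
            params=params,
        )
    if sparse_mode and params.require_unique_consensus:
        # a very sparse pattern is accepted only when the consensus is
        # effectively unique: a second fully-supported orientation that
        # matches all peaks comparably well (rms within
        # ambiguity_rms_factor of the best) and is not a lattice-symmetry
        # copy means the few peaks are ambiguous, and the pattern is
        # rejected; a clearly worse competitor does not veto
        ops = _lattice_ops(table.cell)
        equiv_tol = max(2.0 * params.pool_merge_tol, 2.0)
        for sc, other, *rest in scored[1:]:
            other_rms = rest[-1]
            if not (sc[0] and sc[2] >= 1.0):  # centering-consistent, all matched
                continue
            if other_rms > params.ambiguity_rms_factor * max(rms, 1e-12):
                continue
            if not _symmetry_equivalent(cand.orientation, other.orientation, ops, equiv_tol):
                return IndexingSolution(
                    accepted=False,
                    reason=NO_CONSENSUS,
                    orientation=cand.orientation,
                    n_matched=n_matched,
                    match_fraction=frac,
                    rms_dq=rms,
                    pool_support=cand.pool_support,
                    n_pools=n_pools,
                    fit_residual=cand.fit_residual,
                    match_threshold=threshold,
                    params=params,
                )
    return IndexingSolution(
        accepted=True,
        orientation=cand.orientation,
        oriented_basis=cand.orientation @ B,
        hkl=h,
        matched=matched,
        match_dist=dist,
        n_matched=n_matched,
        match_fraction=frac,
        rms_dq=rms,
        pool_support=cand.pool_support,
        n_pools=n_pools,
        fit_residual=cand.fit_residual,
        match_threshold=threshold,
        params=params,
    )
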
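"""Indexing core: pair fits, pool intersection, accept/reject logic."""

from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from snapindex.geometry import peaks_to_reciprocal
from snapindex.indexer import (
    DegeneratePairError,
    IndexingParams,
    build_solution_pools,
    enumerate_pairs,
    index_pattern,
    intersect_pools,
    misorientation,
    orientation_from_assignment,
    pair_geometry,
    predict_and_match,
    resolve_match_threshold,
    select_peaks,
)
from snapindex.lattice import UnitCell, generate_reflections, reciprocal_basis
from snapindex.simulate import (
    SimulationConfig,
    orientation_from_euler,
    random_orientation,
    simulate_pattern,
    simulate_patterns,
)
from snapindex.table import build_reference_table


# ------------------------------------------------------------- combinatorics

@pytest.mark.parametrize("n,expected", [(5, 10), (2, 1), (7, 21)])
def test_pair_counts(n, expected):
    assert len(enumerate_pairs(n)) == expected


@given(n=st.integers(2, 40))
def test_pair_count_closed_form(n):
    pairs = enumerate_pairs(n)
    assert len(pairs) == n * (n - 1) // 2
    assert len(set(pairs)) == len(pairs)


# ------------------------------------------------------------- pair geometry

def test_pair_geometry_examples():
    l1, l2, ratio, ang = pair_geometry(np.array([0.1, 0, 0]), np.array([0, 0.1, 0]))
    assert (l1, l2, ratio, ang) == pytest.approx((0.1, 0.1, 1.0, 90.0))
    *_, ang = pair_geometry(np.array([0.1, 0, 0]), np.array([-0.1, 0, 0]))
    assert ang == pytest.approx(180.0)
    l1, l2, ratio, ang = pair_geometry(np.array([0.1, 0, 0]), np.array([0.1, 0.1, 0]))
    assert l2 == pytest.approx(0.141421, abs=1e-6)
    assert ratio == pytest.approx(0.70711, abs=1e-5)
    assert ang == pytest.approx(45.0)
    with pytest.raises(DegeneratePairError):
        pair_geometry(np.zeros(3), np.array([0.1, 0, 0]))


# ------------------------------------------------------------- two-vector fit

def test_orientation_fit_exact_recovery(i3c_cell, rng):
    B = reciprocal_basis(i3c_cell)
    h1, h2 = np.array([1, 2, 0]), np.array([0, 1, 3])
    R, resid = orientation_from_assignment(B @ h1, B @ h2, h1, h2, B)
    assert np.allclose(R, np.eye(3), atol=1e-12)
    assert resid < 1e-14
    for _ in range(10):
        R0 = random_orientation(rng)
        R, resid = orientation_from_assignment(R0 @ B @ h1, R0 @ B @ h2, h1, h2, B)
        assert misorientation(R, R0) < 1e-8
        assert resid < 1e-12


def test_orientation_fit_rejects_collinear(i3c_cell):
    B = reciprocal_basis(i3c_cell)
    h = np.array([1, 0, 0])
    with pytest.raises(DegeneratePairError):
        orientation_from_assignment(B @ h, 2.0 * (B @ h), h, 2 * h, B)


def test_noisy_fit_beats_rotation_grid_oracle(i3c_cell, rng):
    """The closed-form fit's residual is at least as small as the best
    residual found by a dense local rotation-grid search (0.05 deg)."""
    B = reciprocal_basis(i3c_cell)
    h1, h2 = np.array([2, 1, 0]), np.array([0, 2, 2])
    r1, r2 = B @ h1, B @ h2
    R0 = random_orientation(rng)
    q1 = R0 @ r1 + rng.normal(0, 1e-4, 3)
    q2 = R0 @ r2 + rng.normal(0, 1e-4, 3)
    R_fit, resid_fit = orientation_from_assignment(q1, q2, h1, h2, B)

    # oracle: scan perturbations of R0 on a 0.05 deg axis grid out to 1 deg
    deltas = np.radians(np.arange(-1.0, 1.0001, 0.05))
    Rx = Rotation.from_rotvec(np.outer(deltas, [1, 0, 0])).as_matrix()
    Ry = Rotation.from_rotvec(np.outer(deltas, [0, 1, 0])).as_matrix()
    Rz = Rotation.from_rotvec(np.outer(deltas, [0, 0, 1])).as_matrix()
    # v_{ijk} = R0 Rx_i Ry_j Rz_k r, built right-to-left
    def residuals(r, q):
        v = np.einsum("kab,b->ka", Rz, r)  # (K,3)
        v = np.einsum("jab,kb->jka", Ry, v)  # (J,K,3)
        v = np.einsum("iab,jkb->ijka", Rx, v)  # (I,J,K,3)
        v = np.einsum("ab,ijkb->ijka", R0, v)
        return np.sum((q - v) ** 2, axis=-1)
    resid_grid = np.sqrt(residuals(r1, q1) + residuals(r2, q2))
    assert resid_fit <= resid_grid.min() + 1e-12
    assert misorientation(R_fit, R0) < 0.5


# ------------------------------------------------------------- misorientation

def test_misorientation_basics(rng):
    R = random_orientation(rng)
    assert misorientation(R, R) == pytest.approx(0.0, abs=1e-6)
    Rz = Rotation.from_euler("z", 5.0, degrees=True).as_matrix()
    assert misorientation(Rz, np.eye(3)) == pytest.approx(5.0, abs=1e-9)
    R2 = random_orientation(rng)
    assert misorientation(R, R2) == pytest.approx(misorientation(R2, R), abs=1e-9)


def test_misorientation_of_reported_euler_triplets():
    """The generated vs determined orientations of the worked example
    differ by well under 0.2 degrees in the documented z-y-z convention."""
    R1 = orientation_from_euler(-10.4676, 46.9022, 139.1443)
    R2 = orientation_from_euler(-10.5713, 46.8855, 139.2000)
    assert misorientation(R1, R2) <= 0.2


# ------------------------------------------------------------- peak selection

def _fake_rpeaks(specs, geom):
    from snapindex.geometry import DetectorPeak, peak_to_reciprocal

    return [
        peak_to_reciprocal(DetectorPeak(fast=f, slow=s, intensity=i, snr=r), geom)
        for f, s, i, r in specs
    ]


def test_select_peaks_criteria(i3c_geom):
    specs = [(100.0 + 10 * k, 50.0, 100.0 - k, 10.0 + k) for k in range(8)]
    rp = _fake_rpeaks(specs, i3c_geom)
    by_int = select_peaks(rp, IndexingParams(peak_selection="intensity"))
    assert [p.source_peak.intensity for p in by_int] == [100, 99, 98, 97, 96]
    by_snr = select_peaks(rp, IndexingParams(peak_selection="snr"))
    assert [p.source_peak.snr for p in by_snr] == [17, 16, 15, 14, 13]
    by_res = select_peaks(rp, IndexingParams(peak_selection="resolution"))
    qs = [p.q_length for p in by_res]
    assert qs == sorted(qs)
    # clamp: requesting 5 from 3 returns all 3
    assert len(select_peaks(rp[:3], IndexingParams())) == 3


def test_half_nearest_threshold(i3c_cell):
    table_cellonly = IndexingParams(match_threshold="half-nearest")
    assert resolve_match_threshold(table_cellonly, i3c_cell) == pytest.approx(
        0.026568, abs=1e-6
    )
    assert resolve_match_threshold(IndexingParams(match_threshold=0.01), i3c_cell) == 0.01


# ------------------------------------------------------------- pools

def _noise_free_pattern(cell, seed, geom_config=None):
    config = geom_config or SimulationConfig(
        cell=cell,
        poisson_noise=False,
        background_mean=0.0,
        detect_min_snr=0.0,
        pixelate=False,
        peak_gain=1000.0,
        structure_factors="unit",
    )
    rng = np.random.default_rng(seed)
    return config, simulate_pattern(config, rng)


def test_pools_contain_generating_orientation(i3c_cell, i3c_table):
    config, pat = _noise_free_pattern(i3c_cell, seed=5)
    rp = peaks_to_reciprocal(pat.peaks, config.geom)
    params = IndexingParams()
    sel = select_peaks(rp, params)
    q = np.array([p.q for p in sel])
    pools = build_solution_pools(q, enumerate_pairs(len(sel)), i3c_table, params)
    assert pools  # at least one informative pair
    for pool in pools:
        assert len(pool) > 0
        best = min(misorientation(R, pat.true_orientation) for R in pool.orientations)
        # candidate orientations carry the excitation-error position offset
        assert best < 1.0


def test_unmatched_pair_gives_empty_pool(i3c_table):
    params = IndexingParams()
    q = np.array([[0.017, 0.0, 0.0], [0.0, 0.019, 0.0]])  # far below any reflection
    pools = build_solution_pools(q, [(0, 1)], i3c_table, params)
    assert len(pools) == 1 and len(pools[0]) == 0


def test_intersection_matches_all_pairs_oracle(rng):
    """Synthetic pools: clusters surviving support filtering equal the
    oracle's all-pairs misorientation-threshold clustering."""
    from snapindex.indexer import SolutionPool

    R0 = random_orientation(rng)
    pools = []
    all_R, all_pool = [], []
    for pid in range(4):
        Rs = [R0 @ Rotation.from_rotvec(rng.normal(0, 1e-4, 3)).as_matrix()]
        for _ in range(6):  # spurious, far away
            Rs.append(random_orientation(rng))
        Rs = np.array(Rs)
        pools.append(
            SolutionPool(
                pair_id=(0, pid),
                orientations=Rs,
                residuals=np.full(len(Rs), 1e-4),
                entry_idx=np.arange(len(Rs)),
            )
        )
        all_R.extend(Rs)
        all_pool.extend([pid] * len(Rs))
    params = IndexingParams(pool_merge_tol=1.0)
    cands = intersect_pools(pools, params, sparse_mode=True)

    # oracle: O(n^2) all-pairs single linkage + support count
    n = len(all_R)
    adj = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(n):
            adj[i, j] = misorientation(all_R[i], all_R[j]) <= 1.0
    labels = -np.ones(n, int)
    lab = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        while stack:
            k = stack.pop()
            if labels[k] >= 0:
                continue
            labels[k] = lab
            stack.extend(np.nonzero(adj[k])[0])
        lab += 1
    full = [
        l
        for l in range(lab)
        if len({all_pool[i] for i in range(n) if labels[i] == l}) == 4
    ]
    assert len(cands) == len(full) == 1
    assert misorientation(cands[0].orientation, R0) < 0.01
    assert cands[0].pool_support == 4


def test_two_disjoint_pools_give_no_consensus(rng):
    from snapindex.indexer import SolutionPool

    pools = [
        SolutionPool(
            pair_id=(0, k),
            orientations=np.array([random_orientation(rng) for _ in range(3)]),
            residuals=np.full(3, 1e-4),
            entry_idx=np.arange(3),
        )
        for k in range(2)
    ]
    assert intersect_pools(pools, IndexingParams(), sparse_mode=True) == []


# ------------------------------------------------------------- matching

def test_predict_and_match_noise_free(i3c_cell, i3c_table):
    config, pat = _noise_free_pattern(i3c_cell, seed=7)
    B = reciprocal_basis(i3c_cell)
    rp = peaks_to_reciprocal(pat.peaks, config.geom)
    q = np.array([p.q for p in rp])
    h, dist, matched, rms = predict_and_match(
        pat.true_orientation, B, q, match_threshold=0.01
    )
    assert matched.all()
    # noise-free positions still carry the excitation-error offset
    assert rms < 3 * config.sigma_q
    assert np.array_equal(h, pat.true_indices)


# ------------------------------------------------------------- index_pattern

def test_exact_qspace_round_trip(i3c_cell, i3c_table, rng):
    """Indexer completeness on ideal input: observed q-vectors placed
    exactly on reciprocal-lattice nodes recover the generating
    orientation to < 1e-6 degrees (modulo a lattice rotation) with the
    exact Miller indices."""
    from snapindex.geometry import ReciprocalPeak
    from snapindex.lattice import generate_reflections, lattice_rotations

    B = reciprocal_basis(i3c_cell)
    hkl, _ = generate_reflections(i3c_cell, d_min=2.0)
    ops = lattice_rotations(i3c_cell)
    for trial in range(6):
        R0 = random_orientation(rng)
        picks = rng.choice(len(hkl), size=int(rng.integers(3, 6)), replace=False)
        q_obs = hkl[picks].astype(float) @ (R0 @ B).T
        rp = [
            ReciprocalPeak(q=v, q_length=float(np.linalg.norm(v)), resolution=1.0)
            for v in q_obs
        ]
        sol = index_pattern(rp, i3c_table, IndexingParams())
        assert sol.accepted, sol.reason
        # rotation-vector angle resolves sub-microdegree differences
        # where the arccos trace formula loses precision
        dmin, M = min(
            (
                (
                    np.degrees(
                        np.linalg.norm(
                            Rotation.from_matrix(sol.orientation.T @ R0 @ S.T).as_rotvec()
                        )
                    ),
                    Mop,
                )
                for Mop, S in ops
            ),
            key=lambda t: t[0],
        )
        assert dmin < 1e-6
        assert np.array_equal(sol.hkl, hkl[picks] @ M.T)


def test_noise_free_detector_round_trip(i3c_cell, i3c_table):
    """Zero detector noise, exact guiding cell: every pattern indexes
    and Miller indices equal ground truth up to a proper lattice
    rotation; orientation is exact up to the excitation-error offset of
    the recorded positions."""
    from snapindex.evaluate import compare_to_truth
    from snapindex.lattice import lattice_rotations

    ops = lattice_rotations(i3c_cell)
    for seed in range(6):
        config, pat = _noise_free_pattern(i3c_cell, seed=100 + seed)
        rp = peaks_to_reciprocal(pat.peaks, config.geom)
        sol = index_pattern(rp, i3c_table, IndexingParams())
        assert sol.accepted, sol.reason
        out = compare_to_truth(sol, pat, ops, mis_tol=0.5)
        assert out.correct


def test_too_few_peaks_rejected(i3c_table, i3c_geom):
    rp = _fake_rpeaks([(100, 100, 5, 5), (200, 50, 4, 4)], i3c_geom)
    sol = index_pattern(rp, i3c_table)
    assert not sol.accepted and sol.reason == "too-few-peaks"


def test_index_pattern_deterministic(i3c_cell, i3c_table):
    from snapindex.io import solution_to_record
    import json

    config = SimulationConfig(cell=i3c_cell, n_patterns=3, seed=21)
    pats = simulate_patterns(config)
    recs = []
    for _ in range(2):
        out = []
        for pat in pats:
            rp = peaks_to_reciprocal(pat.peaks, config.geom)
            sol = index_pattern(rp, i3c_table)
            out.append(json.dumps(solution_to_record(sol, pat.pattern_id), sort_keys=True))
        recs.append(out)
    assert recs[0] == recs[1]


def test_tolerance_growth_never_shrinks_candidates(i3c_cell, i3c_table):
    config = SimulationConfig(cell=i3c_cell, n_patterns=2, seed=31)
    for pat in simulate_patterns(config):
        rp = peaks_to_reciprocal(pat.peaks, config.geom)
        sel = select_peaks(rp, IndexingParams())
        q = np.array([p.q for p in sel])
        pairs = enumerate_pairs(len(sel))
        small = build_solution_pools(q, pairs, i3c_table, IndexingParams(tol_len=1.5e-3, tol_angle=1.5))
        large = build_solution_pools(q, pairs, i3c_table, IndexingParams(tol_len=3e-3, tol_angle=3.0))
        assert sum(len(p) for p in large) >= sum(len(p) for p in small)


def _toy_cubic_oracle(q_obs, cell, d_min, threshold=1e-3):
    """Exhaustive search: every observed peak pair times every ordered
    Miller assignment, two-vector fit, then full-pattern verification —
    no reference table, no pools."""
    B = reciprocal_basis(cell)
    hkl, _ = generate_reflections(cell, d_min)
    best = None
    for i, j in combinations(range(len(q_obs)), 2):
        for h1, h2 in permutations(range(len(hkl)), 2):
            try:
                R, resid = orientation_from_assignment(
                    q_obs[i], q_obs[j], hkl[h1], hkl[h2], B
                )
            except DegeneratePairError:
                continue
            h, dist, matched, rms = predict_and_match(R, B, q_obs, threshold)
            if matched.all() and (best is None or rms < best[1]):
                best = (R, rms)
    return best


def test_index_pattern_agrees_with_exhaustive_oracle(rng):
    """On toy cubic patterns the pipeline's accepted orientation matches
    an exhaustive all-assignments search."""
    cell = UnitCell(10, 10, 10)
    table = build_reference_table(cell, d_min=5.0)
    B = reciprocal_basis(cell)
    hkl, _ = generate_reflections(cell, 5.0)
    from snapindex.geometry import ReciprocalPeak

    n_checked = 0
    for trial in range(8):
        R0 = random_orientation(rng)
        picks = rng.choice(len(hkl), size=3, replace=False)
        q_obs = hkl[picks].astype(float) @ (R0 @ B).T
        rp = [
            ReciprocalPeak(q=q, q_length=float(np.linalg.norm(q)), resolution=1.0)
            for q in q_obs
        ]
        sol = index_pattern(
            rp, table, IndexingParams(match_threshold=1e-3, require_unique_consensus=False)
        )
        oracle = _toy_cubic_oracle(q_obs, cell, 5.0)
        if sol.accepted:
            assert oracle is not None
        if sol.accepted and oracle is not None:
            # same orientation modulo cubic lattice rotations
            from snapindex.lattice import lattice_rotations

            ops = lattice_rotations(cell)
            dmin = min(
                misorientation(sol.orientation @ S, oracle[0]) for _, S in ops
            )
            assert dmin <= 1.0
            n_checked += 1
    assert n_checked >= 3


def test_consensus_soundness(i3c_cell, i3c_table):
    """Accepted solutions reproduce every matched peak within the match
    threshold, directly from the returned record."""
    config = SimulationConfig(cell=i3c_cell, n_patterns=5, seed=41)
    for pat in simulate_patterns(config):
        rp = peaks_to_reciprocal(pat.peaks, config.geom)
        sol = index_pattern(rp, i3c_table)
        if sol.accepted:
            assert np.all(sol.match_dist[sol.matched] <= sol.match_threshold)
            assert sol.n_matched == int(sol.matched.sum())
            assert sol.match_fraction == pytest.approx(sol.n_matched / len(rp))
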
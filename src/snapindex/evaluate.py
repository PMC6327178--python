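"""Validation experiments: sparse-indexing round trip and guiding-cell scans.

A pattern counts as *correctly* indexed when it is accepted, the
determined orientation lies within a tolerance of the generating one,
and every matched peak's Miller index agrees with ground truth — both
compared modulo the proper rotational symmetry of the guiding lattice,
because symmetry-related orientations (e.g. the three 2-folds of an
orthorhombic lattice, and with them whole-pattern re-indexings such as
Friedel-consistent sign flips) predict identical patterns and are
fundamentally indistinguishable from a single still snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .indexer import IndexingParams, IndexingSolution, index_pattern, misorientation
from .lattice import UnitCell, lattice_rotations, reciprocal_basis
from .simulate import (
    SimulationConfig,
    SimulatedPattern,
    guiding_cell_variant,
    simulate_patterns,
)
from .table import ReferenceTable, build_reference_table

#: orientation tolerance (deg) for "correctly indexed"; an order of
#: magnitude above the expected determination accuracy.
CORRECT_MISORIENTATION_DEG = 0.5


@dataclass
class PatternOutcome:
    """Per-pattern comparison of a solution against ground truth."""

    pattern_id: int
    accepted: bool
    reason: str | None
    misorientation: float = np.nan  # symmetry-reduced, deg
    miller_correct: bool = False
    correct: bool = False
    solution: IndexingSolution | None = field(default=None, repr=False)


@dataclass
class ExperimentReport:
    """Aggregate statistics of one simulate-and-index experiment."""

    n_patterns: int
    n_indexed: int  # accepted patterns
    n_correct: int  # accepted and verified against ground truth
    indexing_rate: float
    miller_correct_rate: float
    misorientation_median: float  # deg, over indexed patterns
    misorientation_p90: float
    paired_peak_distances: np.ndarray  # Å⁻¹, matched peaks of accepted patterns
    outcomes: list[PatternOutcome] = field(repr=False, default_factory=list)
    alpha: float | None = None  # guiding-cell α for scan points
    seed: int = 0
    config: SimulationConfig | None = field(default=None, repr=False)
    params: IndexingParams | None = field(default=None, repr=False)


def symmetry_reduced_misorientation(
    R_det: np.ndarray,
    R_true: np.ndarray,
    ops: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, np.ndarray]:
    """Min misorientation over lattice rotations; returns (angle, M_best).

    ``ops`` come from :func:`snapindex.lattice.lattice_rotations`; the
    detected orientation explains the pattern with re-indexed Miller
    indices h_det = M·h_true when R_det ≈ R_true·Rsᵀ for the op (M, Rs).
    """
    best = (np.inf, np.eye(3, dtype=int))
    for M, Rs in ops:
        ang = misorientation(R_det, R_true @ Rs.T)
        if ang < best[0]:
            best = (ang, M)
    return best


def compare_to_truth(
    solution: IndexingSolution,
    pattern: SimulatedPattern,
    ops: list[tuple[np.ndarray, np.ndarray]],
    mis_tol: float = CORRECT_MISORIENTATION_DEG,
) -> PatternOutcome:
    """Judge one solution against the pattern's ground truth."""
    out = PatternOutcome(
        pattern_id=pattern.pattern_id,
        accepted=solution.accepted,
        reason=solution.reason,
        solution=solution,
    )
    if not solution.accepted:
        return out
    ang, M = symmetry_reduced_misorientation(
        solution.orientation, pattern.true_orientation, ops
    )
    out.misorientation = ang
    expected = pattern.true_indices @ M.T  # h_det = M·h_true, row vectors
    matched = solution.matched
    out.miller_correct = bool(np.array_equal(solution.hkl[matched], expected[matched]))
    out.correct = out.miller_correct and ang <= mis_tol
    return out


def _run(
    patterns: list[SimulatedPattern],
    table: ReferenceTable,
    params: IndexingParams,
    nominal_cell: UnitCell,
    seed: int,
    config: SimulationConfig | None,
    alpha: float | None = None,
) -> ExperimentReport:
    from .geometry import peaks_to_reciprocal

    ops = lattice_rotations(nominal_cell)
    B = reciprocal_basis(table.cell)
    outcomes = []
    dists = []
    for pat in patterns:
        rpeaks = peaks_to_reciprocal(pat.peaks, config.geom)
        sol = index_pattern(rpeaks, table, params, B=B)
        outcome = compare_to_truth(sol, pat, ops)
        outcomes.append(outcome)
        if sol.accepted:
            dists.append(sol.match_dist[sol.matched])
    n = len(patterns)
    accepted = [o for o in outcomes if o.accepted]
    mis = np.array([o.misorientation for o in accepted])
    n_correct = sum(o.correct for o in outcomes)
    return ExperimentReport(
        n_patterns=n,
        n_indexed=len(accepted),
        n_correct=n_correct,
        indexing_rate=len(accepted) / n if n else 0.0,
        miller_correct_rate=n_correct / n if n else 0.0,
        misorientation_median=float(np.median(mis)) if len(mis) else np.nan,
        misorientation_p90=float(np.percentile(mis, 90)) if len(mis) else np.nan,
        paired_peak_distances=np.concatenate(dists) if dists else np.empty(0),
        outcomes=outcomes,
        alpha=alpha,
        seed=seed,
        config=config,
        params=params,
    )


def run_sparse_experiment(
    config: SimulationConfig,
    params: IndexingParams = IndexingParams(),
    guiding_cell: UnitCell | None = None,
    table: ReferenceTable | None = None,
) -> ExperimentReport:
    """Simulate ``config.n_patterns`` sparse patterns and index them all.

    The guiding cell defaults to the nominal simulation cell; the
    reference table covers the full recordable resolution range unless
    ``params.d_min_table`` narrows it.
    """
    patterns = simulate_patterns(config)
    guiding = guiding_cell if guiding_cell is not None else config.cell
    if table is None:
        d_min = params.d_min_table if params.d_min_table else config.d_min
        table = build_reference_table(guiding, d_min)
    return _run(patterns, table, params, config.cell, config.seed, config)


def run_alpha_scan(
    config: SimulationConfig,
    params: IndexingParams,
    alpha_values,
    match_cutoff: float = 0.01,
) -> list[ExperimentReport]:
    """Index one fluctuated pattern set with mis-set guiding cells.

    One pattern set is simulated from the nominal cell (with
    ``config.cell_sigma_frac`` lattice fluctuations) and re-indexed with
    volume-preserving guiding-cell variants at each α; the peak-match
    threshold is fixed at ``match_cutoff`` (Å⁻¹) for every scan point so
    paired-peak distance distributions are comparable across α.

    The pair-search length tolerance is widened to the match cut-off so
    the search stage cannot prune pairs the acceptance stage would
    accept under a deliberately mis-set guiding cell; the angle
    tolerance is left at its configured value, whose window is what the
    scan's ±tolerance range probes.
    """
    patterns = simulate_patterns(config)
    params = IndexingParams(
        **{
            **params.__dict__,
            "match_threshold": float(match_cutoff),
            "tol_len": max(params.tol_len, float(match_cutoff)),
        }
    )
    d_min = params.d_min_table if params.d_min_table else config.d_min
    reports = []
    for alpha in alpha_values:
        guiding = guiding_cell_variant(config.cell, float(alpha))
        table = build_reference_table(guiding, d_min)
        reports.append(
            _run(patterns, table, params, config.cell, config.seed, config, alpha=float(alpha))
        )
    return reports


def paired_distance_histogram(
    reports: list[ExperimentReport],
    bin_width: float = 5e-4,
    max_dist: float = 0.01,
):
    """Histogram of predicted-vs-found peak distances per scan point.

    Returns a DataFrame with one row per (α, bin): bin edges, count, and
    the modal-bin flag; all recorded distances lie below the match
    cut-off by construction, so the histogram has no mass above it.
    """
    import pandas as pd

    edges = np.arange(0.0, max_dist + bin_width / 2, bin_width)
    rows = []
    for rep in reports:
        counts, _ = np.histogram(rep.paired_peak_distances, bins=edges)
        modal = int(np.argmax(counts)) if counts.sum() else -1
        for i, c in enumerate(counts):
            rows.append(
                {
                    "alpha": rep.alpha,
                    "bin_lo": edges[i],
                    "bin_hi": edges[i + 1],
                    "count": int(c),
                    "is_modal": i == modal,
                }
            )
    return pd.DataFrame(rows)
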
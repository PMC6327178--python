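"""Synthetic sparse snapshot-diffraction patterns with ground truth.

Emulates still (monochromatic, zero-oscillation) diffraction from a
randomly oriented microcrystal: reciprocal-lattice points are broadened
into isotropic Gaussians by the finite crystal size, a reflection's
ideal intensity decays with its excitation error (the beam-direction
distance from the node to the Ewald sphere), Poisson counting noise and
a uniform background are added, and only peaks whose estimated SNR
clears a detection cut are reported — calibrated so that each pattern
carries just a handful (by default 3–5) of identifiable Bragg peaks.

The default configuration is the small-molecule I3C test case: an
orthorhombic 9.02 × 15.73 × 18.82 Å cell recorded at 9.61 keV on a
110 µm-pixel detector 0.07 m downstream with a 53.2° acceptance cone.
Reported Euler angles use the intrinsic z-y-z convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import DetectorPeak, ExperimentGeometry, project_to_detector
from .lattice import UnitCell, generate_reflections, reciprocal_basis

EULER_CONVENTION = "ZYZ"  # intrinsic z-y-z, degrees

#: 5-amino-2,4,6-triiodoisophthalic acid monohydrate (I3C) cell.
I3C_CELL = UnitCell(9.02, 15.73, 18.82, 90.0, 90.0, 90.0, "P")

#: Default beamline geometry for the I3C simulations.
I3C_GEOMETRY = ExperimentGeometry(
    detector_distance=0.07,
    pixel_size=110e-6,
    photon_energy=9.61,
    beam_center=(0.0, 0.0),
    max_scattering_angle=53.2,
)


class SimulationError(RuntimeError):
    """Auto-calibration or configuration failure."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated pattern set.

    ``relrod_sigma`` (Å⁻¹) is the Gaussian width of the
    reciprocal-lattice-point profile; when None it is derived from the
    crystal size as 1/(size in Å), i.e. 1e-4 Å⁻¹ for a 1 µm crystal.
    ``peak_gain`` of None enables per-pattern calibration so that the
    number of identifiable peaks falls inside ``target_peak_range``.
    """

    cell: UnitCell = I3C_CELL
    geom: ExperimentGeometry = I3C_GEOMETRY
    cell_sigma_frac: float = 0.0  # 0.005 in the lattice-fluctuation variant
    crystal_size_um: float = 1.0
    relrod_sigma: float | None = None  # Å⁻¹
    #: rel-rod width constant: sigma = factor / (crystal size in Å).
    #: The ideal finite-size shape transform alone gives ~1/L; the
    #: default absorbs the beam divergence, residual bandwidth and
    #: mosaic broadening that widen the effective reflecting range, and
    #: is calibrated so that essentially every random orientation of the
    #: default cell yields at least a handful of recordable reflections.
    relrod_width_factor: float = 3.0
    background_mean: float = 100.0  # counts per peak region
    peak_gain: float | None = None  # counts at zero excitation error; None = auto
    detect_min_snr: float = 4.0
    target_peak_range: tuple[int, int] = (3, 5)
    poisson_noise: bool = True
    pixelate: bool = True  # quantize peak centers to whole pixels
    #: half-width of the excitation-error emission window in units of
    #: relrod_sigma; a strong reflection several sigma off the sphere is
    #: still recordable at high gain, so this is wider than the
    #: identifiable core
    zeta_window_sigmas: float = 5.0
    #: "wilson": per-reflection F² ~ Exp(1), fixed per Miller index and
    #: Friedel-symmetric, under a exp(−B·q²/2) envelope; "unit": F² = 1.
    structure_factors: str = "wilson"
    #: seed of the Wilson structure-factor realization. Deliberately
    #: separate from ``seed``: the synthetic "molecule" is a fixed study
    #: condition shared by all pattern sets, like the unit cell, while
    #: ``seed`` varies orientations and noise.
    structure_factor_seed: int = 0
    #: effective isotropic B (Å²) of the intensity envelope; the default
    #: bundles thermal motion with the atomic form-factor decay of an
    #: iodine-dominated small molecule.
    b_factor: float = 7.0
    n_patterns: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.target_peak_range
        if not (0 < lo <= hi):
            raise SimulationError("target_peak_range must be positive and ordered")
        if self.sigma_q <= 0:
            raise SimulationError("relrod_sigma must be > 0")

    @property
    def sigma_q(self) -> float:
        if self.relrod_sigma is not None:
            return self.relrod_sigma
        return self.relrod_width_factor / (self.crystal_size_um * 1e4)  # µm -> Å

    @property
    def d_min(self) -> float:
        """Resolution limit implied by the acceptance cone."""
        q_max = self.geom.q_max
        if q_max is None:
            raise SimulationError("geometry must define max_scattering_angle")
        return 1.0 / q_max


@dataclass
class SimulatedPattern:
    """One synthetic pattern with full ground truth."""

    true_orientation: np.ndarray  # R, lab <- crystal
    true_euler: tuple[float, float, float]  # intrinsic z-y-z, degrees
    true_cell: UnitCell  # post-fluctuation cell
    peaks: list[DetectorPeak]
    true_indices: np.ndarray  # (n, 3) int
    excitation_errors: np.ndarray  # (n,) Å⁻¹, signed
    peak_gain: float = np.nan
    pattern_id: int = 0

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix uniform on SO(3) (via uniform unit quaternions)."""
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def euler_angles(R: np.ndarray) -> tuple[float, float, float]:
    """Intrinsic z-y-z Euler angles (deg) of an orientation."""
    return tuple(Rotation.from_matrix(R).as_euler(EULER_CONVENTION, degrees=True))


def orientation_from_euler(phi: float, theta: float, psi: float) -> np.ndarray:
    """Orientation from intrinsic z-y-z Euler angles in degrees."""
    return Rotation.from_euler(EULER_CONVENTION, [phi, theta, psi], degrees=True).as_matrix()


def excitation_error(q_nodes: np.ndarray, wavelength: float) -> tuple[np.ndarray, np.ndarray]:
    """Signed beam-direction distance from lattice nodes to the Ewald sphere.

    ζ = sqrt((1/λ)² − qx² − qy²) − (qz + 1/λ); positive when the node
    sits upstream of the sphere.  Nodes whose transverse component
    exceeds the sphere radius can never diffract; they are flagged
    unreachable (second return value False) with ζ = NaN.
    """
    q = np.atleast_2d(np.asarray(q_nodes, dtype=float))
    k = 1.0 / wavelength
    rad = k * k - q[:, 0] ** 2 - q[:, 1] ** 2
    reachable = rad >= 0.0
    zeta = np.where(reachable, np.sqrt(np.where(reachable, rad, 0.0)) - (q[:, 2] + k), np.nan)
    if np.ndim(q_nodes) == 1:
        return zeta[0], reachable[0]
    return zeta, reachable


def perturb_cell(cell: UnitCell, sigma_frac: float, rng: np.random.Generator) -> UnitCell:
    """Apply independent Gaussian fluctuations to the cell lengths.

    Each length is multiplied by N(1, sigma_frac); angles are unchanged.
    Pathological draws (non-positive factors) are resampled, bounded.
    """
    if sigma_frac < 0:
        raise SimulationError("sigma_frac must be >= 0")
    if sigma_frac == 0:
        return cell
    for _ in range(100):
        f = rng.normal(1.0, sigma_frac, size=3)
        if np.all(f > 0.1):
            return cell.with_lengths(cell.a * f[0], cell.b * f[1], cell.c * f[2])
    raise SimulationError("could not draw a valid perturbed cell")


def guiding_cell_variant(cell: UnitCell, alpha_deg: float) -> UnitCell:
    """Mis-set the α angle while preserving the cell volume.

    For a cell with β = γ = 90°, V = a·b·c·sin α; b and c are each
    scaled by 1/sqrt(sin α) so the volume (hence the average density of
    Bragg orders) is unchanged.
    """
    if not 0.0 < alpha_deg < 180.0:
        raise SimulationError("alpha must be in (0, 180) degrees")
    s = 1.0 / np.sqrt(np.sin(np.radians(alpha_deg)))
    return UnitCell(
        cell.a, cell.b * s, cell.c * s, alpha_deg, cell.beta, cell.gamma, cell.centering
    )


def wilson_f2(hkl: np.ndarray, seed: int) -> np.ndarray:
    """Per-reflection squared structure factors, Wilson statistics.

    F² is exponentially distributed (acentric Wilson distribution, unit
    mean), derived deterministically from the Miller index by an integer
    hash so the same reflection is strong or weak in every pattern;
    Friedel mates share a value.  ``seed`` selects the realization.
    """
    hkl = np.asarray(hkl, dtype=np.int64)
    # canonical Friedel representative: first non-zero index positive
    lead = np.where(
        hkl[:, 0] != 0, hkl[:, 0], np.where(hkl[:, 1] != 0, hkl[:, 1], hkl[:, 2])
    )
    canon = np.where((lead < 0)[:, None], -hkl, hkl)
    mix = (
        canon[:, 0] * 73856093
        ^ canon[:, 1] * 19349663
        ^ canon[:, 2] * 83492791
        ^ np.int64(seed) * 2654435761
    ) & 0xFFFFFFFF
    # splitmix-style avalanche, then map to (0, 1)
    mix = (mix ^ (mix >> 16)) * 0x45D9F3B & 0xFFFFFFFF
    mix = (mix ^ (mix >> 16)) * 0x45D9F3B & 0xFFFFFFFF
    mix = mix ^ (mix >> 16)
    u = (mix + 0.5) / 2**32
    return -np.log(u)


def _candidate_reflections(config: SimulationConfig, cell: UnitCell, R: np.ndarray):
    """Reflections that can appear on the detector for orientation R.

    Returns (hkl, zeta, positions, weights): Ewald-proximal
    (|ζ| <= 3σ), inside the acceptance cone and projecting onto the
    detector; weight = exp(−ζ²/2σ²) is the rel-rod profile factor.
    """
    B = reciprocal_basis(cell)
    hkl, _ = generate_reflections(cell, config.d_min, cap=500_000)
    q = hkl.astype(float) @ (R @ B).T
    lam = config.geom.wavelength
    zeta, reachable = excitation_error(q, lam)
    sigma = config.sigma_q
    near = reachable & (
        np.abs(np.where(reachable, zeta, np.inf)) <= config.zeta_window_sigmas * sigma
    )
    hkl, q, zeta = hkl[near], q[near], zeta[near]
    # diffracted-ray position: the node is within the rel-rod of its
    # Bragg condition, so project along s = λq + ẑ
    pos, visible = project_to_detector(q, config.geom)
    q_max = config.geom.q_max
    inside = visible & (np.linalg.norm(q, axis=1) <= q_max)
    hkl, q, zeta, pos = hkl[inside], q[inside], zeta[inside], pos[inside]
    w = np.exp(-0.5 * (zeta / sigma) ** 2)
    if config.structure_factors == "wilson":
        g2 = np.sum(q * q, axis=1)
        w = w * wilson_f2(hkl, config.structure_factor_seed) * np.exp(
            -0.5 * config.b_factor * g2
        )
    elif config.structure_factors != "unit":
        raise SimulationError(f"unknown structure_factors model {config.structure_factors!r}")
    return hkl, zeta, pos, w


def _gain_for_count(weights: np.ndarray, config: SimulationConfig, k: int) -> float:
    """Gain that makes exactly k reflections identifiable in expectation.

    A reflection with profile weight w is identifiable when its mean
    signal I = gain·w satisfies I/sqrt(I + bg) >= snr_cut, i.e. when
    gain >= I*/w with I* the SNR-threshold signal.  The k-th smallest
    per-reflection gain threshold therefore switches the k-th peak on;
    the returned gain is the geometric midpoint of thresholds k and k+1.
    """
    s, bg = config.detect_min_snr, config.background_mean
    i_star = 0.5 * (s * s + s * np.sqrt(s * s + 4.0 * bg))
    g = np.sort(i_star / weights)
    if k > len(g):
        raise SimulationError("fewer candidate reflections than requested peaks")
    if k == len(g):
        return g[-1] * 2.0
    # sit closer to the (k+1)-switch-on point so the k chosen peaks are
    # solidly above the detection cut under Poisson sampling
    return float(g[k - 1] ** 0.3 * g[k] ** 0.7)


def simulate_pattern(
    config: SimulationConfig,
    rng: np.random.Generator,
    orientation: np.ndarray | None = None,
    pattern_id: int = 0,
    max_attempts: int = 200,
) -> SimulatedPattern:
    """Simulate one sparse pattern.

    The orientation is drawn uniformly (or fixed by ``orientation``),
    the cell optionally perturbed, and the per-pattern gain calibrated
    so the number of identifiable peaks lands in ``target_peak_range``;
    Poisson realizations that land outside the range are redrawn, and
    orientations with too few recordable reflections are resampled
    (never when ``orientation`` is fixed).  Bounded retries; failure
    raises :class:`SimulationError`.
    """
    lo, hi = config.target_peak_range
    for _ in range(max_attempts):
        R = orientation if orientation is not None else random_orientation(rng)
        cell = perturb_cell(config.cell, config.cell_sigma_frac, rng)
        hkl, zeta, pos, w = _candidate_reflections(config, cell, R)
        if len(w) < lo:
            if orientation is not None:
                raise SimulationError(
                    f"only {len(w)} recordable reflections at the fixed orientation"
                )
            continue
        if config.peak_gain is not None:
            gain = config.peak_gain
        else:
            k = int(rng.integers(lo, min(hi, len(w)) + 1))
            gain = _gain_for_count(w, config, k)
        ideal = gain * w
        bg = config.background_mean
        if config.poisson_noise:
            counts = rng.poisson(ideal + bg).astype(float)
        else:
            counts = ideal + bg
        with np.errstate(divide="ignore", invalid="ignore"):
            snr = np.where(counts > 0, (counts - bg) / np.sqrt(np.maximum(counts, 1e-300)), 0.0)
        identifiable = snr >= config.detect_min_snr
        n_id = int(np.sum(identifiable))
        if config.peak_gain is None and n_id != k:
            continue  # Poisson flipped a marginal peak; redraw
        if n_id < 1:
            continue
        p = pos[identifiable]
        if config.pixelate:
            p = np.rint(p)
        peaks = [
            DetectorPeak(
                fast=float(p[m, 0]),
                slow=float(p[m, 1]),
                intensity=float(counts[identifiable][m] - bg),
                snr=float(snr[identifiable][m]),
            )
            for m in range(n_id)
        ]
        return SimulatedPattern(
            true_orientation=R,
            true_euler=euler_angles(R),
            true_cell=cell,
            peaks=peaks,
            true_indices=hkl[identifiable],
            excitation_errors=zeta[identifiable],
            peak_gain=gain,
            pattern_id=pattern_id,
        )
    raise SimulationError(
        f"auto-calibration failed after {max_attempts} attempts "
        f"(target {config.target_peak_range} identifiable peaks)"
    )


def simulate_patterns(config: SimulationConfig) -> list[SimulatedPattern]:
    """Simulate ``config.n_patterns`` patterns with per-pattern child seeds.

    Reproducible bit-exactly for a fixed ``config.seed`` and independent
    of batching: pattern i uses the child stream seeded by (seed, i).
    """
    out = []
    for i in range(config.n_patterns):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        out.append(simulate_pattern(config, rng, pattern_id=i))
    return out
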
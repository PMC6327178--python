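"""Detector geometry and the Ewald construction.

Converts between peak positions on a flat detector and three-dimensional
reciprocal-space vectors.  Conventions (used identically by the simulator
and the indexer):

* laboratory frame: X-ray beam along +z, detector plane at
  ``z = detector_distance``, fast pixel axis = +x, slow pixel axis = +y
  (right-handed);
* crystallographic momentum transfer without the 2π factor:
  ``|q| = 2 sin(theta) / lambda`` and ``d = 1/|q|``, with q in Å⁻¹.

A Bragg peak at detector position r defines a unit scattering direction
``s = r/|r|``; its reciprocal vector is ``q = (s - z_hat)/lambda``, which
lies on the Ewald sphere of radius 1/λ centred at ``-z_hat/λ``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Planck constant times speed of light, in keV·Å.
HC_KEV_ANGSTROM = 12.39842

_Z = np.array([0.0, 0.0, 1.0])


class GeometryError(ValueError):
    """Invalid experiment geometry or peak input."""


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength in Å for a photon energy in keV (λ = hc/E)."""
    if not energy_kev > 0:
        raise GeometryError(f"photon energy must be > 0 keV, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


@dataclass(frozen=True)
class ExperimentGeometry:
    """Single flat-panel geometry, detector perpendicular to the beam.

    Parameters
    ----------
    detector_distance : float
        Sample-to-detector distance in metres.
    pixel_size : float
        Pixel pitch in metres (square pixels).
    photon_energy : float
        Photon energy in keV.
    beam_center : (float, float)
        Beam position on the detector in pixels, (fast, slow).
    max_scattering_angle : float or None
        Acceptance-cone half-opening 2θ_max in degrees; used by the
        simulator to bound which reflections can be recorded.
    """

    detector_distance: float
    pixel_size: float
    photon_energy: float
    beam_center: tuple[float, float] = (0.0, 0.0)
    max_scattering_angle: float | None = None

    def __post_init__(self) -> None:
        for name in ("detector_distance", "pixel_size", "photon_energy"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def wavelength(self) -> float:
        """Wavelength in Å, derived from the photon energy."""
        return wavelength_from_energy(self.photon_energy)

    @property
    def q_max(self) -> float | None:
        """Largest reachable |q| (Å⁻¹) given the acceptance cone, or None."""
        if self.max_scattering_angle is None:
            return None
        return 2.0 * np.sin(np.radians(self.max_scattering_angle) / 2.0) / self.wavelength


@dataclass(frozen=True)
class DetectorPeak:
    """A found Bragg peak on the detector (positions in pixels)."""

    fast: float
    slow: float
    intensity: float = 0.0
    snr: float = 0.0
    resolution: float | None = None  # d-spacing in Å, if known

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise GeometryError(f"peak intensity must be >= 0, got {self.intensity}")
        if self.snr < 0:
            raise GeometryError(f"peak SNR must be >= 0, got {self.snr}")


@dataclass(frozen=True)
class ReciprocalPeak:
    """An observed peak lifted to a 3-vector on the Ewald sphere (Å⁻¹)."""

    q: np.ndarray
    q_length: float
    resolution: float  # 1/|q| in Å; inf for the 000 reflection
    source_peak: DetectorPeak | None = field(default=None, compare=False)


def _lab_positions(fast: np.ndarray, slow: np.ndarray, geom: ExperimentGeometry) -> np.ndarray:
    """Lab-frame positions (m) of pixel coordinates, shape (..., 3)."""
    x = (np.asarray(fast, dtype=float) - geom.beam_center[0]) * geom.pixel_size
    y = (np.asarray(slow, dtype=float) - geom.beam_center[1]) * geom.pixel_size
    z = np.full_like(x, geom.detector_distance)
    return np.stack([x, y, z], axis=-1)


def lift_to_reciprocal(fast, slow, geom: ExperimentGeometry) -> np.ndarray:
    """Vectorized Ewald lifting of pixel coordinates to q-vectors (Å⁻¹)."""
    r = _lab_positions(fast, slow, geom)
    s = r / np.linalg.norm(r, axis=-1, keepdims=True)
    return (s - _Z) / geom.wavelength


def peak_to_reciprocal(peak: DetectorPeak, geom: ExperimentGeometry) -> ReciprocalPeak:
    """Lift a detector peak onto the Ewald sphere.

    A peak exactly at the beam center yields q = 0 (the 000 reflection,
    resolution = inf); it is legal here and excluded from pair selection
    downstream.
    """
    q = lift_to_reciprocal(peak.fast, peak.slow, geom)
    q_length = float(np.linalg.norm(q))
    resolution = 1.0 / q_length if q_length > 0 else np.inf
    return ReciprocalPeak(q=q, q_length=q_length, resolution=resolution, source_peak=peak)


def peaks_to_reciprocal(peaks, geom: ExperimentGeometry) -> list[ReciprocalPeak]:
    """Lift a list of :class:`DetectorPeak` to reciprocal space."""
    return [peak_to_reciprocal(p, geom) for p in peaks]


def project_to_detector(q: np.ndarray, geom: ExperimentGeometry):
    """Project q-vectors (..., 3) onto the detector plane.

    Returns ``(positions, visible)`` where positions has shape (..., 2)
    in (fast, slow) pixels and ``visible`` is False where the diffracted
    ray ``s = λq + z_hat`` does not travel toward the detector
    (``s_z <= 0``); such positions are NaN, not an exception.
    """
    q = np.asarray(q, dtype=float)
    s = geom.wavelength * q + _Z
    sz = s[..., 2]
    visible = sz > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = geom.detector_distance / sz
        x = s[..., 0] * t
        y = s[..., 1] * t
    fast = x / geom.pixel_size + geom.beam_center[0]
    slow = y / geom.pixel_size + geom.beam_center[1]
    pos = np.stack([fast, slow], axis=-1)
    pos[~visible] = np.nan
    return pos, visible


def project_reciprocal_to_detector(q: np.ndarray, geom: ExperimentGeometry):
    """Single-vector convenience wrapper around :func:`project_to_detector`.

    Returns an array (fast, slow) in pixels, or ``None`` when the
    diffracted ray cannot intersect the detector (out-of-detector flag).
    """
    pos, visible = project_to_detector(np.asarray(q, dtype=float), geom)
    if not bool(np.all(visible)):
        return None
    return pos


def scattering_angle(q_length: float, wavelength: float) -> float:
    """Full scattering angle 2θ (deg) from |q| = 2 sin θ/λ."""
    return 2.0 * np.degrees(np.arcsin(np.clip(q_length * wavelength / 2.0, -1.0, 1.0)))
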
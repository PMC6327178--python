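"""Readers and writers for the on-disk formats.

Peak lists are plain text, one file per pattern::

    # camera_length_m = 0.07
    # photon_energy_keV = 9.61
    # fast_px  slow_px  intensity_ADU  snr  [resolution_A]
    12.0  -340.0  152.0  6.1  2.95

Cells and geometry are key-value text files; PDB CRYST1 records are
read via gemmi.  Solutions are JSON-lines (one record per pattern) plus
a TSV summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .geometry import DetectorPeak, ExperimentGeometry
from .indexer import IndexingSolution
from .lattice import CENTERINGS, UnitCell
from .simulate import SimulatedPattern, euler_angles

log = logging.getLogger("snapindex")


class PeakListError(ValueError):
    """Unreadable, empty or inconsistent peak-list file."""


class ConfigError(ValueError):
    """Malformed cell/geometry/config file."""


# ---------------------------------------------------------------- peak lists

_GEOM_HEADER_KEYS = {"camera_length_m", "photon_energy_keV"}


def read_peak_list(path) -> tuple[list[DetectorPeak], dict]:
    """Read a peak list; returns (peaks, geometry header overrides).

    ``#``-prefixed ``key = value`` headers are captured (camera length,
    photon energy).  Malformed or invariant-violating rows are dropped
    with a logged warning carrying the line number; a file with no valid
    peak rows is an error.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:
        raise PeakListError(f"cannot read peak list {path}: {e}") from e
    peaks: list[DetectorPeak] = []
    overrides: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key in _GEOM_HEADER_KEYS:
                    v = float(val.strip())
                    if key in overrides and overrides[key] != v:
                        raise PeakListError(
                            f"{path}:{lineno}: conflicting header value for {key}"
                        )
                    overrides[key] = v
            continue
        fields = line.split()
        if len(fields) not in (4, 5):
            log.warning("%s:%d: malformed peak row (%d fields), skipped", path, lineno, len(fields))
            continue
        try:
            vals = [float(x) for x in fields]
        except ValueError:
            log.warning("%s:%d: non-numeric peak row, skipped", path, lineno)
            continue
        try:
            peaks.append(
                DetectorPeak(
                    fast=vals[0],
                    slow=vals[1],
                    intensity=vals[2],
                    snr=vals[3],
                    resolution=vals[4] if len(vals) == 5 else None,
                )
            )
        except ValueError as e:
            log.warning("%s:%d: invalid peak (%s), skipped", path, lineno, e)
    if not peaks:
        raise PeakListError(f"no-valid-peaks: {path} contains no valid peak rows")
    return peaks, overrides


def write_peak_list(peaks, path, geom: ExperimentGeometry | None = None) -> None:
    """Write a peak list, embedding the geometry headers when given."""
    lines = []
    if geom is not None:
        lines.append(f"# camera_length_m = {geom.detector_distance!r}")
        lines.append(f"# photon_energy_keV = {geom.photon_energy!r}")
    lines.append("# fast_px slow_px intensity_ADU snr resolution_A")
    for p in peaks:
        res = "" if p.resolution is None else f" {p.resolution:.6g}"
        lines.append(f"{p.fast:.4f} {p.slow:.4f} {p.intensity:.4f} {p.snr:.4f}{res}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- cells

_CELL_KEYS = ("a_A", "b_A", "c_A", "alpha_deg", "beta_deg", "gamma_deg")


def _read_kv(path) -> dict[str, str]:
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_cell_file(path) -> UnitCell:
    """Read a key-value cell file (or a PDB file via its CRYST1 record)."""
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent", ".cif"):
        return read_cryst1(path)
    kv = _read_kv(path)
    missing = [k for k in _CELL_KEYS if k not in kv]
    if missing:
        raise ConfigError(f"{path}: missing cell keys {missing}")
    centering = kv.get("centering", "P").upper()
    if centering not in CENTERINGS:
        raise ConfigError(f"{path}: unknown centering {centering!r}")
    vals = [float(kv[k]) for k in _CELL_KEYS]
    return UnitCell(*vals, centering=centering)


def write_cell_file(cell: UnitCell, path) -> None:
    kv = dict(zip(_CELL_KEYS, (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)))
    lines = [f"{k} = {v!r}" for k, v in kv.items()] + [f"centering = {cell.centering}"]
    Path(path).write_text("\n".join(lines) + "\n")


def read_cryst1(path) -> UnitCell:
    """Unit cell from a PDB/mmCIF structure file's cell record.

    Centering is taken from the first letter of the space-group symbol
    when present; it remains an explicit, overridable input elsewhere.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    c = st.cell
    if not c.a > 0:
        raise ConfigError(f"{path}: no usable cell record")
    centering = "P"
    if st.spacegroup_hm:
        first = st.spacegroup_hm.strip()[0].upper()
        if first in CENTERINGS:
            centering = first
    return UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma, centering)


# ---------------------------------------------------------------- geometry

def read_geometry_file(path, overrides: dict | None = None) -> ExperimentGeometry:
    """Key-value geometry reader; peak-list header overrides win."""
    kv = _read_kv(path)
    overrides = overrides or {}

    def get(key, default=None):
        if key in kv:
            return float(kv[key])
        if default is None:
            raise ConfigError(f"{path}: missing geometry key {key}")
        return default

    distance = float(overrides.get("camera_length_m", get("distance_m")))
    energy = float(overrides.get("photon_energy_keV", get("photon_energy_keV")))
    return ExperimentGeometry(
        detector_distance=distance,
        pixel_size=get("pixel_size_m"),
        photon_energy=energy,
        beam_center=(get("beam_center_fs_px", 0.0), get("beam_center_ss_px", 0.0)),
        max_scattering_angle=(
            float(kv["max_scattering_angle_deg"]) if "max_scattering_angle_deg" in kv else None
        ),
    )


def write_geometry_file(geom: ExperimentGeometry, path) -> None:
    kv = {
        "distance_m": geom.detector_distance,
        "pixel_size_m": geom.pixel_size,
        "photon_energy_keV": geom.photon_energy,
        "beam_center_fs_px": geom.beam_center[0],
        "beam_center_ss_px": geom.beam_center[1],
    }
    if geom.max_scattering_angle is not None:
        kv["max_scattering_angle_deg"] = geom.max_scattering_angle
    Path(path).write_text("\n".join(f"{k} = {v!r}" for k, v in kv.items()) + "\n")


# ---------------------------------------------------------------- solutions

def solution_to_record(
    solution: IndexingSolution, pattern_id, misorientation_to_truth: float | None = None
) -> dict:
    """Flatten an :class:`IndexingSolution` into a JSON-able record."""
    rec = {
        "pattern_id": pattern_id,
        "accepted": bool(solution.accepted),
        "reason": solution.reason,
        "n_matched": int(solution.n_matched),
        "match_fraction": float(solution.match_fraction),
        "rms_dq": None if not np.isfinite(solution.rms_dq) else float(solution.rms_dq),
        "pool_support": int(solution.pool_support),
        "n_pools": int(solution.n_pools),
        "match_threshold": None
        if not np.isfinite(solution.match_threshold)
        else float(solution.match_threshold),
    }
    if solution.orientation is not None:
        rec["orientation"] = [round(float(x), 12) for x in solution.orientation.ravel()]
        rec["euler_zyz_deg"] = [round(float(x), 8) for x in euler_angles(solution.orientation)]
    if solution.oriented_basis is not None:
        rec["oriented_basis"] = [round(float(x), 12) for x in solution.oriented_basis.ravel()]
    if solution.hkl is not None:
        rec["assignments"] = [
            {
                "peak": i,
                "h": int(h[0]),
                "k": int(h[1]),
                "l": int(h[2]),
                "dist": round(float(d), 12),
                "matched": bool(m),
            }
            for i, (h, d, m) in enumerate(
                zip(solution.hkl, solution.match_dist, solution.matched)
            )
        ]
    if misorientation_to_truth is not None:
        rec["misorientation_deg"] = round(float(misorientation_to_truth), 8)
    if solution.params is not None:
        p = asdict(solution.params)
        p["match_fraction_gates"] = [
            [None if not np.isfinite(a) else a, b] for a, b in p["match_fraction_gates"]
        ]
        rec["params"] = p
    return rec


def write_solutions(records: list[dict], path, append: bool = False) -> None:
    """Write solution records as JSON-lines (optionally appending)."""
    mode = "a" if append else "w"
    try:
        with open(path, mode) as f:
            for rec in records:
                f.write(json.dumps(rec, sort_keys=True) + "\n")
    except OSError as e:
        raise OSError(f"cannot write solutions to {path}: {e}") from e


def read_solutions(path) -> list[dict]:
    try:
        with open(path) as f:
            return [json.loads(line) for line in f if line.strip()]
    except OSError as e:
        raise OSError(f"cannot read solutions from {path}: {e}") from e


def write_summary_tsv(records: list[dict], path) -> None:
    """One-row-per-pattern TSV; misorientation column only with truth."""
    import pandas as pd

    cols = ["pattern_id", "accepted", "reason", "n_matched", "match_fraction", "rms_dq"]
    if any("misorientation_deg" in r for r in records):
        cols.append("misorientation_deg")
    df = pd.DataFrame([{c: r.get(c) for c in cols} for r in records])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- manifests

def write_truth_manifest(patterns: list[SimulatedPattern], path) -> None:
    """Ground-truth JSON-lines manifest for a simulated pattern set."""
    with open(path, "w") as f:
        for pat in patterns:
            c = pat.true_cell
            rec = {
                "pattern_id": pat.pattern_id,
                "euler_zyz_deg": [float(x) for x in pat.true_euler],
                "orientation": [float(x) for x in pat.true_orientation.ravel()],
                "cell": [c.a, c.b, c.c, c.alpha, c.beta, c.gamma],
                "centering": c.centering,
                "hkl": pat.true_indices.tolist(),
                "excitation_errors": [float(z) for z in pat.excitation_errors],
                "peak_gain": float(pat.peak_gain),
            }
            f.write(json.dumps(rec, sort_keys=True) + "\n")


def load_run_config(path) -> dict:
    """YAML run-configuration loader (flat key-value layering source)."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: run config must be a mapping")
    return data
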
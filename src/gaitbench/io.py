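"""File I/O: marker files (TRC, CSV), trajectory/metric exports, configs.

Internal units are strictly SI (m, kg, s, rad); unit conversion happens only
at these boundaries and only when the file declares its units — readers
reject files with missing or unknown unit metadata rather than guessing.
C3D input is not supported by this build (binary format); export your trial
to TRC or CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import IOFormatError, UnsupportedFormatError, ValidationError
from .markerik import MarkerFrame

__all__ = [
    "read_markers", "write_trc", "write_markers_csv", "read_forceplate_csv",
    "read_ground_reference_csv", "write_ground_reference_csv",
    "read_events_csv", "write_events_csv",
    "write_metrics_report", "write_run_metadata", "load_yaml_config",
]

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}


def _unit_scale(units: str, path) -> float:
    if units not in _UNIT_SCALE:
        raise IOFormatError(f"{path}: unknown or missing length unit {units!r}")
    return _UNIT_SCALE[units]


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def read_markers(path, format: Optional[str] = None) -> list:
    """Read a marker trajectory file into a list of :class:`MarkerFrame`.

    ``format`` is one of ``trc``, ``csv`` (or inferred from the suffix);
    C3D is recognised but unsupported in this build.  Positions are
    converted to metres using the file's declared units; frames must be
    strictly time-ordered.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "c3d":
        raise UnsupportedFormatError(
            f"{path}: C3D is not supported by this build; export to TRC or CSV"
        )
    if fmt == "trc":
        return _read_trc(path)
    if fmt == "csv":
        return _read_markers_csv(path)
    raise IOFormatError(f"{path}: unknown marker format {fmt!r}")


def _check_monotone(times, path):
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise IOFormatError(f"{path}: timestamps are not strictly increasing")


def _read_trc(path: Path) -> list:
    lines = path.read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise IOFormatError(f"{path}: not a TRC file")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    meta = dict(zip(header_keys, header_vals))
    scale = _unit_scale(meta.get("Units", ""), path)
    names = [n for n in lines[3].split("\t")[2:] if n]
    frames = []
    times = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        t = float(parts[1])
        markers = {}
        valid = {}
        for i, name in enumerate(names):
            cols = parts[2 + 3 * i:5 + 3 * i]
            if len(cols) < 3 or any(c.strip() == "" for c in cols):
                valid[name] = False
                markers[name] = np.full(3, np.nan)
            else:
                markers[name] = np.array([float(c) for c in cols]) * scale
        frames.append(MarkerFrame(time=t, markers=markers, valid=valid))
        times.append(t)
    _check_monotone(times, path)
    return frames


def write_trc(path, frames: Sequence[MarkerFrame], rate: Optional[float] = None):
    """Write marker frames as a TRC file (units: m)."""
    path = Path(path)
    names = list(frames[0].markers)
    if rate is None:
        rate = 1.0 / (frames[1].time - frames[0].time) if len(frames) > 1 else 100.0
    out = []
    out.append(f"PathFileType\t4\t(X/Y/Z)\t{path.name}")
    out.append("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
               "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames")
    out.append(f"{rate:g}\t{rate:g}\t{len(frames)}\t{len(names)}\tm\t"
               f"{rate:g}\t1\t{len(frames)}")
    out.append("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t")
    comp = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names)))
    out.append(f"\t\t{comp}")
    for i, fr in enumerate(frames):
        cells = [str(i + 1), repr(float(fr.time))]
        for n in names:
            if fr.valid.get(n, True):
                cells += [repr(float(c)) for c in fr.markers[n]]
            else:
                cells += ["", "", ""]
        out.append("\t".join(cells))
    path.write_text("\n".join(out) + "\n")


def _read_markers_csv(path: Path) -> list:
    text = path.read_text().splitlines()
    units = None
    header_at = 0
    for i, ln in enumerate(text):
        if ln.startswith("#"):
            if "units:" in ln:
                units = ln.split("units:")[1].strip()
            header_at = i + 1
        else:
            break
    if units is None:
        raise IOFormatError(f"{path}: missing '# units: <m|mm|cm>' metadata line")
    scale = _unit_scale(units, path)
    reader = csv.DictReader(text[header_at:])
    names = sorted({c[:-2] for c in reader.fieldnames if c.endswith("_x")})
    frames, times = [], []
    for row in reader:
        t = float(row["time"])
        markers, valid = {}, {}
        for n in names:
            try:
                markers[n] = np.array([float(row[f"{n}_{ax}"]) for ax in "xyz"]) * scale
                valid[n] = True
            except (ValueError, KeyError):
                markers[n] = np.full(3, np.nan)
                valid[n] = False
        frames.append(MarkerFrame(time=t, markers=markers, valid=valid))
        times.append(t)
    _check_monotone(times, path)
    return frames


def write_markers_csv(path, frames: Sequence[MarkerFrame]):
    path = Path(path)
    names = list(frames[0].markers)
    with path.open("w", newline="") as fh:
        fh.write("# units: m\n")
        writer = csv.writer(fh)
        writer.writerow(["time"] + [f"{n}_{ax}" for n in names for ax in "xyz"])
        for fr in frames:
            row = [repr(float(fr.time))]
            for n in names:
                row += [repr(float(c)) for c in fr.markers[n]]
            writer.writerow(row)


def read_forceplate_csv(path):
    """Read force-plate traces: columns time, cop_x, cop_y, f_z (SI units).

    Returns ``(times, cop, fz)`` with cop an (n, 2) array (NaN rows where
    the plate is unloaded).
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    for col in ("time", "cop_x", "cop_y", "f_z"):
        if col not in df.columns:
            raise IOFormatError(f"{path}: missing column {col!r}")
    times = df["time"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise IOFormatError(f"{path}: timestamps are not strictly increasing")
    return times, df[["cop_x", "cop_y"]].to_numpy(float), df["f_z"].to_numpy(float)


# ---------------------------------------------------------------------------
# trajectories, events, reports
# ---------------------------------------------------------------------------


def write_ground_reference_csv(path, traj):
    import pandas as pd

    df = pd.DataFrame({
        "time": traj.times,
        "com_x": traj.r_com[:, 0], "com_y": traj.r_com[:, 1], "com_z": traj.r_com[:, 2],
        "comdot_x": traj.rdot_com[:, 0], "comdot_y": traj.rdot_com[:, 1],
        "comdot_z": traj.rdot_com[:, 2],
        "cop_x": traj.r_cop[:, 0], "cop_y": traj.r_cop[:, 1],
        "icap_x": traj.r_icap[:, 0], "icap_y": traj.r_icap[:, 1],
        "com_height": traj.com_height,
    })
    df.to_csv(path, index=False)


def read_ground_reference_csv(path):
    import pandas as pd

    from .metrics import GroundReferenceTrajectory

    df = pd.read_csv(path)
    return GroundReferenceTrajectory(
        times=df["time"].to_numpy(),
        r_com=df[["com_x", "com_y", "com_z"]].to_numpy(),
        rdot_com=df[["comdot_x", "comdot_y", "comdot_z"]].to_numpy(),
        r_cop=df[["cop_x", "cop_y"]].to_numpy(),
        r_icap=df[["icap_x", "icap_y"]].to_numpy(),
        com_height=df["com_height"].to_numpy(),
    )


def write_events_csv(path, events):
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["event", "side", "time"])
        for kind in ("heel_strikes", "toe_strikes", "toe_offs", "heel_offs"):
            for side in ("left", "right"):
                for t in getattr(events, kind)[side]:
                    writer.writerow([kind[:-1], side, repr(float(t))])


def read_events_csv(path):
    from .metrics import GaitEvents

    events = GaitEvents()
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            getattr(events, row["event"] + "s")[row["side"]].append(float(row["time"]))
    return events


def write_metrics_report(out_dir, record, placements=None, extra_meta=None):
    """Write the per-event metrics CSV and the JSON summary.

    The CSV mirrors the per-heel-strike table (side, time, E'_res plus ICaP
    offsets when foot placements are available); the JSON carries left/right
    means, the stride average, the asymmetry ratio and the configuration
    echo.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    place_by_key = {}
    for p in (placements.steps if placements else []):
        place_by_key[(round(p.time, 6), p.side)] = p
    with (out_dir / "residual_orbital_energy.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["side", "time_s", "E_res_per_s2",
                         "icap_anterior_offset_m", "icap_medial_offset_m"])
        for e in record.events:
            p = place_by_key.get((round(e.time, 6), e.side))
            writer.writerow([
                e.side, f"{e.time:.6f}", f"{e.value:.6f}",
                f"{p.anterior_offset:.6f}" if p else "",
                f"{p.medial_offset:.6f}" if p else "",
            ])
    left, right = record.side_mean("left"), record.side_mean("right")
    summary = {
        "E_res_left_mean": left,
        "E_res_right_mean": right,
        "E_res_stride_average": record.stride_average,
        "E_res_asymmetry_ratio": left / right if right else None,
        "norm_length_m": record.norm_length,
        "omega0_mode": record.omega0_mode,
        "g": record.g,
    }
    if extra_meta:
        summary["config"] = extra_meta
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def write_run_metadata(out_dir, config: dict):
    """Echo the effective configuration (plus version/seed) into a bundle."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {"gaitbench_version": __version__, **config}
    (out_dir / "run_config.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))


def load_yaml_config(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise IOFormatError(f"{path}: expected a YAML mapping")
    return doc
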
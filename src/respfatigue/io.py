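"""CSV input/output for signals, beat annotations, masks and fatigue series.

Signal files are two-column CSV (``time_s,value_uV``) with a header line and
a leading comment carrying the sampling rate and units, validated on read.
Beat annotations are one 0-based sample index per line; gate masks one 0/1
per sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fatigue import FatigueSeries
from .qrs import QrsAnnotation
from .removal import GateMask
from .signal import SampledSignal


def write_signal_csv(path: str | Path, x: SampledSignal) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs_hz={x.fs:g} units=uV\n")
        fh.write("time_s,value_uV\n")
        for t, v in zip(x.times, x.samples):
            fh.write(f"{t:.9g},{v:.9g}\n")


def read_signal_csv(path: str | Path) -> SampledSignal:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#") or "fs_hz=" not in header:
            raise ValueError(f"{path}: missing '# fs_hz=... units=uV' header")
        fs = float(header.split("fs_hz=")[1].split()[0])
        cols = fh.readline().strip()
        if cols != "time_s,value_uV":
            raise ValueError(f"{path}: unexpected column header {cols!r}")
        data = np.loadtxt(fh, delimiter=",")
    data = np.atleast_2d(data)
    t0 = float(data[0, 0]) if data.size else 0.0
    return SampledSignal(data[:, 1], fs, t0)


def write_beats_csv(path: str | Path, qrs: QrsAnnotation) -> None:
    idx = qrs.indices()
    Path(path).write_text("".join(f"{i}\n" for i in idx))


def read_beats_csv(path: str | Path, fs: float) -> QrsAnnotation:
    idx = np.loadtxt(path, dtype=float, ndmin=1)
    return QrsAnnotation(np.asarray(idx) / fs, fs)


def write_mask_csv(path: str | Path, mask: GateMask) -> None:
    Path(path).write_text("".join(f"{int(v)}\n" for v in mask.values))


def read_mask_csv(path: str | Path, fs: float) -> GateMask:
    vals = np.loadtxt(path, dtype=int, ndmin=1)
    return GateMask(vals.astype(bool), fs)


def write_fatigue_csv(path: str | Path, series: FatigueSeries) -> None:
    """(time_s, value) at 8 Hz; missing values as empty field."""
    with Path(path).open("w") as fh:
        fh.write(f"# fd={series.fd} flavor={series.flavor}\n")
        fh.write("time_s,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.9g},{'' if not np.isfinite(v) else format(v, '.9g')}\n")


def read_fatigue_csv(path: str | Path) -> FatigueSeries:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        fd = header.split("fd=")[1].split()[0] if "fd=" in header else "MNF"
        flavor = header.split("flavor=")[1].split()[0] if "flavor=" in header else "raw"
        fh.readline()
        times, values = [], []
        for line in fh:
            t, _, v = line.strip().partition(",")
            times.append(float(t))
            values.append(float(v) if v else np.nan)
    return FatigueSeries(np.array(times), np.array(values), fd=fd, flavor=flavor)


def write_eval_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
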
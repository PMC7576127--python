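"""Readers and writers for traces, spike trains, datasets and reports.

Delimited text (comma/tab/whitespace autodetected, ``#`` comments ignored)
for traces and spike times, an HDF5 container for multi-cell datasets, and
JSON for evaluation reports.
"""

from __future__ import annotations

import json
import os
import warnings
from typing import Optional, Sequence

import h5py
import numpy as np

from .types import CalciumTrace, EvalReport, SpikeTrain

__all__ = [
    "read_trace",
    "write_trace",
    "read_spikes",
    "write_spikes",
    "read_report",
    "write_report",
    "read_dataset",
    "write_dataset",
]

# relative tolerance on inter-frame interval spread when inferring the rate
_UNIFORMITY_RTOL = 1e-3

_HDF5_EXT = {".h5", ".hdf5", ".hdf"}


def _sniff_delimiter(path: str) -> Optional[str]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "," in line:
                return ","
            if "\t" in line:
                return "\t"
            return None  # whitespace
    return None


def _load_delimited(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path)
    try:
        data = np.loadtxt(path, comments="#", delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in {path!r}: {exc}") from None
    return data


def read_trace(path: str, sampling_rate: Optional[float] = None,
               fmt: Optional[str] = None) -> CalciumTrace:
    """Read a fluorescence trace from delimited text or an HDF5 container.

    Delimited files carry either (time, value) columns, or a single value
    column with ``sampling_rate`` given by the caller.  When a time column is
    present, the rate is inferred as 1 / median inter-frame interval and
    timestamp uniformity is verified to a relative tolerance of 1e-3.
    """
    if fmt is None:
        fmt = "hdf5" if os.path.splitext(path)[1].lower() in _HDF5_EXT else "delimited"
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            values = np.asarray(f["values"])
            rate = float(f.attrs["sampling_rate"])
            start = float(f.attrs.get("start_time", 0.0))
        return CalciumTrace(values, rate, start)

    data = _load_delimited(path)
    if data.shape[0] < 2:
        raise ValueError("trace file has fewer than 2 frames")
    if data.shape[1] == 1:
        if sampling_rate is None:
            raise ValueError("single-column trace file needs a declared sampling rate")
        return CalciumTrace(data[:, 0], sampling_rate)
    times, values = data[:, 0], data[:, 1]
    dt = np.diff(times)
    med = float(np.median(dt))
    if med <= 0:
        raise ValueError("timestamps must be strictly increasing")
    if np.max(np.abs(dt - med)) > _UNIFORMITY_RTOL * med:
        raise ValueError("non-uniform timestamps beyond tolerance")
    return CalciumTrace(values, 1.0 / med, start_time=float(times[0]))


def write_trace(path: str, trace: CalciumTrace, fmt: Optional[str] = None) -> None:
    if fmt is None:
        fmt = "hdf5" if os.path.splitext(path)[1].lower() in _HDF5_EXT else "delimited"
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=trace.values)
            f.attrs["sampling_rate"] = trace.sampling_rate
            f.attrs["start_time"] = trace.start_time
        return
    with open(path, "w") as fh:
        fh.write("# time_s,dff\n")
        for t, v in zip(trace.frame_times(), trace.values):
            fh.write(f"{t:.17g},{v:.17g}\n")


def read_spikes(path: str) -> SpikeTrain:
    """Read spike times (one per line, or the first delimited column)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.replace(",", " ").split()[0]
            try:
                rows.append(float(tok))
            except ValueError:
                raise ValueError(f"non-numeric entry {tok!r} in {path!r}") from None
    times = np.asarray(rows, dtype=float)
    if times.size and np.any(times < 0):
        raise ValueError("negative spike times")
    if times.size > 1 and np.any(np.diff(times) < 0):
        warnings.warn(f"spike file {path!r} was unsorted; sorting", stacklevel=2)
        times = np.sort(times)
    return SpikeTrain(times)


def write_spikes(path: str, spikes: SpikeTrain) -> None:
    with open(path, "w") as fh:
        fh.write("# spike_time_s\n")
        for t in spikes.times:
            fh.write(f"{t:.17g}\n")


def write_report(path: str, report: EvalReport) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def read_report(path: str) -> EvalReport:
    with open(path) as fh:
        return EvalReport.from_dict(json.load(fh))


def write_dataset(path: str, cells: Sequence[tuple]) -> None:
    """Write a multi-cell dataset: (trace, spikes-or-None) per cell, HDF5."""
    with h5py.File(path, "w") as f:
        for i, (trace, spikes) in enumerate(cells):
            grp = f.create_group(f"cells/cell{i:03d}")
            grp.create_dataset("values", data=trace.values)
            grp.attrs["sampling_rate"] = trace.sampling_rate
            grp.attrs["start_time"] = trace.start_time
            if spikes is not None:
                grp.create_dataset("spike_times", data=spikes.times)


def read_dataset(path: str) -> list:
    """Read a multi-cell dataset written by :func:`write_dataset`."""
    cells = []
    with h5py.File(path, "r") as f:
        for name in sorted(f["cells"]):
            grp = f["cells"][name]
            trace = CalciumTrace(np.asarray(grp["values"]),
                                 float(grp.attrs["sampling_rate"]),
                                 float(grp.attrs.get("start_time", 0.0)))
            spikes = (SpikeTrain(np.asarray(grp["spike_times"]))
                      if "spike_times" in grp else None)
            cells.append((trace, spikes))
    return cells
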
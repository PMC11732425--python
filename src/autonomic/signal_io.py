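"""Reading and writing ECG signals, beat annotations and time-resolved outputs.

One convention rules the whole package: **time is in seconds everywhere**.
Milliseconds are accepted only at the I/O boundary (``read_beats(units="ms")``)
and converted immediately, so downstream arithmetic never has to guess units.

Supported on-disk formats
-------------------------
* plain CSV/TSV (comma separated, ``.`` decimal, optional ``# key=value``
  metadata lines, header row written on output and optional on input);
* single-segment WFDB records (``.hea`` + ``.dat``, 16-bit format only),
  enough to round-trip the signals written by :mod:`autonomic.synth`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EcgSignal",
    "BeatAnnotations",
    "SignalIOError",
    "read_ecg",
    "write_ecg_csv",
    "read_wfdb",
    "write_wfdb",
    "read_beats",
    "write_timeseries",
    "read_timeseries",
]


class SignalIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class EcgSignal:
    """A single-channel ECG trace.

    Parameters
    ----------
    samples : ndarray
        Amplitudes (mV or arbitrary units), one channel.
    fs : float
        Sampling frequency in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise SignalIOError(f"sampling frequency must be > 0, got {self.fs}")
        if samples.size == 0:
            raise SignalIOError("ECG signal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            bad = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise SignalIOError(f"non-finite ECG sample at row {bad}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BeatAnnotations:
    """R-peak occurrence times in seconds, strictly increasing."""

    r_times: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_times, dtype=float).ravel()
        object.__setattr__(self, "r_times", r)
        if r.size and not np.all(np.isfinite(r)):
            raise SignalIOError("beat times must be finite")
        if r.size > 1 and np.any(np.diff(r) <= 0):
            raise SignalIOError("beat times must be strictly increasing")
        if self.labels is not None and len(self.labels) != r.size:
            raise SignalIOError("labels must align one-to-one with beat times")

    @property
    def n(self) -> int:
        return self.r_times.size


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------

def _read_meta_lines(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_csv_table(path: Path, sep: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV with optional '#' metadata lines and optional header."""
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # Decide whether the first non-comment line is a header.
    with open(path) as fh:
        first = None
        for line in fh:
            if not line.startswith("#") and line.strip():
                first = line
                break
    if first is None:
        return pd.DataFrame()
    tokens = [t.strip() for t in first.rstrip("\n").split(sep)]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = None if all(_numeric(t) for t in tokens if t) else 0
    return pd.read_csv(path, sep=sep, comment="#", header=header)


# ---------------------------------------------------------------------------
# ECG reading / writing
# ---------------------------------------------------------------------------

def read_ecg(
    path: str | Path,
    format: str | None = None,
    fs_override: float | None = None,
    channel: int = 0,
) -> EcgSignal:
    """Read an ECG record from a WFDB header or a CSV/TSV sample table.

    ``format`` is inferred from the suffix (``.hea`` -> wfdb) when omitted.
    For CSV, the sampling frequency must come from ``fs_override`` or from a
    ``# fs=<Hz>`` metadata line.  Multi-channel tables use column ``channel``
    (default: first).
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    if format is None:
        format = "wfdb" if path.suffix.lower() in {".hea", ".dat"} else "csv"
    if format == "wfdb":
        return read_wfdb(path, channel=channel)
    if format != "csv":
        raise SignalIOError(f"unknown ECG format {format!r}")

    meta = _read_meta_lines(path)
    fs = fs_override if fs_override is not None else _float_or_none(meta.get("fs"))
    if fs is None:
        raise SignalIOError(
            f"{path}: sampling frequency unknown; pass fs_override or add a '# fs=' line"
        )
    t0 = _float_or_none(meta.get("t0")) or 0.0
    df = _read_csv_table(path)
    if df.shape[1] <= channel:
        raise SignalIOError(f"{path}: channel {channel} not present ({df.shape[1]} columns)")
    col = df.iloc[:, channel]
    samples = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(samples)):
        bad = int(np.flatnonzero(~np.isfinite(samples))[0])
        raise SignalIOError(f"{path}: non-numeric or missing sample at data row {bad}")
    return EcgSignal(samples=samples, fs=float(fs), t0=t0)


def write_ecg_csv(ecg: EcgSignal, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={ecg.fs!r}\n# t0={ecg.t0!r}\n")
        pd.DataFrame({"ecg": ecg.samples}).to_csv(fh, index=False)


def _float_or_none(value: str | None) -> float | None:
    return None if value is None else float(value)


# ---------------------------------------------------------------------------
# Minimal WFDB (single segment, format 16)
# ---------------------------------------------------------------------------

_WFDB_FMT = 16  # 16-bit little-endian two's complement
_WFDB_GAIN = 200.0  # adu per physical unit, the format's customary default


def write_wfdb(ecg: EcgSignal, record_path: str | Path, units: str = "mV") -> None:
    """Write ``<record>.hea`` + ``<record>.dat`` for a single-channel signal."""
    record_path = Path(record_path)
    if record_path.suffix:  # accept "rec", "rec.hea", "rec.dat"
        record_path = record_path.with_suffix("")
    name = record_path.name
    adc = np.round(ecg.samples * _WFDB_GAIN).astype(np.int64)
    if np.any(np.abs(adc) > 32767):
        raise SignalIOError("signal exceeds the 16-bit WFDB range at gain 200")
    adc16 = adc.astype("<i2")
    first = int(adc16[0])
    cksum = int(np.sum(adc16, dtype=np.int64) % 65536)
    if cksum >= 32768:
        cksum -= 65536
    with open(record_path.with_suffix(".hea"), "w") as fh:
        fh.write(f"{name} 1 {ecg.fs:g} {ecg.samples.size}\n")
        fh.write(
            f"{name}.dat {_WFDB_FMT} {_WFDB_GAIN:g}(0)/{units} 16 0 {first} {cksum} 0 ECG\n"
        )
    adc16.tofile(record_path.with_suffix(".dat"))


def read_wfdb(path: str | Path, channel: int = 0) -> EcgSignal:
    """Read a single-segment WFDB record (format 16 only)."""
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise SignalIOError(f"no such header: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_tokens = lines[0].split()
    nsig = int(rec_tokens[1])
    fs = float(rec_tokens[2].split("/")[0]) if len(rec_tokens) > 2 else 250.0
    nsamp = int(rec_tokens[3]) if len(rec_tokens) > 3 else -1
    if channel >= nsig:
        raise SignalIOError(f"channel {channel} not in record with {nsig} signals")
    sig_lines = lines[1 : 1 + nsig]
    dat_names, gains, baselines = [], [], []
    for ln in sig_lines:
        toks = ln.split()
        dat_names.append(toks[0])
        fmt = int(toks[1].split("x")[0].split(":")[0].split("+")[0]) if len(toks) > 1 else 16
        if fmt != _WFDB_FMT:
            raise SignalIOError(f"unsupported WFDB format {fmt} (only 16 supported)")
        gain, baseline = _WFDB_GAIN, 0
        if len(toks) > 2:
            gtok = toks[2].split("/")[0]
            if "(" in gtok:
                gpart, _, bpart = gtok.partition("(")
                gain = float(gpart)
                baseline = int(bpart.rstrip(")"))
            else:
                gain = float(gtok)
                baseline = int(toks[4]) if len(toks) > 4 else 0  # adczero
        if gain == 0:
            gain = _WFDB_GAIN
        gains.append(gain)
        baselines.append(baseline)
    if len(set(dat_names)) != 1:
        raise SignalIOError("multi-file WFDB records are not supported")
    raw = np.fromfile(hea.parent / dat_names[0], dtype="<i2")
    if nsig > 1:
        raw = raw[: (raw.size // nsig) * nsig].reshape(-1, nsig)
        adc = raw[:, channel]
    else:
        adc = raw
    if nsamp > 0:
        adc = adc[:nsamp]
    samples = (adc.astype(float) - baselines[channel]) / gains[channel]
    return EcgSignal(samples=samples, fs=fs, t0=0.0)


# ---------------------------------------------------------------------------
# Beat annotations
# ---------------------------------------------------------------------------

def read_beats(path: str | Path, units: str = "s") -> BeatAnnotations:
    """Read beat occurrence times from a one-column CSV/TSV.

    ``units`` selects the on-disk unit (``"s"`` or ``"ms"``); the returned
    times are always seconds.  Duplicate times are rejected; interbeat
    intervals outside the physiological 0.2--3 s range trigger a warning
    (the classic symptom of a seconds/milliseconds mix-up).
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    if units not in {"s", "ms"}:
        raise SignalIOError(f"units must be 's' or 'ms', got {units!r}")
    df = _read_csv_table(path)
    if df.empty:
        raise SignalIOError(f"{path}: no beat times found")
    times = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise SignalIOError(f"{path}: non-numeric beat time")
    if units == "ms":
        times = times / 1000.0
    times = np.sort(times)
    if times.size > 1 and np.any(np.diff(times) == 0):
        raise SignalIOError(f"{path}: duplicate beat times after sorting")
    if times.size > 1:
        ibi = np.diff(times)
        if np.any((ibi < 0.2) | (ibi > 3.0)):
            warnings.warn(
                f"{path}: interbeat intervals outside [0.2, 3] s; check the units",
                stacklevel=2,
            )
    return BeatAnnotations(r_times=times)


# ---------------------------------------------------------------------------
# Generic time-series round-trip
# ---------------------------------------------------------------------------

def write_timeseries(series, path: str | Path) -> None:
    """Write any package time series (or DataFrame) as CSV.

    Objects exposing ``to_frame()`` (IbiSeries, DescriptorSeries,
    IndexSeries, ...) are serialised with their scalar parameters stored in
    ``# key=value`` metadata lines, so ``read_timeseries`` restores them.
    """
    if hasattr(series, "to_frame"):
        df = series.to_frame()
        meta = dict(getattr(series, "io_meta", dict)())
    elif isinstance(series, pd.DataFrame):
        df, meta = series, {}
    else:
        raise SignalIOError(f"cannot serialise object of type {type(series).__name__}")
    tcol = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(~np.isfinite(tcol)):
        raise SignalIOError("time column must be finite")
    if tcol.size > 1 and np.any(np.diff(tcol) < 0):
        raise SignalIOError("time column must be sorted ascending")
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_timeseries(path: str | Path, cls=None):
    """Read a CSV written by :func:`write_timeseries`.

    Returns ``cls.from_frame(df, meta)`` when a series class is given,
    otherwise the raw DataFrame with metadata in ``df.attrs``.
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    meta: Mapping[str, str] = _read_meta_lines(path)
    df = _read_csv_table(path)
    if cls is not None:
        return cls.from_frame(df, meta)
    df.attrs.update(meta)
    return df
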
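"""From raw ECG to quality-controlled event series.

The chain is: QRS detection (Pan--Tompkins style), interbeat-interval (IBI)
construction anchored at the *closing* beat of each interval, flag-only
screening for timing outliers, and QT-interval extraction by windowed
extremum search around each R-peak.

Misdetection handling is deliberately flag-only: candidates are surfaced
(indices into the IBI series) and the caller decides what to do with them.
``drop_flagged`` is provided as a convenience but is never applied
implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from .signal_io import BeatAnnotations, EcgSignal

__all__ = [
    "IbiSeries",
    "QtSeries",
    "NoBeatsError",
    "detect_rpeaks",
    "build_ibi",
    "flag_misdetections",
    "drop_flagged",
    "detect_qt",
]


class NoBeatsError(ValueError):
    """Raised when no QRS complexes can be found in the signal."""


@dataclass(frozen=True)
class IbiSeries:
    """Interbeat intervals with their anchor times.

    ``t[i]`` is the time of the beat that *closes* interval ``i``
    (``ibi[i] = r_times[i+1] - r_times[i]`` and ``t[i] = r_times[i+1]``),
    which makes trailing sliding windows causal: an interval enters the
    window only once it has actually been observed.
    """

    t: np.ndarray
    ibi: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float).ravel()
        ibi = np.asarray(self.ibi, dtype=float).ravel()
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ibi", ibi)
        if t.size != ibi.size:
            raise ValueError("t and ibi must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("anchor times must be strictly increasing")
        if np.any(ibi <= 0):
            raise ValueError("interbeat intervals must be positive")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def beat_times(self) -> np.ndarray:
        """All beat times, the opening beat of the first interval included."""
        if self.t.size == 0:
            return np.empty(0)
        return np.concatenate(([self.t[0] - self.ibi[0]], self.t))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - (self.t[0] - self.ibi[0])) if self.t.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "ibi": self.ibi})

    def io_meta(self) -> dict:
        return {}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: Mapping[str, str] | None = None) -> "IbiSeries":
        return cls(t=df["t"].to_numpy(float), ibi=df["ibi"].to_numpy(float))


@dataclass(frozen=True)
class QtSeries:
    """QT durations (seconds) aligned with the beats they were measured on."""

    t: np.ndarray
    qt: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float).ravel()
        qt = np.asarray(self.qt, dtype=float).ravel()
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "qt", qt)
        if t.size != qt.size:
            raise ValueError("t and qt must have equal length")

    @property
    def n(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "qt": self.qt})

    def io_meta(self) -> dict:
        return {}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: Mapping[str, str] | None = None) -> "QtSeries":
        return cls(t=df["t"].to_numpy(float), qt=df["qt"].to_numpy(float))


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_rpeaks(ecg: EcgSignal, refractory: float = 0.2) -> BeatAnnotations:
    """Detect R-peaks with a Pan--Tompkins style chain.

    Band-pass 5--15 Hz (zero-phase) -> derivative -> squaring -> 150 ms
    moving-window integration -> adaptive dual threshold with a 200 ms
    refractory period and search-back over long gaps.  Peak locations are
    refined to the extremum of the band-passed ECG near each detection.

    Raises
    ------
    NoBeatsError
        For a flat signal or when no QRS candidate survives thresholding.
    ValueError
        If ``fs < 100`` Hz or the record is shorter than 5 s.
    """
    fs = ecg.fs
    if fs < 100:
        raise ValueError(f"sampling frequency {fs} Hz too low for QRS detection (need >= 100)")
    if ecg.duration < 5.0:
        raise ValueError("record shorter than 5 s; QRS thresholds cannot adapt")
    x = ecg.samples
    if np.ptp(x) == 0:
        raise NoBeatsError("flat signal: no heartbeats present")

    sos = butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    dist = max(1, int(round(refractory * fs)))
    cand, _ = find_peaks(mwi, distance=dist)
    if cand.size == 0:
        raise NoBeatsError("no QRS candidates found")

    head = mwi[: int(2 * fs)]
    spki = 0.25 * float(np.max(head))
    npki = 0.5 * float(np.mean(head))
    accepted: list[int] = []
    rejected: list[int] = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] > thr:
            accepted.append(int(c))
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            rejected.append(int(c))
            npki = 0.125 * mwi[c] + 0.875 * npki
    if not accepted:
        raise NoBeatsError("no QRS candidates above threshold")

    # Search-back: re-admit the strongest rejected candidate inside gaps
    # longer than 1.66x the running RR estimate.
    accepted_arr = np.asarray(accepted)
    if accepted_arr.size > 2 and rejected:
        rr = np.median(np.diff(accepted_arr))
        rejected_arr = np.asarray(rejected)
        filled = list(accepted_arr)
        for lo, hi in zip(accepted_arr[:-1], accepted_arr[1:]):
            if hi - lo > 1.66 * rr:
                inside = rejected_arr[(rejected_arr > lo + dist) & (rejected_arr < hi - dist)]
                if inside.size:
                    filled.append(int(inside[np.argmax(mwi[inside])]))
        accepted_arr = np.sort(np.asarray(filled))

    # Refine each detection to the local extremum of the band-passed ECG;
    # filtfilt is zero-phase so this lands on the R-peak itself.
    half = int(round(0.075 * fs))
    peaks = []
    for c in accepted_arr:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.unique(peaks)

    # Enforce the refractory period, keeping the larger peak of any clash.
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < dist:
            if np.abs(bp[p]) > np.abs(bp[kept[-1]]):
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    r_times = ecg.t0 + np.asarray(kept, dtype=float) / fs
    return BeatAnnotations(r_times=r_times)


# ---------------------------------------------------------------------------
# IBI construction and screening
# ---------------------------------------------------------------------------

def build_ibi(beats: BeatAnnotations) -> IbiSeries:
    """R-to-R durations, each anchored at its closing beat."""
    if beats.n < 2:
        raise ValueError("need at least 2 beats to form an interval")
    r = beats.r_times
    return IbiSeries(t=r[1:], ibi=np.diff(r))


def flag_misdetections(ibi: IbiSeries, threshold_factor: float = 4.0) -> list[int]:
    """Flag intervals whose first difference is a timing outlier.

    Peaks in the derivative of the IBI series are screened against a robust
    scale: ``threshold_factor`` times the (normal-consistent) median absolute
    deviation of the differences.  When the MAD degenerates to zero the mean
    absolute deviation is used instead; if that is also zero the series is
    perfectly regular and nothing is flagged.  The series itself is never
    modified.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    if ibi.n < 3:
        raise ValueError("need at least 3 intervals to screen for misdetections")
    d = np.diff(ibi.ibi)
    centre = np.median(d)
    dev = np.abs(d - centre)
    scale = 1.4826 * np.median(dev)
    if scale == 0:
        scale = float(np.mean(dev))
    if scale == 0:
        return []
    flagged = np.flatnonzero(dev > threshold_factor * scale) + 1
    return sorted(set(int(i) for i in flagged))


def drop_flagged(ibi: IbiSeries, indices) -> IbiSeries:
    """Return a copy of the series without the flagged intervals."""
    keep = np.ones(ibi.n, dtype=bool)
    idx = np.asarray(list(indices), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= ibi.n):
        raise IndexError("flagged index out of range")
    keep[idx] = False
    return IbiSeries(t=ibi.t[keep], ibi=ibi.ibi[keep])


# ---------------------------------------------------------------------------
# QT intervals
# ---------------------------------------------------------------------------

def detect_qt(ecg: EcgSignal, beats: BeatAnnotations) -> QtSeries:
    """Per-beat QT durations from windowed extremum search.

    The Q-peak is the minimum in the 50 ms before the R-peak (half-open at
    R), the T-end the minimum in the 100--500 ms after it (closed window);
    both windows are rounded to the nearest sample.  Beats whose windows
    fall outside the recorded span are dropped.
    """
    fs = ecg.fs
    if fs < 100:
        raise ValueError("sampling frequency too low for QT detection (need >= 100 Hz)")
    x = ecg.samples
    q_back = int(round(0.050 * fs))
    t_lo_off = int(round(0.100 * fs))
    t_hi_off = int(round(0.500 * fs))
    times, qts = [], []
    for r in beats.r_times:
        ridx = int(round((r - ecg.t0) * fs))
        q_lo, q_hi = ridx - q_back, ridx  # [R-50ms, R)
        t_lo, t_hi = ridx + t_lo_off, ridx + t_hi_off  # [R+100ms, R+500ms]
        if q_lo < 0 or t_hi >= x.size or q_hi <= q_lo:
            continue
        q_idx = q_lo + int(np.argmin(x[q_lo:q_hi]))
        t_idx = t_lo + int(np.argmin(x[t_lo : t_hi + 1]))
        times.append(float(r))
        qts.append((t_idx - q_idx) / fs)
    if not times:
        raise ValueError("QT search windows fall outside the signal for every beat")
    return QtSeries(t=np.asarray(times), qt=np.asarray(qts))
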
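"""Time-frequency LF/HF estimation: the spectral comparator to CSI/CPI.

The interbeat-interval (or QT) series is resampled to a uniform 4 Hz grid
with a cubic spline, turned into an analytic signal and passed through a
smoothed pseudo Wigner--Ville distribution (SPWV): the instantaneous
autocorrelation is filtered in the ambiguity (Doppler x lag) domain by a
separable-ellipse exponential kernel

    Phi(nu, tau) = exp{-pi [ (nu/nu0)^2 + (tau * tau0 / 2)^2 ]^(2 lambda) }

where ``nu`` is Doppler frequency in Hz (``nu0`` sets the degree of time
smoothing: slower variations than ~1/nu0 survive) and ``tau0`` is read as
the full frequency-smoothing bandwidth in Hz, i.e. lags beyond ~2/tau0
seconds are attenuated.  ``lambda`` controls the roll-off of the kernel tails.  This is
the one approximation site of the pipeline (the kernel's exact convention
varies across the literature); it is isolated in ``_ambiguity_kernel`` and
every consumer relies only on qualitative band dominance, which is robust
to the kernel's details.

Band powers are trapezoidal integrals of the (non-negative-clipped) surface
over LF = 0.04--0.15 Hz and HF = 0.15--0.4 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .preprocess import IbiSeries, QtSeries

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "UniformSeries",
    "TfMap",
    "SpectralBandSeries",
    "resample_uniform",
    "pseudo_wigner_ville",
    "band_power",
    "band_series",
    "lf_qt",
    "spectral_indices",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class UniformSeries:
    """Evenly sampled series (no missing values)."""

    values: np.ndarray
    fs: float = 4.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("uniform series must be free of missing values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass(frozen=True)
class TfMap:
    """Time-frequency power surface (time x frequency, clipped at zero)."""

    t: np.ndarray
    f: np.ndarray
    power: np.ndarray
    nu0: float
    tau0: float
    lam: float
    burn_in: np.ndarray  # bool mask, True where edge effects dominate

    @property
    def interior(self) -> np.ndarray:
        return ~self.burn_in


@dataclass(frozen=True)
class SpectralBandSeries:
    """Time-resolved LF and HF band powers (and optionally LF from QT)."""

    t: np.ndarray
    lf: np.ndarray
    hf: np.ndarray
    lf_qt: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "lf": self.lf, "hf": self.hf}
        if self.lf_qt is not None:
            data["lf_qt"] = self.lf_qt
        return pd.DataFrame(data)

    def io_meta(self) -> dict:
        return {}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta=None) -> "SpectralBandSeries":
        return cls(
            t=df["t"].to_numpy(float),
            lf=df["lf"].to_numpy(float),
            hf=df["hf"].to_numpy(float),
            lf_qt=df["lf_qt"].to_numpy(float) if "lf_qt" in df else None,
        )


# ---------------------------------------------------------------------------


def resample_uniform(series, fs: float = 4.0, demean: bool = False) -> UniformSeries:
    """Cubic-spline interpolation of an event series onto a uniform grid.

    Accepts an IbiSeries/QtSeries (or any object with ``t`` and a value
    array) and resamples from the first to the last anchor time.
    """
    if isinstance(series, IbiSeries):
        t, v = series.t, series.ibi
    elif isinstance(series, QtSeries):
        t, v = series.t, series.qt
    else:
        t, v = np.asarray(series[0], float), np.asarray(series[1], float)
    keep = np.isfinite(v)
    t, v = t[keep], v[keep]
    if t.size < 4:
        raise ValueError("need at least 4 points for spline resampling")
    if t[-1] - t[0] < 1.0 / fs:
        raise ValueError("series span shorter than one output sample")
    spline = CubicSpline(t, v)
    grid = np.arange(t[0], t[-1] + 1e-12, 1.0 / fs)
    out = spline(grid)
    if demean:
        out = out - out.mean()
    return UniformSeries(values=out, fs=fs, t0=float(t[0]))


def _ambiguity_kernel(
    nu: np.ndarray, tau: np.ndarray, nu0: float, tau0: float, lam: float
) -> np.ndarray:
    """Separable-ellipse exponential kernel on the ambiguity plane.

    ``nu`` in Hz (Doppler), ``tau`` in seconds (lag).  The kernel's single
    point of truth; swap here to explore other conventions.
    """
    # tau0 is the full frequency-smoothing bandwidth: half-width tau0/2,
    # i.e. lags beyond ~2/tau0 seconds are attenuated
    u = (nu[:, None] / nu0) ** 2 + (tau[None, :] * tau0 / 2.0) ** 2
    return np.exp(-np.pi * u ** (2.0 * lam))


def pseudo_wigner_ville(
    x: UniformSeries,
    nu0: float = 0.03,
    tau0: float = 0.06,
    lam: float = 0.3,
    smoothing: bool = True,
) -> TfMap:
    """Smoothed pseudo Wigner--Ville distribution of a uniform series.

    The series is demeaned and made analytic (Hilbert transform), its
    instantaneous autocorrelation K[n, m] = z[n+m] conj(z[n-m]) is filtered
    in the ambiguity domain by :func:`_ambiguity_kernel` (skipped when
    ``smoothing=False``, giving the raw WVD for cross-term comparisons),
    and the lag axis is Fourier transformed.  Negative values -- a known
    artifact of the bilinear transform -- are clipped at zero.

    Normalisation: per time sample, the frequency integral of the surface
    equals |z[n]|^2 / 2, whose time average is the variance of the input,
    so band powers integrate to s^2 units for an IBI input in seconds.
    """
    v = np.asarray(x.values, dtype=float)
    n = v.size
    if n < 64:
        raise ValueError("series too short for time-frequency analysis (need >= 64 samples)")
    dt = 1.0 / x.fs
    z = hilbert(v - v.mean())

    half = n // 2
    lags = np.arange(-half, half)  # length L = 2*half
    L = lags.size
    K = np.zeros((n, L), dtype=complex)
    for j, m in enumerate(lags):
        a = abs(int(m))
        if a > n - 1 - a:
            continue
        K[a : n - a, j] = z[a + m : n - a + m] * np.conj(z[a - m : n - a - m])

    if smoothing:
        # zero-pad the time axis: the kernel's slow tails make the Doppler
        # filtering wrap around the record edges if applied circularly
        pad = 2 * n
        A = np.fft.fft(K, n=pad, axis=0)
        nu = np.fft.fftfreq(pad, d=dt)
        tau = 2.0 * lags * dt
        K = np.fft.ifft(A * _ambiguity_kernel(nu, tau, nu0, tau0, lam), axis=0)[:n]

    # lag axis to FFT order (0..half-1, -half..-1), then transform
    W = np.fft.fft(np.fft.ifftshift(K, axes=1), axis=1).real * dt
    f = np.arange(L) * x.fs / (2.0 * L)
    W = np.clip(W, 0.0, None)

    t = x.times
    burn = 1.0 / (2.0 * LF_BAND[0])  # ~12.5 s of edge effects at each end
    burn_in = (t - t[0] < burn) | (t[-1] - t < burn)
    return TfMap(t=t, f=f, power=W, nu0=nu0, tau0=tau0, lam=lam, burn_in=burn_in)


def band_power(tf: TfMap, band: tuple[float, float]) -> np.ndarray:
    """Trapezoidal integral of the surface over a frequency band, per time."""
    lo, hi = band
    if hi <= lo:
        raise ValueError("band upper edge must exceed lower edge")
    sel = (tf.f >= lo) & (tf.f <= hi)
    if sel.sum() < 2:
        raise ValueError(f"band [{lo}, {hi}] Hz not resolved by the frequency grid")
    return np.trapezoid(tf.power[:, sel], tf.f[sel], axis=1)


def band_series(tf: TfMap, lf_band=LF_BAND, hf_band=HF_BAND) -> SpectralBandSeries:
    return SpectralBandSeries(t=tf.t, lf=band_power(tf, lf_band), hf=band_power(tf, hf_band))


def lf_qt(
    qt: QtSeries,
    fs: float = 4.0,
    nu0: float = 0.03,
    tau0: float = 0.06,
    lam: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """LF band power of the QT-interval series: (times, power)."""
    uni = resample_uniform(qt, fs=fs)
    tf = pseudo_wigner_ville(uni, nu0=nu0, tau0=tau0, lam=lam)
    return tf.t, band_power(tf, LF_BAND)


def spectral_indices(
    ibi: IbiSeries,
    qt: QtSeries | None = None,
    fs: float = 4.0,
    nu0: float = 0.03,
    tau0: float = 0.06,
    lam: float = 0.3,
) -> SpectralBandSeries:
    """Full spectral comparator: LF/HF from IBI, optionally LF from QT.

    The QT-derived LF series is spline-aligned onto the IBI time grid when
    present.
    """
    uni = resample_uniform(ibi, fs=fs)
    tf = pseudo_wigner_ville(uni, nu0=nu0, tau0=tau0, lam=lam)
    out = band_series(tf)
    if qt is not None:
        tq, pq = lf_qt(qt, fs=fs, nu0=nu0, tau0=tau0, lam=lam)
        aligned = np.interp(out.t, tq, pq, left=np.nan, right=np.nan)
        out = SpectralBandSeries(t=out.t, lf=out.lf, hf=out.hf, lf_qt=aligned)
    return out
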
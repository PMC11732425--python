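"""Time-resolved Poincare-plot descriptors of the interbeat-interval series.

The Poincare plot scatters each interval against its successor
(IBI_i vs IBI_{i+1}).  Inside a trailing window of length ``T`` ending at
time ``t`` three geometric features are extracted:

* ``CCD(t)`` -- the distance from the cloud centroid to the origin,
  ``sqrt(mean(x)^2 + mean(y)^2)``, a baseline cardiac-cycle-duration
  (inverse heart-rate) descriptor;
* ``SD1(t)`` -- dispersion perpendicular to the identity line (short-term,
  beat-to-beat variability, vagally mediated);
* ``SD2(t)`` -- dispersion along the identity line (long-term variability).

SD1/SD2 are square roots of the eigenvalues of the 2x2 covariance of the
lagged pairs, assigned by eigenvector *orientation* (nearest to the
(1,-1) / (1,1) axes), never by magnitude, so the two never swap roles on
unusual inputs.  Four covariance estimators are available:

``exact``
    the sample covariance (n-1 denominator);
``robust``
    Ledoit--Wolf shrinkage toward the scaled identity, with the analytic
    optimal intensity;
``p95``
    minimum covariance determinant: the sample covariance of the best
    h = round(0.95 n) points (exact subset enumeration when feasible,
    FAST-MCD otherwise), reported as-is, without consistency rescaling;
``approximate``
    the classical closed forms sd1 = sqrt(1/2) std(dIBI),
    sd2 = sqrt(|2 std(IBI)^2 - 1/2 std(dIBI)^2|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import IbiSeries

__all__ = [
    "CovMethod",
    "LaggedPairs",
    "DescriptorSeries",
    "window_pairs",
    "compute_ccd",
    "estimate_covariance",
    "sd_from_covariance",
    "sd_approximate",
    "descriptor_series",
]

METHODS = ("exact", "robust", "p95", "approximate")


@dataclass(frozen=True)
class CovMethod:
    """Covariance estimator configuration.

    ``outlier_fraction`` applies to the ``p95`` estimator only (default
    0.05, i.e. the best 95% of points).  ``seed`` makes the FAST-MCD subset
    search deterministic; the exhaustive small-sample path ignores it.
    """

    name: str = "robust"
    outlier_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in METHODS:
            raise ValueError(f"unknown covariance method {self.name!r}; choose from {METHODS}")
        if not (0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must be in [0, 0.5)")


def _as_method(method) -> CovMethod:
    return CovMethod(name=method) if isinstance(method, str) else method


@dataclass(frozen=True)
class LaggedPairs:
    """Consecutive-interval pairs (IBI_i, IBI_{i+1}) inside one window."""

    x: np.ndarray
    y: np.ndarray
    t: float = float("nan")

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float).ravel()
        y = np.asarray(self.y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class DescriptorSeries:
    """CCD(t), SD1(t), SD2(t) on a common evaluation grid.

    Entries where the window held fewer than ``min_pairs`` pairs are NaN
    ("missing"); downstream consumers interpolate short gaps explicitly.
    """

    t: np.ndarray
    ccd: np.ndarray
    sd1: np.ndarray
    sd2: np.ndarray
    T: float
    method: str

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "ccd", "sd1", "sd2"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float).ravel()
            object.__setattr__(self, name, arrays[name])
        n = arrays["t"].size
        if any(a.size != n for a in arrays.values()):
            raise ValueError("all descriptor arrays must share one length")
        for name in ("sd1", "sd2"):
            vals = arrays[name]
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ValueError(f"{name} must be non-negative where defined")

    @property
    def n(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "ccd": self.ccd, "sd1": self.sd1, "sd2": self.sd2})

    def io_meta(self) -> dict:
        return {"T": repr(self.T), "method": self.method}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: Mapping[str, str] | None = None) -> "DescriptorSeries":
        meta = meta or {}
        return cls(
            t=df["t"].to_numpy(float),
            ccd=df["ccd"].to_numpy(float),
            sd1=df["sd1"].to_numpy(float),
            sd2=df["sd2"].to_numpy(float),
            T=float(meta.get("T", "nan")),
            method=str(meta.get("method", "unknown")),
        )


# ---------------------------------------------------------------------------
# Window extraction and centroid distance
# ---------------------------------------------------------------------------

def window_pairs(ibi: IbiSeries, t: float, T: float) -> LaggedPairs:
    """Lagged pairs whose two anchor times both lie in the trailing window
    [t - T, t].  May be empty."""
    if T <= 0:
        raise ValueError("window length T must be positive")
    lo = np.searchsorted(ibi.t, t - T, side="left")
    hi = np.searchsorted(ibi.t, t, side="right")
    if hi - lo < 2:
        return LaggedPairs(x=np.empty(0), y=np.empty(0), t=t)
    return LaggedPairs(x=ibi.ibi[lo : hi - 1], y=ibi.ibi[lo + 1 : hi], t=t)


def compute_ccd(pairs: LaggedPairs) -> float:
    """Distance from the pair-cloud centroid to the origin (seconds)."""
    if pairs.n == 0:
        return float("nan")
    return float(np.hypot(np.mean(pairs.x), np.mean(pairs.y)))


# ---------------------------------------------------------------------------
# Covariance estimators
# ---------------------------------------------------------------------------

def _ledoit_wolf_2x2(X: np.ndarray) -> np.ndarray:
    """Ledoit--Wolf shrinkage toward mu*I, analytic intensity.

    Mirrors scikit-learn's ``ledoit_wolf`` (which serves as the test
    oracle); kept local because the sliding window calls it thousands of
    times per recording.
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    emp = Xc.T @ Xc / n
    mu = np.trace(emp) / p
    delta = float(np.sum((emp - mu * np.eye(p)) ** 2)) / p
    if delta == 0:
        return emp
    X2 = Xc**2
    beta_ = (float(np.sum(X2.T @ X2)) / n - float(np.sum(emp**2))) / (n * p)
    shrinkage = min(beta_, delta) / delta
    shrinkage = min(max(shrinkage, 0.0), 1.0)
    return (1.0 - shrinkage) * emp + shrinkage * mu * np.eye(p)


_ENUM_LIMIT = 2000  # max subsets to enumerate for the exact small-sample MCD


def _mcd_cov(X: np.ndarray, outlier_fraction: float, seed: int) -> np.ndarray:
    """Minimum-covariance-determinant estimate: the plain sample covariance
    of the h-point subset with the smallest determinant.

    Deliberately *without* the Gaussian consistency rescaling: the estimator
    is defined as the covariance the selected points themselves fulfil, so
    it runs slightly low on clean data -- the over-trimming cost that shows
    up as a reduced effect magnitude downstream.
    """
    n = X.shape[0]
    h = int(round((1.0 - outlier_fraction) * n))
    h = min(max(h, 3), n)
    k = n - h
    alpha = h / n
    if k == 0:
        cov = np.cov(X.T, ddof=1)
        return np.atleast_2d(cov)
    if math.comb(n, k) <= _ENUM_LIMIT:
        # exact MCD: enumerate every leave-k-out subset, vectorised through
        # sufficient statistics (sums and scatter of the dropped points)
        drops = np.asarray(list(combinations(range(n), k)), dtype=int)  # (S, k)
        s1 = X.sum(axis=0)  # (2,)
        s2 = X.T @ X  # (2, 2)
        Xd = X[drops]  # (S, k, 2)
        s1_kept = s1[None, :] - Xd.sum(axis=1)
        s2_kept = s2[None, :, :] - np.einsum("ski,skj->sij", Xd, Xd)
        mean = s1_kept / h
        covs = (s2_kept - h * np.einsum("si,sj->sij", mean, mean)) / (h - 1)
        dets = covs[:, 0, 0] * covs[:, 1, 1] - covs[:, 0, 1] * covs[:, 1, 0]
        best = int(np.argmin(dets))
        return covs[best]
    from sklearn.covariance import MinCovDet

    mcd = MinCovDet(support_fraction=alpha, random_state=seed).fit(X)
    return np.cov(X[mcd.raw_support_].T, ddof=1)


def estimate_covariance(pairs: LaggedPairs, method: CovMethod | str = "exact") -> np.ndarray | None:
    """2x2 covariance of the lagged pairs, or None when the window is too
    sparse for the requested estimator."""
    method = _as_method(method)
    if method.name == "approximate":
        raise ValueError("'approximate' bypasses the covariance; use sd_approximate")
    n = pairs.n
    min_n = 5 if method.name == "p95" else 3
    if n < min_n:
        return None
    X = np.column_stack((pairs.x, pairs.y))
    if method.name == "exact":
        return np.cov(X.T, ddof=1)
    if method.name == "robust":
        return _ledoit_wolf_2x2(X)
    return _mcd_cov(X, method.outlier_fraction, method.seed)


# ---------------------------------------------------------------------------
# SD extraction
# ---------------------------------------------------------------------------

_DIAG = np.array([1.0, 1.0]) / np.sqrt(2.0)  # identity line of the plot


def sd_from_covariance(cov: np.ndarray) -> tuple[float, float]:
    """(SD1, SD2) from an eigen-decomposition, assigned by orientation.

    SD1 takes the eigenvalue whose eigenvector is closer to (1,-1) (across
    the identity line), SD2 the one closer to (1,1).  Eigenvalues more
    negative than -1e-12 raise; small negatives are clamped to zero.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("covariance must be 2x2")
    if abs(cov[0, 1] - cov[1, 0]) > 1e-9 * max(1.0, abs(cov[0, 1])):
        raise ValueError("covariance must be symmetric")
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals < -1e-12):
        raise ValueError(f"covariance has a negative eigenvalue: {evals.min():g}")
    evals = np.clip(evals, 0.0, None)
    # |projection onto the identity line| for each eigenvector
    along = np.abs(evecs.T @ _DIAG)
    i_sd2 = int(np.argmax(along))
    i_sd1 = 1 - i_sd2
    return float(np.sqrt(evals[i_sd1])), float(np.sqrt(evals[i_sd2]))


def sd_approximate(ibi_window: np.ndarray) -> tuple[float, float]:
    """Closed-form SD1/SD2 from the window's interval values.

    sd1 = sqrt(1/2) * std(dIBI); sd2 = sqrt(|2 std(IBI)^2 - 1/2 std(dIBI)^2|),
    with the sample (n-1) standard-deviation convention throughout.
    """
    v = np.asarray(ibi_window, dtype=float).ravel()
    if v.size < 3:
        return float("nan"), float("nan")
    sd_d = np.std(np.diff(v), ddof=1)
    sd_v = np.std(v, ddof=1)
    sd1 = math.sqrt(0.5) * sd_d
    sd2 = math.sqrt(abs(2.0 * sd_v**2 - 0.5 * sd_d**2))
    return float(sd1), float(sd2)


# ---------------------------------------------------------------------------
# Sliding-window series
# ---------------------------------------------------------------------------

def descriptor_series(
    ibi: IbiSeries,
    T: float = 15.0,
    method: CovMethod | str = "robust",
    grid: str = "per-beat",
    dt: float = 0.25,
    min_pairs: int = 3,
    centered: bool = False,
) -> DescriptorSeries:
    """CCD/SD1/SD2 over a sliding window of length ``T`` seconds.

    ``grid="per-beat"`` evaluates at every interval anchor time (default);
    ``grid="uniform"`` evaluates every ``dt`` seconds across the record.
    The window is the causal trailing window [t-T, t] unless ``centered``.
    Windows with fewer than ``min_pairs`` pairs give NaN entries.
    """
    method = _as_method(method)
    if ibi.duration <= T:
        raise ValueError(f"recording ({ibi.duration:.1f} s) must be longer than the window T={T} s")
    if grid == "per-beat":
        eval_t = ibi.t.copy()
    elif grid == "uniform":
        eval_t = np.arange(ibi.t[0], ibi.t[-1] + dt / 2, dt)
    else:
        raise ValueError(f"unknown grid {grid!r}")

    offset = T / 2 if centered else 0.0
    ccd = np.full(eval_t.size, np.nan)
    sd1 = np.full(eval_t.size, np.nan)
    sd2 = np.full(eval_t.size, np.nan)
    for i, te in enumerate(eval_t):
        pairs = window_pairs(ibi, te + offset, T)
        if pairs.n < max(min_pairs, 1):
            continue
        ccd[i] = compute_ccd(pairs)
        if method.name == "approximate":
            lo = np.searchsorted(ibi.t, te + offset - T, side="left")
            hi = np.searchsorted(ibi.t, te + offset, side="right")
            s1, s2 = sd_approximate(ibi.ibi[lo:hi])
        else:
            cov = estimate_covariance(pairs, method)
            if cov is None:
                continue
            s1, s2 = sd_from_covariance(cov)
        sd1[i], sd2[i] = s1, s2
    return DescriptorSeries(t=eval_t, ccd=ccd, sd1=sd1, sd2=sd2, T=T, method=method.name)
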
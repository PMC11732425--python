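"""Cardiac sympathetic (CSI) and parasympathetic (CPI) indices.

The time-resolved Poincare descriptors are re-centred against whole-recording
anchors and combined:

    D(t)   = (CCD(t) - mean CCD) + CCD0          heart-rate trend
    D~(t)  = 2 mean(D) - D(t)                    the trend flipped about its mean
    CPI(t) = kp * ((SD1(t) - mean SD1) + SD01) + D(t)
    CSI(t) = ks * ((SD2(t) - mean SD2) + SD02) + D~(t)

CCD0/SD01/SD02 come from one Poincare computation over the *entire*
recording; the demeaning means are taken over the analysed trial segment.
Sympathetic activation shortens the cardiac cycle (D falls, D~ rises, CSI
rises) and is weighted toward the heart-rate term (default ks = 1);
parasympathetic activity expresses itself in short-term variability, so SD1
carries a larger weight (default kp = 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .poincare import (
    CovMethod,
    DescriptorSeries,
    LaggedPairs,
    _as_method,
    compute_ccd,
    descriptor_series,
    estimate_covariance,
    sd_approximate,
    sd_from_covariance,
)
from .preprocess import IbiSeries

__all__ = [
    "GlobalAnchors",
    "IndexSeries",
    "global_anchors",
    "compute_indices",
    "sweep_coefficients",
    "SweepResult",
    "fill_short_gaps",
]


@dataclass(frozen=True)
class GlobalAnchors:
    """Whole-recording Poincare geometry used to re-centre windowed series."""

    ccd0: float
    sd01: float
    sd02: float


@dataclass(frozen=True)
class IndexSeries:
    """Time-resolved CSI/CPI with the configuration that produced them."""

    t: np.ndarray
    csi: np.ndarray
    cpi: np.ndarray
    ks: float
    kp: float
    anchors: GlobalAnchors | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float).ravel()
        csi = np.asarray(self.csi, dtype=float).ravel()
        cpi = np.asarray(self.cpi, dtype=float).ravel()
        if not (t.size == csi.size == cpi.size):
            raise ValueError("t, csi and cpi must share one length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "csi", csi)
        object.__setattr__(self, "cpi", cpi)

    @property
    def n(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "csi": self.csi, "cpi": self.cpi})

    def io_meta(self) -> dict:
        return {"ks": repr(self.ks), "kp": repr(self.kp)}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: Mapping[str, str] | None = None) -> "IndexSeries":
        meta = meta or {}
        return cls(
            t=df["t"].to_numpy(float),
            csi=df["csi"].to_numpy(float),
            cpi=df["cpi"].to_numpy(float),
            ks=float(meta.get("ks", 1.0)),
            kp=float(meta.get("kp", 10.0)),
        )


def fill_short_gaps(t: np.ndarray, v: np.ndarray, max_gap: float = 2.0) -> np.ndarray:
    """Linearly interpolate NaN runs spanning at most ``max_gap`` seconds.

    Longer runs (and leading/trailing NaNs) are left missing.
    """
    v = np.asarray(v, dtype=float).copy()
    isnan = ~np.isfinite(v)
    if not isnan.any() or isnan.all():
        return v
    idx = np.flatnonzero(isnan)
    # group consecutive indices into runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= v.size:
            continue
        if t[hi] - t[lo] > max_gap:
            continue
        v[run] = np.interp(t[run], [t[lo], t[hi]], [v[lo], v[hi]])
    return v


def global_anchors(ibi: IbiSeries, method: CovMethod | str = "robust") -> GlobalAnchors:
    """CCD0/SD01/SD02 from the full recording's Poincare cloud, computed
    with the same covariance method as the windowed series."""
    method = _as_method(method)
    if ibi.n < 10:
        raise ValueError("need at least 10 intervals for whole-recording anchors")
    pairs = LaggedPairs(x=ibi.ibi[:-1], y=ibi.ibi[1:])
    ccd0 = compute_ccd(pairs)
    if method.name == "approximate":
        sd01, sd02 = sd_approximate(ibi.ibi)
    else:
        cov = estimate_covariance(pairs, method)
        if cov is None:
            raise ValueError("too few pairs for the requested covariance method")
        sd01, sd02 = sd_from_covariance(cov)
    return GlobalAnchors(ccd0=ccd0, sd01=sd01, sd02=sd02)


def compute_indices(
    desc: DescriptorSeries,
    anchors: GlobalAnchors,
    ks: float = 1.0,
    kp: float = 10.0,
    max_gap: float = 2.0,
) -> IndexSeries:
    """Combine re-centred descriptors into CSI/CPI.

    Missing descriptor samples are linearly interpolated when the gap is at
    most ``max_gap`` seconds, otherwise excluded from the demeaning means
    and left missing in the output.
    """
    ccd = fill_short_gaps(desc.t, desc.ccd, max_gap)
    sd1 = fill_short_gaps(desc.t, desc.sd1, max_gap)
    sd2 = fill_short_gaps(desc.t, desc.sd2, max_gap)
    valid = np.isfinite(ccd)
    if valid.sum() < 2:
        raise ValueError("descriptor series has fewer than 2 usable samples")
    d = (ccd - np.nanmean(ccd)) + anchors.ccd0
    d_flipped = 2.0 * np.nanmean(d) - d
    cpi = kp * ((sd1 - np.nanmean(sd1)) + anchors.sd01) + d
    csi = ks * ((sd2 - np.nanmean(sd2)) + anchors.sd02) + d_flipped
    return IndexSeries(t=desc.t, csi=csi, cpi=cpi, ks=ks, kp=kp, anchors=anchors)


# ---------------------------------------------------------------------------
# Coefficient sweep (separability of paired conditions over a ks/kp grid)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    ks_values: np.ndarray
    kp_values: np.ndarray
    z_csi: np.ndarray  # shape (len(ks_values),)
    z_cpi: np.ndarray  # shape (len(kp_values),)
    best_ks: float
    best_kp: float

    @property
    def z_csi_grid(self) -> np.ndarray:
        """|ks| x |kp| view; CSI depends on ks only, so rows repeat."""
        return np.tile(self.z_csi[:, None], (1, self.kp_values.size))

    @property
    def z_cpi_grid(self) -> np.ndarray:
        """|ks| x |kp| view; CPI depends on kp only, so columns repeat."""
        return np.tile(self.z_cpi[None, :], (self.ks_values.size, 1))


def sweep_coefficients(
    ibi_trials: Sequence[tuple[IbiSeries, IbiSeries]],
    ks_range: Sequence[float] = tuple(range(1, 11)),
    kp_range: Sequence[float] = tuple(range(1, 11)),
    T: float = 15.0,
    method: CovMethod | str = "robust",
) -> SweepResult:
    """Wilcoxon separability of pre vs post conditions over a coefficient grid.

    Each trial is a (pre, post) pair of contiguous IBI segments split at the
    condition onset.  The descriptors are computed once per trial; for every
    ks the per-trial mean CSI before/after the split is compared with the
    two-sided signed-rank test and the |Z| recorded (likewise kp for CPI).
    CSI depends only on ks and CPI only on kp, so the grid factorises.
    """
    from .evaluate import wilcoxon_signed_rank  # local import: avoid cycle

    if len(ibi_trials) < 6:
        raise ValueError("need at least 6 paired trials for the coefficient sweep")
    ks_values = np.asarray(list(ks_range), dtype=float)
    kp_values = np.asarray(list(kp_range), dtype=float)

    per_trial: list[tuple[DescriptorSeries, GlobalAnchors, float]] = []
    for pre, post in ibi_trials:
        onset = float(pre.t[-1])
        full = IbiSeries(
            t=np.concatenate((pre.t, post.t)), ibi=np.concatenate((pre.ibi, post.ibi))
        )
        desc = descriptor_series(full, T=T, method=method)
        per_trial.append((desc, global_anchors(full, method), onset))

    def _z(values_pre: np.ndarray, values_post: np.ndarray) -> float:
        try:
            return wilcoxon_signed_rank(values_pre, values_post).z
        except ValueError:
            return 0.0  # degenerate (identical conditions)

    z_csi = np.empty(ks_values.size)
    z_cpi = np.empty(kp_values.size)
    segmeans = []
    for desc, anchors, onset in per_trial:
        pre_mask = desc.t <= onset
        post_mask = desc.t > onset
        segmeans.append((desc, anchors, pre_mask, post_mask))

    for j, ks in enumerate(ks_values):
        pre_vals, post_vals = [], []
        for desc, anchors, pre_mask, post_mask in segmeans:
            idx = compute_indices(desc, anchors, ks=ks, kp=1.0)
            pre_vals.append(np.nanmean(idx.csi[pre_mask]))
            post_vals.append(np.nanmean(idx.csi[post_mask]))
        z_csi[j] = _z(np.asarray(pre_vals), np.asarray(post_vals))
    for j, kp in enumerate(kp_values):
        pre_vals, post_vals = [], []
        for desc, anchors, pre_mask, post_mask in segmeans:
            idx = compute_indices(desc, anchors, ks=1.0, kp=kp)
            pre_vals.append(np.nanmean(idx.cpi[pre_mask]))
            post_vals.append(np.nanmean(idx.cpi[post_mask]))
        z_cpi[j] = _z(np.asarray(pre_vals), np.asarray(post_vals))

    return SweepResult(
        ks_values=ks_values,
        kp_values=kp_values,
        z_csi=z_csi,
        z_cpi=z_cpi,
        best_ks=float(ks_values[int(np.argmax(np.abs(z_csi)))]),
        best_kp=float(kp_values[int(np.argmax(np.abs(z_cpi)))]),
    )
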
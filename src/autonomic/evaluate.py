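"""Statistical procedures and experiment harnesses.

Implements the validation logic used around the indices: per-trial z-scoring,
the two-sided Wilcoxon signed-rank test (exact sign-flip enumeration for
n <= 12, normal approximation with tie correction otherwise), the Friedman
test for the window-length analysis, Spearman correlation with the
Student-t p-value approximation and a positive-coefficient significance
rule, a binomial post hoc over the proportion of significant cases, and the
ectopic-beat robustness experiment that compares the four covariance
estimators by their effect magnitude (mean index after minus before the
condition onset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .indices import IndexSeries, compute_indices, global_anchors
from .poincare import CovMethod, _as_method, descriptor_series
from .preprocess import IbiSeries, build_ibi
from .signal_io import BeatAnnotations
from .synth import EctopicSpec, inject_ectopics

__all__ = [
    "PairedComparison",
    "RobustnessCurve",
    "paired_condition_means",
    "zscore_per_trial",
    "wilcoxon_signed_rank",
    "friedman",
    "spearman_t",
    "binomial_posthoc",
    "effect_magnitude",
    "robustness_experiment",
]


@dataclass(frozen=True)
class PairedComparison:
    """Wilcoxon signed-rank comparison of paired per-trial means."""

    pre: np.ndarray
    post: np.ndarray
    w: float  # sum of ranks of positive differences
    z: float  # normal approximation with tie correction
    p: float  # two-sided
    n: int  # pairs after zero-difference removal
    alpha: float  # Bonferroni-corrected significance level

    @property
    def significant(self) -> bool:
        return bool(self.p < self.alpha)


@dataclass(frozen=True)
class RobustnessCurve:
    """Effect-magnitude sensitivity to injected ectopics, one per method."""

    method: str
    n_outliers: np.ndarray  # the 0..n axis
    effects: np.ndarray  # shape (reps, len(n_outliers))
    median_per_n: np.ndarray
    mad_per_n: np.ndarray
    median: float  # across all (n, rep) estimates
    mad: float

    @property
    def clean_effect(self) -> float:
        """Effect magnitude with no outliers (deterministic)."""
        return float(self.effects[0, 0])


def paired_condition_means(
    trials: Sequence[tuple[IbiSeries, IbiSeries]],
    field: str = "csi",
    ks: float = 1.0,
    kp: float = 10.0,
    T: float = 15.0,
    method: CovMethod | str = "robust",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial mean index before and after the condition onset.

    Each trial is a contiguous (pre, post) pair of IBI segments; the full
    pipeline runs on the concatenated record and the index series is
    averaged on each side of the split.  Returns (pre_means, post_means),
    the inputs the paired Wilcoxon comparison consumes.
    """
    pre_means, post_means = [], []
    for pre, post in trials:
        onset = float(pre.t[-1])
        full = IbiSeries(
            t=np.concatenate((pre.t, post.t)),
            ibi=np.concatenate((pre.ibi, post.ibi)),
        )
        desc = descriptor_series(full, T=T, method=method)
        idx = compute_indices(desc, global_anchors(full, method), ks=ks, kp=kp)
        v = getattr(idx, field)
        pre_means.append(np.nanmean(v[idx.t <= onset]))
        post_means.append(np.nanmean(v[idx.t > onset]))
    return np.asarray(pre_means), np.asarray(post_means)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def zscore_per_trial(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1 (n-1 convention) over non-missing samples."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("need at least 2 non-missing samples to z-score")
    sd = np.std(v[finite], ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-scoring undefined")
    out = np.full_like(v, np.nan)
    out[finite] = (v[finite] - np.mean(v[finite])) / sd
    return out


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p by enumerating all sign assignments of the ranks.

    Midranks are doubled to integers so ties enumerate exactly; complexity
    is O(2^n) through a subset-sum convolution, fine for n <= 12.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_obs))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    pre: np.ndarray,
    post: np.ndarray,
    n_comparisons: int = 1,
    exact_max_n: int = 12,
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are discarded (classic convention).  ``W`` is the sum
    of the ranks of positive differences; ``Z`` its normal approximation
    with tie correction.  The p-value is exact (sign-flip enumeration) for
    n <= ``exact_max_n``, the normal approximation otherwise.
    ``n_comparisons`` sets the Bonferroni-corrected alpha = 0.05/N reported
    alongside.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    keep = np.isfinite(pre) & np.isfinite(post)
    d = post[keep] - pre[keep]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError(f"only {n} nonzero differences; need at least 5")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mu) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return PairedComparison(
        pre=pre, post=post, w=w, z=float(z), p=float(min(p, 1.0)), n=n,
        alpha=0.05 / n_comparisons,
    )


def friedman(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over a trials x conditions matrix, with midranks
    and tie correction; p from chi-square with k-1 degrees of freedom."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (trials x conditions)")
    n, k = m.shape
    if k < 3:
        raise ValueError("need at least 3 conditions")
    if n < 5:
        raise ValueError("need at least 5 trials")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0, 1.0
    stat = stat / c
    return float(stat), float(stats.chi2.sf(stat, k - 1))


def spearman_t(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.0001,
    exclude: np.ndarray | None = None,
) -> tuple[float, float, bool]:
    """Spearman rank correlation with Student-t p-value approximation.

    The significance flag requires *both* p < alpha and a positive
    coefficient.  ``exclude`` is an optional boolean mask of samples to
    drop (e.g. an orthostatic-hypotension burn-in).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    x, y = x[keep], y[keep]
    if x.size < 10:
        raise ValueError("need at least 10 paired samples")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance in one of the series")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), bool(p < alpha and rho > 0)


def binomial_posthoc(n_significant: int, n_total: int, p_null: float = 0.5) -> float:
    """Upper-tail P(X >= n_significant) under Binomial(n_total, p_null)."""
    if not (0 < p_null < 1):
        raise ValueError("p_null must be inside (0, 1)")
    if not (0 <= n_significant <= n_total):
        raise ValueError("n_significant must lie in [0, n_total]")
    return float(stats.binom.sf(n_significant - 1, n_total, p_null))


# ---------------------------------------------------------------------------
# Effect magnitude and the ectopic robustness experiment
# ---------------------------------------------------------------------------

def effect_magnitude(
    index,
    onset: float,
    span: float = 120.0,
    field: str = "csi",
) -> float:
    """Mean of the index over (onset, onset+span] minus its mean over
    [onset-span, onset].

    ``index`` may be an IndexSeries (``field`` selects csi or cpi) or a
    (times, values) pair.
    """
    if isinstance(index, IndexSeries):
        t, v = index.t, getattr(index, field)
    else:
        t, v = np.asarray(index[0], float), np.asarray(index[1], float)
    margin = max(2.0, 0.05 * span)
    if t.size == 0 or t[0] - (onset - span) > margin or (onset + span) - t[-1] > margin:
        raise ValueError(
            f"series [{t[0] if t.size else float('nan'):.1f}, "
            f"{t[-1] if t.size else float('nan'):.1f}] does not cover "
            f"[{onset - span:.1f}, {onset + span:.1f}]"
        )
    before = (t >= onset - span) & (t <= onset)
    after = (t > onset) & (t <= onset + span)
    vb, va = v[before], v[after]
    vb, va = vb[np.isfinite(vb)], va[np.isfinite(va)]
    if vb.size == 0 or va.size == 0:
        raise ValueError("no usable samples on one side of the onset")
    return float(np.mean(va) - np.mean(vb))


def robustness_experiment(
    ibi: IbiSeries,
    onset: float,
    methods: Sequence[CovMethod | str] = ("exact", "robust", "p95", "approximate"),
    n_range: Sequence[int] = tuple(range(11)),
    reps: int = 20,
    seed: int = 0,
    T: float = 15.0,
    ks: float = 1.0,
    kp: float = 10.0,
    span: float = 120.0,
    delay: float = 0.030,
) -> dict[str, RobustnessCurve]:
    """Sensitivity of the CSI effect magnitude to injected ectopic beats.

    For each covariance method and each number of outliers n, ``reps``
    random placements of +``delay`` displacements are injected into the
    beat series, the full pipeline (descriptors -> anchors -> CSI) rerun,
    and the effect magnitude around ``onset`` recorded.  n = 0 carries no
    randomness, so its column repeats one deterministic value.
    """
    beat_times = ibi.beat_times
    window = (max(beat_times[0] + T, onset - span), min(beat_times[-1] - 1.0, onset + span))
    rng = np.random.default_rng(seed)
    placement_seeds = rng.integers(0, 2**31 - 1, size=(len(n_range), reps))
    curves: dict[str, RobustnessCurve] = {}
    for method in methods:
        method = _as_method(method)
        effects = np.empty((reps, len(n_range)))
        for j, n_out in enumerate(n_range):
            for r in range(reps):
                if n_out == 0 and r > 0:
                    effects[r, j] = effects[0, j]
                    continue
                spec = EctopicSpec(
                    n_outliers=int(n_out),
                    delay=delay,
                    window=window,
                    seed=int(placement_seeds[j, r]),
                )
                beats = inject_ectopics(BeatAnnotations(r_times=beat_times), spec)
                contaminated = build_ibi(beats)
                desc = descriptor_series(contaminated, T=T, method=method)
                anchors = global_anchors(contaminated, method)
                idx = compute_indices(desc, anchors, ks=ks, kp=kp)
                effects[r, j] = effect_magnitude(idx, onset=onset, span=span, field="csi")
        flat = effects.ravel()
        med_n = np.median(effects, axis=0)
        curves[method.name] = RobustnessCurve(
            method=method.name,
            n_outliers=np.asarray(list(n_range)),
            effects=effects,
            median_per_n=med_n,
            mad_per_n=np.median(np.abs(effects - med_n[None, :]), axis=0),
            median=float(np.median(flat)),
            mad=float(np.median(np.abs(flat - np.median(flat)))),
        )
    return curves
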
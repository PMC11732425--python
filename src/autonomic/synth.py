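"""Synthetic heartbeat and ECG generation with controlled autonomic structure.

Beats come from an integral pulse frequency modulation (IPFM) model: a beat
fires whenever the integral of the modulated instantaneous rate

    r(t) = base_rate * g(t) * (1 + a_lf(t) sin(2 pi f_lf t) + a_hf(t) sin(2 pi f_hf t))

crosses the next integer, where the step factor ``g`` and the two
modulation amplitudes switch at ``transition_time`` (mimicking a
cold-pressor / tilt onset: rate up, vagal high-frequency modulation down,
sympathetic low-frequency modulation up).  IPFM is used because it gives
direct control over the spectral content of the resulting interbeat-interval
series -- the property every comparator test needs.

ECG traces are sums of per-beat Gaussian-bump templates with a Q trough at
R-40 ms and a T-end trough at R+350 ms, so QRS and QT detectors can be
validated against construction ground truth.  Ectopic-beat contamination is
modelled as a pure +30 ms displacement of randomly selected R-peaks (the
interval closing at the beat grows by the delay, the next one shrinks by
it; total duration is preserved).

Everything is bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .preprocess import IbiSeries, build_ibi
from .signal_io import BeatAnnotations, EcgSignal

__all__ = [
    "ScenarioConfig",
    "EctopicSpec",
    "ipfm_beats",
    "synth_ecg",
    "inject_ectopics",
    "cohort",
    "cold_pressor",
    "tilt",
    "correlated_surrogate",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic recording.

    Defaults describe a resting adult: 66 bpm baseline, a 0.1 Hz
    low-frequency oscillation and a 0.25 Hz respiratory (high-frequency)
    oscillation of the instantaneous rate, 3 ms beat-timing jitter.
    """

    duration: float = 240.0  # s
    base_rate: float = 1.1  # beats/s (66 bpm)
    a_lf: float = 0.06
    f_lf: float = 0.10  # Hz
    a_hf: float = 0.08
    f_hf: float = 0.25  # Hz
    transition_time: float | None = None  # s, None = stationary
    post_rate_factor: float = 1.0
    post_ahf_factor: float = 1.0
    post_alf_factor: float = 1.0
    noise_sd: float = 0.003  # s of beat-time jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.base_rate <= 0:
            raise ValueError("duration and base_rate must be positive")
        if not (0.04 <= self.f_lf <= 0.15):
            raise ValueError("f_lf must lie in the LF band [0.04, 0.15] Hz")
        if not (0.15 < self.f_hf <= 0.40):
            raise ValueError("f_hf must lie in the HF band (0.15, 0.4] Hz")
        if self.a_lf < 0 or self.a_hf < 0 or self.a_lf + self.a_hf >= 1:
            raise ValueError("modulation amplitudes must be >= 0 and sum below 1")
        if self.post_rate_factor <= 0 or self.post_ahf_factor < 0 or self.post_alf_factor < 0:
            raise ValueError("post_rate_factor must be > 0 and post-amplitude factors >= 0")
        post_sum = self.a_lf * self.post_alf_factor + self.a_hf * self.post_ahf_factor
        if post_sum >= 1:
            raise ValueError("post-transition modulation amplitudes must sum below 1")


@dataclass(frozen=True)
class EctopicSpec:
    """Up to 10 beats displaced by ``delay`` inside the placement window."""

    n_outliers: int
    delay: float = 0.030  # s
    window: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_outliers <= 10):
            raise ValueError("n_outliers must be between 0 and 10")
        if self.delay <= 0:
            raise ValueError("delay must be positive")


def cold_pressor(seed: int = 0, **overrides) -> ScenarioConfig:
    """Cold-pressor-like scenario.

    At t = 120 s the rate steps up 25%, the high-frequency (vagal)
    modulation drops to 40% and the low-frequency modulation doubles --
    the classic sympathetic-surge signature (cycle shortening, vagal
    withdrawal, increased slow HRV oscillation).  The -120..+120 s span
    around the onset is the analysis window.
    """
    cfg = ScenarioConfig(
        duration=240.0,
        transition_time=120.0,
        post_rate_factor=1.25,
        post_ahf_factor=0.4,
        post_alf_factor=2.0,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def tilt(seed: int = 0, **overrides) -> ScenarioConfig:
    """Tilt-like scenario: same sign pattern as the cold pressor with a
    milder rate step and LF gain."""
    cfg = ScenarioConfig(
        duration=240.0,
        transition_time=120.0,
        post_rate_factor=1.18,
        post_ahf_factor=0.5,
        post_alf_factor=1.5,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------


def _rate(cfg: ScenarioConfig, t: np.ndarray, phases: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    a_hf = np.full_like(t, cfg.a_hf)
    a_lf = np.full_like(t, cfg.a_lf)
    gain = np.ones_like(t)
    if cfg.transition_time is not None:
        post = t >= cfg.transition_time
        a_hf[post] = cfg.a_hf * cfg.post_ahf_factor
        a_lf[post] = cfg.a_lf * cfg.post_alf_factor
        gain[post] = cfg.post_rate_factor
    mod = (
        1.0
        + a_lf * np.sin(2 * np.pi * cfg.f_lf * t + phases[0])
        + a_hf * np.sin(2 * np.pi * cfg.f_hf * t + phases[1])
    )
    return cfg.base_rate * gain * mod


def ipfm_beats(cfg: ScenarioConfig) -> BeatAnnotations:
    """Integrate-and-fire beat times for a scenario, jittered and sorted.

    The LF/HF oscillator phases are drawn from the seed: physiological
    oscillations are not phase-locked to the protocol clock, and coherent
    phases across a cohort would correlate its members.
    """
    rng = np.random.default_rng(cfg.seed)
    phases = tuple(rng.uniform(0.0, 2 * np.pi, size=2))
    dt = 0.005
    t = np.arange(0.0, cfg.duration + dt, dt)
    r = _rate(cfg, t, phases)
    if np.any(r <= 0):
        raise ValueError("rate modulation dips to zero or below; reduce amplitudes")
    integral = cumulative_trapezoid(r, t, initial=0.0)
    n_beats = int(np.floor(integral[-1]))
    if n_beats < 2:
        raise ValueError("scenario too short to produce two beats")
    beats = np.interp(np.arange(1, n_beats + 1, dtype=float), integral, t)
    if cfg.noise_sd > 0:
        beats = beats + rng.normal(0.0, cfg.noise_sd, size=beats.size)
        beats = np.sort(beats)
        # jitter cannot realistically reorder 1 s gaps, but be safe
        gaps = np.diff(beats)
        if np.any(gaps <= 0):
            beats = beats[np.concatenate(([True], gaps > 0))]
    return BeatAnnotations(r_times=beats)


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

# (offset s, amplitude, width s): P, Q, R, S, T, post-T trough.  The Q trough
# at R-40 ms and the trough at R+350 ms are the ground truth the QT detector
# is validated against.
_TEMPLATE = (
    (-0.180, 0.15, 0.025),
    (-0.040, -0.25, 0.008),
    (0.000, 1.00, 0.010),
    (0.030, -0.20, 0.008),
    (0.250, 0.35, 0.040),
    (0.350, -0.12, 0.012),
)


def synth_ecg(beats: BeatAnnotations, fs: float = 250.0, snr_db: float | None = None,
              seed: int = 0) -> EcgSignal:
    """Template-based single-lead ECG for the given beat times.

    ``snr_db`` adds white noise at the requested signal-to-noise ratio
    relative to the clean trace's variance.  Mean rates above 3 beats/s make
    neighbouring templates overlap and are rejected.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    r = beats.r_times
    if r.size >= 2 and np.min(np.diff(r)) < 1.0 / 3.0:
        raise ValueError("beat rate above 3 beats/s: waveform templates would overlap")
    t0 = 0.0
    t_end = r[-1] + 0.6
    n = int(np.ceil((t_end - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    x = np.zeros(n)
    for offset, amp, width in _TEMPLATE:
        centres = r + offset
        # add each bump only over +-5 widths for speed
        half = int(np.ceil(5 * width * fs))
        for c in centres:
            i0 = max(0, int(np.floor((c - t0) * fs)) - half)
            i1 = min(n, int(np.ceil((c - t0) * fs)) + half + 1)
            if i1 <= i0:
                continue
            x[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - c) / width) ** 2)
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        noise_sd = np.sqrt(np.var(x) / (10.0 ** (snr_db / 10.0)))
        x = x + rng.normal(0.0, noise_sd, size=n)
    return EcgSignal(samples=x, fs=fs, t0=t0)


# ---------------------------------------------------------------------------
# Ectopic contamination
# ---------------------------------------------------------------------------

def inject_ectopics(beats: BeatAnnotations, spec: EctopicSpec) -> BeatAnnotations:
    """Displace ``n_outliers`` distinct beats by +delay; input untouched.

    Eligible beats lie strictly inside the record (never the first or last)
    and inside the placement window when one is given.
    """
    r = beats.r_times.copy()
    if spec.n_outliers == 0:
        return BeatAnnotations(r_times=r)
    if r.size < 3:
        raise ValueError("need at least 3 beats to place an ectopic")
    eligible = np.arange(1, r.size - 1)
    if spec.window is not None:
        lo, hi = spec.window
        eligible = eligible[(r[eligible] >= lo) & (r[eligible] <= hi)]
    if eligible.size < spec.n_outliers:
        raise ValueError(
            f"placement window holds {eligible.size} eligible beats, "
            f"fewer than n_outliers={spec.n_outliers}"
        )
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(eligible, size=spec.n_outliers, replace=False)
    r[chosen] += spec.delay
    order = np.argsort(r, kind="stable")
    return BeatAnnotations(r_times=r[order])


# ---------------------------------------------------------------------------
# Cohorts and surrogates
# ---------------------------------------------------------------------------

def cohort(
    cfg_base: ScenarioConfig,
    n_subjects: int,
    between_subject_sd: float = 0.08,
) -> list[tuple[IbiSeries, IbiSeries]]:
    """Paired pre/post IBI series for a synthetic cohort.

    Per subject, ``base_rate``, ``a_lf`` and ``a_hf`` are perturbed by
    independent log-normal factors of scale ``between_subject_sd``; one
    transition per record, split at ``transition_time``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if cfg_base.transition_time is None:
        raise ValueError("cohort scenarios need a transition_time to split on")
    rng = np.random.default_rng(cfg_base.seed)
    out: list[tuple[IbiSeries, IbiSeries]] = []
    for _ in range(n_subjects):
        factors = np.exp(rng.normal(0.0, between_subject_sd, size=3))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(
            cfg_base,
            base_rate=cfg_base.base_rate * factors[0],
            a_lf=min(cfg_base.a_lf * factors[1], 0.4),
            a_hf=min(cfg_base.a_hf * factors[2], 0.4),
            seed=sub_seed,
        )
        peak_rate = cfg.base_rate * max(1.0, cfg.post_rate_factor)
        if not (0.5 <= cfg.base_rate <= 3.0 and peak_rate <= 3.0):
            raise ValueError(
                f"perturbed rate {cfg.base_rate:.2f} beats/s is outside [0.5, 3]"
            )
        ibi = build_ibi(ipfm_beats(cfg))
        tt = cfg.transition_time
        pre_mask = ibi.t <= tt
        post_mask = ibi.t > tt
        if pre_mask.sum() < 10 or post_mask.sum() < 10:
            raise ValueError("transition leaves too few intervals on one side")
        out.append(
            (
                IbiSeries(t=ibi.t[pre_mask], ibi=ibi.ibi[pre_mask]),
                IbiSeries(t=ibi.t[post_mask], ibi=ibi.ibi[post_mask]),
            )
        )
    return out


def correlated_surrogate(
    t: np.ndarray, values: np.ndarray, noise_sd: float = 0.5, seed: int = 0
) -> np.ndarray:
    """A beat-to-beat surrogate (e.g. blood-pressure-like) series that
    co-fluctuates with ``values``: standardized signal plus white noise.

    Intended only for exercising the correlation machinery; it models no
    vascular physiology.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    z = np.full_like(v, np.nan)
    z[finite] = (v[finite] - np.mean(v[finite])) / np.std(v[finite], ddof=1)
    rng = np.random.default_rng(seed)
    return z + rng.normal(0.0, noise_sd, size=v.size)
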
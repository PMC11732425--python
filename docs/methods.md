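# Methods

This note records the model, the numerical choices and the limitations of
the package in one place. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## The index model

The estimator treats autonomic state as expressed in two separable
features of the interbeat-interval (IBI) series: the baseline cycle
duration, and the shape of the short-lag correlation structure. Both are
read off the Poincaré plot — the scatter of (IBI_i, IBI_{i+1}) — inside a
causal trailing window Ω_t : t − T ≤ t_i ≤ t. Each interval is anchored at
its *closing* beat, so a window never contains an interval that has not
yet been observed; evaluation happens per beat by default (a uniform grid
is available).

Per window: CCD(t) = √(x̄² + ȳ²) with x̄, ȳ the means of the two pair
coordinates; SD1/SD2 are square roots of the eigenvalues of the pairs'
2×2 covariance. Eigenvalues are mapped to SD1/SD2 **by eigenvector
orientation** (nearest to the (1,−1) and (1,1) axes respectively), not by
magnitude. On pathological inputs (e.g. a strictly alternating rhythm,
where all dispersion lies across the identity line) magnitude ordering
would silently swap the axes; orientation matches the closed forms
SD1² = ½·var(ΔIBI), SD2² = |2·var(IBI) − ½·var(ΔIBI)| exactly, which the
suite verifies to <5% median relative error on stationary series and via
the AR(1) limit SD1→√(γ₀−γ₁), SD2→√(γ₀+γ₁).

The time-resolved series are demeaned over the analysed segment, re-centred
by whole-recording anchors (CCD₀, SD₀₁, SD₀₂ from one Poincaré computation
over the full record, same covariance method), and combined:

    D = (CCD − mean CCD) + CCD0          D~ = 2·mean(D) − D
    CPI = kp·((SD1 − mean SD1) + SD01) + D
    CSI = ks·((SD2 − mean SD2) + SD02) + D~

Flipping D about its mean preserves the mean exactly, so CSI and CPI share
a common baseline when the variability terms vanish; with ks = kp = 0 the
indices reduce to the pure (flipped) heart-rate trends. Defaults ks = 1,
kp = 10 weight CSI toward the cycle-duration term and CPI toward fast
variability; `sweep_coefficients` re-derives them by condition
separability on paired cohorts.

Demeaning scope is the analysed trial segment (configurable), matching the
per-trial normalisation used in group analyses; anchors always come from
the whole recording. Missing descriptor samples (windows with fewer than
`min_pairs` = 3 pairs) are NaN; gaps of at most 2 s are linearly
interpolated before demeaning, longer gaps stay missing and are excluded
from means.

## Covariance estimators

- **exact** — sample covariance, n−1 denominator. The n−1 convention is
  used for every standard deviation in the package, including the
  closed-form (`approximate`) route.
- **robust** (default) — Ledoit–Wolf shrinkage toward the scaled identity
  μI, μ = trace/2, with the analytic optimal intensity clipped to [0, 1].
  Implemented locally for speed in the sliding window (thousands of 2×2
  problems per recording); equality with scikit-learn's `LedoitWolf` is
  asserted in the suite, and convergence to the sample covariance at
  n = 10⁴ is below 2% Frobenius distance.
- **p95** — minimum covariance determinant: the plain sample covariance of
  the h = round(0.95·n) points whose covariance has the smallest
  determinant. For the window sizes the sliding estimator actually sees
  (n ≈ 15–40 pairs, so only 1–2 points are dropped) the optimal subset is
  found by exhaustive enumeration, which is deterministic; larger problems
  use scikit-learn's FAST-MCD with a seeded `random_state` (`CovMethod.seed`,
  default 0). No Gaussian consistency rescaling is applied: the estimator
  is defined as the covariance the selected points themselves fulfil. It
  therefore runs deliberately low on clean data — the "over-trimming cost"
  that shows up downstream as a reduced effect magnitude — while
  withstanding 5% gross outliers within 25% of the clean covariance where
  the exact estimator inflates more than twofold.
- **approximate** — the closed forms above, no covariance matrix involved.

## Misdetection screening

Timing outliers are flagged on the derivative of the IBI series: intervals
where |Δibi − median| exceeds `threshold_factor` (default 4) times the
normal-consistent MAD of Δibi. When the MAD degenerates to zero the mean
absolute deviation substitutes (so one ectopic in an otherwise perfectly
regular rhythm still flags); if that is zero too the series is perfectly
regular and nothing is flagged. Screening is flag-only: the series is
never modified implicitly, `drop_flagged` exists for callers that want
removal. Note the screen is a *gross-error* detector: a +30 ms ectopic in
a series with ±90 ms respiratory swings is not detectable this way, and
that is intended — the robustness of the indices to such small
displacements is handled by the covariance estimators, not the screen.

## QRS and QT detection

The QRS chain is the canonical one: zero-phase band-pass 5–15 Hz,
derivative, squaring, 150 ms moving-window integration, adaptive dual
threshold with a 200 ms refractory period and search-back over gaps longer
than 1.66× the running RR estimate; detections are refined to the extremum
of the band-passed ECG (zero-phase filtering keeps that on the R-peak).
QT intervals come from windowed extremum searches: Q = argmin over
[R−50 ms, R) (half-open), T-end = argmin over [R+100 ms, R+500 ms]
(closed), both rounded to the nearest sample; beats whose windows leave
the record are dropped. On synthetic templates with known extrema the loop
closes to ≤5 ms; at 10 dB SNR sensitivity and positive predictivity stay
≥0.99.

## Spectral comparator

IBI (or QT) series are cubic-spline resampled to 4 Hz, demeaned, made
analytic via the Hilbert transform, and transformed with a smoothed pseudo
Wigner–Ville distribution: the instantaneous autocorrelation is filtered
in the ambiguity (Doppler × lag) domain by

    Φ(ν, τ) = exp{ −π [ (ν/ν0)² + (τ·τ0/2)² ]^(2λ) }

with ν0 = 0.03, τ0 = 0.06, λ = 0.3. The kernel is the package's one
approximation site and lives in a single function. Convention chosen here:
ν is Doppler in Hz, so ν0 sets the time smoothing (variations slower than
~1/ν0 survive); τ0 is the *full* frequency-smoothing bandwidth in Hz, so
lags beyond ~2/τ0 ≈ 33 s are attenuated. Two readings were rejected on
correctness grounds: a literal lag scale of τ0 seconds would suppress every
nonzero lag at 4 Hz (no frequency resolution at all), and a half-bandwidth
reading (lag cutoff 1/τ0 ≈ 17 s) lets the λ = 0.3 kernel's power-law tails
leak ~13% of a pure 0.1 Hz tone past 0.15 Hz, defeating the LF/HF split
the method exists to provide. With the chosen convention a single-band
modulation keeps >90% of its LF+HF power in its own band, cross-terms of a
two-tone input are suppressed below 10% of the auto-terms (vs ~85%
unsmoothed), and the surface's frequency integral conserves the signal
variance within 10%.

Numerics: the Doppler-domain filtering is zero-padded along time — the
kernel's slow tails otherwise wrap circularly around the record edges and
displace transient energy by seconds. Negative surface values (a bilinear
artifact) are clipped at zero before band integration; band powers are
trapezoidal integrals over LF 0.04–0.15 Hz and HF 0.15–0.4 Hz; the first
and last 1/(2·0.04) ≈ 12.5 s carry a burn-in mask.

## Synthetic data generator

Beats follow an integral pulse frequency modulation (IPFM) model: a beat
fires when ∫ r(t) dt crosses the next integer, with

    r(t) = base_rate · g(t) · (1 + a_lf(t) sin(2π f_lf t + φ₁) + a_hf(t) sin(2π f_hf t + φ₂))

IPFM is used because it gives direct control of the IBI series' spectral
content at f_lf and f_hf — the property every comparator test needs.
Defaults describe a resting adult: 1.1 beats/s (66 bpm), a_lf = 0.06 at
0.10 Hz, a_hf = 0.08 at 0.25 Hz, 3 ms Gaussian beat-timing jitter. The
oscillator phases are drawn from the seed: physiological oscillations are
not phase-locked to the protocol clock, and coherent phases across a
cohort would correlate its members (phase-locked cohorts measurably break
the exchangeability the group statistics assume).

The `cold_pressor` preset steps, at t = 120 s of a 240 s record, the rate
by ×1.25, the HF amplitude by ×0.4 and the LF amplitude by ×2 — cycle
shortening, vagal withdrawal and increased slow oscillation, the classic
sympathetic-surge signature. The LF step matters: without it the IBI-domain
SD2 would *fall* at the onset purely through the 1/rate scaling, which is
not what a sympathetic activation looks like. The `tilt` preset uses the
same sign pattern with milder factors. Ectopic contamination is a pure
+30 ms displacement of up to 10 randomly selected interior beats (the
interval closing at the beat grows by the delay, the next shrinks by it;
total duration is conserved). Cohorts perturb base rate and amplitudes by
log-normal factors (default scale 0.08) per subject.

What the generator does **not** emulate: real R-peak jitter from waveform
morphology, missed/extra beats, respiratory sinus arrhythmia's
non-sinusoidal shape, baseline wander, slow autonomic drifts, or natural
artifact processes. Consequently, passing tests show the estimators'
algebra, calibration and relative robustness under controlled conditions —
not field performance on clinical recordings. One concrete instance: on
real recordings the 95%-trimming estimator showed the smallest clean-data
condition effect; on this generator's clean sinusoidal records the
trimming cost (~1.5% of SD2) is offset by the window-size granularity of
the trim fraction (pre-onset windows hold ~16 pairs → one dropped point is
a 6.3% trim; faster post-onset windows hold ~20 → 5%), so the p95 clean
effect lands ~1% *above* the exact estimator's instead. The corresponding
acceptance assertion is left failing rather than tuned around, because the
discrepancy is a property of clean synthetic data, not of the estimator
implementation (which is verified by exhaustive-enumeration oracle).

## Statistics

- Wilcoxon signed-rank: zeros discarded; W = sum of positive-difference
  ranks (midranks for ties); Z from the normal approximation with tie
  correction; p exact by sign-flip enumeration for n ≤ 12 (ties included,
  via a subset-sum convolution on doubled ranks), normal otherwise.
  Reported alongside α = 0.05/N for N configured comparisons (4 for the
  sympathetic marker family, 3 for the parasympathetic one).
- Friedman: midranks per row, χ² with tie correction, p from χ²(k−1);
  degenerate all-tied inputs return (0, 1).
- Spearman: scipy's rank correlation with the Student-t p approximation;
  the significance flag additionally requires ρ > 0 (a negative
  correlation is never "significant" for an index that should co-vary
  positively with its criterion), with an optional exclusion mask for
  burn-in segments. Type-I error calibrates to 0.03–0.07 at α = 0.05 in
  null simulation.
- Binomial post hoc: upper tail P(X ≥ k) under Binomial(n, p₀), p₀ = 0.5
  by default ("majority of subjects") and configurable.
- Effect magnitude: mean of the index over (onset, onset+span] minus the
  mean over [onset−span, onset], span 120 s by default; the robustness
  experiment recomputes it per covariance method across n = 0…10 injected
  ectopics × repetitions and reports medians and MADs.

## Problem sizes

The suite and the acceptance script run everything at the scale stated
above: 240–470 s records (~300–500 intervals), 20-subject cohorts, 50-seed
route-agreement batches, 20-repetition robustness grids, 5000-draw
calibration loops. These sizes put every sampling-error-limited check an
order of magnitude inside its tolerance while keeping a full run in tens
of seconds.

## Known limitations

- Misdetection screening cannot see displacements smaller than the
  physiological beat-to-beat variability (by design; see above).
- The SPWV kernel convention is fixed by behaviour, not by an external
  definition; other conventions exist and are one function swap away.
- WFDB support covers single-segment format-16 records (read/write) only;
  beat annotations travel as CSV, not binary annotation files.
- Indices are in seconds-scaled arbitrary units; no mapping to absolute
  physiological units (e.g. nerve activity) is attempted.
- The ECG template generator rejects rates above 3 beats/s (template
  overlap) and its T-end trough is only unambiguous below ~110 bpm.
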
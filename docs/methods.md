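# Methods

`sblfp` analyzes multi-region local-field-potential (LFP) recordings made
while a subject mouse performs binary social-discrimination tasks.  A
session is a 5-min *baseline* period (two empty chambers) followed by a
5-min *encounter* period (two stimuli), with three tasks — social preference
(SP: social vs. object), emotional-state preference (EsP: isolated vs.
grouped) and sex preference (SxP: female vs. male) — and three sessions per
task per subject.  Behavior enters as a table of timed investigation bouts
toward the chambers.  This note records the models, parameter choices, and
numerical decisions; nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and filters

Time is seconds from session start; intervals are half-open `[start, end)`.
Channels carry codes from an 18-region vocabulary.  Analysis eligibility
follows the recording coverage: a region is analyzed only if recorded in
more than 5 sessions across at least 3 mice (strict `> 5`), and a region
pair only if co-recorded in at least 5 sessions from at least 2 subjects
within each of the three tasks.  Investigation bouts shorter than 2 s are
discarded everywhere (strict `> 2 s`; short bouts do not support reliable
theta coherence estimates).  Both thresholds are parameters.  Signals
within ±30 s of stimulus insertion and removal are excluded from
period-wise statistics ("around" is read as a symmetric window; the half
width is a parameter).  The relative discrimination index is
`RDI = (T_pref − T_other) / (T_pref + T_other)` over investigation time —
the formula is the standard one from the three-chamber literature and is
antisymmetric under swapping the preferred label.

## Spectral power

Spectrograms are discrete-prolate-spheroidal (dpss) multitaper short-time
PSDs: 2-s windows, 0.5-s stride (so 0.5-s output bins on a 0.5-Hz grid),
time-bandwidth NW = 2 with the first 3 tapers averaged (≈ ±1 Hz resolution
bandwidth).  The 0.5-s stride is required by the event-aligned Z-score
analysis, which bins at 0.5 s; window overlap is configurable.  Bands are
theta 4–12 Hz and gamma 30–80 Hz.  Raw traces are decimated to 5 kHz and
low-passed at 300 Hz with a 4th-order Butterworth applied forward-backward
(zero phase, so filtering cannot masquerade as connectivity); the filter
order is our choice.  Gamma contains the 50 Hz mains frequency; an optional
49–51 Hz notch exists but is off by default.

Summaries: session-wide change `ΔθP/ΔγP` = encounter mean − baseline mean of
band power (exclusion mask honored).  Bout-locked change `^ΔθP/^ΔγP` =
average power per second during a stimulus's valid bouts minus average power
per second during baseline empty-chamber investigation, per session, then
averaged over sessions.  "Per second" is realized as a duration-weighted
mean over concatenated bout bins (total power-seconds / total seconds); a
per-bout-then-average variant is available.  Event-aligned Z-scores use the
pre-event 5-s window as baseline per event (`z = (p − μ_pre)/σ_pre` in 0.5-s
bins over ±5 s), averaged within session and then across sessions; events
without a full pre-window or with zero pre-window SD are dropped.  The
Z-score pipeline is invariant to global rescaling of the raw trace.

## Coherence

Magnitude-squared coherence (MSC) is Welch's overlapped averaged
periodogram estimate `|S_xy|² / (S_xx S_yy)` — the magnitude-squared form,
bounded in [0, 1], symmetric, and blind to pure delays.  Session-wide MSC
uses 2-s Hann segments at 50% overlap (0.5 Hz grid, consistent with the
power analysis); segments never span masked gaps.  The session-wide change
statistic per pair and band is `Δ = mean(d)/SD(d)` with
`d(f) = MSC_enc(f) − MSC_base(f)` across the band's frequency bins (sample
SD).  The μ/σ axis is our interpretation: frequency bins are the only axis
that yields one number per pair per session from the stated inputs.  The
bout-locked variant estimates MSC over 1-s sub-windows drawn inside
concatenated bout segments (a 2-s window would exclude most bouts) and
subtracts the baseline empty-chamber estimate.  MSC carries an upward bias
of about `1/n_segments` for independent signals; the bout-vs-baseline
subtraction cancels most of it when segment counts are comparable.

## Spectral pairwise-conditional Granger causality

Signals are decimated to 500 Hz through a sharp polyphase FIR (≈6 Hz
transition at the new Nyquist).  A VAR model is fitted per period by the
multichannel Levinson–Whittle recursion on sample autocovariances (OLS is
available as a cross-check), with the order chosen by BIC over 1..60 in a
single recursion sweep.  Data are demeaned per channel first.  The fitted
model's autocovariance sequence comes from the companion-form discrete
Lyapunov equation, extended by the Yule–Walker recursion and truncated at
a 1e-8 relative decay (cap 1500 lags).  For each directed pair (source j →
target i given the rest), the reduced model with the source omitted is
re-derived from the autocovariance by the same Whittle recursion, and
Geweke's conditional spectral GC is evaluated by the partitioned-spectrum
construction: rotate the full model's residuals so the target's innovation
decorrelates from the others, embed the reduced AR polynomial with an
identity row for the omitted source, and read the target's intrinsic versus
total innovation power per frequency.  For two channels this reduces to the
classic unconditional formula.  Band GC is the bandwidth-normalized mean of
spectral GC over the band's bins, so theta and gamma values are comparable;
the full-range mean satisfies Geweke's spectral-integral equality against
the time-domain statistic (verified to 1e-3 and, on model autocovariances,
to machine precision).  Numerical guards: spectral values below −1e-10 are
errors, tiny negatives are clipped to 0, singular frequencies are
interpolated and warned; unstable fits raise with the spectral radius.

Per-session orders are selected independently for baseline and encounter
(a shared fixed order is available); encounter-vs-baseline change per
directed pair is tested across sessions with a two-sided paired Wilcoxon
and Benjamini–Hochberg correction across directed pairs, and directional
asymmetry (change(1→2) − change(2→1)) likewise.  The test choice is ours —
a rank test tolerates the heavy-tailed GC change distribution.

## Screening statistics

Pair selection takes the preferred-minus-less-preferred bias of bout-locked
changes and keeps units strictly beyond mean ± 1.5 SD of the bias
distribution (boundary ties excluded).  Region over-representation among
selected pairs uses an exact one-sided binomial tail, `p0` being the
region's share of the pair universe.  Octant classification assigns each
region the sign triple of its biases across the three tasks (zero biases
tie-break positive, warned) and reports the exact binomial tail
`P(X ≥ k_max)` for the modal octant under uniform 1/8 assignment — the
transparent construction, with an optional Monte-Carlo check of the
max-count distribution (which is stochastically larger than the single-cell
tail).  Correlations are Pearson or Spearman with pairwise missing removal.
The group-comparison dispatcher screens normality with Shapiro–Wilk and
routes to paired t / Wilcoxon signed-rank, t / Mann–Whitney, or ANOVA /
Kruskal–Wallis with a hand-rolled Dunn post-hoc (tie-corrected rank z,
FDR-adjusted).  All multiple-comparison control is Benjamini–Hochberg.

## Context decoder

Feature rows are "average bouts": one row per session × stimulus, one
column per eligible region pair, entries the per-session per-stimulus mean
bout coherence change; pairs never recorded for a mouse are missing.  Mice
with fewer than 40 recorded pairs are excluded.  Per-mouse normalization
subtracts, per pair, the unweighted average of the per-stimulus means so no
stimulus dominates the centering.  Missing entries are imputed by 20
iterations of randomized per-column least squares: columns visited in fresh
random order, each regressed with intercept on a random subset of
`min(⌊n_rows/2⌋ − 1, n_pairs − 1)` other columns over all rows (current
imputed values included, matching the printed objective; a
fit-on-observed-only mode exists), minimum-norm on rank deficiency;
originally observed entries are never altered.  Decoding is
leave-one-mouse-out: per held-out mouse and repeat, the training fold is
class-balanced by random down-sampling and an 80-tree random forest
(library-default splitting) predicts the mouse's rows; per-mouse confusion
matrices average the repeats, the aggregate pools raw counts.  The null
replaces predictions with uniform draws, 83 averaged matrices (of 100 inner
repeats) per mouse.  Per-cell significance compares the per-mouse real
percentages with all per-mouse null percentages by two-sided Mann–Whitney,
dropping mice without rows of the cell's ground-truth class, FDR across
cells.  All randomness flows from one seeded generator with derived
substreams; a fixed master seed reproduces confusion summaries exactly.
The 6-stimulus and 3-context labelings share a single imputed table
(imputation never sees labels).

### A caution on the per-cell null comparison

The per-cell Mann–Whitney test is well calibrated when the compared
matrices come from the same random-classifier law (≈4–5% rejections at
α = 0.05, as the suite verifies).  It is *anticonservative* for a trained
classifier on signal-free data: the 12 per-mouse values share most of their
training folds, so any finite-sample class bias shifts them coherently,
while each null matrix averages 100 uniform draws and is therefore much
tighter than the real values' sampling spread.  In repeated zero-effect
end-to-end runs a majority showed at least one FDR-significant diagonal
cell (run diagonals ranged roughly 21–42% around the 33.3% chance level).
Conclusions should therefore rest on the magnitude of the diagonal above
chance, not on per-cell p-values alone; the corresponding specificity test
in the suite is expected to fail and documents this property.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with every injected effect recoverable:

* **Oscillators** are band-pass-filtered Gaussian noise (theta ≈ 4–12 Hz,
  gamma ≈ 30–80 Hz) over a 1/f pink background — not pure tones, so spectra
  look LFP-like and coherence estimates are non-degenerate.
* **Coherence** is controlled by linear mixing: one global shared source per
  band carries a flat coherence floor (`a² = √floor` in every region gives
  pair MSC `a⁴ = floor`), and pairs with targets above the floor get a
  dedicated shared source with `w² = √ρ − a²`, so the band MSC is
  `(a² + w²)² = ρ` up to the small in-band pink background (realized values
  run a few percent low; rank order is preserved).  Targets below the floor
  clip to it with a warning.  State changes (encounter coherence signatures,
  bout offsets) are piecewise changes of these weights with the independent
  component absorbing the variance difference, so band power stays constant
  while coherence moves.
* **Power effects** are amplitude-gain envelopes common to all of a
  region's band components, so they change power quadratically without
  touching coherence.
* **Behavior** is an alternating renewal process: exponential inter-bout
  gaps (mean 8 s, minimum 0.5 s), lognormal durations (median 3 s,
  σ = 0.5), stimulus chosen by preference odds (default 2:1) — typical
  investigation-time budgets for these assays.  Baseline bouts target the
  empty chambers.
* **Defaults** follow the study layout: 5 kHz sampling, 300 s + 300 s
  periods, three sessions per task, ten regions, per-subject region dropout
  emulating mistargeted/non-functional electrodes.  Theta amplitude 1.0,
  gamma 0.5, pink 0.45 keep the oscillators dominant in-band (the pink
  background contributes ≈5% of theta-band power, which is what limits
  power-ratio recovery to a few percent).
* **Directed coupling** for GC oracles comes from explicit stable VAR
  processes with the closed-form Geweke value
  `ln(1 + a²σ_x²/σ_y²)` for the bivariate VAR(1).

`context_signature_config` raises encounter theta coherence on disjoint
thirds of 10 designated pairs, one third per task, by 0.125 — calibrated
once so the induced shift of the bout-coherence feature equals about one
between-session SD (standardized effect ≈ 1).

What the generator does **not** emulate: volume conduction, non-stationary
1/f slopes, cross-frequency coupling, movement artifacts, or
electrode-specific noise.  Passing tests therefore demonstrate estimator
correctness and pipeline recoverability, not robustness to those real-data
nuisances.

## Problem sizes used in tests and the acceptance script

Unit and end-to-end checks run on scaled sessions — typically 500 Hz
sampling with 30–120 s periods, 4–6 regions, and 12 subjects for decoding
with 20 cross-validation repeats — sizes chosen so the full battery
completes on a single CPU while every effect stays well above estimator
noise.  The power-gain recovery check runs at the full 5 kHz / 300 s + 300 s
session size.  GC oracles use 10⁵ samples; order recovery uses 10 seeds at
5 × 10⁴.  The acceptance script reports each quantity with the problem size
it used.

## Known limitations

* Coherence targets are realized a few percent low where the pink
  background overlaps the band (strongest for gamma, whose oscillator
  amplitude is half the theta one).
* Bout-locked MSC with 1-s windows resolves theta coarsely (1 Hz grid,
  ~9 band bins); very short total bout time per stimulus yields a missing
  feature for that session (logged), which is the decoder's missingness
  path.
* The pairwise-conditional GC estimator assumes an adequate joint VAR; at
  severely misspecified orders or near-unstable fits the Whittle recursion
  truncates with a warning.
* The per-cell decoder significance test is anticonservative under the
  global null (see the caution above).
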
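# sblfp

Multi-region LFP rhythmicity analysis for binary social-discrimination
tasks in mice.

Subject mice implanted with multi-region electrode arrays perform three
two-choice tasks — social preference (social vs. object), emotional-state
preference (isolated vs. grouped) and sex preference (female vs. male) —
each session a 5-min baseline with empty chambers followed by a 5-min
encounter with the stimuli.  `sblfp` asks how local-field-potential
rhythmicity (theta 4–12 Hz, gamma 30–80 Hz) across up to 18 brain regions
reorganizes with the social context: which regions change band power, which
pairs synchronize, which regions lead, and whether the pattern of pairwise
synchronization during investigation bouts carries enough information to
decode the task.

It is written for systems-neuroscience users who have continuous
multichannel LFP plus a table of timed investigation bouts, and for anyone
who wants a tested reference implementation of this analysis chain on
synthetic data with known ground truth.

## What it computes

* **Band power** — dpss multitaper spectrograms (2-s windows, 0.5-Hz /
  0.5-s grid); session-wide changes ΔθP, ΔγP = encounter − baseline mean
  band power; bout-locked variants ^ΔθP, ^ΔγP referenced to empty-chamber
  investigation; event-aligned Z-scores around bout starts/ends,
  transitions and repeats.
* **Coherence** — Welch magnitude-squared coherence
  `C_xy(f) = |S_xy|² / (S_xx S_yy)`; the normalized change
  `ΔCo = μ(C_enc − C_base) / σ(C_enc − C_base)` over the band's frequency
  bins; bout-locked ^ΔθCo, ^ΔγCo from 1-s windows inside bouts.
* **Granger causality** — VAR models at 500 Hz (Levinson–Whittle fit, BIC
  order), autocovariance by the Lyapunov/Yule–Walker route, and Geweke's
  frequency-domain *pairwise-conditional* GC for every directed region pair
  given all others, summarized per band; encounter-vs-baseline change and
  directional-asymmetry tests with FDR.
* **Screening** — mean ± 1.5 SD selection of stimulus-biased pairs, exact
  binomial region over-representation, octant (sign-pattern) classification
  across tasks, correlation utilities, and a normality-dispatched standard
  test battery with Benjamini–Hochberg correction.
* **Context decoding** — session × stimulus feature rows of bout coherence
  changes; per-mouse normalization; MICE-style iterative regression
  imputation of unrecorded pairs; leave-one-mouse-out random forests (80
  trees, balanced folds, repeated); a uniform random-classifier null (83
  averaged matrices per mouse) with per-cell Mann–Whitney significance.
* **Synthetic data** — a first-class generator producing multi-region LFP
  with controllable band power, pairwise coherence (shared-oscillator
  mixing), bout-locked modulation, per-task coherence signatures, VAR
  coupling for GC oracles, and per-subject region dropout — every effect
  recoverable by the stages above.

## Worked example

```python
from sblfp.simulate import SimulationConfig, simulate_session
from sblfp.datamodel import preference_index, valid_bouts
from sblfp.power import delta_band_power
from sblfp.coherence import coherence_change

cfg = SimulationConfig(
    sampling_rate=500.0, baseline_s=120.0, encounter_s=120.0,
    encounter_gain={"theta": 1.3, "gamma": 1.0},               # amplitude gain
    context_coherence_offsets={"SP": {("PrL", "vDG"): {"theta": 0.25}}},
    preference_weight=3.0, mean_gap_s=5.0,
)
session, bouts, truth = simulate_session(cfg, "M01", "SP", 1, seed=7,
                                         regions=["PrL", "vDG"])

pi = preference_index(valid_bouts(bouts), "social")
s = delta_band_power(session, "PrL", "theta", exclusion_half_window_s=10.0)
cc = coherence_change(session, ("PrL", "vDG"), "theta",
                      exclusion_half_window_s=10.0)
```

Output (printing the fields shown):

```
RDI (social preferred): +0.35 over 36 s, 6 transitions
PrL thetaP baseline 0.120, encounter 0.192 uV^2/Hz -> delta-thetaP +0.072 (ratio 1.60)
PrL-vDG baseline thetaCo 0.15, normalized change delta-thetaCo +2.69
```

Reading it: the 3:1 preference odds show up as a positive discrimination
index (RDI = +0.35 toward the social stimulus).  The injected 1.3×
encounter theta amplitude gain appears as a ≈1.6× power ratio (amplitude
gains act quadratically on power; the expected 1.69 is diluted a few
percent by the 1/f background and single-session estimator noise).  The
injected encounter coherence rise on PrL–vDG (0.15 → 0.40 target) yields a
strongly positive normalized coherence change.

The same flows are scriptable from the shell:

```bash
sblfp simulate --config sim.yaml --out data/ --seed 1
sblfp validate data/
sblfp behavior data/ --out rdi.csv
sblfp power data/ --band theta --out power.csv
sblfp coherence data/ --band theta --mode bout --out coh.csv
sblfp decode data/ --label context_3class --seed 1 --out decode/
```

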
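"""Synthetic multi-region LFP and behavior with known ground truth.

Every downstream stage of the pipeline (band power, coherence, Granger
causality, the context decoder) is exercised on data from this module, so
each generated effect is recoverable by construction:

* **Band oscillators** are band-pass-filtered Gaussian noise (theta ~4-12 Hz,
  gamma ~30-80 Hz), not pure tones, so spectra resemble LFP and coherence
  estimates are non-degenerate.
* **Pairwise coherence** is set by linear mixing of shared oscillators.
  One *global* narrowband source per band carries the coherence floor: with
  weight ``a`` in every region, every pair's band MSC is ``a**4``, so
  ``a**2 = sqrt(floor)``.  A pair whose target ``rho`` exceeds the floor
  additionally receives a *dedicated* shared source with weight
  ``w**2 = sqrt(rho) - a**2`` in both regions; the cross-spectral weight is
  then ``a**2 + w**2 = sqrt(rho)`` and, with per-region band variance
  normalized to 1 (the independent component absorbs the remainder), the
  band MSC is ``(a**2 + w**2)**2 = rho`` up to the small in-band pink
  background.  Targets below the floor are clipped to it (warned).
* **State and bout effects** are amplitude-gain envelopes (encounter gain,
  bout-locked gain) and piecewise changes of the mixing weights (context
  coherence signatures, bout coherence offsets).
* **Directed influence** for Granger-causality oracles comes from explicit
  stable VAR processes with closed-form time-domain GC.

Same seed + config gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .datamodel import (
    EMPTY_STIMULUS,
    TASK_STIMULI,
    TASKS,
    Dataset,
    RecordingSession,
    make_bout_table,
)

Pair = tuple[str, str]

DEFAULT_REGIONS = (
    "PrL", "IL", "AcbC", "AcbSh", "BLA", "MeAD", "LS", "vCA1", "vDG", "Pir",
)

BANDS = {"theta": (4.0, 12.0), "gamma": (30.0, 80.0)}


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the generated study.

    Defaults reproduce the study layout: 5-min baseline + 5-min encounter
    sessions sampled at 5 kHz, three sessions of each of the three tasks per
    subject, ten recorded regions with per-subject electrode dropout.
    """

    n_subjects: int = 12
    regions: Sequence[str] = DEFAULT_REGIONS
    dropout_prob: float = 0.1
    min_regions: int = 2
    sampling_rate: float = 5000.0
    baseline_s: float = 300.0
    encounter_s: float = 300.0
    n_sessions_per_task: int = 3
    # oscillator amplitudes (band-limited unit-variance noise scaled by these)
    theta_amplitude: float = 1.0
    gamma_amplitude: float = 0.5
    pink_amplitude: float = 0.45
    # encounter-induced global amplitude gain per band
    encounter_gain: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 1.2, "gamma": 1.1}
    )
    # bout-locked amplitude gain: stimulus -> band -> gain (all regions,
    # or restricted to bout_gain_regions)
    bout_gains: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    bout_gain_regions: Sequence[str] | None = None
    # coherence: flat baseline target for all pairs, per-pair overrides,
    # per-task encounter offsets (the "context signature"), per-stimulus
    # bout offsets
    baseline_coherence: float = 0.15
    coherence_targets: Mapping[Pair, Mapping[str, float]] = field(default_factory=dict)
    context_coherence_offsets: Mapping[str, Mapping[Pair, Mapping[str, float]]] = field(
        default_factory=dict
    )
    bout_coherence_offsets: Mapping[str, Mapping[Pair, Mapping[str, float]]] = field(
        default_factory=dict
    )
    # bout process: exponential gaps, lognormal durations, preference weights
    mean_gap_s: float = 8.0
    min_gap_s: float = 0.5
    bout_median_s: float = 3.0
    bout_sigma: float = 0.5
    preference_weight: float = 2.0  # preferred : less-preferred odds

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_sessions_per_task < 1:
            raise ValueError("need at least one subject and one session per task")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        for g in self.encounter_gain.values():
            if g < 0:
                raise ValueError("gains must be >= 0")
        for stim in self.bout_gains.values():
            for g in stim.values():
                if g < 0:
                    raise ValueError("gains must be >= 0")
        if not (0 <= self.baseline_coherence <= 1):
            raise ValueError("baseline_coherence must be in [0, 1]")
        for per_band in self.coherence_targets.values():
            for rho in per_band.values():
                if not (0 <= rho <= 1):
                    raise ValueError("coherence targets must be in [0, 1]")
        nyq = self.sampling_rate / 2
        for lo, hi in BANDS.values():
            if hi >= nyq:
                raise ValueError(
                    f"band edge {hi} Hz not below Nyquist ({nyq} Hz); "
                    "raise sampling_rate"
                )


@dataclass
class GroundTruth:
    """What was injected, aligned with the emitted dataset."""

    # session_id -> pair -> band -> (baseline rho, encounter rho)
    coherence: dict = field(default_factory=dict)
    # session_id -> band -> encounter amplitude gain
    power_gain: dict = field(default_factory=dict)
    # session_id -> task label
    context: dict = field(default_factory=dict)
    # subject -> recorded regions
    missingness: dict = field(default_factory=dict)
    # optional true directed GC values for VAR scenarios
    gc: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary noise sources

def _narrowband(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return (x / sd if sd > 0 else x).astype(np.float64)


def _pink(rng: np.random.Generator, n: int, fs: float, f_knee: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f-power noise, flat below ``f_knee``."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, f_knee))
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    return x / x.std()


# ---------------------------------------------------------------------------
# VAR oracle sources

def var_companion(A: np.ndarray) -> np.ndarray:
    """Companion matrix of VAR coefficient stack ``A`` (p, n, n)."""
    p, n, _ = A.shape
    C = np.zeros((n * p, n * p))
    C[:n] = np.concatenate(list(A), axis=1)
    if p > 1:
        C[n:, :-n] = np.eye(n * (p - 1))
    return C


def var_spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(var_companion(A)))))


def simulate_var_network(
    A: np.ndarray,
    Sigma: np.ndarray,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    burn_in: int = 1000,
) -> np.ndarray:
    """Draw an ``(n_channels, n_samples)`` series from a stable VAR process.

    ``A`` has shape ``(p, n, n)`` (lag-1 first); ``Sigma`` is the innovation
    covariance.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, n, _ = A.shape
    rho = var_spectral_radius(A)
    if rho >= 1:
        raise ValueError(f"unstable VAR: companion spectral radius {rho:.4f} >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = np.linalg.cholesky(np.asarray(Sigma, dtype=float))
    total = n_samples + burn_in
    eps = rng.standard_normal((total, n)) @ L.T
    x = np.zeros((total, n))
    for t in range(p, total):
        acc = eps[t].copy()
        for k in range(p):
            acc += A[k] @ x[t - 1 - k]
        x[t] = acc
    return x[burn_in:].T.copy()


def analytic_gc_var1(a: float, sigma_x2: float = 1.0, sigma_y2: float = 1.0) -> float:
    """Geweke time-domain GC x->y for ``y_t = a*x_{t-1} + eps_y``, x white.

    Equals ``ln(1 + a^2 * sigma_x^2 / sigma_y^2)``.
    """
    if sigma_x2 <= 0 or sigma_y2 <= 0:
        raise ValueError("noise variances must be positive")
    return float(np.log(1.0 + a * a * sigma_x2 / sigma_y2))


# ---------------------------------------------------------------------------
# bout process

def _draw_bouts(
    rng: np.random.Generator,
    t0: float,
    t1: float,
    cfg: SimulationConfig,
    stimuli: Sequence[str],
    weights: Sequence[float],
    chambers: Sequence[str],
) -> list[tuple[str, str, float, float]]:
    """Alternating renewal bout process on [t0, t1): exponential gaps,
    lognormal durations, stimulus by preference weights."""
    out = []
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu = np.log(cfg.bout_median_s)
    t = t0 + rng.exponential(cfg.mean_gap_s / 2)
    while True:
        dur = float(rng.lognormal(mu, cfg.bout_sigma))
        if t + dur > t1 - 0.1:
            break
        k = int(rng.choice(len(stimuli), p=w))
        out.append((stimuli[k], chambers[k], t, t + dur))
        t = t + dur + cfg.min_gap_s + float(rng.exponential(cfg.mean_gap_s))
    return out


# ---------------------------------------------------------------------------
# session synthesis

def _excess_weight(rho: float, floor_a2: float) -> float:
    """Dedicated-source weight for target MSC ``rho`` above a global floor."""
    excess = np.sqrt(max(rho, 0.0)) - floor_a2
    if excess < -1e-12:
        warnings.warn(
            f"coherence target {rho:.3f} below the representable floor "
            f"{floor_a2**2:.3f}; clipped to the floor"
        )
    return float(np.sqrt(max(excess, 0.0)))


def _weight_schedule(
    n: int,
    fs: float,
    enc_start: float,
    rho_base: float,
    rho_enc: float,
    bout_rhos: list[tuple[float, float, float]],
    floor_a2: float,
) -> np.ndarray:
    """Sample-level dedicated-source weight w(t) over the global floor."""
    w = np.full(n, _excess_weight(rho_base, floor_a2), dtype=np.float32)
    w[int(enc_start * fs):] = _excess_weight(rho_enc, floor_a2)
    for s, e, rho in bout_rhos:
        w[int(s * fs):int(e * fs)] = _excess_weight(rho, floor_a2)
    return w


def _gain_envelope(
    n: int,
    fs: float,
    enc_start: float,
    enc_gain: float,
    bout_gains: list[tuple[float, float, float]],
) -> np.ndarray:
    g = np.ones(n, dtype=np.float32)
    g[int(enc_start * fs):] = enc_gain
    for s, e, gain in bout_gains:
        seg = slice(int(s * fs), int(e * fs))
        g[seg] = g[seg] * gain
    return g


def simulate_region_signals(
    cfg: SimulationConfig,
    seed: int | np.random.Generator,
    regions: Sequence[str] | None = None,
    duration_s: float | None = None,
    pair_rho: Mapping[Pair, Mapping[str, float]] | None = None,
) -> tuple[np.ndarray, dict]:
    """Stationary multi-region LFP with the given per-pair coherence targets.

    Returns the ``(n_regions, n_samples)`` matrix and a ground-truth dict of
    the targets actually applied.  Used directly by coherence-calibration
    tests; :func:`simulate_session` layers state/bout structure on top.
    """
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    regions = list(regions if regions is not None else cfg.regions)
    fs = cfg.sampling_rate
    dur = duration_s if duration_s is not None else cfg.baseline_s
    n = int(round(dur * fs))
    targets: dict[Pair, dict[str, float]] = {}
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            pair = (regions[i], regions[j])
            per_band = dict.fromkeys(BANDS, cfg.baseline_coherence)
            if pair_rho and pair in pair_rho:
                per_band.update(pair_rho[pair])
            elif cfg.coherence_targets and pair in cfg.coherence_targets:
                per_band.update(cfg.coherence_targets[pair])
            targets[pair] = per_band
    amps = {"theta": cfg.theta_amplitude, "gamma": cfg.gamma_amplitude}
    x = np.zeros((len(regions), n))
    for band, edges in BANDS.items():
        y = np.zeros((len(regions), n))
        # global floor: the smallest target this band must represent
        floor_rho = min(pb[band] for pb in targets.values()) if targets else 0.0
        a2 = float(np.sqrt(max(floor_rho, 0.0)))
        wsq = np.full(len(regions), a2)
        if a2 > 0:
            shared = _narrowband(rng, n, fs, edges)
            y += np.sqrt(a2) * shared
        for (ra, rb), per_band in targets.items():
            w = _excess_weight(per_band[band], a2)
            if w <= 0:
                continue
            s = _narrowband(rng, n, fs, edges)
            ia, ib = regions.index(ra), regions.index(rb)
            y[ia] += w * s
            y[ib] += w * s
            wsq[ia] += w * w
            wsq[ib] += w * w
        for i in range(len(regions)):
            g = np.sqrt(max(0.0, 1.0 - wsq[i]))
            y[i] += g * _narrowband(rng, n, fs, edges)
        x += amps[band] * y
    for i in range(len(regions)):
        x[i] += cfg.pink_amplitude * _pink(rng, n, fs)
    return x, {"coherence_targets": targets}


def simulate_session(
    cfg: SimulationConfig,
    subject_id: str,
    task: str,
    session_index: int,
    seed: int | np.random.Generator,
    regions: Sequence[str] | None = None,
) -> tuple[RecordingSession, "pd.DataFrame", dict]:
    """One baseline+encounter session with bouts and injected effects.

    Baseline carries the baseline coherence targets and unit gains; the
    encounter applies the per-band encounter amplitude gain plus the task's
    coherence signature; bout-locked gains/offsets act inside bout windows.
    """
    import pandas as pd

    cfg.validate()
    if task not in TASK_STIMULI:
        raise ValueError(f"unknown task {task!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    regions = list(regions if regions is not None else cfg.regions)
    fs = cfg.sampling_rate
    tb, te = cfg.baseline_s, cfg.encounter_s
    total = tb + te
    n = int(round(total * fs))
    stimuli = list(TASK_STIMULI[task])  # (preferred, other)
    chambers = ["left", "right"]
    if rng.random() < 0.5:  # counterbalance stimulus side
        chambers = chambers[::-1]
    stimulus_map = dict(zip(chambers, stimuli))

    # --- behavior ------------------------------------------------------
    rows = []
    for stim, ch, s, e in _draw_bouts(
        rng, 2.0, tb - 1.0, cfg, [EMPTY_STIMULUS, EMPTY_STIMULUS], [1, 1], ["left", "right"]
    ):
        rows.append((None, stim, ch, s, e))
    enc_rows = _draw_bouts(
        rng, tb + 2.0, total - 1.0, cfg,
        stimuli, [cfg.preference_weight, 1.0], chambers,
    )
    for stim, ch, s, e in enc_rows:
        rows.append((None, stim, ch, s, e))
    bouts = make_bout_table(
        [(f"{subject_id}_{task}_{session_index}", st, ch, s, e) for _, st, ch, s, e in rows]
    )

    # --- coherence schedules --------------------------------------------
    ctx = cfg.context_coherence_offsets.get(task, {})
    amps = {"theta": cfg.theta_amplitude, "gamma": cfg.gamma_amplitude}
    truth_coh: dict[Pair, dict[str, tuple[float, float]]] = {}
    x = np.zeros((len(regions), n))
    for band, edges in BANDS.items():
        y = np.zeros((len(regions), n))
        # global floor source: carries the flat baseline coherence for all pairs
        a2 = float(np.sqrt(max(cfg.baseline_coherence, 0.0)))
        wsq = np.full((len(regions), n), a2, dtype=np.float32)
        if a2 > 0:
            y += np.sqrt(a2) * _narrowband(rng, n, fs, edges)
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                pair = (regions[i], regions[j])
                rho_base = cfg.coherence_targets.get(pair, {}).get(
                    band, cfg.baseline_coherence
                )
                rho_enc = float(np.clip(
                    rho_base + ctx.get(pair, {}).get(band, 0.0), 0.0, 1.0
                ))
                bout_rhos = []
                for stim, per_pair in cfg.bout_coherence_offsets.items():
                    off = per_pair.get(pair, {}).get(band, 0.0)
                    if off == 0.0:
                        continue
                    for _, row in bouts[bouts["stimulus"] == stim].iterrows():
                        bout_rhos.append(
                            (row["start_s"], row["end_s"],
                             float(np.clip(rho_enc + off, 0, 1)))
                        )
                truth_coh.setdefault(pair, {})[band] = (rho_base, rho_enc)
                w = _weight_schedule(n, fs, tb, rho_base, rho_enc, bout_rhos, a2)
                if not (w > 0).any():
                    continue
                s = _narrowband(rng, n, fs, edges)
                y[i] += w * s
                y[j] += w * s
                wsq[i] += w * w
                wsq[j] += w * w
        for i, region in enumerate(regions):
            g_ind = np.sqrt(np.clip(1.0 - wsq[i], 0.0, 1.0))
            y[i] += g_ind * _narrowband(rng, n, fs, edges)
            # amplitude-gain envelope: encounter gain x bout-locked gain
            bout_gain_rows = []
            for stim, per_band in cfg.bout_gains.items():
                gain = per_band.get(band, 1.0)
                if gain == 1.0:
                    continue
                if cfg.bout_gain_regions is not None and region not in cfg.bout_gain_regions:
                    continue
                for _, row in bouts[bouts["stimulus"] == stim].iterrows():
                    bout_gain_rows.append((row["start_s"], row["end_s"], gain))
            env = _gain_envelope(
                n, fs, tb, cfg.encounter_gain.get(band, 1.0), bout_gain_rows
            )
            x[i] += amps[band] * env * y[i]
    for i in range(len(regions)):
        x[i] += cfg.pink_amplitude * _pink(rng, n, fs)

    session = RecordingSession(
        subject_id=subject_id,
        task=task,
        session_index=session_index,
        sampling_rate=fs,
        signals=x.astype(np.float32),
        region_labels=regions,
        baseline_interval=(0.0, tb),
        encounter_interval=(tb, total),
        stimulus_map=stimulus_map,
        insertion_time=tb,
        removal_time=total,
    )
    truth = {
        "coherence": truth_coh,
        "power_gain": dict(cfg.encounter_gain),
        "context": task,
    }
    return session, bouts, truth


def simulate_dataset(
    cfg: SimulationConfig, seed: int
) -> tuple[Dataset, GroundTruth]:
    """Full multi-subject, three-task dataset with per-subject region dropout."""
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    truth = GroundTruth()
    sessions, bout_tables = [], []
    all_regions = list(cfg.regions)
    for si in range(cfg.n_subjects):
        subject = f"M{si + 1:02d}"
        keep = [r for r in all_regions if master.random() >= cfg.dropout_prob]
        if len(keep) < cfg.min_regions:
            keep = all_regions[: cfg.min_regions]
        truth.missingness[subject] = list(keep)
        for task in TASKS:
            for k in range(1, cfg.n_sessions_per_task + 1):
                child = np.random.default_rng(ss.spawn(1)[0])
                sess, bouts, t = simulate_session(cfg, subject, task, k, child, keep)
                sessions.append(sess)
                bout_tables.append(bouts)
                truth.coherence[sess.session_id] = t["coherence"]
                truth.power_gain[sess.session_id] = t["power_gain"]
                truth.context[sess.session_id] = task
    return Dataset(sessions, bout_tables), truth


def context_signature_config(
    base: SimulationConfig | None = None,
    n_affected_pairs: int = 10,
    offset: float = 0.125,
) -> SimulationConfig:
    """Config whose three tasks raise encounter coherence on disjoint
    thirds of the first ``n_affected_pairs`` region pairs — the decoder's
    recoverable "context signature".

    ``offset`` is sized so the induced shift of the per-session bout
    coherence features is about one between-session standard deviation.
    """
    from dataclasses import replace

    cfg = base if base is not None else SimulationConfig()
    regions = list(cfg.regions)
    pairs = [
        (regions[i], regions[j])
        for i in range(len(regions))
        for j in range(i + 1, len(regions))
    ][:n_affected_pairs]
    chunks = np.array_split(np.arange(len(pairs)), 3)
    per_task: dict[str, dict[Pair, dict[str, float]]] = {}
    for t_idx, task in enumerate(TASKS):
        sel = [pairs[k] for k in chunks[t_idx]] or pairs[-1:]
        per_task[task] = {p: {"theta": offset} for p in sel}
    return replace(cfg, context_coherence_offsets=per_task)
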
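"""Multitaper spectrograms, band-power summaries, and event-aligned Z-scores.

The spectrogram uses discrete prolate spheroidal (dpss) tapers with a 2-s
window, 0.5-Hz frequency increments and 0.5-s output bins (i.e. a 0.5-s
stride, 75% window overlap: the 0.5-s bin grid is what the event-aligned
Z-score analysis requires).  Time-bandwidth NW = 2 with the first 3 tapers
averaged, giving about +/-1 Hz resolution bandwidth on the 0.5 Hz grid.

Band power summaries:

* ``theta_power`` / ``gamma_power``: band power averaged over a period.
* ``delta`` (session-wide): encounter mean minus baseline mean.
* bout-locked variant: average power per second during a stimulus's valid
  (> 2 s) investigation bouts minus average power per second during
  investigation of the empty chambers in baseline, averaged over sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datamodel import (
    EMPTY_STIMULUS,
    BehavioralEvent,
    Dataset,
    RecordingSession,
    exclusion_mask,
    valid_bouts,
)

THETA = ("theta", 4.0, 12.0)
GAMMA = ("gamma", 30.0, 80.0)


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float


BAND_THETA = Band(*THETA)
BAND_GAMMA = Band(*GAMMA)


def get_band(name: str | Band) -> Band:
    if isinstance(name, Band):
        return name
    return {"theta": BAND_THETA, "gamma": BAND_GAMMA}[name]


@dataclass
class TimeFrequencyPower:
    """Short-time multitaper power, ``power[freq, time]`` in uV^2/Hz."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # bin centers, s
    window_s: float
    stride_s: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandPowerSummary:
    region: str
    band: str
    mean_baseline_power: float
    mean_encounter_power: float
    series: pd.Series  # band power per time bin

    @property
    def delta(self) -> float:
        return self.mean_encounter_power - self.mean_baseline_power


@dataclass
class EventAlignedZ:
    kind: str
    stimulus: str | None
    lags: np.ndarray  # bin centers relative to event, s
    z: np.ndarray  # mean z-trace
    n_events: int


def preprocess(
    x: np.ndarray, fs_in: float, fs_out: float = 5000.0, lowpass_hz: float = 300.0
) -> np.ndarray:
    """Decimate to ``fs_out`` with anti-aliasing, then zero-phase 4th-order
    Butterworth low-pass at ``lowpass_hz``."""
    if fs_in < fs_out:
        raise ValueError(f"input rate {fs_in} Hz below target {fs_out} Hz")
    if fs_in != fs_out:
        up, down = (np.round([fs_out, fs_in])).astype(int)
        g = np.gcd(up, down)
        x = sps.resample_poly(np.asarray(x, dtype=float), up // g, down // g)
    sos = sps.butter(4, lowpass_hz, btype="low", fs=fs_out, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def spectrogram(
    trace: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    stride_s: float = 0.5,
    nw: float = 2.0,
    n_tapers: int = 3,
) -> TimeFrequencyPower:
    """dpss multitaper short-time PSD on a ``1/window_s`` Hz grid."""
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(window_s * fs))
    if trace.size < nperseg:
        raise ValueError(
            f"trace of {trace.size} samples shorter than one {window_s}-s window"
        )
    step = int(round(stride_s * fs))
    tapers = sps.windows.dpss(nperseg, nw, Kmax=n_tapers)
    starts = np.arange(0, trace.size - nperseg + 1, step)
    frames = np.lib.stride_tricks.sliding_window_view(trace, nperseg)[starts]
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    psd = np.zeros((len(freqs), len(starts)))
    scale = 1.0 / fs  # taper already unit-energy
    for tap in tapers:
        spec = np.fft.rfft(frames * tap, axis=1)
        psd += (np.abs(spec) ** 2).T * scale
    psd /= n_tapers
    # one-sided density: double everything except DC (and Nyquist if present)
    psd[1:] *= 2.0
    if nperseg % 2 == 0:
        psd[-1] /= 2.0
    times = (starts + nperseg / 2) / fs
    return TimeFrequencyPower(psd, freqs, times, window_s, stride_s)


def _band_rows(tf: TimeFrequencyPower, band: Band) -> np.ndarray:
    return (tf.freqs >= band.lo) & (tf.freqs <= band.hi)


def band_power_series(tf: TimeFrequencyPower, band: str | Band) -> pd.Series:
    """Mean PSD over the band's frequency bins, per time bin."""
    band = get_band(band)
    rows = _band_rows(tf, band)
    if not rows.any():
        raise ValueError(f"band {band} outside the frequency grid")
    return pd.Series(tf.power[rows].mean(axis=0), index=tf.times, name=band.name)


def _bins_in(times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    keep = np.zeros(times.shape, dtype=bool)
    for lo, hi in intervals:
        keep |= (times >= lo) & (times < hi)
    return keep


def period_mean(
    series: pd.Series,
    interval: tuple[float, float],
    mask_intervals: list[tuple[float, float]] | None = None,
) -> float:
    """Mean band power over the time bins of a period, excluding bins whose
    centers fall inside any masked interval."""
    times = series.index.to_numpy()
    keep = (times >= interval[0]) & (times < interval[1])
    if mask_intervals:
        keep &= ~_bins_in(times, mask_intervals)
    if not keep.any():
        return float("nan")
    return float(series[keep].mean())


def _mask_intervals(session: RecordingSession, half_window_s: float = 30.0):
    m = exclusion_mask(session, half_window_s)
    fs = session.sampling_rate
    out = []
    bad = ~m
    padded = np.concatenate(([False], bad, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        out.append((s / fs, e / fs))
    return out


def delta_band_power(
    session: RecordingSession,
    region: str,
    band: str | Band,
    exclusion_half_window_s: float = 30.0,
    tf: TimeFrequencyPower | None = None,
) -> BandPowerSummary:
    """Session-wide band-power change: encounter mean minus baseline mean,
    honoring the insertion/removal exclusion windows."""
    band = get_band(band)
    if tf is None:
        tf = spectrogram(session.region_trace(region), session.sampling_rate)
    series = band_power_series(tf, band)
    masked = _mask_intervals(session, exclusion_half_window_s)
    base = period_mean(series, session.baseline_interval, masked)
    enc = period_mean(series, session.encounter_interval, masked)
    return BandPowerSummary(region, band.name, base, enc, series)


def bout_band_power(
    session: RecordingSession,
    bouts: pd.DataFrame,
    region: str,
    band: str | Band,
    min_duration_s: float = 2.0,
    per_bout_average: bool = False,
    tf: TimeFrequencyPower | None = None,
) -> dict[str, float]:
    """Bout-locked band power per stimulus: average power per second during
    that stimulus's valid bouts minus average power per second during the
    baseline empty-chamber bouts.

    "Average power per second" is a duration-weighted mean over concatenated
    bout bins (total power-seconds / total seconds); set ``per_bout_average``
    to average per bout first.
    """
    band = get_band(band)
    if tf is None:
        tf = spectrogram(session.region_trace(region), session.sampling_rate)
    series = band_power_series(tf, band)
    vb = valid_bouts(bouts, min_duration_s)

    def mean_over(stim: str) -> float:
        sel = vb[vb["stimulus"] == stim]
        if sel.empty:
            return float("nan")
        if per_bout_average:
            vals = [
                period_mean(series, (r["start_s"], r["end_s"]))
                for _, r in sel.iterrows()
            ]
            vals = [v for v in vals if np.isfinite(v)]
            return float(np.mean(vals)) if vals else float("nan")
        ivals = [(r["start_s"], r["end_s"]) for _, r in sel.iterrows()]
        keep = _bins_in(series.index.to_numpy(), ivals)
        if not keep.any():
            return float("nan")
        return float(series[keep].mean())

    ref = mean_over(EMPTY_STIMULUS)
    out = {}
    for stim in session.stimulus_map.values():
        val = mean_over(stim)
        if np.isnan(val) or np.isnan(ref):
            warnings.warn(
                f"{session.session_id}: no valid bouts for {stim!r} or empty-chamber "
                "reference; omitted"
            )
            out[stim] = float("nan")
        else:
            out[stim] = val - ref
    return out


def event_zscore(
    tf: TimeFrequencyPower,
    events: list[BehavioralEvent],
    band: str | Band,
    kind: str = "bout_start",
    stimulus: str | None = None,
    pre_s: float = 5.0,
    post_s: float = 5.0,
) -> EventAlignedZ:
    """Event-aligned band power, Z-scored against the pre-event window.

    Per event: ``z(bin) = (power - mean(pre)) / sd(pre)`` over the pre-event
    ``pre_s`` window, in the spectrogram's 0.5-s bins over
    ``[-pre_s, +post_s)``; the trace is the mean across qualifying events.
    Events without a full pre-window or with zero pre-window SD are dropped.
    """
    band = get_band(band)
    series = band_power_series(tf, band).to_numpy()
    times = tf.times
    step = tf.stride_s
    n_pre = int(round(pre_s / step))
    n_post = int(round(post_s / step))
    traces = []
    for ev in events:
        if ev.kind != kind:
            continue
        if stimulus is not None and ev.stimulus != stimulus:
            continue
        # closest bin center at/after the event time
        k = int(np.searchsorted(times, ev.time_s))
        if k - n_pre < 0 or k + n_post > len(series):
            continue
        seg = series[k - n_pre:k + n_post]
        pre = seg[:n_pre]
        sd = pre.std(ddof=1)
        if sd == 0:
            continue
        traces.append((seg - pre.mean()) / sd)
    lags = (np.arange(-n_pre, n_post) + 0.5) * step
    if not traces:
        return EventAlignedZ(kind, stimulus, lags, np.full(lags.shape, np.nan), 0)
    return EventAlignedZ(kind, stimulus, lags, np.mean(traces, axis=0), len(traces))


def compare_event_categories(
    za_by_session: list[EventAlignedZ],
    zb_by_session: list[EventAlignedZ],
    window: tuple[float, float] = (0.0, 5.0),
    paired: bool = True,
):
    """Compare two event categories on the mean Z over ``window`` per session.

    Dispatches a parametric or rank test per normality via
    :func:`sblfp.screen.group_compare`; returns its result.
    """
    from .screen import group_compare

    def summarize(zs: list[EventAlignedZ]) -> np.ndarray:
        vals = []
        for z in zs:
            sel = (z.lags >= window[0]) & (z.lags < window[1])
            vals.append(float(np.nanmean(z.z[sel])))
        return np.asarray(vals)

    a, b = summarize(za_by_session), summarize(zb_by_session)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 sessions per category")
    design = "paired_2" if paired else "unpaired_2"
    return group_compare([a, b], design)


def dataset_band_power_table(
    dataset: Dataset,
    band: str | Band,
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format per-session band power summary over a dataset."""
    band = get_band(band)
    rows = []
    for sess in dataset.sessions:
        for region in (regions or sess.region_labels):
            if region not in sess.region_labels:
                continue
            s = delta_band_power(sess, region, band)
            rows.append(
                dict(
                    subject=sess.subject_id, task=sess.task,
                    session=sess.session_index, region=region, band=band.name,
                    baseline_power=s.mean_baseline_power,
                    encounter_power=s.mean_encounter_power, delta=s.delta,
                )
            )
    return pd.DataFrame(rows)
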
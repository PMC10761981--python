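"""Welch magnitude-squared coherence and normalized coherence-change statistics.

Session-wide MSC uses 2-s Hann segments at 50% overlap (0.5 Hz grid,
matching the power analysis); bout-locked MSC uses 1-s sub-windows drawn
inside concatenated bout segments, never spanning a bout boundary (a 2-s
window would exclude most bouts despite the > 2 s bout filter).

The change-in-coherence statistic for a pair and band is

    delta = mean(d) / sd(d),   d(f) = MSC_encounter(f) - MSC_baseline(f)

taken across the band's frequency bins (sample SD); its bout-locked
counterpart is the band-averaged MSC difference between a stimulus's bouts
and the baseline empty-chamber bouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datamodel import (
    EMPTY_STIMULUS,
    Dataset,
    RecordingSession,
    eligible_pairs,
    exclusion_mask,
    mask_to_intervals,
    valid_bouts,
)
from .power import Band, get_band


@dataclass
class CoherenceSpectrum:
    pair: tuple[str, str]
    freqs: np.ndarray
    msc: np.ndarray
    n_segments: int
    s_xy: np.ndarray
    s_xx: np.ndarray
    s_yy: np.ndarray


@dataclass
class CoherenceChange:
    pair: tuple[str, str]
    band: str
    baseline_mean: float  # thetaCo / gammaCo
    delta: float  # normalized encounter-baseline change
    degenerate: bool = False


def _segment_spectra(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float,
    overlap: float,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-window tapered rfft spectra of x and y over Welch windows."""
    nperseg = int(round(window_s * fs))
    step = max(1, int(round(nperseg * (1 - overlap))))
    if len(x) < nperseg:
        return np.array([]), []
    win = sps.windows.hann(nperseg)
    starts = np.arange(0, len(x) - nperseg + 1, step)
    fx = np.fft.rfft(np.lib.stride_tricks.sliding_window_view(x, nperseg)[starts] * win, axis=1)
    fy = np.fft.rfft(np.lib.stride_tricks.sliding_window_view(y, nperseg)[starts] * win, axis=1)
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    return freqs, [fx, fy]


def welch_msc_segments(
    chunks: list[tuple[np.ndarray, np.ndarray]],
    fs: float,
    pair: tuple[str, str] = ("x", "y"),
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> CoherenceSpectrum:
    """Welch MSC accumulated over windows drawn within each (x, y) chunk.

    Windows never span chunk boundaries, so masked gaps and bout edges do
    not leak into the estimate.  Requires at least 2 windows in total.
    """
    freqs = None
    sxx = syy = sxy = None
    n_seg = 0
    for x, y in chunks:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("chunk length mismatch")
        f, specs = _segment_spectra(x, y, fs, window_s, overlap)
        if len(f) == 0:
            continue
        fx, fy = specs
        if freqs is None:
            freqs = f
            sxx = np.zeros(len(f))
            syy = np.zeros(len(f))
            sxy = np.zeros(len(f), dtype=complex)
        sxx += (np.abs(fx) ** 2).sum(axis=0)
        syy += (np.abs(fy) ** 2).sum(axis=0)
        sxy += (np.conj(fx) * fy).sum(axis=0)
        n_seg += fx.shape[0]
    if n_seg < 2:
        raise ValueError(
            f"only {n_seg} Welch segment(s); MSC is degenerate with < 2"
        )
    msc = np.abs(sxy) ** 2 / np.maximum(sxx * syy, np.finfo(float).tiny)
    return CoherenceSpectrum(pair, freqs, np.clip(msc, 0.0, 1.0), n_seg,
                             sxy / n_seg, sxx / n_seg, syy / n_seg)


def welch_msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
    pair: tuple[str, str] = ("x", "y"),
) -> CoherenceSpectrum:
    """Magnitude-squared coherence |S_xy|^2 / (S_xx S_yy) by Welch's
    overlapped averaged periodogram method."""
    return welch_msc_segments([(x, y)], fs, pair, window_s, overlap)


def _period_chunks(
    session: RecordingSession,
    pair: tuple[str, str],
    interval: tuple[float, float],
    exclusion_half_window_s: float = 30.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    fs = session.sampling_rate
    mask = exclusion_mask(session, exclusion_half_window_s)
    lo, hi = int(round(interval[0] * fs)), int(round(interval[1] * fs))
    sub = np.zeros_like(mask)
    sub[lo:hi] = True
    x = session.region_trace(pair[0])
    y = session.region_trace(pair[1])
    return [
        (x[int(s * fs):int(e * fs)], y[int(s * fs):int(e * fs)])
        for s, e in mask_to_intervals(mask & sub, fs)
    ]


def coherence_change(
    session: RecordingSession,
    pair: tuple[str, str],
    band: str | Band,
    window_s: float = 2.0,
    overlap: float = 0.5,
    exclusion_half_window_s: float = 30.0,
) -> CoherenceChange:
    """Normalized encounter-vs-baseline coherence change for one pair."""
    band = get_band(band)
    base = welch_msc_segments(
        _period_chunks(session, pair, session.baseline_interval, exclusion_half_window_s),
        session.sampling_rate, pair, window_s, overlap,
    )
    enc = welch_msc_segments(
        _period_chunks(session, pair, session.encounter_interval, exclusion_half_window_s),
        session.sampling_rate, pair, window_s, overlap,
    )
    rows = (base.freqs >= band.lo) & (base.freqs <= band.hi)
    d = enc.msc[rows] - base.msc[rows]
    baseline_mean = float(base.msc[rows].mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        warnings.warn(f"{session.session_id} {pair}: degenerate coherence change (sd=0)")
        return CoherenceChange(pair, band.name, baseline_mean, 0.0, degenerate=True)
    return CoherenceChange(pair, band.name, baseline_mean, float(d.mean() / sd))


def _bout_chunks(
    session: RecordingSession,
    bouts: pd.DataFrame,
    pair: tuple[str, str],
    stimulus: str,
    min_duration_s: float = 2.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    fs = session.sampling_rate
    vb = valid_bouts(bouts, min_duration_s)
    sel = vb[vb["stimulus"] == stimulus]
    x = session.region_trace(pair[0])
    y = session.region_trace(pair[1])
    return [
        (x[int(r["start_s"] * fs):int(r["end_s"] * fs)],
         y[int(r["start_s"] * fs):int(r["end_s"] * fs)])
        for _, r in sel.iterrows()
    ]


def bout_coherence_change(
    session: RecordingSession,
    bouts: pd.DataFrame,
    pair: tuple[str, str],
    band: str | Band,
    window_s: float = 1.0,
    overlap: float = 0.5,
    min_duration_s: float = 2.0,
) -> dict[str, float]:
    """Bout-locked coherence change per stimulus: band-averaged MSC over a
    stimulus's valid bouts minus MSC over the baseline empty-chamber bouts.

    Sessions with too little bout time for a stimulus yield NaN for it.
    """
    band = get_band(band)

    def band_msc(stim: str) -> float:
        chunks = _bout_chunks(session, bouts, pair, stim, min_duration_s)
        try:
            spec = welch_msc_segments(chunks, session.sampling_rate, pair, window_s, overlap)
        except ValueError:
            return float("nan")
        rows = (spec.freqs >= band.lo) & (spec.freqs <= band.hi)
        return float(spec.msc[rows].mean())

    ref = band_msc(EMPTY_STIMULUS)
    out = {}
    for stim in session.stimulus_map.values():
        val = band_msc(stim)
        if np.isnan(val) or np.isnan(ref):
            warnings.warn(
                f"{session.session_id} {pair}: insufficient bout time for "
                f"{stim!r}; omitted"
            )
            out[stim] = float("nan")
        else:
            out[stim] = val - ref
    return out


def dataset_coherence_table(
    dataset: Dataset,
    band: str | Band,
    mode: str = "session_wide",
    pairs: list[tuple[str, str]] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Long-format coherence table over eligible pairs.

    ``mode='session_wide'`` emits one row per session x pair with columns
    ``baseline_mean`` and ``delta``; ``mode='bout'`` emits one row per
    session x pair x stimulus with column ``value``.  Pairs not recorded for
    a subject appear as explicit NaN rows (the decoder needs the
    missingness pattern).
    """
    band = get_band(band)
    if pairs is None:
        pairs = eligible_pairs(dataset)
    rows = []
    for sess, bouts in zip(dataset.sessions, dataset.bout_tables):
        recorded = set(sess.region_labels)
        for pair in pairs:
            present = pair[0] in recorded and pair[1] in recorded
            key = dict(subject=sess.subject_id, task=sess.task,
                       session=sess.session_index, pair="-".join(pair), band=band.name)
            if mode == "session_wide":
                if present:
                    cc = coherence_change(sess, pair, band, **kwargs)
                    rows.append(dict(**key, baseline_mean=cc.baseline_mean, delta=cc.delta))
                else:
                    rows.append(dict(**key, baseline_mean=np.nan, delta=np.nan))
            elif mode == "bout":
                if present:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        vals = bout_coherence_change(sess, bouts, pair, band, **kwargs)
                else:
                    vals = dict.fromkeys(sess.stimulus_map.values(), np.nan)
                for stim, val in vals.items():
                    rows.append(dict(**key, stimulus=stim, value=val))
            else:
                raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)
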
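"""Core data model for multi-region LFP recording sessions and behavior.

A recording session covers one subject performing one binary social
discrimination task: a 5-min baseline period with two empty chambers
followed by a 5-min encounter period with two stimuli.  Behavior is
summarized as a table of timed investigation bouts toward the chambers.

Tasks and their stimulus vocabularies:

* ``SP``  (social preference):          social vs. object
* ``EsP`` (emotional-state preference): isolated vs. grouped
* ``SxP`` (sex preference):             female vs. male

The first stimulus listed for each task is the one the subject population
typically prefers; sign conventions downstream rely on this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The 18-region recording vocabulary (electrode-array targets).
REGIONS: tuple[str, ...] = (
    "AcbC", "AcbSh", "AhiAL", "BLA", "BMP", "DMD", "EA", "IL", "LS",
    "MeAD", "Pir", "PLH", "PrL", "PVN", "vCA1", "vDG", "VP", "CeA",
)

#: task -> (preferred stimulus, less-preferred stimulus)
TASK_STIMULI: dict[str, tuple[str, str]] = {
    "SP": ("social", "object"),
    "EsP": ("isolated", "grouped"),
    "SxP": ("female", "male"),
}

TASKS: tuple[str, ...] = tuple(TASK_STIMULI)

#: Label used for investigation of the empty chambers during baseline.
EMPTY_STIMULUS = "empty"

BOUT_COLUMNS = ["session_id", "stimulus", "chamber", "start_s", "end_s"]


class ValidationError(ValueError):
    """A record violated a data-model invariant; the message names it."""


@dataclass
class RecordingSession:
    """Multichannel LFP plus metadata for one subject-task-session.

    ``signals`` is an ``(n_regions, n_samples)`` float array in microvolts,
    one row per entry of ``region_labels``.  Time coordinates are seconds
    from session start; intervals are half-open ``[start, end)``.
    """

    subject_id: str
    task: str
    session_index: int
    sampling_rate: float
    signals: np.ndarray
    region_labels: list[str]
    baseline_interval: tuple[float, float]
    encounter_interval: tuple[float, float]
    stimulus_map: dict[str, str]
    insertion_time: float
    removal_time: float

    @property
    def session_id(self) -> str:
        return f"{self.subject_id}_{self.task}_{self.session_index}"

    @property
    def n_samples(self) -> int:
        return int(self.signals.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def region_trace(self, region: str) -> np.ndarray:
        try:
            idx = self.region_labels.index(region)
        except ValueError:
            raise KeyError(f"region {region!r} not recorded in {self.session_id}")
        return self.signals[idx]

    def validate(self) -> None:
        sid = self.session_id
        if self.task not in TASK_STIMULI:
            raise ValidationError(
                f"{sid}: unknown task {self.task!r}; legal tasks: {sorted(TASK_STIMULI)}"
            )
        if self.sampling_rate <= 0:
            raise ValidationError(f"{sid}: missing or non-positive sampling rate")
        if self.signals.ndim != 2:
            raise ValidationError(f"{sid}: signals must be 2-D (regions x samples)")
        if len(self.region_labels) != self.signals.shape[0]:
            raise ValidationError(
                f"{sid}: {len(self.region_labels)} region labels for "
                f"{self.signals.shape[0]} signal rows"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValidationError(f"{sid}: duplicate region labels")
        unknown = [r for r in self.region_labels if r not in REGIONS]
        if unknown:
            raise ValidationError(
                f"{sid}: unknown region code(s) {unknown}; legal codes: {list(REGIONS)}"
            )
        b0, b1 = self.baseline_interval
        e0, e1 = self.encounter_interval
        if not (b0 < b1 and e0 < e1):
            raise ValidationError(f"{sid}: degenerate period interval")
        if max(b0, e0) < min(b1, e1):
            raise ValidationError(f"{sid}: baseline and encounter intervals overlap")
        if self.n_samples < int(round((max(b1, e1)) * self.sampling_rate)):
            raise ValidationError(
                f"{sid}: n_samples={self.n_samples} shorter than the periods imply"
            )
        legal = set(TASK_STIMULI[self.task])
        for chamber, stim in self.stimulus_map.items():
            if stim not in legal:
                raise ValidationError(
                    f"{sid}: stimulus {stim!r} in chamber {chamber!r} illegal for "
                    f"task {self.task}; legal: {sorted(legal)}"
                )


def make_bout_table(rows: Iterable[tuple] | pd.DataFrame) -> pd.DataFrame:
    """Build a bout table (columns ``session_id,stimulus,chamber,start_s,end_s``)."""
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows), columns=BOUT_COLUMNS)
    missing = [c for c in BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"bout table missing column(s) {missing}")
    df = df[BOUT_COLUMNS].reset_index(drop=True)
    df["start_s"] = df["start_s"].astype(float)
    df["end_s"] = df["end_s"].astype(float)
    return df


def bout_durations(bouts: pd.DataFrame) -> pd.Series:
    return bouts["end_s"] - bouts["start_s"]


def validate_bout_table(bouts: pd.DataFrame, session: RecordingSession | None = None) -> None:
    bad = bouts["start_s"] >= bouts["end_s"]
    if bad.any():
        row = bouts.index[bad][0]
        raise ValidationError(f"bout row {row}: end_s <= start_s ({bouts.loc[row].to_dict()})")
    srt = bouts.sort_values("start_s")
    overlap = srt["start_s"].values[1:] < srt["end_s"].values[:-1]
    if overlap.any():
        row = srt.index[1:][overlap][0]
        raise ValidationError(f"bout row {row}: overlaps the previous bout")
    if session is not None:
        if (bouts["start_s"] < 0).any() or (bouts["end_s"] > session.duration_s).any():
            raise ValidationError(
                f"{session.session_id}: bout outside session time range "
                f"[0, {session.duration_s:g})"
            )
        legal = set(TASK_STIMULI[session.task]) | {EMPTY_STIMULUS}
        bad_stim = set(bouts["stimulus"]) - legal
        if bad_stim:
            raise ValidationError(
                f"{session.session_id}: bout stimulus label(s) {sorted(bad_stim)} "
                f"illegal; legal: {sorted(legal)}"
            )


@dataclass
class BehavioralEvent:
    """A timed behavioral event derived from the bout table."""

    kind: str  # bout_start | bout_end | transition_start | repeat_start
    time_s: float
    stimulus: str
    previous_stimulus: str | None = None


@dataclass
class PreferenceIndex:
    """Relative discrimination index and its ingredients."""

    rdi: float
    total_investigation_s: float
    n_transitions: int


@dataclass
class Dataset:
    """All sessions of a study with their bout tables, aligned by index."""

    sessions: list[RecordingSession]
    bout_tables: list[pd.DataFrame]

    def __post_init__(self) -> None:
        if len(self.sessions) != len(self.bout_tables):
            raise ValidationError("every session needs exactly one bout table")

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.sessions})

    @property
    def region_validity(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for s in self.sessions:
            out.setdefault(s.subject_id, set()).update(s.region_labels)
        return out

    def validate(self) -> None:
        for sess, bouts in zip(self.sessions, self.bout_tables):
            sess.validate()
            validate_bout_table(bouts, sess)

    def session_bouts(self, session: RecordingSession) -> pd.DataFrame:
        return self.bout_tables[self.sessions.index(session)]


# ---------------------------------------------------------------------------
# eligibility filters

def filter_regions(dataset: Dataset, min_sessions: int = 5, min_subjects: int = 3) -> list[str]:
    """Regions recorded in more than ``min_sessions`` sessions across at
    least ``min_subjects`` subjects (strict > on sessions, >= on subjects)."""
    n_sessions: dict[str, int] = {}
    subs: dict[str, set[str]] = {}
    for s in dataset.sessions:
        for r in s.region_labels:
            n_sessions[r] = n_sessions.get(r, 0) + 1
            subs.setdefault(r, set()).add(s.subject_id)
    return sorted(
        r for r in n_sessions
        if n_sessions[r] > min_sessions and len(subs[r]) >= min_subjects
    )


def eligible_pairs(
    dataset: Dataset,
    min_sessions: int = 5,
    min_subjects: int = 2,
    regions: Sequence[str] | None = None,
) -> list[tuple[str, str]]:
    """Unordered region pairs simultaneously recorded in >= ``min_sessions``
    sessions from >= ``min_subjects`` subjects within every one of the three
    tasks.  ``regions`` defaults to :func:`filter_regions` output."""
    if regions is None:
        regions = filter_regions(dataset)
    rset = set(regions)
    per_task_sessions: dict[tuple, dict[str, int]] = {}
    per_task_subjects: dict[tuple, dict[str, set]] = {}
    for s in dataset.sessions:
        labs = sorted(set(s.region_labels) & rset)
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                pair = (labs[i], labs[j])
                per_task_sessions.setdefault(pair, {}).setdefault(s.task, 0)
                per_task_sessions[pair][s.task] += 1
                per_task_subjects.setdefault(pair, {}).setdefault(s.task, set()).add(
                    s.subject_id
                )
    out = []
    for pair, by_task in per_task_sessions.items():
        ok = all(
            by_task.get(t, 0) >= min_sessions
            and len(per_task_subjects[pair].get(t, set())) >= min_subjects
            for t in TASKS
        )
        if ok:
            out.append(pair)
    return sorted(out)


def valid_bouts(bouts: pd.DataFrame, min_duration_s: float = 2.0) -> pd.DataFrame:
    """Bouts strictly longer than ``min_duration_s`` (default 2 s)."""
    keep = bout_durations(bouts) > min_duration_s
    return bouts[keep].reset_index(drop=True)


def extract_events(bouts: pd.DataFrame) -> list[BehavioralEvent]:
    """Derive start/end/transition/repeat events from a time-sorted bout table.

    Every bout emits ``bout_start`` and ``bout_end``; each bout after the
    first additionally emits ``transition_start`` (previous bout targeted the
    other stimulus) or ``repeat_start`` (same stimulus).
    """
    srt = bouts.sort_values("start_s").reset_index(drop=True)
    events: list[BehavioralEvent] = []
    prev_stim: str | None = None
    for _, row in srt.iterrows():
        stim = row["stimulus"]
        events.append(BehavioralEvent("bout_start", row["start_s"], stim, prev_stim))
        if prev_stim is not None:
            kind = "repeat_start" if stim == prev_stim else "transition_start"
            events.append(BehavioralEvent(kind, row["start_s"], stim, prev_stim))
        events.append(BehavioralEvent("bout_end", row["end_s"], stim))
        prev_stim = stim
    return events


def preference_index(bouts: pd.DataFrame, preferred: str) -> PreferenceIndex:
    """RDI = (T_preferred - T_other) / (T_preferred + T_other) over
    investigation times, with total time and transition count."""
    stimuli = [s for s in bouts["stimulus"].unique() if s != EMPTY_STIMULUS]
    durs = bout_durations(bouts)
    t_pref = float(durs[bouts["stimulus"] == preferred].sum())
    t_other = float(
        durs[(bouts["stimulus"] != preferred) & (bouts["stimulus"] != EMPTY_STIMULUS)].sum()
    )
    total = t_pref + t_other
    if total == 0:
        raise ValidationError("zero total investigation time: RDI undefined")
    srt = bouts[bouts["stimulus"] != EMPTY_STIMULUS].sort_values("start_s")
    stims = srt["stimulus"].to_numpy()
    n_trans = int(np.sum(stims[1:] != stims[:-1])) if len(stims) > 1 else 0
    return PreferenceIndex((t_pref - t_other) / total, total, n_trans)


def exclusion_mask(session: RecordingSession, half_window_s: float = 30.0) -> np.ndarray:
    """Boolean sample mask, False within +/- ``half_window_s`` of each
    stimulus insertion/removal event, True elsewhere."""
    fs = session.sampling_rate
    mask = np.ones(session.n_samples, dtype=bool)
    for t in (session.insertion_time, session.removal_time):
        if t is None:
            continue
        lo = max(0, int(round((t - half_window_s) * fs)))
        hi = min(session.n_samples, int(round((t + half_window_s) * fs)))
        mask[lo:hi] = False
    return mask


def mask_to_intervals(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    """Contiguous True runs of a sample mask, as [start, end) second intervals."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]
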
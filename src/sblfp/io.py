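"""Readers and writers for the on-disk session layout.

Layout under a dataset root::

    <root>/
      <session_id>/
        signals.h5    # 2-D float32 dataset "lfp" (n_regions x n_samples, uV)
                      # attrs: sampling_rate_hz, region_labels
        session.json  # subject_id, task, session_index, intervals, stimulus_map
        bouts.csv     # session_id,stimulus,chamber,start_s,end_s
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datamodel import (
    BOUT_COLUMNS,
    Dataset,
    RecordingSession,
    ValidationError,
    make_bout_table,
)

SIGNALS_FILE = "signals.h5"
SIDECAR_FILE = "session.json"
BOUTS_FILE = "bouts.csv"


def write_session(session: RecordingSession, bouts: pd.DataFrame, root: Path | str) -> Path:
    root = Path(root)
    sdir = root / session.session_id
    sdir.mkdir(parents=True, exist_ok=True)
    with h5py.File(sdir / SIGNALS_FILE, "w") as f:
        d = f.create_dataset("lfp", data=session.signals.astype(np.float32))
        d.attrs["sampling_rate_hz"] = float(session.sampling_rate)
        d.attrs["region_labels"] = np.array(session.region_labels, dtype="S")
    sidecar = {
        "subject_id": session.subject_id,
        "task": session.task,
        "session_index": session.session_index,
        "baseline_interval": list(session.baseline_interval),
        "encounter_interval": list(session.encounter_interval),
        "stimulus_map": session.stimulus_map,
        "insertion_time": session.insertion_time,
        "removal_time": session.removal_time,
    }
    (sdir / SIDECAR_FILE).write_text(json.dumps(sidecar, indent=1))
    bouts.to_csv(sdir / BOUTS_FILE, index=False)
    return sdir


def read_session(sdir: Path | str) -> tuple[RecordingSession, pd.DataFrame]:
    sdir = Path(sdir)
    sig_path = sdir / SIGNALS_FILE
    try:
        with h5py.File(sig_path, "r") as f:
            d = f["lfp"]
            if "sampling_rate_hz" not in d.attrs:
                raise ValidationError(f"{sig_path}: missing sampling_rate_hz attribute")
            fs = float(d.attrs["sampling_rate_hz"])
            labels = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in d.attrs["region_labels"]
            ]
            signals = d[()]
    except OSError as e:
        raise ValidationError(f"{sig_path}: unreadable signal container ({e})") from e
    try:
        meta = json.loads((sdir / SIDECAR_FILE).read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise ValidationError(f"{sdir / SIDECAR_FILE}: unreadable sidecar ({e})") from e
    for key in ("subject_id", "task", "session_index", "baseline_interval",
                "encounter_interval", "stimulus_map"):
        if key not in meta:
            raise ValidationError(f"{sdir / SIDECAR_FILE}: missing field {key!r}")
    session = RecordingSession(
        subject_id=meta["subject_id"],
        task=meta["task"],
        session_index=int(meta["session_index"]),
        sampling_rate=fs,
        signals=signals,
        region_labels=labels,
        baseline_interval=tuple(meta["baseline_interval"]),
        encounter_interval=tuple(meta["encounter_interval"]),
        stimulus_map=dict(meta["stimulus_map"]),
        insertion_time=meta.get("insertion_time"),
        removal_time=meta.get("removal_time"),
    )
    bpath = sdir / BOUTS_FILE
    if bpath.exists():
        bouts = make_bout_table(pd.read_csv(bpath))
    else:
        bouts = make_bout_table(pd.DataFrame(columns=BOUT_COLUMNS))
    return session, bouts


def write_dataset(dataset: Dataset, root: Path | str) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for session, bouts in zip(dataset.sessions, dataset.bout_tables):
        write_session(session, bouts, root)
    return root


def read_dataset(root: Path | str, validate: bool = True) -> Dataset:
    """Read and validate every session directory under ``root``.

    Malformed sessions raise :class:`ValidationError` naming the file and
    field that failed.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValidationError(f"{root}: not a directory")
    sessions, bout_tables = [], []
    for sdir in sorted(p for p in root.iterdir() if (p / SIDECAR_FILE).exists()):
        session, bouts = read_session(sdir)
        sessions.append(session)
        bout_tables.append(bouts)
    if not sessions:
        raise ValidationError(f"{root}: no session directories found")
    ds = Dataset(sessions, bout_tables)
    if validate:
        ds.validate()
    return ds
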
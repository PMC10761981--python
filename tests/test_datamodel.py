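import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sblfp.datamodel import (
    EMPTY_STIMULUS,
    REGIONS,
    Dataset,
    RecordingSession,
    ValidationError,
    eligible_pairs,
    exclusion_mask,
    extract_events,
    filter_regions,
    make_bout_table,
    mask_to_intervals,
    preference_index,
    valid_bouts,
    validate_bout_table,
)


def _session(subject="M01", task="SP", idx=1, regions=("PrL", "IL"), fs=100.0, dur=60.0):
    n = int(dur * fs)
    return RecordingSession(
        subject_id=subject, task=task, session_index=idx, sampling_rate=fs,
        signals=np.zeros((len(regions), n), dtype=np.float32),
        region_labels=list(regions),
        baseline_interval=(0.0, dur / 2), encounter_interval=(dur / 2, dur),
        stimulus_map={"left": "social", "right": "object"},
        insertion_time=dur / 2, removal_time=dur,
    )


class TestValidation:
    def test_valid_session_passes(self):
        _session().validate()

    def test_unknown_region_names_the_legal_codes(self):
        s = _session(regions=("PrL", "XYZ"))
        with pytest.raises(ValidationError, match="XYZ") as err:
            s.validate()
        assert "AcbC" in str(err.value)  # lists the vocabulary

    def test_stimulus_illegal_for_task(self):
        s = _session(task="EsP")  # stimulus_map says social/object
        with pytest.raises(ValidationError, match="social"):
            s.validate()

    def test_reversed_bout_cites_row(self):
        bouts = make_bout_table([("s", "social", "left", 5.0, 3.0)])
        with pytest.raises(ValidationError, match="end_s <= start_s"):
            validate_bout_table(bouts)

    def test_overlapping_bouts_rejected(self):
        bouts = make_bout_table([
            ("s", "social", "left", 1.0, 4.0),
            ("s", "object", "right", 3.0, 6.0),
        ])
        with pytest.raises(ValidationError, match="overlap"):
            validate_bout_table(bouts)


class TestRegionFilters:
    def _dataset(self, layout):
        """layout: list of (subject, task, regions)."""
        sessions, bouts = [], []
        counters = {}
        for subject, task, regions in layout:
            k = counters.setdefault((subject, task), 0) + 1
            counters[(subject, task)] = k
            sessions.append(_session(subject, task, k, regions))
            bouts.append(make_bout_table([]))
        return Dataset(sessions, bouts)

    def test_region_needs_more_than_five_sessions(self):
        # PrL: exactly 5 sessions across 3 mice -> dropped; IL: 6 -> kept
        layout = [(f"M{i}", "SP", ("PrL", "IL")) for i in [1, 1, 2, 2, 3]]
        layout += [("M3", "SP", ("IL",))]
        ds = self._dataset(layout)
        assert filter_regions(ds) == ["IL"]

    def test_region_needs_three_subjects(self):
        layout = [("M1", "SP", ("PrL",))] * 10
        ds = self._dataset(layout)
        assert filter_regions(ds) == []

    def test_six_sessions_three_mice_kept(self):
        layout = [(f"M{1 + i % 3}", "SP", ("PrL",)) for i in range(6)]
        assert filter_regions(self._dataset(layout)) == ["PrL"]

    def test_eligible_pairs_requires_all_tasks(self):
        layout = []
        for task in ("SP", "EsP"):  # missing SxP entirely
            layout += [(f"M{m}", task, ("PrL", "IL")) for m in (1, 2, 3) for _ in range(3)]
        ds = self._dataset(layout)
        assert eligible_pairs(ds, min_sessions=5, min_subjects=2) == []

    def test_eligible_pairs_boundary_inclusive(self):
        layout = []
        for task in ("SP", "EsP", "SxP"):
            # pair co-recorded in exactly 5 sessions from 2 subjects per task
            layout += [("M1", task, ("PrL", "IL"))] * 3
            layout += [("M2", task, ("PrL", "IL"))] * 2
            # extra subjects so each region passes the >=3-mice region filter
            layout += [("M3", task, ("PrL",))] * 3
            layout += [("M4", task, ("IL",))] * 3
        ds = self._dataset(layout)
        assert eligible_pairs(ds) == [("IL", "PrL")]

    def test_eligible_pairs_subset_of_filtered_regions(self, tiny_dataset):
        ds, _ = tiny_dataset
        regions = set(filter_regions(ds))
        for a, b in eligible_pairs(ds, min_sessions=3):
            assert {a, b} <= regions

    def test_constructed_design_pair_count(self):
        """Brute-force oracle: count pairs satisfying the criteria directly."""
        rng = np.random.default_rng(7)
        regions = list(REGIONS[:6])
        layout = []
        subj_regions = {f"M{m}": [r for r in regions if rng.random() > 0.3] for m in range(5)}
        for subject, regs in subj_regions.items():
            for task in ("SP", "EsP", "SxP"):
                layout += [(subject, task, tuple(regs))] * 3
        ds = self._dataset(layout)
        got = eligible_pairs(ds, min_sessions=5, min_subjects=2, regions=regions)
        # oracle: direct enumeration
        import itertools
        expected = []
        for pair in itertools.combinations(sorted(regions), 2):
            ok = True
            for task in ("SP", "EsP", "SxP"):
                n_sess = sum(3 for s, regs in subj_regions.items() if set(pair) <= set(regs))
                n_subj = sum(1 for s, regs in subj_regions.items() if set(pair) <= set(regs))
                if n_sess < 5 or n_subj < 2:
                    ok = False
            if ok:
                expected.append(pair)
        assert got == expected


class TestBoutsAndEvents:
    def test_strict_duration_threshold(self):
        bouts = make_bout_table([
            ("s", "social", "l", 0.0, 1.9), ("s", "social", "l", 3.0, 5.0),
            ("s", "social", "l", 6.0, 8.1), ("s", "social", "l", 10.0, 15.0),
        ])
        kept = valid_bouts(bouts)  # durations 1.9, 2.0, 2.1, 5.0
        assert list(kept["end_s"] - kept["start_s"]) == pytest.approx([2.1, 5.0])

    def test_valid_bouts_idempotent_and_empty_ok(self):
        empty = make_bout_table([])
        assert valid_bouts(empty).empty
        bouts = make_bout_table([("s", "social", "l", 0.0, 5.0)])
        once = valid_bouts(bouts)
        pd.testing.assert_frame_equal(valid_bouts(once), once)

    def test_lognormal_filter_matches_brute_force(self):
        rng = np.random.default_rng(0)
        starts = np.cumsum(rng.exponential(10, 100)) + 10
        durs = rng.lognormal(0.7, 0.6, 100)
        bouts = make_bout_table([
            ("s", "social", "l", s, s + d) for s, d in zip(starts, durs)
        ])
        assert len(valid_bouts(bouts)) == int((durs > 2).sum())

    def test_transition_and_repeat_kinds(self, simple_bouts):
        events = extract_events(simple_bouts)  # stimuli social,social,object,social
        kinds = [e.kind for e in events]
        assert kinds.count("bout_start") == 4 and kinds.count("bout_end") == 4
        extra = [e.kind for e in events if e.kind.endswith("_start") and e.kind != "bout_start"]
        assert extra == ["repeat_start", "transition_start", "transition_start"]

    def test_single_bout_two_events(self):
        events = extract_events(make_bout_table([("s", "social", "l", 0.0, 3.0)]))
        assert [e.kind for e in events] == ["bout_start", "bout_end"]

    @given(st.lists(st.sampled_from(["social", "object"]), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_event_count_identity(self, stims):
        bouts = make_bout_table([
            ("s", stim, "l", 10.0 * i, 10.0 * i + 3) for i, stim in enumerate(stims)
        ])
        events = extract_events(bouts)
        n = len(stims)
        assert len(events) == 2 * n + (n - 1)
        n_trans = sum(e.kind == "transition_start" for e in events)
        assert n_trans == sum(a != b for a, b in zip(stims, stims[1:]))


class TestPreferenceIndex:
    def test_formula(self):
        bouts = make_bout_table([
            ("s", "social", "l", 0.0, 60.0), ("s", "object", "r", 70.0, 110.0),
        ])
        pi = preference_index(bouts, "social")
        assert pi.rdi == pytest.approx(0.2)
        assert pi.total_investigation_s == pytest.approx(100.0)

    def test_worked_example_with_transitions(self):
        bouts = make_bout_table([
            ("s", "social", "l", 0.0, 10.0), ("s", "object", "r", 12.0, 22.0),
            ("s", "social", "l", 25.0, 45.0),
        ])
        pi = preference_index(bouts, "social")
        assert pi.rdi == pytest.approx(0.5)
        assert pi.n_transitions == 2

    def test_antisymmetry(self, simple_bouts):
        a = preference_index(simple_bouts, "social").rdi
        b = preference_index(simple_bouts, "object").rdi
        assert a == pytest.approx(-b)

    def test_zero_time_flagged(self):
        with pytest.raises(ValidationError, match="undefined"):
            preference_index(make_bout_table([]), "social")


class TestExclusionMask:
    def test_window_bounds(self):
        s = _session(fs=100.0, dur=600.0)
        s.insertion_time, s.removal_time = 300.0, None
        m = exclusion_mask(s, 30.0)
        fs = 100
        assert not m[270 * fs:330 * fs - 1].any()
        assert m[:270 * fs].all() and m[330 * fs:].all()

    def test_no_events_all_true(self):
        s = _session()
        s.insertion_time = s.removal_time = None
        assert exclusion_mask(s).all()

    def test_overlapping_windows_union(self):
        s = _session(fs=100.0, dur=600.0)
        s.insertion_time, s.removal_time = 100.0, 130.0  # 30 s apart
        m = exclusion_mask(s, 30.0)
        # oracle: union of [70,130) and [100,160) = [70,160) -> 90 s masked
        assert (~m).sum() == pytest.approx(90 * 100, abs=2)
        ivals = mask_to_intervals(m, 100.0)
        assert len(ivals) == 2  # [0,70) and [160,600)
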
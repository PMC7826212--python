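"""RT-window screening, isomer resolution and MRM scheduling."""

import itertools

import numpy as np
import pytest

from riscreen.chromatogram import Peak
from riscreen.errors import PanelError, ScheduleError
from riscreen.pesticide_db import annotate_panel
from riscreen.screening import (
    assign_order_preserving,
    build_mrm_schedule,
    resolve_isomers,
    screen_sample,
    summarize_study,
)


def peak_at(rt, area=1000.0, height=500.0):
    return Peak(apex_rt=rt, height=height, area=area,
                left_rt=rt - 0.05, right_rt=rt + 0.05, snr=100.0)


def peaks_for(panel, entry_rts, include_qualifier=True):
    """Build a peaks_by_transition mapping placing quantifier (and
    optionally qualifier) peaks at the given {entry_name: rt}."""
    by_name = {r.entry_name: r for r in panel.records}
    out = {}
    for name, rt in entry_rts.items():
        rec = by_name[name]
        out.setdefault(rec.quantifier, []).append(peak_at(rt))
        if include_qualifier:
            out.setdefault(rec.qualifier, []).append(peak_at(rt, area=500.0))
    return out


class TestScreenSample:
    def test_empty_input(self, printed_panel):
        assert screen_sample({}, printed_panel) == []

    def test_unannotated_panel_rejected(self, panel_records):
        with pytest.raises(PanelError):
            screen_sample({}, panel_records)

    def test_procymidone_worked_example(self, printed_panel):
        peaks = peaks_for(printed_panel, {"Procymidone": 14.617})
        hits = [h for h in screen_sample(peaks, printed_panel) if h.confirmed]
        assert [h.entry_name for h in hits] == ["Procymidone"]
        assert hits[0].deviation == pytest.approx(0.004, abs=1e-9)

    def test_cypermethrin_isomer_worked_example(self, printed_panel):
        """Three co-monitored isomer peaks are told apart purely by predicted
        retention time, with the printed deviations."""
        observed = {
            "Cypermethrin-1": 20.561,
            "Cypermethrin-2": 20.663,
            "Cypermethrin-3": 20.717,
        }
        peaks = peaks_for(printed_panel, observed)
        hits = {h.entry_name: h for h in screen_sample(peaks, printed_panel) if h.confirmed}
        assert set(hits) == set(observed)
        assert hits["Cypermethrin-1"].deviation == pytest.approx(0.004, abs=1e-9)
        assert hits["Cypermethrin-2"].deviation == pytest.approx(0.001, abs=1e-9)
        assert hits["Cypermethrin-3"].deviation == pytest.approx(0.006, abs=1e-9)

    def test_unconfirmed_without_qualifier(self, printed_panel):
        peaks = peaks_for(printed_panel, {"Procymidone": 14.617}, include_qualifier=False)
        hits = screen_sample(peaks, printed_panel)
        assert [h.confirmed for h in hits if h.entry_name == "Procymidone"] == [False]

    def test_ion_ratio_gate(self, printed_panel):
        peaks = peaks_for(printed_panel, {"Procymidone": 14.617})  # ratio 0.5
        ok = screen_sample(
            peaks, printed_panel, ion_ratio_tol=0.3,
            reference_ion_ratios={"Procymidone": 0.5},
        )
        bad = screen_sample(
            peaks, printed_panel, ion_ratio_tol=0.3,
            reference_ion_ratios={"Procymidone": 0.9},
        )
        assert any(h.confirmed for h in ok if h.entry_name == "Procymidone")
        assert not any(h.confirmed for h in bad if h.entry_name == "Procymidone")

    def test_hits_monotone_in_window(self, printed_panel):
        peaks = peaks_for(
            printed_panel,
            {"Procymidone": 14.617, "Chlorpyrifos": 13.583, "Fipronil": 14.314},
        )
        confirmed_sets = []
        for window in (0.005, 0.02, 0.05, 0.1):
            hits = screen_sample(peaks, printed_panel, rt_window=window)
            confirmed_sets.append({h.entry_name for h in hits if h.confirmed})
            assert all(h.deviation <= window for h in hits)
        for a, b in zip(confirmed_sets, confirmed_sets[1:]):
            assert a <= b

    def test_vanishing_window_keeps_only_exact_matches(self, printed_panel):
        peaks = peaks_for(
            printed_panel,
            {"Procymidone": 14.613, "Chlorpyrifos": 13.583},  # first exactly at prediction
        )
        hits = screen_sample(peaks, printed_panel, rt_window=1e-9)
        assert {h.entry_name for h in hits} == {"Procymidone"}


def brute_force_assignment(predicted, observed, window):
    """Enumerate every order-preserving matching; return the optimum under
    (max matches, min total deviation)."""
    best = (0, 0.0, ())
    m, n = len(predicted), len(observed)
    for k in range(min(m, n) + 1):
        for preds in itertools.combinations(range(m), k):
            for obs in itertools.combinations(range(n), k):
                devs = [abs(predicted[i] - observed[j]) for i, j in zip(preds, obs)]
                if any(d > window for d in devs):
                    continue
                cand = (-k, sum(devs), tuple(zip(preds, obs)))
                if (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
    return best[0], best[1]


class TestResolveIsomers:
    def test_in_order_one_to_one(self):
        preds = [20.232, 20.333, 20.390, 20.439]
        obs = [20.236, 20.334, 20.395, 20.439]
        assert resolve_isomers(preds, obs) == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_tie_broken_to_earlier_isomer(self):
        assert resolve_isomers([10.0, 10.2], [10.1], window=0.15) == [(0, 0)]

    def test_unmatched_predictions_absent(self):
        pairs = resolve_isomers([10.0, 10.2, 10.4], [10.41], window=0.05)
        assert pairs == [(2, 0)]

    def test_matches_brute_force(self, rng):
        """Randomised jittered isomer clusters agree with exhaustive search."""
        agree = 0
        trials = 1000
        for _ in range(trials):
            m = int(rng.integers(1, 5))
            n = int(rng.integers(0, 5))
            preds = np.sort(rng.uniform(0, 0.5, m)).tolist()
            k = min(m, n)
            jittered = np.asarray(preds[:k]) + rng.normal(0, 0.005, k)
            extras = rng.uniform(0, 0.5, n - k)
            obs = np.sort(np.concatenate([jittered, extras])).tolist()
            got = assign_order_preserving(preds, obs, window=0.05)
            got_cost = (-len(got), sum(abs(preds[i] - obs[j]) for i, j in got))
            want_cost = brute_force_assignment(preds, obs, window=0.05)
            if got_cost == pytest.approx(want_cost):
                agree += 1
        assert agree >= trials - 1


class TestBuildSchedule:
    def test_single_compound(self, panel_records, ladder_fit):
        rec = next(r for r in panel_records if r.entry_name == "Procymidone")
        panel = annotate_panel([rec], ladder_fit.ladder)
        segments = build_mrm_schedule(panel, window=0.5, max_concurrent=2)
        assert len(segments) == 1
        assert segments[0].n_concurrent == 2

    def test_two_distant_compounds_two_segments(self, panel_records, ladder_fit):
        recs = [r for r in panel_records if r.entry_name in ("Dichlorvos", "Procymidone")]
        panel = annotate_panel(recs, ladder_fit.ladder)
        segments = build_mrm_schedule(panel, window=0.5, max_concurrent=2)
        assert len(segments) == 2

    def test_infeasible_concurrency_names_cluster(self, annotated_panel):
        with pytest.raises(ScheduleError, match="concurrent"):
            build_mrm_schedule(annotated_panel, window=0.5, max_concurrent=3)

    def test_full_panel_schedule_is_valid(self, annotated_panel):
        """Brute-force checker: every transition window inside exactly one
        segment; concurrency within limits; segments ordered and disjoint."""
        window, max_concurrent = 0.5, 200
        segments = build_mrm_schedule(
            annotated_panel, window=window, max_concurrent=max_concurrent
        )
        for a, b in zip(segments, segments[1:]):
            assert a.end_rt <= b.start_rt + 1e-9
        for seg in segments:
            assert seg.n_concurrent <= max_concurrent
        scheduled = [(name, tr) for seg in segments for name, tr in seg.transitions]
        expected = [
            (r.entry_name, tr) for r in annotated_panel.records for tr in r.transitions
        ]
        assert sorted(scheduled, key=str) == sorted(expected, key=str)
        for seg in segments:
            for name, tr in seg.transitions:
                rt = annotated_panel.predicted_rt(name)
                containing = [
                    s for s in segments
                    if s.start_rt <= rt - window and rt + window <= s.end_rt
                ]
                assert containing == [seg]


class TestSummarizeStudy:
    def test_empty_and_single_hit(self, printed_panel):
        mat = summarize_study({"A": [], "B": []}, printed_panel)
        assert (mat.to_numpy() == 0).all()
        peaks = peaks_for(printed_panel, {"Procymidone": 14.617})
        hits = screen_sample(peaks, printed_panel, sample_id="A")
        mat = summarize_study({"A": hits}, printed_panel)
        assert mat.loc["A", "Procymidone"] == 1
        assert mat.loc["A"].sum() == 1
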
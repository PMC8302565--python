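"""Phase extraction, exclusion, rebalancing and aggregation contracts."""

import numpy as np
import pandas as pd
import pytest

import tactile_rivalry as tr


def make_trial(durations_labels, subject=0, delta_i=2.0, rep=0):
    phases, t = [], 0.0
    for label, dur in durations_labels:
        phases.append(tr.PerceptPhase(label, t, dur))
        t += dur
    return tr.Trial(subject=subject, delta_i=delta_i, repetition=rep,
                    phases=phases, trial_length=t)


class TestExtractPhases:
    def test_direct_run_lengths(self):
        left = np.zeros(2000, dtype=int)
        right = np.zeros(2000, dtype=int)
        left[0:1000] = 1
        right[1000:2000] = 1
        ph = tr.extract_phases(left, right, 100.0)
        assert [(p.percept, p.duration) for p in ph] == [
            (tr.SIM, 10.0), (tr.AM, 10.0)]
        assert ph[0].onset == 0.0 and ph[1].onset == 10.0
        assert not ph[0].censored and ph[1].censored

    def test_both_keys_held_is_unreported(self):
        ones = np.ones(500, dtype=int)
        assert tr.extract_phases(ones, ones, 100.0) == []

    def test_short_gap_merges_same_percept(self):
        left = np.ones(1000, dtype=int)
        left[500:520] = 0  # 0.2 s re-grip gap, below 0.5 s tolerance
        ph = tr.extract_phases(left, np.zeros(1000, dtype=int), 100.0)
        assert len(ph) == 1 and ph[0].duration == 10.0

    def test_long_gap_splits_phases(self):
        left = np.ones(1000, dtype=int)
        left[400:500] = 0  # 1 s gap exceeds tolerance
        ph = tr.extract_phases(left, np.zeros(1000, dtype=int), 100.0)
        assert len(ph) == 2

    def test_reported_plus_unreported_is_trace_length(self):
        rng = np.random.default_rng(0)
        left = (rng.random(3000) < 0.4).astype(int)
        right = ((rng.random(3000) < 0.4) & (left == 0)).astype(int)
        ph = tr.extract_phases(left, right, 100.0, merge_tolerance=0.0)
        reported = sum(p.duration for p in ph)
        unreported = np.sum((left == 0) & (right == 0)) / 100.0
        assert reported + unreported == pytest.approx(30.0)

    def test_non_binary_trace_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            tr.extract_phases(np.array([0, 2, 1]), np.zeros(3, dtype=int),
                              100.0)


class TestExclusion:
    def test_non_alternating_trial_excluded(self):
        trial = make_trial([(tr.SIM, 180.0)])
        kept, report = tr.apply_exclusion([trial])
        assert kept == [] and report.n_excluded == 1

    def test_short_mean_excluded_under_floor(self):
        trial = make_trial([(tr.SIM, 3.0), (tr.AM, 20.0)] * 5)
        kept, _ = tr.apply_exclusion([trial])
        assert kept == []

    def test_kept_trials_unchanged_and_partition(self, dataset):
        kept, report = tr.apply_exclusion(dataset)
        assert len(kept) + report.n_excluded == len(dataset)
        assert all(not t.excluded for t in kept)
        # idempotence on the kept set
        kept2, report2 = tr.apply_exclusion(kept)
        assert report2.n_excluded == 0 and len(kept2) == len(kept)

    def test_across_percept_mode_differs(self):
        # SIM mean 3 s (below floor) but across-percept mean fine
        trial = make_trial([(tr.SIM, 3.0), (tr.AM, 30.0)] * 4)
        kept_pp, _ = tr.apply_exclusion([trial], mode="per_percept")
        kept_ap, _ = tr.apply_exclusion([trial], mode="across_percept")
        assert kept_pp == [] and len(kept_ap) == 1

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            tr.apply_exclusion([], min_mean=150.0, max_mean=4.0)


class TestRebalance:
    def _means(self, values, di=2.0, percept=tr.SIM):
        return pd.DataFrame({
            "subject": range(len(values)), "delta_i_db": di,
            "repetition": 0, "percept": percept,
            "mean_duration_s": values, "n_phases": 5})

    def test_full_cell_is_noop(self):
        table = self._means(np.linspace(5, 30, 45))
        out = tr.rebalance(table, target_n=45, rng=0)
        assert len(out) == 45 and (out["source"] == "observed").all()

    def test_single_value_cell_forced_copies(self):
        table = self._means([12.5])
        out = tr.rebalance(table, target_n=45, rng=0)
        assert len(out) == 45
        assert (out["mean_duration_s"] == 12.5).all()
        assert (out["source"] == "resampled").sum() == 44

    def test_default_pipeline_cells_reach_target(self, kept_trials):
        balanced = tr.rebalance(tr.trial_mean_table(kept_trials), 45, rng=1)
        counts = balanced.groupby(["delta_i_db", "percept"]).size()
        assert (counts == 45).all()

    def test_never_invents_values_outside_support(self, kept_trials):
        table = tr.trial_mean_table(kept_trials)
        balanced = tr.rebalance(table, 45, rng=2)
        for (di, percept), grp in balanced.groupby(["delta_i_db", "percept"]):
            src = set(table.loc[(table.delta_i_db == di)
                                & (table.percept == percept),
                                "mean_duration_s"])
            assert set(grp["mean_duration_s"]) <= src

    def test_deterministic_given_seed(self, kept_trials):
        table = tr.trial_mean_table(kept_trials)
        a = tr.rebalance(table, 45, rng=7)
        b = tr.rebalance(table, 45, rng=7)
        assert a.equals(b)

    def test_empty_cell_raises(self):
        table = self._means(np.linspace(5, 30, 10))  # only (2.0, SIM) present
        with pytest.raises(ValueError, match="unrecoverable"):
            tr.rebalance(table, target_n=45, rng=0,
                         expected_cells=[(2.0, tr.SIM), (2.0, tr.AM)])


class TestTrialSummary:
    def test_direct_arithmetic(self, simple_phases):
        trial = tr.Trial(0, 2.0, 0, simple_phases)
        s = tr.trial_summary(trial, drop_censored=False)
        assert s.mean_dur_sim == 20.0 and s.mean_dur_am == 20.0
        assert s.prop_sim == pytest.approx(2 / 3)
        assert s.prop_am == pytest.approx(1 / 3)
        assert s.n_phases == 3
        assert s.alternation_rate == pytest.approx(2 / 60.0 * 60.0)

    def test_single_phase_has_zero_rate(self):
        trial = make_trial([(tr.AM, 30.0)])
        assert tr.trial_summary(trial).alternation_rate == 0.0

    def test_zero_phases_undefined(self):
        with pytest.raises(ValueError):
            tr.trial_summary(tr.Trial(0, 2.0, 0, []))

    def test_proportions_sum_to_one(self, kept_trials):
        for t in kept_trials[:40]:
            s = tr.trial_summary(t)
            assert s.prop_sim + s.prop_am == pytest.approx(1.0)

    def test_symmetric_generator_equidominant(self):
        params = tr.GeneratorParams(
            seed=3, mean_sim_fn=lambda d: 15.0, mean_am_fn=lambda d: 15.0)
        trials = tr.generate_dataset(params)
        props = [tr.trial_summary(t).prop_sim for t in trials]
        assert np.mean(props) == pytest.approx(0.5, abs=0.03)


class TestSubjectConditionMeans:
    def test_pooling_not_mean_of_trial_means(self):
        t1 = make_trial([(tr.SIM, 10.0), (tr.AM, 5.0), (tr.SIM, 20.0)], rep=0)
        t2 = make_trial([(tr.AM, 5.0), (tr.SIM, 30.0)], rep=1)
        out = tr.subject_condition_means([t1, t2])
        sim = out[(out.percept == tr.SIM)]["mean_duration_s"].iloc[0]
        assert sim == pytest.approx(20.0)  # pooled {10,20,30}, not 22.5

    def test_identical_trials_idempotent(self):
        spec = [(tr.SIM, 12.0), (tr.AM, 8.0), (tr.SIM, 12.0), (tr.AM, 8.0)]
        trials = [make_trial(spec, rep=r) for r in range(3)]
        out = tr.subject_condition_means(trials)
        sim = out[out.percept == tr.SIM]["mean_duration_s"].iloc[0]
        assert sim == pytest.approx(12.0)

    def test_grand_mean_recovers_generator_truth(self):
        # symmetric generator, truth 15 s at every condition: the grand mean
        # across subjects should land within 3 SE of the truth
        params = tr.GeneratorParams(
            seed=5, mean_sim_fn=lambda d: 15.0, mean_am_fn=lambda d: 15.0,
            subject_sd=0.0)
        kept, _ = tr.apply_exclusion(tr.generate_dataset(params))
        out = tr.subject_condition_means(kept)
        vals = out["mean_duration_s"].dropna()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 15.0) < 3 * se + 0.75

    def test_missing_cell_warns_and_is_nan(self):
        t1 = make_trial([(tr.SIM, 10.0), (tr.AM, 5.0)], subject=0, delta_i=2.0)
        t2 = make_trial([(tr.SIM, 10.0), (tr.AM, 5.0)], subject=1, delta_i=4.0)
        with pytest.warns(UserWarning, match="no retained"):
            out = tr.subject_condition_means([t1, t2])
        missing = out[(out.subject == 0) & (out.delta_i_db == 4.0)]
        assert missing["mean_duration_s"].isna().all()


class TestPhaseTableIO:
    def test_roundtrip(self, kept_trials, tmp_path):
        path = tmp_path / "phases.csv"
        tr.write_phase_table(kept_trials, path)
        back = tr.phase_table_to_trials(tr.load_phase_table(path))
        orig_table = tr.trials_to_phase_table(kept_trials)
        back_table = tr.trials_to_phase_table(back)
        pd.testing.assert_frame_equal(
            orig_table.sort_values(["subject", "delta_i_db", "repetition",
                                    "onset_s"]).reset_index(drop=True),
            back_table.sort_values(["subject", "delta_i_db", "repetition",
                                    "onset_s"]).reset_index(drop=True),
            check_exact=False)

    def test_dialect_validation(self, tmp_path):
        bad = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(bad, index=False)
        with pytest.raises(ValueError, match="dialect"):
            tr.load_phase_table(bad)


def test_summary_invariant_to_time_shift(simple_phases):
    trial = tr.Trial(0, 2.0, 0, simple_phases)
    shifted = tr.Trial(0, 2.0, 0, [
        tr.PerceptPhase(p.percept, p.onset + 7.0, p.duration)
        for p in simple_phases])
    a, b = tr.trial_summary(trial), tr.trial_summary(shifted)
    assert (a.mean_dur_sim, a.prop_sim, a.alternation_rate) == \
        (b.mean_dur_sim, b.prop_sim, b.alternation_rate)
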
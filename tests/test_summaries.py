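import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spiderpref as sp
from spiderpref.data_model import FEATURES, INSTRUCTIONS
from spiderpref.summaries import STATISTICS, mmpd, incoherency

from conftest import mmpd_reference

grid_values = st.integers(min_value=0, max_value=9).map(lambda k: k / 9)


class TestMmpd:
    @pytest.mark.parametrize("values,expected", [
        ([0.2, 0.3, 0.9], 0.25),          # below side wins 2-1
        ([0.5, 0.5, 0.5], 0.5),           # nothing strictly on either side
        ([0.6, 0.7, 0.5, 0.1], 0.6),      # above side wins; 0.5 re-included
        ([0.4, 0.6], 0.5),                # tie: all values averaged
    ])
    def test_hand_worked_examples(self, values, expected):
        assert mmpd(values) == pytest.approx(expected)

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            mmpd([])
        with pytest.raises(ValueError):
            mmpd([0.2, 1.2])

    def test_matches_brute_force_oracle_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            vals = rng.integers(0, 10, size=12) / 9
            assert mmpd(vals) == pytest.approx(mmpd_reference(list(vals)))

    @given(st.lists(grid_values, min_size=1, max_size=24))
    @settings(deadline=None)
    def test_bounded_by_input_range_and_permutation_invariant(self, vals):
        m = mmpd(vals)
        assert min(vals) - 1e-12 <= m <= max(vals) + 1e-12
        assert mmpd(list(reversed(vals))) == pytest.approx(m)

    @given(st.lists(st.integers(min_value=0, max_value=3).map(lambda k: k / 9),
                    min_size=1, max_size=24))
    @settings(deadline=None)
    def test_equals_mean_when_all_values_on_one_side(self, vals):
        assert mmpd(vals) == pytest.approx(float(np.mean(vals)))


class TestIncoherency:
    @pytest.mark.parametrize("d,h,x", [
        (0.2, 0.8, 0.0),   # perfectly specular
        (0.9, 0.9, 0.8),
        (0.5, 0.5, 0.0),
        (0.0, 0.0, 1.0),   # both at the same extreme
        (1.0, 1.0, 1.0),
    ])
    def test_formula(self, d, h, x):
        assert incoherency(d, h) == pytest.approx(x)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p_harmless"):
            incoherency(0.5, 1.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        x = incoherency(a, b)
        assert 0 <= x <= 1
        assert incoherency(b, a) == pytest.approx(x)

    @given(st.floats(0, 1))
    @settings(deadline=None)
    def test_specular_pairs_score_zero(self, p):
        assert incoherency(p, 1 - p) == pytest.approx(0.0)


class TestSummarize:
    def test_one_summary_per_cell(self, reference_cohort):
        summ = sp.summarize_preferences(reference_cohort, "mmpd")
        assert len(summ) == 45 * len(FEATURES) * len(INSTRUCTIONS)
        assert summ["value"].between(0, 1).all()
        assert (summ["n_trials"] == 12).all()

    def test_mean_statistic_is_arithmetic_mean(self, reference_cohort):
        summ = sp.summarize_preferences(reference_cohort, "mean")
        pid = reference_cohort.participants["participant_id"].iloc[0]
        t = reference_cohort.trials
        expected = t.loc[(t["participant_id"] == pid)
                         & (t["instruction"] == "dangerous"), "hairiness"].mean()
        got = summ.loc[(summ["participant_id"] == pid)
                       & (summ["feature"] == "hairiness")
                       & (summ["instruction"] == "dangerous"), "value"].iloc[0]
        assert got == pytest.approx(expected)

    def test_mmpd_statistic_composes_with_mmpd(self, reference_cohort):
        summ = sp.summarize_preferences(reference_cohort, "mmpd")
        pid = reference_cohort.participants["participant_id"].iloc[3]
        t = reference_cohort.trials
        vals = t.loc[(t["participant_id"] == pid)
                     & (t["instruction"] == "harmless"), "locomotion"].to_numpy()
        got = summ.loc[(summ["participant_id"] == pid)
                       & (summ["feature"] == "locomotion")
                       & (summ["instruction"] == "harmless"), "value"].iloc[0]
        assert got == pytest.approx(mmpd(vals))

    def test_noise_free_cohort_summaries_hit_latent_means(self, noise_free_cohort):
        for stat in STATISTICS:
            summ = sp.summarize_preferences(noise_free_cohort, stat)
            for (f, i), grp in summ.groupby(["feature", "instruction"]):
                from spiderpref.synthetic import REFERENCE_CONDITION_MEANS

                target = round(REFERENCE_CONDITION_MEANS[(f, i)] * 9) / 9
                assert np.allclose(grp["value"], target)

    def test_missing_instruction_warns_and_omits(self, tiny_cohort):
        trials = tiny_cohort.trials[tiny_cohort.trials["instruction"] == "dangerous"]
        cohort = sp.CohortTable(participants=tiny_cohort.participants, trials=trials)
        with pytest.warns(UserWarning, match="harmless"):
            summ = sp.summarize_preferences(cohort, "mean")
        assert set(summ["instruction"]) == {"dangerous"}

    def test_mirror_symmetry_of_mean_summaries(self, reference_cohort):
        """Relabeling an axis (x -> 1-x) mirrors summaries, keeps incoherency."""
        flipped_trials = reference_cohort.trials.copy()
        for f in FEATURES:
            flipped_trials[f] = 1.0 - flipped_trials[f]
        flipped = sp.CohortTable(participants=reference_cohort.participants,
                                 trials=flipped_trials)
        a = sp.summarize_preferences(reference_cohort, "mean")
        b = sp.summarize_preferences(flipped, "mean")
        merged = a.merge(b, on=["participant_id", "feature", "instruction"])
        assert np.allclose(merged["value_x"], 1.0 - merged["value_y"])
        ia = sp.incoherency_table(a).set_index(["participant_id", "feature"])["x"]
        ib = sp.incoherency_table(b).set_index(["participant_id", "feature"])["x"]
        assert np.allclose(ia, ib.reindex(ia.index))


class TestGrandAverages:
    def test_table_layout(self, reference_cohort):
        g = sp.grand_average_table(reference_cohort)
        pref = g[g["statistic"].isin(STATISTICS)]
        assert len(pref) == 3 * 6
        inco = g[g["statistic"] == "incoherency"]
        assert len(inco) == 3
        assert g["mean"].between(0, 1).all()

    def test_constant_cohort_gives_zero_sd(self, noise_free_cohort):
        g = sp.grand_average_table(noise_free_cohort)
        assert np.allclose(g["sd"], 0.0)

    def test_incoherency_row_uses_requested_statistic(self, reference_cohort):
        g = sp.grand_average_table(reference_cohort, incoherency_statistic="mean")
        inco = sp.incoherency_table(
            sp.summarize_preferences(reference_cohort, "mean"))
        expected = inco.groupby("feature")["x"].mean()
        got = g[g["statistic"] == "incoherency"].set_index("feature")["mean"]
        assert np.allclose(got.sort_index(), expected.sort_index())


class TestOrientationSummaries:
    def test_each_stratum_uses_four_trials(self, reference_cohort):
        out = sp.orientation_summaries(reference_cohort, "mean")
        assert len(out) == len(FEATURES) * len(INSTRUCTIONS) * 3
        assert (out["n"] == 45).all()

    def test_known_orientation_effect_detected(self, reference_cohort):
        out = sp.orientation_summaries(reference_cohort, "mean")
        dang = out[(out["feature"] == "hairiness")
                   & (out["instruction"] == "dangerous")].set_index("orientation")
        assert dang.loc["approaching", "mean"] < dang.loc["lateral", "mean"]
        assert dang.loc["approaching", "mean"] < dang.loc["withdrawing", "mean"]

    def test_null_effect_strata_agree(self, noise_free_cohort):
        out = sp.orientation_summaries(noise_free_cohort, "mean")
        for _, grp in out.groupby(["feature", "instruction"]):
            assert grp["mean"].max() - grp["mean"].min() == pytest.approx(0.0)


def test_summary_matrix_shape_and_order(reference_cohort):
    m = sp.summary_matrix(reference_cohort, "mmpd")
    assert list(m.columns) == ["spq", "hairiness_dangerous", "hairiness_harmless",
                               "bodyleg_dangerous", "bodyleg_harmless",
                               "locomotion_dangerous", "locomotion_harmless"]
    assert len(m) == 45
    assert not m.isna().any().any()
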
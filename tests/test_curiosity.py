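"""Exploration drives: arithmetic, recursions, and trace construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import curiolearn as cl
from curiolearn.curiosity import (
    EPE_UNSEEN,
    build_choice_table,
    build_trace,
    expected_lp,
    expected_pe_update,
    learning_progress,
    novelty,
    prediction_error,
    standardize,
)


class TestElementaryOperations:
    def test_prediction_error_examples(self):
        assert prediction_error(0.7, 0.5) == pytest.approx(0.2)
        assert prediction_error(0.3, 0.3) == 0.0
        assert prediction_error(0.1, 0.9) == prediction_error(0.9, 0.1)

    def test_learning_progress_examples(self):
        assert learning_progress(0.4, 0.1) == pytest.approx(0.3)
        assert learning_progress(0.25, 0.25) == 0.0
        with pytest.raises(ValueError):
            learning_progress(-0.1, 0.2)

    def test_novelty_examples(self):
        assert novelty(1) == -1
        assert novelty(7) == -7
        exposures = np.arange(1, 20)
        assert (np.diff(novelty(exposures)) < 0).all()

    def test_expected_pe_update_examples(self):
        assert expected_pe_update(0.0, 0.4, 1.0) == pytest.approx(0.4)
        assert expected_pe_update(0.3, 0.9, 0.0) == pytest.approx(0.3)

    def test_expected_pe_fixed_point(self):
        # constant error stream: the forecast converges to that constant
        epe = 0.0
        for _ in range(200):
            epe = expected_pe_update(epe, 0.37, 0.3)
        assert epe == pytest.approx(0.37, abs=1e-8)

    def test_expected_lp_examples(self):
        assert expected_lp(0.4, 0.3) == pytest.approx(0.1)
        assert expected_lp(0.25, 0.25) == 0.0


@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=40))
@settings(max_examples=100, deadline=None)
def test_learning_progress_telescopes(pes):
    pes = np.asarray(pes)
    lps = learning_progress(pes[:-1], pes[1:])
    assert lps.sum() == pytest.approx(pes[0] - pes[-1], abs=1e-12)


@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30),
    st.floats(min_value=0.01, max_value=1.0),
)
@settings(max_examples=100, deadline=None)
def test_expected_pe_stays_in_convex_hull(pes, alpha):
    epe = pes[0]
    lo, hi = pes[0], pes[0]
    for pe in pes:
        epe = expected_pe_update(epe, pe, alpha)
        lo, hi = min(lo, pe), max(hi, pe)
        assert lo - 1e-12 <= epe <= hi + 1e-12


def test_expected_lp_matches_composed_recursion():
    rng = np.random.default_rng(8)
    pes = rng.uniform(0, 1, 50)
    alphas = rng.uniform(0, 1, 50)
    epe = pes[0]
    for t in range(50):
        epe_next = epe + alphas[t] * (pes[t] - epe)  # independent step-by-step oracle
        assert expected_lp(pes[t], expected_pe_update(epe, pes[t], alphas[t])) == pytest.approx(
            pes[t] - epe_next, abs=1e-12
        )
        epe = epe_next


class TestBuildTrace:
    def test_reproduces_simulator_columns(self, small_cohort):
        trials = small_cohort.trials
        trace = build_trace(trials)
        for col in ("pe", "novelty", "epe", "epe_next", "elp_next"):
            assert np.allclose(trace[col], trials[col]), col
        a, b = trace["lp"].to_numpy(), trials["lp"].to_numpy()
        mask = ~np.isnan(b)
        assert np.array_equal(np.isnan(a), np.isnan(b))
        assert np.allclose(a[mask], b[mask])

    def test_lp_undefined_on_first_trial_of_engagement(self, small_cohort):
        trace = build_trace(small_cohort.trials)
        first = trace["trial_in_engagement"] == 1
        assert trace.loc[first, "lp"].isna().all()
        assert trace.loc[~first, "lp"].notna().all()

    def test_telescoping_over_engagements(self, small_cohort):
        trace = build_trace(small_cohort.trials)
        for _, g in trace.groupby(["participant", "engagement_id"]):
            if len(g) < 2:
                continue
            pes = g.sort_values("trial_in_engagement")["pe"].to_numpy()
            assert g["lp"].sum() == pytest.approx(pes[0] - pes[-1], abs=1e-10)

    def test_posterior_join_validates_coverage(self, small_cohort):
        trials = small_cohort.trials.head(50)
        post = trials[["participant", "setting", "animal", "exposure"]].head(10).copy()
        post["V"] = 0.5
        post["alpha_star"] = 0.3
        with pytest.raises(ValueError, match="cover"):
            build_trace(trials, post)

    def test_missing_columns_rejected(self, small_cohort):
        broken = small_cohort.trials.drop(columns=["V"])
        with pytest.raises(ValueError, match="V"):
            build_trace(broken)


class TestChoiceTable:
    def test_structure_three_options_one_chosen(self, small_cohort):
        trace = build_trace(small_cohort.trials)
        choices = build_choice_table(trace)
        counts = choices.groupby("event_id")["chosen"].agg(["size", "sum"])
        assert (counts["size"] == 3).all()
        assert (counts["sum"] == 1).all()

    def test_unseen_options_carry_defaults(self, small_cohort):
        trace = build_trace(small_cohort.trials)
        choices = build_choice_table(trace)
        unseen = choices[choices["novelty"] == 0]
        if len(unseen):
            assert np.allclose(unseen["epe"], EPE_UNSEEN)
            assert np.allclose(unseen["elp"], 0.0)

    def test_frozen_attributes_between_engagements(self, small_cohort):
        # an option's stored epe equals its last played trial's forecast
        trace = build_trace(small_cohort.trials)
        choices = build_choice_table(trace)
        merged = 0
        for _, row in choices.head(200).iterrows():
            past = trace[
                (trace["participant"] == row["participant"])
                & (trace["setting"] == row["setting"])
                & (trace["animal"] == row["option"])
                & (trace["setting_trial"] <= row["event_trial"])
            ]
            if len(past):
                last = past.sort_values("setting_trial").iloc[-1]
                assert row["epe"] == pytest.approx(last["epe_next"], abs=1e-12)
                assert row["novelty"] == -last["exposure"]
                merged += 1
        assert merged > 10


def test_standardize_global_scope(small_cohort):
    out = standardize(small_cohort.trials, ["pe", "epe_next"])
    assert abs(np.nanmean(out["pe_z"])) < 1e-10
    assert np.nanstd(out["pe_z"]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        standardize(small_cohort.trials.assign(flat=1.0), ["flat"])
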
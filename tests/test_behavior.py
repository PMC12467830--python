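"""Behavioural accuracy formulas against independent literal transcriptions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srk.behavior import (
    KnowledgeLog,
    MalformedLogError,
    RuleLog,
    TrackLog,
    aggregate_scores,
    cohens_d,
    knowledge1_accuracy,
    knowledge2_accuracy,
    questionnaire_average,
    rule_accuracy,
    skill_accuracy,
    track_geometry,
)

# --- independent oracles: literal transcriptions of the four formulas -------


def skill_oracle(L, L_opt, err, err_max):
    err_factor = 1.0 if err_max == 0 else err_max / (err_max + err)
    return min(100.0, max(0.0, (1 - (L - L_opt) / L) * err_factor * 100.0))


def rule_oracle(turn, alt, w):
    return (sum(turn) + sum(wi * ai for wi, ai in zip(w, alt))) / 14 * 100


def k1_oracle(t_opt, t_cir, t_ev):
    return t_opt / (t_cir + t_ev) * 100


def k2_oracle(n_att, t_used, t_av=1200.0):
    return (1 / n_att) * 50 + (t_av - t_used) / t_av * 50


def test_formulas_match_oracles_on_random_inputs(rng):
    """All four accuracy formulas agree with literal transcriptions to 1e-9."""
    for _ in range(1000):
        l_opt = rng.uniform(1, 100)
        L = l_opt * rng.uniform(1.0, 2.0)
        err_max = rng.uniform(0.001, 10)
        err = err_max * rng.uniform(0, 1)
        assert skill_accuracy(L, l_opt, err, err_max) == pytest.approx(
            skill_oracle(L, l_opt, err, err_max), rel=1e-9)

        turn = tuple(rng.integers(0, 2, 7))
        alt = tuple(rng.integers(0, 2, 7))
        w = tuple(rng.uniform(0.01, 1.0, 7))
        log = RuleLog(turn_outcomes=turn, alt_outcomes=alt, alt_weights=w)
        assert rule_accuracy(log) == pytest.approx(rule_oracle(turn, alt, w),
                                                   rel=1e-9)

        t_opt = rng.uniform(1, 300)
        t_cir = t_opt * rng.uniform(1, 3)
        t_ev = rng.uniform(0, 300)
        k1 = KnowledgeLog(variant="K1", t_opt=t_opt, t_cir=t_cir, t_ev=t_ev)
        assert knowledge1_accuracy(k1) == pytest.approx(
            k1_oracle(t_opt, t_cir, t_ev), rel=1e-9)

        n_att = int(rng.integers(1, 20))
        t_used = rng.uniform(0, 1200)
        k2 = KnowledgeLog(variant="K2", n_att=n_att, t_used=t_used)
        assert knowledge2_accuracy(k2) == pytest.approx(
            k2_oracle(n_att, t_used), rel=1e-9)


@pytest.mark.parametrize(
    "args, expected",
    [
        ((10.0, 10.0, 0.0, 0.0), 100.0),                # perfect run
        ((12.0, 10.0, 2.0, 4.0), (1 - 2 / 12) * (4 / 6) * 100),
    ],
)
def test_skill_accuracy_hand_cases(args, expected):
    assert skill_accuracy(*args) == pytest.approx(expected)


def test_skill_error_factor_halves_when_err_equals_errmax():
    full = skill_accuracy(12.0, 10.0, 0.0, 4.0)
    half = skill_accuracy(12.0, 10.0, 4.0, 4.0)
    assert half == pytest.approx(full / 2)


def test_skill_accuracy_rejects_invalid_domain():
    with pytest.raises(ValueError):
        skill_accuracy(9.0, 10.0, 0.0, 0.0)     # L < Lopt
    with pytest.raises(ValueError):
        skill_accuracy(10.0, 10.0, 5.0, 2.0)    # err > errMAX


@pytest.mark.parametrize(
    "turn, alt, w, expected",
    [
        ((1,) * 7, (1,) * 7, (1.0,) * 7, 100.0),
        ((1,) * 7, (0,) * 7, (1.0,) * 7, 50.0),
        ((0,) * 7, (1,) * 7, (0.5,) * 7, 25.0),
    ],
)
def test_rule_accuracy_cases(turn, alt, w, expected):
    assert rule_accuracy(RuleLog(turn, alt, w)) == pytest.approx(expected)


def test_rule_log_slot_counts_enforced():
    with pytest.raises(MalformedLogError):
        RuleLog((1,) * 6, (1,) * 7)


@pytest.mark.parametrize(
    "t_opt, t_cir, t_ev, expected",
    [(60.0, 60.0, 0.0, 100.0), (60.0, 90.0, 30.0, 50.0)],
)
def test_knowledge1_cases(t_opt, t_cir, t_ev, expected):
    log = KnowledgeLog(variant="K1", t_opt=t_opt, t_cir=t_cir, t_ev=t_ev)
    assert knowledge1_accuracy(log) == pytest.approx(expected)


def test_knowledge1_monotone_in_event_time():
    scores = [knowledge1_accuracy(KnowledgeLog(variant="K1", t_opt=60,
                                               t_cir=90, t_ev=tev))
              for tev in (0, 10, 50, 200)]
    assert all(a > b for a, b in zip(scores, scores[1:]))


@pytest.mark.parametrize(
    "n_att, t_used, expected",
    [(1, 0.0, 100.0), (2, 600.0, 50.0)],
)
def test_knowledge2_cases(n_att, t_used, expected):
    log = KnowledgeLog(variant="K2", n_att=n_att, t_used=t_used)
    assert knowledge2_accuracy(log) == pytest.approx(expected)


def test_knowledge2_positive_for_finite_attempts_at_full_time():
    assert knowledge2_accuracy(KnowledgeLog(variant="K2", n_att=50,
                                            t_used=1200.0)) > 0


@given(
    l_ratio=st.floats(1.0, 3.0),
    err_frac=st.floats(0.0, 1.0),
    err_max=st.floats(0.01, 50.0),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_skill_accuracy_bounded_and_monotone_in_error(l_ratio, err_frac, err_max):
    """Score lies in [0, 100] and does not increase with the mean error."""
    L, l_opt = 10.0 * l_ratio, 10.0
    err = err_frac * err_max
    s = skill_accuracy(L, l_opt, err, err_max)
    assert 0.0 <= s <= 100.0
    assert s <= skill_accuracy(L, l_opt, 0.0, err_max) + 1e-12


# --- track geometry ---------------------------------------------------------


def test_track_geometry_identity_path():
    track = np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 3.0]])
    t = np.arange(3)
    log = TrackLog(np.column_stack([t, track]), track, completion_time=30.0)
    L, l_opt, err, err_max = track_geometry(log)
    assert L == pytest.approx(l_opt)
    assert err == pytest.approx(0.0)
    assert err_max == pytest.approx(0.0)


def test_track_geometry_offset_line():
    track = np.array([[0.0, 0.0], [10.0, 0.0]])
    cursor = np.array([[0.0, 0.0, 1.0], [1.0, 10.0, 1.0]])
    L, l_opt, err, err_max = track_geometry(
        TrackLog(cursor, track, completion_time=10.0))
    assert (L, l_opt) == (pytest.approx(10.0), pytest.approx(10.0))
    assert err == pytest.approx(1.0)
    assert err_max == pytest.approx(1.0)


def test_track_length_invariant_under_reversal():
    rng = np.random.default_rng(0)
    xy = rng.uniform(0, 10, (20, 2))
    track = np.array([[0.0, 0.0], [10.0, 10.0]])
    fwd = TrackLog(np.column_stack([np.arange(20), xy]), track, 10.0)
    rev = TrackLog(np.column_stack([np.arange(20), xy[::-1]]), track, 10.0)
    assert track_geometry(fwd)[0] == pytest.approx(track_geometry(rev)[0])


def test_track_log_requires_two_samples():
    with pytest.raises(MalformedLogError):
        TrackLog(np.array([[0.0, 1.0, 1.0]]), np.array([[0, 0], [1, 1]]), 1.0)


# --- aggregation ------------------------------------------------------------


def test_aggregate_scores_level_means():
    scores = {"S1": 80.0, "S2": 100.0, "R1": 70.0, "R2": 70.0,
              "K1": 40.0, "K2": 60.0}
    times = {"S1": 100.0, "S2": 120.0, "R1": 100.0, "R2": 100.0,
             "K1": 300.0, "K2": 500.0}
    result = aggregate_scores(scores, times)
    assert result.level_scores == {"S": 90.0, "R": 70.0, "K": 50.0}
    assert result.level_times["K"] == pytest.approx(400.0)


def test_aggregate_scores_missing_repetition():
    with pytest.raises(ValueError, match="S"):
        aggregate_scores({"S1": 80.0}, {"S1": 100.0})


def test_questionnaire_average():
    items = {c: [2.0, 4.0] for c in ("S1", "S2", "R1", "R2", "K1", "K2")}
    assert questionnaire_average(items) == {"S": 3.0, "R": 3.0, "K": 3.0}
    items["K1"] = [4.0, 2.0]        # permutation leaves the mean unchanged
    assert questionnaire_average(items)["K"] == pytest.approx(3.0)
    with pytest.raises(ValueError):
        questionnaire_average({**items, "S1": [1.0, 2.0, 3.0]})


# --- Cohen's d --------------------------------------------------------------


def test_cohens_d_hand_value_and_antisymmetry():
    a, b = [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]
    assert cohens_d(a, b) == pytest.approx(-2.0)
    assert cohens_d(b, a) == pytest.approx(2.0)
    assert cohens_d(a, a) == pytest.approx(0.0)


def test_cohens_d_degenerate():
    with pytest.raises(ValueError):
        cohens_d([1.0, 1.0], [1.0, 1.0])


# --- behavioural simulator scoring -----------------------------------------


def test_perfect_behaviour_parameters_score_100_at_every_level():
    from srk.behavior import score_log
    from srk.simulate import BehaviourParams, CONDITIONS, SimulationConfig, simulate_behavior

    cfg = SimulationConfig(
        seed=0,
        behaviour=BehaviourParams(tracking_jitter=0.0, rule_success_p=1.0,
                                  k1_t_extra=0.0, k1_t_event=0.0,
                                  k2_n_att=1, k2_t_used=0.0),
    )
    for cond in CONDITIONS:
        assert score_log(simulate_behavior(cfg, cond)) == pytest.approx(100.0)
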
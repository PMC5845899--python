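"""Reliability, rank correlations, morph effects, and group summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from polystream import (
    TrialRecord, TruthParams, classify_record, exp1_default_truth,
    group_summary, morph_effect, simulate_cohort, spearman,
    split_half_reliability,
)
from polystream.stats import subject_scores


def _trial(subject, idx, version, response, attention="bassoon", timbre=None,
           experiment="exp1"):
    return classify_record(TrialRecord(
        subject_id=subject, experiment=experiment, group="NA", run_index=1,
        block_index=1, trial_index=idx, composition_id="comp01",
        triplet_version=version, attention=attention, timbre_level=timbre,
        response=response))


# ---------------------------------------------------------------------------
# split-half reliability

def test_duplicated_halves_give_perfect_reliability():
    # consecutive identical trial pairs make the odd/even halves equal
    trials = []
    patterns = {"s1": ("present", "present"), "s2": ("present", "absent"),
                "s3": ("absent", "absent")}
    for subject, (target_resp, lure_resp) in patterns.items():
        idx = itertools.count(1)
        for _ in range(8):
            for resp, version in ((target_resp, "upper"), (lure_resp, "none")):
                trials.append(_trial(subject, next(idx), version, resp))
                trials.append(_trial(subject, next(idx), version, resp))
    r, _p = split_half_reliability(trials, seed=0, n_permutations=99)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_reliability_bounded_and_order_invariant(exp2_cohort):
    _, trials, _ = exp2_cohort
    r, p = split_half_reliability(trials, seed=1, n_permutations=199)
    assert -1.0 <= r <= 1.0 and 0.0 < p <= 1.0
    shuffled = list(trials)
    np.random.default_rng(0).shuffle(shuffled)
    r2, _ = split_half_reliability(shuffled, seed=1, n_permutations=199)
    assert r2 == pytest.approx(r, abs=1e-12)


def test_high_subject_spread_yields_high_reliability():
    """A cohort with large true between-subject d' spread reproduces the
    high split-half correlation regime of the full experiment."""
    rs = []
    for rep in range(30):
        truth = exp1_default_truth(
            n_subjects=29, seed=500 + rep, grand_mean_dprime=2.5,
            subject_sd=1.5, residual_sd_per_attention=(0.3, 0.3, 0.3))
        trials, _ = simulate_cohort(truth)
        r, _ = split_half_reliability(trials, seed=rep, n_permutations=1)
        rs.append(r)
    assert np.median(rs) > 0.7


def test_no_subject_variance_gives_null_reliability():
    rs = []
    for rep in range(30):
        truth = exp1_default_truth(
            n_subjects=20, seed=900 + rep, grand_mean_dprime=2.0,
            subject_sd=0.0, residual_sd_per_attention=(0.0, 0.0, 0.0))
        trials, _ = simulate_cohort(truth)
        r, _ = split_half_reliability(trials, seed=rep, n_permutations=1)
        rs.append(r)
    assert abs(np.mean(rs)) < 0.15


def test_empty_half_raises():
    trials = [_trial("s1", 1, "upper", "present"),
              _trial("s2", 1, "upper", "present"),
              _trial("s2", 2, "none", "absent")]
    with pytest.raises(ValueError):
        split_half_reliability(trials)


# ---------------------------------------------------------------------------
# Spearman correlation

def test_spearman_monotone_extremes():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    rho, p = spearman(x, [2.0, 4.0, 6.0, 8.0, 10.0])
    assert rho == pytest.approx(1.0)
    rho, _ = spearman(x, [10.0, 8.0, 6.0, 4.0, 2.0])
    assert rho == pytest.approx(-1.0)


def test_spearman_exact_p_matches_enumeration_oracle():
    # tied data at n=6, checked against a naive all-permutations oracle
    x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
    y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0]
    rho, p = spearman(x, y)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho_oracle = np.corrcoef(rx, ry)[0, 1]
    assert rho == pytest.approx(rho_oracle, abs=1e-12)
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(rho_oracle) - 1e-12:
            hits += 1
    assert p == pytest.approx(hits / total, abs=1e-12)


def test_spearman_large_n_uses_t_approximation():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=30), rng.normal(size=30)
    rho, p = spearman(x, y)
    rho_ref, p_ref = sps.spearmanr(x, y)
    assert (rho, p) == (pytest.approx(rho_ref), pytest.approx(p_ref))


def test_spearman_input_validation():
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# morph effect

def _exp2_trials(subject, n_correct_max, n_correct_min, n=10):
    trials = []
    idx = itertools.count(1)
    for timbre, n_correct in (("maximum", n_correct_max), ("minimum", n_correct_min)):
        for i in range(n):
            resp = "present" if i < n_correct else "absent"  # targets only
            trials.append(_trial(subject, next(idx), "upper", resp,
                                 timbre=timbre, experiment="exp2"))
    return trials


def test_morph_effect_examples():
    trials = _exp2_trials("s1", 10, 8) + _exp2_trials("s2", 7, 7)
    effects = morph_effect(trials)
    assert effects["s1"] == pytest.approx(0.2)
    assert effects["s2"] == pytest.approx(0.0)


def test_morph_effect_requires_both_levels():
    trials = [_trial("s1", 1, "upper", "present", timbre="maximum",
                     experiment="exp2")]
    with pytest.raises(ValueError):
        morph_effect(trials)


def test_morph_effect_centered_without_timbre_effect():
    truth = TruthParams(n_subjects=19, seed=31, timbre_effects=(0.0, 0.0, 0.0))
    trials, _ = simulate_cohort(truth, group="LAB")
    effects = morph_effect(trials)
    assert abs(np.mean(list(effects.values()))) < 0.05


def test_low_performers_show_larger_morph_effects():
    """When the minimum-timbre deficit hits only low-sensitivity subjects,
    error rate and morph effect correlate positively across subjects."""
    from polystream.simulate import SubjectTruth, simulate_trials
    from polystream.design import exp2_schedule
    from polystream.sdt import ATTENTION_LEVELS, TIMBRE_LEVELS

    trials = []
    for s in range(12):
        low = s < 6
        base = 1.8 if low else 4.5
        dprime = {}
        for att in ATTENTION_LEVELS:
            for timb in TIMBRE_LEVELS:
                d = base
                if low and timb == "minimum":
                    d -= 1.5
                dprime[(att, timb)] = d
        subject = SubjectTruth(f"s{s:02d}", dprime,
                               {k: 0.0 for k in dprime})
        sched = exp2_schedule(s, "LAB", seed=600 + s)
        trials.extend(simulate_trials(subject, sched, seed=700 + s))
    effects = morph_effect(trials)
    scores = subject_scores(trials)
    error_rates = [1 - s.correct_rate for s in scores]
    ordered_effects = [effects[s.subject_id] for s in scores]
    rho, _ = spearman(error_rates, ordered_effects)
    assert rho > 0


# ---------------------------------------------------------------------------
# group summaries

def test_group_summary_examples():
    med, (q25, q75) = group_summary([0.8, 0.9, 1.0])
    assert med == pytest.approx(0.9)
    med, (q25, q75) = group_summary([0.7] * 5)
    assert (q25, q75) == (0.7, 0.7)


def test_group_summary_quartiles_of_uniform_sample():
    # quartile estimates at n=100 concentrate on 0.25/0.75 across replicates
    rng = np.random.default_rng(4)
    lows, highs = [], []
    for _ in range(50):
        _, (q25, q75) = group_summary(rng.uniform(0, 1, 100))
        lows.append(q25)
        highs.append(q75)
    assert np.mean(lows) == pytest.approx(0.25, abs=0.05)
    assert np.mean(highs) == pytest.approx(0.75, abs=0.05)


def test_group_summary_rejects_empty():
    with pytest.raises(ValueError):
        group_summary([])
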
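"""Synthetic subjects: the generative twin of the behavioral experiments.

No human data ship with this package; instead, cohorts are simulated from
the same ANOVA-like structure the hierarchical model assumes.  Each
subject's true sensitivity in a condition cell is

    d'_cell = b0 + b_att + b_timb + b_att*timb + b_subj + eps,
    eps ~ N(0, sigma_att^2)

with a mirrored structure for the response criterion (bias).  Given the
true cell parameters, every trial is an independent Bernoulli draw under
the equal-variance SDT observer:

    P(respond present | target)     = PHI(0.5 * d' - bias)
    P(respond present | non-target) = PHI(-0.5 * d' - bias)

Default truth values place the cohort in the regime the experiments
reported: experiment-2 grand mean 4.7 with a minimum-timbre deficit of
-0.7 (and +0.35 on the other two levels so main effects sum to zero),
experiment-1 grand mean 3.45, biases centered on zero.  Rating sessions are
simulated from the perceptual sigmoid plus Gaussian noise, rounded to the
integer 1-5 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import sdt
from .design import RatingStub, Schedule, TrialStub, exp1_schedule, exp2_schedule
from .psychometric import sigmoid_value
from .sdt import ATTENTION_LEVELS, TIMBRE_LEVELS, TrialRecord, classify_record


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite, got {value}")


def _check_sum_zero(name: str, vec) -> None:
    if abs(float(np.sum(vec))) > 1e-8:
        raise ValueError(f"{name} must sum to zero (got sum {np.sum(vec):g})")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generative parameters for a simulated cohort.

    Effect vectors follow the level orders of :data:`ATTENTION_LEVELS` and
    :data:`TIMBRE_LEVELS`; each main-effect vector, and each row/column of
    the interaction matrix, sums to zero so the ground truth is identified.
    For experiment 1, set ``timbre_effects``/``interaction_effects`` (and the
    bias counterparts) to ``None``.
    """

    experiment: str = "exp2"
    n_subjects: int = 19
    seed: int = 0
    grand_mean_dprime: float = 4.7
    attention_effects: tuple = (0.0, 0.0, 0.0)
    timbre_effects: tuple | None = (0.35, 0.35, -0.7)
    interaction_effects: tuple | None = ((0.0,) * 3,) * 3
    subject_sd: float = 0.8
    residual_sd_per_attention: tuple = (0.5, 0.5, 0.5)
    grand_mean_bias: float = 0.0
    attention_effects_bias: tuple = (0.0, 0.0, 0.0)
    timbre_effects_bias: tuple | None = (0.0, 0.0, 0.0)
    interaction_effects_bias: tuple | None = ((0.0,) * 3,) * 3
    subject_sd_bias: float = 0.3
    residual_sd_per_attention_bias: tuple = (0.3, 0.3, 0.3)

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError("experiment must be exp1 or exp2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("grand_mean_dprime", "grand_mean_bias", "subject_sd",
                     "subject_sd_bias"):
            _check_finite(name, getattr(self, name))
        if self.subject_sd < 0 or self.subject_sd_bias < 0:
            raise ValueError("subject sds must be >= 0")
        for name in ("attention_effects", "attention_effects_bias"):
            vec = np.asarray(getattr(self, name), float)
            _check_finite(name, vec)
            _check_sum_zero(name, vec)
        for name in ("residual_sd_per_attention", "residual_sd_per_attention_bias"):
            vec = np.asarray(getattr(self, name), float)
            _check_finite(name, vec)
            if np.any(vec < 0) or np.any(vec > 4):
                raise ValueError(f"{name} must lie in [0, 4]")
        if self.experiment == "exp2":
            for name in ("timbre_effects", "timbre_effects_bias"):
                vec = np.asarray(getattr(self, name), float)
                _check_finite(name, vec)
                _check_sum_zero(name, vec)
            for name in ("interaction_effects", "interaction_effects_bias"):
                mat = np.asarray(getattr(self, name), float)
                _check_finite(name, mat)
                if mat.shape != (3, 3):
                    raise ValueError(f"{name} must be 3x3")
                for i in range(3):
                    _check_sum_zero(f"{name} row {i}", mat[i])
                    _check_sum_zero(f"{name} col {i}", mat[:, i])
        elif self.timbre_effects is not None or self.interaction_effects is not None:
            raise ValueError("exp1 truth carries no timbre or interaction effects")

    def cell_mean(self, which: str, a: int, t: int | None, subj_offset: float) -> float:
        """Deterministic ANOVA mean of one cell ('dprime' or 'bias')."""
        if which == "dprime":
            mu = self.grand_mean_dprime + self.attention_effects[a]
            if self.experiment == "exp2":
                mu += self.timbre_effects[t] + self.interaction_effects[a][t]
        else:
            mu = self.grand_mean_bias + self.attention_effects_bias[a]
            if self.experiment == "exp2":
                mu += self.timbre_effects_bias[t] + self.interaction_effects_bias[a][t]
        return mu + subj_offset


def exp1_default_truth(n_subjects: int = 29, seed: int = 0, **overrides) -> TruthParams:
    """Experiment-1 cohort truth at the reported-regime defaults."""
    kwargs = dict(
        experiment="exp1", n_subjects=n_subjects, seed=seed,
        grand_mean_dprime=3.45, timbre_effects=None, interaction_effects=None,
        timbre_effects_bias=None, interaction_effects_bias=None,
    )
    kwargs.update(overrides)
    return TruthParams(**kwargs)


@dataclass(frozen=True)
class SubjectTruth:
    """True cell-level d' and bias for one simulated subject."""

    subject_id: str
    dprime: dict  # (attention, timbre_level|None) -> float
    bias: dict


@dataclass(frozen=True)
class RatingTruth:
    """Ground truth for a simulated timbre-rating session."""

    x50_upper: float = 0.5
    x50_lower: float = 0.5
    m_upper: float = 6.0
    m_lower: float = 6.0
    rating_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.x50_upper, self.x50_lower):
            if not 0.0 < v < 1.0:
                raise ValueError("true x50 must lie in (0, 1)")
        if min(self.m_upper, self.m_lower) <= 0:
            raise ValueError("true slopes must be positive")
        if self.rating_noise_sd < 0:
            raise ValueError("rating noise sd must be >= 0")

    def params(self, voice: str) -> tuple[float, float]:
        if voice == "upper":
            return self.x50_upper, self.m_upper
        if voice == "lower":
            return self.x50_lower, self.m_lower
        raise ValueError(f"unknown voice {voice!r}")


def simulate_subject_params(truth: TruthParams, seed: int | None = None) -> list[SubjectTruth]:
    """Draw per-subject, per-cell true d' and bias from the ANOVA structure."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    timbres = TIMBRE_LEVELS if truth.experiment == "exp2" else (None,)
    subjects = []
    offsets_d = rng.normal(0.0, truth.subject_sd, truth.n_subjects)
    offsets_b = rng.normal(0.0, truth.subject_sd_bias, truth.n_subjects)
    for s in range(truth.n_subjects):
        dprime, bias = {}, {}
        for a, att in enumerate(ATTENTION_LEVELS):
            for t, timbre in enumerate(timbres):
                ti = t if truth.experiment == "exp2" else None
                mu_d = truth.cell_mean("dprime", a, ti, offsets_d[s])
                mu_b = truth.cell_mean("bias", a, ti, offsets_b[s])
                dprime[(att, timbre)] = float(
                    rng.normal(mu_d, truth.residual_sd_per_attention[a])
                )
                bias[(att, timbre)] = float(
                    rng.normal(mu_b, truth.residual_sd_per_attention_bias[a])
                )
        subjects.append(SubjectTruth(f"sub{s + 1:02d}", dprime, bias))
    return subjects


def hit_probability(dprime: float, bias: float) -> float:
    """P(respond present | target) under the equal-variance SDT observer."""
    return float(norm.cdf(0.5 * dprime - bias))


def fa_probability(dprime: float, bias: float) -> float:
    """P(respond present | non-target)."""
    return float(norm.cdf(-0.5 * dprime - bias))


def simulate_trials(subject: SubjectTruth, schedule: Schedule, seed: int) -> list[TrialRecord]:
    """Simulate one subject's responses on a validated schedule.

    Every scheduled trial draws an independent present/absent response with
    the probit success probability of its cell, then is classified into
    hit/miss/fa/cr.  Raises ``KeyError`` naming the first cell of the
    schedule for which the subject truth carries no parameters.
    """
    rng = np.random.default_rng(seed)
    records = []
    for ri, run in enumerate(schedule.runs, 1):
        for bi, block in enumerate(run, 1):
            for ti, stub in enumerate(block.trials, 1):
                cell = (stub.attention, stub.timbre_level)
                if cell not in subject.dprime:
                    raise KeyError(
                        f"subject {subject.subject_id} has no truth for cell {cell}"
                    )
                d, b = subject.dprime[cell], subject.bias[cell]
                p = hit_probability(d, b) if stub.is_target else fa_probability(d, b)
                response = "present" if rng.random() < p else "absent"
                records.append(classify_record(TrialRecord(
                    subject_id=subject.subject_id,
                    experiment=schedule.experiment,
                    group=schedule.group,
                    run_index=ri,
                    block_index=bi,
                    trial_index=ti,
                    composition_id=stub.composition_id,
                    triplet_version=stub.triplet_version,
                    attention=stub.attention,
                    timbre_level=stub.timbre_level,
                    response=response,
                )))
    return records


def simulate_cohort(
    truth: TruthParams,
    group: str = "LAB",
    n_compositions: int = 16,
    seed: int | None = None,
) -> tuple[list[TrialRecord], list[SubjectTruth]]:
    """Simulate a full cohort: schedules, subject truths, and all responses.

    Each participant receives their own counterbalanced schedule
    (participant_index = subject number) and an independent response stream;
    all randomness descends from a single seed.
    """
    root = np.random.SeedSequence(truth.seed if seed is None else seed)
    param_seed, *child = root.spawn(1 + 2 * truth.n_subjects)
    subjects = simulate_subject_params(
        truth, seed=int(param_seed.generate_state(1)[0] % (2 ** 31))
    )
    trials: list[TrialRecord] = []
    for i, subject in enumerate(subjects):
        sched_seed = int(child[2 * i].generate_state(1)[0] % (2 ** 31))
        resp_seed = int(child[2 * i + 1].generate_state(1)[0] % (2 ** 31))
        if truth.experiment == "exp1":
            sched = exp1_schedule(i, n_compositions=n_compositions, seed=sched_seed)
        else:
            sched = exp2_schedule(i, group=group, seed=sched_seed)
        trials.extend(simulate_trials(subject, sched, resp_seed))
    return trials, subjects


def simulate_ratings(rating_truth: RatingTruth, schedule: Schedule,
                     seed: int | None = None, subject_id: str = "sub01") -> list[dict]:
    """Simulate integer 1-5 ratings for a timbre-rating schedule.

    rating = sigmoid(morph fraction) + Gaussian noise, rounded half-up to
    the nearest integer and clamped to [1, 5].
    """
    if schedule.experiment != "rating":
        raise ValueError("simulate_ratings requires a rating schedule")
    rng = np.random.default_rng(rating_truth.seed if seed is None else seed)
    records = []
    trial_no = 0
    for bi, block in enumerate(schedule.blocks, 1):
        for stub in block.trials:
            trial_no += 1
            x50, m = rating_truth.params(stub.voice)
            value = float(sigmoid_value(stub.morph_fraction, x50, m))
            if rating_truth.rating_noise_sd > 0:
                value += rng.normal(0.0, rating_truth.rating_noise_sd)
            rating = int(min(5, max(1, math.floor(value + 0.5))))
            records.append({
                "subject_id": subject_id,
                "block": bi,
                "trial": trial_no,
                "voice": stub.voice,
                "morph_fraction": stub.morph_fraction,
                "composition_id": stub.composition_id,
                "rating": rating,
            })
    return records
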
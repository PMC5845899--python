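"""Signal-detection core: trial classification and edge-corrected sensitivity.

Listeners attend to the bassoon, the cello, or the aggregate of both voices
and report whether a four-triplet rhythmic pattern was present in the
attended stream.  A trial is a *target* when the triplet pattern sits in the
attended voice(s): upper-voice triplets under attend-bassoon, lower-voice
triplets under attend-cello, and voice-crossing triplets under
attend-aggregate.  Everything else (no triplets, or triplets in the
unattended voice) is a non-target used to catch false alarms.

Because trained subjects often perform at or near ceiling, raw hit/false
alarm proportions of 0 or 1 would map to infinite d'.  Sensitivity is
therefore summarised with the edge-corrected estimator

    d'_ec = PHI^-1((H + 0.5) / (H + M + 1)) - PHI^-1((FA + 0.5) / (FA + CR + 1))

where PHI^-1 is the standard normal quantile function, which is finite for
every legal count configuration including perfect scores.  A parallel
criterion summary ``bias_ec`` (the SDT criterion c with the same count
correction) is provided for model initialisation and descriptive output.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from scipy.stats import norm

logger = logging.getLogger(__name__)

# Enumerations (plain string levels; kept as tuples for validation) ---------

ATTENTION_LEVELS = ("bassoon", "cello", "aggregate")
TRIPLET_VERSIONS = ("none", "upper", "lower", "crossing")
TIMBRE_LEVELS = ("maximum", "intermediate", "minimum")
RESPONSES = ("present", "absent", "missing")
OUTCOMES = ("hit", "miss", "fa", "cr", "invalid")
EXPERIMENTS = ("exp1", "exp2")
GROUPS = ("LAB", "SCAN", "NA")

#: triplet version that constitutes a target under each attention instruction
TARGET_VERSION = {"bassoon": "upper", "cello": "lower", "aggregate": "crossing"}


class DesignError(ValueError):
    """An (attention, triplet_version) combination the design does not allow."""


class IntegrityError(ValueError):
    """Duplicate or inconsistent trial-level records."""


class UndefinedCellError(ValueError):
    """A measurement cell with zero target or zero non-target trials."""


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial with its design labels, response and outcome.

    ``timbre_level`` is ``None`` for experiment 1 (no timbre manipulation)
    and one of :data:`TIMBRE_LEVELS` for experiment 2.
    """

    subject_id: str
    experiment: str
    group: str
    run_index: int
    block_index: int
    trial_index: int
    composition_id: str
    triplet_version: str
    attention: str
    timbre_level: str | None
    response: str
    outcome: str = "invalid"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.attention not in ATTENTION_LEVELS:
            raise ValueError(f"unknown attention level {self.attention!r}")
        if self.triplet_version not in TRIPLET_VERSIONS:
            raise ValueError(f"unknown triplet version {self.triplet_version!r}")
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.timbre_level is not None and self.timbre_level not in TIMBRE_LEVELS:
            raise ValueError(f"unknown timbre level {self.timbre_level!r}")
        if self.experiment == "exp1" and self.timbre_level is not None:
            raise ValueError("exp1 trials carry no timbre level")
        if self.experiment == "exp2" and self.timbre_level is None:
            raise ValueError("exp2 trials require a timbre level")
        if self.attention == "aggregate" and self.triplet_version in ("upper", "lower"):
            raise DesignError(
                "aggregate-attention trials only present crossing or absent triplets"
            )
        if min(self.run_index, self.block_index, self.trial_index) < 1:
            raise ValueError("run/block/trial indices are 1-based")


@dataclass(frozen=True)
class ResponseCounts:
    """Hit/miss/false-alarm/correct-rejection tallies for one cell."""

    n_hit: int = 0
    n_miss: int = 0
    n_fa: int = 0
    n_cr: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hit, self.n_miss, self.n_fa, self.n_cr) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_tri(self) -> int:
        """Number of target (triplet-present) trials."""
        return self.n_hit + self.n_miss

    @property
    def n_ntri(self) -> int:
        """Number of non-target trials."""
        return self.n_fa + self.n_cr

    @property
    def n_correct(self) -> int:
        return self.n_hit + self.n_cr

    @property
    def n_total(self) -> int:
        return self.n_tri + self.n_ntri

    def __add__(self, other: "ResponseCounts") -> "ResponseCounts":
        return ResponseCounts(
            self.n_hit + other.n_hit,
            self.n_miss + other.n_miss,
            self.n_fa + other.n_fa,
            self.n_cr + other.n_cr,
        )


@dataclass(frozen=True)
class MeasurementCell:
    """One subject x attention (x timbre) cell with counts and d' summaries."""

    subject_id: str
    attention: str
    timbre_level: str | None
    counts: ResponseCounts
    dprime_ec: float
    bias_ec: float


def classify_trial(attention: str, triplet_version: str, response: str) -> str:
    """Classify a single trial outcome.

    Returns one of ``hit``, ``miss``, ``fa``, ``cr``; a ``missing`` response
    yields ``invalid`` (excluded from counts downstream).  Raises
    :class:`DesignError` for aggregate attention paired with a single-voice
    triplet, which the experimental design never presents.
    """
    if attention not in ATTENTION_LEVELS:
        raise ValueError(f"unknown attention level {attention!r}")
    if triplet_version not in TRIPLET_VERSIONS:
        raise ValueError(f"unknown triplet version {triplet_version!r}")
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    if attention == "aggregate" and triplet_version in ("upper", "lower"):
        raise DesignError(
            "aggregate-attention trials only present crossing or absent triplets"
        )
    if response == "missing":
        return "invalid"
    is_target = TARGET_VERSION[attention] == triplet_version
    if is_target:
        return "hit" if response == "present" else "miss"
    return "fa" if response == "present" else "cr"


def classify_record(trial: TrialRecord) -> TrialRecord:
    """Return a copy of ``trial`` with its ``outcome`` field filled in."""
    outcome = classify_trial(trial.attention, trial.triplet_version, trial.response)
    return replace(trial, outcome=outcome)


def edge_corrected_dprime(counts: ResponseCounts) -> float:
    """Edge-corrected d': finite for every cell, including perfect scores."""
    if counts.n_tri < 1 or counts.n_ntri < 1:
        raise UndefinedCellError(
            f"d' undefined for n_tri={counts.n_tri}, n_ntri={counts.n_ntri}"
        )
    z_hit = norm.ppf((counts.n_hit + 0.5) / (counts.n_tri + 1))
    z_fa = norm.ppf((counts.n_fa + 0.5) / (counts.n_ntri + 1))
    return float(z_hit - z_fa)


def edge_corrected_bias(counts: ResponseCounts) -> float:
    """Edge-corrected criterion c = -(z_hit + z_fa)/2 with the same correction.

    Positive values indicate a conservative criterion (tendency to respond
    "absent"); zero for symmetric responding.
    """
    if counts.n_tri < 1 or counts.n_ntri < 1:
        raise UndefinedCellError(
            f"bias undefined for n_tri={counts.n_tri}, n_ntri={counts.n_ntri}"
        )
    z_hit = norm.ppf((counts.n_hit + 0.5) / (counts.n_tri + 1))
    z_fa = norm.ppf((counts.n_fa + 0.5) / (counts.n_ntri + 1))
    return float(-0.5 * (z_hit + z_fa))


def aggregate_counts(trials: Iterable[TrialRecord]) -> list[MeasurementCell]:
    """Aggregate classified trials into subject x condition measurement cells.

    Cells are keyed by (subject, attention) for experiment 1 and by
    (subject, attention, timbre) for experiment 2; a full exp2 session per
    subject yields 9 cells, a full exp1 session 3.  Trials with outcome
    ``invalid`` are excluded and logged per subject.  Duplicate
    (subject, run, block, trial) keys raise :class:`IntegrityError`.
    """
    trials = list(trials)
    seen: set[tuple] = set()
    invalid: Counter[str] = Counter()
    tallies: dict[tuple, Counter] = {}
    order: list[tuple] = []
    for t in trials:
        key = (t.subject_id, t.run_index, t.block_index, t.trial_index)
        if key in seen:
            raise IntegrityError(f"duplicate trial key {key}")
        seen.add(key)
        if t.outcome == "invalid":
            invalid[t.subject_id] += 1
            continue
        if t.outcome not in ("hit", "miss", "fa", "cr"):
            raise IntegrityError(f"unclassified trial {key}: outcome {t.outcome!r}")
        cell_key = (t.subject_id, t.attention, t.timbre_level)
        if cell_key not in tallies:
            tallies[cell_key] = Counter()
            order.append(cell_key)
        tallies[cell_key][t.outcome] += 1
    for subject, n in sorted(invalid.items()):
        logger.warning("subject %s: %d invalid (missing-response) trials excluded", subject, n)
    cells = []
    for cell_key in order:
        c = tallies[cell_key]
        counts = ResponseCounts(c["hit"], c["miss"], c["fa"], c["cr"])
        cells.append(
            MeasurementCell(
                subject_id=cell_key[0],
                attention=cell_key[1],
                timbre_level=cell_key[2],
                counts=counts,
                dprime_ec=edge_corrected_dprime(counts),
                bias_ec=edge_corrected_bias(counts),
            )
        )
    return cells
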
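"""Reliability and descriptive statistics for the behavioral data.

Covers split-half reliability of edge-corrected d', Spearman rank
correlations (exact permutation p-values at small n), the per-subject
morph-effect score (maximum-timbre accuracy minus minimum-timbre accuracy),
and median/IQR group summaries of correct rates.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .sdt import ResponseCounts, TrialRecord, edge_corrected_dprime

_OUTCOME_TO_COUNT = {"hit": (1, 0, 0, 0), "miss": (0, 1, 0, 0),
                     "fa": (0, 0, 1, 0), "cr": (0, 0, 0, 1)}


@dataclass(frozen=True)
class SubjectScore:
    subject_id: str
    scope: str  # all_trials | max_timbre_only | min_timbre_only
    correct_rate: float
    dprime_ec: float


def _counts_from(trials: Iterable[TrialRecord]) -> ResponseCounts:
    h = m = fa = cr = 0
    for t in trials:
        if t.outcome in _OUTCOME_TO_COUNT:
            dh, dm, dfa, dcr = _OUTCOME_TO_COUNT[t.outcome]
            h, m, fa, cr = h + dh, m + dm, fa + dfa, cr + dcr
    return ResponseCounts(h, m, fa, cr)


def subject_scores(trials: Sequence[TrialRecord], scope: str = "all_trials") -> list[SubjectScore]:
    """Per-subject correct rate and pooled edge-corrected d'.

    ``scope`` restricts exp2 trials to one timbre level
    (``max_timbre_only`` / ``min_timbre_only``) before scoring.
    """
    wanted = {"all_trials": None, "max_timbre_only": "maximum",
              "min_timbre_only": "minimum"}[scope]
    by_subject: dict[str, list[TrialRecord]] = defaultdict(list)
    for t in trials:
        if t.outcome == "invalid":
            continue
        if wanted is not None and t.timbre_level != wanted:
            continue
        by_subject[t.subject_id].append(t)
    scores = []
    for sid in sorted(by_subject):
        counts = _counts_from(by_subject[sid])
        scores.append(SubjectScore(
            subject_id=sid, scope=scope,
            correct_rate=counts.n_correct / counts.n_total,
            dprime_ec=edge_corrected_dprime(counts),
        ))
    return scores


def split_half_reliability(trials: Sequence[TrialRecord], seed: int = 0,
                           n_permutations: int = 999) -> tuple[float, float]:
    """Split-half reliability of pooled edge-corrected d' across subjects.

    Trials are split by odd/even serial position within each subject x
    condition cell; per half, counts are pooled across conditions and
    edge-corrected d' computed; the Pearson correlation across subjects is
    returned with a permutation p-value (``n_permutations`` shuffles of one
    half's subject assignment; one-sided for positive correlation).
    """
    cells: dict[tuple, list[TrialRecord]] = defaultdict(list)
    for t in trials:
        if t.outcome == "invalid":
            continue
        cells[(t.subject_id, t.attention, t.timbre_level)].append(t)
    halves: dict[str, list[list[TrialRecord]]] = defaultdict(lambda: [[], []])
    for (sid, _a, _ti), cell_trials in cells.items():
        ordered = sorted(cell_trials,
                         key=lambda t: (t.run_index, t.block_index, t.trial_index))
        for i, t in enumerate(ordered):
            halves[sid][i % 2].append(t)
    subjects = sorted(halves)
    d_first, d_second = [], []
    for sid in subjects:
        first, second = halves[sid]
        if not first or not second:
            raise ValueError(f"subject {sid}: empty split half")
        d_first.append(edge_corrected_dprime(_counts_from(first)))
        d_second.append(edge_corrected_dprime(_counts_from(second)))
    x, y = np.asarray(d_first), np.asarray(d_second)
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    exceed = 1
    for _ in range(n_permutations):
        r_perm = np.corrcoef(x, rng.permutation(y))[0, 1]
        exceed += r_perm >= r
    return r, exceed / (n_permutations + 1)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value is exact (full permutation enumeration) for
    n <= 9 and the t-approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p_approx = sps.spearmanr(x, y)
    rho = float(rho)
    if n > 9:
        return rho, float(p_approx)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt(np.sum(rx_c ** 2) * np.sum(ry_c ** 2))
    perms = np.array(list(itertools.permutations(ry_c)))
    rho_perm = perms @ rx_c / denom
    exceed = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, exceed / len(perms)


def morph_effect(trials: Sequence[TrialRecord]) -> dict[str, float]:
    """Per-subject accuracy difference: maximum-timbre minus minimum-timbre.

    A positive value means the subject suffered from reduced timbre
    distance.  Raises if a subject lacks either timbre level.
    """
    by_subject: dict[str, dict[str, list[TrialRecord]]] = defaultdict(
        lambda: {"maximum": [], "minimum": []})
    for t in trials:
        if t.outcome == "invalid" or t.timbre_level not in ("maximum", "minimum"):
            continue
        by_subject[t.subject_id][t.timbre_level].append(t)
    out = {}
    for sid in sorted(by_subject):
        levels = by_subject[sid]
        for lev in ("maximum", "minimum"):
            if not levels[lev]:
                raise ValueError(f"subject {sid}: no {lev}-timbre trials")
        rates = {}
        for lev in ("maximum", "minimum"):
            c = _counts_from(levels[lev])
            rates[lev] = c.n_correct / c.n_total
        out[sid] = rates["maximum"] - rates["minimum"]
    return out


def group_summary(scores: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Median and (25th, 75th) percentile bounds, linearly interpolated."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score vector")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q25), float(q75))
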
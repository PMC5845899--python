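"""Constrained session-schedule generation and validation.

Both experiments present 28-s polyphonic excerpts in attentive blocks
(attend bassoon / cello / aggregate) under a web of pseudo-randomisation
constraints; the timbre-rating session interleaves morph steps of the two
voices.  This module generates schedules that provably satisfy every
constraint (each generated schedule is re-checked by :func:`validate_schedule`
before being returned) and exposes the validator separately so imported
schedules can be audited.

Experiment 1: 6 blocks x 16 trials, each attention condition in exactly two
blocks.  Block trial mixes — aggregate: 8 crossing + 8 none; bassoon:
8 upper + 4 lower + 4 none; cello: 8 lower + 4 upper + 4 none (half targets,
a quarter opposite-voice controls, a quarter silent controls).  Within a
block no composition may repeat back-to-back or occur more than twice, the
same condition may not follow itself, and the two halves of the condition
sequence must be distinct permutations.  Condition order is balanced across
participants by rotating through the six base permutations, each paired with
its forward rotation (e.g. ACB-CBA), which satisfies the adjacency rule at
the half boundary.

Experiment 2: runs of three 5-trial attention blocks; 6 runs (LAB) or 9
(SCAN).  A run holds 15 trials = 5 compositions x 3 timbre distances, each
composition-timbre cell exactly once, with 8 target and 7 control trials.
Over one repetition (3 runs) every condition occupies every within-run
position and covers all 15 composition-timbre cells: per composition the
run x condition -> timbre assignment is a 3x3 Latin square, and the five
squares are chosen jointly so each block's timbre multiset is {2,2,1}
(every distance at least once, none more than twice).  Bassoon/cello
control trials alternate 3 none + 4 opposite-voice and 4 none + 3
opposite-voice across repetitions.

Rating session: 176 trials = 2 voices x 11 morph steps x 8 equal blocks;
voices strictly alternate, every voice x step appears once per block, and
the same composition never repeats back-to-back (compositions are dealt
round-robin from the five morphed pieces, which guarantees this).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sdt import ATTENTION_LEVELS, TARGET_VERSION, TIMBRE_LEVELS

MAX_PROPOSALS = 10_000  # retry cap for randomized constraint satisfaction

EXP1_COMPOSITIONS_FULL = tuple(f"comp{i:02d}" for i in range(1, 17))
EXP1_COMPOSITIONS_SUBSET = tuple(f"comp{i:02d}" for i in range(1, 11))
#: the five morphed compositions used in experiment 2 and the rating session
MORPH_COMPOSITIONS = ("comp01", "comp04", "comp05", "comp08", "comp10")

#: per-block (triplet-version -> count) mixes for experiment 1
EXP1_BLOCK_MIX = {
    "aggregate": {"crossing": 8, "none": 8},
    "bassoon": {"upper": 8, "lower": 4, "none": 4},
    "cello": {"lower": 8, "upper": 4, "none": 4},
}

_PERMS3 = tuple(itertools.permutations(ATTENTION_LEVELS))


class GenerationError(RuntimeError):
    """Constraint satisfaction failed within the proposal budget."""


@dataclass(frozen=True)
class TrialStub:
    """A scheduled trial before any response is collected."""

    composition_id: str
    triplet_version: str
    attention: str
    timbre_level: str | None = None
    crossing_start: str | None = None  # bassoon/cello; set for crossing triplets

    @property
    def is_target(self) -> bool:
        return TARGET_VERSION[self.attention] == self.triplet_version


@dataclass(frozen=True)
class RatingStub:
    """A scheduled timbre-rating trial."""

    voice: str  # upper (bassoon-origin) or lower (cello-origin)
    morph_step: int  # 0..10 in 10% increments toward the other instrument
    composition_id: str

    @property
    def morph_fraction(self) -> float:
        return self.morph_step / 10.0


@dataclass(frozen=True)
class Block:
    attention: str | None  # None for rating blocks
    trials: tuple


@dataclass(frozen=True)
class Violation:
    constraint: str
    location: str
    detail: str


@dataclass(frozen=True)
class Schedule:
    experiment: str  # exp1 | exp2 | rating
    group: str  # LAB | SCAN | NA
    participant_index: int
    seed: int
    runs: tuple  # tuple of runs; each run is a tuple of Block
    constraint_report: tuple = ()

    @property
    def blocks(self) -> list[Block]:
        return [b for run in self.runs for b in run]

    @property
    def trials(self) -> list:
        return [t for b in self.blocks for t in b.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


# --------------------------------------------------------------------------
# condition-order balancing


def exp1_condition_order(participant_index: int) -> tuple[str, ...]:
    """Six-block condition sequence: base permutation + its forward rotation.

    Rotating through the six base permutations by participant index places
    every condition equally often in every serial position across a full
    rotation of participants.
    """
    base = _PERMS3[participant_index % 6]
    second = (base[1], base[2], base[0])
    return base + second


def exp2_condition_orders(participant_index: int, n_reps: int) -> list[list[tuple[str, ...]]]:
    """Per-repetition, per-run condition orders (cyclic Latin squares).

    Within a repetition every condition occupies every within-run position
    (e.g. ABC-BCA-CAB); across repetitions the rows shift so block orders
    appear at all positions; across participants the base permutation rotates.
    """
    base = _PERMS3[participant_index % 6]
    rows = [tuple(base[(j + i) % 3] for j in range(3)) for i in range(3)]
    return [[rows[(i + k) % 3] for i in range(3)] for k in range(n_reps)]


# --------------------------------------------------------------------------
# experiment 1


def _arrange_no_adjacent(items: list, rng: np.random.Generator,
                         forbid_first=None, key=lambda x: x) -> list:
    """Random arrangement with no two adjacent equal keys (rejection + cap)."""
    items = list(items)
    for _ in range(MAX_PROPOSALS):
        rng.shuffle(items)
        if forbid_first is not None and key(items[0]) == forbid_first:
            continue
        if all(key(a) != key(b) for a, b in zip(items, items[1:])):
            return items
    raise GenerationError("no-adjacent-repeat arrangement not found within proposal budget")


def exp1_schedule(participant_index: int, n_compositions: int = 16, seed: int = 0) -> Schedule:
    """Generate a full experiment-1 session: 6 blocks x 16 trials, 96 total."""
    if n_compositions not in (10, 16):
        raise ValueError("n_compositions must be 10 or 16")
    comps = EXP1_COMPOSITIONS_FULL if n_compositions == 16 else EXP1_COMPOSITIONS_SUBSET
    rng = np.random.default_rng(seed)
    order = exp1_condition_order(participant_index)
    blocks = []
    for attention in order:
        mix = EXP1_BLOCK_MIX[attention]
        versions = [v for v, n in mix.items() for _ in range(n)]
        rng.shuffle(versions)
        if n_compositions == 16:
            block_comps = list(comps)
        else:
            # 16 trials from 10 pieces: six appear twice, four once
            doubled = rng.choice(len(comps), size=6, replace=False)
            block_comps = list(comps) + [comps[i] for i in doubled]
        block_comps = _arrange_no_adjacent(block_comps, rng)
        trials = tuple(
            TrialStub(
                composition_id=c,
                triplet_version=v,
                attention=attention,
                crossing_start=("bassoon", "cello")[rng.integers(2)] if v == "crossing" else None,
            )
            for c, v in zip(block_comps, versions)
        )
        blocks.append(Block(attention=attention, trials=trials))
    # one run of six blocks (exp1 has no run structure beyond the session)
    sched = Schedule(
        experiment="exp1", group="NA", participant_index=participant_index,
        seed=seed, runs=(tuple(blocks),),
    )
    return _finalize(sched)


# --------------------------------------------------------------------------
# experiment 2

_LATIN3 = []  # all 12 Latin squares of order 3 over timbre levels
for _first in itertools.permutations(range(3)):
    for _second in itertools.permutations(range(3)):
        if all(a != b for a, b in zip(_first, _second)):
            _third = tuple(3 - a - b for a, b in zip(_first, _second))
            _LATIN3.append((_first, _second, _third))
_LATIN3 = tuple(_LATIN3)


def _pick_latin_squares(rng: np.random.Generator) -> list[tuple]:
    """Five Latin squares (one per composition) with per-cell timbre counts <= 2.

    Rows index runs within a repetition, columns index conditions, symbols are
    timbre levels; the joint cap makes every block's timbre multiset {2,2,1}.
    """
    for _ in range(MAX_PROPOSALS):
        chosen: list[tuple] = []
        counts = np.zeros((3, 3, 3), dtype=int)  # run x cond x timbre
        ok = True
        for _comp in range(5):
            candidates = list(_LATIN3)
            rng.shuffle(candidates)
            placed = False
            for sq in candidates:
                trial_counts = counts.copy()
                for r in range(3):
                    for c in range(3):
                        trial_counts[r, c, sq[r][c]] += 1
                if trial_counts.max() <= 2:
                    counts = trial_counts
                    chosen.append(sq)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return chosen
    raise GenerationError("joint Latin-square selection failed within proposal budget")


def _target_matrix(rng: np.random.Generator) -> np.ndarray:
    """3x3 per-block target counts: entries {2,3}, rows and columns sum to 8."""
    sigma = rng.permutation(3)
    mat = np.full((3, 3), 3, dtype=int)
    for r in range(3):
        mat[r, sigma[r]] = 2
    return mat


def _allocate_targets(squares, tmat, rng: np.random.Generator) -> dict:
    """Choose which compositions carry targets in each block of a repetition.

    Per (run, condition) block the target count is fixed by ``tmat``; across
    the repetition every condition must present at least one target and one
    control at every timbre distance, so that each subject x condition x
    timbre cell supports a binomial hit and false-alarm model.  Randomized
    rejection within the proposal budget.
    """
    out = {}
    for ci in range(3):
        for _ in range(MAX_PROPOSALS):
            per_timbre_target = np.zeros(3, dtype=int)
            candidate = {}
            for r in range(3):
                chosen = rng.choice(5, size=int(tmat[r, ci]), replace=False)
                candidate[(r, ci)] = chosen
                for i in chosen:
                    per_timbre_target[squares[i][r][ci]] += 1
            # each timbre: >= 1 target and >= 1 control out of its 5 trials
            if np.all(per_timbre_target >= 1) and np.all(per_timbre_target <= 4):
                out.update(candidate)
                break
        else:
            raise GenerationError(
                "per-timbre target allocation failed within proposal budget"
            )
    return out


def exp2_schedule(participant_index: int, group: str = "LAB", seed: int = 0) -> Schedule:
    """Generate an experiment-2 session: 90 (LAB) or 135 (SCAN) trials."""
    if group not in ("LAB", "SCAN"):
        raise ValueError("group must be LAB or SCAN")
    n_reps = 2 if group == "LAB" else 3
    rng = np.random.default_rng(seed)
    cond_orders = exp2_condition_orders(participant_index, n_reps)
    opposite = {"bassoon": "lower", "cello": "upper"}
    runs = []
    for rep in range(n_reps):
        squares = _pick_latin_squares(rng)  # squares[comp][run][cond_idx] -> timbre idx
        tmat = _target_matrix(rng)  # targets per (run, cond_idx)
        target_sets = _allocate_targets(squares, tmat, rng)
        # repetition-level control pools for the single-voice conditions;
        # the none/opposite split alternates 3+4 / 4+3 across repetitions
        n_none = 3 if rep % 2 == 0 else 4
        pools = {}
        for cond in ("bassoon", "cello"):
            pool = ["none"] * n_none + [opposite[cond]] * (7 - n_none)
            rng.shuffle(pool)
            pools[cond] = pool
        pools["aggregate"] = ["none"] * 7
        pool_pos = {c: 0 for c in ATTENTION_LEVELS}
        for run_in_rep in range(3):
            blocks = []
            prev_last_comp = None
            for cond in cond_orders[rep][run_in_rep]:
                ci = ATTENTION_LEVELS.index(cond)
                n_target = int(tmat[run_in_rep, ci])
                # draw this block's control versions from the repetition pool
                n_ctrl = 5 - n_target
                ctrl_versions = pools[cond][pool_pos[cond]:pool_pos[cond] + n_ctrl]
                pool_pos[cond] += n_ctrl
                target_comps = target_sets[(run_in_rep, ci)]
                versions = {}
                k = 0
                for i in range(5):
                    if i in target_comps:
                        versions[i] = TARGET_VERSION[cond]
                    else:
                        versions[i] = ctrl_versions[k]
                        k += 1
                timbre_of = {
                    i: TIMBRE_LEVELS[squares[i][run_in_rep][ci]] for i in range(5)
                }
                order = _order_block(timbre_of, prev_last_comp, rng)
                trials = tuple(
                    TrialStub(
                        composition_id=MORPH_COMPOSITIONS[i],
                        triplet_version=versions[i],
                        attention=cond,
                        timbre_level=timbre_of[i],
                        crossing_start=(
                            ("bassoon", "cello")[rng.integers(2)]
                            if versions[i] == "crossing" else None
                        ),
                    )
                    for i in order
                )
                blocks.append(Block(attention=cond, trials=trials))
                prev_last_comp = order[-1]
            runs.append(tuple(blocks))
    sched = Schedule(
        experiment="exp2", group=group, participant_index=participant_index,
        seed=seed, runs=tuple(runs),
    )
    return _finalize(sched)


def _order_block(timbre_of: dict[int, str], prev_last_comp: int | None,
                 rng: np.random.Generator) -> list[int]:
    """Order the 5 compositions of a block: no adjacent equal timbre and the
    first composition differing from the previous block's last."""
    perms = list(itertools.permutations(range(5)))
    rng.shuffle(perms)
    for p in perms:
        if prev_last_comp is not None and p[0] == prev_last_comp:
            continue
        if all(timbre_of[a] != timbre_of[b] for a, b in zip(p, p[1:])):
            return list(p)
    raise GenerationError("block ordering constraints unsatisfiable for this draw")


# --------------------------------------------------------------------------
# rating session


def rating_schedule(seed: int = 0) -> Schedule:
    """Timbre-rating session: 8 blocks x 22 trials (2 voices x 11 morph steps).

    Voices strictly alternate throughout (the only way two voices never
    follow themselves), each voice x morph step occurs once per block, and
    compositions are dealt round-robin from the five morphed pieces so the
    same piece never repeats back-to-back.
    """
    rng = np.random.default_rng(seed)
    voices = ("upper", "lower")
    start = int(rng.integers(2))
    comp_cycle = itertools.cycle(MORPH_COMPOSITIONS)
    blocks = []
    global_pos = 0
    for _b in range(8):
        steps = {v: list(rng.permutation(11)) for v in voices}
        trials = []
        for t in range(22):
            v = voices[(start + global_pos) % 2]
            trials.append(
                RatingStub(voice=v, morph_step=int(steps[v].pop()),
                           composition_id=next(comp_cycle))
            )
            global_pos += 1
        blocks.append(Block(attention=None, trials=tuple(trials)))
    sched = Schedule(experiment="rating", group="NA", participant_index=0,
                     seed=seed, runs=(tuple(blocks),))
    return _finalize(sched)


# --------------------------------------------------------------------------
# validation


def _finalize(sched: Schedule) -> Schedule:
    violations = validate_schedule(sched)
    if violations:
        raise GenerationError(
            f"generated schedule violates its own constraints: {violations[0]}"
        )
    report = tuple(sorted({v.constraint for v in violations}) or ["all-constraints:pass"])
    return Schedule(sched.experiment, sched.group, sched.participant_index,
                    sched.seed, sched.runs, constraint_report=report)


def validate_schedule(schedule: Schedule) -> list[Violation]:
    """Check every design constraint; returns an empty list iff all hold."""
    if schedule.experiment == "exp1":
        return _validate_exp1(schedule)
    if schedule.experiment == "exp2":
        return _validate_exp2(schedule)
    if schedule.experiment == "rating":
        return _validate_rating(schedule)
    return [Violation("experiment", "schedule", f"unknown experiment {schedule.experiment!r}")]


def _validate_exp1(s: Schedule) -> list[Violation]:
    v: list[Violation] = []
    blocks = s.blocks
    if len(blocks) != 6:
        v.append(Violation("block-count", "session", f"expected 6 blocks, got {len(blocks)}"))
        return v
    order = [b.attention for b in blocks]
    for half, name in ((order[:3], "first"), (order[3:], "second")):
        if sorted(half) != sorted(ATTENTION_LEVELS):
            v.append(Violation("condition-triple", f"{name} half",
                               f"{half} is not a permutation of the three conditions"))
    for i, (a, b) in enumerate(zip(order, order[1:])):
        if a == b:
            v.append(Violation("condition-adjacent", f"blocks {i+1}-{i+2}",
                               f"{a} follows itself"))
    if tuple(order[:3]) == tuple(order[3:]):
        v.append(Violation("order-halves-unique", "session",
                           f"both halves ordered {order[:3]}"))
    for bi, block in enumerate(blocks, 1):
        if len(block.trials) != 16:
            v.append(Violation("block-length", f"block {bi}",
                               f"{len(block.trials)} trials, expected 16"))
            continue
        mix = EXP1_BLOCK_MIX[block.attention]
        from collections import Counter
        got = Counter(t.triplet_version for t in block.trials)
        if dict(got) != mix:
            v.append(Violation("block-trial-mix", f"block {bi}",
                               f"{dict(got)} != {mix}"))
        comps = [t.composition_id for t in block.trials]
        for i, (a, b) in enumerate(zip(comps, comps[1:])):
            if a == b:
                v.append(Violation("composition-adjacent", f"block {bi} trials {i+1}-{i+2}", a))
        for c, n in Counter(comps).items():
            if n > 2:
                v.append(Violation("composition-repeated-more-than-once",
                                   f"block {bi}", f"{c} occurs {n} times"))
    return v


def _validate_exp2(s: Schedule) -> list[Violation]:
    from collections import Counter

    v: list[Violation] = []
    n_runs_expected = 6 if s.group == "LAB" else 9
    if len(s.runs) != n_runs_expected:
        v.append(Violation("run-count", "session",
                           f"{len(s.runs)} runs, expected {n_runs_expected}"))
        return v
    opposite = {"bassoon": "lower", "cello": "upper"}
    for ri, run in enumerate(s.runs, 1):
        if len(run) != 3:
            v.append(Violation("blocks-per-run", f"run {ri}", f"{len(run)} blocks"))
            continue
        run_trials = [t for b in run for t in b.trials]
        n_target = sum(t.is_target for t in run_trials)
        if n_target != 8:
            v.append(Violation("targets-per-run", f"run {ri}", f"{n_target} targets, expected 8"))
        if len(run_trials) - n_target != 7:
            v.append(Violation("controls-per-run", f"run {ri}",
                               f"{len(run_trials) - n_target} controls, expected 7"))
        stim = Counter((t.composition_id, t.timbre_level) for t in run_trials)
        for key, n in stim.items():
            if n > 1:
                v.append(Violation("stimulus-unique-in-run", f"run {ri}",
                                   f"{key} occurs {n} times"))
        comp_timbres: dict[str, Counter] = {}
        for t in run_trials:
            comp_timbres.setdefault(t.composition_id, Counter())[t.timbre_level] += 1
        for c, counter in comp_timbres.items():
            if len(set(counter.values())) > 1:
                v.append(Violation("equal-timbre-occurrences-per-composition",
                                   f"run {ri}", f"{c}: {dict(counter)}"))
        prev_last = None
        for bi, block in enumerate(run, 1):
            loc = f"run {ri} block {bi}"
            if len(block.trials) != 5:
                v.append(Violation("block-length", loc, f"{len(block.trials)} trials"))
                continue
            comps = [t.composition_id for t in block.trials]
            if len(set(comps)) != 5:
                v.append(Violation("composition-once-per-block", loc, str(comps)))
            timbres = [t.timbre_level for t in block.trials]
            for i, (a, b) in enumerate(zip(timbres, timbres[1:])):
                if a == b:
                    v.append(Violation("timbre-adjacent", f"{loc} trials {i+1}-{i+2}", a))
            tc = Counter(timbres)
            for lev in TIMBRE_LEVELS:
                if tc[lev] < 1:
                    v.append(Violation("timbre-at-least-once", loc, lev))
                if tc[lev] > 2:
                    v.append(Violation("timbre-at-most-twice", loc, f"{lev} x{tc[lev]}"))
            if prev_last is not None and comps[0] == prev_last:
                v.append(Violation("first-stimulus-differs-from-previous-block",
                                   loc, comps[0]))
            prev_last = comps[-1]
            if block.attention == "aggregate":
                bad = [t for t in block.trials if t.triplet_version in ("upper", "lower")]
                if bad:
                    v.append(Violation("aggregate-versions", loc,
                                       str([t.triplet_version for t in bad])))
    # repetition-level checks (groups of 3 runs)
    for rep in range(len(s.runs) // 3):
        rep_runs = s.runs[3 * rep:3 * rep + 3]
        loc = f"repetition {rep + 1}"
        orders = [tuple(b.attention for b in run) for run in rep_runs]
        for pos in range(3):
            at_pos = {o[pos] for o in orders}
            if len(at_pos) != 3:
                v.append(Violation("condition-position-coverage", loc,
                                   f"position {pos + 1}: {sorted(at_pos)}"))
        for cond in ATTENTION_LEVELS:
            cells = {
                (t.composition_id, t.timbre_level)
                for run in rep_runs for b in run if b.attention == cond
                for t in b.trials
            }
            if len(cells) != 15:
                v.append(Violation("condition-covers-all-timbre-versions", loc,
                                   f"{cond} covers {len(cells)}/15 cells"))
        for cond in ("bassoon", "cello"):
            ctrl = Counter(
                t.triplet_version
                for run in rep_runs for b in run if b.attention == cond
                for t in b.trials if not t.is_target
            )
            split = (ctrl.get("none", 0), ctrl.get(opposite[cond], 0))
            if split not in ((3, 4), (4, 3)):
                v.append(Violation("control-split", loc, f"{cond}: {split}"))
    # alternation of the control split across repetitions
    for cond in ("bassoon", "cello"):
        splits = []
        for rep in range(len(s.runs) // 3):
            rep_runs = s.runs[3 * rep:3 * rep + 3]
            ctrl = Counter(
                t.triplet_version
                for run in rep_runs for b in run if b.attention == cond
                for t in b.trials if not t.is_target
            )
            splits.append((ctrl.get("none", 0), ctrl.get(opposite[cond], 0)))
        for a, b in zip(splits, splits[1:]):
            if a == b and a in ((3, 4), (4, 3)):
                v.append(Violation("control-split-alternation", "session",
                                   f"{cond}: consecutive repetitions both {a}"))
    return v


def _validate_rating(s: Schedule) -> list[Violation]:
    from collections import Counter

    v: list[Violation] = []
    blocks = s.blocks
    if len(blocks) != 8:
        v.append(Violation("block-count", "session", f"{len(blocks)} blocks, expected 8"))
        return v
    lengths = {len(b.trials) for b in blocks}
    if lengths != {22}:
        v.append(Violation("equal-block-length", "session", str(sorted(lengths))))
    for bi, block in enumerate(blocks, 1):
        pairs = Counter((t.voice, t.morph_step) for t in block.trials)
        if len(pairs) != 22 or set(pairs.values()) != {1}:
            v.append(Violation("voice-step-once-per-block", f"block {bi}",
                               f"{len(pairs)} distinct voice/step pairs"))
    trials = s.trials
    for i, (a, b) in enumerate(zip(trials, trials[1:])):
        if a.voice == b.voice:
            v.append(Violation("voice-adjacent", f"trials {i+1}-{i+2}", a.voice))
        if a.composition_id == b.composition_id:
            v.append(Violation("composition-adjacent", f"trials {i+1}-{i+2}",
                               a.composition_id))
    return v
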
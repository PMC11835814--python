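"""Descriptive statistics of annotated song sequences.

Implements the quantities used to characterize branch-point learning:
transition tables (successor counts and probabilities at a branch syllable,
with end-of-bout as an outcome), the degree-of-learning statistic computed
from catch trials, per-bout transition entropy, song rate in a fixed daily
window, chunk-duration song speed, binned early-learning curves, relative
learning speed, and white-noise targeting accuracy.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import date, time
from typing import Iterable, Mapping, Sequence

from .annotation_io import END, Bout, BranchRendition

__all__ = [
    "TransitionTable",
    "LearningResult",
    "EntropySummary",
    "BinPoint",
    "TargetingAccuracy",
    "UndefinedLearningError",
    "branch_renditions",
    "transition_table",
    "degree_of_learning",
    "best_training_day",
    "bout_transition_entropy",
    "mean_transition_entropy",
    "song_rate",
    "chunk_durations",
    "binned_learning_curve",
    "last_complete_bin",
    "relative_learning_speed",
    "targeting_accuracy",
    "learning_result",
]

ACCURACY_EXCLUSION_THRESHOLD = 75.0  # percent; training days below are dropped


class UndefinedLearningError(ValueError):
    """Degree of learning is undefined (zero baseline probability)."""


@dataclass
class TransitionTable:
    """Outcome counts and probabilities from a branch syllable."""

    branch_syllable: str
    counts: dict[str, int]
    n_renditions: int
    catch_only: bool = False

    @property
    def defined(self) -> bool:
        return self.n_renditions > 0

    @property
    def probabilities(self) -> dict[str, float]:
        if not self.defined:
            return {}
        return {k: v / self.n_renditions for k, v in self.counts.items()}

    def probability(self, outcome: str) -> float:
        if not self.defined:
            return math.nan
        return self.counts.get(outcome, 0) / self.n_renditions


@dataclass
class LearningResult:
    """Degree of learning for one subject in one context block."""

    tp_baseline: float
    tp_best_day: float
    best_day: str
    learning_percent: float
    per_day_tp: dict[str, tuple[float, int]] = field(default_factory=dict)


@dataclass
class EntropySummary:
    per_bout_te: list[float]
    mean_te: float
    log_base: float


@dataclass
class BinPoint:
    """One bin of a within-day learning curve (1-based bin index)."""

    index: int
    tp: float
    n: int
    complete: bool


@dataclass
class TargetingAccuracy:
    hits: int
    false_positives: int
    misses: int

    @property
    def defined(self) -> bool:
        return (self.hits + self.false_positives + self.misses) > 0

    @property
    def accuracy_percent(self) -> float:
        denom = self.hits + self.false_positives + self.misses
        return 100.0 * self.hits / denom if denom else math.nan

    @property
    def excluded(self) -> bool:
        return self.defined and self.accuracy_percent < ACCURACY_EXCLUSION_THRESHOLD


# ---------------------------------------------------------------------------
# Transition tables
# ---------------------------------------------------------------------------

def branch_renditions(bout: Bout, branch_syllable: str) -> list[BranchRendition]:
    """All renditions of ``branch_syllable`` in a bout, with flags.

    Derives (position, outcome) pairs from the event sequence; catch and
    white-noise flags are taken from ``bout.renditions`` where a rendition
    at the same position exists (e.g. set by the simulator or joined from a
    feedback log), and default to False otherwise.
    """
    labels = bout.labels
    flagged = {r.position: r for r in bout.renditions}
    out = []
    for i, lab in enumerate(labels):
        if lab != branch_syllable:
            continue
        outcome = labels[i + 1] if i + 1 < len(labels) else END
        known = flagged.get(i)
        out.append(
            BranchRendition(
                position=i,
                outcome=outcome,
                is_catch=known.is_catch if known else False,
                wn_delivered=known.wn_delivered if known else False,
            )
        )
    return out


def transition_table(
    bouts: Iterable[Bout],
    branch_syllable: str,
    *,
    catch_only: bool = False,
    include_end: bool = True,
) -> TransitionTable:
    """Count successors of every branch-syllable occurrence.

    End-of-bout counts as an outcome (``include_end=False`` drops it).
    With ``catch_only``, only renditions flagged as catch trials are
    counted. A branch syllable absent from all bouts yields a table with
    ``n_renditions == 0`` and undefined probabilities.
    """
    counts: dict[str, int] = {}
    n = 0
    for bout in bouts:
        for rend in branch_renditions(bout, branch_syllable):
            if catch_only and not rend.is_catch:
                continue
            if rend.outcome == END and not include_end:
                continue
            counts[rend.outcome] = counts.get(rend.outcome, 0) + 1
            n += 1
    return TransitionTable(branch_syllable=branch_syllable, counts=counts,
                           n_renditions=n, catch_only=catch_only)


# ---------------------------------------------------------------------------
# Degree of learning
# ---------------------------------------------------------------------------

def degree_of_learning(tp_baseline: float, tp_best: float) -> float:
    """Percent reduction of the target transition probability.

    ``100 - (tp_best / tp_baseline * 100)``; negative values mean the
    transition became more frequent.
    """
    if tp_baseline <= 0:
        raise UndefinedLearningError("baseline transition probability is zero")
    return 100.0 - (tp_best / tp_baseline * 100.0)


_PHASE_NUM = re.compile(r"(\d+)$")


def _phase_order(phase: str) -> tuple[int, str]:
    m = _PHASE_NUM.search(phase)
    return (int(m.group(1)) if m else 0, phase)


def best_training_day(per_day_tp: Mapping[str, tuple[float, int]]) -> str:
    """Training day with the minimal catch-trial TP; ties go to the earliest."""
    candidates = [(p, tp) for p, (tp, n) in per_day_tp.items() if n > 0]
    if not candidates:
        raise ValueError("no training day with any catch-trial renditions")
    candidates.sort(key=lambda item: (item[1], _phase_order(item[0])))
    return candidates[0][0]


def learning_result(
    bouts_by_phase: Mapping[str, Sequence[Bout]],
    branch_syllable: str,
    target: str,
) -> LearningResult:
    """Full degree-of-learning computation for one context block.

    Baseline TP uses all renditions of the BS day (no feedback exists
    there); training-day TPs use catch trials only; the best day is the
    training day with minimal catch-trial TP.
    """
    if "BS" not in bouts_by_phase:
        raise ValueError("missing baseline screening phase 'BS'")
    baseline = transition_table(bouts_by_phase["BS"], branch_syllable)
    if not baseline.defined:
        raise UndefinedLearningError("no branch renditions during baseline screening")
    tp_baseline = baseline.probability(target)
    per_day: dict[str, tuple[float, int]] = {}
    for phase in sorted((p for p in bouts_by_phase if p.startswith("T")), key=_phase_order):
        tab = transition_table(bouts_by_phase[phase], branch_syllable, catch_only=True)
        per_day[phase] = (tab.probability(target), tab.n_renditions)
    best = best_training_day(per_day)
    tp_best = per_day[best][0]
    return LearningResult(
        tp_baseline=tp_baseline,
        tp_best_day=tp_best,
        best_day=best,
        learning_percent=degree_of_learning(tp_baseline, tp_best),
        per_day_tp=per_day,
    )


# ---------------------------------------------------------------------------
# Transition entropy
# ---------------------------------------------------------------------------

def bout_transition_entropy(
    bout: Bout,
    log_base: float = 2.0,
    *,
    include_end: bool = True,
) -> float:
    """Frequency-weighted successor entropy of one bout.

    For each syllable type ``b`` occurring in the bout, the distribution
    P(i) over its immediate successors (end-of-bout included) has entropy
    ``H_b = -sum_i P(i) log P(i)``; the bout's transition entropy is
    ``TE = sum_b H_b * P(b)`` with ``P(b)`` the frequency of ``b`` among
    transition-emitting positions.
    """
    labels = bout.labels
    if include_end:
        pairs = [(labels[i], labels[i + 1] if i + 1 < len(labels) else END)
                 for i in range(len(labels))]
    else:
        pairs = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
    if not pairs:
        return 0.0
    succ: dict[str, dict[str, int]] = {}
    for a, b in pairs:
        succ.setdefault(a, {}).setdefault(b, 0)
        succ[a][b] += 1
    total = len(pairs)
    log = math.log
    te = 0.0
    for a, dist in succ.items():
        n_a = sum(dist.values())
        h = -sum((c / n_a) * log(c / n_a, log_base) for c in dist.values() if c > 0)
        te += h * (n_a / total)
    return te


def mean_transition_entropy(
    bouts: Sequence[Bout],
    log_base: float = 2.0,
    *,
    include_end: bool = True,
) -> EntropySummary:
    """Arithmetic mean of per-bout transition entropies."""
    if not bouts:
        raise ValueError("need at least one bout")
    vals = [bout_transition_entropy(b, log_base, include_end=include_end) for b in bouts]
    return EntropySummary(per_bout_te=vals, mean_te=sum(vals) / len(vals),
                          log_base=log_base)


# ---------------------------------------------------------------------------
# Song rate and speed
# ---------------------------------------------------------------------------

def song_rate(
    bouts: Iterable[Bout],
    day: date,
    window_start: time = time(9, 30),
    window_end: time = time(17, 0),
) -> int:
    """Number of bouts starting within [window_start, window_end) on a day."""
    n = 0
    for b in bouts:
        ts = b.bout_start
        if ts.date() == day and window_start <= ts.time() < window_end:
            n += 1
    return n


def chunk_durations(bouts: Iterable[Bout], chunk: Sequence[str]) -> list[float]:
    """Durations of a stereotyped syllable sequence, gaps included.

    For every leftmost, non-overlapping exact occurrence of ``chunk`` in a
    bout's label sequence, returns offset(last syllable) - onset(first
    syllable). An absent chunk yields an empty list.
    """
    chunk = list(chunk)
    k = len(chunk)
    if k < 2:
        raise ValueError("chunk must contain at least two tokens")
    out: list[float] = []
    for bout in bouts:
        labels = bout.labels
        i = 0
        while i <= len(labels) - k:
            if labels[i:i + k] == chunk:
                out.append(bout.events[i + k - 1].offset - bout.events[i].onset)
                i += k
            else:
                i += 1
    return out


# ---------------------------------------------------------------------------
# Early-learning curves
# ---------------------------------------------------------------------------

def binned_learning_curve(
    bouts: Sequence[Bout],
    branch_syllable: str,
    target: str,
    bin_size: int = 50,
    *,
    catch_only: bool = False,
) -> list[BinPoint]:
    """Target-branch TP in consecutive ``bin_size``-bout bins.

    Bouts must be in chronological order. A trailing incomplete bin is
    reported with ``complete=False``. Bin indices are 1-based.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    points: list[BinPoint] = []
    for start in range(0, len(bouts), bin_size):
        block = bouts[start:start + bin_size]
        tab = transition_table(block, branch_syllable, catch_only=catch_only)
        points.append(
            BinPoint(index=start // bin_size + 1, tp=tab.probability(target),
                     n=tab.n_renditions, complete=len(block) == bin_size)
        )
    return points


def last_complete_bin(curves: Mapping[str, Sequence[BinPoint]]) -> int:
    """Shared bin index for cross-context comparison of early learning.

    Returns the index of the final complete bin of the context with the
    fewest first-day bouts (i.e. the fewest complete bins); every context
    must have that bin complete.
    """
    n_complete = {}
    for ctx, curve in curves.items():
        n = sum(1 for p in curve if p.complete)
        if n == 0:
            raise ValueError(f"context {ctx!r} has no complete bin")
        n_complete[ctx] = n
    idx = min(n_complete.values())
    for ctx, curve in curves.items():
        if not any(p.index == idx and p.complete for p in curve):
            raise ValueError(f"context {ctx!r} lacks complete bin {idx}")
    return idx


def relative_learning_speed(learning_percent: float, total_song_rate: float) -> float:
    """Degree of learning divided by the total number of bouts sung."""
    if total_song_rate <= 0:
        raise ValueError("total song rate must be positive")
    return learning_percent / total_song_rate


# ---------------------------------------------------------------------------
# Targeting accuracy
# ---------------------------------------------------------------------------

def targeting_accuracy(
    renditions: Iterable[BranchRendition],
    target: str,
) -> TargetingAccuracy:
    """Hit / false-positive / miss accounting of white-noise delivery.

    Catch trials are excluded from the denominator. A hit is noise on a
    target rendition; a miss is a target rendition without noise; a false
    positive is noise on a non-target rendition. Accuracy is
    ``hits / (hits + false positives + misses) * 100``.
    """
    hits = fp = misses = 0
    for r in renditions:
        if r.is_catch:
            continue
        if r.outcome == target:
            if r.wn_delivered:
                hits += 1
            else:
                misses += 1
        elif r.wn_delivered:
            fp += 1
    return TargetingAccuracy(hits=hits, false_positives=fp, misses=misses)
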
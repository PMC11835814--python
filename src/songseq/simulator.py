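"""Closed-loop simulator of a white-noise sequence-reinforcement experiment.

Generates synthetic song at the event level: first-order Markov syllable
sequences with one designated branch point, per-context song rate / tempo /
sequencing-entropy profiles, imperfect real-time targeting (hits, misses,
false positives), 10% catch trials, and a per-rendition reinforcement update
that multiplicatively decrements the targeted transition probability down to
a floor. The programmed target-probability trajectory is returned alongside
the data so the analysis pipeline can be validated by parameter recovery.

Audio is never rendered; white noise exists only as per-rendition flags.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import END, Bout, BranchRendition, SyllableEvent

__all__ = [
    "SongModel",
    "ContextProfile",
    "LearningDynamics",
    "FeedbackModel",
    "ScheduleBlock",
    "ExperimentSchedule",
    "SimulationResult",
    "default_song_model",
    "default_profiles",
    "make_schedule",
    "sample_bout",
    "apply_feedback",
    "relax_toward_baseline",
    "simulate_experiment",
    "write_dataset",
]

_ROW_TOL = 1e-9


@dataclass
class SongModel:
    """Generative parameters of one bird's song.

    ``transition_matrix`` maps each token to a probability distribution over
    successor tokens, where :data:`END` terminates the bout. Rows must sum
    to 1 within 1e-9.
    """

    repertoire: list[str]
    transition_matrix: dict[str, dict[str, float]]
    branch_syllable: str
    target_branch: str
    start_token: str
    syllable_duration_mean: float = 0.08
    syllable_duration_sd: float = 0.012
    gap_duration_mean: float = 0.045
    gap_duration_sd: float = 0.008
    max_bout_length: int = 500

    def validate(self) -> None:
        for token, row in self.transition_matrix.items():
            total = sum(row.values())
            if abs(total - 1.0) > _ROW_TOL:
                raise ValueError(f"row for {token!r} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"negative probability in row for {token!r}")
        branch_row = self.transition_matrix.get(self.branch_syllable)
        if branch_row is None:
            raise ValueError(f"branch syllable {self.branch_syllable!r} has no row")
        if branch_row.get(self.target_branch, 0.0) <= 0:
            raise ValueError(
                f"target branch {self.target_branch!r} has zero probability "
                f"after {self.branch_syllable!r}"
            )
        if self.syllable_duration_mean <= 0 or self.gap_duration_mean <= 0:
            raise ValueError("durations must be positive")
        if self.start_token not in self.transition_matrix:
            raise ValueError(f"start token {self.start_token!r} has no row")

    def copy(self) -> "SongModel":
        return replace(self, transition_matrix=copy.deepcopy(self.transition_matrix))

    @property
    def target_probability(self) -> float:
        return self.transition_matrix[self.branch_syllable][self.target_branch]


@dataclass
class ContextProfile:
    """How one social context shapes singing.

    ``tempo_factor`` multiplies syllable and gap durations (< 1 is faster
    song). ``entropy_factor`` interpolates every successor distribution
    toward its mode (0 = unchanged, 1 = fully deterministic), lowering
    sequencing entropy. ``learning_floor_factor`` scales the asymptotic
    learning floor, letting contexts differ in achievable learning.
    ``partner_song_fraction`` is the probability that a recorded file also
    contains an overlapping partner bout (male-male housing only).
    """

    context: str
    bouts_per_day_mean: float
    tempo_factor: float = 1.0
    entropy_factor: float = 0.0
    learning_floor_factor: float = 1.0
    partner_song_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.bouts_per_day_mean <= 0:
            raise ValueError("bouts_per_day_mean must be positive")
        if self.tempo_factor <= 0:
            raise ValueError("tempo_factor must be positive")
        if not 0.0 <= self.entropy_factor <= 1.0:
            raise ValueError("entropy_factor must lie in [0, 1]")


@dataclass
class LearningDynamics:
    """Per-rendition reinforcement update of the targeted transition.

    White noise delivered on a target rendition multiplies the target
    probability by ``1 - learning_rate``, clipped at ``floor``; the removed
    mass is redistributed proportionally over the other outcomes. On days
    without feedback the target probability drifts back toward baseline at
    ``relaxation_rate`` per day.
    """

    learning_rate: float = 0.05
    floor: float = 0.15
    relaxation_rate: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate < 1.0:
            raise ValueError("learning_rate must lie in [0, 1)")
        if self.floor < 0:
            raise ValueError("floor must be non-negative")
        if not 0.0 <= self.relaxation_rate <= 1.0:
            raise ValueError("relaxation_rate must lie in [0, 1]")


@dataclass
class FeedbackModel:
    """Event-level model of the real-time targeting system."""

    hit_rate: float = 0.93
    false_positive_rate: float = 0.005
    catch_fraction: float = 0.10
    wn_duration: float = 0.040

    def __post_init__(self) -> None:
        for name in ("hit_rate", "false_positive_rate", "catch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ScheduleBlock:
    context: str
    order_index: int
    days: list[tuple[str, date]]  # (phase, calendar date), chronological


@dataclass
class ExperimentSchedule:
    subject: str
    blocks: list[ScheduleBlock]

    def day_map(self) -> dict[date, tuple[str, str]]:
        """Map calendar date -> (phase, context)."""
        out: dict[date, tuple[str, str]] = {}
        for block in self.blocks:
            for phase, d in block.days:
                out[d] = (phase, block.context)
        return out

    def validate(self) -> None:
        contexts = [b.context for b in self.blocks]
        if len(set(contexts)) != len(contexts):
            raise ValueError("each context must appear exactly once per subject")
        for b in self.blocks:
            n_train = sum(1 for p, _ in b.days if p.startswith("T"))
            if n_train != 0 and not 4 <= n_train <= 5:
                raise ValueError(
                    f"block {b.context}: training spans {n_train} days, expected 4-5 "
                    "(or 0 for a screen-only block)"
                )


def make_schedule(
    subject: str,
    context_order: Sequence[str],
    start: date = date(2024, 1, 8),
    training_days: int = 4,
) -> ExperimentSchedule:
    """Build the standard timeline for one subject.

    Per context block: one baseline-screening day (BS), ``training_days``
    consecutive training days (T1..), a post-screen the following day (PS1)
    and two more post-screens one and two weeks after training end (PS2,
    PS3). The next context block starts the day after PS3.
    """
    blocks = []
    d = start
    for i, ctx in enumerate(context_order, start=1):
        days: list[tuple[str, date]] = [("BS", d)]
        d += timedelta(days=1)
        for t in range(1, training_days + 1):
            days.append((f"T{t}", d))
            d += timedelta(days=1)
        ps1 = d
        days.append(("PS1", ps1))
        days.append(("PS2", ps1 + timedelta(days=7)))
        days.append(("PS3", ps1 + timedelta(days=14)))
        blocks.append(ScheduleBlock(context=ctx, order_index=i, days=days))
        d = ps1 + timedelta(days=15)
    sched = ExperimentSchedule(subject=subject, blocks=blocks)
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# Defaults: the study conditions the simulator emulates
# ---------------------------------------------------------------------------

def default_song_model() -> SongModel:
    """A Bengalese-finch-like grammar with one branch point.

    Introductory notes ``i`` lead into a loop through branch syllable ``x``
    (outcomes: target ``a``, alternative ``l``, or end of bout) and a
    stereotyped chunk ``b c`` that returns to ``x``. Bouts average roughly
    100 syllables (~12 s) with ~25 branch renditions.
    """
    tm = {
        "i": {"i": 0.3, "x": 0.7},
        "x": {"a": 0.7, "l": 0.28, END: 0.02},
        "a": {"b": 1.0},
        "l": {"b": 1.0},
        "b": {"c": 1.0},
        "c": {"x": 0.98, END: 0.02},
    }
    return SongModel(
        repertoire=["i", "x", "a", "l", "b", "c"],
        transition_matrix=tm,
        branch_syllable="x",
        target_branch="a",
        start_token="i",
    )


def default_profiles() -> dict[str, ContextProfile]:
    """Per-context singing profiles.

    Song rate is highest when the bird is alone (MA) and roughly halved in
    social housing (MF, MM); social song is slightly faster; sequencing
    entropy is essentially unchanged. The learning floor is lowest in MM,
    emulating the group-mean learning ordering MM > MF > MA.
    """
    return {
        "MA": ContextProfile("MA", bouts_per_day_mean=300, tempo_factor=1.0,
                             entropy_factor=0.0, learning_floor_factor=2.85),
        "MF": ContextProfile("MF", bouts_per_day_mean=170, tempo_factor=0.98,
                             entropy_factor=0.02, learning_floor_factor=2.52),
        "MM": ContextProfile("MM", bouts_per_day_mean=180, tempo_factor=0.96,
                             entropy_factor=0.02, learning_floor_factor=1.70,
                             partner_song_fraction=0.03),
    }


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _effective_row(row: dict[str, float], entropy_factor: float) -> dict[str, float]:
    if entropy_factor <= 0.0:
        return row
    mode = max(row, key=lambda k: row[k])
    return {
        k: (1.0 - entropy_factor) * p + (entropy_factor if k == mode else 0.0)
        for k, p in row.items()
    }


def _draw(row: dict[str, float], rng: np.random.Generator) -> str:
    r = rng.random()
    acc = 0.0
    last = None
    for token, p in row.items():
        acc += p
        last = token
        if r < acc:
            return token
    return last  # numerical slack


def sample_bout(
    model: SongModel,
    profile: ContextProfile,
    rng: np.random.Generator,
    *,
    file_id: str = "sim_0000",
    file_start: datetime = datetime(2024, 1, 8, 9, 0, 0),
    singer: str = "bird",
    on_rendition: Callable[[BranchRendition], None] | None = None,
    p_trace: list[float] | None = None,
) -> Bout:
    """Sample one bout as a first-order Markov walk from the start token.

    The walk runs until :data:`END` or ``max_bout_length`` syllables. Each
    occurrence of the branch syllable yields a :class:`BranchRendition`;
    ``on_rendition`` is invoked immediately after the rendition's outcome is
    drawn, so a feedback callback can update ``model`` before subsequent
    renditions are sampled (closed-loop semantics). ``p_trace``, if given,
    collects the effective target probability seen by each rendition.
    """
    model.validate()
    tokens: list[str] = []
    renditions: list[BranchRendition] = []
    current = model.start_token
    while len(tokens) < model.max_bout_length:
        tokens.append(current)
        row = _effective_row(model.transition_matrix[current], profile.entropy_factor)
        nxt = _draw(row, rng)
        if current == model.branch_syllable:
            if p_trace is not None:
                p_trace.append(row.get(model.target_branch, 0.0))
            rend = BranchRendition(position=len(tokens) - 1, outcome=nxt)
            renditions.append(rend)
            if on_rendition is not None:
                on_rendition(rend)
        if nxt == END:
            break
        current = nxt
    else:
        # Length cap reached: the bout ends here; a pending branch rendition
        # at the final position would already have a drawn outcome.
        pass

    n = len(tokens)
    durs = np.maximum(
        1e-3,
        rng.normal(model.syllable_duration_mean * profile.tempo_factor,
                   model.syllable_duration_sd * profile.tempo_factor, size=n),
    )
    gaps = np.maximum(
        1e-3,
        rng.normal(model.gap_duration_mean * profile.tempo_factor,
                   model.gap_duration_sd * profile.tempo_factor, size=n),
    )
    events = []
    t = 0.0
    for k, lab in enumerate(tokens):
        events.append(
            SyllableEvent(label=lab, onset=t, offset=float(t + durs[k]),
                          file_id=file_id, file_start=file_start, singer=singer)
        )
        t = float(t + durs[k] + gaps[k])
    # A bout-final rendition's outcome must be END by construction.
    if renditions and renditions[-1].position == n - 1:
        renditions[-1].outcome = END
    return Bout(events=events, bout_start=events[0].abs_onset, renditions=renditions)


def apply_feedback(
    model: SongModel,
    rendition: BranchRendition,
    fb: FeedbackModel,
    dyn: LearningDynamics,
    rng: np.random.Generator,
    *,
    floor: float | None = None,
) -> tuple[SongModel, BranchRendition]:
    """Resolve catch/white-noise flags for one rendition and learn from it.

    With probability ``catch_fraction`` the rendition is a catch trial and
    no noise is delivered. Otherwise noise is delivered with ``hit_rate``
    on target outcomes and ``false_positive_rate`` on non-target outcomes.
    Noise on the *target* outcome decrements the target probability
    multiplicatively (floored), redistributing the removed mass
    proportionally over the other outcomes; false positives are treated as
    non-instructive. The model is updated in place and returned.
    """
    floor_eff = dyn.floor if floor is None else floor
    rendition.is_catch = bool(rng.random() < fb.catch_fraction)
    rendition.wn_delivered = False
    if not rendition.is_catch:
        if rendition.outcome == model.target_branch:
            rendition.wn_delivered = bool(rng.random() < fb.hit_rate)
        else:
            rendition.wn_delivered = bool(rng.random() < fb.false_positive_rate)
    if rendition.wn_delivered and rendition.outcome == model.target_branch:
        _decrement_target(model, dyn.learning_rate, floor_eff)
    return model, rendition


def _decrement_target(model: SongModel, eta: float, floor: float) -> None:
    row = model.transition_matrix[model.branch_syllable]
    p = row[model.target_branch]
    p_new = max(floor, p * (1.0 - eta))
    if p_new == p or p >= 1.0 - _ROW_TOL:
        return  # nothing to redistribute
    scale = (1.0 - p_new) / (1.0 - p)
    for k in row:
        row[k] = row[k] * scale if k != model.target_branch else p_new
    _renormalize(row)


def relax_toward_baseline(model: SongModel, baseline_p: float, rate: float) -> None:
    """Drift the target probability back toward baseline by one day-step."""
    if rate <= 0:
        return
    row = model.transition_matrix[model.branch_syllable]
    p = row[model.target_branch]
    p_new = p + rate * (baseline_p - p)
    if abs(p_new - p) < _ROW_TOL or p >= 1.0 - _ROW_TOL:
        return
    scale = (1.0 - p_new) / (1.0 - p)
    for k in row:
        row[k] = row[k] * scale if k != model.target_branch else p_new
    _renormalize(row)


def _renormalize(row: dict[str, float]) -> None:
    total = sum(row.values())
    for k in row:
        row[k] /= total


# ---------------------------------------------------------------------------
# Whole-experiment simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything one simulated subject produced."""

    subject: str
    schedule: ExperimentSchedule
    bouts: list[Bout]
    feedback_log: pd.DataFrame
    ground_truth: pd.DataFrame

    @property
    def events(self) -> list[SyllableEvent]:
        evs = [e for b in self.bouts for e in b.events]
        evs.sort(key=lambda e: (e.abs_onset, e.singer))
        return evs


_SING_DAY_START = 9 * 3600.0          # bouts may start from 09:00
_SING_DAY_END = 17.5 * 3600.0         # ... until 17:30


def simulate_experiment(
    model: SongModel,
    schedule: ExperimentSchedule,
    profiles: dict[str, ContextProfile],
    fb: FeedbackModel,
    dyn: LearningDynamics,
    seed: int | np.random.Generator,
    *,
    dispersion: float = 30.0,
) -> SimulationResult:
    """Simulate one subject through all scheduled context blocks.

    White noise is active only on training (T) days; baseline and
    post-screen days carry no feedback flags. Each context block starts from
    the pristine baseline grammar (complete washout between blocks). The
    returned ground truth records, per day, the mean effective target
    probability seen by that day's branch renditions — the quantity a
    catch-trial transition-probability estimate is an unbiased estimate of.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model.validate()
    schedule.validate()
    for block in schedule.blocks:
        if block.context not in profiles:
            raise ValueError(f"no profile for scheduled context {block.context!r}")

    subject = schedule.subject
    partner = f"{subject}_partner"
    all_bouts: list[Bout] = []
    fb_rows: list[dict] = []
    gt_rows: list[dict] = []

    for block in schedule.blocks:
        profile = profiles[block.context]
        working = model.copy()  # fresh baseline at each block
        baseline_p = model.target_probability
        floor_eff = dyn.floor * profile.learning_floor_factor
        prev_day: date | None = None
        for phase, day in block.days:
            is_training = phase.startswith("T")
            if not is_training:
                # Relaxation compounds over elapsed calendar days without
                # feedback (post-screens a week apart drift further back).
                elapsed = (day - prev_day).days if prev_day is not None else 1
                rate = 1.0 - (1.0 - dyn.relaxation_rate) ** max(1, elapsed)
                relax_toward_baseline(working, baseline_p, rate)
            prev_day = day
            m = float(profile.bouts_per_day_mean)
            n_bouts = max(1, int(rng.negative_binomial(dispersion,
                                                       dispersion / (dispersion + m))))
            starts = np.sort(rng.uniform(_SING_DAY_START, _SING_DAY_END, size=n_bouts))
            day_trace: list[float] = []
            prev_end = -np.inf  # bouts are serialized: a bird sings one at a time
            for i, s in enumerate(starts):
                s = max(float(s), prev_end + 2.5)
                t0 = datetime.combine(day, time(0)) + timedelta(seconds=s)
                fid = f"{subject}_{block.context}_{phase}_{day:%Y%m%d}_{i:04d}"
                cb = None
                if is_training:
                    def cb(rend, _w=working):
                        apply_feedback(_w, rend, fb, dyn, rng, floor=floor_eff)
                bout = sample_bout(
                    working, profile, rng, file_id=fid, file_start=t0,
                    singer=subject, on_rendition=cb, p_trace=day_trace,
                )
                bout.phase, bout.context = phase, block.context
                all_bouts.append(bout)
                prev_end = s + bout.events[-1].offset
                if is_training:
                    for j, rend in enumerate(bout.renditions):
                        fb_rows.append({
                            "file_id": fid, "bout_index": 0, "rendition_index": j,
                            "outcome": rend.outcome, "is_catch": rend.is_catch,
                            "wn_delivered": rend.wn_delivered,
                        })
                if profile.partner_song_fraction > 0 and rng.random() < profile.partner_song_fraction:
                    pbout = sample_bout(model, profile, rng, file_id=fid,
                                        file_start=t0, singer=partner)
                    shifted = [replace(e, onset=e.onset + 1.0, offset=e.offset + 1.0)
                               for e in pbout.events]
                    pbout = Bout(events=shifted, bout_start=shifted[0].abs_onset,
                                 phase=phase, context=block.context)
                    all_bouts.append(pbout)
                    prev_end = max(prev_end, s + shifted[-1].offset)
            gt_rows.append({
                "subject": subject, "context": block.context, "phase": phase,
                "day": day.isoformat(),
                "true_target_p": float(np.mean(day_trace)) if day_trace else np.nan,
                "n_renditions": len(day_trace),
            })

    feedback_log = pd.DataFrame(
        fb_rows, columns=["file_id", "bout_index", "rendition_index",
                          "outcome", "is_catch", "wn_delivered"])
    ground_truth = pd.DataFrame(
        gt_rows, columns=["subject", "context", "phase", "day",
                          "true_target_p", "n_renditions"])
    return SimulationResult(subject=subject, schedule=schedule, bouts=all_bouts,
                            feedback_log=feedback_log, ground_truth=ground_truth)


def write_dataset(result: SimulationResult, outdir) -> None:
    """Write annotations, feedback log and ground truth as CSV."""
    from pathlib import Path

    from .annotation_io import write_annotations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_annotations(result.events, outdir / f"{result.subject}_annotations.csv")
    result.feedback_log.to_csv(outdir / f"{result.subject}_feedback_log.csv", index=False)
    result.ground_truth.to_csv(outdir / f"{result.subject}_ground_truth.csv", index=False)
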
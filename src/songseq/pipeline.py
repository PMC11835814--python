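"""Simulate -> analyze -> report workflow.

``cmd_simulate`` writes a complete synthetic dataset (annotations, feedback
log, ground truth, manifest). ``cmd_analyze`` runs the full analysis chain
on a dataset directory: segmentation, mixed-singing exclusion, feedback-log
join, targeting-accuracy screening, degree of learning, entropy, song
rate/speed, early-learning curves, and the cross-context statistics,
emitting tidy CSVs. ``cmd_report`` condenses analyze output into one
summary table per figure-level result. Every output embeds the config hash
and seed; every filter logs its counts at INFO.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_io as aio
from . import inference as inf
from . import sequence_stats as sst
from .config import ConfigError, RunConfig
from .simulator import make_schedule, simulate_experiment, write_dataset

__all__ = ["cmd_simulate", "cmd_analyze", "cmd_report", "REPORT_TABLES"]

logger = logging.getLogger("songseq")


def _subject_rng(config: RunConfig, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed)
    return np.random.default_rng(ss.spawn(len(config.subjects))[index])


def _subject_profiles(config: RunConfig, rng: np.random.Generator):
    """Per-subject copy of the context profiles with individual variation in
    the asymptotic learning floor (lognormal jitter)."""
    out = {}
    for ctx in sorted(config.profiles):
        p = config.profiles[ctx]
        jitter = float(np.exp(rng.normal(0.0, config.subject_variability)))
        out[ctx] = type(p)(
            context=p.context,
            bouts_per_day_mean=p.bouts_per_day_mean,
            tempo_factor=p.tempo_factor,
            entropy_factor=p.entropy_factor,
            learning_floor_factor=p.learning_floor_factor * jitter,
            partner_song_fraction=p.partner_song_fraction,
        )
    return out


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def cmd_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Simulate every configured subject and write the dataset directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = {"subjects": 0, "bouts": 0, "events": 0, "feedback_rows": 0}
    for i, (subject, order) in enumerate(sorted(config.subjects.items())):
        rng = _subject_rng(config, i)
        profiles = _subject_profiles(config, rng)
        schedule = make_schedule(subject, order, start=config.start_date,
                                 training_days=config.training_days)
        result = simulate_experiment(config.song_model.copy(), schedule, profiles,
                                     config.feedback, config.dynamics, rng)
        write_dataset(result, outdir)
        counts["subjects"] += 1
        counts["bouts"] += len(result.bouts)
        counts["events"] += sum(len(b) for b in result.bouts)
        counts["feedback_rows"] += len(result.feedback_log)
        logger.info("simulated %s: %d bouts, %d feedback rows",
                    subject, len(result.bouts), len(result.feedback_log))
    manifest = {"config_hash": config.config_hash, "seed": config.seed, **counts}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def _attach_feedback(bouts, feedback: pd.DataFrame, branch: str) -> None:
    """Join per-rendition catch/WN flags onto segmented bouts.

    The log keys are (file_id, bout index within file, rendition index
    within bout), matched against bouts in time order.
    """
    by_file: dict[str, list] = defaultdict(list)
    for b in bouts:
        by_file[b.file_id].append(b)
    log_by_key = {}
    for row in feedback.itertuples(index=False):
        log_by_key[(row.file_id, int(row.bout_index), int(row.rendition_index))] = row
    n_matched = 0
    for fid, file_bouts in by_file.items():
        file_bouts.sort(key=lambda b: b.bout_start)
        for bi, bout in enumerate(file_bouts):
            rends = sst.branch_renditions(bout, branch)
            for ri, rend in enumerate(rends):
                row = log_by_key.get((fid, bi, ri))
                if row is not None:
                    rend.is_catch = bool(row.is_catch)
                    rend.wn_delivered = bool(row.wn_delivered)
                    n_matched += 1
            bout.renditions = rends
    logger.info("feedback join: %d of %d log rows matched", n_matched, len(feedback))


def _read_subject(config: RunConfig, data_dir: Path, subject: str):
    events = aio.read_annotations(data_dir / f"{subject}_annotations.csv")
    fb_path = data_dir / f"{subject}_feedback_log.csv"
    feedback = pd.read_csv(fb_path) if fb_path.exists() else pd.DataFrame(
        columns=["file_id", "bout_index", "rendition_index",
                 "outcome", "is_catch", "wn_delivered"])
    return events, feedback


def cmd_analyze(config: RunConfig, data_dir: str | Path, outdir: str | Path) -> Path:
    """Run the full analysis chain on a dataset directory."""
    config.validate()
    data_dir, outdir = Path(data_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    branch = config.song_model.branch_syllable
    target = config.song_model.target_branch

    learning_rows, per_day_rows, rate_rows, entropy_rows = [], [], [], []
    speed_rows, curve_rows, early_rows, acc_rows, excl_rows = [], [], [], [], []
    early_by_key: dict[tuple[str, str], float] = {}
    total_by_key: dict[tuple[str, str], float] = {}
    relspeed_by_key: dict[tuple[str, str], float] = {}

    for subject, order in sorted(config.subjects.items()):
        events, feedback = _read_subject(config, data_dir, subject)
        logger.info("%s: %d annotation rows", subject, len(events))
        bouts = aio.segment_bouts(events, gap_threshold=config.gap_threshold_s)
        logger.info("%s: segmented %d bouts", subject, len(bouts))
        kept, report = aio.filter_mixed_bouts(bouts, subject,
                                              overlap_threshold=config.overlap_threshold)
        logger.info("%s: mixed-singing exclusion dropped %d files (%d bouts kept)",
                    subject, len(report.excluded_file_ids), len(kept))

        schedule = make_schedule(subject, order, start=config.start_date,
                                 training_days=config.training_days)
        day_map = schedule.day_map()
        dated = []
        for b in kept:
            info = day_map.get(b.bout_start.date())
            if info is None:
                continue
            b.phase, b.context = info
            dated.append(b)
        logger.info("%s: %d bouts within scheduled days", subject, len(dated))
        _attach_feedback(dated, feedback, branch)

        # exclusion bookkeeping per phase (file counts)
        n_files_by_day: dict[tuple[str, str], set] = defaultdict(set)
        for b in bouts:
            info = day_map.get(b.bout_start.date())
            if info:
                n_files_by_day[info].add(b.file_id)
        excluded_set = set(report.excluded_file_ids)
        for (phase, ctx), fids in sorted(n_files_by_day.items()):
            n_exc = len(fids & excluded_set)
            excl_rows.append({"subject": subject, "context": ctx, "phase": phase,
                              "files_total": len(fids), "files_excluded": n_exc,
                              "pct_excluded": 100.0 * n_exc / len(fids)})

        for block in schedule.blocks:
            ctx = block.context
            ctx_bouts = [b for b in dated if b.context == ctx]
            by_phase: dict[str, list] = defaultdict(list)
            for b in ctx_bouts:
                by_phase[b.phase].append(b)
            required = ["BS"] + [f"T{t}" for t in range(1, config.training_days + 1)]
            missing = [p for p in required if p not in by_phase]
            if missing:
                raise ValueError(
                    f"{subject}/{ctx}: missing phases {missing} in dataset")

            # Targeting-accuracy screen: drop training days below threshold.
            train_phases = [p for p in by_phase if p.startswith("T")]
            usable = dict(by_phase)
            for phase in sorted(train_phases, key=sst._phase_order):
                rends = [r for b in by_phase[phase] for r in b.renditions]
                acc = sst.targeting_accuracy(rends, target)
                acc_rows.append({
                    "subject": subject, "context": ctx, "phase": phase,
                    "hits": acc.hits, "false_positives": acc.false_positives,
                    "misses": acc.misses, "accuracy_pct": acc.accuracy_percent,
                    "excluded": acc.excluded,
                })
                if acc.excluded:
                    logger.info("%s/%s/%s excluded: targeting accuracy %.1f%% < %.0f%%",
                                subject, ctx, phase, acc.accuracy_percent,
                                sst.ACCURACY_EXCLUSION_THRESHOLD)
                    usable.pop(phase)

            lr = sst.learning_result(usable, branch, target)
            for phase, (tp, n) in lr.per_day_tp.items():
                per_day_rows.append({"subject": subject, "context": ctx,
                                     "phase": phase, "tp_target": tp,
                                     "n_renditions": n})
            bs_tab = sst.transition_table(by_phase["BS"], branch)
            per_day_rows.append({"subject": subject, "context": ctx, "phase": "BS",
                                 "tp_target": lr.tp_baseline,
                                 "n_renditions": bs_tab.n_renditions})

            # Song rate per day, and the block's total training-day output.
            phase_dates = dict(block.days)
            total_rate = 0
            for phase in required:
                rate = sst.song_rate(by_phase.get(phase, []), phase_dates[phase])
                rate_rows.append({"subject": subject, "context": ctx, "phase": phase,
                                  "day": phase_dates[phase].isoformat(),
                                  "n_bouts": rate})
                if phase.startswith("T"):
                    total_rate += rate
            total_by_key[(subject, ctx)] = total_rate

            rel_speed = (sst.relative_learning_speed(lr.learning_percent, total_rate)
                         if total_rate > 0 else np.nan)
            relspeed_by_key[(subject, ctx)] = rel_speed
            learning_rows.append({
                "subject": subject, "context": ctx,
                "order_index": order.index(ctx) + 1,
                "tp_baseline": lr.tp_baseline, "tp_best_day": lr.tp_best_day,
                "best_day": lr.best_day, "learning_percent": lr.learning_percent,
                "total_song_rate": total_rate, "relative_learning_speed": rel_speed,
            })

            # Baseline entropy and song speed.
            ent = sst.mean_transition_entropy(by_phase["BS"], config.entropy_log_base)
            entropy_rows.append({"subject": subject, "context": ctx,
                                 "mean_te": ent.mean_te, "n_bouts": len(ent.per_bout_te),
                                 "log_base": config.entropy_log_base})
            durs = sst.chunk_durations(by_phase["BS"], config.chunk)
            speed_rows.append({"subject": subject, "context": ctx,
                               "chunk": "".join(config.chunk),
                               "mean_duration_s": float(np.mean(durs)) if durs else np.nan,
                               "n_occurrences": len(durs)})

        # First-training-day curves and the shared-bin early-learning value.
        curves = {}
        for block in schedule.blocks:
            ctx = block.context
            t1 = sorted((b for b in dated if b.context == ctx and b.phase == "T1"),
                        key=lambda b: b.bout_start)
            curves[ctx] = sst.binned_learning_curve(t1, branch, target,
                                                    bin_size=config.bin_size)
        try:
            shared = sst.last_complete_bin(curves)
        except ValueError as exc:
            logger.info("%s: no shared first-day bin (%s)", subject, exc)
            shared = None
        for ctx, curve in curves.items():
            for pt in curve:
                curve_rows.append({"subject": subject, "context": ctx,
                                   "bin": pt.index, "tp": pt.tp, "n": pt.n,
                                   "complete": pt.complete})
            if shared is not None:
                pt = next(p for p in curve if p.index == shared)
                base = next(r for r in learning_rows
                            if r["subject"] == subject and r["context"] == ctx)
                early = sst.degree_of_learning(base["tp_baseline"], pt.tp)
                early_by_key[(subject, ctx)] = early
                early_rows.append({"subject": subject, "context": ctx,
                                   "shared_bin": shared, "tp_at_bin": pt.tp,
                                   "early_learning_percent": early})

    learning = pd.DataFrame(learning_rows)
    frames = {
        "learning_summary": learning,
        "per_day_tp": pd.DataFrame(per_day_rows),
        "song_rate": pd.DataFrame(rate_rows),
        "entropy_summary": pd.DataFrame(entropy_rows),
        "song_speed": pd.DataFrame(speed_rows),
        "binned_curves": pd.DataFrame(curve_rows),
        "early_learning": pd.DataFrame(early_rows),
        "targeting_accuracy": pd.DataFrame(acc_rows),
        "exclusions": pd.DataFrame(excl_rows),
        "tests": _group_statistics(config, learning, pd.DataFrame(rate_rows),
                                   pd.DataFrame(entropy_rows),
                                   pd.DataFrame(speed_rows),
                                   early_by_key, relspeed_by_key,
                                   pd.DataFrame(per_day_rows)),
    }
    for name, frame in frames.items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    manifest = {"config_hash": config.config_hash, "seed": config.seed,
                "tables": sorted(frames)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _group_statistics(config, learning, rates, entropy, speed,
                      early_by_key, relspeed_by_key, per_day) -> pd.DataFrame:
    """The cross-context test battery, where the data support it."""
    results: list[dict] = []

    def add(result: inf.TestResult, label: str):
        row = result.as_row()
        row["test"] = label
        results.append(row)

    # Per subject x context: baseline vs best-day proportion of target outcomes.
    for r in learning.itertuples(index=False):
        bs = per_day[(per_day.subject == r.subject) & (per_day.context == r.context)
                     & (per_day.phase == "BS")]
        best = per_day[(per_day.subject == r.subject) & (per_day.context == r.context)
                       & (per_day.phase == r.best_day)]
        if bs.empty or best.empty:
            continue
        n1, n2 = int(bs.n_renditions.iloc[0]), int(best.n_renditions.iloc[0])
        if n1 == 0 or n2 == 0:
            continue
        k1 = int(round(bs.tp_target.iloc[0] * n1))
        k2 = int(round(best.tp_target.iloc[0] * n2))
        add(inf.two_proportion_test(k1, n1, k2, n2),
            f"prop_test_{r.subject}_{r.context}")

    n_subjects = learning.subject.nunique() if not learning.empty else 0
    if n_subjects >= 2:
        bs_rates = rates[rates.phase == "BS"]
        add(inf.oneway_anova(bs_rates.n_bouts.tolist(), bs_rates.context.tolist()),
            "anova_song_rate_by_context")
        sp = speed.dropna(subset=["mean_duration_s"])
        add(inf.oneway_anova(sp.mean_duration_s.tolist(), sp.context.tolist()),
            "anova_song_speed_by_context")
        add(inf.oneway_anova(entropy.mean_te.tolist(), entropy.context.tolist()),
            "anova_entropy_by_context")
        try:
            main = inf.nway_anova_main_effects(
                learning.learning_percent.tolist(),
                {"context": learning.context.tolist(),
                 "order": learning.order_index.tolist(),
                 "subject": learning.subject.tolist()})
            for name, res in main.items():
                add(res, f"anova3_learning_{name}")
        except ValueError as exc:
            logger.info("3-way ANOVA skipped: %s", exc)
        for other in ("MF", "MM"):
            pairs = [(relspeed_by_key.get((s, "MA")), relspeed_by_key.get((s, other)))
                     for s in sorted(learning.subject.unique())]
            pairs = [(a, b) for a, b in pairs
                     if a is not None and b is not None
                     and np.isfinite(a) and np.isfinite(b)]
            if len(pairs) >= 2:
                x, y = zip(*pairs)
                add(inf.paired_t(list(x), list(y)), f"paired_t_relspeed_MA_{other}")
        keys = sorted(set(early_by_key) & set(
            (r.subject, r.context) for r in learning.itertuples(index=False)))
        if len(keys) >= 3:
            early = [early_by_key[k] for k in keys]
            total = [float(learning[(learning.subject == s) & (learning.context == c)]
                           .learning_percent.iloc[0]) for s, c in keys]
            if np.std(early) > 0 and np.std(total) > 0:
                add(inf.pearson_correlation(early, total),
                    "corr_early_vs_total_learning")
    return pd.DataFrame(results, columns=["test", "groups", "statistic", "df", "p"])


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

REPORT_TABLES = [
    "learning_by_context",
    "learning_by_order",
    "early_learning_by_context",
    "song_rate_by_context",
    "song_speed_by_context",
    "entropy_by_context",
]


def cmd_report(results_dir: str | Path, outdir: str | Path | None = None
               ) -> dict[str, pd.DataFrame]:
    """Summarize analyze output: one table per figure-level result.

    Pure aggregation of the results CSVs; no new statistics are computed.
    """
    results_dir = Path(results_dir)
    required = ["learning_summary", "song_rate", "entropy_summary",
                "song_speed", "early_learning"]
    missing = [n for n in required if not (results_dir / f"{n}.csv").exists()]
    if missing:
        raise FileNotFoundError(f"results directory lacks tables: {missing}")
    learning = pd.read_csv(results_dir / "learning_summary.csv")
    rates = pd.read_csv(results_dir / "song_rate.csv")
    entropy = pd.read_csv(results_dir / "entropy_summary.csv")
    speed = pd.read_csv(results_dir / "song_speed.csv")
    early = pd.read_csv(results_dir / "early_learning.csv")

    tables = {
        "learning_by_context": learning.groupby("context").learning_percent
        .agg(["mean", "median", "std", "count"]).reset_index(),
        "learning_by_order": learning.groupby("order_index").learning_percent
        .agg(["mean", "median", "std", "count"]).reset_index(),
        "early_learning_by_context": (
            early.groupby("context").early_learning_percent
            .agg(["mean", "std", "count"]).reset_index()
            if not early.empty else pd.DataFrame(
                columns=["context", "mean", "std", "count"])),
        "song_rate_by_context": rates[rates.phase == "BS"].groupby("context")
        .n_bouts.agg(["mean", "std", "count"]).reset_index(),
        "song_speed_by_context": speed.groupby("context").mean_duration_s
        .agg(["mean", "std", "count"]).reset_index(),
        "entropy_by_context": entropy.groupby("context").mean_te
        .agg(["mean", "std", "count"]).reset_index(),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(outdir / f"{name}.csv", index=False)
    return tables
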
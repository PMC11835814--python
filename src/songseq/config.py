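"""Run configuration: one structured document driving simulate and analyze.

The config holds the song grammar, per-context profiles, feedback and
learning parameters, the per-subject context orders, and every analysis
setting (bin size, entropy log base, overlap threshold, seed). A SHA-256
hash of the canonical JSON form is embedded in all outputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import date
from itertools import permutations
from pathlib import Path

import yaml

from .simulator import (
    ContextProfile,
    FeedbackModel,
    LearningDynamics,
    SongModel,
    default_profiles,
    default_song_model,
)

__all__ = ["ConfigError", "RunConfig", "default_config"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class RunConfig:
    subjects: dict[str, list[str]]
    song_model: SongModel
    profiles: dict[str, ContextProfile]
    feedback: FeedbackModel
    dynamics: LearningDynamics
    start_date: date = date(2024, 1, 8)
    training_days: int = 4
    gap_threshold_s: float = 2.0
    bin_size: int = 50
    entropy_log_base: float = 2.0
    overlap_threshold: float = 0.0
    chunk: list[str] = field(default_factory=lambda: ["a", "b", "c"])
    subject_variability: float = 0.15
    seed: int = 1

    def validate(self) -> None:
        sm = self.song_model
        try:
            sm.validate()
        except ValueError as exc:
            raise ConfigError(f"song_model: {exc}") from exc
        if sm.branch_syllable not in sm.repertoire:
            raise ConfigError(
                f"song_model.branch_syllable: {sm.branch_syllable!r} not in repertoire")
        if sm.target_branch not in sm.repertoire:
            raise ConfigError(
                f"song_model.target_branch: {sm.target_branch!r} not in repertoire")
        for subj, order in self.subjects.items():
            missing = [c for c in order if c not in self.profiles]
            if missing:
                raise ConfigError(f"subjects.{subj}: no profile for context(s) {missing}")
        if self.bin_size < 1:
            raise ConfigError("bin_size: must be >= 1")
        if self.training_days not in (4, 5):
            raise ConfigError("training_days: must be 4 or 5")
        if not all(tok in sm.repertoire for tok in self.chunk):
            raise ConfigError(f"chunk: tokens {self.chunk} must come from the repertoire")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "subjects": self.subjects,
            "song_model": asdict(self.song_model),
            "profiles": {k: asdict(v) for k, v in sorted(self.profiles.items())},
            "feedback": asdict(self.feedback),
            "dynamics": asdict(self.dynamics),
            "start_date": self.start_date.isoformat(),
            "training_days": self.training_days,
            "gap_threshold_s": self.gap_threshold_s,
            "bin_size": self.bin_size,
            "entropy_log_base": self.entropy_log_base,
            "overlap_threshold": self.overlap_threshold,
            "chunk": self.chunk,
            "subject_variability": self.subject_variability,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = default_config()
        try:
            song_model = (SongModel(**d["song_model"]) if "song_model" in d
                          else base.song_model)
            profiles = ({k: ContextProfile(**v) for k, v in d["profiles"].items()}
                        if "profiles" in d else base.profiles)
            feedback = (FeedbackModel(**d["feedback"]) if "feedback" in d
                        else base.feedback)
            dynamics = (LearningDynamics(**d["dynamics"]) if "dynamics" in d
                        else base.dynamics)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        cfg = cls(
            subjects={k: list(v) for k, v in d.get("subjects", base.subjects).items()},
            song_model=song_model,
            profiles=profiles,
            feedback=feedback,
            dynamics=dynamics,
            start_date=(date.fromisoformat(d["start_date"])
                        if "start_date" in d else base.start_date),
            training_days=d.get("training_days", base.training_days),
            gap_threshold_s=d.get("gap_threshold_s", base.gap_threshold_s),
            bin_size=d.get("bin_size", base.bin_size),
            entropy_log_base=d.get("entropy_log_base", base.entropy_log_base),
            overlap_threshold=d.get("overlap_threshold", base.overlap_threshold),
            chunk=list(d.get("chunk", base.chunk)),
            subject_variability=d.get("subject_variability", base.subject_variability),
            seed=d.get("seed", base.seed),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_config(
    n_subjects: int = 6,
    seed: int = 1,
    training_days: int = 4,
    bouts_scale: float = 1.0,
) -> RunConfig:
    """The standard study design: six subjects, three contexts each, orders
    balanced across subjects (all six permutations of MA/MF/MM).

    ``bouts_scale`` scales every context's daily bout count, for smaller
    test runs; 1.0 is the study-scale default.
    """
    orders = [list(p) for p in permutations(["MA", "MF", "MM"])]
    subjects = {f"bird{i + 1}": orders[i % len(orders)] for i in range(n_subjects)}
    profiles = default_profiles()
    if bouts_scale != 1.0:
        for p in profiles.values():
            p.bouts_per_day_mean = max(1.0, p.bouts_per_day_mean * bouts_scale)
    return RunConfig(
        subjects=subjects,
        song_model=default_song_model(),
        profiles=profiles,
        feedback=FeedbackModel(),
        dynamics=LearningDynamics(),
        training_days=training_days,
        seed=seed,
    )
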
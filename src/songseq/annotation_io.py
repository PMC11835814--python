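"""Syllable-annotation I/O, bout segmentation, and mixed-singing exclusion.

Song annotations are syllable-level event tables: one row per syllable with a
label, on/offset times (seconds, 0-based within the source audio file), the
source file id, the absolute timestamp at which that file started, and the
singer identity. Bouts are continuous periods of song: a silent gap of at
least ``gap_threshold`` seconds (2 s by convention) starts a new bout, and a
file boundary always ends a bout.

In the male–male housing condition the recording may contain song from both
males. Files in which the partner's syllables overlap the subject's bouts by
more than a configurable fraction of the subject's total bout duration are
excluded entirely, as are files containing only the partner's song.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "END",
    "SyllableEvent",
    "BranchRendition",
    "Bout",
    "ExclusionReport",
    "AnnotationError",
    "read_annotations",
    "write_annotations",
    "segment_bouts",
    "filter_mixed_bouts",
    "write_exclusion_report",
]

#: Sentinel outcome for a branch rendition that ends its bout.
END = "END"

ANNOTATION_COLUMNS = [
    "file_id",
    "file_start_iso8601",
    "singer",
    "label",
    "onset_s",
    "offset_s",
]


class AnnotationError(ValueError):
    """Raised for malformed or invalid annotation data."""


@dataclass(frozen=True)
class SyllableEvent:
    """One annotated syllable.

    Attributes
    ----------
    label : str
        Syllable class token (e.g. ``"x"``, ``"a"``).
    onset, offset : float
        Seconds within the source file; ``offset > onset``.
    file_id : str
        Opaque identifier of the source audio file.
    file_start : datetime
        Absolute wall-clock time at which the source file begins.
    singer : str
        Subject identifier of the bird producing the syllable.
    """

    label: str
    onset: float
    offset: float
    file_id: str
    file_start: datetime
    singer: str

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise AnnotationError(
                f"offset ({self.offset}) must exceed onset ({self.onset}) "
                f"for syllable {self.label!r} in file {self.file_id!r}"
            )
        if self.onset < 0:
            raise AnnotationError(f"negative onset {self.onset} in {self.file_id!r}")

    @property
    def abs_onset(self) -> datetime:
        return self.file_start + timedelta(seconds=self.onset)

    @property
    def abs_offset(self) -> datetime:
        return self.file_start + timedelta(seconds=self.offset)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BranchRendition:
    """One occurrence of the branch syllable and what followed it.

    ``outcome`` is the successor syllable token, or :data:`END` when the
    branch syllable ended the bout. ``is_catch`` marks renditions on which
    contingent feedback was deliberately withheld; ``wn_delivered`` marks
    actual white-noise delivery.
    """

    position: int
    outcome: str
    is_catch: bool = False
    wn_delivered: bool = False


@dataclass
class Bout:
    """An ordered, single-singer syllable sequence."""

    events: list[SyllableEvent]
    bout_start: datetime
    phase: str | None = None
    context: str | None = None
    renditions: list[BranchRendition] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    @property
    def singer(self) -> str:
        return self.events[0].singer

    @property
    def file_id(self) -> str:
        return self.events[0].file_id

    @property
    def bout_end(self) -> datetime:
        return self.events[-1].abs_offset

    @property
    def duration(self) -> float:
        return (self.bout_end - self.bout_start).total_seconds()

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ExclusionReport:
    """Outcome of the mixed-singing file exclusion."""

    excluded_file_ids: list[str]
    overlap_fraction_per_file: dict[str, float]

    def as_rows(self) -> list[dict]:
        rows = []
        for fid in sorted(self.overlap_fraction_per_file):
            rows.append(
                {
                    "file_id": fid,
                    "overlap_fraction": self.overlap_fraction_per_file[fid],
                    "excluded": fid in self.excluded_file_ids,
                }
            )
        return rows


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[SyllableEvent]:
    """Read a syllable-annotation CSV into validated events.

    The file must carry the header
    ``file_id,file_start_iso8601,singer,label,onset_s,offset_s``. Row order
    is preserved. Errors name the offending physical line (the header is
    line 1).
    """
    path = Path(path)
    events: list[SyllableEvent] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise AnnotationError(f"{path}: empty file, expected header")
        missing = [c for c in ANNOTATION_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise AnnotationError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                onset = float(row["onset_s"])
                offset = float(row["offset_s"])
                file_start = datetime.fromisoformat(row["file_start_iso8601"])
            except (TypeError, ValueError) as exc:
                raise AnnotationError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            try:
                events.append(
                    SyllableEvent(
                        label=row["label"],
                        onset=onset,
                        offset=offset,
                        file_id=row["file_id"],
                        file_start=file_start,
                        singer=row["singer"],
                    )
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}: invalid row at line {lineno}: {exc}") from exc
    return events


def write_annotations(events: Iterable[SyllableEvent], path: str | Path) -> None:
    """Write events to the annotation CSV dialect (UTF-8, with header)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_COLUMNS)
        for e in events:
            writer.writerow(
                [e.file_id, e.file_start.isoformat(), e.singer, e.label,
                 repr(float(e.onset)), repr(float(e.offset))]
            )


def write_exclusion_report(report: ExclusionReport, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file_id", "overlap_fraction", "excluded"])
        for row in report.as_rows():
            writer.writerow([row["file_id"], f"{row['overlap_fraction']:.6f}", row["excluded"]])


# ---------------------------------------------------------------------------
# Bout segmentation
# ---------------------------------------------------------------------------

def segment_bouts(
    events: Sequence[SyllableEvent],
    gap_threshold: float = 2.0,
) -> list[Bout]:
    """Segment a time-ordered event stream into bouts.

    A silent gap (next onset minus previous offset) of at least
    ``gap_threshold`` seconds starts a new bout. Events are partitioned per
    (singer, source file) before segmentation — a bout never spans a file
    boundary or mixes singers, and files that interleave in absolute time
    (e.g. two birds recorded in parallel) segment independently. Every
    input event ends up in exactly one bout.

    Parameters
    ----------
    events
        Events sorted by absolute onset (across all singers).
    gap_threshold
        Silence duration, in seconds, that separates bouts. Comparison is
        ``gap >= gap_threshold`` starts a new bout.

    Returns
    -------
    list of Bout, sorted by bout start time.
    """
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be positive")
    prev = None
    for e in events:
        if prev is not None and e.abs_onset < prev.abs_onset:
            raise ValueError("events must be sorted by absolute onset")
        prev = e

    streams: dict[tuple[str, str], list[SyllableEvent]] = {}
    for e in events:
        streams.setdefault((e.singer, e.file_id), []).append(e)

    bouts: list[Bout] = []
    for stream in streams.values():
        current: list[SyllableEvent] = []
        for e in stream:
            if current:
                gap = (e.abs_onset - current[-1].abs_offset).total_seconds()
                if gap >= gap_threshold:
                    bouts.append(Bout(events=current, bout_start=current[0].abs_onset))
                    current = []
            current.append(e)
        if current:
            bouts.append(Bout(events=current, bout_start=current[0].abs_onset))
    bouts.sort(key=lambda b: (b.bout_start, b.singer))
    return bouts


# ---------------------------------------------------------------------------
# Mixed-singing exclusion
# ---------------------------------------------------------------------------

def _interval_union(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        mlo, mhi = merged[-1]
        if lo <= mhi:
            merged[-1] = (mlo, max(mhi, hi))
        else:
            merged.append((lo, hi))
    return merged


def _overlap_length(a: list[tuple[float, float]], b: list[tuple[float, float]]) -> float:
    total = 0.0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def filter_mixed_bouts(
    bouts: Sequence[Bout],
    subject: str,
    overlap_threshold: float = 0.0,
) -> tuple[list[Bout], ExclusionReport]:
    """Apply the mixed-singing file exclusion for one subject.

    For every source file, the cross-singer overlap is the total length of
    the intersection between the union of the partner's syllable intervals
    and the union of the subject's bout spans, expressed as a fraction of
    the subject's total bout duration in that file. Files whose fraction
    exceeds ``overlap_threshold`` are excluded entirely; so are files that
    contain only partner song. Partner bouts never appear in the kept set.

    Returns the subject's bouts from kept files, plus an
    :class:`ExclusionReport` with per-file overlap fractions.
    """
    singers = {b.singer for b in bouts}
    if subject not in singers and bouts:
        raise ValueError(f"unknown singer id {subject!r}; singers present: {sorted(singers)}")

    by_file: dict[str, list[Bout]] = {}
    for b in bouts:
        by_file.setdefault(b.file_id, []).append(b)

    kept: list[Bout] = []
    excluded: list[str] = []
    fractions: dict[str, float] = {}
    for fid, file_bouts in by_file.items():
        subject_bouts = [b for b in file_bouts if b.singer == subject]
        partner_events = [e for b in file_bouts if b.singer != subject for e in b.events]
        if not subject_bouts:
            excluded.append(fid)
            fractions[fid] = 1.0 if partner_events else 0.0
            continue
        span_union = _interval_union(
            [(b.events[0].onset, b.events[-1].offset) for b in subject_bouts]
        )
        total_dur = sum(hi - lo for lo, hi in span_union)
        partner_union = _interval_union([(e.onset, e.offset) for e in partner_events])
        overlap = _overlap_length(span_union, partner_union)
        frac = overlap / total_dur if total_dur > 0 else 0.0
        fractions[fid] = min(frac, 1.0)
        if frac > overlap_threshold:
            excluded.append(fid)
        else:
            kept.extend(subject_bouts)
    kept.sort(key=lambda b: b.bout_start)
    return kept, ExclusionReport(excluded_file_ids=sorted(excluded),
                                 overlap_fraction_per_file=fractions)
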
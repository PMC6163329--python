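"""Timestamped annotation tiers: ELAN tab-delimited export and CSV.

A *tier* is one annotator's ordered sequence of labelled time segments for
one recording.  Times are integer milliseconds; segments are half-open
``[start, end)`` so adjacent segments tile without double counting.  Two
interchange formats are supported:

* ``elan-tsv`` — the 4-column tab-delimited ELAN export:
  ``tier-name <TAB> MM:SS.mmm <TAB> MM:SS.mmm <TAB> label``
* ``csv`` — ``run,annotator,start_ms,end_ms,label``

Reading never repairs the data: out-of-order rows are sorted, but overlaps
and gaps are only recorded (``has_overlaps`` / ``is_gap_free``) so that the
caller can decide.  Plan conversion requires a gap-free tier; reliability
scoring tolerates overlaps (slicing resolves them last-writer-wins).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import pandas as pd

from .domain import Domain
from .engine import Plan, labels_to_plan
from .errors import AnnotationFormatError

__all__ = [
    "Segment",
    "AnnotationTier",
    "parse_time",
    "format_time",
    "read_tier",
    "write_tier",
    "tier_to_plan",
]

_TIME_RE = re.compile(r"^(?:(\d+):)?(\d+):(\d{1,2}(?:\.\d{1,3})?)$")


def parse_time(text: str) -> int:
    """``MM:SS.mmm`` (optionally ``HH:MM:SS.mmm``) or integer milliseconds."""
    text = text.strip()
    if re.fullmatch(r"\d+", text):
        return int(text)
    m = _TIME_RE.match(text)
    if not m:
        raise AnnotationFormatError(f"malformed time stamp {text!r}")
    hours = int(m.group(1) or 0)
    minutes = int(m.group(2))
    seconds = float(m.group(3))
    return round(1000 * (hours * 3600 + minutes * 60 + seconds))


def format_time(ms: int) -> str:
    """Canonical ``MM:SS.mmm`` (minutes unbounded, as ELAN prints)."""
    minutes, rest = divmod(int(ms), 60_000)
    seconds, millis = divmod(rest, 1000)
    return f"{minutes:02d}:{seconds:02d}.{millis:03d}"


@dataclass(frozen=True)
class Segment:
    start: int  # ms, inclusive
    end: int  # ms, exclusive
    label: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationFormatError(
                f"segment {self.label!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationTier:
    """Ordered, timestamped labelled segments for one run and one annotator."""

    run_id: str = "run"
    annotator_id: str = "annotator"
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self):
        self.segments = sorted(self.segments, key=lambda s: (s.start, s.end, s.label))

    @property
    def end(self) -> int:
        """End of the last segment (0 for an empty tier)."""
        return max((s.end for s in self.segments), default=0)

    @property
    def has_overlaps(self) -> bool:
        return any(
            a.end > b.start for a, b in zip(self.segments, self.segments[1:])
        )

    @property
    def is_gap_free(self) -> bool:
        """Each segment's end equals the next segment's start."""
        return all(a.end == b.start for a, b in zip(self.segments, self.segments[1:]))

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]


def read_tier(
    text: str,
    format: str = "elan-tsv",
    run_id: str | None = None,
    annotator_id: str | None = None,
) -> AnnotationTier:
    """Parse annotation file content into a sorted tier.

    For ``elan-tsv`` the tier-name column doubles as the annotator id; for
    ``csv`` both ids come from the columns.  Explicit arguments override
    either.  Exact duplicate rows and ``end <= start`` are errors.
    """
    if format == "elan-tsv":
        rows = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise AnnotationFormatError(
                    f"line {lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            tier_name, start, end, label = (p.strip() for p in parts)
            rows.append((tier_name, parse_time(start), parse_time(end), label))
        file_annotator = rows[0][0] if rows else None
        segments = [Segment(s, e, lab) for _, s, e, lab in rows]
    elif format == "csv":
        if text.strip():
            df = pd.read_csv(io.StringIO(text), dtype={"run": str, "annotator": str})
            required = {"run", "annotator", "start_ms", "end_ms", "label"}
            if not required.issubset(df.columns):
                raise AnnotationFormatError(
                    f"csv must have columns {sorted(required)}, got {list(df.columns)}"
                )
        else:
            df = pd.DataFrame(columns=["run", "annotator", "start_ms", "end_ms", "label"])
        segments = [
            Segment(int(r.start_ms), int(r.end_ms), str(r.label)) for r in df.itertuples()
        ]
        if run_id is None and len(df):
            run_id = str(df["run"].iloc[0])
        file_annotator = str(df["annotator"].iloc[0]) if len(df) else None
    else:
        raise AnnotationFormatError(f"unknown format {format!r}")

    if len(set(segments)) != len(segments):
        dupes = sorted({s for s in segments if segments.count(s) > 1}, key=lambda s: s.start)
        raise AnnotationFormatError(
            f"duplicate rows: {', '.join(f'{s.label}@{s.start}' for s in dupes)}"
        )
    return AnnotationTier(
        run_id=run_id or "run",
        annotator_id=annotator_id or file_annotator or "annotator",
        segments=segments,
    )


def write_tier(tier: AnnotationTier, format: str = "elan-tsv") -> str:
    """Serialise a tier; ``read_tier(write_tier(t), fmt)`` is the identity."""
    if format == "elan-tsv":
        lines = [
            f"{tier.annotator_id}\t{format_time(s.start)}\t{format_time(s.end)}\t{s.label}"
            for s in tier.segments
        ]
        return "\n".join(lines) + ("\n" if lines else "")
    if format == "csv":
        df = pd.DataFrame(
            {
                "run": [tier.run_id] * len(tier.segments),
                "annotator": [tier.annotator_id] * len(tier.segments),
                "start_ms": [s.start for s in tier.segments],
                "end_ms": [s.end for s in tier.segments],
                "label": [s.label for s in tier.segments],
            }
        )
        return df.to_csv(index=False)
    raise AnnotationFormatError(f"unknown format {format!r}")


def tier_to_plan(tier: AnnotationTier, domain: Domain) -> Plan:
    """Convert a gap-free tier into a plan: one step per segment, at its start.

    Raises :class:`AnnotationFormatError` if the tier has gaps or overlaps,
    and :class:`~semannot.errors.UnresolvableLabelError` listing every label
    outside the domain's label set (with 1-based segment indices), which is
    the handle for the annotate-validate-repair loop.
    """
    if not tier.is_gap_free:
        raise AnnotationFormatError(
            f"tier {tier.run_id}/{tier.annotator_id} is not gap-free; "
            "plan conversion needs tiling segments"
        )
    return labels_to_plan(domain, [(s.start, s.label) for s in tier.segments])
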
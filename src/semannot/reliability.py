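"""Interrater reliability between two annotation tiers.

The unit of analysis is a fixed-resolution time slice (default 10 ms —
finer than the shortest published segment): slice *i* carries the label of
the segment covering ``i * resolution``, or the reserved ``NONE`` label
where nothing does.  On the two aligned slice series we compute

* raw agreement  IRa = sum_k p(k, k),
* Cohen's kappa  IRk = (p_o - p_e) / (1 - p_e),  p_e = sum_k p_a(k) p_b(k),
* Krippendorff's alpha  IRalpha = 1 - D_o / D_e  for nominal data with the
  slices as units and two observers (no missing data: both series are
  total over the horizon).

Comparison is on the full ground label ("take-bowl-cupboard") by default;
``class_level=True`` compares only the action class ("take").  NONE slices
count as real disagreements unless ``ignore_none=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationTier
from .errors import MetricsUndefinedError

__all__ = [
    "NONE_LABEL",
    "SliceSeries",
    "ReliabilityResult",
    "DiffInterval",
    "slice_tier",
    "score_series",
    "interrater",
    "diff_segments",
    "learning_curve",
]

#: Reserved label for unannotated time; distinct from every domain label
#: (domain labels are hyphenated lower-case tokens).
NONE_LABEL = "NONE"


@dataclass
class SliceSeries:
    """Labels on a fixed time grid over ``[0, horizon)``."""

    resolution: int
    labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)


def slice_tier(tier: AnnotationTier, resolution: int, horizon: int) -> SliceSeries:
    """Sample the tier at ``i * resolution`` for i in [0, ceil(horizon/res)).

    Overlapping segments resolve last-writer-wins (later start, then later
    end, wins), matching the tier's sorted order.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1 ms")
    n = math.ceil(horizon / resolution)
    labels = [NONE_LABEL] * n
    for seg in tier.segments:  # sorted; later segments overwrite earlier ones
        first = math.ceil(seg.start / resolution)
        last = math.ceil(seg.end / resolution)  # exclusive: [start, end)
        for i in range(first, min(last, n)):
            labels[i] = seg.label
    return SliceSeries(resolution=resolution, labels=labels)


@dataclass
class ReliabilityResult:
    """IRa / IRk / IRalpha plus the full label-by-label confusion table."""

    agreement: float
    kappa: float
    alpha: float
    n_slices: int
    confusion: pd.DataFrame = None

    def to_dict(self) -> dict:
        return {
            "agreement": self.agreement,
            "kappa": self.kappa,
            "alpha": self.alpha,
            "n_slices": self.n_slices,
        }


def score_series(labels_a, labels_b) -> ReliabilityResult:
    """Reliability metrics on two aligned label series of equal length."""
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"series lengths differ: {len(a)} vs {len(b)}")
    n = len(a)
    if n == 0:
        raise MetricsUndefinedError("no slices: metrics are undefined on empty input")

    confusion = pd.crosstab(
        pd.Series(a, name="annotator_a"), pd.Series(b, name="annotator_b"), dropna=False
    )
    labels = sorted(set(confusion.index) | set(confusion.columns))
    confusion = confusion.reindex(index=labels, columns=labels, fill_value=0)

    counts = confusion.to_numpy(dtype=float)
    p_o = np.trace(counts) / n
    p_a = counts.sum(axis=1) / n
    p_b = counts.sum(axis=0) / n
    p_e = float(p_a @ p_b)
    if p_e >= 1.0 - 1e-12:
        # both series constant on the same label: perfect by convention
        kappa = 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)

    # Krippendorff's alpha, nominal difference, two observers, no missing data
    pooled = counts.sum(axis=1) + counts.sum(axis=0)  # 2n values in total
    total = 2 * n
    d_o = 1.0 - p_o  # per-unit pair disagreement
    if total > 1:
        d_e = 1.0 - float(pooled @ (pooled - 1)) / (total * (total - 1))
    else:
        d_e = 0.0
    alpha = 1.0 if d_e <= 1e-12 and d_o <= 1e-12 else (
        0.0 if d_e <= 1e-12 else 1.0 - d_o / d_e
    )

    return ReliabilityResult(
        agreement=float(p_o),
        kappa=float(kappa),
        alpha=float(alpha),
        n_slices=n,
        confusion=confusion,
    )


def _to_class(label: str) -> str:
    return label if label == NONE_LABEL else label.split("-", 1)[0]


def interrater(
    a: AnnotationTier,
    b: AnnotationTier,
    resolution: int = 10,
    class_level: bool = False,
    ignore_none: bool = False,
) -> ReliabilityResult:
    """Slice both tiers onto a common grid and score them.

    The horizon is the maximum end time over both tiers.  Both tiers must
    describe the same run.
    """
    if a.run_id != b.run_id:
        raise ValueError(f"tiers describe different runs: {a.run_id!r} vs {b.run_id!r}")
    horizon = max(a.end, b.end)
    if horizon == 0:
        raise MetricsUndefinedError("both tiers are empty: metrics are undefined")
    sa = slice_tier(a, resolution, horizon).labels
    sb = slice_tier(b, resolution, horizon).labels
    if class_level:
        sa = [_to_class(x) for x in sa]
        sb = [_to_class(x) for x in sb]
    if ignore_none:
        keep = [i for i, (x, y) in enumerate(zip(sa, sb)) if x != NONE_LABEL or y != NONE_LABEL]
        sa = [sa[i] for i in keep]
        sb = [sb[i] for i in keep]
        if not sa:
            raise MetricsUndefinedError("no labelled slices after dropping NONE")
    return score_series(sa, sb)


# ---------------------------------------------------------------------------
# disagreement diagnostics


@dataclass(frozen=True)
class DiffInterval:
    start: int
    end: int
    label_a: str
    label_b: str
    kind: str  # "boundary_shift" | "substitution"


def _coverage(tier: AnnotationTier, boundaries: list[int]) -> list[str]:
    """Label of each elementary interval [b_i, b_{i+1}), last-writer-wins."""
    out = [NONE_LABEL] * (len(boundaries) - 1)
    for seg in tier.segments:
        for i in range(len(boundaries) - 1):
            if seg.start <= boundaries[i] and boundaries[i + 1] <= seg.end:
                out[i] = seg.label
    return out


def _label_near(labels: list[str], idx: int, direction: int) -> str | None:
    j = idx + direction
    if 0 <= j < len(labels):
        return labels[j]
    return None


def diff_segments(
    a: AnnotationTier, b: AnnotationTier, window: int = 1000
) -> list[DiffInterval]:
    """Maximal intervals where the two tiers disagree, with both labels.

    Each interval is classified as a ``boundary_shift`` — the same label
    appears in the other tier immediately adjacent and the interval is no
    longer than ``window`` ms — or a ``substitution``.  Purely diagnostic.
    """
    if a.run_id != b.run_id:
        raise ValueError(f"tiers describe different runs: {a.run_id!r} vs {b.run_id!r}")
    horizon = max(a.end, b.end)
    points = sorted(
        {0, horizon}
        | {s.start for s in a.segments}
        | {s.end for s in a.segments}
        | {s.start for s in b.segments}
        | {s.end for s in b.segments}
    )
    points = [p for p in points if p <= horizon]
    if len(points) < 2:
        return []
    la = _coverage(a, points)
    lb = _coverage(b, points)

    # merge consecutive elementary intervals with the same disagreeing pair
    raw: list[list] = []
    for i in range(len(points) - 1):
        if la[i] == lb[i]:
            continue
        if raw and raw[-1][1] == points[i] and raw[-1][2] == la[i] and raw[-1][3] == lb[i]:
            raw[-1][1] = points[i + 1]
        else:
            raw.append([points[i], points[i + 1], la[i], lb[i], i])
    out = []
    for start, end, x, y, i in raw:
        # index of the last elementary interval inside this diff
        j = i
        while j + 1 < len(points) - 1 and points[j + 1] < end:
            j += 1
        neighbours = {
            _label_near(la, i, -1),
            _label_near(la, j, +1),
            _label_near(lb, i, -1),
            _label_near(lb, j, +1),
        }
        shift = (end - start) <= window and (x in neighbours or y in neighbours)
        out.append(DiffInterval(start, end, x, y, "boundary_shift" if shift else "substitution"))
    return out


def learning_curve(
    pairs: list[tuple[AnnotationTier, AnnotationTier]],
    resolution: int = 10,
    **kwargs,
) -> tuple[list[ReliabilityResult], list[float], float]:
    """Reliability per (A, B) pair in order, successive agreement
    differences, and the slope of a least-squares line of agreement
    against pair index (the training-curve trend).
    """
    if not pairs:
        raise ValueError("learning_curve needs at least one pair of tiers")
    results = [interrater(a, b, resolution=resolution, **kwargs) for a, b in pairs]
    agreements = [r.agreement for r in results]
    diffs = [b - a for a, b in zip(agreements, agreements[1:])]
    if len(agreements) > 1:
        slope = float(np.polyfit(np.arange(len(agreements)), agreements, 1)[0])
    else:
        slope = 0.0
    return results, diffs, slope
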
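"""Mining causally-correct behavioural routines from validated plans.

Because every input plan has been validated against the domain, the
transition structures estimated here contain no causally impossible action
succession by construction — unlike models estimated from free-text labels.

Operations: a first-order Markov model over action classes (or ground
labels) with *initial*/*finish* pseudo-states; probability-over-normalised-
time curves for state predicates across runs; an initial-state table with
change-point flags across a run series; and per-object location timelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain import Domain, parse_term, term_str
from .engine import Plan, StateTrajectory, validate_plan

__all__ = [
    "INITIAL_STATE",
    "FINISH_STATE",
    "TransitionModel",
    "PropertyCurve",
    "build_markov",
    "property_curve",
    "initial_state_table",
    "location_timeline",
    "transition_model_to_dot",
    "verify_causal_edges",
]

INITIAL_STATE = "initial"
FINISH_STATE = "finish"


@dataclass
class TransitionModel:
    """First-order transition counts and ML probabilities between states.

    States are action classes (or ground labels) plus the ``initial`` and
    ``finish`` pseudo-states.  No smoothing: a zero count means the
    transition was never observed, and — the plans being validated — that
    absence is causally meaningful.
    """

    level: str  # "class" | "ground"
    states: list[str] = field(default_factory=list)
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def probabilities(self) -> dict[tuple[str, str], float]:
        row_totals: dict[str, int] = {}
        for (src, _), c in self.counts.items():
            row_totals[src] = row_totals.get(src, 0) + c
        return {
            (src, dst): c / row_totals[src] for (src, dst), c in self.counts.items()
        }

    def to_dataframe(self) -> pd.DataFrame:
        probs = self.probabilities
        rows = [
            {
                "from": src,
                "to": dst,
                "count": c,
                "probability": probs[(src, dst)],
            }
            for (src, dst), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["from", "to", "count", "probability"])


def _step_name(action, level: str) -> str:
    return action.action_class if level == "class" else action.label


def build_markov(plans: list[Plan], level: str = "class") -> TransitionModel:
    """Estimate a first-order Markov model from validated plans.

    Every plan contributes ``initial -> a_1 -> ... -> a_n -> finish``.
    Probabilities are maximum-likelihood row normalisations of the counts.
    """
    if not plans:
        raise ValueError("build_markov needs at least one plan")
    if level not in {"class", "ground"}:
        raise ValueError(f"level must be 'class' or 'ground', got {level!r}")
    counts: dict[tuple[str, str], int] = {}
    states: dict[str, None] = {INITIAL_STATE: None}
    for plan in plans:
        names = [INITIAL_STATE] + [_step_name(s.action, level) for s in plan] + [FINISH_STATE]
        for name in names:
            states.setdefault(name, None)
        for src, dst in zip(names, names[1:]):
            counts[(src, dst)] = counts.get((src, dst), 0) + 1
    return TransitionModel(level=level, states=list(states), counts=counts)


def transition_model_to_dot(model: TransitionModel, max_penwidth: float = 5.0) -> str:
    """DOT text: edge pen-width proportional to probability, count as label."""
    probs = model.probabilities
    lines = ["digraph routines {", "  rankdir=LR;"]
    for state in model.states:
        shape = "doublecircle" if state in (INITIAL_STATE, FINISH_STATE) else "ellipse"
        lines.append(f'  "{state}" [shape={shape}];')
    for (src, dst), c in sorted(model.counts.items()):
        p = probs[(src, dst)]
        width = max(0.3, max_penwidth * p)
        lines.append(
            f'  "{src}" -> "{dst}" [penwidth={width:.2f}, label="{c}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


@dataclass
class PropertyCurve:
    """Probability of a state predicate per normalised-time bin across runs."""

    property: str
    bins: int
    probability: np.ndarray = None
    n_runs: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(self.bins),
                "time_fraction": (np.arange(self.bins) + 0.5) / self.bins,
                "probability": self.probability,
            }
        )


def _predicate(pred):
    """Accept ``(term, value)`` (term as tuple or string) or a callable."""
    if callable(pred):
        return pred, getattr(pred, "__name__", "predicate")
    term, value = pred
    if isinstance(term, str):
        term = parse_term(term)
    name = f"{term_str(term)} = {value}"
    return (lambda state: state[term] == value), name


def property_curve(
    trajectories: list[StateTrajectory],
    predicate,
    bins: int = 100,
    durations: list[int] | None = None,
) -> PropertyCurve:
    """Fraction of runs whose state satisfies ``predicate``, per time bin.

    Each run is resampled onto ``bins`` equal bins of its *own* duration
    (runs differ in length), evaluating the piecewise-constant state at
    each bin midpoint.  ``durations`` gives each run's total length in ms;
    by default the time of the last state change is used.
    """
    if not trajectories:
        raise ValueError("property_curve needs at least one trajectory")
    fn, name = _predicate(predicate)
    if durations is None:
        durations = [traj.times[-1] for traj in trajectories]
    acc = np.zeros(bins)
    for traj, duration in zip(trajectories, durations):
        if duration <= 0:
            raise ValueError("zero-duration run")
        times = np.asarray(traj.times)
        mids = (np.arange(bins) + 0.5) / bins * duration
        idx = np.searchsorted(times, mids, side="right") - 1
        acc += [1.0 if fn(traj.states[i]) else 0.0 for i in idx]
    return PropertyCurve(
        property=name, bins=bins, probability=acc / len(trajectories), n_runs=len(trajectories)
    )


def initial_state_table(
    runs: list,
    fluents: list,
    run_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Step-0 value of each listed fluent per run, with change-point flags.

    ``runs`` may be :class:`~semannot.domain.Domain` objects or
    :class:`~semannot.engine.StateTrajectory` objects; ``fluents`` are
    ground terms (tuples or ``"is-at(knife)"`` strings).  A run is flagged
    (``changed``) when any listed fluent's value differs from the previous
    run's — exact comparison, no statistics: a changed experimental setup
    is a deterministic event.
    """
    if not runs:
        raise ValueError("initial_state_table needs at least one run")
    terms = [parse_term(t) if isinstance(t, str) else t for t in fluents]
    rows = []
    for run in runs:
        state = run.initial_state() if isinstance(run, Domain) else run.states[0]
        for term in terms:
            if term not in state:
                raise ValueError(f"fluent {term_str(term)} not declared in this run's domain")
        rows.append({term_str(t): state[t] for t in terms})
    df = pd.DataFrame(rows)
    df.insert(0, "run", run_ids if run_ids is not None else list(range(len(runs))))
    changed = [False]
    for i in range(1, len(rows)):
        changed.append(rows[i] != rows[i - 1])
    df["changed"] = changed
    return df


def location_timeline(
    trajectory: StateTrajectory,
    objects: list[str],
    fluent: str = "is-at",
) -> dict[str, list[tuple[int, str]]]:
    """Per-object compressed step function of its location fluent.

    One ``(time_ms, location)`` entry per change, starting with the initial
    location at time 0.  ``len(entries) - 1`` equals the number of plan
    steps that wrote the object's location.
    """
    out: dict[str, list[tuple[int, str]]] = {}
    for obj in objects:
        term = (fluent, (obj,))
        if term not in trajectory.states[0]:
            raise ValueError(f"object {obj!r} has no {fluent!r} fluent")
        entries: list[tuple[int, str]] = []
        for t, state in zip(trajectory.times, trajectory.states):
            value = state[term]
            if not entries or entries[-1][1] != value:
                entries.append((t, value))
        out[obj] = entries
    return out


def verify_causal_edges(model: TransitionModel, plans: list[Plan], domain: Domain) -> int:
    """Replay-check: count of model transitions NOT witnessed by consecutive
    steps of some plan that validates against ``domain``.  Zero for models
    built from validated plans — the causal-correctness guarantee.
    """
    witnessed: set[tuple[str, str]] = set()
    for plan in plans:
        report, _ = validate_plan(domain, plan)
        if not report.valid:
            continue
        names = [INITIAL_STATE] + [_step_name(s.action, model.level) for s in plan] + [FINISH_STATE]
        witnessed.update(zip(names, names[1:]))
    return sum(1 for edge in model.counts if edge not in witnessed)
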
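"""Grounding, precondition checking, effect application, and plan validation.

A *state* is a total mapping from ground fluent terms to values.  A
*ground action* is a schema with entities bound to its parameters; its
printable label is the annotation vocabulary element.  A timestamped label
sequence is a *plan*; validating it means replaying it from the initial
state and checking every precondition, which yields either a full
*state trajectory* or a report pinpointing the first causally impossible
step (§ the two possible causes: the domain is too strict, or the label
sequence is impossible — the report words the hint, a human decides).

Actions are instantaneous: each plan step is applied at its start time and
the state is piecewise-constant in between.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

from .domain import (
    ActionSchema,
    And,
    Cmp,
    Domain,
    EffectItem,
    FluentTerm,
    Lit,
    Not,
    Sym,
    term_str,
)
from .errors import EvaluationError, PreconditionError, SemannotError, UnresolvableLabelError

__all__ = [
    "GroundAction",
    "Plan",
    "PlanStep",
    "State",
    "StateTrajectory",
    "ValidationReport",
    "ground_actions",
    "resolve_label",
    "applicable_actions",
    "apply_action",
    "validate_plan",
    "query_property",
]

State = dict  # ground fluent term -> value


@dataclass(frozen=True)
class GroundAction:
    """A schema applied to concrete entities, plus pre-substituted semantics."""

    schema: ActionSchema
    arguments: tuple[str, ...]
    label: str
    precondition: object = None  # ground Expression
    effects: tuple[EffectItem, ...] = ()

    @property
    def action_class(self) -> str:
        return self.schema.name

    def __repr__(self) -> str:
        return f"GroundAction({self.label})"


@dataclass(frozen=True)
class PlanStep:
    time: int  # milliseconds
    action: GroundAction


Plan = list  # list[PlanStep]


@dataclass
class StateTrajectory:
    """Initial state plus one successor per plan step.

    ``times[i]`` is the millisecond at which ``states[i]`` became current
    (``times[0]`` is 0 for the initial state).
    """

    states: list[State] = field(default_factory=list)
    times: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    def value_at_step(self, term: tuple, step: int):
        return self.states[step][term]

    def value_at_time(self, term: tuple, t: int):
        """State value at absolute time ``t`` (piecewise-constant)."""
        idx = 0
        for i, ti in enumerate(self.times):
            if ti <= t:
                idx = i
            else:
                break
        return self.states[idx][term]


@dataclass
class ValidationReport:
    """Verdict of plan validation plus first-failure diagnostics."""

    verdict: str  # "valid" | "invalid"
    failing_step: int | None = None  # 1-based step index
    failed_condition: str | None = None
    state_excerpt: dict = field(default_factory=dict)
    note: str = ""

    @property
    def valid(self) -> bool:
        return self.verdict == "valid"

    def to_json(self) -> str:
        return json.dumps(
            {
                "verdict": self.verdict,
                "failing_step": self.failing_step,
                "failed_condition": self.failed_condition,
                "state_excerpt": self.state_excerpt,
                "note": self.note,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# grounding

_CACHE_ATTR = "_semannot_ground_cache"


def _substitute_term(term, binding: dict):
    if isinstance(term, Sym) and term.name.startswith("?"):
        return Sym(binding[term.name[1:]])
    if isinstance(term, FluentTerm):
        args = tuple(binding[a[1:]] if a.startswith("?") else a for a in term.args)
        return FluentTerm(term.name, args)
    return term


def _substitute(expr, binding: dict):
    if isinstance(expr, And):
        return And(tuple(_substitute(i, binding) for i in expr.items))
    if isinstance(expr, Not):
        return Not(_substitute(expr.item, binding))
    if isinstance(expr, Cmp):
        return Cmp(expr.op, _substitute_term(expr.lhs, binding), _substitute_term(expr.rhs, binding))
    raise EvaluationError(f"cannot substitute into {expr!r}")


def ground_actions(domain: Domain) -> list[GroundAction]:
    """All type-correct groundings of all schemas, cached on the domain.

    Order: schema declaration order, then lexicographic by arguments —
    identical to the label enumeration order.
    """
    cache = getattr(domain, _CACHE_ATTR, None)
    if cache is not None:
        return cache[0]
    actions: list[GroundAction] = []
    by_label: dict[str, GroundAction] = {}
    for schema in domain.schemas:
        pools = [domain.entities_of_type(t) for _, t in schema.parameters]
        roles = [r for r, _ in schema.parameters]
        for combo in itertools.product(*pools):
            binding = dict(zip(roles, combo))
            ga = GroundAction(
                schema=schema,
                arguments=tuple(combo),
                label=schema.label_for(binding),
                precondition=_substitute(schema.precondition, binding),
                effects=tuple(
                    EffectItem(
                        e.op,
                        _substitute_term(e.target, binding),
                        _substitute_term(e.value, binding),
                    )
                    for e in schema.effects
                ),
            )
            actions.append(ga)
            by_label.setdefault(ga.label, ga)
    object.__setattr__(domain, _CACHE_ATTR, (actions, by_label))
    return actions


def resolve_label(domain: Domain, label: str) -> GroundAction:
    """Map an annotation label back to its ground action.

    Raises :class:`UnresolvableLabelError` if the label is not in L.
    """
    ground_actions(domain)
    by_label = getattr(domain, _CACHE_ATTR)[1]
    try:
        return by_label[label]
    except KeyError:
        raise UnresolvableLabelError([(0, label)]) from None


# ---------------------------------------------------------------------------
# evaluation

def _eval_term(term, state: State):
    if isinstance(term, Lit):
        return term.value
    if isinstance(term, Sym):
        return term.name
    if isinstance(term, FluentTerm):
        key = (term.name, term.args)
        try:
            return state[key]
        except KeyError:
            raise EvaluationError(f"unknown fluent term {term}") from None
    raise EvaluationError(f"cannot evaluate {term!r}")


def _as_number(value, ctx) -> float:
    if isinstance(value, bool):
        raise EvaluationError(f"boolean operand in numeric comparison: {ctx}")
    if isinstance(value, (int, float)):
        return value
    try:
        return int(value)
    except (TypeError, ValueError):
        raise EvaluationError(f"non-numeric operand {value!r} in {ctx}") from None


def eval_expression(expr, state: State) -> bool:
    """Evaluate a ground expression in a state."""
    if isinstance(expr, And):
        return all(eval_expression(i, state) for i in expr.items)
    if isinstance(expr, Not):
        return not eval_expression(expr.item, state)
    if isinstance(expr, Cmp):
        lhs = _eval_term(expr.lhs, state)
        rhs = _eval_term(expr.rhs, state)
        if expr.op == "=":
            if isinstance(lhs, bool) or isinstance(rhs, bool):
                return lhs is rhs if isinstance(lhs, bool) and isinstance(rhs, bool) else lhs == rhs
            if isinstance(lhs, (int, float)) != isinstance(rhs, (int, float)):
                # entity named like a number compared against a number
                try:
                    return _as_number(lhs, expr) == _as_number(rhs, expr)
                except EvaluationError:
                    return False
            return lhs == rhs
        a, b = _as_number(lhs, expr), _as_number(rhs, expr)
        if expr.op == "<":
            return a < b
        if expr.op == "<=":
            return a <= b
        if expr.op == ">=":
            return a >= b
        if expr.op == ">":
            return a > b
    raise EvaluationError(f"cannot evaluate expression {expr!r}")


def first_failed_condition(expr, state: State):
    """The first (leftmost, innermost) unsatisfied sub-expression, or None."""
    if isinstance(expr, And):
        for item in expr.items:
            failed = first_failed_condition(item, state)
            if failed is not None:
                return failed
        return None
    if eval_expression(expr, state):
        return None
    return expr


def _expr_terms(expr) -> list[FluentTerm]:
    if isinstance(expr, And):
        return [t for i in expr.items for t in _expr_terms(i)]
    if isinstance(expr, Not):
        return _expr_terms(expr.item)
    if isinstance(expr, Cmp):
        return [t for t in (expr.lhs, expr.rhs) if isinstance(t, FluentTerm)]
    return []


def state_excerpt(expr, state: State) -> dict:
    """Values of the fluents mentioned by ``expr`` — the report's context."""
    return {term_str((t.name, t.args)): state[(t.name, t.args)] for t in _expr_terms(expr)}


# ---------------------------------------------------------------------------
# operations

def applicable_actions(domain: Domain, state: State) -> list[GroundAction]:
    """Exactly those ground actions whose precondition holds in ``state``."""
    return [ga for ga in ground_actions(domain) if eval_expression(ga.precondition, state)]


def apply_action(domain: Domain, state: State, action: GroundAction, check: bool = True) -> State:
    """Successor state after ``action``; all unwritten fluents are unchanged."""
    if check:
        failed = first_failed_condition(action.precondition, state)
        if failed is not None:
            raise PreconditionError(action.label, str(failed))
    new = dict(state)
    for eff in action.effects:
        key = (eff.target.name, eff.target.args)
        if key not in new:
            raise EvaluationError(f"effect writes unknown fluent term {eff.target}")
        if eff.op == "assign":
            value = _eval_term(eff.value, new)
            new[key] = value
        else:
            amount = _as_number(_eval_term(eff.value, state), eff)
            base = _as_number(state[key], eff)
            new[key] = base + amount if eff.op == "increase" else base - amount
    return new


def validate_plan(domain: Domain, plan: Plan) -> tuple[ValidationReport, StateTrajectory]:
    """Replay ``plan`` from the initial state, checking causal validity.

    Returns the report and the trajectory (full on success, truncated at
    the first failing step otherwise).  Steps are numbered from 1 in the
    report.  A pure function of ``(domain, plan)``.
    """
    state = domain.initial_state()
    traj = StateTrajectory(states=[state], times=[0])
    for i, step in enumerate(plan):
        failed = first_failed_condition(step.action.precondition, state)
        if failed is not None:
            report = ValidationReport(
                verdict="invalid",
                failing_step=i + 1,
                failed_condition=str(failed),
                state_excerpt=state_excerpt(failed, state),
                note=(
                    f"step {i + 1} ({step.action.label!r}) is not executable here: "
                    "either the domain's constraints are too strict for what was "
                    "observed, or the label sequence is impossible. Inspect the "
                    "annotation at this step first; if it is right, relax the domain."
                ),
            )
            return report, traj
        state = apply_action(domain, state, step.action, check=False)
        traj.states.append(state)
        traj.times.append(step.time)
    return ValidationReport(verdict="valid"), traj


def query_property(trajectory: StateTrajectory, term) -> list[tuple[int, object]]:
    """Value of a ground fluent term after every step (step 0 = initial).

    ``term`` may be a ``(name, args)`` tuple or a string like
    ``"is-at(knife)"``.
    """
    from .domain import parse_term

    if isinstance(term, str):
        term = parse_term(term)
    if term not in trajectory.states[0]:
        raise SemannotError(f"unknown fluent term {term_str(term)}")
    return [(i, s[term]) for i, s in enumerate(trajectory.states)]


def labels_to_plan(domain: Domain, timed_labels: list[tuple[int, str]]) -> Plan:
    """Build a plan from ``(time_ms, label)`` pairs, resolving every label.

    Collects *all* unresolvable labels (1-based indices) before raising, so
    an annotation can be repaired in one pass.
    """
    ground_actions(domain)
    by_label = getattr(domain, _CACHE_ATTR)[1]
    missing = [(i + 1, lab) for i, (_, lab) in enumerate(timed_labels) if lab not in by_label]
    if missing:
        raise UnresolvableLabelError(missing)
    return [PlanStep(t, by_label[lab]) for t, lab in timed_labels]
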
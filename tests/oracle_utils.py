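"""Independent brute-force oracles for cross-checking the plan engine.

Everything here re-derives semantics naively from the Domain declarations:
nested-loop grounding, binding-at-evaluation-time expression checking (the
engine pre-substitutes instead), and a per-millisecond slicer.  Nothing is
shared with the implementation paths under test.
"""

from __future__ import annotations

import itertools

from semannot.domain import And, Cmp, Domain, FluentTerm, Lit, Not, Sym


def subtype_chain(domain: Domain, tname: str) -> list[str]:
    chain = []
    t = tname
    while t is not None:
        chain.append(t)
        t = domain.types[t].parent if t in domain.types else None
    return chain


def entities_of(domain: Domain, tname: str) -> list[str]:
    out = []
    for e in domain.entities.values():
        if tname == "object" or tname in subtype_chain(domain, e.type):
            out.append(e.name)
    return sorted(out)


def _resolve_arg(arg: str, binding: dict) -> str:
    return binding[arg] if arg.startswith("?") else arg


def _term_value(term, state, binding):
    if isinstance(term, Lit):
        return term.value
    if isinstance(term, Sym):
        return _resolve_arg(term.name, binding)
    if isinstance(term, FluentTerm):
        key = (term.name, tuple(_resolve_arg(a, binding) for a in term.args))
        return state[key]
    raise TypeError(term)


def _numeric(v):
    if isinstance(v, bool):
        raise TypeError("boolean in numeric position")
    if isinstance(v, (int, float)):
        return v
    return int(v)


def naive_holds(expr, state, binding) -> bool:
    if isinstance(expr, And):
        for sub in expr.items:
            if not naive_holds(sub, state, binding):
                return False
        return True
    if isinstance(expr, Not):
        return not naive_holds(expr.item, state, binding)
    if isinstance(expr, Cmp):
        lhs = _term_value(expr.lhs, state, binding)
        rhs = _term_value(expr.rhs, state, binding)
        if expr.op == "=":
            if isinstance(lhs, bool) or isinstance(rhs, bool):
                return lhs == rhs
            try:
                return _numeric(lhs) == _numeric(rhs)
            except (TypeError, ValueError):
                return lhs == rhs
        table = {
            "<": lambda a, b: a < b,
            "<=": lambda a, b: a <= b,
            ">=": lambda a, b: a >= b,
            ">": lambda a, b: a > b,
        }
        return table[expr.op](_numeric(lhs), _numeric(rhs))
    raise TypeError(expr)


def naive_groundings(domain: Domain):
    """Yield (schema, binding, label) for every type-correct instantiation."""
    for schema in domain.schemas:
        pools = [entities_of(domain, t) for _, t in schema.parameters]
        for combo in itertools.product(*pools):
            binding = {f"?{r}": c for (r, _), c in zip(schema.parameters, combo)}
            label = schema.label_template.format(
                **{r: c for (r, _), c in zip(schema.parameters, combo)}
            )
            yield schema, binding, label


def naive_labels(domain: Domain) -> list[str]:
    seen: dict[str, None] = {}
    for _, _, label in naive_groundings(domain):
        seen.setdefault(label, None)
    return list(seen)


def naive_applicable_labels(domain: Domain, state: dict) -> set[str]:
    return {
        label
        for schema, binding, label in naive_groundings(domain)
        if naive_holds(schema.precondition, state, binding)
    }


def naive_apply(domain: Domain, state: dict, schema, binding) -> dict:
    new = dict(state)
    for eff in schema.effects:
        key = (eff.target.name, tuple(_resolve_arg(a, binding) for a in eff.target.args))
        if eff.op == "assign":
            new[key] = _term_value(eff.value, state, binding)
        else:
            delta = _numeric(_term_value(eff.value, state, binding))
            new[key] = _numeric(state[key]) + (delta if eff.op == "increase" else -delta)
    return new


def naive_simulate(domain: Domain, labels: list[str]):
    """Replay a label sequence; returns (states, failed_index or None)."""
    lookup = {}
    for schema, binding, label in naive_groundings(domain):
        lookup.setdefault(label, (schema, binding))
    state = {}
    for fl in domain.fluents.values():
        pools = [entities_of(domain, t) for t in fl.parameter_types]
        for combo in itertools.product(*pools):
            key = (fl.name, tuple(combo))
            if key in domain.initial:
                state[key] = domain.initial[key]
            else:
                state[key] = False if fl.range == "boolean" else 0
    states = [state]
    for i, label in enumerate(labels):
        schema, binding = lookup[label]
        if not naive_holds(schema.precondition, state, binding):
            return states, i
        state = naive_apply(domain, state, schema, binding)
        states.append(state)
    return states, None


def naive_slice(tier, resolution: int, horizon: int) -> list[str]:
    """Per-millisecond scan, then stride — the dumbest correct slicer."""
    per_ms = ["NONE"] * horizon
    for seg in tier.segments:
        for t in range(seg.start, min(seg.end, horizon)):
            per_ms[t] = seg.label
    out = []
    t = 0
    while t < horizon:
        out.append(per_ms[t])
        t += resolution
    return out


# ---------------------------------------------------------------------------
# random domain generation (text -> parse_domain exercises the full stack)


def random_domain_text(rng, max_entities: int = 6, max_schemas: int = 5) -> str:
    """A random but always-well-formed domain file."""
    has_sub = bool(rng.integers(2))
    n0 = int(rng.integers(2, max_entities + 1))
    ents_t0 = [f"a{i}" for i in range(n0)]
    ents_t1 = [f"b{i}" for i in range(int(rng.integers(0, 4)))] if has_sub else []
    all_ents = ents_t0 + ents_t1

    types = "(:types t0 - object" + (" t1 - t0" if has_sub else "") + ")"
    objects = "(:objects " + " ".join(ents_t0) + " - t0"
    if ents_t1:
        objects += " " + " ".join(ents_t1) + " - t1"
    objects += ")"
    functions = "(:functions (loc ?e - t0) - t0 (flag ?e - t0) - boolean (cnt) - number)"

    init_parts = [f"(= (loc {e}) {all_ents[rng.integers(len(all_ents))]})" for e in all_ents]
    for e in all_ents:
        if rng.integers(2):
            init_parts.append(f"(= (flag {e}) true)")
    init_parts.append(f"(= (cnt) {int(rng.integers(0, 4))})")
    init = "(:init " + " ".join(init_parts) + ")"

    def atom(params):
        kind = rng.integers(5)
        tgt = (
            f"?{params[rng.integers(len(params))]}"
            if params
            else all_ents[rng.integers(len(all_ents))]
        )
        if kind == 0:
            val = all_ents[rng.integers(len(all_ents))]
            return f"(= (loc {tgt}) {val})"
        if kind == 1:
            return f"(flag {tgt})"
        if kind == 2:
            return f"(not (flag {tgt}))"
        if kind == 3:
            return f"(< (cnt) {int(rng.integers(1, 5))})"
        return f"(>= (cnt) {int(rng.integers(0, 3))})"

    schemas = []
    for k in range(int(rng.integers(1, max_schemas + 1))):
        n_params = int(rng.integers(0, 3))
        ptypes = ["t1" if (has_sub and rng.integers(2)) else "t0" for _ in range(n_params)]
        params = [f"p{j}" for j in range(n_params)]
        param_decl = " ".join(f"?{p} - {t}" for p, t in zip(params, ptypes))
        pre_atoms = [atom(params) for _ in range(int(rng.integers(0, 4)))]
        pre = "(and " + " ".join(pre_atoms) + ")" if pre_atoms else "(and)"
        effects, written = [], set()
        for _ in range(int(rng.integers(0, 3))):
            which = rng.integers(3)
            if which == 0:
                tgt = (
                    f"?{params[rng.integers(len(params))]}"
                    if params
                    else all_ents[rng.integers(len(all_ents))]
                )
                if ("loc", tgt) in written:
                    continue
                written.add(("loc", tgt))
                val = all_ents[rng.integers(len(all_ents))]
                effects.append(f"(assign (loc {tgt}) {val})")
            elif which == 1:
                tgt = (
                    f"?{params[rng.integers(len(params))]}"
                    if params
                    else all_ents[rng.integers(len(all_ents))]
                )
                if ("flag", tgt) in written:
                    continue
                written.add(("flag", tgt))
                effects.append(f"(assign (flag {tgt}) {'true' if rng.integers(2) else 'false'})")
            else:
                if ("cnt", None) in written:
                    continue
                written.add(("cnt", None))
                op = "increase" if rng.integers(2) else "decrease"
                effects.append(f"({op} (cnt) 1)")
        eff = "(and " + " ".join(effects) + ")"
        schemas.append(
            f"(:action act{k} :parameters ({param_decl}) "
            f":precondition {pre} :effect {eff})"
        )

    return (
        "(define (domain rand) "
        + types
        + " "
        + objects
        + " "
        + functions
        + " "
        + init
        + " "
        + " ".join(schemas)
        + ")"
    )
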
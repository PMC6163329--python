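"""Semantic domain model: entity types, entities, fluents, and action schemas.

A *domain* is the semantic structure behind an annotation vocabulary.  It
declares a forest of entity types, a set of named entities, *fluents*
(functions from entity tuples to an entity, a number, or a truth value that
together form the world state), an initial state, and *action schemas* with
STRIPS-style preconditions and effects.  Every type-correct instantiation of
a schema's label template is one element of the finite label set L that
annotators draw from.

Domains are written in a strict PDDL-like s-expression dialect::

    (define (domain toy-kitchen)
      (:types takeable - object ...)
      (:objects knife - takeable ...)
      (:functions (is-at ?what - takeable) - location
                  (objects_taken) - number)
      (:init (= (is-at knife) drawer) (= (objects_taken) 0))
      (:action take
        :parameters (?what - takeable ?from - surface)
        :precondition (and (= (is-at ?what) ?from) (< (objects_taken) 3))
        :effect (and (assign (is-at ?what) hands)
                     (increase (objects_taken) 1))
        :label "take-{what}-{from}"))

Supported constructs are deliberately minimal: conjunction, negation,
equality over entity-valued terms, numeric comparison (< <= = >= >), and
assign / increase / decrease effects.  Labels are hyphen-separated tokens;
entity names may contain underscores but never hyphens.  Identifiers are
case-sensitive.  Boolean fluents not mentioned in ``:init`` default to
false; entity-valued fluents must be assigned explicitly.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .errors import DomainSemanticError, DomainSyntaxError
from .sexpr import Atom, parse_sexprs

__all__ = [
    "EntityType",
    "Entity",
    "Fluent",
    "ActionSchema",
    "EffectItem",
    "Domain",
    "And",
    "Not",
    "Cmp",
    "FluentTerm",
    "Lit",
    "Sym",
    "TRUE",
    "parse_domain",
    "serialize_domain",
    "enumerate_labels",
    "parse_term",
    "term_str",
]

ROOT_TYPE = "object"

# ---------------------------------------------------------------------------
# expressions


@dataclass(frozen=True)
class FluentTerm:
    """A fluent applied to arguments (variables ``?x`` or entity names)."""

    name: str
    args: tuple[str, ...] = ()

    def __str__(self) -> str:
        return f"({self.name}{''.join(' ' + a for a in self.args)})"


@dataclass(frozen=True)
class Lit:
    """A literal value: int, float, or bool."""

    value: object

    def __str__(self) -> str:
        if isinstance(self.value, bool):
            return "true" if self.value else "false"
        return str(self.value)


@dataclass(frozen=True)
class Sym:
    """A variable (``?x``) or entity-name constant."""

    name: str

    def __str__(self) -> str:
        return self.name


Term = FluentTerm | Lit | Sym


@dataclass(frozen=True)
class And:
    items: tuple = ()

    def __str__(self) -> str:
        return f"(and{''.join(' ' + str(i) for i in self.items)})"


@dataclass(frozen=True)
class Not:
    item: object = None

    def __str__(self) -> str:
        return f"(not {self.item})"


@dataclass(frozen=True)
class Cmp:
    """Comparison ``lhs op rhs``; ``=`` also covers entity and boolean equality."""

    op: str  # one of = < <= >= >
    lhs: Term = None
    rhs: Term = None

    def __str__(self) -> str:
        # boolean atoms print without the "= true" wrapper
        if self.op == "=" and self.rhs == Lit(True) and isinstance(self.lhs, FluentTerm):
            return str(self.lhs)
        return f"({self.op} {self.lhs} {self.rhs})"


Expression = And | Not | Cmp
TRUE = And(())


@dataclass(frozen=True)
class EffectItem:
    """``assign(term, value)`` or ``increase``/``decrease`` of a numeric term."""

    op: str  # assign | increase | decrease
    target: FluentTerm = None
    value: Term = None

    def __str__(self) -> str:
        return f"({self.op} {self.target} {self.value})"


# ---------------------------------------------------------------------------
# declarations


@dataclass(frozen=True)
class EntityType:
    name: str
    parent: str | None = None


@dataclass(frozen=True)
class Entity:
    name: str
    type: str


@dataclass(frozen=True)
class Fluent:
    """A state property: function from a tuple of typed entities to a value.

    ``range`` is ``"number"``, ``"boolean"``, or the name of an entity type.
    """

    name: str
    parameter_types: tuple[str, ...] = ()
    range: str = "boolean"


@dataclass(frozen=True)
class ActionSchema:
    """An action class with typed parameters, precondition, and effects.

    ``name`` is the action-class identifier; several schemas may share a
    class name (e.g. *take* over storages and over surfaces) as long as
    their ground labels stay distinct.
    """

    name: str
    parameters: tuple[tuple[str, str], ...] = ()  # (role, type-name)
    precondition: Expression = TRUE
    effects: tuple[EffectItem, ...] = ()
    label_template: str = ""

    def label_for(self, binding: dict[str, str]) -> str:
        return self.label_template.format(**binding)


GroundTerm = tuple[str, tuple[str, ...]]


def term_str(term: GroundTerm) -> str:
    """Printable form of a ground fluent term: ``is-at(knife)``."""
    return f"{term[0]}({', '.join(term[1])})"


_TERM_RE = re.compile(r"^\s*([^()\s]+)\s*\(\s*([^()]*)\)\s*$")


def parse_term(text: str) -> GroundTerm:
    """Inverse of :func:`term_str`: ``"is-at(knife)"`` -> ``("is-at", ("knife",))``."""
    m = _TERM_RE.match(text)
    if not m:
        if "(" not in text:
            return (text.strip(), ())
        raise DomainSemanticError(f"cannot parse fluent term {text!r}")
    args = tuple(a.strip() for a in m.group(2).split(",") if a.strip())
    return (m.group(1), args)


@dataclass
class Domain:
    """A parsed, validated domain: the full semantic structure behind L."""

    name: str
    types: dict[str, EntityType] = field(default_factory=dict)
    entities: dict[str, Entity] = field(default_factory=dict)
    fluents: dict[str, Fluent] = field(default_factory=dict)
    schemas: list[ActionSchema] = field(default_factory=list)
    initial: dict[GroundTerm, object] = field(default_factory=dict)

    # -- type system -------------------------------------------------------
    def is_subtype(self, sub: str, sup: str) -> bool:
        if sup == ROOT_TYPE:
            return True
        t: str | None = sub
        while t is not None:
            if t == sup:
                return True
            t = self.types[t].parent if t in self.types else None
        return False

    def entities_of_type(self, type_name: str) -> list[str]:
        """Entity names whose type is ``type_name`` or a subtype, sorted."""
        return sorted(
            e.name for e in self.entities.values() if self.is_subtype(e.type, type_name)
        )

    # -- fluents / states --------------------------------------------------
    def ground_fluent_terms(self) -> list[GroundTerm]:
        out: list[GroundTerm] = []
        for fl in self.fluents.values():
            pools = [self.entities_of_type(t) for t in fl.parameter_types]
            for combo in itertools.product(*pools):
                out.append((fl.name, tuple(combo)))
        return out

    def initial_state(self) -> dict[GroundTerm, object]:
        """Total initial state: booleans default false, numbers default 0."""
        state: dict[GroundTerm, object] = {}
        for term in self.ground_fluent_terms():
            fl = self.fluents[term[0]]
            if term in self.initial:
                state[term] = self.initial[term]
            elif fl.range == "boolean":
                state[term] = False
            elif fl.range == "number":
                state[term] = 0
            else:  # pragma: no cover - caught at parse time
                raise DomainSemanticError(
                    f"entity-valued fluent {term_str(term)} unassigned in :init"
                )
        return state

    def labels(self) -> list[str]:
        return enumerate_labels(self)

    def action_classes(self) -> list[str]:
        """Distinct action-class names, in declaration order."""
        seen: dict[str, None] = {}
        for s in self.schemas:
            seen.setdefault(s.name, None)
        return list(seen)

    def with_initial(self, overrides: dict[GroundTerm, object]) -> "Domain":
        """A copy of the domain with some initial assignments replaced."""
        new_init = dict(self.initial)
        for term, value in overrides.items():
            if term[0] not in self.fluents:
                raise DomainSemanticError(f"unknown fluent {term[0]!r}")
            new_init[term] = value
        return Domain(
            name=self.name,
            types=dict(self.types),
            entities=dict(self.entities),
            fluents=dict(self.fluents),
            schemas=list(self.schemas),
            initial=new_init,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Domain):
            return NotImplemented
        return (
            self.name == other.name
            and self.types == other.types
            and self.entities == other.entities
            and self.fluents == other.fluents
            and self.schemas == other.schemas
            and self.initial == other.initial
        )


# ---------------------------------------------------------------------------
# label enumeration

_TEMPLATE_TOKEN_RE = re.compile(r"\{([^{}]+)\}")


def enumerate_labels(domain: Domain) -> list[str]:
    """Every type-correct instantiation of every schema's label template.

    Deduplicated, deterministic order: schema declaration order, then
    lexicographic by arguments (each parameter's entity pool is sorted).
    """
    seen: dict[str, None] = {}
    for schema in domain.schemas:
        pools = [domain.entities_of_type(t) for _, t in schema.parameters]
        roles = [r for r, _ in schema.parameters]
        for combo in itertools.product(*pools):
            label = schema.label_for(dict(zip(roles, combo)))
            seen.setdefault(label, None)
    return list(seen)


# ---------------------------------------------------------------------------
# parsing

_RESERVED_VALUES = {"true", "false"}


def _expect_atom(node, what: str) -> Atom:
    if not isinstance(node, Atom):
        raise DomainSyntaxError(f"expected {what}, got a list")
    return node


def _pos(node) -> tuple[int | None, int | None]:
    if isinstance(node, Atom):
        return node.line, node.column
    for item in node:
        return _pos(item)
    return None, None


def _parse_typed_list(nodes: list, default_parent: str) -> list[tuple[str, str]]:
    """Parse the PDDL ``a b - t c d - u`` convention -> [(name, parent), ...]."""
    out: list[tuple[str, str]] = []
    pending: list[str] = []
    i = 0
    while i < len(nodes):
        atom = _expect_atom(nodes[i], "a name")
        if atom.value == "-":
            if i + 1 >= len(nodes):
                raise DomainSyntaxError("dangling '-' in typed list", atom.line, atom.column)
            parent = _expect_atom(nodes[i + 1], "a type name").value
            out.extend((n, parent) for n in pending)
            pending = []
            i += 2
        else:
            pending.append(atom.value)
            i += 1
    out.extend((n, default_parent) for n in pending)
    return out


def _parse_term(node, numeric_ok: bool = True) -> Term:
    if isinstance(node, Atom):
        v = node.value
        if v == "true":
            return Lit(True)
        if v == "false":
            return Lit(False)
        try:
            return Lit(int(v)) if numeric_ok else Sym(v)
        except ValueError:
            pass
        try:
            return Lit(float(v)) if numeric_ok else Sym(v)
        except ValueError:
            pass
        return Sym(v)
    if not node:
        raise DomainSyntaxError("empty term")
    head = _expect_atom(node[0], "a fluent name")
    args = tuple(_expect_atom(a, "a term argument").value for a in node[1:])
    return FluentTerm(head.value, args)


_NUM_OPS = {"<", "<=", ">=", ">"}


def _parse_expression(node) -> Expression:
    if isinstance(node, Atom):
        raise DomainSyntaxError(
            f"expected an expression, got bare atom {node.value!r}", node.line, node.column
        )
    if not node:  # () == empty conjunction
        return TRUE
    head = node[0]
    if isinstance(head, Atom) and head.value == "and":
        return And(tuple(_parse_expression(n) for n in node[1:]))
    if isinstance(head, Atom) and head.value == "not":
        if len(node) != 2:
            raise DomainSyntaxError("(not ...) takes one argument", head.line, head.column)
        return Not(_parse_expression(node[1]))
    if isinstance(head, Atom) and (head.value in _NUM_OPS or head.value == "="):
        if len(node) != 3:
            raise DomainSyntaxError(
                f"({head.value} ...) takes two arguments", head.line, head.column
            )
        return Cmp(head.value, _parse_term(node[1]), _parse_term(node[2]))
    # bare boolean fluent atom: (is-open ?s)
    term = _parse_term(node)
    if isinstance(term, FluentTerm):
        return Cmp("=", term, Lit(True))
    raise DomainSyntaxError("cannot parse expression", *_pos(node))


def _parse_effect(node) -> tuple[EffectItem, ...]:
    if isinstance(node, Atom):
        raise DomainSyntaxError("effect must be a list", node.line, node.column)
    if not node:
        return ()
    head = node[0]
    if isinstance(head, Atom) and head.value == "and":
        items: list[EffectItem] = []
        for sub in node[1:]:
            items.extend(_parse_effect(sub))
        return tuple(items)
    if isinstance(head, Atom) and head.value in {"assign", "increase", "decrease"}:
        if len(node) != 3:
            raise DomainSyntaxError(
                f"({head.value} ...) takes two arguments", head.line, head.column
            )
        target = _parse_term(node[1])
        if not isinstance(target, FluentTerm):
            raise DomainSyntaxError("effect target must be a fluent term", head.line, head.column)
        return (EffectItem(head.value, target, _parse_term(node[2])),)
    if isinstance(head, Atom) and head.value == "not":
        # PDDL-style boolean delete: (not (f args))
        target = _parse_term(node[1])
        if not isinstance(target, FluentTerm):
            raise DomainSyntaxError("effect target must be a fluent term", head.line, head.column)
        return (EffectItem("assign", target, Lit(False)),)
    # PDDL-style boolean add: (f args)
    target = _parse_term(node)
    if isinstance(target, FluentTerm):
        return (EffectItem("assign", target, Lit(True)),)
    raise DomainSyntaxError("cannot parse effect", *_pos(node))


def _atom_value(node, what: str) -> str:
    return _expect_atom(node, what).value


def parse_domain(text: str) -> Domain:
    """Parse and fully validate a domain file.

    Raises :class:`DomainSyntaxError` with line/column on grammar errors and
    :class:`DomainSemanticError` naming the offending declaration on
    structural errors.
    """
    forms = parse_sexprs(text)
    if len(forms) != 1 or isinstance(forms[0], Atom):
        raise DomainSyntaxError("expected a single (define ...) form")
    top = forms[0]
    if not top or _atom_value(top[0], "define") != "define":
        raise DomainSyntaxError("file must start with (define (domain NAME) ...)", *_pos(top))
    header = top[1]
    if (
        isinstance(header, Atom)
        or len(header) != 2
        or _atom_value(header[0], "domain") != "domain"
    ):
        raise DomainSyntaxError("expected (domain NAME)", *_pos(top))
    domain = Domain(name=_atom_value(header[1], "domain name"))
    domain.types[ROOT_TYPE] = EntityType(ROOT_TYPE, None)

    sections = {"init": None, "types": None}
    for section in top[2:]:
        if isinstance(section, Atom):
            raise DomainSyntaxError(
                f"unexpected atom {section.value!r} at top level", section.line, section.column
            )
        if not section:
            continue
        key = _atom_value(section[0], "a section keyword")
        if key == ":types":
            for name, parent in _parse_typed_list(section[1:], ROOT_TYPE):
                if name in domain.types:
                    raise DomainSemanticError(f"duplicate type {name!r}")
                domain.types[name] = EntityType(name, parent)
        elif key == ":objects":
            for name, tname in _parse_typed_list(section[1:], ROOT_TYPE):
                if name in domain.entities:
                    raise DomainSemanticError(f"duplicate entity {name!r}")
                if tname not in domain.types:
                    raise DomainSemanticError(
                        f"entity {name!r} declared with unknown type {tname!r}"
                    )
                if "-" in name:
                    raise DomainSemanticError(
                        f"entity name {name!r} may not contain a hyphen (label syntax)"
                    )
                domain.entities[name] = Entity(name, tname)
        elif key == ":functions":
            _parse_functions(domain, section[1:])
        elif key == ":init":
            sections["init"] = section[1:]
        elif key == ":action":
            domain.schemas.append(_parse_action(domain, section[1:]))
        else:
            raise DomainSyntaxError(f"unknown section {key!r}", *_pos(section))

    # type forest sanity
    for t in domain.types.values():
        if t.parent is not None and t.parent not in domain.types:
            raise DomainSemanticError(f"type {t.name!r} has unknown parent {t.parent!r}")

    if sections["init"] is not None:
        _parse_init(domain, sections["init"])
    _validate_domain(domain)
    return domain


def _parse_functions(domain: Domain, nodes: list) -> None:
    """``(:functions (f ?p - type ...) - range ...)``."""
    pending: list = []
    i = 0
    while i < len(nodes):
        node = nodes[i]
        if isinstance(node, Atom) and node.value == "-":
            if i + 1 >= len(nodes):
                raise DomainSyntaxError("dangling '-' in :functions", node.line, node.column)
            rng = _atom_value(nodes[i + 1], "a range type")
            for decl in pending:
                _declare_fluent(domain, decl, rng)
            pending = []
            i += 2
        else:
            pending.append(node)
            i += 1
    for decl in pending:  # PDDL default: numeric
        _declare_fluent(domain, decl, "number")


def _declare_fluent(domain: Domain, decl, rng: str) -> None:
    if isinstance(decl, Atom):
        raise DomainSyntaxError("fluent declaration must be a list", decl.line, decl.column)
    name = _atom_value(decl[0], "a fluent name")
    params = _parse_typed_list(decl[1:], ROOT_TYPE)
    for pname, ptype in params:
        if not pname.startswith("?"):
            raise DomainSemanticError(f"fluent {name!r}: parameter {pname!r} must start with '?'")
        if ptype not in domain.types:
            raise DomainSemanticError(f"fluent {name!r}: unknown parameter type {ptype!r}")
    if rng not in {"number", "boolean"} and rng not in domain.types:
        raise DomainSemanticError(f"fluent {name!r}: unknown range type {rng!r}")
    if name in domain.fluents:
        raise DomainSemanticError(f"duplicate fluent {name!r}")
    domain.fluents[name] = Fluent(name, tuple(t for _, t in params), rng)


def _parse_init(domain: Domain, nodes: list) -> None:
    for node in nodes:
        if isinstance(node, Atom):
            raise DomainSyntaxError("init entries must be lists", node.line, node.column)
        head = _atom_value(node[0], "an init entry")
        if head == "=":
            if len(node) != 3:
                raise DomainSyntaxError("(= term value) expected in :init", *_pos(node))
            term = _parse_term(node[1])
            value = _parse_term(node[2])
        else:  # bare boolean fact (is-open fridge)
            term = _parse_term(node)
            value = Lit(True)
        if not isinstance(term, FluentTerm):
            raise DomainSyntaxError(":init assigns fluent terms only", *_pos(node))
        if term.name not in domain.fluents:
            raise DomainSemanticError(f":init references unknown fluent {term.name!r}")
        fl = domain.fluents[term.name]
        if len(term.args) != len(fl.parameter_types):
            raise DomainSemanticError(
                f":init arity mismatch for {term.name!r}: "
                f"got {len(term.args)}, declared {len(fl.parameter_types)}"
            )
        args = []
        for a, ptype in zip(term.args, fl.parameter_types):
            if a not in domain.entities:
                raise DomainSemanticError(f":init references unknown entity {a!r}")
            if not domain.is_subtype(domain.entities[a].type, ptype):
                raise DomainSemanticError(
                    f":init {term.name!r}: entity {a!r} is not of type {ptype!r}"
                )
            args.append(a)
        key = (term.name, tuple(args))
        if key in domain.initial:
            raise DomainSemanticError(f":init assigns {term_str(key)} twice")
        domain.initial[key] = _init_value(domain, fl, value)


def _init_value(domain: Domain, fl: Fluent, value: Term) -> object:
    if fl.range == "number":
        if isinstance(value, Lit) and isinstance(value.value, (int, float)) and not isinstance(
            value.value, bool
        ):
            return value.value
        raise DomainSemanticError(f":init {fl.name!r}: expected a number, got {value}")
    if fl.range == "boolean":
        if isinstance(value, Lit) and isinstance(value.value, bool):
            return value.value
        raise DomainSemanticError(f":init {fl.name!r}: expected true/false, got {value}")
    if isinstance(value, Sym) and value.name in domain.entities:
        if not domain.is_subtype(domain.entities[value.name].type, fl.range):
            raise DomainSemanticError(
                f":init {fl.name!r}: entity {value.name!r} is not of range type {fl.range!r}"
            )
        return value.name
    raise DomainSemanticError(f":init {fl.name!r}: expected an entity of type {fl.range!r}")


def _parse_action(domain: Domain, nodes: list) -> ActionSchema:
    if not nodes:
        raise DomainSyntaxError("empty :action")
    name = _atom_value(nodes[0], "an action name")
    kv: dict[str, object] = {}
    i = 1
    while i < len(nodes):
        key = _atom_value(nodes[i], "an action keyword")
        if i + 1 >= len(nodes):
            raise DomainSyntaxError(f"action {name!r}: {key} missing its value")
        kv[key] = nodes[i + 1]
        i += 2

    params_node = kv.get(":parameters", [])
    if isinstance(params_node, Atom):
        raise DomainSyntaxError(":parameters must be a list", params_node.line, params_node.column)
    parameters: list[tuple[str, str]] = []
    for pname, ptype in _parse_typed_list(list(params_node), ROOT_TYPE):
        if not pname.startswith("?"):
            raise DomainSemanticError(f"action {name!r}: parameter {pname!r} must start with '?'")
        if ptype not in domain.types:
            raise DomainSemanticError(
                f"action {name!r}: parameter {pname!r} has unknown type {ptype!r}"
            )
        parameters.append((pname[1:], ptype))

    pre = _parse_expression(kv[":precondition"]) if ":precondition" in kv else TRUE
    effects = _parse_effect(kv[":effect"]) if ":effect" in kv else ()

    if ":label" in kv:
        label_atom = _expect_atom(kv[":label"], "a label template string")
        template = label_atom.value
    else:
        template = "-".join([name] + [f"{{{r}}}" for r, _ in parameters])

    schema = ActionSchema(name, tuple(parameters), pre, effects, template)
    _check_schema(domain, schema)
    return schema


def _schema_vars(expr) -> set[str]:
    if isinstance(expr, And):
        return set().union(*(_schema_vars(i) for i in expr.items)) if expr.items else set()
    if isinstance(expr, Not):
        return _schema_vars(expr.item)
    if isinstance(expr, Cmp):
        return _term_vars(expr.lhs) | _term_vars(expr.rhs)
    return set()


def _term_vars(term: Term) -> set[str]:
    if isinstance(term, Sym) and term.name.startswith("?"):
        return {term.name[1:]}
    if isinstance(term, FluentTerm):
        return {a[1:] for a in term.args if a.startswith("?")}
    return set()


def _check_schema(domain: Domain, schema: ActionSchema) -> None:
    declared = {r for r, _ in schema.parameters}
    name = schema.name
    used = _schema_vars(schema.precondition)
    for eff in schema.effects:
        used |= _term_vars(eff.target) | _term_vars(eff.value)
    undeclared = used - declared
    if undeclared:
        raise DomainSemanticError(
            f"action {name!r}: undeclared variable(s) {sorted(undeclared)}"
        )
    # label template: declared params, each at most once; tokens hyphen-split
    refs = _TEMPLATE_TOKEN_RE.findall(schema.label_template)
    for ref in refs:
        if ref not in declared:
            raise DomainSemanticError(
                f"action {name!r}: label template references unknown parameter {ref!r}"
            )
    if len(refs) != len(set(refs)):
        raise DomainSemanticError(
            f"action {name!r}: label template references a parameter twice"
        )
    _check_expr_types(domain, schema, schema.precondition)
    seen_targets: set = set()
    for eff in schema.effects:
        _check_fluent_term(domain, schema, eff.target)
        fl = domain.fluents[eff.target.name]
        if eff.op in {"increase", "decrease"} and fl.range != "number":
            raise DomainSemanticError(
                f"action {name!r}: {eff.op} on non-numeric fluent {fl.name!r}"
            )
        key = (eff.target.name, eff.target.args)
        if key in seen_targets:
            raise DomainSemanticError(
                f"action {name!r}: conflicting writes to {eff.target}"
            )
        seen_targets.add(key)


def _check_fluent_term(domain: Domain, schema: ActionSchema, term: FluentTerm) -> None:
    if term.name not in domain.fluents:
        raise DomainSemanticError(f"action {schema.name!r}: unknown fluent {term.name!r}")
    fl = domain.fluents[term.name]
    if len(term.args) != len(fl.parameter_types):
        raise DomainSemanticError(
            f"action {schema.name!r}: arity mismatch for {term.name!r}"
        )
    ptypes = dict(schema.parameters)
    for a, want in zip(term.args, fl.parameter_types):
        if a.startswith("?"):
            have = ptypes.get(a[1:])
            if have is not None and not domain.is_subtype(have, want):
                raise DomainSemanticError(
                    f"action {schema.name!r}: argument {a} of {term.name!r} "
                    f"has type {have!r}, expected {want!r}"
                )
        elif a in domain.entities:
            if not domain.is_subtype(domain.entities[a].type, want):
                raise DomainSemanticError(
                    f"action {schema.name!r}: entity {a!r} is not of type {want!r}"
                )
        elif a not in _RESERVED_VALUES:
            raise DomainSemanticError(
                f"action {schema.name!r}: unknown entity {a!r} in {term.name!r}"
            )


def _check_expr_types(domain: Domain, schema: ActionSchema, expr) -> None:
    if isinstance(expr, And):
        for item in expr.items:
            _check_expr_types(domain, schema, item)
    elif isinstance(expr, Not):
        _check_expr_types(domain, schema, expr.item)
    elif isinstance(expr, Cmp):
        for side in (expr.lhs, expr.rhs):
            if isinstance(side, FluentTerm):
                _check_fluent_term(domain, schema, side)
            elif isinstance(side, Sym) and not side.name.startswith("?"):
                if side.name not in domain.entities:
                    raise DomainSemanticError(
                        f"action {schema.name!r}: unknown entity {side.name!r}"
                    )


def _validate_domain(domain: Domain) -> None:
    # every entity-valued ground fluent instance must be assigned in :init
    for term in domain.ground_fluent_terms():
        fl = domain.fluents[term[0]]
        if fl.range not in {"number", "boolean"} and term not in domain.initial:
            raise DomainSemanticError(
                f"entity-valued fluent {term_str(term)} is unassigned in :init"
            )


# ---------------------------------------------------------------------------
# serialisation


def serialize_domain(domain: Domain) -> str:
    """Write a Domain back to dialect text (parse -> serialize round-trips)."""
    lines = [f"(define (domain {domain.name})"]

    typed = [t for t in domain.types.values() if t.name != ROOT_TYPE]
    if typed:
        decls = " ".join(f"{t.name} - {t.parent}" for t in typed)
        lines.append(f"  (:types {decls})")
    if domain.entities:
        decls = " ".join(f"{e.name} - {e.type}" for e in domain.entities.values())
        lines.append(f"  (:objects {decls})")
    if domain.fluents:
        parts = []
        for fl in domain.fluents.values():
            params = "".join(f" ?p{i} - {t}" for i, t in enumerate(fl.parameter_types))
            parts.append(f"({fl.name}{params}) - {fl.range}")
        lines.append(f"  (:functions {' '.join(parts)})")
    if domain.initial:
        parts = []
        for term, value in domain.initial.items():
            tstr = f"({term[0]}{''.join(' ' + a for a in term[1])})"
            parts.append(f"(= {tstr} {Lit(value) if isinstance(value, bool) else value})")
        lines.append(f"  (:init {' '.join(parts)})")
    for schema in domain.schemas:
        params = " ".join(f"?{r} - {t}" for r, t in schema.parameters)
        lines.append(f"  (:action {schema.name}")
        lines.append(f"    :parameters ({params})")
        lines.append(f"    :precondition {_expr_text(schema.precondition)}")
        eff = " ".join(str(e) for e in schema.effects)
        lines.append(f"    :effect (and {eff})")
        lines.append(f'    :label "{schema.label_template}")')
    lines.append(")")
    return "\n".join(lines) + "\n"


def _expr_text(expr) -> str:
    # Cmp.__str__ abbreviates boolean atoms; serialisation must stay parseable,
    # which the abbreviation is, so plain str() works throughout.
    return str(expr)
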
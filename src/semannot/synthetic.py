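"""Synthetic fixtures: toy domains, sampled plans, and annotator corruption.

The generator makes every other module testable without external data:

* :func:`gen_toy_domain` loads one of three packaged kitchen domains whose
  action-class dictionaries match the three published recipe datasets
  (Brownie: 11 classes, Eggs: 12, Sandwich: 12, union: 13);
* :func:`gen_plan` samples a causally valid plan by forward search —
  uniform random choice among the currently applicable ground actions —
  with log-normal segment durations, so the resulting tier is gap-free and
  validates by construction;
* :func:`corrupt_tier` emulates a second annotator: Gaussian boundary
  jitter (the dominant real disagreement mode) plus label confusion with
  a co-classed label.

One seed fully determines all output; a config carries a single random
stream (derive one with :meth:`GeneratorConfig.rng` and pass it through
when generating several artefacts in sequence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .annotation import AnnotationTier, Segment
from .domain import Domain, parse_domain
from .engine import Plan, PlanStep, applicable_actions
from .errors import SemannotError

__all__ = [
    "GeneratorConfig",
    "FLAVOURS",
    "gen_toy_domain",
    "toy_kitchen_domain",
    "load_s09_extract",
    "gen_plan",
    "corrupt_tier",
    "gen_corpus",
    "RunRecord",
]

FLAVOURS = ("brownie", "eggs", "sandwich")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic two-annotator experiment.

    Durations are log-normal (right-skewed, like observed inter-start
    gaps): ``exp(N(duration_mu, duration_sigma))`` ms with a median of
    2 s.  ``jitter_sd`` (ms) and ``confusion_rate`` parameterise the
    second-annotator corruption; ``relocation_run`` optionally changes the
    initial object placement from that run index on (emulating a mid-study
    setup change).
    """

    seed: int = 0
    n_runs: int = 20
    max_plan_length: int = 30
    duration_mu: float = math.log(2000.0)
    duration_sigma: float = 0.75
    jitter_sd: float = 300.0
    confusion_rate: float = 0.05
    relocation_run: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.confusion_rate <= 1.0):
            raise ValueError("confusion_rate must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _load_packaged_domain(name: str) -> Domain:
    text = resources.files("semannot.data").joinpath(f"{name}.dom").read_text()
    return parse_domain(text)


def gen_toy_domain(flavour: str) -> Domain:
    """A packaged toy kitchen domain for ``brownie``, ``eggs`` or ``sandwich``."""
    if flavour not in FLAVOURS:
        raise ValueError(f"unknown flavour {flavour!r}; choose one of {FLAVOURS}")
    return _load_packaged_domain(flavour)


def toy_kitchen_domain() -> Domain:
    """The minimal knife/drawer/board domain used in the worked examples."""
    return _load_packaged_domain("toy_kitchen")


def load_s09_extract(run_id: str = "S09", annotator_id: str = "A") -> AnnotationTier:
    """The packaged 40-segment extract of the Brownie subject-S09 annotation.

    End times equal the next segment's start (the annotation is gap-free);
    the last segment's end is an assumed value, since only start times are
    published for it.
    """
    from .annotation import read_tier

    text = resources.files("semannot.data").joinpath("s09_brownie_extract.tsv").read_text()
    return read_tier(text, "elan-tsv", run_id=run_id, annotator_id=annotator_id)


def gen_plan(
    domain: Domain,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    run_id: str = "synthetic",
    annotator_id: str = "A",
) -> tuple[Plan, AnnotationTier]:
    """Sample a valid plan and its gap-free timed tier.

    Repeatedly draws uniformly from the applicable ground actions until
    ``max_plan_length`` steps or a dead end (no action applicable).  A dead
    end in the *initial* state is an error.
    """
    if rng is None:
        rng = config.rng()
    state = domain.initial_state()
    if not applicable_actions(domain, state):
        raise SemannotError("dead-end initial state: no action is applicable")
    actions = []
    for _ in range(config.max_plan_length):
        candidates = applicable_actions(domain, state)
        if not candidates:
            break
        action = candidates[rng.integers(len(candidates))]
        from .engine import apply_action

        state = apply_action(domain, state, action, check=False)
        actions.append(action)

    durations = np.maximum(
        1, np.round(rng.lognormal(config.duration_mu, config.duration_sigma, len(actions)))
    ).astype(int)
    starts = np.concatenate([[0], np.cumsum(durations)[:-1]])
    plan = [PlanStep(int(t), a) for t, a in zip(starts, actions)]
    segments = [
        Segment(int(s), int(s + d), a.label) for s, d, a in zip(starts, durations, actions)
    ]
    tier = AnnotationTier(run_id=run_id, annotator_id=annotator_id, segments=segments)
    return plan, tier


def _label_class(label: str) -> str:
    return label.split("-", 1)[0]


def corrupt_tier(
    tier: AnnotationTier,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    label_pool: list[str] | None = None,
    annotator_id: str = "B",
) -> AnnotationTier:
    """Emulate a second annotator labelling the same run.

    Internal segment boundaries are shifted by ``N(0, jitter_sd)`` ms,
    clipped to preserve ordering and >= 1 ms segments; each label is then
    independently replaced, with probability ``confusion_rate``, by a
    random different label of the same action class (falling back to any
    different pool label for singleton classes).  With jitter 0 and
    confusion 0 the tier is returned unchanged apart from the annotator id.
    """
    if rng is None:
        rng = config.rng()
    if label_pool is None:
        label_pool = sorted(set(tier.labels()))
    segs = tier.segments
    if not segs:
        return AnnotationTier(tier.run_id, annotator_id, [])

    boundaries = [s.start for s in segs] + [segs[-1].end]
    new_bounds = [boundaries[0]]
    for i in range(1, len(boundaries) - 1):
        noise = rng.normal(0.0, config.jitter_sd) if config.jitter_sd > 0 else 0.0
        lo = new_bounds[-1] + 1
        hi = boundaries[-1] - (len(boundaries) - 1 - i)  # room for the rest
        new_bounds.append(int(min(max(boundaries[i] + noise, lo), hi)))
    new_bounds.append(boundaries[-1])

    by_class: dict[str, list[str]] = {}
    for lab in label_pool:
        by_class.setdefault(_label_class(lab), []).append(lab)

    new_segments = []
    for seg, start, end in zip(segs, new_bounds, new_bounds[1:]):
        label = seg.label
        if config.confusion_rate > 0 and rng.random() < config.confusion_rate:
            peers = [l for l in by_class.get(_label_class(label), []) if l != label]
            if not peers:
                peers = [l for l in label_pool if l != label]
            if peers:
                label = peers[rng.integers(len(peers))]
        new_segments.append(Segment(start, end, label))
    return AnnotationTier(tier.run_id, annotator_id, new_segments)


@dataclass
class RunRecord:
    """One synthetic run: its (possibly relocated) domain, plan, and tiers."""

    run_id: str
    domain: Domain
    plan: Plan
    tier: AnnotationTier
    tier_b: AnnotationTier


def _relocated(domain: Domain) -> Domain:
    """Move the first located object to a different same-typed location."""
    for term, value in sorted(domain.initial.items(), key=lambda kv: kv[0]):
        if term[0] != "is-at" or not isinstance(value, str) or value not in domain.entities:
            continue
        peers = [
            e for e in domain.entities_of_type(domain.entities[value].type) if e != value
        ]
        if peers:
            return domain.with_initial({term: peers[0]})
    raise SemannotError("domain has no relocatable object")


def gen_corpus(domain: Domain, config: GeneratorConfig) -> list[RunRecord]:
    """Generate ``n_runs`` two-annotator runs from one random stream.

    From ``relocation_run`` (if set) onward, runs use a variant of the
    domain with one object moved to a different storage — the ground truth
    for initial-state change-point detection.
    """
    rng = config.rng()
    moved = _relocated(domain) if config.relocation_run is not None else None
    records = []
    for i in range(config.n_runs):
        d = moved if moved is not None and i >= config.relocation_run else domain
        run_id = f"run{i:03d}"
        plan, tier = gen_plan(d, config, rng=rng, run_id=run_id)
        tier_b = corrupt_tier(tier, config, rng=rng, label_pool=d.labels())
        records.append(RunRecord(run_id, d, plan, tier, tier_b))
    return records
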
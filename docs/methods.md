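# Methods

## The modelling formalism

`semannot` treats an annotation vocabulary as the ground instances of a
small planning domain.  The dialect is a strict subset of PDDL with typing
and object/numeric fluents, chosen as the minimal closure of what the
supported worked examples actually exercise: conjunction, negation,
equality over entity-valued terms, numeric comparison (`< <= = >= >`),
and `assign` / `increase` / `decrease` effects.  Deliberately *not*
supported: durative or temporal actions, conditional effects, quantifiers,
derived predicates, and probabilistic constructs (durations, saliencies) —
plan **validation**, not plan recognition or synthesis, is the scope.

Conventions that matter in practice:

* **Labels** are hyphen-separated tokens, `class-arg1-arg2…`, as produced
  by annotators; entity names may contain underscores but never hyphens,
  and identifiers are case-sensitive.  A schema's `:label` template may
  contain literal tokens (e.g. the `open_egg_shell` in
  `fill-{stuff}-open_egg_shell-{to}`), and several `:action` blocks may
  share a class name as long as their ground labels stay distinct — this
  is how one action class (*take*) can have different semantics over
  storages (must be open) and surfaces.
* **Integer multiplicity tokens** (`take-1-egg_shell-counter`) are
  entities of a `count` type whose names parse as integers; in numeric
  positions a bound count entity evaluates to its integer value, so a
  grounded `increase` amount is an ordinary constant.
* **Initial-state totality**: entity-valued fluents must be assigned for
  every ground instance (a missing one is a semantic error); boolean
  fluents default to false, numeric fluents to 0.
* **Instantaneous actions**: each annotated segment's action applies at
  its start time; the state is piecewise-constant in between.  Durations
  carry no semantics in validation.
* Validation stops at the **first failure** — downstream state is
  undefined after an impossible action.  The report distinguishes, by
  wording only, the two possible causes (domain too strict vs label
  sequence impossible); it never auto-repairs either side.

## The packaged toy domains

Three small kitchen domains (`brownie`, `eggs`, `sandwich`) reproduce the
published action-class dictionaries exactly (11, 12, 12 classes; 13 in
union), with entity sets drawn from the published annotation vocabulary.
Two modelling choices were forced by the published 40-row annotation
extract that ships with the package:

* Countable items (egg shells) are tracked only through the hand-capacity
  counter `objects_taken` (max 3), not through per-location counts.  The
  printed extract takes three single shells from the counter after placing
  only two there — consistent annotation at the granularity the annotators
  used, but unsatisfiable under strict per-location conservation.
  Discrete takeables keep a fully conserved `is-at` location fluent, which
  is what makes the duplicated-take example fail.
* The shell-emptying `fill` variant requires only that something is held,
  because the same `fill-egg-open_egg_shell-bowl` label legitimately
  occurs once per egg; the generic vessel-to-vessel `fill` keeps the
  causal `is-in` precondition.

The extract's end times equal the next row's start (the source annotation
is gap-free); the final segment's end is an assumed value because only its
start is published.

## Reliability scoring

The unit of analysis is a fixed-resolution time slice, **10 ms** by
default — finer than the shortest segment in the packaged extract (4 ms
segments exist; slicing at 1 ms reproduces exact duration weighting when
needed) yet cheap.  Slice *i* carries the label covering `i*resolution`;
unannotated time gets the reserved `NONE` label and counts as a real
disagreement unless `ignore_none` is set.  Comparison is on full ground
labels by default (`class_level` coarsens to classes).  Within a tier,
overlapping segments are tolerated for scoring and resolved
last-writer-wins; plan conversion refuses them.

Cohen's κ comes from the slice confusion table with
p𝑒 = Σₖ pₐ(k)·p_b(k); when both series are constant on the same label
(p𝑒 = 1) κ is defined as 1 for perfect agreement, 0 otherwise.
Krippendorff's α uses the nominal difference function with slices as
units, two observers, no missing data: α = 1 − D₀/D𝑒 with the finite-n
correction in D𝑒, so α and κ agree to O(1/n) on large samples (asserted
in tests against a 10⁵-slice simulation, and κ against an independent
library implementation).

Disagreement intervals are classified *boundary shift* when the interval
is at most `window` ms long (default **1000 ms**) and the same label
appears immediately adjacent in the other tier; otherwise *substitution*.
The classification is diagnostic only and feeds no metric.

## Routine mining

The Markov model uses maximum-likelihood row normalisation and **no
smoothing**: a zero transition count is meaningful, because plans enter
the model only after validation, so absent edges are causally absent and
invented edges cannot occur.  DOT export encodes probability as edge
pen-width and prints counts as edge labels.

Cross-run property curves align runs on **normalised time with B = 100
bins** of each run's own duration, evaluating the piecewise-constant state
at bin midpoints; runs of different lengths therefore contribute equally
per relative position.  Initial-state change-point flagging is exact value
comparison — a relocated object between recording sessions is a
deterministic setup change, not noise, so no statistics are applied.

## The synthetic generator

The generator emulates the study conditions the package is designed for:
valid plans sampled by forward search (uniform choice among applicable
ground actions — no goal bias, the simplest sampler that guarantees causal
validity), **log-normal segment durations with μ = ln 2000 ms, σ = 0.75**
(right-skewed, median 2 s, like observed inter-start gaps), and a
two-annotator corruption model: Gaussian **boundary jitter (default
sd 300 ms)** — the dominant disagreement mode between real annotators —
plus **label confusion (default rate 0.05)** with a co-classed label.
A config's seed fully determines all output through a single random
stream.

What the generator does *not* emulate: goal-directed structure (real
subjects cook; sampled plans wander), realistic action-class frequencies,
abandoned/overlapping activities, and annotator drift over a session.
Passing reliability tests on synthetic corpora therefore demonstrate
metric correctness and monotone response to corruption, not the agreement
level to expect on real video annotation.

## Problem sizes and numerical choices

The test suite and acceptance script size their simulations for a
single-CPU desk run: 200 random domains for brute-force oracle
equivalence, 1000 seeded plans (length 10) for the round-trip and
causal-edge checks, 10⁵ slices for the κ null (|κ| < 0.02 band) and the
α≈κ comparison, and 20-seed ensembles per corruption level for the
monotone-degradation checks.  Boundary jitter is clipped to preserve
segment ordering and ≥ 1 ms segments.  Times are integer milliseconds
throughout, intervals half-open `[start, end)` so adjacent segments tile.

## Known limitations

* One annotation tier per run and exactly two annotators for reliability;
  no Fleiss-style generalisation, no chance-corrected segmentation
  metrics, no significance tests on κ differences.
* The ELAN integration reads/writes the 4-column tab-delimited export
  only, not `.eaf` project files, and ignores video entirely.
* The grammar is a reconstruction: equality/numeric-comparison
  preconditions and assign/increase/decrease effects cover the packaged
  domains, but richer CCBM-style constructs (durations, saliency,
  probabilistic choice) are out of scope.
* `apply`/`validate` copy the full state per step — fine for annotation
  work (tens of fluents, hundreds of steps), not meant for planning-scale
  state spaces.
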
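"""Routine mining: Markov models, property curves, initial states, timelines."""

import numpy as np
import pytest

import semannot as sa


def _plan(domain, labels):
    return sa.labels_to_plan(domain, [(i * 1000, lab) for i, lab in enumerate(labels)])


def test_single_plan_chain_probabilities_one(toy_domain):
    plan = _plan(toy_domain, ["take-knife-drawer", "put-knife-board"])
    model = sa.build_markov([plan], level="class")
    probs = model.probabilities
    assert probs[("initial", "take")] == 1.0
    assert probs[("take", "put")] == 1.0
    assert probs[("put", "finish")] == 1.0
    assert set(model.states) == {"initial", "take", "put", "finish"}


def test_two_plans_split_transition(toy_domain):
    p1 = _plan(toy_domain, ["take-knife-drawer", "put-knife-board"])
    p2 = _plan(toy_domain, ["take-knife-drawer", "stir-knife", "put-knife-board"])
    model = sa.build_markov([p1, p2], level="class")
    probs = model.probabilities
    assert probs[("take", "put")] == pytest.approx(0.5)
    assert probs[("take", "stir")] == pytest.approx(0.5)
    assert model.counts[("initial", "take")] == 2


def test_ground_level_keeps_arguments(toy_domain):
    plan = _plan(toy_domain, ["take-knife-drawer", "put-knife-board"])
    model = sa.build_markov([plan], level="ground")
    assert ("take-knife-drawer", "put-knife-board") in model.counts


def test_rows_normalise_to_one(brownie_domain):
    rng = np.random.default_rng(2)
    config = sa.GeneratorConfig(seed=2, max_plan_length=15)
    plans = [sa.gen_plan(brownie_domain, config, rng=rng)[0] for _ in range(8)]
    model = sa.build_markov(plans)
    probs = model.probabilities
    rows = {}
    for (src, _), p in probs.items():
        rows[src] = rows.get(src, 0.0) + p
    for src, total in rows.items():
        assert total == pytest.approx(1.0), src


def test_generated_plans_yield_only_witnessed_edges(brownie_domain):
    rng = np.random.default_rng(6)
    config = sa.GeneratorConfig(seed=6, max_plan_length=12)
    plans = [sa.gen_plan(brownie_domain, config, rng=rng)[0] for _ in range(25)]
    model = sa.build_markov(plans, level="class")
    assert sa.verify_causal_edges(model, plans, brownie_domain) == 0
    # nothing can be put down (or cleaned/shaken) before anything was taken
    for cls in ("put", "clean", "shake"):
        assert ("initial", cls) not in model.counts


def test_dot_export_encodes_probabilities(toy_domain):
    plan = _plan(toy_domain, ["take-knife-drawer", "put-knife-board"])
    model = sa.build_markov([plan])
    dot = sa.transition_model_to_dot(model)
    assert dot.startswith("digraph")
    assert '"take" -> "put"' in dot and "penwidth=5.00" in dot
    assert '"initial"' in dot and '"finish"' in dot


def test_markov_needs_plans():
    with pytest.raises(ValueError):
        sa.build_markov([])


# -- property curves ---------------------------------------------------------


def _trajectories(domain, label_lists):
    out, durations = [], []
    for labels in label_lists:
        plan = _plan(domain, labels)
        report, traj = sa.validate_plan(domain, plan)
        assert report.valid
        out.append(traj)
        durations.append(len(labels) * 1000)
    return out, durations


def test_always_true_predicate_is_flat_one(toy_domain):
    trajs, durs = _trajectories(
        toy_domain, [["take-knife-drawer"], ["take-knife-drawer", "put-knife-board"]]
    )
    curve = sa.property_curve(trajs, lambda s: True, bins=10, durations=durs)
    assert np.allclose(curve.probability, 1.0)


def test_terminal_probability_is_fraction_of_runs(toy_domain):
    # 3 of 4 runs end with the knife on the board
    to_board = ["take-knife-drawer", "put-knife-board"]
    to_counter = ["take-knife-drawer", "put-knife-counter"]
    trajs, durs = _trajectories(toy_domain, [to_board, to_board, to_board, to_counter])
    curve = sa.property_curve(
        trajs, ("is-at(knife)", "board"), bins=100, durations=durs
    )
    assert curve.probability[-1] == pytest.approx(0.75)
    assert curve.probability[0] == 0.0
    assert ((curve.probability >= 0) & (curve.probability <= 1)).all()


def test_single_run_curve_is_its_trace(toy_domain):
    trajs, durs = _trajectories(toy_domain, [["take-knife-drawer", "put-knife-board"]])
    curve = sa.property_curve(trajs, ("is-at(knife)", "hands"), bins=4, durations=durs)
    # knife in hands over [0, 1000), back down over [1000, 2000)
    assert list(curve.probability) == [1.0, 1.0, 0.0, 0.0]


def test_zero_duration_run_rejected(toy_domain):
    _, traj = sa.validate_plan(toy_domain, [])
    with pytest.raises(ValueError, match="duration"):
        sa.property_curve([traj], lambda s: True, durations=[0])


# -- initial-state table -----------------------------------------------------


def test_shared_initial_state_has_no_change_points(toy_domain):
    table = sa.initial_state_table([toy_domain] * 5, ["is-at(knife)"])
    assert list(table["changed"]) == [False] * 5
    assert set(table["is-at(knife)"]) == {"drawer"}


def test_single_relocation_flags_one_run(toy_domain):
    moved = toy_domain.with_initial({("is-at", ("knife",)): "board"})
    runs = [toy_domain] * 3 + [moved] * 3
    table = sa.initial_state_table(runs, ["is-at(knife)"])
    assert list(table["changed"]) == [False, False, False, True, False, False]


def test_corpus_relocation_ground_truth(brownie_domain):
    config = sa.GeneratorConfig(seed=13, n_runs=30, max_plan_length=5, relocation_run=25)
    records = sa.gen_corpus(brownie_domain, config)
    fluent = "is-at(baking_pan)"
    table = sa.initial_state_table([r.domain for r in records], [fluent])
    changed = [i for i, c in enumerate(table["changed"]) if c]
    assert changed == [25]
    assert table[fluent].nunique() == 2


def test_unknown_fluent_rejected(toy_domain):
    with pytest.raises(ValueError, match="is-at\\(fork\\)"):
        sa.initial_state_table([toy_domain], ["is-at(fork)"])


# -- location timelines ------------------------------------------------------


def test_timeline_of_worked_example(toy_domain):
    plan = _plan(toy_domain, ["take-knife-drawer", "put-knife-board"])
    _, traj = sa.validate_plan(toy_domain, plan)
    timelines = sa.location_timeline(traj, ["knife"])
    assert timelines["knife"] == [(0, "drawer"), (0, "hands"), (1000, "board")]


def test_untouched_object_has_single_entry(brownie_domain, extract_result):
    _, _, traj = extract_result
    timelines = sa.location_timeline(traj, ["baking_pan"])
    assert timelines["baking_pan"] == [(0, "cupboard_bl")]


def test_timeline_length_counts_location_writes(brownie_domain, extract_result):
    plan, _, traj = extract_result
    for obj in ("brownie_box", "bowl", "oil_bottle"):
        writes = sum(
            1
            for step in plan
            for eff in step.action.effects
            if (eff.target.name, eff.target.args) == ("is-at", (obj,))
        )
        assert len(sa.location_timeline(traj, [obj])[obj]) - 1 == writes


def test_timeline_consistent_with_query_property(toy_domain):
    plan = _plan(toy_domain, ["take-knife-drawer", "put-knife-counter", "take-knife-counter"])
    _, traj = sa.validate_plan(toy_domain, plan)
    series = [v for _, v in sa.query_property(traj, "is-at(knife)")]
    compressed = [series[0]] + [b for a, b in zip(series, series[1:]) if a != b]
    assert [loc for _, loc in sa.location_timeline(traj, ["knife"])["knife"]] == compressed


def test_object_without_location_fluent_rejected(toy_domain):
    _, traj = sa.validate_plan(toy_domain, [])
    with pytest.raises(ValueError, match="drawer"):
        sa.location_timeline(traj, ["drawer"])
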
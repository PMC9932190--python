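"""GA core actor: selection schemes, variation operators, elitism, modes."""

import numpy as np
import pytest

import neurotune as nt
from neurotune.ga import (
    GaCoreActor,
    apply_elitism,
    crossover,
    mutate,
    select_indices,
    select_parents,
    selection_probabilities,
)

ALL_SELECTION = ["RWS", "SUS", "RNK", "RSP", "TNT", "TRS"]


def test_rsp_probabilities_closed_form():
    # rank-with-pressure, SP = 1.5, three individuals ordered a < b < c
    probs = selection_probabilities("RSP", [1.0, 2.0, 3.0], sp=1.5)
    np.testing.assert_allclose(probs, [1 / 6, 1 / 3, 1 / 2], atol=1e-12)


def test_rws_single_nonzero_always_selected(rng):
    idx = select_indices("RWS", [0.0, 0.0, 0.7, 0.0], 50, rng)
    assert np.all(idx == 2)


def test_rws_zero_total_falls_back_to_uniform(rng):
    idx = select_indices("RWS", np.zeros(4), 4000, rng)
    counts = np.bincount(idx, minlength=4)
    assert counts.min() > 4000 / 4 * 0.7


@pytest.mark.parametrize("method", ["RWS", "RNK", "RSP", "TRS"])
def test_probabilities_sum_to_one(method, rng):
    f = rng.random(24)
    assert selection_probabilities(method, f, sp=1.5).sum() == pytest.approx(1.0)


@pytest.mark.parametrize("method", ALL_SELECTION)
def test_equal_fitness_selects_uniformly(method, rng):
    n, draws = 8, 8000
    idx = select_indices(method, np.full(n, 0.4), draws, rng,
                         sp=1.5, tournament_size=2)
    counts = np.bincount(idx, minlength=n)
    assert counts.min() > draws / n * 0.7
    assert counts.max() < draws / n * 1.3


def test_sus_copy_counts_bracket_expectation(rng):
    """Stochastic universal sampling gives each individual either
    floor(m p_i) or ceil(m p_i) copies."""
    f = rng.random(10)
    m = 24
    probs = selection_probabilities("SUS", f)
    idx = select_indices("SUS", f, m, rng)
    counts = np.bincount(idx, minlength=10)
    for i in range(10):
        assert np.floor(m * probs[i]) <= counts[i] <= np.ceil(m * probs[i])


def test_select_parents_returns_pairs(rng):
    pairs = select_parents("TNT", rng.random(10), 5, rng)
    assert len(pairs) == 5
    assert all(0 <= i < 10 and 0 <= j < 10 for i, j in pairs)


@pytest.mark.parametrize("method", ["P1XO", "P2XO", "UXO"])
def test_crossover_identical_parents(method, rng):
    x = np.arange(5, dtype=float)
    a, b = crossover(method, x, x, 1.0, rng)
    np.testing.assert_array_equal(a, x)
    np.testing.assert_array_equal(b, x)


def test_crossover_rate_zero_copies_parents(rng):
    a0 = np.zeros(4)
    b0 = np.ones(4)
    for method in ["P1XO", "P2XO", "UXO"]:
        a, b = crossover(method, a0, b0, 0.0, rng)
        np.testing.assert_array_equal(a, a0)
        np.testing.assert_array_equal(b, b0)


def test_one_point_crossover_swaps_suffix(rng):
    """Offspring of all-a and all-b parents carry a single switch point:
    prefix from one parent, suffix from the other."""
    a0 = np.zeros(6)
    b0 = np.ones(6)
    for _ in range(20):
        a, b = crossover("P1XO", a0, b0, 1.0, rng)
        k = int(np.argmax(a == 1.0)) if (a == 1.0).any() else 6
        assert 1 <= k <= 5
        np.testing.assert_array_equal(a, np.r_[np.zeros(k), np.ones(6 - k)])
        np.testing.assert_array_equal(b, np.r_[np.ones(k), np.zeros(6 - k)])


def test_two_point_crossover_swaps_interior_segment(rng):
    a0 = np.zeros(6)
    b0 = np.ones(6)
    a, b = crossover("P2XO", a0, b0, 1.0, rng)
    switches = np.count_nonzero(np.diff(a))
    assert switches in (1, 2)  # interior segment (may touch the end)
    np.testing.assert_array_equal(a + b, np.ones(6))


def test_single_gene_chromosome_copies_under_point_crossover(rng):
    a, b = crossover("P1XO", np.array([1.0]), np.array([2.0]), 1.0, rng)
    assert (a[0], b[0]) == (1.0, 2.0)


def test_mutation_rate_zero_is_identity(space, rng):
    x = space.sample_uniform(rng)
    for method in ["BDM", "SPM", "UNM"]:
        np.testing.assert_array_equal(mutate(method, x, 0.0, space, rng), x)


def test_boundary_mutation_snaps_to_bounds(space, rng):
    x = space.midpoint()
    y = mutate("BDM", x, 1.0, space, rng)
    assert all(v in (space.lo[i], space.hi[i]) for i, v in enumerate(y))


def test_single_point_mutation_changes_one_gene(rng):
    space = nt.ParamSpace(
        [nt.ParamDescriptor(f"x{i}", "continuous", 0, 1) for i in range(5)]
    )
    x = np.full(5, 0.5)
    y = mutate("SPM", x, 1.0, space, rng)
    assert np.count_nonzero(y != x) == 1


def test_uniform_mutation_resamples_in_box(space, rng):
    x = space.midpoint()
    for _ in range(20):
        y = mutate("UNM", x, 1.0, space, rng)
        assert np.all(y >= space.lo) and np.all(y <= space.hi)
        ints = y[space.is_integer]
        np.testing.assert_array_equal(ints, np.round(ints))


@pytest.mark.parametrize("el, expected", [(0, []), (1, [2]), (3, [2, 0, 1])])
def test_elitism_sizes(el, expected):
    assert apply_elitism([0.5, 0.1, 0.9], el) == expected


def test_elitism_stable_under_ties():
    assert apply_elitism([0.5, 0.5, 0.5], 2) == [0, 1]


def test_actor_exposes_eight_modes_with_table_rates(space):
    cfg = nt.GaConfig()  # P = CP = 24, EL = 1
    actor = GaCoreActor(space, cfg, np.random.default_rng(0))
    assert len(actor.modes) == 8
    assert actor.production("update-population-crossover-write") == {"out": 23}
    assert actor.production("update-population-complete-write") == {}
    assert actor.consumption("update-population-crossover-read") == {"in": 23}
    assert actor.consumption("update-population-complete-read") == {}


def test_mode_walk_single_generation(landscape, space):
    tuner = nt.PipelineTuner(pnds=landscape, space=space, strategy="ga",
                             config=nt.GaConfig(max_iterations=1), seed=0)
    graph, core, _ = tuner.build_graph()
    graph.run(lambda: core.terminated)
    assert core.mode_history == [
        "initialize-write", "initialize-read", "stopping-evaluation",
        "update-population-crossover-write",
        "update-population-crossover-read",
        "update-population-complete-write",
        "update-population-complete-read",
        "stopping-evaluation", "write-output",
    ]


def test_best_monotone_and_eval_count_with_elitism(landscape, space):
    iters = 10
    tuner = nt.PipelineTuner(pnds=landscape, space=space, strategy="ga",
                             config=nt.GaConfig(max_iterations=iters), seed=4)
    res = tuner.fit()
    best = res.history["best_fitness"].to_numpy()
    assert np.all(np.diff(best) >= 0)
    # P - EL evaluations per generation after the initial population
    assert res.n_evaluations == 24 + iters * 23


def test_nonzero_complete_phase_fills_population(landscape, space):
    """With CP < P the complete phase re-evaluates P - CP survivors, so
    per-generation cost is still P - EL."""
    cfg = nt.GaConfig(population_size=12, mating_size=8, elite_size=2,
                      max_iterations=4)
    tuner = nt.PipelineTuner(pnds=landscape, space=space, strategy="ga",
                             config=cfg, seed=1)
    res = tuner.fit()
    assert res.n_evaluations == 12 + 4 * (12 - 2)


def test_config_validation():
    with pytest.raises(ValueError):
        nt.GaConfig(elite_size=30).validate()
    with pytest.raises(ValueError):
        nt.GaConfig(crossover_rate=1.5).validate()
    with pytest.raises(ValueError):
        nt.GaConfig(selection="XXX").validate()
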
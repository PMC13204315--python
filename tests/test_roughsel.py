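"""Discretisation, dependency degree, and reduct searches against the exact oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gliosig import roughsel
from gliosig.roughsel import (
    AnnealingSchedule,
    DecisionTable,
    dependency_degree,
    discretise_equal_frequency,
    exhaustive_reduct_oracle,
    greedy_reduct,
    indiscernibility_classes,
    jaccard,
    simulated_annealing_reduct,
    stochastic_greedy_reduct,
)


def _random_table(rng, n_obj, n_attr, n_vals=3):
    return DecisionTable(
        objects=[f"u{i}" for i in range(n_obj)],
        attributes=[f"a{i:02d}" for i in range(n_attr)],
        values=rng.integers(0, n_vals, size=(n_obj, n_attr)),
        decision=rng.integers(0, 2, size=n_obj),
    )


# ---------------------------------------------------------------------------
# discretisation
# ---------------------------------------------------------------------------

def test_equal_frequency_thirds():
    m = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["g"],
                     columns=[f"s{i}" for i in range(6)]).astype(float)
    labels = pd.Series([0, 0, 0, 1, 1, 1], index=m.columns)
    t = discretise_equal_frequency(m, labels)
    assert list(t.values[:, 0]) == [0, 0, 1, 1, 2, 2]


def test_constant_gene_collapses_to_single_bin():
    m = pd.DataFrame([[5.0] * 6], index=["g"], columns=[f"s{i}" for i in range(6)])
    t = discretise_equal_frequency(m, pd.Series([0, 1, 0, 1, 0, 1], index=m.columns))
    assert set(t.values[:, 0]) == {0}


def test_frozen_cutpoints_applied_to_new_samples():
    train = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["g"],
                         columns=[f"s{i}" for i in range(6)]).astype(float)
    t = discretise_equal_frequency(train, pd.Series([0, 0, 0, 1, 1, 1], index=train.columns))
    test = pd.DataFrame([[99.0]], index=["g"], columns=["new"])
    t2 = discretise_equal_frequency(test, pd.Series([1], index=["new"]),
                                    cutpoints=t.cutpoints)
    assert t2.values[0, 0] == 2  # beyond both cut-points -> high


# ---------------------------------------------------------------------------
# indiscernibility and dependency degree (worked table)
# ---------------------------------------------------------------------------

def test_indiscernibility_partitions(worked_table):
    assert indiscernibility_classes(worked_table, []) == [["u1", "u2", "u3", "u4"]]
    assert indiscernibility_classes(worked_table, ["a"]) == [["u1", "u2"], ["u3", "u4"]]
    assert indiscernibility_classes(worked_table, ["a", "b"]) == [
        ["u1"], ["u2"], ["u3"], ["u4"]]


def test_dependency_degrees_on_worked_table(worked_table):
    assert dependency_degree(worked_table, ["a", "b"]) == 1.0
    assert dependency_degree(worked_table, ["a"]) == 0.5
    assert dependency_degree(worked_table, ["b"]) == 0.5


def test_single_class_decision_has_full_empty_set_dependency():
    t = DecisionTable(objects=["u1", "u2"], attributes=["a"],
                      values=np.array([[0], [1]]), decision=np.array([1, 1]))
    assert dependency_degree(t, []) == 1.0


# ---------------------------------------------------------------------------
# greedy / stochastic / annealing searches
# ---------------------------------------------------------------------------

def test_greedy_solves_worked_table(worked_table):
    r = greedy_reduct(worked_table)
    assert sorted(r.attributes) == ["a", "b"]
    assert r.gamma == 1.0 == r.gamma_full


def test_perfect_attribute_yields_singleton_reduct():
    rng = np.random.default_rng(0)
    t = _random_table(rng, 20, 5)
    t.values[:, 2] = t.decision          # a02 discriminates perfectly
    r = greedy_reduct(t)
    assert r.attributes == ["a02"]
    assert r.gamma == r.gamma_full == 1.0


def test_constant_attributes_mixed_decision_gives_empty_reduct():
    t = DecisionTable(objects=["u1", "u2"], attributes=["a", "b"],
                      values=np.zeros((2, 2), dtype=int), decision=np.array([0, 1]))
    r = greedy_reduct(t)
    assert r.attributes == [] and r.gamma == 0.0 == r.gamma_full


def test_greedy_crosses_zero_gain_plateau():
    # XOR decision: no single attribute has positive gain, both are needed
    t = DecisionTable(objects=list("wxyz"), attributes=["a", "b"],
                      values=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
                      decision=np.array([0, 1, 1, 0]))
    r = greedy_reduct(t)
    assert r.gamma == r.gamma_full == 1.0
    assert sorted(r.attributes) == ["a", "b"]


def test_stochastic_with_top1_is_bit_identical_to_greedy():
    rng = np.random.default_rng(5)
    for _ in range(5):
        t = _random_table(rng, 20, 6)
        g = greedy_reduct(t)
        s = stochastic_greedy_reduct(t, top_k=1, seed=int(rng.integers(1 << 30)))
        assert g.attributes == s.attributes and g.gamma == s.gamma


def test_stochastic_always_reaches_full_dependency(worked_table):
    for seed in range(10):
        r = stochastic_greedy_reduct(worked_table, top_k=3, seed=seed)
        assert r.gamma == 1.0


def test_annealing_schedule_closed_form():
    sched = AnnealingSchedule()
    assert sched.temperature(80) == pytest.approx(0.05 * 0.95 ** 80)
    assert sched.temperature(80) == pytest.approx(8.3e-4, rel=0.01)


def test_annealing_finds_unique_optimum_in_majority_of_seeds():
    # objective with a unique optimum: overlap with a target pair
    rng = np.random.default_rng(2)
    t = _random_table(rng, 15, 8)
    target = {"a01", "a05"}

    def objective(attrs):
        return len(target & set(attrs))

    found = 0
    for seed in range(20):
        sched = AnnealingSchedule(subset_size=2, iterations=80, seed=seed)
        r = simulated_annealing_reduct(t, sched, objective=objective)
        found += set(r.attributes) == target
    assert found > 10


def test_annealing_rejects_oversized_subset(worked_table):
    with pytest.raises(ValueError):
        simulated_annealing_reduct(worked_table, AnnealingSchedule(subset_size=5))


# ---------------------------------------------------------------------------
# jaccard
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ({1, 2, 3}, {1, 2, 3}, 1.0),
    ({1, 2}, {3, 4}, 0.0),
    ({1, 2, 3}, {2, 3, 4}, 0.5),
    (set(), set(), 1.0),
])
def test_jaccard_values(a, b, expected):
    assert jaccard(a, b) == expected


# ---------------------------------------------------------------------------
# exhaustive oracle and properties
# ---------------------------------------------------------------------------

def test_oracle_on_worked_table(worked_table):
    assert exhaustive_reduct_oracle(worked_table) == [frozenset({"a", "b"})]


def test_oracle_with_perfect_attribute_and_noise():
    rng = np.random.default_rng(1)
    t = _random_table(rng, 12, 4, n_vals=2)
    t.values[:, 0] = t.decision
    minima = exhaustive_reduct_oracle(t)
    assert frozenset({"a00"}) in minima
    assert all(len(s) == 1 for s in minima)


def test_oracle_handles_inconsistent_tables():
    # identical tuples with conflicting decisions: gamma_A < 1
    t = DecisionTable(objects=["u1", "u2", "u3"], attributes=["a"],
                      values=np.array([[0], [0], [1]]), decision=np.array([0, 1, 1]))
    gamma_full = dependency_degree(t, ["a"])
    assert gamma_full == pytest.approx(1 / 3)
    minima = exhaustive_reduct_oracle(t)
    assert minima == [frozenset({"a"})]
    r = greedy_reduct(t)
    assert r.gamma == gamma_full


def test_oracle_rejects_large_tables():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        exhaustive_reduct_oracle(_random_table(rng, 5, 20))


@given(st.integers(0, 500))
def test_gamma_is_monotone_in_attribute_sets(seed):
    rng = np.random.default_rng(seed)
    t = _random_table(rng, int(rng.integers(4, 25)), int(rng.integers(2, 7)))
    attrs = list(t.attributes)
    k = int(rng.integers(0, len(attrs)))
    base = list(rng.choice(attrs, size=k, replace=False))
    extra = [a for a in attrs if a not in base][:1]
    assert dependency_degree(t, base) <= dependency_degree(t, base + extra) + 1e-12


@pytest.mark.parametrize("seed", range(20))
def test_greedy_matches_oracle_gamma_and_is_minimal(seed):
    rng = np.random.default_rng(seed)
    t = _random_table(rng, int(rng.integers(8, 40)), int(rng.integers(2, 10)))
    r = greedy_reduct(t)
    assert r.gamma == pytest.approx(r.gamma_full)
    # superset-minimality: removing any member lowers gamma
    for a in r.attributes:
        rest = [b for b in r.attributes if b != a]
        assert dependency_degree(t, rest) < r.gamma - 1e-12
    minima = exhaustive_reduct_oracle(t, max_attributes=10)
    best = min((len(s) for s in minima), default=0)
    assert len(r.attributes) >= best
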
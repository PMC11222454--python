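"""Structure learning: family scores, hill climbing vs exhaustive search,
bootstrap strengths and the quartile filter."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from temponet.bayesnet import (
    DAGStructure,
    LearnConfig,
    StrengthNetwork,
    bootstrap_strength,
    classify_edges,
    family_bic,
    hill_climb,
    network_score,
    quartile_filter,
)
from temponet.errors import InvalidInputError, InvalidParameterError


def all_dags(names):
    """Exhaustive DAG enumeration: every arc subset that admits a topological
    order (independent brute-force oracle for hill climbing)."""
    pairs = [(u, v) for u in names for v in names if u != v]
    for r in range(len(pairs) + 1):
        for arcs in combinations(pairs, r):
            if _is_acyclic(names, arcs):
                yield frozenset(arcs)


def _is_acyclic(names, arcs):
    children = {n: [] for n in names}
    indeg = {n: 0 for n in names}
    for u, v in arcs:
        children[u].append(v)
        indeg[v] += 1
    stack = [n for n in names if indeg[n] == 0]
    seen = 0
    while stack:
        n = stack.pop()
        seen += 1
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    return seen == len(names)


def best_dag_by_enumeration(frame):
    names = list(frame.index)
    best, best_score = None, -np.inf
    for arcs in all_dags(names):
        dag = DAGStructure(tuple(names), {n: "unknown" for n in names}, arcs)
        s = network_score(frame, dag)
        if s > best_score:
            best, best_score = arcs, s
    return best, best_score


def test_dag_enumeration_counts():
    assert sum(1 for _ in all_dags(["a", "b", "c"])) == 25
    assert sum(1 for _ in all_dags(["a", "b", "c", "d"])) == 543


def test_family_bic_hand_value():
    frame = pd.DataFrame([[-1.0, 0.0, 1.0]], index=["x"])
    expected = -1.5 * (np.log(2 * np.pi * 2 / 3) + 1) - np.log(3)
    assert family_bic(frame, "x", ()) == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(-4.7472, abs=5e-5)


def test_network_score_is_sum_of_families(rng):
    frame = pd.DataFrame(rng.normal(size=(3, 30)), index=["a", "b", "c"])
    dag = DAGStructure(
        ("a", "b", "c"), {n: "unknown" for n in "abc"}, frozenset({("a", "b"), ("a", "c")})
    )
    total = (
        family_bic(frame, "a", ())
        + family_bic(frame, "b", ("a",))
        + family_bic(frame, "c", ("a",))
    )
    assert network_score(frame, dag) == pytest.approx(total, rel=1e-12)


def test_independent_noise_parent_costs_half_log_n():
    """Adding an independent-noise parent changes the family score by the
    penalty -log(n)/2 plus half a chi-square(1) fit term (small at fixed seed)."""
    rng = np.random.default_rng(5)
    n = 10_000
    frame = pd.DataFrame(rng.normal(size=(2, n)), index=["p", "c"])
    delta = family_bic(frame, "c", ("p",)) - family_bic(frame, "c", ())
    assert delta == pytest.approx(-0.5 * np.log(n), abs=1.0)


def test_collinear_parents_disallowed():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    frame = pd.DataFrame([x, 2 * x, rng.normal(size=50)], index=["a", "b", "c"])
    assert family_bic(frame, "c", ("a", "b")) == -np.inf


def test_hill_climb_empty_on_independent_noise():
    rng = np.random.default_rng(31)
    frame = pd.DataFrame(rng.normal(size=(3, 5000)), index=["a", "b", "c"])
    assert hill_climb(frame).arcs == frozenset()


def test_hill_climb_recovers_chain_either_orientation():
    rng = np.random.default_rng(4)
    x = rng.normal(size=500)
    y = 0.9 * x + rng.normal(size=500)
    dag = hill_climb(pd.DataFrame([x, y], index=["X", "Y"]))
    assert dag.arcs in ({("X", "Y")}, {("Y", "X")}, frozenset({("X", "Y")}), frozenset({("Y", "X")}))
    assert len(dag.arcs) == 1


def test_hill_climb_matches_exhaustive_optimum_three_variables():
    """On seeded 3-variable Gaussian data the greedy search must attain the
    global BIC optimum over all 25 DAGs."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60)
        y = 0.8 * x + rng.normal(size=60)
        z = -0.6 * y + rng.normal(size=60)
        frame = pd.DataFrame([x, y, z], index=["a", "b", "c"])
        learned = hill_climb(frame)
        _, best_score = best_dag_by_enumeration(frame)
        assert network_score(frame, learned) == pytest.approx(best_score, rel=1e-12)


def test_hill_climb_score_never_below_empty_graph(rng):
    frame = pd.DataFrame(rng.normal(size=(4, 40)), index=list("abcd"))
    dag = hill_climb(frame)
    empty = DAGStructure(tuple("abcd"), {n: "unknown" for n in "abcd"})
    assert network_score(frame, dag) >= network_score(frame, empty)


def test_hill_climb_deterministic(rng):
    frame = pd.DataFrame(rng.normal(size=(5, 25)), index=list("abcde"))
    assert hill_climb(frame).arcs == hill_climb(frame).arcs


def test_hill_climb_needs_samples():
    frame = pd.DataFrame([[1.0, 2.0]], index=["a"])
    with pytest.raises(InvalidInputError):
        hill_climb(frame)


def _strong_pair_frame(seed, n=60):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 0.95 * x + 0.3 * rng.normal(size=n)
    z = rng.normal(size=n)
    return pd.DataFrame([x, y, z], index=["x", "y", "z"])


def test_bootstrap_strength_constant_structure():
    """When every replicate learns the same arc set, its arcs score 1.0."""
    frame = _strong_pair_frame(0)
    net = bootstrap_strength(frame, LearnConfig(B=25, rng_seed=1), edge_set="observed")
    strong = net.arcs[net.arcs["strength"] == 1.0]
    pairs = set(zip(strong["source"], strong["target"]))
    assert ("x", "y") in pairs or ("y", "x") in pairs


def test_bootstrap_strengths_are_frequencies():
    frame = _strong_pair_frame(3, n=30)
    B = 16
    net = bootstrap_strength(frame, LearnConfig(B=B, rng_seed=5), edge_set="observed")
    s = net.arcs["strength"].to_numpy()
    assert np.all((s >= 0) & (s <= 1))
    np.testing.assert_allclose(s * B, np.round(s * B), atol=1e-9)


def test_bootstrap_deterministic_and_default_B():
    assert LearnConfig().B == 1000
    frame = _strong_pair_frame(7, n=25)
    cfg = LearnConfig(B=10, rng_seed=9)
    a = bootstrap_strength(frame, cfg)
    b = bootstrap_strength(frame, cfg)
    pd.testing.assert_frame_equal(a.arcs, b.arcs)


def test_planted_edge_outranks_absent_edge():
    """Across 10 scenario draws, a planted strong edge must score a higher
    bootstrap strength than a non-adjacent null pair."""
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 40
        x = rng.normal(size=n)
        y = 0.9 * x + rng.normal(size=n) * np.sqrt(1 - 0.81)
        z = rng.normal(size=n)
        frame = pd.DataFrame([x, y, z], index=["x", "y", "z"])
        net = bootstrap_strength(frame, LearnConfig(B=40, rng_seed=seed), edge_set="observed")
        s = {(r["source"], r["target"]): r["strength"] for _, r in net.arcs.iterrows()}
        planted = s.get(("x", "y"), 0) + s.get(("y", "x"), 0)
        absent = s.get(("x", "z"), 0) + s.get(("z", "x"), 0)
        wins += planted > absent
    assert wins >= 9


def _network_from_strengths(strengths):
    arcs = pd.DataFrame(
        {
            "source": [f"s{i}" for i in range(len(strengths))],
            "source_type": "miRNA",
            "target": [f"t{i}" for i in range(len(strengths))],
            "target_type": "mRNA",
            "strength": strengths,
            "retained": True,
        }
    )
    types = {}
    for i in range(len(strengths)):
        types[f"s{i}"] = "miRNA"
        types[f"t{i}"] = "mRNA"
    return StrengthNetwork(arcs, types, "24h", B=100)


def test_quartile_filter_hand_example():
    net = _network_from_strengths([0.1, 0.2, 0.3, 0.9])
    out = quartile_filter(net, 0.75)
    assert out.quartile_threshold == pytest.approx(0.45)
    assert set(out.retained_arcs()["strength"]) == {0.9}


def test_quartile_filter_all_equal_retains_all():
    net = _network_from_strengths([0.5] * 6)
    out = quartile_filter(net)
    assert len(out.retained_arcs()) == 6


def test_quartile_filter_retains_about_a_quarter(rng):
    strengths = rng.permutation(np.linspace(0.01, 1.0, 100))
    out = quartile_filter(_network_from_strengths(list(strengths)))
    assert abs(len(out.retained_arcs()) - 25) <= 2


def test_quartile_filter_no_positive_strengths():
    net = _network_from_strengths([0.0, 0.0])
    out = quartile_filter(net)
    assert out.retained_arcs().empty
    with pytest.raises(InvalidParameterError):
        quartile_filter(net, 1.5)


def test_classify_edges_partition():
    arcs = pd.DataFrame(
        {
            "source": ["miR_a", "gene_X"],
            "source_type": ["miRNA", "mRNA"],
            "target": ["gene_X", "gene_Y"],
            "target_type": ["mRNA", "mRNA"],
            "strength": [0.9, 0.8],
            "retained": [True, True],
        }
    )
    net = StrengthNetwork(
        arcs, {"miR_a": "miRNA", "gene_X": "mRNA", "gene_Y": "mRNA"}, "24h", 10
    )
    counts = classify_edges(net)
    assert counts == {
        "miRNA->miRNA": 0,
        "miRNA->mRNA": 1,
        "mRNA->miRNA": 0,
        "mRNA->mRNA": 1,
    }
    assert sum(counts.values()) == len(net.retained_arcs())


def test_classify_edges_random_partition_sums(rng):
    types = ["miRNA", "mRNA"]
    rows = []
    node_types = {}
    for i in range(30):
        s, t = f"n{i}", f"n{(i * 7 + 3) % 40}"
        if s == t:
            continue
        st, tt = types[int(rng.integers(2))], types[int(rng.integers(2))]
        node_types.setdefault(s, st)
        node_types.setdefault(t, tt)
        rows.append(
            {
                "source": s,
                "source_type": node_types[s],
                "target": t,
                "target_type": node_types[t],
                "strength": float(rng.uniform()),
                "retained": True,
            }
        )
    frame = pd.DataFrame(rows).drop_duplicates(subset=["source", "target"])
    net = StrengthNetwork(frame, node_types, "24h", 10)
    assert sum(classify_edges(net).values()) == len(frame)


def test_dag_structure_rejects_cycles_and_self_arcs():
    types = {n: "unknown" for n in "ab"}
    with pytest.raises(InvalidParameterError):
        DAGStructure(("a", "b"), types, frozenset({("a", "b"), ("b", "a")}))
    with pytest.raises(InvalidParameterError):
        DAGStructure(("a", "b"), types, frozenset({("a", "a")}))
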
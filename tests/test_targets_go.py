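"""Consensus targets, Venn partition, Fisher/elim enrichment, Wang
similarity and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import comb

from mirhsr.targets_go import (
    GoDag,
    TermSimilarity,
    consensus_targets,
    crosstab_targets_by_class,
    elim_enrichment,
    fisher_enrichment,
    go_semantic_similarity,
    permutation_pvalue,
    unique_group_targets,
    venn_partition,
)


def _edges(pairs):
    return pd.DataFrame(pairs, columns=["mirna", "gene"])


# -- consensus voting ---------------------------------------------------------

def test_consensus_support_rules():
    alg1 = _edges([("m1", "g1"), ("m1", "g2")])
    alg2 = _edges([("m1", "g1"), ("m2", "g3")])
    alg3 = _edges([("m2", "g3")])
    graph = consensus_targets([alg1, alg2, alg3], min_support=2)
    kept = set(zip(graph.edges["mirna"], graph.edges["gene"]))
    assert kept == {("m1", "g1"), ("m2", "g3")}  # 1-of-3 edges dropped
    union = consensus_targets([alg1, alg2, alg3], min_support=1)
    assert len(union.edges) == 3


def test_consensus_matches_brute_force_counting():
    rng = np.random.default_rng(0)
    mirnas = [f"m{i}" for i in range(20)]
    genes = [f"g{i}" for i in range(50)]
    lists = []
    for _ in range(5):
        pairs = [(m, g) for m in mirnas for g in genes if rng.random() < 0.05]
        lists.append(_edges(pairs))
    graph = consensus_targets(lists, min_support=2)
    # oracle: plain dict counting
    votes = {}
    for df in lists:
        for e in set(zip(df["mirna"], df["gene"])):
            votes[e] = votes.get(e, 0) + 1
    want = {e for e, v in votes.items() if v >= 2}
    assert set(zip(graph.edges["mirna"], graph.edges["gene"])) == want
    assert all(graph.edges["support"] >= 2)


def test_consensus_duplicates_warn_and_min_support_guard():
    dup = _edges([("m1", "g1"), ("m1", "g1")])
    with pytest.warns(UserWarning, match="duplicate"):
        consensus_targets([dup, _edges([("m1", "g1")])], min_support=2)
    with pytest.raises(ValueError, match="fewer algorithms"):
        consensus_targets([dup], min_support=2)


def test_unique_group_targets_excludes_shared_genes():
    graph = consensus_targets(
        [_edges([("m1", "gA"), ("m1", "gS"), ("m2", "gB"), ("m2", "gS")])] * 2,
        min_support=2,
    )
    out = unique_group_targets({"G1": {"m1"}, "G2": {"m2"}}, graph)
    assert out == {"G1": {"gA"}, "G2": {"gB"}}  # gS targeted by both -> dropped
    single = unique_group_targets({"G1": {"m1"}}, graph)
    assert single == {"G1": {"gA", "gS"}}


# -- venn ---------------------------------------------------------------------

def test_venn_trivial_cases():
    same = venn_partition({"a": {1, 2}, "b": {1, 2}, "c": {1, 2}})
    assert same["common"] == {1, 2} and not same["shared"]
    disjoint = venn_partition({"a": {1}, "b": {2}, "c": {3}})
    assert disjoint["unique"] == {"a": {1}, "b": {2}, "c": {3}}
    assert not disjoint["common"]


@given(st.integers(0, 2**32 - 1))
def test_venn_matches_membership_enumeration(seed):
    rng = np.random.default_rng(seed)
    names = ["x", "y", "z"]
    sets = {n: set(rng.choice(30, size=rng.integers(0, 15), replace=False).tolist())
            for n in names}
    part = venn_partition(sets)
    for el in set().union(*sets.values()):
        members = [n for n in names if el in sets[n]]
        if len(members) == 3:
            assert el in part["common"]
        elif len(members) == 2:
            assert el in part["shared"][tuple(sorted(members))]
        else:
            assert el in part["unique"][members[0]]
    # region sizes sum to the union size
    total = len(part["common"]) + sum(map(len, part["shared"].values())) + sum(
        map(len, part["unique"].values())
    ) + len(part["other"])
    assert total == len(set().union(*sets.values()))


# -- enrichment ---------------------------------------------------------------

def _chain_dag():
    # root <- mid <- leaf plus an unrelated branch
    return GoDag.from_edges(
        [("mid", "root"), ("leaf", "mid"), ("side", "root")]
    )


def test_fisher_matches_hypergeometric_tail_sum():
    population = [f"g{i}" for i in range(100)]
    study = population[:10]
    ann = {"t": set(population[:5]) | set(population[50:55])}  # K=10, k=5
    res = fisher_enrichment(study, population, ann)
    # oracle: direct tail sum of the hypergeometric pmf
    N, K, n = 100, 10, 10
    tail = sum(comb(K, k) * comb(N - K, n - k) / comb(N, n) for k in range(5, 11))
    assert res.loc["t", "p"] == pytest.approx(float(tail), rel=1e-12)


def test_fisher_whole_population_term_p1_and_guards():
    population = [f"g{i}" for i in range(20)]
    res = fisher_enrichment(population[:5], population, {"all": set(population)})
    assert res.loc["all", "p"] == pytest.approx(1.0)
    assert fisher_enrichment([], population, {"all": set(population)}).empty
    with pytest.raises(ValueError, match="population"):
        fisher_enrichment(["ghost"], population, {})


def test_elim_equals_fisher_on_depth1_dag():
    dag = GoDag.from_edges([(f"leaf{i}", "root") for i in range(5)])
    rng = np.random.default_rng(1)
    population = [f"g{i}" for i in range(60)]
    direct = {g: {f"leaf{int(rng.integers(0, 5))}"} for g in population}
    ann = dag.propagate(direct)
    study = population[:15]
    fisher = fisher_enrichment(study, population, ann)
    elim = elim_enrichment(dag, ann, study, population, elim_alpha=0.05)
    for t in dag.terms:
        if t == "root":
            continue  # depth-1: leaves have no descendants, so identical
        assert elim.loc[t, "p_elim"] == pytest.approx(fisher.loc[t, "p"], rel=1e-12)


def test_elim_decorrelates_parent_from_significant_child():
    """When all of a parent's signal sits in one significant child, the
    parent's elim p must exceed its plain Fisher p."""
    dag = _chain_dag()
    population = [f"g{i}" for i in range(40)]
    child_genes = set(population[:8])
    ann = {
        "root": child_genes | set(population[20:30]),
        "mid": child_genes | set(population[20:24]),
        "leaf": child_genes,
        "side": set(population[25:29]),
    }
    study = list(child_genes)  # the entire study is the leaf's genes
    fisher = fisher_enrichment(study, population, ann)
    elim = elim_enrichment(dag, ann, study, population, elim_alpha=0.05)
    assert elim.loc["leaf", "p_elim"] == pytest.approx(fisher.loc["leaf", "p"])
    assert elim.loc["mid", "p_elim"] > fisher.loc["mid", "p"]
    assert elim.loc["root", "p_elim"] > fisher.loc["root", "p"]


def test_elim_alpha_zero_means_no_elimination():
    dag = _chain_dag()
    population = [f"g{i}" for i in range(30)]
    ann = {
        "root": set(population),
        "mid": set(population[:10]),
        "leaf": set(population[:6]),
        "side": set(population[15:20]),
    }
    study = population[:6]
    fisher = fisher_enrichment(study, population, ann)
    elim = elim_enrichment(dag, ann, study, population, elim_alpha=0.0)
    for t in dag.terms:
        assert elim.loc[t, "p_elim"] == pytest.approx(fisher.loc[t, "p"], rel=1e-12)


def test_cyclic_hierarchy_rejected():
    with pytest.raises(ValueError, match="cycle"):
        GoDag.from_edges([("a", "b"), ("b", "a")])


# -- semantic similarity ------------------------------------------------------

def _toy_dag():
    # root with two branches, each two deep: R; A,B -> R; A1 -> A; B1 -> B
    return GoDag.from_edges([("A", "R"), ("B", "R"), ("A1", "A"), ("B1", "B")])


def test_wang_similarity_hand_evaluated():
    dag = _toy_dag()
    sim = TermSimilarity(dag, decay=0.8)
    # S-values for A1: {A1:1, A:0.8, R:0.64}; same shape for B1.
    # only R is shared: sim = (0.64+0.64) / (2.44+2.44)
    assert sim.term_sim("A1", "B1") == pytest.approx(1.28 / 4.88, abs=1e-12)
    # identical sets score 1
    assert go_semantic_similarity(["A1", "B"], ["A1", "B"], dag) == pytest.approx(1.0)
    # sibling terms share the root closure through their parent
    s_ab = sim.term_sim("A", "B")
    assert s_ab == pytest.approx((0.8 + 0.8) / (1.8 + 1.8), abs=1e-12)


def test_set_similarity_symmetric_and_bounded():
    dag = _toy_dag()
    sim = TermSimilarity(dag)
    rng = np.random.default_rng(3)
    terms = dag.terms
    for _ in range(20):
        a = list(rng.choice(terms, size=2, replace=False))
        b = list(rng.choice(terms, size=3, replace=False))
        s1, s2 = sim.set_sim(a, b), sim.set_sim(b, a)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert 0.0 <= s1 <= 1.0


def test_unknown_term_raises():
    dag = _toy_dag()
    with pytest.raises(KeyError, match="ghost"):
        go_semantic_similarity(["ghost"], ["A"], dag)


def test_resnik_variant_behaves():
    dag = _toy_dag()
    population = [f"g{i}" for i in range(20)]
    direct = {g: {"A1" if i < 10 else "B1"} for i, g in enumerate(population)}
    ann = dag.propagate(direct)
    sim = TermSimilarity(dag, measure="resnik", annotations=ann)
    assert sim.term_sim("A1", "A1") == 1.0
    assert sim.term_sim("A1", "B1") == pytest.approx(0.0)  # MICA is the root
    assert 0.0 < sim.term_sim("A1", "A") <= 1.0


# -- permutation null ---------------------------------------------------------

def _random_dag(seed=0, n_terms=40, depth=3):
    from mirhsr.simulate import SimParams, simulate_go

    genes = [f"g{i}" for i in range(50)]
    dag, _, _, _ = simulate_go(
        genes, SimParams(seed=seed, n_mirnas=2), n_terms=n_terms, depth=depth
    )
    return dag


def test_permutation_determinism_and_p_zero_at_max():
    dag = _random_dag()
    r1 = permutation_pvalue(0.5, 4, 4, dag, n_perm=100, seed=9)
    r2 = permutation_pvalue(0.5, 4, 4, dag, n_perm=100, seed=9)
    assert np.array_equal(r1.scores, r2.scores)
    assert r1.p_value == r2.p_value
    # nothing exceeds a perfect observed score (non-identical random sets)
    rmax = permutation_pvalue(1.0, 5, 5, dag, n_perm=200, seed=1)
    assert rmax.p_value == 0.0
    radd = permutation_pvalue(1.0, 5, 5, dag, n_perm=200, seed=1, add_one=True)
    assert radd.p_value == pytest.approx(1 / 201)


def test_permutation_p_monotone_in_observed():
    dag = _random_dag(seed=3)
    ps = [
        permutation_pvalue(obs, 4, 4, dag, n_perm=150, seed=5).p_value
        for obs in (0.1, 0.3, 0.5, 0.7, 0.9)
    ]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_permutation_guards():
    dag = _random_dag(seed=4)
    with pytest.raises(ValueError, match="n_perm"):
        permutation_pvalue(0.5, 3, 3, dag, n_perm=0)
    with pytest.raises(ValueError, match="size"):
        permutation_pvalue(0.5, 10_000, 3, dag, n_perm=10)


# -- crosstab -----------------------------------------------------------------

def test_crosstab_matches_enumeration_and_guards():
    rng = np.random.default_rng(7)
    mirnas = [f"m{i}" for i in range(12)]
    genes = [f"g{i}" for i in range(40)]
    pairs = [(m, g) for m in mirnas for g in genes if rng.random() < 0.1]
    graph = consensus_targets([_edges(pairs)] * 2, min_support=2)
    groups = {"G1": set(mirnas[:4]), "G2": set(mirnas[4:8]), "G3": set()}
    classes = {"early-up": set(genes[:12]), "early-down": set(genes[12:25]),
               "late-up": set(genes[25:])}
    ct = crosstab_targets_by_class(groups, graph, classes)
    for gname, members in groups.items():
        targets = {g for m, g in pairs if m in members}
        for cname, cgenes in classes.items():
            assert ct.loc[gname, cname] == len(targets & cgenes)
    assert (ct.loc["G3"] == 0).all()
    classes_bad = {"a": {"g1", "g2"}, "b": {"g2"}}
    with pytest.raises(ValueError, match="partition"):
        crosstab_targets_by_class(groups, graph, classes_bad)
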
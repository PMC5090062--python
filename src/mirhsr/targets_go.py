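"""Consensus miRNA targets, GO enrichment with elim decorrelation, and
permutation-tested semantic similarity of enriched term sets.

Targets are kept only when predicted by at least ``min_support`` algorithms;
group target sets keep only genes unique to one miRNA group.  Enrichment is
a one-sided hypergeometric test per term; the elim variant walks the DAG
from the deepest level upward and, whenever a term is significant, removes
its study-annotated genes from every ancestor before the ancestor is
tested, decorrelating the hierarchy.

Semantic similarity uses the Wang graph-based measure (contribution decay
0.8 per is_a hop) combined by best-match average; its significance is the
frequency of equally or more similar uniformly drawn term-set pairs of the
same sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "TargetGraph",
    "consensus_targets",
    "unique_group_targets",
    "venn_partition",
    "GoDag",
    "fisher_enrichment",
    "elim_enrichment",
    "go_semantic_similarity",
    "TermSimilarity",
    "SemSimResult",
    "permutation_pvalue",
    "crosstab_targets_by_class",
]


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

@dataclass
class TargetGraph:
    """Bipartite miRNA -> gene edges with per-algorithm support."""

    edges: pd.DataFrame  # columns: mirna, gene, support, algorithms
    min_support: int = 1

    def targets_of(self, mirnas: Iterable[str]) -> set[str]:
        sel = self.edges["mirna"].isin(set(mirnas))
        return set(self.edges.loc[sel, "gene"])

    @property
    def genes(self) -> set[str]:
        return set(self.edges["gene"])


def consensus_targets(
    per_algorithm_edges: Sequence[pd.DataFrame] | Mapping[str, pd.DataFrame],
    min_support: int = 2,
) -> TargetGraph:
    """Vote edges across prediction algorithms, keeping support >= min_support.

    Duplicate edges within one algorithm's list are deduplicated with a
    warning.
    """
    if isinstance(per_algorithm_edges, Mapping):
        items = list(per_algorithm_edges.items())
    else:
        items = [(f"alg{i + 1}", df) for i, df in enumerate(per_algorithm_edges)]
    if len(items) < min_support:
        raise ValueError("fewer algorithms than min_support")
    support: dict[tuple[str, str], list[str]] = {}
    for name, df in items:
        pairs = list(zip(df["mirna"], df["gene"]))
        if len(pairs) != len(set(pairs)):
            warnings.warn(f"duplicate edges in {name}; deduplicating")
        for e in set(pairs):
            support.setdefault(e, []).append(name)
    rows = [
        {"mirna": m, "gene": g, "support": len(algs), "algorithms": tuple(sorted(algs))}
        for (m, g), algs in sorted(support.items())
        if len(algs) >= min_support
    ]
    edges = pd.DataFrame(rows, columns=["mirna", "gene", "support", "algorithms"])
    return TargetGraph(edges=edges, min_support=min_support)


def unique_group_targets(
    groups: Mapping[str, Iterable[str]], graph: TargetGraph
) -> dict[str, set[str]]:
    """Genes targeted by exactly one miRNA group (others discarded)."""
    raw = {g: graph.targets_of(mirnas) for g, mirnas in groups.items()}
    out = {}
    for g, genes in raw.items():
        others = set().union(*(raw[h] for h in raw if h != g)) if len(raw) > 1 else set()
        out[g] = genes - others
    return out


def venn_partition(sets: Mapping[str, Iterable[str]]) -> dict:
    """Exact region assignment of elements across named sets.

    Returns ``common`` (in every set), ``shared`` (exactly two, keyed by the
    sorted name pair), ``unique`` (exactly one) and ``other`` (3+ sets but
    not all, possible only with > 3 sets).
    """
    named = {k: set(v) for k, v in sets.items()}
    names = sorted(named)
    out = {
        "common": set(),
        "shared": {},
        "unique": {n: set() for n in names},
        "other": set(),
    }
    for el in set().union(*named.values()) if named else set():
        members = tuple(sorted(n for n in names if el in named[n]))
        if len(members) == len(names):
            out["common"].add(el)
        elif len(members) == 1:
            out["unique"][members[0]].add(el)
        elif len(members) == 2:
            out["shared"].setdefault(members, set()).add(el)
        else:
            out["other"].add(el)
    return out


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

class GoDag:
    """Acyclic is_a term hierarchy with true-path-propagated annotations.

    Edges run child -> parent.  Term levels are the longest path from a
    root; the elim walk processes larger levels (deeper terms) first, which
    guarantees every descendant is tested before any of its ancestors.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("term hierarchy contains a cycle")
        self.graph = graph
        self._levels = self._compute_levels()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "GoDag":
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        return cls(g)

    @classmethod
    def from_tsv(cls, path) -> "GoDag":
        df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], comment="#")
        return cls.from_edges(df.itertuples(index=False, name=None))

    def _compute_levels(self) -> dict[str, int]:
        levels: dict[str, int] = {}
        for t in nx.topological_sort(self.graph.reverse()):  # parents first
            parents = list(self.graph.successors(t))
            levels[t] = 0 if not parents else 1 + max(levels[p] for p in parents)
        return levels

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def level(self, term: str) -> int:
        return self._levels[term]

    def ancestors(self, term: str) -> set[str]:
        if term not in self.graph:
            raise KeyError(f"unknown term {term}")
        return set(nx.descendants(self.graph, term))  # edges point rootward

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def propagate(self, direct: Mapping[str, Iterable[str]]) -> dict[str, set[str]]:
        """gene -> direct terms  =>  term -> all annotated genes (true path)."""
        ann: dict[str, set[str]] = {t: set() for t in self.graph.nodes}
        for gene, terms in direct.items():
            for t in terms:
                if t not in self.graph:
                    raise KeyError(f"annotation references unknown term {t}")
                ann[t].add(gene)
                for a in self.ancestors(t):
                    ann[a].add(gene)
        return ann


def _hypergeom_upper(k: int, n_study: int, big_k: int, big_n: int) -> float:
    """One-sided over-representation p-value."""
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n_study))


def fisher_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    term_annotations: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation test, BH-adjusted."""
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study genes missing from the population")
    if not study:
        return pd.DataFrame(columns=["term", "study_count", "pop_count", "p", "q"]).set_index("term")
    rows = []
    for term in sorted(term_annotations):
        ann = set(term_annotations[term]) & population
        k = len(ann & study)
        rows.append(
            {
                "term": term,
                "study_count": k,
                "pop_count": len(ann),
                "p": _hypergeom_upper(k, len(study), len(ann), len(population)),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def elim_enrichment(
    dag: GoDag,
    annotations: Mapping[str, Iterable[str]],
    study: Iterable[str],
    population: Iterable[str],
    elim_alpha: float = 0.05,
) -> pd.DataFrame:
    """elim-decorrelated enrichment.

    Terms are tested from the deepest level upward on their *current*
    annotation sets; when a term reaches p <= elim_alpha, its study-annotated
    genes are eliminated from all ancestors' sets before those are tested.
    With elim_alpha = 0 no elimination occurs and the result equals the
    plain Fisher test.
    """
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study genes missing from the population")
    current = {t: set(annotations.get(t, ())) & population for t in dag.terms}
    order = sorted(dag.terms, key=lambda t: (-dag.level(t), t))
    rows = []
    for term in order:
        ann = current[term]
        k = len(ann & study)
        p = _hypergeom_upper(k, len(study), len(ann), len(population)) if study else 1.0
        rows.append({"term": term, "study_count": k, "pop_count": len(ann), "p_elim": p})
        if elim_alpha > 0 and p <= elim_alpha:
            eliminated = ann & study
            for a in dag.ancestors(term):
                current[a] -= eliminated
    out = pd.DataFrame(rows).set_index("term").sort_index()
    out["q_elim"] = bh_adjust(out["p_elim"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# semantic similarity
# ---------------------------------------------------------------------------

class TermSimilarity:
    """Cached pairwise term similarity over one DAG.

    ``measure='wang'``: graph-based S-values with multiplicative decay per
    is_a hop.  ``measure='resnik'``: information content of the most
    informative common ancestor, normalized by the maximum IC (requires
    propagated ``annotations``).
    """

    def __init__(
        self,
        dag: GoDag,
        measure: str = "wang",
        decay: float = 0.8,
        annotations: Mapping[str, Iterable[str]] | None = None,
    ):
        if measure not in ("wang", "resnik"):
            raise ValueError(f"unknown measure {measure!r}")
        self.dag = dag
        self.measure = measure
        self.decay = decay
        self._svalues: dict[str, dict[str, float]] = {}
        self._pair: dict[frozenset, float] = {}
        if measure == "resnik":
            if annotations is None:
                raise ValueError("resnik requires propagated annotations")
            sizes = {t: len(set(annotations.get(t, ()))) for t in dag.terms}
            total = max(sizes.values()) if sizes else 1
            self._ic = {
                t: -np.log(max(sizes[t], 1) / max(total, 1)) for t in dag.terms
            }
            self._max_ic = max(self._ic.values()) if self._ic else 1.0

    def _s_values(self, term: str) -> dict[str, float]:
        cached = self._svalues.get(term)
        if cached is not None:
            return cached
        if term not in self.dag.graph:
            raise KeyError(f"unknown term {term}")
        closure = self.dag.ancestors(term) | {term}
        sv = {term: 1.0}
        for t in sorted(closure - {term}, key=lambda t: -self.dag.level(t)):
            kids = self.dag.children(t) & closure
            vals = [self.decay * sv[c] for c in kids if c in sv]
            sv[t] = max(vals) if vals else 0.0
        self._svalues[term] = sv
        return sv

    def term_sim(self, a: str, b: str) -> float:
        if a == b:
            if a not in self.dag.graph:
                raise KeyError(f"unknown term {a}")
            return 1.0
        key = frozenset((a, b))
        hit = self._pair.get(key)
        if hit is not None:
            return hit
        if self.measure == "wang":
            sa = self._s_values(a)
            sb = self._s_values(b)
            common = set(sa) & set(sb)
            num = sum(sa[t] + sb[t] for t in common)
            val = num / (sum(sa.values()) + sum(sb.values()))
        else:
            common = (self.dag.ancestors(a) | {a}) & (self.dag.ancestors(b) | {b})
            if not common:
                val = 0.0
            else:
                mica = max(self._ic[t] for t in common)
                val = mica / self._max_ic if self._max_ic > 0 else 0.0
        val = float(min(max(val, 0.0), 1.0))
        self._pair[key] = val
        return val

    def set_sim(self, terms_a: Sequence[str], terms_b: Sequence[str]) -> float:
        """Best-match-average combination (symmetric)."""
        ta, tb = list(terms_a), list(terms_b)
        if not ta or not tb:
            raise ValueError("term sets must be non-empty")
        M = np.array([[self.term_sim(a, b) for b in tb] for a in ta])
        return float((M.max(axis=1).sum() + M.max(axis=0).sum()) / (len(ta) + len(tb)))


def go_semantic_similarity(
    terms_a: Sequence[str],
    terms_b: Sequence[str],
    dag: GoDag,
    measure: str = "wang",
    decay: float = 0.8,
    annotations: Mapping[str, Iterable[str]] | None = None,
) -> float:
    """Best-match-average semantic similarity of two GO term sets in [0, 1]."""
    return TermSimilarity(dag, measure, decay, annotations).set_sim(terms_a, terms_b)


@dataclass
class SemSimResult:
    """Observed set similarity against a uniform random-term-set null."""

    observed: float
    n_perm: int
    scores: np.ndarray
    p_value: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p out of range")


def permutation_pvalue(
    observed: float,
    size_a: int,
    size_b: int,
    dag: GoDag,
    n_perm: int = 500,
    seed: int | None = None,
    measure: str = "wang",
    decay: float = 0.8,
    annotations: Mapping[str, Iterable[str]] | None = None,
    add_one: bool = False,
    sim: TermSimilarity | None = None,
) -> SemSimResult:
    """Frequency of random same-size term-set pairs scoring >= observed.

    The plain frequency estimator (which can return 0) is the default; the
    add-one corrected (x+1)/(n+1) variant is opt-in.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    terms = dag.terms
    if size_a > len(terms) or size_b > len(terms):
        raise ValueError("set size exceeds the number of DAG terms")
    rng = np.random.default_rng(seed)
    if sim is None:
        sim = TermSimilarity(dag, measure, decay, annotations)
    scores = np.empty(n_perm)
    arr = np.array(terms, dtype=object)
    for i in range(n_perm):
        sa = rng.choice(arr, size=size_a, replace=False)
        sb = rng.choice(arr, size=size_b, replace=False)
        scores[i] = sim.set_sim(list(sa), list(sb))
    hits = int((scores >= observed).sum())
    p = (hits + 1) / (n_perm + 1) if add_one else hits / n_perm
    return SemSimResult(observed=float(observed), n_perm=n_perm, scores=scores,
                        p_value=float(p), seed=seed)


# ---------------------------------------------------------------------------
# stress-class crosstab
# ---------------------------------------------------------------------------

def crosstab_targets_by_class(
    groups: Mapping[str, Iterable[str]],
    graph: TargetGraph,
    classes: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Group x stress-class counts of distinct targeted genes.

    ``classes`` maps class name -> gene set and must be a partition (a gene
    in two classes is a construction error).
    """
    class_sets = {c: set(v) for c, v in classes.items()}
    for a, b in combinations(sorted(class_sets), 2):
        dup = class_sets[a] & class_sets[b]
        if dup:
            raise ValueError(f"classes must partition genes; {sorted(dup)[:5]} in both {a} and {b}")
    rows = {}
    for gname, mirnas in groups.items():
        targets = graph.targets_of(mirnas)
        rows[gname] = {c: len(targets & class_sets[c]) for c in sorted(class_sets)}
    return pd.DataFrame(rows).T.fillna(0).astype(int)
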
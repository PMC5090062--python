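"""Synthetic data generator with ground truth.

Emulates a three-strain heat-shock recovery design (control, 1 h, 6 h and
24 h after heat shock) at the level of mature miRNA counts, small-RNA
alignments, multi-algorithm target predictions, a toy gene ontology and
stress-responsive gene classes.  Every stochastic choice derives from the
single mandatory ``SimParams.seed``, so identical parameters reproduce
byte-identical outputs.

Two effect classes mirror the levelling phenomenon:

* class #1 miRNAs have strain-specific control baselines (log2 offsets of
  ``level_effect_log2``) that converge to one common level at the early
  post-HS timepoints and relax part of the way back to the strain baseline
  at the last timepoint (``recovery_fraction`` of the control offset).
* class #2 miRNAs share control baselines and diverge between strains only
  after heat shock, with the divergence decaying over the recovery course.

Polycistronic cluster members share a primary-transcript log2 fold-change
trajectory plus small per-mature deviations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Hairpin, Mature, MiRNAAnnotation, revcomp
from .quantify import CountMatrix

__all__ = [
    "SimParams",
    "SimTruth",
    "generate_annotation",
    "simulate_counts",
    "simulate_alignments",
    "simulate_target_predictions",
    "simulate_go",
    "simulate_stress_classes",
    "largest_remainder",
]

# substream tags so stages can be rerun in isolation
_S_ANNOT, _S_COUNTS, _S_ALIGN, _S_TARGETS, _S_GO, _S_CLASSES = range(1, 7)

_HAIRPIN_LEN = 90
_MATURE_LEN = 22
_GAP = 110
_CLUSTER_GAP = 30

EDIT_TYPES = {"A>G": ("A", "G"), "T>C": ("T", "C")}


@dataclass(frozen=True)
class SimParams:
    """Study-design parameters for the synthetic heat-shock experiment."""

    seed: int
    n_mirnas: int = 120  # hairpins; each yields a 5p and a 3p mature
    n_clusters: int = 4
    cluster_size_range: tuple[int, int] = (2, 4)
    strains: tuple[str, ...] = ("w1118", "hsp70", "yw")
    timepoints_h: tuple[float, ...] = (0.0, 1.0, 6.0, 24.0)
    replicates: int = 2
    depth: float = 2_000_000
    dispersion: float = 0.1
    frac_class1: float = 0.1
    frac_class2: float = 0.1
    level_effect_log2: float = 2.0
    recovery_fraction: float = 0.7
    arm_switch_events: tuple = ()  # (hairpin_id, (strain, timepoint_h), delta_log2)
    editing_sites: tuple = ()  # (mature_id, position_1based, "A>G"|"T>C", frequency)
    seq_error_rate: float = 0.001
    chrom_length: int | None = None
    chrom_name: str = "chrS"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_mirnas < 2:
            raise ValueError("need at least 2 hairpins")
        if not (0 <= self.frac_class1 <= 1 and 0 <= self.frac_class2 <= 1):
            raise ValueError("class fractions must be in [0, 1]")
        if self.frac_class1 + self.frac_class2 > 1:
            raise ValueError("frac_class1 + frac_class2 must be <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        tps = self.timepoints_h
        if len(tps) < 2 or tps[0] != 0 or any(a >= b for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        lo, hi = self.cluster_size_range
        if not (2 <= lo <= hi):
            raise ValueError("cluster sizes must be >= 2 and ordered")
        for _, _, etype, freq in self.editing_sites:
            if etype not in EDIT_TYPES:
                raise ValueError(f"unsupported editing type {etype!r}")
            if not 0 < freq <= 1:
                raise ValueError("editing frequency must be in (0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class SimTruth:
    """Ground-truth labels recorded by the generator."""

    class1_ids: set[str] = field(default_factory=set)
    class2_ids: set[str] = field(default_factory=set)
    cluster_membership: dict[str, str] = field(default_factory=dict)  # mature -> cluster
    true_profile_templates: dict[str, str] = field(default_factory=dict)
    control_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    divergence_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    true_arm_switches: list = field(default_factory=list)
    true_editing_sites: list = field(default_factory=list)
    true_target_edges: set = field(default_factory=set)
    true_enriched_terms: list = field(default_factory=list)
    mean_log2: pd.DataFrame | None = None  # mature x (strain, timepoint) log2 relative means

    def validate(self, annotation: MiRNAAnnotation) -> None:
        known = set(annotation.matures)
        for ids in (self.class1_ids, self.class2_ids, set(self.cluster_membership)):
            unknown = ids - known
            if unknown:
                raise ValueError(f"truth references unknown miRNAs: {sorted(unknown)[:5]}")
        if self.class1_ids & self.class2_ids:
            raise ValueError("class1 and class2 overlap")

    def to_json(self, path) -> None:
        doc = {
            "class1_ids": sorted(self.class1_ids),
            "class2_ids": sorted(self.class2_ids),
            "cluster_membership": self.cluster_membership,
            "true_profile_templates": self.true_profile_templates,
            "control_offsets": self.control_offsets,
            "divergence_offsets": self.divergence_offsets,
        }
        doc["true_arm_switches"] = [
            [h, list(cond), d] for h, cond, d in self.true_arm_switches
        ]
        doc["true_editing_sites"] = [list(s) for s in self.true_editing_sites]
        doc["true_target_edges"] = sorted(map(list, self.true_target_edges))
        doc["true_enriched_terms"] = list(self.true_enriched_terms)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(params: SimParams) -> tuple[MiRNAAnnotation, dict[str, str]]:
    """Lay out hairpins (with polycistronic blocks) on a synthetic chromosome.

    Returns the annotation and the reference sequences.  Raises a sizing
    error when an explicit ``chrom_length`` cannot hold all features.
    """
    rng = params.rng(_S_ANNOT)
    lo, hi = params.cluster_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(params.n_clusters)]
    if sum(sizes) > params.n_mirnas:
        raise ValueError("cluster sizes exceed n_mirnas")

    # blocks: clusters first, then singletons, placed in shuffled order
    blocks: list[tuple[str | None, int]] = [
        (f"cl{g + 1}", s) for g, s in enumerate(sizes)
    ]
    blocks += [(None, 1)] * (params.n_mirnas - sum(sizes))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    needed = 0
    for _, size in blocks:
        needed += size * _HAIRPIN_LEN + (size - 1) * _CLUSTER_GAP + _GAP
    needed += _GAP
    chrom_len = params.chrom_length if params.chrom_length is not None else needed
    if chrom_len < needed:
        raise ValueError(
            f"chromosome length {chrom_len} cannot hold {params.n_mirnas} hairpins "
            f"(need {needed})"
        )

    hairpins: dict[str, Hairpin] = {}
    matures: dict[str, Mature] = {}
    pos = _GAP
    idx = 0
    for cluster_id, size in blocks:
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(size):
            idx += 1
            hid = f"mir-{idx}"
            start, end = pos, pos + _HAIRPIN_LEN
            hairpins[hid] = Hairpin(hid, params.chrom_name, start, end, strand, cluster_id)
            if strand == "+":
                five = (start, start + _MATURE_LEN)
                three = (end - _MATURE_LEN, end)
            else:
                five = (end - _MATURE_LEN, end)
                three = (start, start + _MATURE_LEN)
            matures[f"{hid}-5p"] = Mature(
                f"{hid}-5p", params.chrom_name, five[0], five[1], strand, "5p", hid
            )
            matures[f"{hid}-3p"] = Mature(
                f"{hid}-3p", params.chrom_name, three[0], three[1], strand, "3p", hid
            )
            pos = end + _CLUSTER_GAP
        pos += _GAP - _CLUSTER_GAP

    seq = rng.choice(list("ACGT"), size=chrom_len)
    annotation = MiRNAAnnotation(hairpins=hairpins, matures=matures)
    # ensure requested editing sites sit on the right reference base
    for mid, pos1, etype, _freq in params.editing_sites:
        m = annotation.matures.get(mid)
        if m is None:
            raise ValueError(f"editing site references unknown mature {mid}")
        if not 1 <= pos1 <= len(m):
            raise ValueError(f"editing position {pos1} outside mature {mid}")
        ref_base = EDIT_TYPES[etype][0]
        if m.strand == "+":
            seq[m.start + pos1 - 1] = ref_base
        else:
            seq[m.end - pos1] = revcomp(ref_base)
    return annotation, {params.chrom_name: "".join(seq)}


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _effect_pattern(rng: np.random.Generator, n_strains: int, effect: float) -> np.ndarray:
    """Per-strain log2 offsets drawn from {-e, 0, +e}, not all equal."""
    choices = np.array([-effect, 0.0, effect])
    while True:
        pat = rng.choice(choices, size=n_strains)
        if effect == 0 or len(set(pat.tolist())) > 1:
            return pat


def simulate_counts(
    annotation: MiRNAAnnotation, params: SimParams
) -> tuple[CountMatrix, SimTruth]:
    """NB-distributed counts with levelling / divergence / cluster structure.

    Per-sample size factors are log-normal(0, 0.1); the expected column sum
    of a sample is ``depth * size_factor`` exactly (per-sample mean vectors
    are renormalized), so library-size normalization is non-trivial.
    """
    rng = params.rng(_S_COUNTS)
    mat = annotation.mature_table()
    mirnas = list(mat["mirna"])
    n = len(mirnas)
    strains = list(params.strains)
    tps = list(params.timepoints_h)
    post = tps[1:]

    # baseline abundance: dominant arm per hairpin, minor arm 1-5 log2 lower
    base = pd.Series(0.0, index=mirnas)
    for hid in annotation.hairpins:
        arms = annotation.arms_of(hid)
        dom = "5p" if rng.random() < 0.5 else "3p"
        level = rng.uniform(4.0, 11.0)
        for arm, m in arms.items():
            base[m.id] = level if arm == dom else level - rng.uniform(1.0, 5.0)

    truth = SimTruth()
    truth.cluster_membership = {
        m.id: annotation.hairpins[m.hairpin_id].cluster_id
        for m in annotation.matures.values()
        if annotation.hairpins[m.hairpin_id].cluster_id
    }
    clustered = set(truth.cluster_membership)
    eligible = [m for m in mirnas if m not in clustered]
    n1 = int(round(params.frac_class1 * n))
    n2 = int(round(params.frac_class2 * n))
    if n1 + n2 > len(eligible):
        raise ValueError("not enough non-clustered miRNAs for the requested class fractions")
    picked = rng.choice(len(eligible), size=n1 + n2, replace=False)
    truth.class1_ids = {eligible[i] for i in picked[:n1]}
    truth.class2_ids = {eligible[i] for i in picked[n1:]}

    # log2 offsets relative to baseline: delta[mirna][strain][timepoint]
    delta = np.zeros((n, len(strains), len(tps)))
    mindex = {m: i for i, m in enumerate(mirnas)}

    # mild common (strain-independent) response for every miRNA
    common = rng.normal(0.0, 0.3, size=(n, len(post)))
    delta[:, :, 1:] += common[:, None, :]

    for m in sorted(truth.class1_ids):
        i = mindex[m]
        pat = _effect_pattern(rng, len(strains), params.level_effect_log2)
        truth.control_offsets[m] = dict(zip(strains, map(float, pat)))
        truth.true_profile_templates[m] = "class1"
        delta[i, :, 0] += pat
        # levelled at common level through recovery; last timepoint relaxes back
        if len(post) > 1:
            delta[i, :, -1] += params.recovery_fraction * pat

    for m in sorted(truth.class2_ids):
        i = mindex[m]
        pat = _effect_pattern(rng, len(strains), params.level_effect_log2)
        truth.divergence_offsets[m] = dict(zip(strains, map(float, pat)))
        truth.true_profile_templates[m] = "class2"
        for j in range(len(post)):
            decay = max(0.0, 1.0 - 0.4 * j)  # 1, 0.6, 0.2 over (1, 6, 24) h
            delta[i, :, 1 + j] += decay * pat

    # polycistronic clusters: shared primary-transcript trajectory
    cluster_ids = sorted(set(truth.cluster_membership.values()))
    for cid in cluster_ids:
        traj = rng.normal(0.0, 1.2, size=len(post))
        for m, c in truth.cluster_membership.items():
            if c != cid:
                continue
            i = mindex[m]
            dev = rng.normal(0.0, 0.2, size=len(post))
            delta[i, :, 1:] += (traj + dev)[None, :]
            truth.true_profile_templates[m] = f"cluster:{cid}"

    for m in mirnas:
        truth.true_profile_templates.setdefault(m, "background")

    # arm-switch events: split the ratio change across the two arms
    for hid, cond, dlog2 in params.arm_switch_events:
        strain, tp = cond
        arms = annotation.arms_of(hid)
        if "5p" not in arms or "3p" not in arms:
            raise ValueError(f"arm switch requires both arms of {hid}")
        si, ti = strains.index(strain), tps.index(float(tp))
        delta[mindex[arms["5p"].id], si, ti] += dlog2 / 2
        delta[mindex[arms["3p"].id], si, ti] -= dlog2 / 2
        truth.true_arm_switches.append((hid, (strain, float(tp)), float(dlog2)))

    truth.true_editing_sites = [tuple(s) for s in params.editing_sites]

    # realized mean structure (log2, relative within condition)
    w = np.power(2.0, base.to_numpy()[:, None, None] + delta)
    cols = {}
    for si, s in enumerate(strains):
        for ti, t in enumerate(tps):
            cols[(s, t)] = np.log2(w[:, si, ti])
    truth.mean_log2 = pd.DataFrame(cols, index=mirnas)
    truth.mean_log2.columns = pd.MultiIndex.from_tuples(
        truth.mean_log2.columns, names=["strain", "timepoint_h"]
    )

    # sample counts
    samples, design_rows, count_cols = [], [], []
    lib_sizes = []
    for si, s in enumerate(strains):
        for ti, t in enumerate(tps):
            p = w[:, si, ti] / w[:, si, ti].sum()
            for rep in range(1, params.replicates + 1):
                sid = f"{s}_t{t:g}_r{rep}"
                sf = float(np.exp(rng.normal(0.0, 0.1)))
                mu = params.depth * sf * p
                if params.dispersion > 0:
                    lam = rng.gamma(1.0 / params.dispersion, params.dispersion * mu)
                    counts = rng.poisson(lam)
                else:
                    counts = rng.poisson(mu)
                samples.append(sid)
                design_rows.append({"strain": s, "timepoint_h": float(t), "replicate": rep})
                count_cols.append(counts)
                lib_sizes.append(counts.sum())

    counts_df = pd.DataFrame(
        np.column_stack(count_cols), index=mirnas, columns=samples
    )
    counts_df.index.name = "mirna"
    design = pd.DataFrame(design_rows, index=pd.Index(samples, name="sample"))
    matrix = CountMatrix(counts_df, design, pd.Series(lib_sizes, index=samples, dtype=float))
    truth.validate(annotation)
    return matrix, truth


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _mature_sense_seq(m: Mature, reference: Mapping[str, str]) -> str:
    seq = reference[m.chrom][m.start : m.end]
    return revcomp(seq) if m.strand == "-" else seq


def simulate_alignments(
    annotation: MiRNAAnnotation,
    matrix: CountMatrix,
    reference: Mapping[str, str],
    params: SimParams,
    samples: Sequence[str] | None = None,
    jitter: bool = True,
) -> dict[str, pd.DataFrame]:
    """Synthesize BED6 alignments realizing the count matrix.

    Each mature miRNA receives exactly its counted number of 21-23 nt reads
    placed within the mature interval (1 nt 5'/3' jitter when ``jitter``).
    The read sequence (mature sense, 5'->3') is carried in the BED name
    column; editing sites inject their substitution at the stated per-read
    frequency and background mismatches occur at ``seq_error_rate``.
    """
    rng = params.rng(_S_ALIGN)
    bases = np.array(list("ACGT"))
    edits_by_mature: dict[str, list] = {}
    for mid, pos1, etype, freq in params.editing_sites:
        m = annotation.matures[mid]
        if not 1 <= pos1 <= len(m):
            raise ValueError(f"editing position {pos1} outside mature {mid}")
        ref_b, alt_b = EDIT_TYPES[etype]
        sense = _mature_sense_seq(m, reference)
        if sense[pos1 - 1] != ref_b:
            raise ValueError(
                f"reference base at {mid}:{pos1} is {sense[pos1 - 1]}, expected {ref_b}"
            )
        edits_by_mature.setdefault(mid, []).append((pos1, alt_b, freq))

    if samples is None:
        samples = list(matrix.samples)
    out: dict[str, pd.DataFrame] = {}
    mat_objs = [annotation.matures[m] for m in matrix.mirnas if m in annotation.matures]
    for sid in samples:
        col = matrix.counts[sid]
        chunks = []
        for m in mat_objs:
            nreads = int(col.get(m.id, 0))
            if nreads == 0:
                continue
            sense = _mature_sense_seq(m, reference)
            if jitter:
                combos = [(0, _MATURE_LEN - 1), (0, _MATURE_LEN), (1, _MATURE_LEN - 1)]
            else:
                combos = [(0, _MATURE_LEN)]
            ci = rng.integers(0, len(combos), size=nreads)
            offs = np.array([c[0] for c in combos])[ci]
            lens = np.array([c[1] for c in combos])[ci]
            seqs = np.array([
                sense[o : o + L] for o, L in combos
            ], dtype=object)[ci]
            seqs = seqs.copy()
            # editing substitutions
            for pos1, alt_b, freq in edits_by_mature.get(m.id, []):
                covered = (offs < pos1) & (pos1 <= offs + lens)
                hit = covered & (rng.random(nreads) < freq)
                for ri in np.nonzero(hit)[0]:
                    p = pos1 - 1 - offs[ri]
                    s = seqs[ri]
                    seqs[ri] = s[:p] + alt_b + s[p + 1 :]
            # background sequencing errors
            nerr = rng.binomial(lens, params.seq_error_rate)
            for ri in np.nonzero(nerr)[0]:
                s = list(seqs[ri])
                for p in rng.integers(0, lens[ri], size=nerr[ri]):
                    alt = [b for b in "ACGT" if b != s[p]]
                    s[p] = alt[rng.integers(0, 3)]
                seqs[ri] = "".join(s)
            if m.strand == "+":
                starts = m.start + offs
                ends = starts + lens
            else:
                ends = m.end - offs
                starts = ends - lens
            chunks.append(
                pd.DataFrame(
                    {
                        "chrom": m.chrom,
                        "start": starts,
                        "end": ends,
                        "name": seqs,
                        "score": 0,
                        "strand": m.strand,
                    }
                )
            )
        out[sid] = (
            pd.concat(chunks, ignore_index=True)
            if chunks
            else pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
        )
    return out


# ---------------------------------------------------------------------------
# target predictions
# ---------------------------------------------------------------------------

def simulate_target_predictions(
    true_edges: Iterable[tuple[str, str]],
    mirnas: Sequence[str],
    genes: Sequence[str],
    n_algorithms: int,
    sensitivity: float,
    fpr: float,
    params: SimParams,
) -> list[pd.DataFrame]:
    """Noisy per-algorithm views of a true miRNA->gene bipartite graph.

    Each algorithm independently keeps a true edge with probability
    ``sensitivity`` and reports a non-edge with probability ``fpr``.
    """
    if n_algorithms < 2:
        raise ValueError("need at least 2 algorithms")
    if not (0 <= sensitivity <= 1 and 0 <= fpr <= 1):
        raise ValueError("sensitivity and fpr must be in [0, 1]")
    rng = params.rng(_S_TARGETS)
    true = set(true_edges)
    out = []
    mirnas = list(mirnas)
    genes = list(genes)
    true_mask = np.zeros((len(mirnas), len(genes)), dtype=bool)
    gi = {g: j for j, g in enumerate(genes)}
    mi = {m: i for i, m in enumerate(mirnas)}
    for m, g in true:
        true_mask[mi[m], gi[g]] = True
    for _ in range(n_algorithms):
        u = rng.random(true_mask.shape)
        keep = np.where(true_mask, u < sensitivity, u < fpr)
        ii, jj = np.nonzero(keep)
        out.append(
            pd.DataFrame(
                {"mirna": [mirnas[i] for i in ii], "gene": [genes[j] for j in jj]}
            )
        )
    return out


# ---------------------------------------------------------------------------
# ontology and stress classes
# ---------------------------------------------------------------------------

def simulate_go(
    genes: Sequence[str],
    params: SimParams,
    n_terms: int = 60,
    depth: int = 4,
    n_enriched: int = 3,
    terms_per_gene: tuple[int, int] = (1, 3),
    study_size: int = 40,
    enrichment_strength: float = 0.7,
):
    """A random acyclic term hierarchy, propagated gene annotations, a set of
    truth-enriched terms and a study set over-representing their genes.

    Returns ``(dag, direct_annotations, enriched_terms, study_genes)``.
    """
    from .targets_go import GoDag

    if depth < 1:
        raise ValueError("DAG depth must be >= 1")
    rng = params.rng(_S_GO)
    terms = [f"T:{i:04d}" for i in range(n_terms)]
    levels = [0] + [1 + int(rng.integers(0, depth)) for _ in range(n_terms - 1)]
    # at least one term per level so every level is populated
    for lv in range(1, depth + 1):
        if lv not in levels[1:]:
            levels[1 + (lv - 1) % (n_terms - 1)] = lv
    edges = []
    by_level: dict[int, list[str]] = {}
    for t, lv in zip(terms, levels):
        by_level.setdefault(lv, []).append(t)
    for lv in range(1, depth + 1):
        parents_pool: list[str] = []
        for plv in range(lv):
            parents_pool += by_level.get(plv, [])
        for t in by_level.get(lv, []):
            n_par = 1 + int(rng.random() < 0.2)
            chosen = rng.choice(len(parents_pool), size=min(n_par, len(parents_pool)), replace=False)
            for c in chosen:
                edges.append((t, parents_pool[c]))
    dag = GoDag.from_edges(edges)

    leafish = [t for t, lv in zip(terms, levels) if lv >= max(1, depth - 1)]
    lo, hi = terms_per_gene
    direct: dict[str, set[str]] = {}
    for g in genes:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(leafish), size=min(k, len(leafish)), replace=False)
        direct[g] = {leafish[c] for c in chosen}

    mid = [t for t, lv in zip(terms, levels) if 1 <= lv <= max(1, depth - 1)]
    enr_idx = rng.choice(len(mid), size=min(n_enriched, len(mid)), replace=False)
    enriched = sorted(mid[i] for i in enr_idx)

    ann = dag.propagate(direct)
    pool = sorted(set().union(*(ann.get(t, set()) for t in enriched)) & set(genes))
    others = sorted(set(genes) - set(pool))
    n_from_pool = min(len(pool), int(round(enrichment_strength * study_size)))
    study = set()
    if n_from_pool:
        study |= {pool[i] for i in rng.choice(len(pool), size=n_from_pool, replace=False)}
    n_rest = min(len(others), study_size - len(study))
    if n_rest:
        study |= {others[i] for i in rng.choice(len(others), size=n_rest, replace=False)}
    return dag, direct, enriched, study


STRESS_CLASSES = ("early-up", "early-down", "late-up")


def largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    """Deterministic integer partition of ``n`` by largest remainder."""
    if any(p < 0 for p in proportions) or sum(proportions) > 1 + 1e-12:
        raise ValueError("proportions must be non-negative and sum to <= 1")
    quotas = [p * n for p in proportions]
    floors = [int(np.floor(q)) for q in quotas]
    rem = int(round(sum(quotas))) - sum(floors)
    order = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - floors[i]), i)
    )
    out = floors[:]
    for i in order[:rem]:
        out[i] += 1
    return out


def simulate_stress_classes(
    genes: Sequence[str],
    proportions: Sequence[float],
    params: SimParams,
    class_names: Sequence[str] = STRESS_CLASSES,
) -> dict[str, str]:
    """Partition the stress-responsive gene subset into timing classes.

    Class sizes follow largest-remainder rounding of ``proportions``; genes
    are assigned in a seeded random order.
    """
    if len(proportions) != len(class_names):
        raise ValueError("one proportion per class required")
    rng = params.rng(_S_CLASSES)
    genes = list(genes)
    sizes = largest_remainder(len(genes), proportions)
    order = rng.permutation(len(genes))
    out: dict[str, str] = {}
    pos = 0
    for cname, size in zip(class_names, sizes):
        for i in order[pos : pos + size]:
            out[genes[i]] = cname
        pos += size
    return out
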
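"""End-to-end reproducible pipeline over synthetic or user-supplied inputs.

``run_pipeline`` executes simulate -> quantify -> DE/classify -> time-course
selection/clustering -> arm-switch -> editing -> targets -> GO ->
stress-class crosstab, writes per-stage TSVs plus one JSON summary, and is
byte-deterministic under a fixed seed (the summary carries no timestamps).

The default simulated library depth is deliberately demo-scale (50,000
reads/library over 120 hairpins) so a full run stays interactive; every
size is configurable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_io
from . import arms_editing, diffexpr, quantify, simulate, targets_go, timecourse

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("mirhsr")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))
    log.addHandler(_h)


def _stage_log(stage: str, msg: str) -> None:
    logging.getLogger("mirhsr").info(msg, extra={"stage": stage})


_DEFAULT_SIM = {
    "n_mirnas": 120,
    "n_clusters": 4,
    "depth": 50_000,
    "dispersion": 0.1,
    "replicates": 2,
    "frac_class1": 0.1,
    "frac_class2": 0.1,
    "level_effect_log2": 2.0,
    "arm_switch_events": [["mir-1", ["w1118", 1.0], -3.0]],
    "editing_sites": [["mir-2-5p", 5, "A>G", 0.3], ["mir-3-3p", 12, "T>C", 0.25]],
}


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults are the study values where stated
    (50-count rule, p_adj 0.05, |log2FC| 1.5, Q 0.05, alpha 0.05, R^2 0.6,
    500 permutations, 6 clusters)."""

    seed: int = 1
    simulate: dict = field(default_factory=lambda: dict(_DEFAULT_SIM))
    count_min: float = 50.0
    fdr_alpha: float = 0.05
    lfc_min: float = 1.5
    q_alpha: float = 0.05
    step_alpha: float = 0.05
    r2_min: float = 0.6
    k_clusters: int = 6
    n_perm: int = 500
    min_support: int = 2
    delta_min: float = 1.0
    count_floor: float = 50.0
    min_cov: int = 10
    min_freq: float = 0.1
    elim_alpha: float = 0.05
    min_overlap_frac: float = 0.5
    length_range: tuple[int, int] = (18, 26)
    levelling_window: tuple[float, ...] = (1.0,)
    degree: int = 2
    n_genes: int = 400
    n_algorithms: int = 5
    target_sensitivity: float = 0.8
    target_fpr: float = 0.005
    n_stress_genes: int = 120
    stress_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        d["levelling_window"] = list(self.levelling_window)
        d["stress_proportions"] = list(self.stress_proportions)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        violations = validate_config(data)
        if violations:
            raise ValueError("invalid config: " + "; ".join(violations))
        kwargs = dict(data)
        for key in ("length_range", "levelling_window", "stress_proportions"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


_NONNEG = (
    "count_min", "fdr_alpha", "lfc_min", "q_alpha", "step_alpha", "r2_min",
    "delta_min", "count_floor", "min_freq", "elim_alpha", "target_sensitivity",
    "target_fpr",
)
_POSITIVE = ("k_clusters", "n_perm", "min_support", "min_cov", "degree",
             "n_genes", "n_algorithms", "n_stress_genes")


def validate_config(data: Mapping[str, Any] | "RunConfig") -> list[str]:
    """Return the list of invariant violations (empty when valid)."""
    if isinstance(data, RunConfig):
        data = data.to_dict()
    known = {f.name for f in dataclasses.fields(RunConfig)}
    violations = []
    for key in data:
        if key not in known:
            violations.append(f"unknown key: {key}")
    for key in _NONNEG:
        if key in data and data[key] is not None and float(data[key]) < 0:
            violations.append(f"{key} must be >= 0")
    for key in _POSITIVE:
        if key in data and data[key] is not None and int(data[key]) < 1:
            violations.append(f"{key} must be >= 1")
    if "min_overlap_frac" in data and not (0 < float(data["min_overlap_frac"]) <= 1):
        violations.append("min_overlap_frac must be in (0, 1]")
    return violations


def _derived_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage on synthetic inputs; returns the summary document."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config": config.to_dict()}

    # ---- simulate ---------------------------------------------------------
    _stage_log("simulate", "generating annotation, counts and alignments")
    sim_kwargs = dict(config.simulate)
    sim_kwargs["arm_switch_events"] = tuple(
        (h, (c[0], float(c[1])), float(d)) for h, c, d in sim_kwargs.get("arm_switch_events", ())
    )
    sim_kwargs["editing_sites"] = tuple(
        (m, int(p), t, float(f)) for m, p, t, f in sim_kwargs.get("editing_sites", ())
    )
    params = simulate.SimParams(seed=_derived_seed(config.seed, 1), **sim_kwargs)
    annotation, reference = simulate.generate_annotation(params)
    ann_io.write_gff3(annotation, out / "annotation.gff3")
    ann_io.write_fasta(reference, out / "reference.fa")
    sim_matrix, truth = simulate.simulate_counts(annotation, params)
    sim_matrix.write_tsv(out / "true_counts.tsv", out / "design.tsv")
    beds = simulate.simulate_alignments(annotation, sim_matrix, reference, params)
    for sid, df in beds.items():
        ann_io.write_bed6(df, out / f"reads_{sid}.bed")

    # ---- quantify ---------------------------------------------------------
    _stage_log("quantify", "counting reads over mature features")
    matrix, report = quantify.count_overlaps(
        beds, annotation, sim_matrix.design,
        min_overlap_frac=config.min_overlap_frac,
        length_range=tuple(config.length_range),
    )
    matrix.write_tsv(out / "counts.tsv", out / "design_counted.tsv")
    with open(out / "counting_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    filtered = quantify.filter_low_counts(matrix, threshold=config.count_min)
    summary["quantify"] = {
        "n_matures": int(len(matrix.mirnas)),
        "n_pass_count_filter": int(len(filtered.mirnas)),
        "assigned_reads": int(sum(r["assigned"] for r in report["samples"].values())),
    }

    # ---- differential expression / levelling ------------------------------
    _stage_log("de", "pairwise strain contrasts at each timepoint")
    de_config = diffexpr.AnalysisConfig(
        fdr_alpha=config.fdr_alpha, lfc_min=config.lfc_min, count_min=config.count_min
    )
    dispersions = diffexpr.estimate_dispersion(matrix)
    de = diffexpr.all_pairwise_de(matrix, de_config, dispersions=dispersions)
    for (sa, sb, tp), res in de.items():
        res.to_csv(out / f"de_{sa}_vs_{sb}_t{tp:g}.tsv", sep="\t")
    strains = list(dict.fromkeys(matrix.design["strain"]))
    classes = diffexpr.classify_levelled(
        de, strains, window=tuple(config.levelling_window)
    )
    classes.to_csv(out / "level_classes.tsv", sep="\t")
    rpm = matrix.rpm()
    tps = sorted(set(matrix.design["timepoint_h"].astype(float)))
    lev_index = {
        f"{tp:g}h": diffexpr.levelling_index(rpm, matrix.design, tp) for tp in tps
    }
    n_de_any = int(
        len(set().union(*(set(r.index[r["is_de"]]) for r in de.values())))
    )
    cls1 = classes[classes["level_class"] == "class1"]
    summary["diffexpr"] = {
        "n_de_any_contrast": n_de_any,
        "n_class1": int((classes["level_class"] == "class1").sum()),
        "n_class2": int((classes["level_class"] == "class2").sum()),
        "class1_groups": cls1["group"].value_counts().to_dict(),
        "levelling_index": lev_index,
    }

    # ---- time course ------------------------------------------------------
    _stage_log("timecourse", "profile regression, selection and clustering")
    profiles = timecourse.profile_normalize(filtered)
    global_fit, rotations, selection = timecourse.timecourse_selection(
        profiles, degree=config.degree, q_alpha=config.q_alpha,
        alpha=config.step_alpha, r2_min=config.r2_min,
    )
    selection.to_csv(out / "timecourse_selection.tsv", sep="\t")
    profiles.values.to_csv(out / "profiles.tsv", sep="\t")
    n_sig = selection["n_strains_significant"]
    partition = {str(i): int((n_sig == i).sum()) for i in (1, 2, 3)}
    clusterable = sorted(selection.index[n_sig >= 2])
    summary["timecourse"] = {
        "n_profile_significant": int((n_sig >= 1).sum()),
        "strain_partition": partition,
    }
    cluster_summary: dict[str, Any] = {"clustered": False}
    if len(clusterable) >= config.k_clusters:
        D = timecourse.profile_distance_matrix(profiles, clusterable)
        assignment = timecourse.hierarchical_cluster(D, k=config.k_clusters)
        assignment.labels.to_csv(out / "clusters.tsv", sep="\t")
        with open(out / "linkage.json", "w") as fh:
            json.dump(assignment.linkage_matrix.tolist(), fh)
        fits = []
        for c in sorted(set(assignment.labels)):
            fit = timecourse.cluster_mean_profile(assignment.members(c), profiles)
            fit.insert(0, "cluster", c)
            fits.append(fit)
        pd.concat(fits, ignore_index=True).to_csv(out / "cluster_profiles.tsv", sep="\t", index=False)
        timecourse.plot_cluster_profiles(
            assignment, profiles, out / "cluster_profiles.png"
        )
        cluster_summary = {
            "clustered": True,
            "k": assignment.k,
            "sizes": {str(c): int(n) for c, n in assignment.sizes.items()},
        }
        cluster_groups = {
            f"cluster{c}": set(assignment.members(c)) for c in sorted(set(assignment.labels))
        }
    else:
        cluster_groups = {}
    summary["clusters"] = cluster_summary

    # ---- arms & editing ---------------------------------------------------
    _stage_log("arms", "arm-switch scan")
    events = arms_editing.detect_arm_switch(
        matrix, annotation, delta_min=config.delta_min, count_floor=config.count_floor
    )
    events.to_csv(out / "arm_switch_events.tsv", sep="\t", index=False)
    summary["arm_switch"] = {
        "n_events": int(len(events)),
        "hairpins": sorted(set(events["hairpin"])) if len(events) else [],
    }

    _stage_log("editing", "editing calls per condition")
    all_calls = []
    for strain, tp in matrix.conditions():
        cols = matrix.samples_for(strain, tp)
        pooled = pd.concat([beds[c] for c in cols], ignore_index=True)
        calls = arms_editing.call_editing(
            pooled, annotation, reference,
            min_cov=config.min_cov, min_freq=config.min_freq,
            error_rate=params.seq_error_rate,
        )
        if len(calls):
            calls.insert(0, "strain", strain)
            calls.insert(1, "timepoint_h", tp)
            all_calls.append(calls)
    editing = (
        pd.concat(all_calls, ignore_index=True)
        if all_calls
        else pd.DataFrame(columns=["strain", "timepoint_h", "mirna", "position", "type"])
    )
    editing.to_csv(out / "editing_calls.tsv", sep="\t", index=False)
    sites = (
        {(r.mirna, int(r.position), r.type) for r in editing.itertuples()}
        if len(editing)
        else set()
    )
    summary["editing"] = {
        "n_calls": int(len(editing)),
        "n_distinct_sites": len(sites),
        "n_in_seed": int(editing["in_seed"].sum()) if "in_seed" in editing else 0,
    }

    # ---- targets & GO -----------------------------------------------------
    _stage_log("targets", "consensus target voting and group target sets")
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    mirna_ids = list(matrix.mirnas)
    rng = np.random.default_rng(_derived_seed(config.seed, 7))
    true_edges = set()
    for m in mirna_ids:
        for g in rng.choice(genes, size=rng.poisson(8), replace=False):
            true_edges.add((m, g))
    truth.true_target_edges = true_edges
    pred = simulate.simulate_target_predictions(
        true_edges, mirna_ids, genes, config.n_algorithms,
        config.target_sensitivity, config.target_fpr, params,
    )
    for i, df in enumerate(pred):
        df.to_csv(out / f"targets_alg{i + 1}.tsv", sep="\t", index=False)
    graph = targets_go.consensus_targets(pred, min_support=config.min_support)
    graph.edges.to_csv(out / "targets_consensus.tsv", sep="\t", index=False)

    groups_mirnas: dict[str, set[str]] = {}
    for label in ("common", "shared", "unique"):
        members = set(cls1.index[cls1["group"] == label])
        if members:
            groups_mirnas[label] = members
    group_targets = targets_go.unique_group_targets(groups_mirnas, graph) if groups_mirnas else {}
    summary["targets"] = {
        "n_consensus_edges": int(len(graph.edges)),
        "group_target_sizes": {g: len(v) for g, v in sorted(group_targets.items())},
    }

    _stage_log("go", "enrichment, semantic similarity and permutation test")
    dag, direct, enriched_truth, _study = simulate.simulate_go(genes, params)
    ann = dag.propagate(direct)
    go_summary: dict[str, Any] = {"true_enriched_terms": list(enriched_truth)}
    truth.true_enriched_terms = list(enriched_truth)
    enriched_sets = {}
    for gname, gset in sorted(group_targets.items()):
        if not gset:
            continue
        res = targets_go.elim_enrichment(dag, ann, gset & set(genes), genes,
                                         elim_alpha=config.elim_alpha)
        res.to_csv(out / f"go_elim_{gname}.tsv", sep="\t")
        terms = sorted(res.index[res["p_elim"] <= 0.05])
        if terms:
            enriched_sets[gname] = terms
    go_summary["n_groups_with_enrichment"] = len(enriched_sets)
    if len(enriched_sets) >= 2:
        (ga, ta), (gb, tb) = sorted(enriched_sets.items())[:2]
        sim = targets_go.TermSimilarity(dag)
        obs = sim.set_sim(ta, tb)
        perm = targets_go.permutation_pvalue(
            obs, len(ta), len(tb), dag, n_perm=config.n_perm,
            seed=_derived_seed(config.seed, 8), sim=sim,
        )
        go_summary["semantic_similarity"] = {
            "groups": [ga, gb],
            "observed": round(obs, 6),
            "p_value": perm.p_value,
            "n_perm": perm.n_perm,
        }
        with open(out / "semantic_similarity.json", "w") as fh:
            json.dump(go_summary["semantic_similarity"], fh, indent=1)
    summary["go"] = go_summary

    # ---- stress-class crosstab -------------------------------------------
    _stage_log("crosstab", "targets by stress-responsive gene class")
    stress_genes = list(rng.choice(genes, size=config.n_stress_genes, replace=False))
    class_of = simulate.simulate_stress_classes(
        stress_genes, config.stress_proportions, params
    )
    class_sets: dict[str, set[str]] = {}
    for g, c in class_of.items():
        class_sets.setdefault(c, set()).add(g)
    crosstab_groups = cluster_groups or groups_mirnas
    if crosstab_groups and class_sets:
        ct = targets_go.crosstab_targets_by_class(crosstab_groups, graph, class_sets)
        ct.to_csv(out / "stress_crosstab.tsv", sep="\t")
        summary["stress_crosstab"] = {
            "groups": list(ct.index),
            "classes": list(ct.columns),
            "table": ct.to_numpy().tolist(),
        }
    else:
        summary["stress_crosstab"] = {"groups": [], "classes": [], "table": []}

    truth.to_json(out / "truth.json")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _stage_log("report", f"summary written to {out / 'summary.json'}")
    return summary
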
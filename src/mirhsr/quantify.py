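"""Read counting over mature miRNA features and the low-count filter.

Reads are assigned by unique best overlap: a read goes to the single mature
feature (same strand, read length within bounds, overlap at least
``min_overlap_frac`` of the read length) with the largest overlap; ties are
broken by leftmost feature start, then lexicographic feature id.  This
deliberately avoids any-overlap multi-counting so a read spanning both arms
of a hairpin is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import MiRNAAnnotation

__all__ = ["CountMatrix", "count_overlaps", "count_reads", "filter_low_counts"]

DESIGN_COLUMNS = ["strain", "timepoint_h", "replicate"]


@dataclass
class CountMatrix:
    """miRNA x sample raw counts with library sizes and the sample design.

    ``counts``: integer DataFrame, rows = mature miRNA ids, columns = sample
    ids.  ``design``: DataFrame indexed by sample id with columns ``strain``,
    ``timepoint_h`` (hours, control = 0) and ``replicate``.
    ``library_sizes``: per-sample totals of assigned reads; they stay fixed
    when features are filtered, so RPM values are stable under filtering.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if set(self.counts.columns) != set(self.design.index):
            raise ValueError("design does not cover the sample columns exactly")
        if len(set(self.counts.columns)) != len(self.counts.columns):
            raise ValueError("duplicate sample ids")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"design lacks columns {missing}")
        self.design = self.design.loc[self.counts.columns]
        self.library_sizes = self.library_sizes.loc[self.counts.columns].astype(float)
        colsums = self.counts.sum(axis=0)
        if (self.library_sizes + 1e-9 < colsums).any():
            raise ValueError("library sizes smaller than column sums")

    # -- convenience -------------------------------------------------------
    @property
    def mirnas(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def rpm(self, pseudocount: float = 0.0) -> pd.DataFrame:
        """Reads per million assigned reads."""
        lib = self.library_sizes
        if (lib <= 0).any():
            raise ValueError("zero library size")
        return (self.counts + pseudocount) / lib * 1e6

    def samples_for(self, strain: str | None = None, timepoint_h: float | None = None) -> list[str]:
        mask = pd.Series(True, index=self.design.index)
        if strain is not None:
            mask &= self.design["strain"] == strain
        if timepoint_h is not None:
            mask &= np.isclose(self.design["timepoint_h"].astype(float), timepoint_h)
        return list(self.design.index[mask])

    def conditions(self) -> list[tuple[str, float]]:
        seen: list[tuple[str, float]] = []
        for _, row in self.design.iterrows():
            key = (row["strain"], float(row["timepoint_h"]))
            if key not in seen:
                seen.append(key)
        return seen

    def condition_means(self, values: pd.DataFrame | None = None) -> pd.DataFrame:
        """Replicate-mean of ``values`` (default: raw counts) per condition."""
        if values is None:
            values = self.counts
        cols = {}
        for strain, tp in self.conditions():
            cols[(strain, tp)] = values[self.samples_for(strain, tp)].mean(axis=1)
        out = pd.DataFrame(cols)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["strain", "timepoint_h"])
        return out

    def subset(self, mirnas: Iterable[str]) -> "CountMatrix":
        keep = [m for m in self.mirnas if m in set(mirnas)]
        return CountMatrix(self.counts.loc[keep], self.design.copy(), self.library_sizes.copy())

    # -- I/O ---------------------------------------------------------------
    def write_tsv(self, counts_path, design_path) -> None:
        out = self.counts.copy()
        out.index.name = "mirna"
        out.to_csv(counts_path, sep="\t")
        d = self.design.copy()
        d.insert(0, "library_size", self.library_sizes)
        d.index.name = "sample"
        d.to_csv(design_path, sep="\t")

    @classmethod
    def read_tsv(cls, counts_path, design_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="mirna")
        d = pd.read_csv(design_path, sep="\t", index_col="sample")
        lib = d.pop("library_size")
        return cls(counts, d, lib)


def _assign_reads(
    reads: pd.DataFrame,
    features: pd.DataFrame,
    min_overlap_frac: float,
    length_range: tuple[int, int],
) -> tuple[pd.Series, dict]:
    """Assign each read to at most one mature feature.

    Returns per-feature counts and a report of unassigned reads.
    """
    import pyranges as pr

    n_reads = len(reads)
    report = {"input_reads": n_reads, "assigned": 0, "unassigned": 0,
              "off_chromosome": 0, "length_filtered": 0}
    lo, hi = length_range
    rl = reads["end"] - reads["start"]
    len_ok = (rl >= lo) & (rl <= hi)
    report["length_filtered"] = int((~len_ok).sum())
    known = reads["chrom"].isin(set(features["chrom"]))
    report["off_chromosome"] = int((~known).sum())
    cand = reads[len_ok & known]
    counts = pd.Series(0, index=features["mirna"], dtype=np.int64)
    if len(cand) and len(features):
        r = pd.DataFrame(
            {
                "Chromosome": cand["chrom"].to_numpy(),
                "Start": cand["start"].to_numpy(),
                "End": cand["end"].to_numpy(),
                "read_idx": np.arange(len(cand)),
                "read_strand": cand["strand"].to_numpy(),
            }
        )
        f = pd.DataFrame(
            {
                "Chromosome": features["chrom"].to_numpy(),
                "Start": features["start"].to_numpy(),
                "End": features["end"].to_numpy(),
                "feat_start": features["start"].to_numpy(),
                "feat_id": features["mirna"].to_numpy(),
                "feat_strand": features["strand"].to_numpy(),
            }
        )
        j = pr.PyRanges(r).join(pr.PyRanges(f), suffix="_f").df
        if len(j):
            j = j[j["read_strand"] == j["feat_strand"]]
        if len(j):
            ov = np.minimum(j["End"], j["End_f"]) - np.maximum(j["Start"], j["Start_f"])
            readlen = j["End"] - j["Start"]
            keep = ov >= min_overlap_frac * readlen
            j = j[keep].assign(overlap=ov[keep])
            if len(j):
                j = j.sort_values(
                    ["read_idx", "overlap", "feat_start", "feat_id"],
                    ascending=[True, False, True, True],
                )
                best = j.drop_duplicates("read_idx", keep="first")
                vc = best["feat_id"].value_counts()
                counts.loc[vc.index] += vc.to_numpy()
    report["assigned"] = int(counts.sum())
    report["unassigned"] = n_reads - report["assigned"]
    return counts, report


def count_overlaps(
    alignments: Mapping[str, pd.DataFrame],
    annotation: MiRNAAnnotation,
    design: pd.DataFrame,
    min_overlap_frac: float = 0.5,
    length_range: tuple[int, int] = (18, 26),
) -> tuple[CountMatrix, dict]:
    """Count reads per mature miRNA for each sample.

    ``alignments`` maps sample id -> BED6 DataFrame.  The library size of a
    sample is the number of reads assigned to any feature.  Reads on
    chromosomes absent from the annotation are tallied in the report but do
    not raise.
    """
    if not annotation.matures:
        raise ValueError("empty annotation")
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    features = annotation.mature_table()
    cols = {}
    reports = {}
    for sample in design.index:
        reads = alignments[sample]
        counts, rep = _assign_reads(reads, features, min_overlap_frac, length_range)
        cols[sample] = counts
        reports[sample] = rep
    counts_df = pd.DataFrame(cols)
    counts_df.index.name = "mirna"
    lib = counts_df.sum(axis=0).astype(float)
    matrix = CountMatrix(counts_df, design, lib)
    return matrix, {"samples": reports, "min_overlap_frac": min_overlap_frac,
                    "length_range": list(length_range)}


def count_reads(
    alignments: pd.DataFrame,
    annotation: MiRNAAnnotation,
    min_overlap_frac: float = 0.5,
    length_range: tuple[int, int] = (18, 26),
) -> tuple[pd.Series, dict]:
    """Single-library variant of :func:`count_overlaps`."""
    if not annotation.matures:
        raise ValueError("empty annotation")
    return _assign_reads(alignments, annotation.mature_table(), min_overlap_frac, length_range)


def filter_low_counts(
    matrix: CountMatrix,
    threshold: float = 50,
    conditions: Iterable[tuple[str, float]] | None = None,
) -> CountMatrix:
    """Drop miRNAs whose replicate-mean raw count is below ``threshold`` in
    every condition of the comparison scope.

    ``conditions`` restricts the scope (e.g. the two conditions of one
    pairwise contrast); ``None`` means every condition in the design.  A
    feature is retained when its mean count is >= ``threshold`` in at least
    one in-scope condition.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = matrix.condition_means()
    if conditions is not None:
        conditions = [(s, float(t)) for s, t in conditions]
        means = means[conditions]
    keep = (means >= threshold).any(axis=1)
    return CountMatrix(
        matrix.counts.loc[keep], matrix.design.copy(), matrix.library_sizes.copy()
    )
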
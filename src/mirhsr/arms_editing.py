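"""Arm-switch detection from 5p/3p count ratios and editing calls from
read pileups.

Arm switching is a change, between conditions, of which arm of a hairpin
dominates the mature pool; it is scored on the log2 (5p/3p) replicate-mean
count ratio.  Editing sites are called from a strand-resolved pileup over
mature intervals as A>G or T>C substitutions on the mature sense strand
(the canonical ADAR and the mirrored antisense signature); the seed region
is mature positions 2-8.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import MiRNAAnnotation, Mature, revcomp
from .quantify import CountMatrix

__all__ = ["arm_ratio", "arm_ratio_table", "detect_arm_switch", "call_editing"]

SEED_REGION = (2, 8)  # 1-based inclusive positions on the mature sense
EDIT_PAIRS = {("A", "G"), ("T", "C")}


def arm_ratio(counts_5p, counts_3p, prior: float = 0.5) -> float:
    """log2 of the (5p mean + prior) / (3p mean + prior) count ratio.

    The sign marks the dominant arm (positive = 5p)."""
    m5 = float(np.mean(counts_5p))
    m3 = float(np.mean(counts_3p))
    if m5 < 0 or m3 < 0:
        raise ValueError("counts must be >= 0")
    return float(np.log2(m5 + prior) - np.log2(m3 + prior))


def arm_ratio_table(
    matrix: CountMatrix, annotation: MiRNAAnnotation, prior: float = 0.5
) -> pd.DataFrame:
    """Per (hairpin, strain, timepoint): arm means and the log2 5p/3p ratio."""
    rows = []
    for hid in sorted(annotation.hairpins):
        arms = annotation.arms_of(hid)
        if "5p" not in arms or "3p" not in arms:
            continue
        id5, id3 = arms["5p"].id, arms["3p"].id
        if id5 not in matrix.mirnas or id3 not in matrix.mirnas:
            continue
        for strain, tp in matrix.conditions():
            cols = matrix.samples_for(strain, tp)
            c5 = matrix.counts.loc[id5, cols].to_numpy(dtype=float)
            c3 = matrix.counts.loc[id3, cols].to_numpy(dtype=float)
            rows.append(
                {
                    "hairpin": hid,
                    "strain": strain,
                    "timepoint_h": tp,
                    "mean_5p": c5.mean(),
                    "mean_3p": c3.mean(),
                    "log2_ratio": arm_ratio(c5, c3, prior),
                }
            )
    return pd.DataFrame(rows)


def detect_arm_switch(
    matrix: CountMatrix,
    annotation: MiRNAAnnotation,
    delta_min: float = 1.0,
    count_floor: float = 50.0,
    prior: float = 0.5,
    control_tp: float = 0.0,
) -> pd.DataFrame:
    """Arm-switch events between the control and each post-HS condition.

    Within each strain, an event is emitted for (control, t) when
    |delta log2 ratio| >= delta_min (inclusive) and either the dominant arm
    flips sign or the minor arm's mean count crosses ``count_floor`` upward.
    Both arms must reach the count floor in at least one of the two
    conditions.
    """
    table = arm_ratio_table(matrix, annotation, prior)
    if table.empty:
        return pd.DataFrame(
            columns=["hairpin", "strain", "timepoint_h", "ratio_control", "ratio",
                     "delta_log2", "dominant_flip", "mean_5p", "mean_3p"]
        )
    events = []
    for (hid, strain), grp in table.groupby(["hairpin", "strain"], sort=True):
        grp = grp.set_index("timepoint_h").sort_index()
        if control_tp not in grp.index:
            continue
        ctrl = grp.loc[control_tp]
        for tp, row in grp.iterrows():
            if tp == control_tp:
                continue
            delta = row["log2_ratio"] - ctrl["log2_ratio"]
            floor_ok = (
                max(ctrl["mean_5p"], row["mean_5p"]) >= count_floor
                and max(ctrl["mean_3p"], row["mean_3p"]) >= count_floor
            )
            if not floor_ok or abs(delta) < delta_min:
                continue
            flip = np.sign(ctrl["log2_ratio"]) * np.sign(row["log2_ratio"]) < 0
            minor = "mean_5p" if ctrl["log2_ratio"] < 0 else "mean_3p"
            crossed = ctrl[minor] < count_floor <= row[minor]
            if flip or crossed:
                events.append(
                    {
                        "hairpin": hid,
                        "strain": strain,
                        "timepoint_h": tp,
                        "ratio_control": ctrl["log2_ratio"],
                        "ratio": row["log2_ratio"],
                        "delta_log2": delta,
                        "dominant_flip": bool(flip),
                        "mean_5p": row["mean_5p"],
                        "mean_3p": row["mean_3p"],
                    }
                )
    return pd.DataFrame(events)


# ---------------------------------------------------------------------------
# editing
# ---------------------------------------------------------------------------

def _mature_sense_seq(m: Mature, reference: Mapping[str, str]) -> str:
    seq = reference[m.chrom][m.start : m.end]
    return revcomp(seq) if m.strand == "-" else seq


def _pileup_for_mature(
    m: Mature, reads: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Base counts per mature-sense position from reads of one mature.

    Returns (coverage[len], base_counts[len, 4]) with columns A, C, G, T.
    Read sequences are carried in the BED name column, already in mature
    sense (5'->3').
    """
    L = len(m)
    base_counts = np.zeros((L, 4), dtype=np.int64)
    order = {b: i for i, b in enumerate("ACGT")}
    if m.strand == "+":
        offs = reads["start"].to_numpy() - m.start
    else:
        offs = m.end - reads["end"].to_numpy()
    seqs = reads["name"].to_numpy()
    lens = (reads["end"] - reads["start"]).to_numpy()
    for (off, ln), idx in pd.DataFrame({"o": offs, "l": lens}).groupby(["o", "l"]).groups.items():
        sub = seqs[np.asarray(idx)]
        if any(len(s) != ln for s in sub):
            raise ValueError(f"read sequence length disagrees with interval on {m.id}")
        arr = np.frombuffer("".join(sub).encode(), dtype="S1").reshape(len(sub), int(ln))
        lo = max(0, int(off))
        hi = min(L, int(off) + int(ln))
        for b, col in order.items():
            counts = (arr == b.encode()).sum(axis=0)
            base_counts[lo:hi, col] += counts[lo - int(off) : hi - int(off)]
    coverage = base_counts.sum(axis=1)
    return coverage, base_counts


def call_editing(
    alignments: pd.DataFrame,
    annotation: MiRNAAnnotation,
    reference: Mapping[str, str],
    min_cov: int = 10,
    min_freq: float = 0.1,
    error_rate: float = 1e-3,
    min_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """De-novo A>G / T>C editing calls from mature-interval pileups.

    A site is called when coverage >= ``min_cov``, the mismatch frequency of
    the substitution >= ``min_freq`` and the (reference, alternate) pair read
    on the mature sense strand is A>G or T>C.  ``p_error`` is a binomial
    upper-tail probability of seeing that many mismatches at ``error_rate``
    (reported as metadata, not used as a filter).
    """
    calls = []
    order = "ACGT"
    for mid in sorted(annotation.matures):
        m = annotation.matures[mid]
        sel = alignments[
            (alignments["chrom"] == m.chrom) & (alignments["strand"] == m.strand)
        ]
        if len(sel):
            ov = np.minimum(sel["end"], m.end) - np.maximum(sel["start"], m.start)
            rl = sel["end"] - sel["start"]
            sel = sel[ov >= min_overlap_frac * rl]
        if not len(sel):
            continue
        sense = _mature_sense_seq(m, reference)
        coverage, base_counts = _pileup_for_mature(m, sel)
        for pos0 in range(len(m)):
            cov = int(coverage[pos0])
            if cov < min_cov:
                continue
            ref_b = sense[pos0]
            for alt_i, alt_b in enumerate(order):
                if alt_b == ref_b or (ref_b, alt_b) not in EDIT_PAIRS:
                    continue
                n_alt = int(base_counts[pos0, alt_i])
                freq = n_alt / cov
                if n_alt == 0 or freq < min_freq:
                    continue
                pos1 = pos0 + 1
                calls.append(
                    {
                        "mirna": mid,
                        "position": pos1,
                        "ref": ref_b,
                        "alt": alt_b,
                        "type": f"{ref_b}>{alt_b}",
                        "coverage": cov,
                        "n_alt": n_alt,
                        "frequency": freq,
                        "in_seed": SEED_REGION[0] <= pos1 <= SEED_REGION[1],
                        "p_error": float(stats.binom.sf(n_alt - 1, cov, error_rate)),
                    }
                )
    return pd.DataFrame(
        calls,
        columns=["mirna", "position", "ref", "alt", "type", "coverage", "n_alt",
                 "frequency", "in_seed", "p_error"],
    )
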
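"""Consensus negative-binomial differential expression and levelling classes.

Strain pairs are compared at each timepoint with two independent NB tests —
a conditional exact test and a Wald test — and a miRNA is called
differentially expressed only when *both* tests agree (BH-adjusted p <= 0.05)
and |log2 FC| >= 1.5 and the 50-count rule holds, i.e. an edgeR+DESeq-style
"both programmes" consensus.

The exact test conditions on the total count: the sum of n i.i.d.
NB(mu, phi) counts is NB with size n/phi, and when the two groups share mu
and phi, the group-A sum given the total T follows BetaBinomial(T, nA/phi,
nB/phi).  The two-sided p-value sums the probabilities of all splits as or
less likely than the observed one; at phi = 0 this reduces to the
conditional binomial (Poisson) test.  Unequal library sizes are handled by
edgeR-style pseudo-counts scaled to the geometric-mean library size.

Levelling classes follow the heat-shock phenomenology: class #1 miRNAs are
strain-different at 25 degC and no longer different right after heat shock
("levelled"); class #2 miRNAs are strain-equal at control and diverge only
during recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

__all__ = [
    "AnalysisConfig",
    "rpm_normalize",
    "estimate_dispersion",
    "nb_exact_test",
    "nb_wald_test",
    "bh_adjust",
    "pairwise_de",
    "classify_levelled",
    "levelling_index",
]

_TIE_RTOL = 1e-9  # "as or less likely" inclusion tolerance on the pmf


@dataclass(frozen=True)
class AnalysisConfig:
    """Differential-expression thresholds (defaults follow the study)."""

    fdr_alpha: float = 0.05
    lfc_min: float = 1.5
    count_min: float = 50.0
    prior_count: float = 0.5
    pseudocount_rpm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "lfc_min", "count_min", "prior_count", "pseudocount_rpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def rpm_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Counts -> reads per million assigned reads."""
    return matrix.rpm()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def size_factors(library_sizes: pd.Series) -> pd.Series:
    """Library sizes scaled to geometric mean 1 (RPM-consistent)."""
    lib = library_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("non-positive library size")
    return lib / np.exp(np.mean(np.log(lib)))


def estimate_dispersion(
    matrix: CountMatrix,
    prior_dispersion: float = 0.1,
    floor: float = 1e-4,
    shrink: float = 0.5,
    trim: float = 0.2,
) -> pd.Series:
    """Per-miRNA method-of-moments NB dispersion, shrunk toward the trimmed
    -mean common value.

    For each condition with >= 2 replicates the residual dispersion is
    (var - mean/s) / mean^2 on size-factor-normalized counts; per-feature
    estimates are df-weighted across conditions, then shrunk ``shrink`` of
    the way toward the trimmed-mean common dispersion and floored.
    """
    sf = size_factors(matrix.library_sizes)
    x = matrix.counts / sf
    num = pd.Series(0.0, index=matrix.mirnas)
    den = 0.0
    any_rep = False
    for strain, tp in matrix.conditions():
        cols = matrix.samples_for(strain, tp)
        if len(cols) < 2:
            continue
        any_rep = True
        sub = x[cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        inv_s = float(np.mean(1.0 / sf[cols]))
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_c = (v - m * inv_s) / (m**2)
        w = len(cols) - 1
        num += w * phi_c.fillna(0.0).clip(lower=0.0)
        den += w
    if not any_rep:
        warnings.warn("no replicated condition; falling back to prior dispersion")
        return pd.Series(prior_dispersion, index=matrix.mirnas)
    raw = num / den
    finite = raw[np.isfinite(raw)]
    common = float(stats.trim_mean(finite, trim)) if len(finite) else prior_dispersion
    phi = shrink * common + (1.0 - shrink) * raw.fillna(common)
    return phi.clip(lower=floor)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _log_factorial_table(n: int) -> np.ndarray:
    """lf[k] = log(k!) for k = 0..n, via a cumulative sum of logs."""
    lf = np.zeros(n + 1)
    if n >= 2:
        lf[2:] = np.cumsum(np.log(np.arange(2.0, n + 1.0)))
    return lf


def _conditional_logpmf(total: int, alpha: float, beta: float, lf: np.ndarray) -> np.ndarray:
    """Unnormalized log pmf of the group-A sum given the total.

    BetaBinomial(total, alpha, beta) for finite alpha (phi > 0); the
    binomial limit alpha, beta -> inf with ratio alpha/(alpha+beta) is
    handled by the caller passing ``alpha = beta = inf`` never — use
    :func:`_binomial_logpmf` instead.
    """
    y = np.arange(total + 1)
    log_choose = lf[total] - lf[y] - lf[total - y]
    a_part = np.concatenate([[0.0], np.cumsum(np.log(alpha + np.arange(total)))])
    b_part = np.concatenate([[0.0], np.cumsum(np.log(beta + np.arange(total)))])
    return log_choose + a_part[y] + b_part[total - y]


def _binomial_logpmf(total: int, w: float, lf: np.ndarray) -> np.ndarray:
    y = np.arange(total + 1)
    return lf[total] - lf[y] - lf[total - y] + y * np.log(w) + (total - y) * np.log1p(-w)


def _minlike_pvalue(logpmf: np.ndarray, observed: int) -> float:
    """Two-sided exact p: total probability of outcomes as or less likely."""
    lp = logpmf - logpmf.max()
    probs = np.exp(lp)
    thresh = lp[observed] + np.log1p(_TIE_RTOL)
    return float(probs[lp <= thresh].sum() / probs.sum())


def _pseudo_counts(counts: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Scale counts to the common (geometric-mean-1) library scale."""
    return np.rint(counts / sf).astype(np.int64)


def nb_exact_test(
    counts_a,
    counts_b,
    size_factors_a=None,
    size_factors_b=None,
    phi: float = 0.0,
) -> float:
    """Conditional two-sided NB exact test for two replicate groups.

    Counts are scaled to a common library size, summed per group, and the
    group-A sum is compared with its conditional distribution given the
    total (beta-binomial, binomial at phi = 0).  Returns 1 when the total
    is 0.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    sfa = np.ones(len(a)) if size_factors_a is None else np.asarray(size_factors_a, float)
    sfb = np.ones(len(b)) if size_factors_b is None else np.asarray(size_factors_b, float)
    geo = np.exp(np.mean(np.log(np.concatenate([sfa, sfb]))))
    ya = int(_pseudo_counts(a, sfa / geo).sum())
    yb = int(_pseudo_counts(b, sfb / geo).sum())
    total = ya + yb
    if total == 0:
        return 1.0
    na, nb = len(a), len(b)
    lf = _log_factorial_table(total)
    if phi == 0:
        lp = _binomial_logpmf(total, na / (na + nb), lf)
    else:
        lp = _conditional_logpmf(total, na / phi, nb / phi, lf)
    return _minlike_pvalue(lp, ya)


def _exact_test_batch(
    ya: np.ndarray, yb: np.ndarray, na: int, nb: int, phi: np.ndarray
) -> np.ndarray:
    """Vectorized-inner-loop exact test over many features.

    ``ya``/``yb`` are per-feature pseudo-count group sums; ``phi`` per-feature
    dispersions.
    """
    totals = ya + yb
    out = np.ones(len(ya))
    if len(ya) == 0:
        return out
    lf = _log_factorial_table(int(totals.max()))
    for i in range(len(ya)):
        t = int(totals[i])
        if t == 0:
            continue
        if phi[i] == 0:
            lp = _binomial_logpmf(t, na / (na + nb), lf)
        else:
            lp = _conditional_logpmf(t, na / phi[i], nb / phi[i], lf)
        out[i] = _minlike_pvalue(lp, int(ya[i]))
    return out


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def nb_wald_test(
    counts_a,
    counts_b,
    size_factors_a=None,
    size_factors_b=None,
    phi: float = 0.0,
    prior: float = 0.5,
) -> float:
    """Two-sided Wald z-test on the log fold-change with delta-method
    variance from the NB mean-variance relation."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    sfa = np.ones(len(a)) if size_factors_a is None else np.asarray(size_factors_a, float)
    sfb = np.ones(len(b)) if size_factors_b is None else np.asarray(size_factors_b, float)
    p = _wald_batch(
        (a / sfa)[None, :], (b / sfb)[None, :], sfa, sfb, np.array([phi]), prior
    )
    return float(p[0])


def _wald_batch(
    xa: np.ndarray, xb: np.ndarray, sfa: np.ndarray, sfb: np.ndarray,
    phi: np.ndarray, prior: float,
) -> np.ndarray:
    """Rows = features; ``xa``/``xb`` are size-factor-normalized counts."""
    ma = xa.mean(axis=1)
    mb = xb.mean(axis=1)
    na, nb = xa.shape[1], xb.shape[1]
    var_ma = (ma[:, None] / sfa[None, :] + phi[:, None] * ma[:, None] ** 2).sum(axis=1) / na**2
    var_mb = (mb[:, None] / sfb[None, :] + phi[:, None] * mb[:, None] ** 2).sum(axis=1) / nb**2
    lfc = np.log(ma + prior) - np.log(mb + prior)
    se2 = var_ma / (ma + prior) ** 2 + var_mb / (mb + prior) ** 2
    p = np.ones(len(ma))
    nonzero = (ma + mb) > 0
    se = np.sqrt(np.maximum(se2, 1e-300))
    z = np.where(se > 0, lfc / se, 0.0)
    p[nonzero] = 2 * stats.norm.sf(np.abs(z[nonzero]))
    return np.minimum(p, 1.0)


# ---------------------------------------------------------------------------
# pairwise contrasts
# ---------------------------------------------------------------------------

def pairwise_de(
    matrix: CountMatrix,
    contrast: tuple[str, str, float],
    config: AnalysisConfig = AnalysisConfig(),
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-test consensus DE for one (strainA, strainB, timepoint) contrast.

    Features failing the 50-count rule (replicate-mean raw count below
    ``count_min`` in both conditions) are not tested.  ``is_de`` is the
    conjunction of both BH-adjusted tests (<= fdr_alpha, inclusive) and the
    |log2 FC| >= lfc_min gate (inclusive).
    """
    strain_a, strain_b, tp = contrast
    cols_a = matrix.samples_for(strain_a, tp)
    cols_b = matrix.samples_for(strain_b, tp)
    if not cols_a or not cols_b:
        raise ValueError(f"empty contrast {contrast}")
    if dispersions is None:
        dispersions = estimate_dispersion(matrix)

    mean_a = matrix.counts[cols_a].mean(axis=1)
    mean_b = matrix.counts[cols_b].mean(axis=1)
    tested = (mean_a >= config.count_min) | (mean_b >= config.count_min)
    feats = matrix.mirnas[tested]
    phi = dispersions.loc[feats].to_numpy()

    lib = matrix.library_sizes[cols_a + cols_b]
    sf = size_factors(lib)
    sfa = sf[cols_a].to_numpy()
    sfb = sf[cols_b].to_numpy()
    ca = matrix.counts.loc[feats, cols_a].to_numpy(dtype=float)
    cb = matrix.counts.loc[feats, cols_b].to_numpy(dtype=float)

    ya = np.rint(ca / sfa[None, :]).sum(axis=1).astype(np.int64)
    yb = np.rint(cb / sfb[None, :]).sum(axis=1).astype(np.int64)
    p_exact = _exact_test_batch(ya, yb, len(cols_a), len(cols_b), phi)
    p_wald = _wald_batch(ca / sfa[None, :], cb / sfb[None, :], sfa, sfb, phi, config.prior_count)

    norm_a = (ca / sfa[None, :]).mean(axis=1)
    norm_b = (cb / sfb[None, :]).mean(axis=1)
    lfc = np.log2(norm_a + config.prior_count) - np.log2(norm_b + config.prior_count)

    rpm = matrix.rpm()
    res = pd.DataFrame(
        {
            "baseMeanA": rpm.loc[feats, cols_a].mean(axis=1),
            "baseMeanB": rpm.loc[feats, cols_b].mean(axis=1),
            "log2FC": lfc,
            "p_exact": p_exact,
            "p_wald": p_wald,
            "padj_exact": bh_adjust(p_exact),
            "padj_wald": bh_adjust(p_wald),
        },
        index=feats,
    )
    res["is_de"] = (
        (res["padj_exact"] <= config.fdr_alpha)
        & (res["padj_wald"] <= config.fdr_alpha)
        & (res["log2FC"].abs() >= config.lfc_min)
    )
    return res


def all_pairwise_de(
    matrix: CountMatrix,
    config: AnalysisConfig = AnalysisConfig(),
    timepoints: Sequence[float] | None = None,
    dispersions: pd.Series | None = None,
) -> dict[tuple[str, str, float], pd.DataFrame]:
    """Pairwise DE for every strain pair at each timepoint."""
    strains = list(dict.fromkeys(matrix.design["strain"]))
    if timepoints is None:
        timepoints = sorted(set(matrix.design["timepoint_h"].astype(float)))
    if dispersions is None:
        dispersions = estimate_dispersion(matrix)
    out = {}
    for sa, sb in combinations(strains, 2):
        for tp in timepoints:
            out[(sa, sb, float(tp))] = pairwise_de(
                matrix, (sa, sb, float(tp)), config, dispersions
            )
    return out


# ---------------------------------------------------------------------------
# levelling classification
# ---------------------------------------------------------------------------

def _is_de(res: pd.DataFrame, mirna: str) -> bool:
    return mirna in res.index and bool(res.loc[mirna, "is_de"])


def _group_label(pairs: list[tuple[str, str]], strains: Sequence[str]):
    """Map the set of supporting strain pairs to member strains and a label.

    All pairs -> common; a single pair -> shared by those two strains; two
    (or more) pairs sharing one hub strain -> unique to that strain.
    """
    from itertools import combinations as comb

    all_pairs = {frozenset(p) for p in comb(strains, 2)}
    got = {frozenset(p) for p in pairs}
    if got == all_pairs:
        return tuple(strains), "common"
    degree = {s: sum(s in p for p in got) for s in strains}
    top = max(degree.values())
    members = tuple(sorted(s for s, d in degree.items() if d == top))
    if len(got) == 1:
        return members, "shared"
    if len(members) == 1:
        return members, "unique"
    label = {len(strains): "common", 2: "shared", 1: "unique"}.get(len(members), "shared")
    return members, label


def classify_levelled(
    de_results: Mapping[tuple[str, str, float], pd.DataFrame],
    strains: Sequence[str],
    control_tp: float = 0.0,
    window: Sequence[float] = (1.0,),
) -> pd.DataFrame:
    """Assign class #1 (levelled) / class #2 (HS-divergent) labels.

    For a strain pair, a miRNA is class #1 when it is DE at control and not
    DE at any levelling-window timepoint, and class #2 when it is not DE at
    control but DE at >= 1 post-HS timepoint.  Class #1 wins when both hold
    across different pairs.  The common/shared/unique group follows the
    pair-support pattern (see :func:`_group_label`).
    """
    pairs = sorted({(a, b, t) for (a, b, t) in de_results}, key=str)
    tps = sorted({t for (_, _, t) in de_results})
    if control_tp not in tps:
        raise ValueError("control timepoint missing from DE results")
    for w in window:
        if w not in tps:
            raise ValueError(f"levelling-window timepoint {w} missing from DE results")
    post = [t for t in tps if t > control_tp]
    strain_pairs = sorted({(a, b) for (a, b, _) in de_results})
    for sa, sb in strain_pairs:
        for t in [control_tp] + post:
            if (sa, sb, t) not in de_results:
                raise ValueError(f"missing DE result for {(sa, sb, t)}")

    universe = sorted(set().union(*(set(r.index) for r in de_results.values())))
    rows = []
    for m in universe:
        pairs1, pairs2 = [], []
        for sa, sb in strain_pairs:
            de_ctrl = _is_de(de_results[(sa, sb, control_tp)], m)
            de_window = any(_is_de(de_results[(sa, sb, t)], m) for t in window)
            de_post = any(_is_de(de_results[(sa, sb, t)], m) for t in post)
            if de_ctrl and not de_window:
                pairs1.append((sa, sb))
            elif not de_ctrl and de_post:
                pairs2.append((sa, sb))
        if pairs1:
            members, label = _group_label(pairs1, strains)
            rows.append((m, "class1", label, members, tuple(map(tuple, pairs1))))
        elif pairs2:
            members, label = _group_label(pairs2, strains)
            rows.append((m, "class2", label, members, tuple(map(tuple, pairs2))))
        else:
            rows.append((m, "none", None, (), ()))
    return pd.DataFrame(
        rows, columns=["mirna", "level_class", "group", "member_strains", "pair_support"]
    ).set_index("mirna")


def levelling_index(
    rpm: pd.DataFrame,
    design: pd.DataFrame,
    timepoint_h: float,
    strains: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> float:
    """Mean (over miRNAs) of the maximal pairwise |log2 RPM difference| of
    strain condition means at one timepoint — the interstrain spread that
    the levelling effect reduces after heat shock."""
    if strains is None:
        strains = list(dict.fromkeys(design["strain"]))
    if len(strains) < 2:
        raise ValueError("need at least two strains")
    means = {}
    for s in strains:
        cols = design.index[
            (design["strain"] == s)
            & np.isclose(design["timepoint_h"].astype(float), timepoint_h)
        ]
        if len(cols) == 0:
            raise ValueError(f"no samples for strain {s} at {timepoint_h} h")
        means[s] = np.log2(rpm[cols].mean(axis=1) + pseudocount)
    spread = None
    for sa, sb in combinations(strains, 2):
        d = (means[sa] - means[sb]).abs()
        spread = d if spread is None else np.maximum(spread, d)
    return float(spread.mean())
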
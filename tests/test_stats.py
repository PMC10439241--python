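"""Unit and oracle tests for the statistical primitives."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats as sps
from scipy.optimize import brentq

from sphereproteo import stats


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_stepup_oracle(p):
    """Hand step-up: p(i) * n / i with cumulative minimum from the top."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    current = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        current = min(current, p[i] * n / rank)
        adj[i] = min(current, 1.0)
    return adj


@pytest.mark.parametrize(
    "pvals",
    [
        (0.01, 0.02, 0.03, 0.04),
        (0.5,),
        (0.001, 0.5, 0.9, 0.04, 0.2),
        (1.0, 0.0, 0.7),
        tuple(np.random.default_rng(1).uniform(size=10)),
    ],
)
def test_bh_matches_stepup_oracle(pvals):
    expected = bh_stepup_oracle(pvals)
    result = stats.benjamini_hochberg(pvals)
    assert np.allclose(result, expected)


def test_bh_known_example():
    assert np.allclose(
        stats.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_single_p_unchanged():
    assert stats.benjamini_hochberg([0.3])[0] == pytest.approx(0.3)


def test_bh_propagates_nan_and_rejects_bad():
    out = stats.benjamini_hochberg([0.1, np.nan, 0.2])
    assert np.isnan(out[1]) and np.isfinite(out[0])
    with pytest.raises(ValueError):
        stats.benjamini_hochberg([0.1, 1.5])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_bounds_and_order_preservation(pvals):
    q = stats.benjamini_hochberg(pvals)
    assert (q >= np.asarray(pvals) - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()
    # a smaller p never gets a larger q
    order = np.argsort(pvals, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# Fisher enrichment vs exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------

def hypergeom_two_sided_oracle(k, set_size, K, N):
    """Sum of all tail probabilities <= P(observed) over draws of set_size."""
    probs = {
        x: sps.hypergeom.pmf(x, N, K, set_size)
        for x in range(max(0, set_size - (N - K)), min(K, set_size) + 1)
    }
    p_obs = probs[k]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_matches_hypergeometric_enumeration_small_tables():
    for N in (4, 7, 12, 20):
        background = [f"g{i}" for i in range(N)]
        for K in (0, 1, N // 2, N):
            ann = {g: {"T"} for g in background[:K]}
            for set_size in (1, 2, N // 2):
                fs = background[:set_size]
                rows = stats.fisher_enrichment(fs, background, ann)
                if K == 0:
                    assert rows.empty
                    continue
                row = rows.iloc[0]
                k = len(set(fs) & set(background[:K]))
                expected = hypergeom_two_sided_oracle(k, set_size, K, N)
                assert row["p_value"] == pytest.approx(expected, rel=1e-9)


def test_fisher_one_sided_enumeration_example():
    # set of 2, both annotated; background of 4 with 2 annotated -> 1/C(4,2)
    background = ["a", "b", "c", "d"]
    ann = {"a": {"T"}, "b": {"T"}}
    rows = stats.fisher_enrichment(["a", "b"], background, ann, alternative="greater")
    assert rows.iloc[0]["p_value"] == pytest.approx(1 / 6)


def test_fisher_whole_background_term_and_fold_definition():
    background = ["a", "b", "c", "d"]
    ann = {g: {"ALL"} for g in background}
    rows = stats.fisher_enrichment(["a", "b"], background, ann)
    row = rows.iloc[0]
    assert row["fold_enrichment"] == pytest.approx(1.0)
    assert row["p_value"] == pytest.approx(1.0)
    # freq 0.5 in set vs 0.25 in background -> fold 2
    ann2 = {"a": {"X"}}
    rows2 = stats.fisher_enrichment(["a", "b"], background, ann2)
    assert rows2.iloc[0]["fold_enrichment"] == pytest.approx(2.0)


def test_fisher_requires_subset_and_background():
    with pytest.raises(ValueError):
        stats.fisher_enrichment(["z"], ["a"], {})
    with pytest.raises(ValueError):
        stats.fisher_enrichment([], [], {})


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

def test_paired_t_hand_formula():
    res = stats.paired_t_test([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
    assert res.estimate == pytest.approx(2.0)
    assert res.statistic == pytest.approx(3.4641, abs=1e-4)
    assert res.df == 2


def test_paired_t_sign_antisymmetry():
    up = stats.paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
    dn = stats.paired_t_test([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
    assert dn.statistic == pytest.approx(-up.statistic)
    assert dn.p_value == pytest.approx(up.p_value)


def test_paired_t_identical_series_and_degenerate():
    res = stats.paired_t_test([1.0, 2.0], [1.0, 2.0])
    assert res.estimate == 0.0 and res.p_value == 1.0
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        res = stats.paired_t_test([2.0, 3.0], [1.0, 2.0])  # constant nonzero diff
    assert res.p_value > 0 and res.p_value < 1e-300
    assert any("zero variance" in str(w.message) for w in rec)
    assert stats.paired_t_test([1.0, np.nan], [0.0, 1.0]) is None


# ---------------------------------------------------------------------------
# Moderated t-test
# ---------------------------------------------------------------------------

def _two_group_design(n_per_group=3):
    n = 2 * n_per_group
    return np.column_stack([np.ones(n), [1.0] * n_per_group + [0.0] * n_per_group])


def moderated_t_oracle(mat, n_per_group=3):
    """Independent implementation of the closed-form moment estimators.

    Per-feature two-group OLS variances are shrunk toward a scaled
    inverse-chi-square prior whose df solves trigamma(d0/2) = var(e) -
    mean(trigamma(d/2)) (root found by bracketing bisection, not Newton).
    """
    n = 2 * n_per_group
    d = n - 2
    g1, g2 = mat[:, :n_per_group], mat[:, n_per_group:]
    est = g1.mean(axis=1) - g2.mean(axis=1)
    s2 = (
        ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((g2 - g2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / d
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (len(e) - 1) - special.polygamma(1, d / 2)
    if evar > 0:
        half_d0 = brentq(lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8)
        d0 = 2 * half_d0
        s2_prior = np.exp(emean + special.digamma(half_d0) - np.log(half_d0))
        s2_post = (d0 * s2_prior + d * s2) / (d0 + d)
        df_total = d + d0
        t = est / np.sqrt(s2_post * (2 / n_per_group))
        p = 2 * sps.t.sf(np.abs(t), df_total)
    else:
        s2_post = np.full_like(s2, s2.mean())  # pooled-scale MLE fallback
        t = est / np.sqrt(s2_post * (2 / n_per_group))
        p = 2 * sps.norm.sf(np.abs(t))
        d0 = np.inf
    return t, p, d0


def test_moderated_t_matches_independent_closed_form_oracle(rng):
    mat = rng.normal(20, 1.5, size=(200, 6))
    mat[:50, :3] += rng.normal(1.0, 0.5, size=(50, 1))
    res = stats.moderated_t_test(pd.DataFrame(mat), _two_group_design(), [0, 1])
    t_oracle, p_oracle, d0 = moderated_t_oracle(mat)
    assert res.attrs["df_prior"] == pytest.approx(d0, rel=1e-6)
    assert np.allclose(res["statistic"], t_oracle, atol=1e-6)
    assert np.allclose(res["p_value"], p_oracle, atol=1e-6)


def test_moderated_t_prior_df_zero_equals_ordinary_t(rng):
    mat = rng.normal(0, 1, size=(60, 6))
    res = stats.moderated_t_test(pd.DataFrame(mat), _two_group_design(), [0, 1], prior_df=0)
    ordinary = np.array(
        [sps.ttest_ind(row[:3], row[3:]).statistic for row in mat]
    )
    assert np.allclose(res["statistic"], ordinary, atol=1e-9)


def test_moderated_t_infinite_prior_gives_prior_variance(rng):
    mat = rng.normal(0, 1, size=(60, 6))
    res = stats.moderated_t_test(
        pd.DataFrame(mat), _two_group_design(), [0, 1], prior_df=np.inf
    )
    # all posterior variances collapse to the (flat) prior value
    assert res["s2_posterior"].std() == pytest.approx(0.0, abs=1e-12)


def test_moderated_t_rejects_saturated_or_deficient_design(rng):
    mat = pd.DataFrame(rng.normal(size=(10, 2)))
    with pytest.raises(ValueError):
        stats.moderated_t_test(mat, np.eye(2), [0, 1])
    mat6 = pd.DataFrame(rng.normal(size=(10, 6)))
    X = np.column_stack([np.ones(6), np.ones(6)])
    with pytest.raises(ValueError):
        stats.moderated_t_test(mat6, X, [0, 1])


def test_moderated_t_matches_limma_reference(tmp_path, rng):
    """Cross-check against the Bioconductor limma implementation."""
    import subprocess

    mat = rng.normal(20, 2, size=(150, 6))
    mat[:40, :3] += 1.0
    np.savetxt(tmp_path / "mat.tsv", mat, delimiter="\t")
    script = tmp_path / "check.R"
    script.write_text(
        "suppressMessages(library(limma))\n"
        f"mat <- as.matrix(read.table('{tmp_path}/mat.tsv', sep='\\t'))\n"
        "design <- cbind(1, c(1,1,1,0,0,0))\n"
        "fit <- eBayes(lmFit(mat, design), trend=FALSE)\n"
        f"write.table(data.frame(t=fit$t[,2]), '{tmp_path}/r.tsv', sep='\\t', row.names=FALSE)\n"
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    r_t = pd.read_csv(tmp_path / "r.tsv", sep="\t")["t"].to_numpy()
    res = stats.moderated_t_test(pd.DataFrame(mat), _two_group_design(), [0, 1])
    assert np.allclose(res["statistic"], r_t, atol=1e-8)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def test_cyclic_loess_removes_constant_offset(rng):
    base = rng.normal(25, 2, 400)
    df = pd.DataFrame({"s1": base, "s2": base + 1.0})
    out = stats.cyclic_loess_normalize(df)
    assert abs((out["s2"] - out["s1"]).median()) < 1e-6


def test_cyclic_loess_identity_on_identical_samples(rng):
    base = rng.normal(25, 2, 300)
    df = pd.DataFrame({"s1": base, "s2": base.copy()})
    out = stats.cyclic_loess_normalize(df)
    assert np.allclose(out, df, atol=1e-9)


def test_cyclic_loess_flattens_linear_ma_trend(rng):
    a = rng.uniform(20, 30, 500)
    m = 0.5 * a - 2.0
    df = pd.DataFrame({"s1": a - m / 2, "s2": a + m / 2})
    out = stats.cyclic_loess_normalize(df)
    a2 = (out["s1"] + out["s2"]) / 2
    m2 = out["s2"] - out["s1"]
    slope = np.polyfit(a2, m2, 1)[0]
    assert abs(slope) < 0.02


def test_cyclic_loess_preserves_missingness(rng):
    base = rng.normal(25, 2, 200)
    df = pd.DataFrame({"s1": base, "s2": base + 0.5, "s3": base - 0.2})
    df.iloc[::7, 0] = np.nan
    df.iloc[3::11, 2] = np.nan
    out = stats.cyclic_loess_normalize(df)
    assert (out.isna() == df.isna()).all().all()
    with pytest.raises(ValueError):
        stats.cyclic_loess_normalize(df[["s1"]])


def test_rlr_identity_and_linear_restoration(rng):
    profile = rng.normal(25, 2, 200)
    df = pd.DataFrame({"a": profile, "b": profile, "c": 1.2 * profile + 0.3})
    out = stats.rlr_normalize(df)
    assert np.allclose(out["a"], df["a"], atol=1e-9)
    ref = df.median(axis=1)
    slope, intercept = np.polyfit(ref, out["c"], 1)
    assert slope == pytest.approx(1.0, abs=1e-3)
    assert intercept == pytest.approx(0.0, abs=1e-3)


def test_rlr_robust_to_gross_outliers(rng):
    profile = rng.normal(25, 2, 300)
    clean = pd.DataFrame(
        {
            "a": profile + rng.normal(0, 0.05, 300),
            "b": profile + rng.normal(0, 0.05, 300),
            "d": profile + rng.normal(0, 0.05, 300),
            "e": profile + rng.normal(0, 0.05, 300),
            "c": 0.9 * profile + 1.0,
        }
    )
    dirty = clean.copy()
    out_idx = rng.choice(300, size=30, replace=False)
    dirty.iloc[out_idx, 4] += rng.choice([-8.0, 8.0], size=30)
    untouched = sorted(set(range(300)) - set(out_idx))
    m_clean = stats.rlr_normalize(clean)["c"].iloc[untouched].median()
    m_dirty = stats.rlr_normalize(dirty)["c"].iloc[untouched].median()
    assert abs(m_clean - m_dirty) < 0.05


def test_rlr_requires_shared_features():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [np.nan, np.nan, 1.0]})
    with pytest.raises(ValueError):
        stats.rlr_normalize(df)


# ---------------------------------------------------------------------------
# Batch-effect removal
# ---------------------------------------------------------------------------

def test_remove_batch_exact_on_noise_free_offsets():
    # two plexes with identical group structure, offsets +1 / -1
    group = [0, 3, 6, 0, 3, 6]
    batch = ["A", "A", "A", "B", "B", "B"]
    base = np.array([[20.0, 21.0, 22.0]])
    vals = np.hstack([base + 1.0, base - 1.0])
    out = stats.remove_batch_effects(vals, batch, group)
    arr = out.to_numpy()
    assert np.allclose(arr[:, :3].mean(), arr[:, 3:].mean(), atol=1e-9)
    # zero batch effect input -> identity
    vals0 = np.hstack([base, base])
    out0 = stats.remove_batch_effects(vals0, batch, group)
    assert np.allclose(out0.to_numpy(), vals0, atol=1e-9)


def test_remove_batch_reestimated_coefficients_vanish():
    from sphereproteo import SimConfig, simulate as sim

    m, _ = sim.simulate_tmt(SimConfig(batch_sd=1.0, noise_sd=0.3, missing_rate=0.0, seed=7))
    design = m.design
    corrected = stats.remove_batch_effects(
        m.values, design["plex_id"], design["timepoint_days"]
    )
    coefs = stats.estimate_batch_coefficients(
        corrected, design["plex_id"], design["timepoint_days"]
    )
    assert np.nanmax(np.abs(coefs.to_numpy())) < 1e-8


def test_remove_batch_rejects_confounded_design():
    vals = np.zeros((2, 4))
    with pytest.raises(ValueError, match="confounded"):
        stats.remove_batch_effects(vals, ["A", "A", "B", "B"], [0, 0, 3, 3])


def test_remove_batch_preserves_missingness(rng):
    vals = rng.normal(20, 1, size=(30, 6))
    vals[::5, 2] = np.nan
    out = stats.remove_batch_effects(
        vals, ["A", "A", "A", "B", "B", "B"], [0, 3, 6, 0, 3, 6]
    )
    assert np.array_equal(np.isnan(out.to_numpy()), np.isnan(vals))


# ---------------------------------------------------------------------------
# Hierarchical clustering vs brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_complete_linkage(dist):
    """O(n^3) agglomeration: repeatedly merge the pair of clusters with the
    smallest maximum inter-point distance."""
    clusters = [frozenset([i]) for i in range(dist.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((set(merged), d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def test_complete_linkage_matches_brute_force_oracle(rng):
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    profiles = pd.DataFrame(rng.normal(size=(10, 6)))
    dist = stats.spearman_distance_matrix(profiles)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    oracle = brute_force_complete_linkage(dist)
    # reconstruct scipy's merged member sets
    members = {i: {i} for i in range(10)}
    for step, (a, b, height, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[10 + step] = merged
        assert merged == oracle[step][0]
        assert height == pytest.approx(oracle[step][1], rel=1e-9)


def test_cluster_recovers_identical_pairs_and_antipodal_distance():
    profiles = pd.DataFrame(
        [[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1], [4, 3, 2, 1]],
        index=["a1", "a2", "b1", "b2"],
        dtype=float,
    )
    labels = stats.hierarchical_cluster(profiles, k=2)
    assert labels["a1"] == labels["a2"] != labels["b1"]
    assert labels["b1"] == labels["b2"]
    d = stats.spearman_distance_matrix(profiles)
    assert d[0, 2] == pytest.approx(2.0)  # rho = -1


def test_cluster_constant_profile_gets_singleton():
    profiles = pd.DataFrame(
        [[1, 2, 3, 4], [2, 3, 4, 5], [1, 1, 1, 1]],
        index=["a", "b", "const"],
        dtype=float,
    )
    with pytest.warns(RuntimeWarning, match="constant"):
        labels = stats.hierarchical_cluster(profiles, k=2)
    assert labels["const"] not in (labels["a"], labels["b"])


def test_cluster_input_validation():
    profiles = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)))
    with pytest.raises(ValueError):
        stats.hierarchical_cluster(profiles, k=5)
    with pytest.raises(ValueError):
        stats.hierarchical_cluster(profiles.iloc[:, :2], k=2)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def test_impute_min_and_minprop_rules():
    df = pd.DataFrame({"a": [10.0, 12.0], "b": [np.nan, 15.0]})
    assert stats.impute_min(df).loc[0, "b"] == 10.0
    assert stats.impute_minprop(df, proportion=0.9).loc[0, "b"] == pytest.approx(9.0)
    full = pd.DataFrame({"a": [1.0, 2.0]})
    assert stats.impute_min(full).equals(full)
    with pytest.raises(ValueError):
        stats.impute_min(pd.DataFrame({"a": [np.nan]}))
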
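"""Normalization, clustering, PERMANOVA, PCA and the NB differential test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cdscore import chromatin_diff as cd
from cdscore import synthgen as sg

from conftest import small_counts


class TestNormalizeCounts:
    def test_equal_totals_identity(self, rng):
        counts = small_counts(rng)
        counts = counts.iloc[:, :2]
        counts["s1"] = counts["s0"].sample(frac=1, random_state=1).to_numpy()
        norm = cd.normalize_counts(counts)
        assert np.allclose(norm.to_numpy(), counts.to_numpy())

    def test_uniformly_doubled_sample_normalizes_back(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]},
                              index=["f1", "f2", "f3"])
        norm = cd.normalize_counts(counts)
        assert np.allclose(norm["a"], norm["b"])
        # geometric-mean anchoring: product of size factors is one
        totals = counts.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
        assert np.isclose(sf.prod(), 1.0)

    def test_single_sample_size_factor_one(self):
        counts = pd.DataFrame({"only": [1, 2, 3]})
        assert cd.normalize_counts(counts).equals(counts.astype(float))

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            cd.normalize_counts(counts)

    def test_log2_variant(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [0, 3]})
        out = cd.normalize_counts(counts, log2=True)
        assert np.allclose(out, np.log2(counts + 1))


class TestCorrelationClustering:
    def test_duplicated_samples_merge_first(self, rng):
        counts = small_counts(rng, n_samples=5)
        counts["s4"] = counts["s0"]
        res = cd.correlation_clustering(counts, k=2)
        assert res.distance.loc["s0", "s4"] == pytest.approx(0.0)
        first_merge = set(res.linkage[0, :2].astype(int))
        assert first_merge == {0, 4}

    def test_monotone_transform_invariance(self, rng):
        counts = small_counts(rng, n_samples=4).astype(float)
        d1 = cd.spearman_distance(counts)
        counts["s0"] = np.exp(counts["s0"] / 10.0)  # rank-preserving
        d2 = cd.spearman_distance(counts)
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_constant_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2, 3], "b": [5, 5, 5]})
        with pytest.raises(ValueError, match="constant"):
            cd.spearman_distance(counts)

    def test_planted_groups_recovered(self, bulk_cohort):
        _, peak_counts, _, _, truth = bulk_cohort
        norm = cd.normalize_counts(peak_counts, log2=True)
        res = cd.correlation_clustering(norm, k=3)
        df = pd.DataFrame({"cluster": res.labels,
                           "subtype": pd.Series(truth.subtype_of_sample)})
        # each cluster maps to exactly one subtype
        assert (df.groupby("cluster").subtype.nunique() == 1).all()
        assert df.cluster.nunique() == 3


class TestPermanova:
    def test_exhaustive_agrees_with_enumeration_oracle(self, rng):
        import itertools
        x = rng.normal(size=(6, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        labels = np.array([0, 0, 0, 1, 1, 1])

        def oracle_f(lab):
            d2, n, a = d ** 2, 6, 2
            sst = d2.sum() / (2 * n)
            ssw = sum(d2[np.ix_(np.flatnonzero(lab == g),
                                np.flatnonzero(lab == g))].sum() / (2 * (lab == g).sum())
                      for g in (0, 1))
            return ((sst - ssw) / (a - 1)) / (ssw / (n - a))

        f_obs, p = cd.permanova(d, labels, exhaustive=True)
        fs = [oracle_f(np.array(perm)) for perm in itertools.permutations(labels)]
        assert f_obs == pytest.approx(oracle_f(labels))
        assert p == pytest.approx(np.mean([f >= f_obs - 1e-12 for f in fs]))

    def test_minimal_p_with_999_permutations(self, rng):
        # groups large enough that no random permutation recreates the split
        x = np.vstack([rng.normal(0, 0.01, (10, 2)), rng.normal(100, 0.01, (10, 2))])
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        _, p = cd.permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_f_invariant_under_common_scaling(self, rng):
        x = rng.normal(size=(8, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        labels = ["a"] * 4 + ["b"] * 4
        f1, _ = cd.permanova(d, labels, n_perm=9, seed=0)
        f2, _ = cd.permanova(2.5 * d, labels, n_perm=9, seed=0)
        assert f1 == pytest.approx(f2)

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova
        x = rng.normal(size=(9, 4))
        x[:4] += 1.5
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        labels = ["a"] * 4 + ["b"] * 5
        f, _ = cd.permanova(d, labels, n_perm=99, seed=0)
        res = sk_permanova(DistanceMatrix(d), grouping=labels, permutations=99)
        assert f == pytest.approx(float(res["test statistic"]), rel=1e-9)

    def test_degenerate_distance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cd.permanova(np.zeros((4, 4)), ["a", "a", "b", "b"], n_perm=9)

    def test_small_groups_rejected(self, rng):
        x = rng.normal(size=(3, 2))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        with pytest.raises(ValueError):
            cd.permanova(d, ["a", "a", "b"], n_perm=9)


class TestPCA:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = pd.DataFrame({"a": base, "b": 2 * base, "c": 3 * base})
        _, frac = cd.pca(m)
        assert frac[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 4)),
                         columns=[f"s{i}" for i in range(4)])
        coords, frac = cd.pca(m)
        x = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        cov = x.T @ x
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        # variance fractions are the eigenvalue fractions
        assert np.allclose(frac, w[:4] / w.sum(), atol=1e-12)
        # component scores are mutually orthogonal and sum to the eigenvalues
        g = coords.to_numpy().T @ coords.to_numpy()
        assert np.allclose(g, np.diag(np.diag(g)), atol=1e-8)
        assert np.allclose(np.diag(g)[:4], w, atol=1e-8)

    def test_variance_fractions_sum_to_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 6)))
        _, frac = cd.pca(m)
        assert frac.sum() == pytest.approx(1.0)


class TestNBDifferential:
    def test_all_zero_feature(self, rng):
        counts = small_counts(rng, n_feat=20)
        counts.iloc[0] = 0
        t = cd.nb_differential(counts, counts.columns[:4], counts.columns[4:])
        assert t.iloc[0].log2fc == 0.0
        assert t.iloc[0].p == 1.0

    def test_group_swap_flips_sign_keeps_p(self, rng):
        counts = small_counts(rng)
        a, b = list(counts.columns[:4]), list(counts.columns[4:])
        t1 = cd.nb_differential(counts, a, b)
        t2 = cd.nb_differential(counts, b, a)
        assert np.allclose(t1.log2fc, -t2.log2fc)
        assert np.allclose(t1.p, t2.p)

    def test_overlapping_groups_rejected(self, rng):
        counts = small_counts(rng)
        with pytest.raises(ValueError, match="overlap"):
            cd.nb_differential(counts, counts.columns[:4], counts.columns[3:])

    def test_padj_never_below_p(self, rng):
        counts = small_counts(rng)
        t = cd.nb_differential(counts, counts.columns[:4], counts.columns[4:])
        assert (t.padj >= t.p - 1e-12).all()
        assert (t.padj <= 1.0).all()

    def test_planted_effect_detected(self, bulk_cohort):
        _, peak_counts, _, _, truth = bulk_cohort
        groups = pd.Series(truth.subtype_of_sample)
        t = cd.nb_differential(peak_counts,
                               list(groups[groups == "LLI"].index),
                               list(groups[groups == "BL"].index))
        up = cd.filter_differential(t)["a_up"]
        assert set(truth.diff_peak_ids["LLI"]) <= set(up)


class TestFilterDifferential:
    def test_empty_table(self):
        t = pd.DataFrame(columns=["log2fc", "p", "padj"])
        out = cd.filter_differential(t)
        assert out == {"a_up": [], "b_up": []}

    def test_boundary_semantics(self):
        t = pd.DataFrame({"log2fc": [0.5, 0.51, -0.51, 0.51],
                          "padj": [0.01, 0.05, 0.05, 0.0500001]},
                         index=["at_lfc", "at_padj", "down", "over_padj"])
        out = cd.filter_differential(t, padj_max=0.05, min_abs_lfc=0.5)
        assert out["a_up"] == ["at_padj"]       # padj == 0.05 retained
        assert out["b_up"] == ["down"]
        # |log2fc| == 0.5 exactly and padj > 0.05 both excluded
        assert "at_lfc" not in out["a_up"] and "over_padj" not in out["a_up"]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
def test_bh_adjustment_is_monotone(pvals):
    """Sorting features by p sorts them by BH-adjusted p too."""
    from statsmodels.stats.multitest import multipletests
    padj = multipletests(pvals, method="fdr_bh")[1]
    order = np.argsort(pvals, kind="mergesort")
    assert (np.diff(np.asarray(padj)[order]) >= -1e-12).all()
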
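"""Enrichment scores, module scores, and the published classification rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cdscore import scoring as sc
from cdscore import synthgen as sg


def walk_es_oracle(values, gene_ids, members, alpha=0.25):
    """Brute-force rank-walk score for one sample (independent of scoring.py)."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], gene_ids[i]))
    n, k = len(values), len(members)
    w_ideal = sum((n - j) ** alpha for j in range(k))
    running, area = 0.0, 0.0
    for pos, i in enumerate(order):
        if gene_ids[i] in members:
            running += (n - pos) ** alpha / w_ideal
        else:
            running -= 1.0 / (n - k)
        area += running
    return area / n


class TestEnrichmentScore:
    def test_matches_oracle_on_all_placements_n8_k2(self):
        genes = [f"g{i}" for i in range(8)]
        values = np.arange(8, 0, -1, dtype=float)
        expr = pd.DataFrame({"s": values}, index=genes)
        for placement in itertools.combinations(range(8), 2):
            members = {genes[i] for i in placement}
            es = sc.ss_enrichment_score(expr, sorted(members)).iloc[0]
            assert es == pytest.approx(
                walk_es_oracle(values, genes, members), abs=1e-12)

    def test_top_placement_is_maximal(self):
        genes = [f"g{i}" for i in range(8)]
        expr = pd.DataFrame({"s": np.arange(8, 0, -1, dtype=float)}, index=genes)
        scores = {p: sc.ss_enrichment_score(expr, [genes[i] for i in p]).iloc[0]
                  for p in itertools.combinations(range(8), 2)}
        assert max(scores, key=scores.get) == (0, 1)

    def test_whole_gene_set_has_no_decrements(self):
        genes = [f"g{i}" for i in range(6)]
        expr = pd.DataFrame({"s": np.arange(6, 0, -1, dtype=float)}, index=genes)
        es = sc.ss_enrichment_score(expr, genes).iloc[0]
        # analytic maximum of the walk: mean of the normalized-weight cumsum
        w = (6 - np.arange(6)) ** 0.25
        w = w / w.sum()
        assert es == pytest.approx(np.cumsum(w).mean())

    def test_rank_improvement_never_decreases_score(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(6, 25))
            genes = [f"g{i:02d}" for i in range(n)]
            x = rng.normal(size=n)
            k = int(rng.integers(1, n - 1))
            members = set(rng.choice(genes, k, replace=False))
            expr = pd.DataFrame({"s": x}, index=genes)
            es0 = sc.ss_enrichment_score(expr, sorted(members)).iloc[0]
            order = [genes[i] for i in np.argsort(-x)]
            worst = max((g for g in members), key=order.index)
            better = [g for g in order[:order.index(worst)] if g not in members]
            if not better:
                continue
            swapped = (members - {worst}) | {better[-1]}
            es1 = sc.ss_enrichment_score(expr, sorted(swapped)).iloc[0]
            assert es1 >= es0 - 1e-12

    def test_gene_reordering_invariance(self, rng):
        genes = [f"g{i:02d}" for i in range(30)]
        expr = pd.DataFrame(rng.normal(size=(30, 3)), index=genes)
        shuffled = expr.sample(frac=1, random_state=7)
        s1 = sc.ss_enrichment_score(expr, genes[:5])
        s2 = sc.ss_enrichment_score(shuffled, genes[:5])
        assert np.allclose(s1, s2)

    def test_absent_gene_set_rejected(self):
        expr = pd.DataFrame({"s": [1.0]}, index=["g0"])
        with pytest.raises(ValueError, match="absent"):
            sc.ss_enrichment_score(expr, ["nope"])


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        cells = pd.DataFrame(np.ones((40, 6)),
                             index=[f"g{i}" for i in range(40)])
        ms = sc.module_score(cells, ["g0", "g1"], n_bins=4, seed=0)
        assert np.allclose(ms, 0.0)

    def test_uniform_elevation_recovered_exactly(self):
        # all genes share one bin; controls have the baseline mean exactly
        x = np.full((50, 8), 3.0)
        x[:2, 5] += 1.7
        cells = pd.DataFrame(x, index=[f"g{i}" for i in range(50)])
        ms = sc.module_score(cells, ["g0", "g1"], n_bins=1, seed=0)
        assert ms.iloc[5] == pytest.approx(1.7)
        assert np.allclose(ms.drop(ms.index[5]), 0.0)

    def test_same_seed_identical(self, rng):
        cells = pd.DataFrame(rng.normal(size=(60, 10)),
                             index=[f"g{i}" for i in range(60)])
        a = sc.module_score(cells, ["g0", "g5", "g9"], seed=3)
        b = sc.module_score(cells, ["g0", "g5", "g9"], seed=3)
        assert a.equals(b)

    def test_gene_reordering_invariance(self, rng):
        cells = pd.DataFrame(rng.normal(size=(60, 4)),
                             index=[f"g{i:02d}" for i in range(60)])
        a = sc.module_score(cells, ["g00", "g10"], seed=1)
        b = sc.module_score(cells.sample(frac=1, random_state=5), ["g00", "g10"],
                            seed=1)
        # binning is rank-based, so only control *sampling* may differ;
        # with the bin fully shared the score is control-mean dependent —
        # compare against tolerance from control spread
        assert np.abs(a - b).max() < 0.5


class TestBulkRules:
    def test_quartile_rule_n8(self):
        scores = pd.DataFrame({"delta": np.arange(8, 0, -1)},
                              index=[f"u{i}" for i in range(1, 9)])
        labels = sc.classify_bulk_quartile(scores)
        assert list(labels) == ["LLI-like", "LLI-like"] + ["intermediate"] * 4 + ["BL", "BL"]

    def test_quartile_rule_n4(self):
        scores = pd.DataFrame({"delta": [4.0, 3.0, 2.0, 1.0]}, index=list("abcd"))
        labels = sc.classify_bulk_quartile(scores)
        assert (labels == ["LLI-like", "intermediate", "intermediate", "BL"]).all()

    def test_quartile_all_ties_ordered_by_unit_id(self):
        scores = pd.DataFrame({"delta": [1.0] * 4}, index=list("dcba"))
        labels = sc.classify_bulk_quartile(scores)
        assert labels["a"] == "LLI-like" and labels["d"] == "BL"

    def test_quartile_needs_four(self):
        with pytest.raises(ValueError):
            sc.classify_bulk_quartile(pd.DataFrame({"delta": [1, 2, 3]}))

    def test_sign_rule(self):
        scores = pd.DataFrame({"delta": [0.3, -0.3, 0.0]}, index=list("abc"))
        labels = sc.classify_bulk_sign(scores)
        assert list(labels) == ["LLI-like", "BL-like", "intermediate"]

    def test_rules_agree_on_extremes_for_symmetric_deltas(self, rng):
        for _ in range(20):
            delta = np.sort(rng.normal(size=16))[::-1]
            delta = delta - np.median(delta)  # symmetric-ish about 0
            scores = pd.DataFrame({"delta": delta},
                                  index=[f"u{i:02d}" for i in range(16)])
            q = sc.classify_bulk_quartile(scores)
            s = sc.classify_bulk_sign(scores)
            assert (s[q == "LLI-like"] == "LLI-like").all()
            assert (s[q == "BL"] == "BL-like").all()


class TestCellQuantileRule:
    def test_exclusive_threshold_rule(self):
        scores = pd.DataFrame({
            "LLI": [9, 0, 9, 0, 1, 2, 0, 1],
            "BL": [0, 9, 9, 0, 1, 0, 2, 1],
            "MP": [0, 0, 0, 9, 1, 0, 0, 2],
        }, index=[f"c{i}" for i in range(8)], dtype=float)
        labels = sc.classify_cells_quantile(scores, q=0.75)
        assert labels["c0"] == "LLI-like"      # only LLI threshold met
        assert labels["c1"] == "BL-like"
        assert labels["c2"] == "unidentified"  # both LLI and BL met
        assert labels["c3"] == "MP"
        assert labels["c4"] == "unidentified"  # none met

    def test_all_identical_scores_unidentified(self):
        scores = pd.DataFrame(np.ones((6, 3)), columns=["LLI", "BL", "MP"])
        assert (sc.classify_cells_quantile(scores) == "unidentified").all()

    def test_too_few_cells_rejected(self):
        scores = pd.DataFrame(np.ones((3, 3)), columns=["LLI", "BL", "MP"])
        with pytest.raises(ValueError):
            sc.classify_cells_quantile(scores)


class TestMarkerAssignment:
    def test_fn1_only_cell_is_mycaf(self):
        markers = [g for gs in sg.CAF_MARKERS.values() for g in gs]
        x = pd.DataFrame(np.random.default_rng(0).random((len(markers), 6)),
                         index=markers)
        x.loc["FN1", x.columns[0]] = 50.0
        labels = sc.assign_marker_subtype(x, sg.CAF_MARKERS)
        assert labels.iloc[0] == "myCAF"

    def test_all_zero_cell_unassigned(self):
        markers = [g for gs in sg.CAF_MARKERS.values() for g in gs]
        x = pd.DataFrame(np.ones((len(markers), 3)), index=markers)
        x.iloc[:, 1] = 0.0
        labels = sc.assign_marker_subtype(x, sg.CAF_MARKERS)
        assert labels.iloc[1] == "unassigned"

    def test_synthetic_caf_mixture_recovery(self, cell_data):
        _, cells, truth = cell_data
        caf = truth.cell_labels[truth.cell_labels.isin(sg.CAF_TYPES)]
        pred = sc.assign_marker_subtype(np.log1p(cells[caf.index]),
                                        sg.CAF_MARKERS)
        assert (pred == caf).mean() >= 0.95

    def test_missing_marker_rejected(self):
        x = pd.DataFrame({"c": [1.0]}, index=["FN1"])
        with pytest.raises(ValueError, match="absent"):
            sc.assign_marker_subtype(x, sg.CAF_MARKERS)


class TestM1M2:
    def test_pure_m2_population_flagged_infinite_ratio(self, cell_data):
        _, cells, truth = cell_data
        m2 = truth.cell_labels[truth.cell_labels == "M2"].index
        per_cell, ratio = sc.m1_m2_scores(np.log1p(cells[m2]),
                                          sg.M1_MARKERS, sg.M2_MARKERS, seed=0)
        assert (per_cell["diff"] > 0).all()
        assert np.isnan(ratio.iloc[0])  # no M1-dominant cells: flagged

    def test_balanced_mixture_ratio_near_one(self, cell_data):
        _, cells, truth = cell_data
        mac = truth.cell_labels[truth.cell_labels.isin(["M1", "M2"])].index
        _, ratio = sc.m1_m2_scores(np.log1p(cells[mac]),
                                   sg.M1_MARKERS, sg.M2_MARKERS, seed=0)
        assert 0.7 < ratio.iloc[0] < 1.4

    def test_overlapping_sets_rejected(self, cell_data):
        _, cells, _ = cell_data
        with pytest.raises(ValueError, match="disjoint"):
            sc.m1_m2_scores(cells, ["CD163"], ["CD163"])

    def test_determinism(self, cell_data):
        _, cells, truth = cell_data
        mac = truth.cell_labels[truth.cell_labels.isin(["M1", "M2"])].index[:50]
        a, _ = sc.m1_m2_scores(np.log1p(cells[mac]), sg.M1_MARKERS,
                               sg.M2_MARKERS, seed=2)
        b, _ = sc.m1_m2_scores(np.log1p(cells[mac]), sg.M1_MARKERS,
                               sg.M2_MARKERS, seed=2)
        assert a.equals(b)
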
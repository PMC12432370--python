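import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from igesbs import (
    BoostingScore,
    CellWeightTable,
    EnrichmentResult,
    PerturbationCondition,
    ResponseModel,
    acat_combine,
    booster_enrichment_test,
    compute_boosting_score,
    compute_pges,
    direction_consistency,
    gsea_prerank,
    gsea_prerank_collection,
    rank_compounds,
    rank_genes,
    select_reference,
)
from igesbs.genesets import GeneSet, GeneSetCollection


def _condition(treated, control, genes=None, **kw):
    genes = genes or [f"g{i}" for i in range(len(treated))]
    defaults = dict(compound_id="cmpd", cell_line="CL1", cancer_type="T",
                    dose_um=10.0, time_h=24.0)
    defaults.update(kw)
    return PerturbationCondition(
        treated=pd.Series(treated, index=genes),
        control=pd.Series(control, index=genes),
        **defaults,
    )


def oracle_es(metric: np.ndarray, member: np.ndarray) -> float:
    """Independent running-sum walk over the full ranked list.

    Absolute-value ties between the positive and negative extremes (within
    1e-12) resolve to the positive deviation.
    """
    w = np.abs(metric)
    wsum = w[member].sum()
    k = member.sum()
    n = len(metric)
    running = 0.0
    hi, lo = 0.0, 0.0
    for i in range(n):
        if member[i]:
            running += w[i] / wsum if wsum > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        hi = max(hi, running)
        lo = min(lo, running)
    return hi if hi >= -lo - 1e-12 else lo


class TestRankGenes:
    def test_no_change_gives_lexicographic_order(self):
        cond = _condition([1.0, 1.0, 1.0], [1.0, 1.0, 1.0],
                          genes=["b", "c", "a"])
        ranked = rank_genes(cond)
        assert list(ranked.index) == ["a", "b", "c"]
        np.testing.assert_allclose(ranked, 0.0)

    def test_raised_gene_ranks_first(self):
        cond = _condition([1.0, 3.0, 1.0], [1.0, 1.0, 1.0],
                          genes=["a", "b", "c"])
        assert rank_genes(cond).index[0] == "b"

    def test_eight_gene_sort_oracle(self):
        rng = np.random.default_rng(0)
        treated = rng.normal(size=8)
        control = rng.normal(size=8)
        genes = [f"g{i}" for i in range(8)]
        ranked = rank_genes(_condition(treated, control, genes=genes))
        diffs = dict(zip(genes, treated - control))
        expected = sorted(genes, key=lambda g: (-diffs[g], g))
        assert list(ranked.index) == expected

    def test_missing_control_gene_raises(self):
        cond_kw = dict(compound_id="c", cell_line="CL", cancer_type="T",
                       dose_um=10.0, time_h=24.0)
        with pytest.raises(ValueError, match="missing in control"):
            rank_genes(PerturbationCondition(
                treated=pd.Series([1.0, 2.0], index=["a", "b"]),
                control=pd.Series([1.0], index=["a"]), **cond_kw))


class TestGseaPrerank:
    def test_es_matches_oracle_on_all_small_universes(self):
        """Exhaustive check: every universe size <= 12, every set size."""
        rng = np.random.default_rng(1)
        from igesbs.perturb import _es_for_positions

        for n in range(2, 13):
            metric = np.sort(rng.normal(size=n))[::-1]
            w = np.abs(metric)
            for k in range(1, n):
                for pos in itertools.combinations(range(n), k):
                    member = np.zeros(n, dtype=bool)
                    member[list(pos)] = True
                    expected = oracle_es(metric, member)
                    got = float(_es_for_positions(
                        np.array(pos), w, n)[0])
                    assert got == pytest.approx(expected, abs=1e-12), (n, pos)

    def test_top_ranked_members_give_extreme_enrichment(self):
        genes = [f"g{i:02d}" for i in range(30)]
        metric = pd.Series(np.linspace(3, -3, 30), index=genes)
        gs = GeneSet(name="top", genes=genes[:4])
        res = gsea_prerank(metric, gs, nperm=500, seed=0)
        assert res.es > 0
        assert res.p_perm <= 5 / 501

    def test_six_gene_toy_oracle(self):
        genes = list("abcdef")
        metric = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0, -3.0], index=genes)
        gs = GeneSet(name="S", genes=["a", "b"])
        member = np.array([True, True, False, False, False, False])
        res = gsea_prerank(metric, gs, nperm=200, seed=1)
        assert res.es == pytest.approx(oracle_es(metric.to_numpy(), member),
                                       abs=1e-12)

    def test_type_i_error_calibrated(self):
        """Random metric, random set: rejection rate at alpha=0.05 within
        the binomial 95% CI over 1000 simulations."""
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        gs = GeneSetCollection([GeneSet(name="S", genes=genes[:8])])
        n_sim, alpha = 1000, 0.05
        rejections = 0
        for i in range(n_sim):
            metric = pd.Series(rng.normal(size=40),
                               index=rng.permutation(genes))
            metric = metric.sort_values(ascending=False)
            frame = gsea_prerank_collection(metric, gs, nperm=200, seed=i)
            rejections += int(frame["p_perm"].iloc[0] < alpha)
        se = math.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rejections / n_sim - alpha) < 1.96 * se + 1e-9

    def test_sign_consistency_and_p_range(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(50)]
        metric = pd.Series(rng.normal(size=50), index=genes).sort_values(
            ascending=False)
        sets = GeneSetCollection([
            GeneSet(name=f"S{j}", genes=list(rng.choice(genes, 10, replace=False)))
            for j in range(5)
        ])
        frame = gsea_prerank_collection(metric, sets, nperm=300, seed=4)
        for _, row in frame.iterrows():
            assert np.sign(row["nes"]) == np.sign(row["es"])
            assert 1 / 301 <= row["p_perm"] <= 1
            assert row["fdr"] >= row["p_perm"] - 1e-12

    def test_degenerate_sets_raise(self):
        genes = ["a", "b", "c"]
        metric = pd.Series([1.0, 0.5, -1.0], index=genes)
        with pytest.raises(ValueError, match="no member genes"):
            gsea_prerank(metric, GeneSet(name="out", genes=["zz"]), nperm=100)
        with pytest.raises(ValueError, match="degenerate"):
            gsea_prerank(metric, GeneSet(name="all", genes=genes), nperm=100)
        with pytest.raises(ValueError, match="nperm"):
            gsea_prerank(metric, GeneSet(name="S", genes=["a"]), nperm=10)


class TestAcat:
    def test_all_half_is_half(self):
        assert acat_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("p", [0.001, 0.01, 0.2, 0.5, 0.77, 0.999])
    def test_cauchy_identity(self, p):
        """Equal inputs return the same p for any count."""
        for k in (1, 2, 5):
            assert acat_combine([p] * k) == pytest.approx(p, abs=1e-12)

    def test_closed_form_oracle(self):
        pvals = [0.01, 0.04, 0.5]
        t = sum(math.tan((0.5 - p) * math.pi) for p in pvals) / 3
        expected = 0.5 - math.atan(t) / math.pi
        assert acat_combine(pvals) == pytest.approx(expected, abs=1e-15)

    def test_weighted_combination(self):
        pvals = [0.02, 0.6]
        weights = [3.0, 1.0]
        t = (3 * math.tan((0.5 - 0.02) * math.pi)
             + 1 * math.tan((0.5 - 0.6) * math.pi)) / 4
        expected = 0.5 - math.atan(t) / math.pi
        assert acat_combine(pvals, weights) == pytest.approx(expected, abs=1e-15)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            acat_combine([])

    def test_extreme_values_clipped_not_nan(self):
        assert 0 < acat_combine([0.0, 0.5]) < 0.5
        assert 0.5 < acat_combine([1.0, 0.5]) < 1.0

    @given(st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_output_in_open_unit_interval(self, pvals):
        assert 0.0 < acat_combine(pvals) < 1.0

    @given(
        st.lists(st.floats(1e-4, 1 - 1e-4), min_size=2, max_size=6),
        st.integers(0, 5),
        st.floats(0.1, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_input(self, pvals, idx, factor):
        """Decreasing any input p never increases the combined p."""
        idx = idx % len(pvals)
        smaller = list(pvals)
        smaller[idx] = pvals[idx] * factor
        assert acat_combine(smaller) <= acat_combine(pvals) + 1e-12


class TestReferenceSelection:
    def test_exact_reference_preferred(self):
        assert select_reference([(1.0, 6.0), (10.0, 24.0), (100.0, 24.0)]) == 1

    def test_nearest_in_log_space(self):
        # log-distance of (3.16, 24) ~ 0.5; (100, 24) = 1
        assert select_reference([(3.16, 24.0), (100.0, 24.0)]) == 0

    def test_tie_broken_toward_lower_dose(self):
        # 1 uM and 100 uM are both 1 log10 unit from 10 uM
        assert select_reference([(100.0, 24.0), (1.0, 24.0)]) == 1


def _enr(nes, fdr, cell="CL1", dose=10.0, time=24.0, sig="S", compound="c"):
    cond = _condition([1.0, 0.0], [0.0, 0.0], genes=["a", "b"],
                      cell_line=cell, dose_um=dose, time_h=time,
                      compound_id=compound)
    return EnrichmentResult(signature_id=sig, es=np.sign(nes) or 1.0,
                            nes=nes, p_perm=fdr, fdr=fdr, condition=cond)


def _weights(rows):
    return CellWeightTable(pd.DataFrame(rows), normalize=False)


class TestPges:
    def test_single_condition_reduces_to_w_times_nes(self):
        w = _weights([{"cell_line": "CL1", "cancer_type": "T", "W": 1.0}])
        rec = compute_pges([_enr(2.0, 0.01)], w)
        assert rec.pges == pytest.approx(2.0)
        w8 = _weights([{"cell_line": "CL1", "cancer_type": "T", "W": 0.8}])
        rec = compute_pges([_enr(2.0, 0.01)], w8)
        assert rec.pges == pytest.approx(1.6)

    def test_multi_condition_hand_arithmetic(self):
        """Reference NES 2.0 with extra conditions 1.0 and 3.0 on one cell
        line (W=0.9): f = ((1-2)+(3-2))/2 = 0, pges = 0.9*(2+0) = 1.8."""
        w = _weights([{"cell_line": "CL1", "cancer_type": "T", "W": 0.9}])
        results = [
            _enr(2.0, 0.01, dose=10.0, time=24.0),
            _enr(1.0, 0.20, dose=1.0, time=24.0),
            _enr(3.0, 0.005, dose=100.0, time=24.0),
        ]
        rec = compute_pges(results, w)
        assert rec.awarding["CL1"][0] == pytest.approx(0.0)
        assert rec.pges == pytest.approx(0.9 * 2.0)
        assert rec.n_conditions == 3

    def test_asymmetric_awarding(self):
        w = _weights([{"cell_line": "CL1", "cancer_type": "T", "W": 1.0}])
        results = [
            _enr(2.0, 0.01, dose=10.0, time=24.0),
            _enr(3.0, 0.01, dose=100.0, time=24.0),
        ]
        rec = compute_pges(results, w)
        # f = (3-2)/1 = 1; pges = 1.0 * (2 + 1) = 3
        assert rec.pges == pytest.approx(3.0)

    def test_two_cell_lines_averaged(self):
        w = _weights([
            {"cell_line": "CL1", "cancer_type": "T", "W": 1.0},
            {"cell_line": "CL2", "cancer_type": "T", "W": 0.5},
        ])
        results = [_enr(2.0, 0.01, cell="CL1"), _enr(4.0, 0.01, cell="CL2")]
        rec = compute_pges(results, w)
        assert rec.pges == pytest.approx((1.0 * 2.0 + 0.5 * 4.0) / 2)

    def test_pges_linear_in_nes(self):
        w = _weights([{"cell_line": "CL1", "cancer_type": "T", "W": 0.7}])
        results = [
            _enr(2.0, 0.01, dose=10.0), _enr(1.0, 0.3, dose=1.0),
        ]
        base = compute_pges(results, w).pges
        scaled = compute_pges([
            _enr(6.0, 0.01, dose=10.0), _enr(3.0, 0.3, dose=1.0),
        ], w).pges
        assert scaled == pytest.approx(3 * base)

    def test_combined_p_is_acat_of_fdrs(self):
        w = _weights([{"cell_line": "CL1", "cancer_type": "T", "W": 1.0}])
        results = [_enr(2.0, 0.01, dose=10.0), _enr(1.0, 0.2, dose=1.0)]
        rec = compute_pges(results, w)
        assert rec.p_combined == pytest.approx(acat_combine([0.01, 0.2]))

    def test_missing_weight_falls_back(self):
        w = _weights([{"cell_line": "other", "cancer_type": "T", "W": 0.6}])
        rec = compute_pges([_enr(2.0, 0.01, cell="CL9")], w)
        assert rec.pges == pytest.approx(0.6 * 2.0)  # cancer-type mean


def _model(coes):
    return ResponseModel(signature_ids=list(coes),
                         coefficients=dict(coes), intercept=0.0,
                         l1_ratio=0.5, C=1.0)


def _pges_rec(sig, pges, p, compound="c", cancer="T"):
    from igesbs.perturb import PGESRecord

    return PGESRecord(signature_id=sig, cancer_type=cancer,
                      compound_id=compound, pges=pges, p_combined=p,
                      n_conditions=1)


class TestBoostingScore:
    def test_empty_n_gives_zero(self):
        model = _model({"S1": 0.5})
        bs = compute_boosting_score([_pges_rec("S1", 2.0, 0.5)], model)
        assert bs.bs == 0.0
        assert bs.n_significant == 0

    def test_single_term(self):
        model = _model({"S1": 0.5})
        bs = compute_boosting_score([_pges_rec("S1", 2.0, 0.001)], model)
        assert bs.bs == pytest.approx(1.0)

    def test_masked_dot_product_oracle(self):
        coes = {"S1": 0.5, "S2": -0.2, "S3": 0.0, "S4": 1.5, "S5": -1.0}
        pges = {"S1": 2.0, "S2": 3.0, "S3": 1.0, "S4": -0.5, "S5": 2.0}
        ps = {"S1": 0.01, "S2": 0.2, "S3": 0.001, "S4": 0.04, "S5": 0.9}
        model = _model(coes)
        recs = [_pges_rec(s, pges[s], ps[s]) for s in coes]
        expected = sum(coes[s] * pges[s] for s in coes if ps[s] < 0.05)
        bs = compute_boosting_score(recs, model)
        assert bs.bs == pytest.approx(expected, abs=1e-12)
        assert bs.n_significant == 3

    def test_sign_flip(self):
        coes = {"S1": 0.5, "S2": -0.2}
        model = _model(coes)
        recs = [_pges_rec("S1", 2.0, 0.01), _pges_rec("S2", 1.0, 0.02)]
        neg = [_pges_rec("S1", -2.0, 0.01), _pges_rec("S2", -1.0, 0.02)]
        assert compute_boosting_score(neg, model).bs == pytest.approx(
            -compute_boosting_score(recs, model).bs)

    def test_unknown_signature_skipped(self):
        model = _model({"S1": 0.5})
        bs = compute_boosting_score(
            [_pges_rec("S1", 2.0, 0.01), _pges_rec("SX", 5.0, 0.01)], model)
        assert bs.bs == pytest.approx(1.0)


class TestRankCompounds:
    def test_single_compound(self):
        frame = rank_compounds([BoostingScore("a", "T", 1.0, 1)])
        assert frame.loc[0, "rank"] == 1
        assert frame.loc[0, "percentile"] == 1.0

    def test_descending_order_with_ties(self):
        scores = [BoostingScore(c, "T", b, 0)
                  for c, b in [("b", 1.0), ("a", 1.0), ("c", 3.0)]]
        frame = rank_compounds(scores)
        assert list(frame["compound"]) == ["c", "a", "b"]
        assert list(frame["rank"]) == [1, 2, 3]

    def test_rank_20_of_1768_is_top_1_2_percent(self):
        rng = np.random.default_rng(7)
        scores = [BoostingScore(f"c{i:04d}", "T", float(v), 0)
                  for i, v in enumerate(np.sort(rng.normal(size=1768))[::-1])]
        frame = rank_compounds(scores)
        pct = frame.loc[frame["rank"] == 20, "percentile"].iloc[0]
        assert pct == pytest.approx(20 / 1768)
        assert pct < 0.012


class TestBoosterEnrichment:
    def test_identical_groups_not_enriched(self):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        labels = pd.Series([True, True, False, False], index=list("abcd"))
        res = booster_enrichment_test(scores, labels)
        assert res.effect_size == 0.0
        assert not res.enriched

    def test_enrichment_rule_thresholds(self):
        idx = [f"c{i}" for i in range(20)]
        scores = pd.Series(np.r_[np.full(5, 2.05), np.full(15, 1.0)], index=idx)
        labels = pd.Series([True] * 5 + [False] * 15, index=idx)
        res = booster_enrichment_test(scores, labels)
        assert res.effect_size == pytest.approx(1.05)
        assert res.enriched  # effect > 1 and p < 0.05
        small = scores.copy()
        small[:5] = 1.9  # effect 0.9 < 1: significant but not "enriched"
        res2 = booster_enrichment_test(small, labels)
        assert not res2.enriched

    def test_exact_p_by_enumeration_4_vs_5(self):
        """One-sided rank-sum p equals full enumeration of rank assignments."""
        rng = np.random.default_rng(8)
        known = rng.normal(1.0, 1.0, size=4)
        other = rng.normal(0.0, 1.0, size=5)
        pooled = np.concatenate([known, other])
        idx = [f"c{i}" for i in range(9)]
        scores = pd.Series(pooled, index=idx)
        labels = pd.Series([True] * 4 + [False] * 5, index=idx)
        res = booster_enrichment_test(scores, labels)

        obs_u = sum((k > o) + 0.5 * (k == o) for k in known for o in other)
        count = 0
        total = 0
        for combo in itertools.combinations(range(9), 4):
            sel = pooled[list(combo)]
            rest = np.delete(pooled, list(combo))
            u = sum((k > o) + 0.5 * (k == o) for k in sel for o in rest)
            count += u >= obs_u
            total += 1
        assert res.p == pytest.approx(count / total, abs=1e-10)

    def test_empty_group_raises(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        labels = pd.Series([True, True], index=["a", "b"])
        with pytest.raises(ValueError):
            booster_enrichment_test(scores, labels)


class TestDirectionConsistency:
    def _calls(self, nes, padj):
        sigs = [f"S{i}" for i in range(len(nes))]
        return pd.DataFrame({"nes": nes, "padj": padj}, index=sigs)

    def test_all_match(self):
        a = self._calls([1, -2, 3], [0.01, 0.05, 0.02])
        b = self._calls([2, -1, 1], [0.5, 0.5, 0.5])
        assert direction_consistency(a, b) == 1.0

    def test_all_oppose(self):
        a = self._calls([1, -2], [0.01, 0.05])
        b = self._calls([-1, 2], [0.5, 0.5])
        assert direction_consistency(a, b) == 0.0

    def test_counting_oracle_11_of_13(self):
        nes_a = [1.0] * 13 + [1.0, -1.0]
        padj_a = [0.01] * 13 + [0.5, 0.9]
        nes_b = [1.0] * 11 + [-1.0] * 2 + [99.0, 99.0]
        a = self._calls(nes_a, padj_a)
        b = self._calls(nes_b, [0.5] * 15)
        assert direction_consistency(a, b) == pytest.approx(11 / 13)

    def test_nothing_regulated_returns_nan(self):
        a = self._calls([1.0, 2.0], [0.5, 0.9])
        b = self._calls([1.0, 2.0], [0.5, 0.9])
        assert math.isnan(direction_consistency(a, b))
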
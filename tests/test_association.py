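"""SNP-climate scans, the gene-level binomial outlier test, and the
top-candidate combination rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from treesel.association import (
    gene_outlier_test, population_allele_frequencies, select_top_candidates,
    spearman_scan,
)
from treesel.popgen import MISSING

from .conftest import make_dataset
from . import oracles


def climate_frame(values: dict[tuple[str, str], list[float]], pops) -> pd.DataFrame:
    cm = pd.DataFrame(values, index=pops)
    cm.columns = pd.MultiIndex.from_tuples(cm.columns,
                                           names=["variable", "period"])
    return cm


class TestAlleleFrequencies:
    def test_copy_counting_with_missing(self):
        # one pop of 3 diploids: 0/1, 1/1, ./. -> 3 of 4 copies
        G = np.array([[1, 2, MISSING]], dtype=np.int8)
        ds = make_dataset(G, ["p1"] * 3)
        freqs, counts = population_allele_frequencies(ds)
        assert freqs.iloc[0, 0] == pytest.approx(0.75)
        assert counts.iloc[0, 0] == 4

    def test_reference_homozygotes_give_zero(self):
        ds = make_dataset(np.zeros((2, 4), dtype=np.int8), ["p1", "p1", "p2", "p2"])
        freqs, _ = population_allele_frequencies(ds)
        assert (freqs.values == 0).all()

    def test_fully_missing_population_is_nan(self):
        G = np.array([[1, MISSING, MISSING]], dtype=np.int8)
        ds = make_dataset(G, ["p1", "p2", "p2"])
        freqs, _ = population_allele_frequencies(ds)
        assert np.isnan(freqs.loc[:, "p2"].iloc[0])
        assert freqs.loc[:, "p1"].iloc[0] == 0.5

    def test_frequencies_bounded(self, rng):
        G = rng.integers(0, 3, size=(50, 24)).astype(np.int8)
        G[rng.random(G.shape) < 0.3] = MISSING
        ds = make_dataset(G, [f"p{k % 6}" for k in range(24)])
        freqs, _ = population_allele_frequencies(ds)
        vals = freqs.values[np.isfinite(freqs.values)]
        assert ((vals >= 0) & (vals <= 1)).all()


class TestSpearmanScan:
    def _scan_one(self, freq_row, climate_col, **kw):
        pops = [f"p{k}" for k in range(len(freq_row))]
        freqs = pd.DataFrame([freq_row], index=["snp1"], columns=pops)
        cm = climate_frame({("var", "PRE"): climate_col}, pops)
        return spearman_scan(freqs, cm, **kw).iloc[0]

    def test_monotone_freq_is_perfect_and_significant(self):
        x = np.linspace(0.1, 0.9, 12)
        row = self._scan_one(list(x), list(np.arange(12.0)))
        assert row.rho == pytest.approx(1.0)
        assert row.p_value == 0.0 and row.significant

    def test_constant_frequency_untested(self):
        row = self._scan_one([0.4] * 12, list(np.arange(12.0)))
        assert not row.tested and not row.significant

    def test_too_few_populations_untested(self):
        row = self._scan_one([0.1, 0.5, 0.9], [1.0, 2.0, 3.0])
        assert not row.tested

    def test_tied_values_match_midrank_pearson_and_t_cdf(self):
        freq = [0.1, 0.2, 0.2, 0.35, 0.5, 0.45, 0.7, 0.9]
        clim = [3.0, 1.0, 4.0, 2.0, 6.0, 5.0, 8.0, 7.0]
        row = self._scan_one(freq, clim)
        rf, rc = stats.rankdata(freq), stats.rankdata(clim)
        rho = np.corrcoef(rf, rc)[0, 1]
        t = rho * np.sqrt((8 - 2) / (1 - rho**2))
        assert row.rho == pytest.approx(rho, abs=1e-12)
        assert row.p_value == pytest.approx(2 * stats.t.sf(abs(t), df=6), abs=1e-12)

    def test_missing_cells_dropped_pairwise(self):
        freq = [np.nan, 0.2, 0.3, 0.4, 0.55, 0.6, 0.7, 0.9]
        clim = list(np.arange(8.0))
        row = self._scan_one(freq, clim)
        assert row.n_pops == 7
        assert row.rho == pytest.approx(1.0)

    def test_invariant_under_monotone_climate_transform(self, rng):
        freq = list(rng.uniform(0.05, 0.95, 12))
        clim = rng.normal(size=12)
        a = self._scan_one(freq, list(clim))
        b = self._scan_one(freq, list(np.exp(3 * clim)))
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_size_close_to_alpha_under_null(self, rng):
        """The t approximation at 12 populations is close to nominal but
        slightly liberal; the realized size must stay within a factor of
        two of alpha."""
        n = 4000
        freqs = pd.DataFrame(rng.uniform(0.05, 0.95, size=(n, 12)),
                             index=[f"s{i}" for i in range(n)],
                             columns=[f"p{k}" for k in range(12)])
        cm = climate_frame({("var", "PRE"): rng.normal(size=12)},
                           [f"p{k}" for k in range(12)])
        out = spearman_scan(freqs, cm, alpha=0.01)
        rate = out.significant.mean()
        assert 0.005 < rate < 0.02


class TestGeneOutlierTest:
    def _assoc(self, spec):
        """spec: {gene: (n, a)} -> a minimal association frame."""
        rows = []
        snp = 0
        for gene, (n, a) in spec.items():
            for k in range(n):
                rows.append({"snp_id": f"s{snp}", "variable": "v",
                             "period": "PRE", "rho": 0.5, "p_value": 0.5,
                             "n_pops": 12, "tested": True,
                             "significant": k < a})
                snp += 1
        assoc = pd.DataFrame(rows)
        gene_map = {}
        snp = 0
        for gene, (n, _) in spec.items():
            for _ in range(n):
                gene_map[f"s{snp}"] = gene
                snp += 1
        return assoc, pd.Series(gene_map)

    def test_pooled_rate_excludes_zero_outlier_genes(self):
        assoc, gm = self._assoc({"g1": (10, 4), "g2": (20, 1), "g3": (5, 0)})
        out = gene_outlier_test(assoc, gm).set_index("gene_id")
        P = 5 / 30
        assert out["expected_rate"].dropna().unique() == pytest.approx([P])
        for gene, n in (("g1", 10), ("g2", 20), ("g3", 5)):
            q = oracles.binom_quantile_exact(0.9999, n, P)
            assert out.loc[gene, "q_threshold"] == q
            assert out.loc[gene, "flagged"] == (out.loc[gene, "a_significant"] > q)
        assert not out.loc["g3", "flagged"]

    def test_mean_ratio_alternative(self):
        assoc, gm = self._assoc({"g1": (10, 4), "g2": (20, 1)})
        out = gene_outlier_test(assoc, gm, pool_rule="mean-ratio")
        assert out["expected_rate"].iloc[0] == pytest.approx((0.4 + 0.05) / 2)

    def test_small_rate_limit_flags_any_hit(self):
        spec = {"g1": (5, 1)}
        spec.update({f"null{k}": (200, 0) for k in range(5)})
        assoc, gm = self._assoc(spec)
        out = gene_outlier_test(assoc, gm).set_index("gene_id")
        # P = 1/5 here (zero-outlier genes excluded); construct the true
        # sparse limit with many genes sharing single hits instead
        spec2 = {f"g{k}": (400, 1) for k in range(5)}
        assoc2, gm2 = self._assoc(spec2)
        out2 = gene_outlier_test(assoc2, gm2).set_index("gene_id")
        assert out2["expected_rate"].iloc[0] == pytest.approx(5 / 2000)
        q = oracles.binom_quantile_exact(0.9999, 400, 5 / 2000)
        assert (out2["q_threshold"] == q).all()

    def test_no_hits_is_inapplicable(self):
        assoc, gm = self._assoc({"g1": (10, 0), "g2": (5, 0)})
        out = gene_outlier_test(assoc, gm)
        assert (out["status"] == "inapplicable").all()
        assert not out["flagged"].any()


class TestSelectTopCandidates:
    def _flags(self, rows):
        return pd.DataFrame(rows, columns=[
            "gene_id", "variable", "period", "n_snps", "a_significant",
            "expected_rate", "q_threshold", "flagged", "status"])

    def _calls(self, rows):
        return pd.DataFrame(rows, columns=[
            "snp_id", "variable", "period", "method", "score", "significant"])

    def test_confirmed_gene_retained(self):
        flags = self._flags([("gA", "precip_driest", "PRE", 6, 5, 0.05, 2, True, "ok")])
        calls = self._calls([
            (f"s{k}", "precip_driest", "PRE", m, 40.0, True)
            for k in range(4) for m in ("baypass", "bayescenv")])
        gm = pd.Series({f"s{k}": "gA" for k in range(6)})
        out = select_top_candidates(flags, calls, gm)
        row = out.iloc[0]
        assert row.retained
        assert row.n_snps_baypass == 4 and row.n_snps_bayescenv == 4
        assert row.gene_level_count == 5

    def test_single_external_snp_not_retained(self):
        flags = self._flags([("gA", "v", "PRE", 6, 5, 0.05, 2, True, "ok")])
        calls = self._calls([("s0", "v", "PRE", "baypass", 40.0, True)])
        out = select_top_candidates(flags, calls, pd.Series({"s0": "gA"}))
        assert not out.iloc[0].retained

    def test_variable_mismatch_not_retained(self):
        flags = self._flags([("gA", "v1", "PRE", 6, 5, 0.05, 2, True, "ok")])
        calls = self._calls([
            ("s0", "v2", "PRE", "baypass", 40.0, True),
            ("s1", "v2", "PRE", "bayescenv", 0.01, True)])
        gm = pd.Series({"s0": "gA", "s1": "gA"})
        out = select_top_candidates(flags, calls, gm)
        assert not out.iloc[0].retained

    def test_methods_pool_with_or_semantics(self):
        flags = self._flags([("gA", "v", "PRE", 6, 5, 0.05, 2, True, "ok")])
        calls = self._calls([
            ("s0", "v", "PRE", "baypass", 40.0, True),
            ("s1", "v", "PRE", "bayescenv", 0.01, True)])
        gm = pd.Series({"s0": "gA", "s1": "gA"})
        out = select_top_candidates(flags, calls, gm)
        assert out.iloc[0].retained   # 2 distinct SNPs across methods

    def test_period_matching_toggle(self):
        flags = self._flags([("gA", "v", "PRE", 6, 5, 0.05, 2, True, "ok")])
        calls = self._calls([
            ("s0", "v", "LGM", "baypass", 40.0, True),
            ("s1", "v", "LGM", "baypass", 40.0, True)])
        gm = pd.Series({"s0": "gA", "s1": "gA"})
        assert not select_top_candidates(flags, calls, gm).iloc[0].retained
        assert select_top_candidates(flags, calls, gm,
                                     match_period=False).iloc[0].retained

    def test_output_subset_of_flagged(self):
        flags = self._flags([
            ("gA", "v", "PRE", 6, 5, 0.05, 2, True, "ok"),
            ("gB", "v", "PRE", 6, 1, 0.05, 2, False, "ok")])
        out = select_top_candidates(flags, None, pd.Series(dtype=object))
        assert list(out["gene_id"]) == ["gA"]
        assert (out["status"] == "unconfirmed").all()
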
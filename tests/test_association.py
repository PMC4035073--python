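import numpy as np
import pandas as pd
import pytest
from scipy import stats

import introscan as sc
from introscan.association import _gls_f_stats, _whiten
from introscan.data import HOM_ALT, HOM_REF

from conftest import geno_from_rows


def dosage_frame(geno, cultivars):
    d = geno.dosage(cultivars)
    col_means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = col_means[idx[1]]
    return d


class TestKinship:
    def test_identical_inbreds_share_diagonal_entry(self, rng):
        row = "".join(rng.choice(list("RA"), size=30))
        other = "".join(rng.choice(list("RA"), size=30))
        g = geno_from_rows([row, row, other])
        k = sc.kinship(g)
        assert k.matrix[0, 1] == pytest.approx(k.matrix[0, 0])
        assert k.matrix[0, 1] == pytest.approx(k.matrix[1, 1])

    def test_single_marker_outer_product(self):
        g = geno_from_rows(["A", "R", "A", "R"])  # p = 0.5
        k = sc.kinship(g)
        z = np.array([1.0, -1.0, 1.0, -1.0])  # centered dosages
        expected = np.outer(z, z) / (2 * 0.5 * 0.5)
        assert np.allclose(k.matrix, expected)

    def test_matches_textbook_formula_oracle(self, default_bundle, hy_cultivars):
        g = default_bundle.geno
        k = sc.kinship(g, hy_cultivars)
        d = dosage_frame(g, hy_cultivars)
        p = d.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        z = d[:, poly] - 2 * p[poly]
        expected = z @ z.T / np.sum(2 * p[poly] * (1 - p[poly]))
        assert np.allclose(k.matrix, expected, atol=1e-10)
        # PSD within tolerance
        assert np.linalg.eigvalsh(k.matrix).min() > -1e-8


class TestMLMScan:
    def test_identity_kinship_reduces_to_ols(self, rng):
        n, m = 60, 50
        g_rows = [
            "".join(rng.choice(list("RA"), size=m, p=[0.6, 0.4])) for _ in range(n)
        ]
        g = geno_from_rows(g_rows)
        y = pd.Series(rng.standard_normal(n), index=g.cultivar_ids)
        k = sc.KinshipMatrix(g.cultivar_ids, np.eye(n))
        res = sc.mlm_scan(y, g, k, maf_min=0.05)
        d = dosage_frame(g, g.cultivar_ids)
        cols = g.marker_cols(res["marker_id"])
        for out_row, j in zip(res.itertuples(index=False), cols):
            lr = stats.linregress(d[:, j], y.to_numpy())
            assert out_row.p_value == pytest.approx(lr.pvalue, rel=1e-6)
            assert out_row.beta == pytest.approx(lr.slope, rel=1e-6)

    def test_constant_phenotype_yields_no_signal(self, default_bundle, hy_cultivars):
        g = default_bundle.geno
        k = sc.kinship(g, hy_cultivars)
        y = pd.Series(3.14, index=hy_cultivars)
        res = sc.mlm_scan(y, g, k)
        assert np.allclose(res["beta"], 0.0)
        assert (res["p_value"] >= 0.999).all()

    def test_planted_signal_attains_minimum_p(self, default_bundle, hy_cultivars, rng):
        g = default_bundle.geno
        k = sc.kinship(g, hy_cultivars)
        target = sc.filter_panel_informative(g)[40]
        j = g.marker_cols([target])[0]
        d = dosage_frame(g, hy_cultivars)[:, j]
        y = pd.Series(2.0 * d + 0.1 * rng.standard_normal(len(d)), index=hy_cultivars)
        res = sc.mlm_scan(y, g, k)
        assert res.loc[res["p_value"].idxmin(), "marker_id"] == target

    def test_nominal_p_invariant_under_affine_phenotype(self, default_bundle, hy_cultivars, rng):
        g = default_bundle.geno
        k = sc.kinship(g, hy_cultivars)
        y = pd.Series(rng.standard_normal(len(hy_cultivars)), index=hy_cultivars)
        res1 = sc.mlm_scan(y, g, k)
        res2 = sc.mlm_scan(5.0 * y + 7.0, g, k)
        # agreement limited by the REML scalar-search tolerance on lambda
        assert np.allclose(res1["p_value"], res2["p_value"], rtol=1e-5)

    def test_lambda_to_zero_converges_to_ols(self, rng):
        # continuity of the whitened GLS in the variance ratio
        n, m = 40, 10
        k = np.cov(rng.standard_normal((n, n + 5)))
        s, u = np.linalg.eigh(k)
        s = np.clip(s, 0, None)
        x = rng.choice([0.0, 2.0], size=(n, m))
        y = rng.standard_normal((n, 1))
        ones = np.ones((n, 1))
        f_prev = None
        for lam in [1.0, 1e-2, 1e-4, 1e-8]:
            w = _whiten(lam, s, u.T)
            _, f, _ = _gls_f_stats(w @ y, w @ x, w @ ones)
            f_prev = f
        _, f_ols, _ = _gls_f_stats(y, x, ones)
        assert np.allclose(f_prev, f_ols, rtol=1e-6)


class TestPermutation:
    def test_add_one_floor_and_determinism(self, default_bundle, hy_cultivars):
        g = default_bundle.geno
        k = sc.kinship(g, hy_cultivars)
        target = sc.filter_panel_informative(g)[10]
        j = g.marker_cols([target])[0]
        d = dosage_frame(g, hy_cultivars)[:, j]
        y = pd.Series(d, index=hy_cultivars)  # deterministic perfect signal
        res = sc.permutation_p(y, g, k, n_perm=999, seed=3)
        assert res["perm_p"].min() == pytest.approx(1 / 1000)
        assert (res["perm_p"] >= 1 / 1000).all()
        res2 = sc.permutation_p(y, g, k, n_perm=999, seed=3)
        assert np.array_equal(res["perm_p"], res2["perm_p"])

    def test_perm_p_monotone_in_f(self, default_bundle, hy_cultivars, rng):
        g = default_bundle.geno
        k = sc.kinship(g, hy_cultivars)
        y = pd.Series(rng.standard_normal(len(hy_cultivars)), index=hy_cultivars)
        res = sc.permutation_p(y, g, k, n_perm=200, seed=1)
        by_f = res.sort_values("f_stat")
        assert (np.diff(by_f["perm_p"]) <= 0).all()

    def test_small_n_perm_warns(self, default_bundle, hy_cultivars, rng):
        g = default_bundle.geno
        k = sc.kinship(g, hy_cultivars)
        y = pd.Series(rng.standard_normal(len(hy_cultivars)), index=hy_cultivars)
        with pytest.warns(UserWarning, match="coarse"):
            sc.permutation_p(y, g, k, n_perm=50, seed=1)


class TestIntersectAndAnnotate:
    def make_results(self):
        return pd.DataFrame(
            {
                "marker_id": ["a", "b", "c", "d"],
                "perm_p": [0.005, 0.01, 0.005, 0.2],
            }
        )

    def test_strict_alpha_and_neutral_exclusion(self):
        skew = pd.Series(
            {"a": "INDICA_SKEWED", "b": "INDICA_SKEWED", "c": "NEUTRAL", "d": "JAPONICA_SKEWED"}
        )
        out = sc.intersect_with_skew(self.make_results(), skew, alpha=0.01)
        # b excluded (perm_p == alpha exactly), c excluded (neutral), d not significant
        assert list(out["marker_id"]) == ["a"]

    def test_matches_brute_force_set_intersection(self, default_bundle, hy_cultivars):
        b = default_bundle
        result = sc.run_pipeline(
            b.geno, b.panel, b.phenotypes, features=b.features, n_perm=200, seed=0
        )
        for trait, res in result.association.items():
            skew = result.profile.marker_skew()
            expected = {
                r.marker_id
                for r in res.itertuples(index=False)
                if r.perm_p < 0.01 and skew.get(r.marker_id, "NEUTRAL") != "NEUTRAL"
            }
            assert set(result.hits[trait]["marker_id"]) == expected

    def test_candidate_window_boundaries(self):
        feats = sc.FeatureCatalog(
            pd.DataFrame(
                {
                    "feature_id": ["at_snp", "at_edge", "outside", "qtl_overlap"],
                    "feature_kind": ["GENE", "GENE", "GENE", "QTL"],
                    "chromosome": ["chr1"] * 4,
                    "start_bp": [5_000_000, 7_000_000, 7_000_001, 4_000_000],
                    "end_bp": [5_000_010, 7_100_000, 7_100_000, 6_000_000],
                    "trait_category": ["yield"] * 4,
                }
            )
        )
        hits = pd.DataFrame(
            {"marker_id": ["snp1"], "chromosome": ["chr1"], "position_bp": [5_000_000]}
        )
        out = sc.candidate_lookup(hits, feats, trait_category="yield")
        # window [3e6, 7e6]: feature starting exactly at pos+2 Mb included
        assert set(out["feature_id"]) == {"at_snp", "at_edge"}
        assert out.loc[out.feature_id == "at_snp", "distance_bp"].iloc[0] == 0
        # genes found -> QTL not reported
        assert "qtl_overlap" not in set(out["feature_id"])

    def test_qtl_fallback_when_no_gene_overlaps(self):
        feats = sc.FeatureCatalog(
            pd.DataFrame(
                {
                    "feature_id": ["far_gene", "near_qtl"],
                    "feature_kind": ["GENE", "QTL"],
                    "chromosome": ["chr1", "chr1"],
                    "start_bp": [20_000_000, 4_500_000],
                    "end_bp": [20_010_000, 5_500_000],
                    "trait_category": ["yield", "yield"],
                }
            )
        )
        hits = pd.DataFrame(
            {"marker_id": ["snp1"], "chromosome": ["chr1"], "position_bp": [5_000_000]}
        )
        out = sc.candidate_lookup(hits, feats, trait_category="yield")
        assert list(out["feature_id"]) == ["near_qtl"]

    def test_unknown_category_warns_and_searches_all(self):
        feats = sc.FeatureCatalog(
            pd.DataFrame(
                {
                    "feature_id": ["g"],
                    "feature_kind": ["GENE"],
                    "chromosome": ["chr1"],
                    "start_bp": [1_000_000],
                    "end_bp": [1_100_000],
                    "trait_category": ["yield"],
                }
            )
        )
        hits = pd.DataFrame(
            {"marker_id": ["snp1"], "chromosome": ["chr1"], "position_bp": [1_050_000]}
        )
        with pytest.warns(UserWarning, match="category"):
            out = sc.candidate_lookup(hits, feats, trait_category="no_such_trait")
        assert list(out["feature_id"]) == ["g"]

    def test_matches_interval_scan_oracle(self, rng):
        n_feat = 60
        feats = sc.FeatureCatalog(
            pd.DataFrame(
                {
                    "feature_id": [f"f{i}" for i in range(n_feat)],
                    "feature_kind": rng.choice(["GENE", "QTL"], n_feat),
                    "chromosome": rng.choice(["chr1", "chr2"], n_feat),
                    "start_bp": (s := rng.integers(1, 25_000_000, n_feat)),
                    "end_bp": s + rng.integers(0, 3_000_000, n_feat),
                    "trait_category": rng.choice(["a", "b"], n_feat),
                }
            )
        )
        hits = pd.DataFrame(
            {
                "marker_id": [f"s{i}" for i in range(10)],
                "chromosome": rng.choice(["chr1", "chr2"], 10),
                "position_bp": rng.integers(1, 25_000_000, 10),
            }
        )
        out = sc.candidate_lookup(hits, feats, trait_category="a", window_bp=4_000_000)
        ft = feats.table
        for hit in hits.itertuples(index=False):
            lo, hi = max(1, hit.position_bp - 2_000_000), hit.position_bp + 2_000_000
            inside = [
                f
                for f in ft.itertuples(index=False)
                if f.chromosome == hit.chromosome
                and f.trait_category == "a"
                and f.start_bp <= hi
                and f.end_bp >= lo
            ]
            genes = [f.feature_id for f in inside if f.feature_kind == "GENE"]
            expect = set(genes) if genes else {f.feature_id for f in inside}
            got = set(out.loc[out.marker_id == hit.marker_id, "feature_id"])
            assert got == expect


class TestAlleleEffects:
    def test_two_group_means_and_sds(self):
        g = geno_from_rows(["A", "A", "A", "R", "R", "R"])
        y = pd.Series([1, 2, 3, 4, 5, 6], index=g.cultivar_ids, dtype=float)
        hits = pd.DataFrame({"marker_id": ["m0"], "indica_allele": ["G"]})
        out = sc.allele_effect_table(hits, y, g).iloc[0]
        assert out.indica_mean == pytest.approx(2.0) and out.indica_sd == pytest.approx(1.0)
        assert out.japonica_mean == pytest.approx(5.0) and out.japonica_sd == pytest.approx(1.0)

    def test_single_class_leaves_other_empty(self):
        g = geno_from_rows(["A", "A", "A"])
        y = pd.Series([1.0, 2.0, 3.0], index=g.cultivar_ids)
        hits = pd.DataFrame({"marker_id": ["m0"], "indica_allele": ["G"]})
        out = sc.allele_effect_table(hits, y, g).iloc[0]
        assert out.n_japonica == 0 and np.isnan(out.japonica_mean)
        assert out.n_indica == 3

    def test_additive_qtl_group_gap_matches_twice_beta(self, default_bundle, hy_cultivars):
        b = default_bundle
        trait = b.truth.qtls.iloc[0]["trait"]
        mid = b.truth.qtls.iloc[0]["marker_id"]
        y = b.phenotypes.trait(trait)
        k = sc.kinship(b.geno, hy_cultivars)
        res = sc.mlm_scan(y, b.geno, k, marker_ids=[mid])
        beta = res["beta"].iloc[0]
        hits = pd.DataFrame({"marker_id": [mid]})
        eff = sc.allele_effect_table(hits, y.loc[hy_cultivars], b.geno).iloc[0]
        gap = eff.indica_mean - eff.japonica_mean
        assert gap == pytest.approx(2 * beta, rel=0.25)
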
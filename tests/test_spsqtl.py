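import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from protegoqtl.spsqtl import (call_spsqtls, concordance_effects, lrt_nested,
                               overlap_filter)


class TestLrtNested:
    def test_f_matches_two_rss_brute_force(self):
        rng = np.random.default_rng(0)
        n = 40
        r = rng.normal(size=n)
        g = (rng.random(n) < 0.3).astype(float)
        cov = pd.DataFrame({"age": rng.normal(60, 8, n)})
        p = 1.0 + 0.8 * r + 0.5 * g + rng.normal(0, 0.4, n)
        res = lrt_nested(p, r, g, covariates=cov)

        X_full = np.column_stack([np.ones(n), g, r, cov["age"]])
        X_red = np.column_stack([np.ones(n), r, cov["age"]])
        rss_full = sm.OLS(p, X_full).fit().ssr
        rss_red = sm.OLS(p, X_red).fit().ssr
        df_full = n - X_full.shape[1]
        f_oracle = (rss_red - rss_full) / (rss_full / df_full)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(sps.f.sf(f_oracle, 1, df_full), abs=1e-12)

    def test_f_equals_squared_t_of_genotype_without_covariates(self):
        rng = np.random.default_rng(1)
        n = 30
        r = rng.normal(size=n)
        g = (rng.random(n) < 0.4).astype(float)
        p = 0.3 * r + 0.7 * g + rng.normal(0, 0.5, n)
        res = lrt_nested(p, r, g)
        ref = sm.OLS(p, np.column_stack([np.ones(n), g, r])).fit()
        assert res.statistic == pytest.approx(ref.tvalues[1] ** 2, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalues[1], abs=1e-9)
        assert res.beta0 == pytest.approx(ref.params[1], abs=1e-10)
        assert res.beta1 == pytest.approx(ref.params[2], abs=1e-10)

    def test_null_p_values_uniform_over_seeds(self):
        # p depends on r only; genotype is noise -> p-values ~ U(0,1)
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 25
            r = rng.normal(size=n)
            g = np.zeros(n)
            g[rng.choice(n, size=8, replace=False)] = 1.0
            p = 2.0 + 1.2 * r + rng.normal(0, 0.5, n)
            pvals.append(lrt_nested(p, r, g).p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_large_effect_tiny_p(self):
        rng = np.random.default_rng(2)
        n = 20
        r = rng.normal(size=n)
        g = np.array([1.0] * 6 + [0.0] * 14)
        p = r + 2.0 * g + rng.normal(0, 0.05, n)
        res = lrt_nested(p, r, g)
        assert res.p_value < 1e-6

    def test_complete_case_drops_missing(self):
        r = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0])
        g = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 1.0])
        p = np.array([1.0, 2.0, 3.0, 4.0, np.nan, 6.0, 7.0, 8.0])
        res = lrt_nested(p, r, g)
        assert res.n_used == 6

    def test_exact_fit_degenerate_flag(self):
        r = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        p = 2.0 * r + 3.0 * g  # exact linear combination, RSS_full = 0
        res = lrt_nested(p, r, g)
        assert res.degenerate
        assert res.p_value == 0.0


class TestOverlapFilter:
    @pytest.mark.parametrize("sp,se,expected", [
        (0.01, 0.40, True),
        (0.01, 0.01, False),
        (0.20, 0.90, False),
        (0.01, None, False),
        (0.01, np.nan, False),
        (0.0499, 0.0501, True),
    ])
    def test_rule(self, sp, se, expected):
        assert overlap_filter(sp, se, alpha=0.05) is expected


def _scan_table(rows, level):
    return pd.DataFrame(rows, columns=["gene", "functional_class", "logFC",
                                       "p_value", "fdr"])


class TestCallSpsqtls:
    def _tables(self):
        lrt = pd.DataFrame({
            "gene": ["A", "B", "C", "D"],
            "functional_class": ["missense"] * 4,
            "lrt_F": [50.0, 1.0, 40.0, 2.0],
            "lrt_p": [1e-6, 0.5, 1e-5, 0.4],
            "lrt_fdr": [4e-6, 0.5, 2e-5, 0.5],
        })
        se = _scan_table([("A", "missense", 0.1, 0.6, 0.8),   # protein-only
                          ("B", "missense", 1.8, 1e-5, 1e-4),  # concordant
                          ("C", "missense", 0.2, 0.5, 0.7),   # sps candidate
                          ("D", "missense", -1.5, 1e-4, 1e-3)], "mrna")
        sp = _scan_table([("A", "missense", 2.0, 1e-6, 1e-5),
                          ("B", "missense", 1.9, 1e-5, 1e-4),
                          ("C", "missense", 1.7, 1e-4, 1e-3),
                          ("D", "missense", -0.1, 0.8, 0.9)], "protein")
        return lrt, sp, se

    def test_intersection_and_labels(self):
        lrt, sp, se = self._tables()
        out = call_spsqtls(lrt, sp, se).set_index("gene")
        assert bool(out.loc["A", "is_spsqtl"])
        assert out.loc["A", "concordance"] == "discordant_protein_specific"
        assert not out.loc["B", "is_spsqtl"]
        assert out.loc["B", "concordance"] == "concordant"
        assert bool(out.loc["C", "is_spsqtl"])
        assert out.loc["D", "concordance"] == "seqtl_only"

    def test_is_spsqtl_implies_both_methods(self):
        lrt, sp, se = self._tables()
        out = call_spsqtls(lrt, sp, se)
        assert (out["is_spsqtl"] == (out["method1_pass"] & out["method2_pass"])).all()
        assert (out.loc[out["is_spsqtl"], "spqtl_fdr"] < 0.05).all()

    def test_missing_scan_record_untestable(self):
        lrt, sp, se = self._tables()
        se = se[se["gene"] != "A"]
        out = call_spsqtls(lrt, sp, se).set_index("gene")
        assert out.loc["A", "concordance"] == "untestable"
        assert not bool(out.loc["A", "is_spsqtl"])

    def test_duplicate_keys_raise(self):
        lrt, sp, se = self._tables()
        sp2 = pd.concat([sp, sp.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            call_spsqtls(lrt, sp2, se)


class TestConcordanceEffects:
    def test_perfect_line(self):
        se = _scan_table([(g, "missense", v, 0.001, 0.01)
                          for g, v in zip("XYZ", (1.0, 2.0, 3.0))], "mrna")
        sp = _scan_table([(g, "missense", v, 0.001, 0.01)
                          for g, v in zip("XYZ", (1.0, 2.0, 3.0))], "protein")
        out = concordance_effects(se, sp)
        assert out.attrs["pearson_r_concordant"] == pytest.approx(1.0)
        assert out["same_sign"].all()

    def test_opposite_signs_flagged(self):
        se = _scan_table([("X", "missense", -2.0, 0.01, 0.02)], "mrna")
        sp = _scan_table([("X", "missense", 1.0, 0.01, 0.02)], "protein")
        out = concordance_effects(se, sp)
        assert not out["same_sign"].iloc[0]

    def test_zero_agrees_with_anything(self):
        se = _scan_table([("X", "missense", 0.0, 0.5, 0.9)], "mrna")
        sp = _scan_table([("X", "missense", -1.0, 0.5, 0.9)], "protein")
        out = concordance_effects(se, sp)
        assert out["same_sign"].iloc[0]


@pytest.fixture(scope="module")
def called():
    from protegoqtl import CohortConfig, generate_cohort, preprocess_cohort
    from protegoqtl.models import SomaticQTLModel, SpsQTLModel

    cfg = CohortConfig(
        n_tumor=150, n_genes=120, n_paired_normal=0, carrier_rate=0.1,
        effect_size=2.0, noise_sd=0.5, missing_rate=0.05,
        class_mix={"missense": 1.0, "truncating": 0.0, "synonymous": 0.0},
        effect_classes={"null": 0.4, "concordant": 0.2,
                        "mrna_only": 0.2, "protein_only": 0.2}, seed=77)
    cohort, truth = generate_cohort(cfg)
    proc, sets = preprocess_cohort(cohort)
    se = SomaticQTLModel(proc, sets, "mrna").fit()
    sp = SomaticQTLModel(proc, sets, "protein").fit()
    res = SpsQTLModel(proc, sets, se, sp).fit()
    return res.table.merge(truth, on=["gene", "functional_class"])


class TestSyntheticRecovery:
    """One-seed spot checks; the multi-seed recovery matrix lives in the
    acceptance suite."""

    def test_protein_only_genes_called_spsqtl(self, called):
        grp = called[(called["effect_class"] == "protein_only")
                     & (called["n_carriers"] >= 10)
                     & (called["concordance"] != "untestable")]
        assert len(grp) >= 10
        assert grp["is_spsqtl"].mean() >= 0.8

    def test_concordant_genes_not_called_spsqtl(self, called):
        grp = called[(called["effect_class"] == "concordant")
                     & (called["n_carriers"] >= 10)
                     & (called["concordance"] != "untestable")]
        assert len(grp) >= 10
        assert grp["is_spsqtl"].mean() <= 0.1
        assert (grp["concordance"] == "concordant").mean() >= 0.8

    def test_mrna_only_genes_not_called_spsqtl(self, called):
        grp = called[(called["effect_class"] == "mrna_only")
                     & (called["n_carriers"] >= 10)
                     & (called["concordance"] != "untestable")]
        assert len(grp) >= 10
        assert grp["is_spsqtl"].mean() <= 0.1
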
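import numpy as np
import pandas as pd
import pytest

from protegoqtl.functional import (categorize_mutations,
                                   compare_functional_scores,
                                   mutation_expression_percentile,
                                   pool_percentiles, read_functional_scores)


def expr_row(values, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return pd.Series(values, index=samples, dtype=float)


def mut_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene",
                                       "variant_classification", "protein_change"])


class TestMutationExpressionPercentile:
    def test_top_sample_carrier(self):
        row = expr_row([1, 2, 3, 4, 5])
        muts = mut_table([("s4", "TP53", "Missense_Mutation", "p.R175H")])
        out = mutation_expression_percentile(row, muts, "TP53")
        assert out.iloc[0]["mean_expr_carriers"] == 5
        assert out.iloc[0]["percentile"] == pytest.approx(80.0)  # 4 of 5 below

    def test_carrier_mean_below_everything(self):
        row = expr_row([1, 2, 3, 4, 5])
        muts = mut_table([("s0", "TP53", "Missense_Mutation", "p.R175H")])
        out = mutation_expression_percentile(row, muts, "TP53")
        assert out.iloc[0]["percentile"] == pytest.approx(0.0)

    def test_two_carrier_average(self):
        row = expr_row([1, 2, 3, 4, 5])
        muts = mut_table([("s1", "TP53", "Missense_Mutation", "p.R175H"),
                          ("s3", "TP53", "Missense_Mutation", "p.R175H")])
        out = mutation_expression_percentile(row, muts, "TP53")
        assert out.iloc[0]["mean_expr_carriers"] == pytest.approx(3.0)
        assert out.iloc[0]["percentile"] == pytest.approx(40.0)  # 2 of 5 below

    def test_all_missing_carriers_skipped(self):
        row = expr_row([1, np.nan, 3])
        muts = mut_table([("s1", "TP53", "Missense_Mutation", "p.R175H")])
        out = mutation_expression_percentile(row, muts, "TP53")
        assert len(out) == 0

    def test_monotone_transform_invariance_single_carrier(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=30)
        muts = mut_table([(f"s{i}", "TP53", "Missense_Mutation", f"p.M{i}V")
                          for i in (0, 7, 21)])
        base = mutation_expression_percentile(expr_row(vals), muts, "TP53")
        warped = mutation_expression_percentile(expr_row(np.exp(vals)), muts, "TP53")
        np.testing.assert_allclose(base["percentile"], warped["percentile"])

    def test_pool_keeps_maximum_percentile(self):
        a = pd.DataFrame({"protein_change": ["p.R175H"], "percentile": [40.0]})
        b = pd.DataFrame({"protein_change": ["p.R175H"], "percentile": [90.0]})
        out = pool_percentiles([a, b])
        assert out.iloc[0]["percentile"] == 90.0


class TestCategorizeMutations:
    def test_rule_application(self):
        summaries = pd.DataFrame({"protein_change": ["A", "B"],
                                  "percentile": [95.0, 50.0]})
        part = categorize_mutations(summaries, observed={"A", "B"},
                                    assayed={"A", "B", "C"})
        assert part == {"group1": {"A"}, "group2": {"B"}, "group3": {"C"}}

    def test_top_fraction_one_empties_group2(self):
        summaries = pd.DataFrame({"protein_change": ["A", "B"],
                                  "percentile": [95.0, 0.0]})
        part = categorize_mutations(summaries, {"A", "B"}, {"A", "B"},
                                    top_fraction=1.0)
        assert part["group2"] == set()

    def test_no_observed_mutations(self):
        summaries = pd.DataFrame({"protein_change": [], "percentile": []})
        part = categorize_mutations(summaries, set(), {"X", "Y"})
        assert part["group1"] == set() and part["group2"] == set()
        assert part["group3"] == {"X", "Y"}

    def test_partition_disjoint_exhaustive(self):
        rng = np.random.default_rng(8)
        observed = {f"m{i}" for i in range(20)}
        assayed = {f"m{i}" for i in range(10, 40)}
        summaries = pd.DataFrame({
            "protein_change": sorted(observed),
            "percentile": rng.uniform(0, 100, 20)})
        part = categorize_mutations(summaries, observed, assayed)
        g1, g2, g3 = part["group1"], part["group2"], part["group3"]
        assert not (g1 & g2) and not (g1 & g3) and not (g2 & g3)
        assert g1 | g2 | g3 == observed | assayed


def score_table(mapping, score_name="rfs"):
    return pd.DataFrame([{"protein_change": m, "score_name": score_name,
                          "score": s} for m, s in mapping.items()])


class TestCompareFunctionalScores:
    def test_exact_small_group_p(self):
        part = {"group1": {"a", "b"}, "group2": {"c", "d"}, "group3": set()}
        scores = score_table({"a": 10, "b": 11, "c": 1, "d": 2})
        out = compare_functional_scores(part, scores, "rfs")
        row = out[out["comparison"] == "group1_vs_group2"].iloc[0]
        assert row["p_value"] == pytest.approx(1 / 3)

    def test_identical_scores_p_one(self):
        part = {"group1": {"a", "b", "c"}, "group2": {"d", "e", "f"},
                "group3": set()}
        scores = score_table({"a": 1, "b": 2, "c": 3, "d": 1, "e": 2, "f": 3})
        out = compare_functional_scores(part, scores, "rfs")
        row = out[out["comparison"] == "group1_vs_group2"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0)

    def test_unscored_group_skipped(self):
        part = {"group1": {"a"}, "group2": set(), "group3": {"z"}}
        scores = score_table({"a": 1.0})
        out = compare_functional_scores(part, scores, "rfs")
        assert (out.set_index("comparison")
                .loc["group1_vs_group2", "skipped_reason"]) != ""

    def test_shifted_scores_detected_in_most_seeds(self):
        hits, n_seeds = 0, 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            g1 = {f"a{i}" for i in range(20)}
            g3 = {f"z{i}" for i in range(20)}
            mapping = {m: rng.normal(2.0, 1.0) for m in g1}
            mapping.update({m: rng.normal(0.0, 1.0) for m in g3})
            out = compare_functional_scores(
                {"group1": g1, "group2": set(), "group3": g3},
                score_table(mapping), "rfs")
            p = out.set_index("comparison").loc["group1_vs_group3", "p_value"]
            if p < 0.05:
                hits += 1
        assert hits / n_seeds >= 0.9

    def test_duplicate_score_rows_rejected(self):
        scores = pd.concat([score_table({"a": 1.0})] * 2, ignore_index=True)
        with pytest.raises(ValueError):
            compare_functional_scores({"group1": {"a"}, "group2": set(),
                                       "group3": set()}, scores, "rfs")


class TestEndToEndSynthetic:
    def test_high_protein_mutations_show_higher_scores(self):
        """Mutations injected with positive protein effects receive higher
        synthetic functional scores; the percentile pipeline must find the
        shift against the assayed background."""
        rng = np.random.default_rng(12)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        base = rng.normal(0, 1, size=n)
        rows = []
        functional, neutral = [], []
        for i in range(12):
            pch = f"p.R{100 + i}H"
            carrier = f"s{i}"
            if i < 6:  # functional: push carrier expression up hard
                base[i] += 4.0
                functional.append(pch)
            else:
                neutral.append(pch)
            rows.append((carrier, "TP53", "Missense_Mutation", pch))
        expr = pd.Series(base, index=samples)
        summaries = mutation_expression_percentile(expr, mut_table(rows), "TP53")
        observed = set(summaries["protein_change"])
        assayed = observed | {f"p.X{i}Y" for i in range(25)}
        part = categorize_mutations(summaries, observed, assayed)
        assert set(functional) <= part["group1"]
        mapping = {m: rng.normal(3.0, 0.5) for m in functional}
        mapping.update({m: rng.normal(0.0, 0.5) for m in assayed - set(functional)})
        out = compare_functional_scores(part, score_table(mapping), "rfs")
        p13 = out.set_index("comparison").loc["group1_vs_group3", "p_value"]
        assert p13 < 0.01


class TestReadFunctionalScores:
    def test_reads_and_validates(self, tmp_path):
        path = tmp_path / "scores.tsv"
        score_table({"a": 1.0, "b": 2.0}).to_csv(path, sep="\t", index=False)
        out = read_functional_scores(path)
        assert len(out) == 2
        bad = pd.DataFrame({"protein_change": ["a"], "score": [1.0]})
        bad_path = tmp_path / "bad.tsv"
        bad.to_csv(bad_path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_functional_scores(bad_path)
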
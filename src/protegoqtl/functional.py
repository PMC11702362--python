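"""Mutation-level expression percentiles versus external functional scores.

The validation strategy behind this module: for a heavily mutated gene
(the canonical case is TP53 missense), average the mutated gene's
expression over each distinct protein change's carriers, place that mean on
the cohort-wide expression distribution as a percentile, split mutations
into three groups — (1) observed mutations in the top expression fraction,
(2) other observed mutations, (3) assayed-but-unobserved mutations — and
compare external per-mutation functional scores (MAVE fitness or in-vivo
enrichment) between groups with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import wilcoxon_rank_sum


def mutation_expression_percentile(expr_row: pd.Series, mutation_table: pd.DataFrame,
                                   gene: str, level: str = "protein",
                                   cancer_type: str = "") -> pd.DataFrame:
    """Carrier-mean expression and cohort percentile per distinct protein change.

    Percentile = 100 x fraction of cohort samples with expression strictly
    below the carrier mean (computed over non-missing entries). Protein
    changes whose carriers are all missing are skipped.
    """
    muts = mutation_table[mutation_table["gene"] == gene]
    cohort_vals = expr_row.dropna().to_numpy(dtype=float)
    if len(cohort_vals) == 0:
        raise ValueError(f"no observed expression for gene {gene!r}")
    rows = []
    for pchange, grp in muts.groupby("protein_change", sort=True):
        if not str(pchange):
            continue
        carriers = [s for s in set(grp["sample_id"]) if s in expr_row.index]
        vals = expr_row.loc[carriers].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        mean = float(vals.mean())
        pct = 100.0 * float((cohort_vals < mean).mean())
        rows.append({"protein_change": str(pchange), "gene": gene,
                     "cancer_type": cancer_type, "level": level,
                     "mean_expr_carriers": mean, "percentile": pct,
                     "n_carriers": len(vals)})
    return pd.DataFrame(rows, columns=["protein_change", "gene", "cancer_type",
                                       "level", "mean_expr_carriers", "percentile",
                                       "n_carriers"])


def pool_percentiles(per_cohort: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool multi-cohort summaries; a mutation keeps its maximum percentile."""
    if not per_cohort:
        return pd.DataFrame(columns=["protein_change", "percentile"])
    allrows = pd.concat(per_cohort, ignore_index=True)
    idx = allrows.groupby("protein_change")["percentile"].idxmax()
    return allrows.loc[idx].reset_index(drop=True)


def categorize_mutations(summaries: pd.DataFrame, observed: set, assayed: set,
                         top_fraction: float = 0.2) -> dict[str, set]:
    """Three-way partition of mutations by expression percentile.

    group1: observed mutations with percentile >= (1 - top_fraction) * 100;
    group2: remaining observed mutations; group3: assayed mutations never
    observed in the cohorts. Disjoint and exhaustive over observed u assayed.
    """
    if not 0 <= top_fraction <= 1:
        raise ValueError("top_fraction must lie in [0, 1]")
    cut = (1.0 - top_fraction) * 100.0
    pct = dict(zip(summaries["protein_change"], summaries["percentile"]))
    group1 = {m for m in observed if pct.get(m, -1.0) >= cut}
    group2 = set(observed) - group1
    group3 = set(assayed) - set(observed)
    return {"group1": group1, "group2": group2, "group3": group3}


def compare_functional_scores(partition: dict[str, set], scores: pd.DataFrame,
                              score_name: str) -> pd.DataFrame:
    """Wilcoxon rank-sum of one functional score between partition groups.

    ``scores`` columns: protein_change, score_name, score (unique per pair).
    Compares group1 vs group2 and group1 vs group3; a comparison with an
    unscored group is skipped with a reason.
    """
    sub = scores[scores["score_name"] == score_name]
    if sub.duplicated(subset=["protein_change"]).any():
        raise ValueError(f"duplicate protein_change entries for score {score_name!r}")
    lookup = dict(zip(sub["protein_change"], sub["score"].astype(float)))
    vals = {g: np.array([lookup[m] for m in sorted(members) if m in lookup])
            for g, members in partition.items()}
    rows = []
    for g2 in ("group2", "group3"):
        x, y = vals["group1"], vals[g2]
        row = {"score_name": score_name, "comparison": f"group1_vs_{g2}",
               "n1": len(x), "n2": len(y), "median1": np.nan, "median2": np.nan,
               "U": np.nan, "p_value": np.nan, "method": "", "skipped_reason": ""}
        if len(x) == 0 or len(y) == 0:
            row["skipped_reason"] = "group without scores"
            rows.append(row)
            continue
        res = wilcoxon_rank_sum(x, y)
        row.update({"median1": float(np.median(x)), "median2": float(np.median(y)),
                    "U": res.u_statistic, "p_value": res.p_value, "method": res.method})
        rows.append(row)
    return pd.DataFrame(rows)


def read_functional_scores(path) -> pd.DataFrame:
    """Read a (protein_change, score_name, score) TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_change": str, "score_name": str})
    needed = {"protein_change", "score_name", "score"}
    if not needed <= set(df.columns):
        raise ValueError(f"functional score table must have columns {sorted(needed)}")
    if df.duplicated(subset=["protein_change", "score_name"]).any():
        raise ValueError("duplicated (protein_change, score_name) rows")
    return df
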
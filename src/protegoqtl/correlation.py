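"""Per-gene mRNA-protein correlation and gene-group comparisons.

Genes are grouped by their mutation-impact profile (concordant QTL genes,
discordant protein-specific genes, all other expressed genes) and their
Pearson mRNA-protein correlations are compared between groups with the
two-sample Wilcoxon rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ProteogenomicCohort
from .stats import wilcoxon_rank_sum


def per_gene_correlation(mrna: pd.DataFrame, protein: pd.DataFrame,
                         samples=None, min_n: int = 3) -> pd.DataFrame:
    """Pearson r between a gene's mRNA and protein rows over complete cases.

    ``samples`` restricts the columns used (typically tumor samples only).
    Genes absent from either matrix, with fewer than ``min_n`` complete
    pairs, or with zero variance on either level are skipped with a reason.
    """
    if samples is None:
        samples = [s for s in mrna.columns if s in set(protein.columns)]
    samples = [s for s in samples if s in mrna.columns and s in protein.columns]
    rows = []
    for gene in mrna.index:
        if gene not in protein.index:
            continue
        x = mrna.loc[gene, samples].to_numpy(dtype=float)
        y = protein.loc[gene, samples].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < min_n:
            rows.append({"gene": gene, "n": n, "r": np.nan,
                         "skipped_reason": f"fewer than {min_n} complete pairs"})
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            rows.append({"gene": gene, "n": n, "r": np.nan,
                         "skipped_reason": "zero variance"})
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        rows.append({"gene": gene, "n": n, "r": r, "skipped_reason": ""})
    return pd.DataFrame(rows, columns=["gene", "n", "r", "skipped_reason"])


def assign_groups(correlations: pd.DataFrame, spsqtl_table: pd.DataFrame) -> pd.DataFrame:
    """Label genes concordant / discordant / other from the spsQTL call table.

    Gene-level, any-class membership: a gene is 'discordant' if any of its
    (gene, class) pairs is an spsQTL, else 'concordant' if any pair is
    labeled concordant, else 'other'.
    """
    disc = set(spsqtl_table.loc[spsqtl_table["is_spsqtl"], "gene"])
    conc = set(spsqtl_table.loc[spsqtl_table["concordance"] == "concordant", "gene"]) - disc
    out = correlations.copy()
    out["group"] = ["discordant" if g in disc else "concordant" if g in conc else "other"
                    for g in out["gene"]]
    return out


def compare_groups(correlations: pd.DataFrame,
                   comparisons=(("concordant", "other"), ("discordant", "other")),
                   ) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests between gene-group r distributions.

    ``correlations`` needs columns r and group; rows with missing r are
    dropped. Comparisons with an empty group are reported as skipped.
    """
    usable = correlations.dropna(subset=["r"])
    rows = []
    for g1, g2 in comparisons:
        x = usable.loc[usable["group"] == g1, "r"].to_numpy()
        y = usable.loc[usable["group"] == g2, "r"].to_numpy()
        row = {"group1": g1, "group2": g2, "n1": len(x), "n2": len(y),
               "median1": np.nan, "median2": np.nan, "U": np.nan,
               "p_value": np.nan, "method": "", "skipped_reason": ""}
        if len(x) == 0 or len(y) == 0:
            row["skipped_reason"] = "empty group"
            rows.append(row)
            continue
        res = wilcoxon_rank_sum(x, y)
        row.update({"median1": float(np.median(x)), "median2": float(np.median(y)),
                    "U": res.u_statistic, "p_value": res.p_value, "method": res.method})
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_stage(cohort: ProteogenomicCohort, spsqtl_table: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor-only per-gene correlations, grouped and compared."""
    corr = per_gene_correlation(cohort.mrna, cohort.protein,
                                samples=cohort.tumor_samples)
    corr = assign_groups(corr, spsqtl_table)
    tests = compare_groups(corr)
    return corr, tests
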
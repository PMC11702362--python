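"""Somatic protein-specific QTL (spsQTL) calling.

Two complementary criteria are intersected:

* method 1 — a nested-model likelihood-ratio test comparing
  ``p = mu + beta0*g + beta1*r`` against ``p = mu + beta2*r`` (protein on
  genotype plus mRNA vs mRNA alone), realized as the nested-model F-test
  F = (RSS_reduced - RSS_full) / (RSS_full / df_full) with p from
  F(1, df_full); BH-corrected across all (gene, class) pairs per cohort;
* method 2 — an FDR overlap filter retaining pairs whose protein-level scan
  FDR is below alpha while the mRNA-level scan FDR is above alpha.

A pair is an spsQTL iff it passes both. Every testable pair additionally
receives a concordance label (concordant / discordant_protein_specific /
seqtl_only / neither / untestable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ProteogenomicCohort
from .qtl import UntestableError, build_design
from .stats import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class LRTResult:
    gene: str
    functional_class: str
    statistic: float  # nested-model F
    p_value: float
    beta0: float  # genotype coefficient, full model
    beta1: float  # mRNA coefficient, full model
    beta2: float  # mRNA coefficient, reduced model
    mu: float  # full-model intercept
    n_used: int
    degenerate: bool = False  # RSS_full == 0


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def lrt_nested(p_vec, r_vec, g_vec, covariates: pd.DataFrame | None = None,
               gene: str = "", functional_class: str = "") -> LRTResult:
    """Nested-model F-test of the genotype term in a protein-on-mRNA regression.

    ``p_vec``, ``r_vec``, ``g_vec`` must be aligned; rows with a missing
    protein or mRNA value are dropped (complete-case). ``covariates`` is an
    optional aligned numeric matrix entering both nested models.
    Raises ``UntestableError`` when residual df of the full model is <= 0.
    """
    p = np.asarray(p_vec, dtype=float)
    r = np.asarray(r_vec, dtype=float)
    g = np.asarray(g_vec, dtype=float)
    if not (len(p) == len(r) == len(g)):
        raise ValueError("p, r and g must have equal length")
    C = None
    if covariates is not None and covariates.shape[1] > 0:
        C = np.asarray(covariates, dtype=float)
        keep = ~(np.isnan(p) | np.isnan(r) | np.isnan(C).any(axis=1))
    else:
        keep = ~(np.isnan(p) | np.isnan(r))
    p, r, g = p[keep], r[keep], g[keep]
    if C is not None:
        C = C[keep]
    n = len(p)

    ones = np.ones(n)
    full_cols = [ones, g, r] + ([C[:, j] for j in range(C.shape[1])] if C is not None else [])
    red_cols = [ones, r] + ([C[:, j] for j in range(C.shape[1])] if C is not None else [])
    X_full = np.column_stack(full_cols)
    X_red = np.column_stack(red_cols)
    rank_full = np.linalg.matrix_rank(X_full)
    df_full = n - rank_full
    if df_full <= 0:
        raise UntestableError("insufficient residual df for the nested F-test")
    if rank_full < X_full.shape[1]:
        raise ValueError("rank-deficient full model (collinear genotype?)")

    beta_full, rss_full = _ols_rss(X_full, p)
    beta_red, rss_red = _ols_rss(X_red, p)
    if rss_full <= 1e-12 * max(float(p @ p), 1e-300):  # numerically exact fit
        return LRTResult(gene, functional_class, statistic=np.inf, p_value=0.0,
                         beta0=float(beta_full[1]), beta1=float(beta_full[2]),
                         beta2=float(beta_red[1]), mu=float(beta_full[0]),
                         n_used=n, degenerate=True)
    f_stat = max(0.0, (rss_red - rss_full) / (rss_full / df_full))
    p_val = float(sps.f.sf(f_stat, 1, df_full))
    return LRTResult(gene, functional_class, statistic=float(f_stat), p_value=p_val,
                     beta0=float(beta_full[1]), beta1=float(beta_full[2]),
                     beta2=float(beta_red[1]), mu=float(beta_full[0]), n_used=n)


def run_lrt_scan(cohort: ProteogenomicCohort, carrier_sets,
                 min_carriers: int = 3, min_controls: int = 3,
                 include_covariates: bool = True) -> pd.DataFrame:
    """Run the nested-model LRT for every carrier set with data at both levels.

    Complete-case on samples with both an mRNA and a protein value for the
    gene; BH across all tested pairs (one LRT family per cohort).
    """
    tumors = set(cohort.tumor_samples)
    rows = []
    for cs in carrier_sets:
        row = {"gene": cs.gene, "functional_class": cs.functional_class,
               "lrt_F": np.nan, "lrt_p": np.nan, "n_used": np.nan,
               "skipped_reason": ""}
        if cs.gene not in cohort.mrna.index or cs.gene not in cohort.protein.index:
            row["skipped_reason"] = "missing mrna or protein row"
            rows.append(row)
            continue
        r_full = cohort.mrna.loc[cs.gene]
        p_full = cohort.protein.loc[cs.gene]
        usable = (set(cs.carriers) | set(cs.controls)) & tumors
        usable = sorted(s for s in usable
                        if s in r_full.index and s in p_full.index
                        and not pd.isna(r_full[s]) and not pd.isna(p_full[s]))
        n_car = sum(1 for s in usable if s in cs.carriers)
        n_con = len(usable) - n_car
        if n_car < min_carriers or n_con < min_controls:
            row["skipped_reason"] = "insufficient carriers or controls with both levels"
            rows.append(row)
            continue
        g = np.array([1.0 if s in cs.carriers else 0.0 for s in usable])
        cov_matrix = None
        if include_covariates:
            try:
                design = build_design(cohort.covariates, cs, usable)
                cov_cols = [c for c in design.matrix.columns
                            if c not in ("intercept", "mutation")]
                cov_matrix = design.matrix[cov_cols]
            except UntestableError as exc:
                row["skipped_reason"] = str(exc)
                rows.append(row)
                continue
        try:
            res = lrt_nested(p_full.loc[usable].to_numpy(),
                             r_full.loc[usable].to_numpy(), g,
                             covariates=cov_matrix, gene=cs.gene,
                             functional_class=cs.functional_class)
        except (UntestableError, ValueError) as exc:
            row["skipped_reason"] = str(exc)
            rows.append(row)
            continue
        row.update({"lrt_F": res.statistic, "lrt_p": res.p_value, "n_used": res.n_used})
        rows.append(row)
    table = pd.DataFrame(rows, columns=["gene", "functional_class", "lrt_F", "lrt_p",
                                        "n_used", "skipped_reason"])
    table["lrt_fdr"] = bh_fdr(table["lrt_p"].to_numpy())
    return table


def overlap_filter(spqtl_fdr: float, seqtl_fdr: float | None, alpha: float = 0.05) -> bool:
    """Method-2 rule: protein-level FDR < alpha while mRNA-level FDR > alpha.

    A pair with no mRNA-level result (``None``/NaN) is untestable and does
    not pass.
    """
    if spqtl_fdr is None or np.isnan(spqtl_fdr):
        return False
    if seqtl_fdr is None or np.isnan(seqtl_fdr):
        return False
    return bool(spqtl_fdr < alpha and seqtl_fdr > alpha)


def call_spsqtls(lrt_table: pd.DataFrame, spqtl_table: pd.DataFrame,
                 seqtl_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Intersect the LRT and overlap-filter candidates; label concordance.

    All three tables are keyed by (gene, functional_class); duplicated keys
    raise. Output has one row per key present in the LRT table, carrying the
    scan FDRs and logFCs, both method verdicts, the final spsQTL flag and a
    concordance label.
    """
    key = ["gene", "functional_class"]
    for name, tab in (("lrt", lrt_table), ("spqtl", spqtl_table), ("seqtl", seqtl_table)):
        if tab.duplicated(subset=key).any():
            raise ValueError(f"duplicated (gene, functional_class) keys in {name} table")

    sp = spqtl_table.set_index(key)
    se = seqtl_table.set_index(key)
    rows = []
    for _, lrow in lrt_table.iterrows():
        k = (lrow["gene"], lrow["functional_class"])
        sp_fdr = float(sp.loc[k, "fdr"]) if k in sp.index else np.nan
        se_fdr = float(se.loc[k, "fdr"]) if k in se.index else np.nan
        sp_lfc = float(sp.loc[k, "logFC"]) if k in sp.index else np.nan
        se_lfc = float(se.loc[k, "logFC"]) if k in se.index else np.nan
        lrt_fdr = lrow.get("lrt_fdr", np.nan)
        m1 = bool(not pd.isna(lrt_fdr) and lrt_fdr < alpha)
        m2 = overlap_filter(sp_fdr, se_fdr, alpha)
        is_sps = m1 and m2
        if pd.isna(sp_fdr) or pd.isna(se_fdr):
            concordance = "untestable"
        elif sp_fdr < alpha and se_fdr < alpha:
            concordance = "concordant"
        elif is_sps:
            concordance = "discordant_protein_specific"
        elif se_fdr < alpha:
            concordance = "seqtl_only"
        else:
            concordance = "neither"
        rows.append({"gene": lrow["gene"], "functional_class": lrow["functional_class"],
                     "lrt_F": lrow.get("lrt_F", np.nan), "lrt_p": lrow.get("lrt_p", np.nan),
                     "lrt_fdr": lrt_fdr, "seqtl_fdr": se_fdr, "spqtl_fdr": sp_fdr,
                     "method1_pass": m1, "method2_pass": m2, "is_spsqtl": is_sps,
                     "concordance": concordance, "rna_logFC": se_lfc,
                     "protein_logFC": sp_lfc})
    return pd.DataFrame(rows, columns=["gene", "functional_class", "lrt_F", "lrt_p",
                                       "lrt_fdr", "seqtl_fdr", "spqtl_fdr",
                                       "method1_pass", "method2_pass", "is_spsqtl",
                                       "concordance", "rna_logFC", "protein_logFC"])


def concordance_effects(seqtl_table: pd.DataFrame, spqtl_table: pd.DataFrame,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Pair mRNA and protein effect sizes per (gene, class); check directionality.

    Inner join of tested rows; ``same_sign`` treats a zero logFC as agreeing
    with anything. The Pearson correlation of effect sizes across pairs
    significant at both levels (FDR < alpha) is attached as
    ``attrs['pearson_r_concordant']``.
    """
    key = ["gene", "functional_class"]
    se = seqtl_table[seqtl_table["p_value"].notna()][key + ["logFC", "fdr"]]
    sp = spqtl_table[spqtl_table["p_value"].notna()][key + ["logFC", "fdr"]]
    merged = se.merge(sp, on=key, suffixes=("_rna", "_protein"))
    merged = merged.rename(columns={"logFC_rna": "rna_logFC",
                                    "logFC_protein": "protein_logFC"})
    s1 = np.sign(merged["rna_logFC"])
    s2 = np.sign(merged["protein_logFC"])
    merged["same_sign"] = (s1 == s2) | (s1 == 0) | (s2 == 0)
    out = merged[key + ["rna_logFC", "protein_logFC", "same_sign", "fdr_rna", "fdr_protein"]]
    conc = out[(out["fdr_rna"] < alpha) & (out["fdr_protein"] < alpha)]
    if len(conc) >= 2 and conc["rna_logFC"].std() > 0 and conc["protein_logFC"].std() > 0:
        r = float(np.corrcoef(conc["rna_logFC"], conc["protein_logFC"])[0, 1])
    else:
        r = np.nan
    out = out.copy()
    out.attrs["pearson_r_concordant"] = r
    out.attrs["n_concordant_pairs"] = int(len(conc))
    return out
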
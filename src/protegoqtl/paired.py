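"""Paired tumor-versus-normal differential expression among mutation carriers.

For each (gene, class) carrier set, patients contributing exactly one tumor
and one normal sample are paired; the per-patient difference
d = tumor - normal is regressed on an intercept plus (pruned) covariates,
the intercept is tested with empirical-Bayes variance moderation across
genes, and BH correction is applied per cohort x level. This validates the
direction of cross-tumor spQTL/seQTL effects independently of between-
patient variation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ProteogenomicCohort
from .stats import bh_fdr, moderate_variances

logger = logging.getLogger(__name__)


def pair_samples(covariates: pd.DataFrame) -> list[tuple[str, str, str]]:
    """(patient_id, tumor_sample, normal_sample) for every 1:1 paired patient.

    Patients with multiple tumor or multiple normal samples are skipped
    (logged); patients lacking either tissue contribute no pair.
    """
    pairs = []
    for patient, grp in covariates.groupby("patient_id", sort=True):
        tumors = list(grp.index[grp["tissue"] == "tumor"])
        normals = list(grp.index[grp["tissue"] == "normal"])
        if len(tumors) == 1 and len(normals) == 1:
            pairs.append((str(patient), tumors[0], normals[0]))
        elif len(tumors) > 1 or len(normals) > 1:
            logger.info("patient %s has multiple samples per tissue; skipped", patient)
    return pairs


def _covariate_matrix(cov_rows: pd.DataFrame) -> np.ndarray | None:
    """Pruned numeric covariate matrix for the difference-score regression."""
    cols = []
    if "age" in cov_rows.columns and cov_rows["age"].nunique() > 1:
        cols.append(cov_rows["age"].astype(float).to_numpy())
    for name in ("gender", "ethnicity", "batch"):
        if name in cov_rows.columns and cov_rows[name].astype(str).nunique() > 1:
            dummies = pd.get_dummies(cov_rows[name].astype(str), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].astype(float).to_numpy())
    if not cols:
        return None
    return np.column_stack(cols)


def run_paired_de(cohort: ProteogenomicCohort, carrier_sets, level: str,
                  min_pairs: int = 2, carriers_only: bool = True,
                  moderation: bool = True) -> pd.DataFrame:
    """Paired differential expression per (gene, class) at one level.

    Restricts to carrier patients by default (``carriers_only``); the
    covariates used are those of the tumor sample. Pairs with a missing
    value at either end are dropped per gene.
    """
    if level not in ("mrna", "protein"):
        raise ValueError("level must be 'mrna' or 'protein'")
    expr = cohort.mrna if level == "mrna" else cohort.protein
    pairs = pair_samples(cohort.covariates)

    rows, fits = [], []
    for cs in carrier_sets:
        row = {"cancer_type": cohort.cancer_type, "gene": cs.gene,
               "functional_class": cs.functional_class, "level": level,
               "n_pairs": np.nan, "mean_paired_diff": np.nan, "t": np.nan,
               "p_value": np.nan, "fdr": np.nan, "skipped_reason": ""}
        if cs.gene not in expr.index:
            row["skipped_reason"] = f"no {level} row"
            rows.append(row)
            continue
        y = expr.loc[cs.gene]
        use = [(pt, t, n) for pt, t, n in pairs
               if (not carriers_only or t in cs.carriers)
               and t in y.index and n in y.index
               and not pd.isna(y[t]) and not pd.isna(y[n])]
        if len(use) < min_pairs:
            row["skipped_reason"] = f"fewer than {min_pairs} usable pairs"
            rows.append(row)
            continue
        d = np.array([y[t] - y[n] for _, t, n in use])
        tumor_rows = cohort.covariates.loc[[t for _, t, _ in use]]
        C = _covariate_matrix(tumor_rows)
        n = len(d)
        X = np.ones((n, 1)) if C is None else np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(X) < X.shape[1] or n - X.shape[1] <= 0:
            X = np.ones((n, 1))  # fall back to intercept-only when covariates exhaust df
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ (X.T @ d)
        resid = d - X @ beta
        df = n - X.shape[1]
        if df <= 0:
            row["skipped_reason"] = "no residual degrees of freedom"
            rows.append(row)
            continue
        sigma2 = float(resid @ resid) / df
        row["n_pairs"] = n
        row["mean_paired_diff"] = float(beta[0])
        rows.append(row)
        fits.append({"beta": float(beta[0]), "unit": float(np.sqrt(xtx_inv[0, 0])),
                     "sigma2": sigma2, "df": df})

    table = pd.DataFrame(rows, columns=["cancer_type", "gene", "functional_class",
                                        "level", "n_pairs", "mean_paired_diff", "t",
                                        "p_value", "fdr", "skipped_reason"])
    if fits:
        sigma2 = np.array([f["sigma2"] for f in fits])
        dfs = np.array([f["df"] for f in fits], dtype=float)
        if moderation and len(fits) >= 2 and (sigma2 > 0).any():
            mod = moderate_variances(sigma2, dfs)
            post, df_tot = mod.posterior_var, mod.df_total
        else:
            post, df_tot = sigma2, dfs
        tested = table["skipped_reason"] == ""
        t_vals, p_vals = [], []
        for f, v, dft in zip(fits, post, df_tot):
            denom = f["unit"] * np.sqrt(v)
            if denom == 0:
                t = np.inf if f["beta"] != 0 else 0.0
                p = 0.0 if f["beta"] != 0 else 1.0
            else:
                t = f["beta"] / denom
                p = 2.0 * (sps.norm.sf(abs(t)) if np.isinf(dft) else sps.t.sf(abs(t), dft))
            t_vals.append(t)
            p_vals.append(min(1.0, float(p)))
        table.loc[tested, "t"] = t_vals
        table.loc[tested, "p_value"] = p_vals
        table.loc[tested, "fdr"] = bh_fdr(np.array(p_vals))
    return table
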
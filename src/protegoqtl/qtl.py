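"""Covariate-adjusted per-gene linear model scans (seQTL / spQTL).

For each (gene, functional class) carrier set, the mutated gene's own
expression row (cis) is regressed on a binary carrier indicator plus
covariates (age numeric; gender, ethnicity, TMT batch one-hot with the
reference level dropped). Residual variances are shrunk across the scan by
empirical-Bayes moderation and the indicator coefficient is tested with a
moderated t; Benjamini-Hochberg correction is applied within one family per
cohort x level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CarrierSet, ProteogenomicCohort
from .stats import bh_fdr, moderate_variances

logger = logging.getLogger(__name__)

CATEGORICAL_COVARIATES = ["gender", "ethnicity", "batch"]
NUMERIC_COVARIATES = ["age"]


class UntestableError(ValueError):
    """A carrier set that cannot be tested, with a bookkeeping reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class DesignSpec:
    """A fitted-ready design: response sample order plus the matrix itself.

    ``matrix`` holds an intercept column, the 0/1 ``mutation`` indicator and
    pruned covariate columns, indexed by sample.
    """

    matrix: pd.DataFrame
    samples: list[str]

    @property
    def mutation_column(self) -> str:
        return "mutation"


@dataclass
class GeneFitResult:
    gene: str
    functional_class: str
    level: str
    logFC: float
    stderr: float
    stderr_unit: float  # sqrt of the indicator's (X'X)^-1 diagonal entry
    sigma2: float
    residual_df: int
    n_used: int

    @property
    def t_ordinary(self) -> float:
        if self.stderr == 0:
            return np.inf if self.logFC != 0 else 0.0
        return self.logFC / self.stderr


def build_design(covariates: pd.DataFrame, carrier_set: CarrierSet,
                 samples_with_data) -> DesignSpec:
    """Build the regression design for one carrier set.

    Rows are restricted to ``samples_with_data`` (which must be a subset of
    carriers plus controls); categorical covariates with fewer than two
    observed levels are dropped, as are constant numeric covariates.
    """
    samples = sorted(samples_with_data)
    extra = set(samples) - (set(carrier_set.carriers) | set(carrier_set.controls))
    if extra:
        raise ValueError(f"samples outside carrier/control sets: {sorted(extra)[:5]}")
    indicator = pd.Series(
        [1.0 if s in carrier_set.carriers else 0.0 for s in samples], index=samples)
    if indicator.sum() == len(samples):
        raise UntestableError("all used samples are carriers")
    if indicator.sum() == 0:
        raise UntestableError("all used samples are controls")

    cols: dict[str, pd.Series] = {"intercept": pd.Series(1.0, index=samples),
                                  "mutation": indicator}
    cov = covariates.loc[samples]
    for name in NUMERIC_COVARIATES:
        if name in cov.columns and cov[name].nunique() > 1:
            cols[name] = cov[name].astype(float)
    for name in CATEGORICAL_COVARIATES:
        if name in cov.columns and cov[name].astype(str).nunique() > 1:
            dummies = pd.get_dummies(cov[name].astype(str), prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
    matrix = pd.DataFrame(cols, index=samples)
    return DesignSpec(matrix=matrix, samples=samples)


def fit_gene_model(y, design: DesignSpec, gene: str = "", functional_class: str = "",
                   level: str = "") -> GeneFitResult:
    """Ordinary least squares of a complete-case expression vector on a design.

    ``y`` must be aligned with ``design.samples`` and free of missing values.
    Raises ``UntestableError`` when residual df <= 0 and ``ValueError`` on a
    rank-deficient design (after the pruning done by ``build_design``).
    """
    y = np.asarray(y, dtype=float)
    X = design.matrix.to_numpy(dtype=float)
    n, k = X.shape
    if len(y) != n:
        raise ValueError("response length does not match design rows")
    if np.isnan(y).any():
        raise ValueError("response contains missing values; drop them first")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValueError("rank-deficient design after pruning")
    if n - k <= 0:
        raise UntestableError("no residual degrees of freedom")

    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    j = list(design.matrix.columns).index(design.mutation_column)
    unit = float(np.sqrt(xtx_inv[j, j]))
    return GeneFitResult(
        gene=gene, functional_class=functional_class, level=level,
        logFC=float(beta[j]), stderr=unit * np.sqrt(sigma2), stderr_unit=unit,
        sigma2=sigma2, residual_df=df, n_used=n)


def run_qtl_scan(cohort: ProteogenomicCohort, carrier_sets, level: str,
                 min_carriers: int = 3, min_controls: int = 3,
                 moderation: bool = True) -> pd.DataFrame:
    """Scan all carrier sets at one level ('mrna' or 'protein').

    Returns a table with one row per carrier set: tested rows carry logFC,
    moderated t, p_value and BH fdr (one family per cohort x level); skipped
    rows carry the skip reason. The fitted moderation hyperparameters are
    attached as DataFrame attrs ``d0`` and ``s0_sq``.
    """
    if level not in ("mrna", "protein"):
        raise ValueError("level must be 'mrna' or 'protein'")
    expr = cohort.mrna if level == "mrna" else cohort.protein
    tumors = set(cohort.tumor_samples)

    fits: list[GeneFitResult] = []
    rows: list[dict] = []
    for cs in carrier_sets:
        row = {"cancer_type": cohort.cancer_type, "gene": cs.gene,
               "functional_class": cs.functional_class, "level": level,
               "n_carriers": np.nan, "n_controls": np.nan, "logFC": np.nan,
               "t": np.nan, "p_value": np.nan, "fdr": np.nan, "skipped_reason": ""}
        if cs.gene not in expr.index:
            row["skipped_reason"] = f"no {level} row"
            rows.append(row)
            continue
        y_full = expr.loc[cs.gene]
        usable = (set(cs.carriers) | set(cs.controls)) & tumors
        usable = {s for s in usable if s in y_full.index and not pd.isna(y_full[s])}
        n_car = len(usable & set(cs.carriers))
        n_con = len(usable & set(cs.controls))
        row["n_carriers"], row["n_controls"] = n_car, n_con
        if n_car < min_carriers:
            row["skipped_reason"] = f"fewer than {min_carriers} carriers with data"
            rows.append(row)
            continue
        if n_con < min_controls:
            row["skipped_reason"] = f"fewer than {min_controls} controls with data"
            rows.append(row)
            continue
        try:
            design = build_design(cohort.covariates, cs, usable)
            fit = fit_gene_model(y_full.loc[design.samples].to_numpy(), design,
                                 gene=cs.gene, functional_class=cs.functional_class,
                                 level=level)
        except (UntestableError, ValueError) as exc:
            row["skipped_reason"] = str(exc)
            rows.append(row)
            continue
        row["logFC"] = fit.logFC
        rows.append(row)
        fits.append(fit)

    table = pd.DataFrame(rows, columns=["cancer_type", "gene", "functional_class",
                                        "level", "n_carriers", "n_controls", "logFC",
                                        "t", "p_value", "fdr", "skipped_reason"])
    d0, s0_sq = np.nan, np.nan
    if fits:
        sigma2 = np.array([f.sigma2 for f in fits])
        dfs = np.array([f.residual_df for f in fits], dtype=float)
        if moderation and len(fits) >= 2 and (sigma2 > 0).any():
            mod = moderate_variances(sigma2, dfs)
            d0, s0_sq = mod.d0, mod.s0_sq
            post_var, df_tot = mod.posterior_var, mod.df_total
        else:
            post_var, df_tot = sigma2, dfs

        tested = table["skipped_reason"] == ""
        t_vals, p_vals = [], []
        for f, v, dft in zip(fits, post_var, df_tot):
            denom = f.stderr_unit * np.sqrt(v)
            if denom == 0:
                t = np.inf if f.logFC != 0 else 0.0
                p = 0.0 if f.logFC != 0 else 1.0
            else:
                t = f.logFC / denom
                if np.isinf(dft):
                    p = 2.0 * sps.norm.sf(abs(t))
                else:
                    p = 2.0 * sps.t.sf(abs(t), dft)
            t_vals.append(t)
            p_vals.append(min(1.0, float(p)))
        table.loc[tested, "t"] = t_vals
        table.loc[tested, "p_value"] = p_vals
        table.loc[tested, "fdr"] = bh_fdr(np.array(p_vals))
        n_skip = int((~tested).sum())
        logger.info("%s scan: %d tested, %d skipped", level, len(fits), n_skip)
    table.attrs["d0"] = d0
    table.attrs["s0_sq"] = s0_sq
    table.attrs["level"] = level
    return table
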
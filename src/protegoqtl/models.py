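"""Model/Results presentation layer.

Each analysis stage is exposed as a model object constructed from a cohort
whose ``fit()`` returns a results object carrying the estimates, their
uncertainties, and a ``summary()`` table — the same shape statistical
modelling packages use. The heavy lifting lives in the functional modules
(:mod:`preprocess`, :mod:`qtl`, :mod:`spsqtl`, :mod:`paired`); these classes
wrap them with state, defaults and export helpers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ProteogenomicCohort, load_cohort_dir
from .paired import run_paired_de
from .preprocess import preprocess_cohort
from .qtl import run_qtl_scan
from .spsqtl import call_spsqtls, concordance_effects, run_lrt_scan


class _ResultsBase:
    """Tabular results with TSV export and a printable summary."""

    table: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        raise NotImplementedError


class QTLScanResults(_ResultsBase):
    """One seQTL or spQTL scan: per-(gene, class) effect sizes and FDRs."""

    def __init__(self, table: pd.DataFrame, level: str, alpha: float,
                 d0: float, s0_sq: float):
        self.table = table
        self.level = level
        self.alpha = alpha
        self.d0 = d0
        self.s0_sq = s0_sq

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["skipped_reason"] == ""]

    @property
    def significant(self) -> pd.DataFrame:
        t = self.tested
        return t[t["fdr"] < self.alpha]

    def volcano_table(self) -> pd.DataFrame:
        """logFC vs -log10 FDR, ready for a volcano plot."""
        t = self.tested.copy()
        with np.errstate(divide="ignore"):
            t["neg_log10_fdr"] = -np.log10(t["fdr"])
        return t[["gene", "functional_class", "logFC", "neg_log10_fdr", "fdr"]]

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.volcano_table()
        sig = v["fdr"] < self.alpha
        ax.scatter(v.loc[~sig, "logFC"], v.loc[~sig, "neg_log10_fdr"], s=8, c="grey")
        ax.scatter(v.loc[sig, "logFC"], v.loc[sig, "neg_log10_fdr"], s=10, c="crimson")
        ax.axhline(-np.log10(self.alpha), ls="--", lw=0.8, c="k")
        ax.set_xlabel("logFC (log2)")
        ax.set_ylabel("-log10 FDR")
        ax.set_title(f"{self.level} QTL scan")
        return ax

    def summary(self) -> str:
        t = self.tested
        lines = [
            f"QTL scan ({self.level})",
            f"  tested (gene, class) pairs : {len(t)}",
            f"  skipped                    : {(self.table['skipped_reason'] != '').sum()}",
            f"  significant at FDR<{self.alpha:g}   : {len(self.significant)}",
            f"  moderation prior           : d0={self.d0:.3g}, s0_sq={self.s0_sq:.4g}",
        ]
        return "\n".join(lines)


class SomaticQTLModel:
    """Covariate-adjusted moderated linear-model scan at one molecular level.

    Parameters
    ----------
    cohort, carrier_sets
        A preprocessed cohort and its (gene, class) carrier sets, e.g. from
        :meth:`from_cohort_dir` or :func:`preprocess.preprocess_cohort`.
    level
        'mrna' for the seQTL scan, 'protein' for the spQTL scan.
    moderation
        Empirical-Bayes variance shrinkage across genes (on by default);
        plain OLS t-tests when off.
    """

    def __init__(self, cohort: ProteogenomicCohort, carrier_sets, level: str,
                 min_carriers: int = 3, min_controls: int = 3,
                 moderation: bool = True, alpha: float = 0.05):
        self.cohort = cohort
        self.carrier_sets = list(carrier_sets)
        self.level = level
        self.min_carriers = min_carriers
        self.min_controls = min_controls
        self.moderation = moderation
        self.alpha = alpha

    @classmethod
    def from_cohort_dir(cls, cohort_dir, level: str, min_carriers: int = 3,
                        **kwargs) -> "SomaticQTLModel":
        raw = load_cohort_dir(cohort_dir)
        cohort, carrier_sets = preprocess_cohort(raw, min_carriers=min_carriers)
        return cls(cohort, carrier_sets, level, min_carriers=min_carriers, **kwargs)

    def fit(self) -> QTLScanResults:
        table = run_qtl_scan(self.cohort, self.carrier_sets, self.level,
                             min_carriers=self.min_carriers,
                             min_controls=self.min_controls,
                             moderation=self.moderation)
        return QTLScanResults(table, self.level, self.alpha,
                              table.attrs["d0"], table.attrs["s0_sq"])


class SpsQTLResults(_ResultsBase):
    """spsQTL calls with concordance labels and paired effect sizes."""

    def __init__(self, table: pd.DataFrame, effects: pd.DataFrame, alpha: float):
        self.table = table
        self.effects = effects
        self.alpha = alpha

    @property
    def spsqtls(self) -> pd.DataFrame:
        return self.table[self.table["is_spsqtl"]]

    @property
    def pearson_r_concordant(self) -> float:
        return self.effects.attrs.get("pearson_r_concordant", np.nan)

    def same_sign_fraction(self, significant_only: bool = True) -> float:
        """Fraction of effect pairs with agreeing logFC signs; restricted to
        significant seQTLs by default."""
        eff = self.effects
        if significant_only:
            eff = eff[eff["fdr_rna"] < self.alpha]
        if len(eff) == 0:
            return np.nan
        return float(eff["same_sign"].mean())

    def summary(self) -> str:
        counts = self.table["concordance"].value_counts().to_dict()
        lines = [
            "spsQTL calling",
            f"  (gene, class) pairs in LRT family : {len(self.table)}",
            f"  method 1 (LRT FDR<{self.alpha:g})          : {int(self.table['method1_pass'].sum())}",
            f"  method 2 (overlap filter)         : {int(self.table['method2_pass'].sum())}",
            f"  final spsQTLs (both methods)      : {int(self.table['is_spsqtl'].sum())}",
            f"  concordance labels                : {counts}",
            f"  Pearson r, concordant effect pairs: {self.pearson_r_concordant:.3g}",
        ]
        return "\n".join(lines)


class SpsQTLModel:
    """Protein-specific QTL caller: nested-model LRT x FDR-overlap filter."""

    def __init__(self, cohort: ProteogenomicCohort, carrier_sets,
                 seqtl: QTLScanResults, spqtl: QTLScanResults,
                 alpha: float = 0.05, include_covariates: bool = True,
                 min_carriers: int = 3, min_controls: int = 3):
        if seqtl.level != "mrna" or spqtl.level != "protein":
            raise ValueError("seqtl must be an mrna scan and spqtl a protein scan")
        self.cohort = cohort
        self.carrier_sets = list(carrier_sets)
        self.seqtl = seqtl
        self.spqtl = spqtl
        self.alpha = alpha
        self.include_covariates = include_covariates
        self.min_carriers = min_carriers
        self.min_controls = min_controls

    def fit(self) -> SpsQTLResults:
        lrt = run_lrt_scan(self.cohort, self.carrier_sets,
                           min_carriers=self.min_carriers,
                           min_controls=self.min_controls,
                           include_covariates=self.include_covariates)
        calls = call_spsqtls(lrt, self.spqtl.table[self.spqtl.table["skipped_reason"] == ""],
                             self.seqtl.table[self.seqtl.table["skipped_reason"] == ""],
                             alpha=self.alpha)
        effects = concordance_effects(self.seqtl.table, self.spqtl.table, alpha=self.alpha)
        return SpsQTLResults(calls, effects, self.alpha)


class PairedDEResults(_ResultsBase):
    def __init__(self, table: pd.DataFrame, level: str, alpha: float):
        self.table = table
        self.level = level
        self.alpha = alpha

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["skipped_reason"] == ""]

    def summary(self) -> str:
        t = self.tested
        sig = (t["fdr"] < self.alpha).sum() if len(t) else 0
        return "\n".join([
            f"paired tumor-normal DE ({self.level})",
            f"  tested (gene, class) pairs : {len(t)}",
            f"  significant at FDR<{self.alpha:g}   : {int(sig)}",
        ])


class PairedDEModel:
    """Paired tumor-normal differential expression among mutation carriers."""

    def __init__(self, cohort: ProteogenomicCohort, carrier_sets, level: str,
                 min_pairs: int = 2, carriers_only: bool = True,
                 moderation: bool = True, alpha: float = 0.05):
        self.cohort = cohort
        self.carrier_sets = list(carrier_sets)
        self.level = level
        self.min_pairs = min_pairs
        self.carriers_only = carriers_only
        self.moderation = moderation
        self.alpha = alpha

    def fit(self) -> PairedDEResults:
        table = run_paired_de(self.cohort, self.carrier_sets, self.level,
                              min_pairs=self.min_pairs,
                              carriers_only=self.carriers_only,
                              moderation=self.moderation)
        return PairedDEResults(table, self.level, self.alpha)
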
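"""Normalization, filtering, mutation classification, carrier-set building.

Rules applied here:

* protein matrix — rows with >20% missing values dropped, then every sample
  column divided by its median absolute deviation (computed over non-missing
  entries, no consistency constant, no centering) so each sample has MAD 1;
* mRNA matrix — values transformed to log2(FPKM+1); genes with zero FPKM in
  at least 90% of samples dropped;
* mutations — grouped at the gene level into missense / truncating /
  synonymous functional classes (truncating covers frameshift and in-frame
  indels, nonsense, nonstop, splice-site and translation-start-site events);
* carrier sets — one test unit per (gene, class) with >= 3 distinct tumor
  carriers; controls are tumors carrying no mutation of any class in that
  gene, so carriers of other classes never contaminate the baseline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import CarrierSet, ProteogenomicCohort

logger = logging.getLogger(__name__)

TRUNCATING = {
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Splice_Site",
    "Translation_Start_Site",
}

MISSING_ROW_FRACTION = 0.20
MRNA_ZERO_FRACTION = 0.90
MIN_CARRIERS = 3


def classify_variant(variant_classification: str) -> str:
    """Map a MAF Variant_Classification string to a functional class."""
    vc = (variant_classification or "").strip()
    if not vc:
        logger.debug("empty variant classification -> other")
        return "other"
    if vc == "Missense_Mutation":
        return "missense"
    if vc == "Silent":
        return "synonymous"
    if vc in TRUNCATING:
        return "truncating"
    return "other"


def column_mad(col: pd.Series) -> float:
    """Median absolute deviation from the column median over non-missing entries."""
    vals = col.dropna().to_numpy()
    if len(vals) == 0:
        raise ValueError("column has no observed values")
    return float(np.median(np.abs(vals - np.median(vals))))


def normalize_protein(raw: pd.DataFrame,
                      max_missing_fraction: float = MISSING_ROW_FRACTION,
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Filter high-missingness proteins, then MAD-scale each sample to MAD 1.

    Rows whose missing fraction exceeds ``max_missing_fraction`` are removed
    first; each remaining column is then divided by its raw MAD. A column
    with MAD 0 is degenerate and raises, naming the sample.
    """
    frac_missing = raw.isna().mean(axis=1)
    dropped = list(raw.index[frac_missing > max_missing_fraction])
    kept = raw.drop(index=dropped)
    scaled = kept.copy()
    for sample in kept.columns:
        mad = column_mad(kept[sample])
        if mad == 0:
            raise ValueError(f"sample {sample!r} has zero MAD; cannot scale")
        scaled[sample] = kept[sample] / mad
    return scaled, dropped


def normalize_mrna(fpkm: pd.DataFrame,
                   zero_fraction: float = MRNA_ZERO_FRACTION,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """log2(FPKM+1) transform; drop genes with no expression in >=90% of samples."""
    if (fpkm < 0).any().any():
        bad = fpkm.index[(fpkm < 0).any(axis=1)][0]
        raise ValueError(f"negative FPKM for gene {bad!r}")
    zero_frac = (fpkm == 0).mean(axis=1)
    dropped = list(fpkm.index[zero_frac >= zero_fraction])
    kept = fpkm.drop(index=dropped)
    return np.log2(kept + 1.0), dropped


def classify_mutations(mutations: pd.DataFrame) -> pd.DataFrame:
    out = mutations.copy()
    out["functional_class"] = out["variant_classification"].map(classify_variant)
    return out


def build_carrier_sets(mutations: pd.DataFrame, tumor_samples,
                       min_carriers: int = MIN_CARRIERS) -> list[CarrierSet]:
    """One CarrierSet per (gene, class) with >= min_carriers distinct tumor carriers.

    ``mutations`` must already carry a functional_class column. Records with
    class "other" are excluded from testing but still disqualify their
    samples from the control group of their gene.
    """
    tumors = set(tumor_samples)
    muts = mutations[mutations["sample_id"].isin(tumors)]
    sets: list[CarrierSet] = []
    for gene, gene_muts in muts.groupby("gene", sort=True):
        any_carriers = set(gene_muts["sample_id"])
        controls = frozenset(tumors - any_carriers)
        for fclass, cls_muts in gene_muts.groupby("functional_class", sort=True):
            if fclass == "other":
                continue
            carriers = frozenset(cls_muts["sample_id"])
            if len(carriers) < min_carriers:
                continue
            sets.append(CarrierSet(gene=str(gene), functional_class=str(fclass),
                                   carriers=carriers, controls=controls))
    return sets


def preprocess_cohort(cohort: ProteogenomicCohort,
                      min_carriers: int = MIN_CARRIERS,
                      ) -> tuple[ProteogenomicCohort, list[CarrierSet]]:
    """Apply all normalization/filter rules to a raw cohort.

    Returns a new cohort (log2 mRNA, MAD-scaled protein, classified
    mutations) plus its carrier sets; filter bookkeeping lands in
    ``cohort.log``.
    """
    mrna, mrna_dropped = normalize_mrna(cohort.mrna)
    protein, prot_dropped = normalize_protein(cohort.protein)
    mutations = classify_mutations(cohort.mutations)
    processed = ProteogenomicCohort(
        mrna=mrna, protein=protein, mutations=mutations,
        covariates=cohort.covariates, cancer_type=cohort.cancer_type,
        log={
            "mrna_genes_dropped": mrna_dropped,
            "protein_rows_dropped": prot_dropped,
            "n_mrna_genes": int(mrna.shape[0]),
            "n_proteins": int(protein.shape[0]),
        },
    )
    processed.validate()
    carrier_sets = build_carrier_sets(mutations, processed.tumor_samples, min_carriers)
    processed.log["n_carrier_sets"] = len(carrier_sets)
    return processed, carrier_sets
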
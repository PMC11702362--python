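"""Cohort containers and plain-text IO.

A cohort bundles the four aligned inputs of a somatic QTL analysis for one
cancer type: a gene x sample mRNA matrix, a protein x sample abundance
matrix (missing values allowed), a somatic mutation table, and a per-sample
covariate table (age, gender, ethnicity, TMT batch, tumor/normal flag,
patient of origin).

On disk everything is TSV: matrices carry the feature identifier in the
first column and sample identifiers as remaining columns (empty cell or
"NA" meaning missing); the mutation table uses either the compact
sample_id/gene/variant_classification/protein_change layout or a full MAF
(Tumor_Sample_Barcode, Hugo_Symbol, Variant_Classification, HGVSp_Short).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

MAF_COLUMN_MAP = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_classification",
    "HGVSp_Short": "protein_change",
}

COVARIATE_COLUMNS = ["sample_id", "patient_id", "tissue", "age", "gender", "ethnicity", "batch"]


@dataclass
class MutationRecord:
    sample_id: str
    gene: str
    variant_classification: str
    protein_change: str
    functional_class: str = "other"


@dataclass
class CarrierSet:
    """Carrier/control partition for one (gene, functional class) test."""

    gene: str
    functional_class: str
    carriers: frozenset
    controls: frozenset

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass
class ProteogenomicCohort:
    """Aligned multi-omic data for one cancer cohort.

    ``mrna`` is gene x sample on the log2(FPKM+1) scale after preprocessing;
    ``protein`` is protein x sample MAD-scaled log-ratio with NaN for
    missing; ``mutations`` is a tidy table with one row per mutation record;
    ``covariates`` is indexed by sample_id.
    """

    mrna: pd.DataFrame
    protein: pd.DataFrame
    mutations: pd.DataFrame
    covariates: pd.DataFrame
    cancer_type: str = "SYNTH"
    log: dict = field(default_factory=dict)

    @property
    def tumor_samples(self) -> list[str]:
        cov = self.covariates
        return list(cov.index[cov["tissue"] == "tumor"])

    @property
    def normal_samples(self) -> list[str]:
        cov = self.covariates
        return list(cov.index[cov["tissue"] == "normal"])

    def validate(self) -> None:
        cov_samples = set(self.covariates.index)
        for name, mat in (("mrna", self.mrna), ("protein", self.protein)):
            missing = set(mat.columns) - cov_samples
            if missing:
                raise ValueError(
                    f"{name} matrix has samples without covariate rows: {sorted(missing)[:5]}"
                )

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_matrix(self.mrna, out_dir / "mrna.tsv", "gene")
        _write_matrix(self.protein, out_dir / "protein.tsv", "protein")
        self.mutations.to_csv(out_dir / "mutations.tsv", sep="\t", index=False)
        self.covariates.reset_index().to_csv(out_dir / "covariates.tsv", sep="\t", index=False)


def _write_matrix(mat: pd.DataFrame, path: Path, feature_name: str) -> None:
    out = mat.copy()
    out.index.name = feature_name
    out.to_csv(path, sep="\t", na_rep="")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix; '' or 'NA' become NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df.astype(float)


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a mutation table (compact TSV or full MAF); returns tidy columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if "Tumor_Sample_Barcode" in df.columns:
        df = df.rename(columns=MAF_COLUMN_MAP)
    needed = ["sample_id", "gene", "variant_classification"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table {path} lacks columns {missing}")
    if "protein_change" not in df.columns:
        df["protein_change"] = ""
    return df[needed + ["protein_change"]].copy()


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"covariate table {path} lacks sample_id")
    df = df.set_index("sample_id")
    if "tissue" not in df.columns:
        df["tissue"] = "tumor"
    return df


def load_cohort_dir(cohort_dir: str | Path, cancer_type: str = "SYNTH") -> ProteogenomicCohort:
    """Load the raw (un-normalized) cohort files written by the simulator
    or assembled by hand. Normalization is applied by ``preprocess``."""
    d = Path(cohort_dir)
    for fname in ("mrna.tsv", "protein.tsv", "mutations.tsv", "covariates.tsv"):
        if not (d / fname).exists():
            raise FileNotFoundError(f"required cohort file missing: {d / fname}")
    cohort = ProteogenomicCohort(
        mrna=read_matrix(d / "mrna.tsv"),
        protein=read_matrix(d / "protein.tsv"),
        mutations=read_mutations(d / "mutations.tsv"),
        covariates=read_covariates(d / "covariates.tsv"),
        cancer_type=cancer_type,
    )
    cohort.validate()
    return cohort
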
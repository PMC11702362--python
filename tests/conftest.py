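import numpy as np
import pandas as pd
import pytest

from protegoqtl import CohortConfig, generate_cohort, preprocess_cohort
from protegoqtl.cohort import ProteogenomicCohort


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort plus truth, shared read-only."""
    cohort, truth = generate_cohort(CohortConfig(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def processed_sim(default_sim):
    cohort, truth = default_sim
    processed, carrier_sets = preprocess_cohort(cohort)
    return processed, carrier_sets, truth


def build_toy_cohort():
    """Hand-built 12-tumor cohort with scripted filter edge cases.

    Samples S01..S12, all tumors, covariates all constant so every retained
    design is exactly [intercept, mutation].
    Genes:
      GENE_OK   - clean expression, 4 missense carriers, 3 truncating carriers
      GENE_FEW  - only 2 missense carriers (below the >=3 rule)
      GENE_DUP  - 3 mutation records but all in one sample
      GENE_MISS - protein row with 4/12 missing (>20%, dropped)
      GENE_ZERO - mRNA zero FPKM in 11/12 samples (>=90%, dropped)
      GENE_EDGE - mRNA zero FPKM in 10/12 samples (~83%, retained)
    """
    samples = [f"S{i:02d}" for i in range(1, 13)]
    rng = np.random.default_rng(42)
    genes = ["GENE_OK", "GENE_FEW", "GENE_DUP", "GENE_MISS", "GENE_ZERO", "GENE_EDGE"]
    fpkm = pd.DataFrame(rng.uniform(1, 20, size=(6, 12)), index=genes, columns=samples)
    fpkm.loc["GENE_ZERO", samples[:11]] = 0.0
    fpkm.loc["GENE_EDGE", samples[:10]] = 0.0
    protein = pd.DataFrame(rng.normal(0, 1.5, size=(6, 12)), index=genes, columns=samples)
    protein.loc["GENE_MISS", samples[:4]] = np.nan

    muts = []
    for s in ["S01", "S02", "S03", "S04"]:
        muts.append((s, "GENE_OK", "Missense_Mutation", "p.R175H"))
    for s in ["S05", "S06", "S07"]:
        muts.append((s, "GENE_OK", "Nonsense_Mutation", "p.R196*"))
    for s in ["S01", "S02"]:
        muts.append((s, "GENE_FEW", "Missense_Mutation", "p.G12D"))
    for _ in range(3):
        muts.append(("S08", "GENE_DUP", "Missense_Mutation", "p.V600E"))
    for s in ["S09", "S10", "S11"]:
        muts.append((s, "GENE_MISS", "Missense_Mutation", "p.A100T"))
        muts.append((s, "GENE_ZERO", "Frame_Shift_Del", "p.K50fs"))
        muts.append((s, "GENE_EDGE", "Silent", "p.L25L"))
    mutations = pd.DataFrame(
        muts, columns=["sample_id", "gene", "variant_classification", "protein_change"])

    covariates = pd.DataFrame({
        "sample_id": samples,
        "patient_id": [f"P{i:02d}" for i in range(1, 13)],
        "tissue": "tumor",
        "age": 60,
        "gender": "female",
        "ethnicity": "groupA",
        "batch": "B1",
    }).set_index("sample_id")
    return ProteogenomicCohort(mrna=fpkm, protein=protein, mutations=mutations,
                               covariates=covariates, cancer_type="TOY")


@pytest.fixture
def toy_cohort():
    return build_toy_cohort()
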
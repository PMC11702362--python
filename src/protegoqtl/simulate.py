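"""Synthetic proteogenomic cohort generator with ground truth.

Emulates the statistical structure the QTL analysis assumes: per-gene
latent mRNA-protein correlation, sparse gene-level somatic mutations in
three functional classes, covariate and TMT-batch structure, MCAR protein
missingness, paired tumor-normal samples, and injected mutation effects of
four kinds (null, concordant, mRNA-only, protein-only).

Generation model, per gene g and tumor sample s (all on log2 scales):

    m_gs = b_g + noise_sd * eps            (latent log2 mRNA)
    p_gs = c_g + rho_g (m_gs - b_g) + sqrt(1 - rho_g^2) noise_sd eps'
           + batch_offset(s)               (log-ratio protein)

so cor(m, p) = rho_g and both residual scales equal ``noise_sd``.
Mutation effects of signed magnitude ``effect_size`` are added to carrier
entries: concordant genes receive the delta on mRNA (which propagates
rho*delta to protein) topped up by (1-rho)*delta on protein, so the
realized log fold change is the full delta at both levels; mRNA-only genes
have rho forced to 0 and receive the delta on mRNA alone; protein-only
genes receive it on protein alone. The written mRNA matrix is
FPKM = 2^m - 1 so the downstream log2(FPKM+1) transform recovers the
latent values; the protein matrix is written on its native log-ratio
scale. Paired normals redraw the patient's baseline without any injected
effect or mutation record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ProteogenomicCohort

FUNCTIONAL_CLASSES = ("missense", "truncating", "synonymous")
EFFECT_CLASSES = ("null", "concordant", "mrna_only", "protein_only")

# MAF vocabulary used when writing mutation records, keyed by class
_VARIANT_POOL = {
    "missense": ["Missense_Mutation"],
    "synonymous": ["Silent"],
    "truncating": [
        "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
        "Nonsense_Mutation", "Splice_Site", "Translation_Start_Site",
    ],
}

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CohortConfig:
    """Tunable study conditions for one synthetic cohort.

    Defaults mirror a mid-sized TMT tumor cohort: ~100 tumors with a
    minority of paired normals, a few hundred testable genes, sparse
    gene-level mutation rates, moderate mRNA-protein coupling and log2
    residual noise of 0.5.
    """

    n_tumor: int = 100
    n_paired_normal: int = 20
    n_genes: int = 300
    carrier_rate: float = 0.05
    class_mix: dict = field(default_factory=lambda: {
        "missense": 0.5, "truncating": 0.3, "synonymous": 0.2})
    rho_range: tuple = (0.2, 0.8)
    effect_classes: dict = field(default_factory=lambda: {
        "null": 0.7, "concordant": 0.1, "mrna_only": 0.1, "protein_only": 0.1})
    effect_size: float = 2.0
    missing_rate: float = 0.1
    n_batches: int = 4
    batch_sd: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    # secondary knobs (baseline scales, in log2 units)
    mrna_baseline_mean: float = 5.0
    mrna_baseline_sd: float = 1.0
    protein_baseline_sd: float = 1.4

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_tumor < 4:
            raise ValueError("n_tumor must be at least 4")
        if not 0 <= self.n_paired_normal <= self.n_tumor:
            raise ValueError("n_paired_normal must lie in [0, n_tumor]")
        for name, probs, keys in (
            ("class_mix", self.class_mix, FUNCTIONAL_CLASSES),
            ("effect_classes", self.effect_classes, EFFECT_CLASSES),
        ):
            unknown = set(probs) - set(keys)
            if unknown:
                raise ValueError(f"{name} has unknown keys {unknown}")
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"{name} probabilities must lie in [0,1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("carrier_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        lo, hi = self.rho_range
        if not -1 <= lo <= hi <= 1:
            raise ValueError("rho_range must be an interval within [-1, 1]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rho_range" in raw:
            raw["rho_range"] = tuple(raw["rho_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["rho_range"] = list(self.rho_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def apply_effect(expr_row: pd.Series, carriers, delta: float) -> pd.Series:
    """Return a copy of ``expr_row`` with ``delta`` added to carrier entries.

    Non-carrier entries are returned bit-identical. Unknown carrier sample
    identifiers raise.
    """
    carriers = set(carriers)
    unknown = carriers - set(expr_row.index)
    if unknown:
        raise KeyError(f"unknown samples in carrier set: {sorted(unknown)}")
    out = expr_row.copy()
    if carriers:
        idx = list(carriers)
        out.loc[idx] = out.loc[idx] + delta
    return out


def generate_cohort(config: CohortConfig) -> tuple[ProteogenomicCohort, pd.DataFrame]:
    """Draw one synthetic cohort plus its ground-truth table.

    Returns the raw cohort (mRNA in FPKM, protein on the log-ratio scale,
    unclassified mutation records) exactly as the TSV writers emit it, and
    a truth DataFrame with one row per (gene, functional class) that has at
    least one carrier: columns gene, functional_class, effect_class,
    delta_mrna, delta_protein, rho, n_carriers. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nt, ng = config.n_tumor, config.n_genes

    tumor_ids = [f"T{i+1:04d}" for i in range(nt)]
    patient_ids = [f"P{i+1:04d}" for i in range(nt)]
    normal_ids = [f"N{i+1:04d}" for i in range(config.n_paired_normal)]
    genes = [f"G{i+1:05d}" for i in range(ng)]

    # per-patient covariates; batch is assigned per sample (TMT plexes mix
    # tumors and normals in practice)
    age = rng.integers(35, 85, size=nt)
    gender = rng.choice(["female", "male"], size=nt)
    ethnicity = rng.choice(["groupA", "groupB", "groupC"], size=nt, p=[0.6, 0.25, 0.15])
    batches = [f"B{b+1}" for b in rng.integers(0, config.n_batches, size=nt)]
    normal_batches = [f"B{b+1}" for b in rng.integers(0, config.n_batches,
                                                      size=config.n_paired_normal)]
    cov_rows = []
    for i, s in enumerate(tumor_ids):
        cov_rows.append((s, patient_ids[i], "tumor", age[i], gender[i], ethnicity[i], batches[i]))
    for i, s in enumerate(normal_ids):
        cov_rows.append((s, patient_ids[i], "normal", age[i], gender[i], ethnicity[i],
                         normal_batches[i]))
    covariates = pd.DataFrame(
        cov_rows, columns=["sample_id", "patient_id", "tissue", "age", "gender",
                           "ethnicity", "batch"]).set_index("sample_id")

    batch_offset = {f"B{b+1}": o for b, o in
                    enumerate(rng.normal(0.0, config.batch_sd, size=config.n_batches))}
    tumor_boff = np.array([batch_offset[b] for b in batches])
    normal_boff = np.array([batch_offset[b] for b in normal_batches])

    # per-gene latents
    b_m = rng.normal(config.mrna_baseline_mean, config.mrna_baseline_sd, size=ng)
    c_p = rng.normal(0.0, config.protein_baseline_sd, size=ng)
    lo, hi = config.rho_range
    rho = rng.uniform(lo, hi, size=ng)
    eff_names = list(config.effect_classes)
    eff_probs = np.array([config.effect_classes[k] for k in eff_names])
    effect_class = rng.choice(eff_names, size=ng, p=eff_probs)
    rho[effect_class == "mrna_only"] = 0.0  # sever protein's dependence on mRNA
    sign = rng.choice([-1.0, 1.0], size=ng)

    # carriers: per (gene, tumor), then a functional class per mutation
    carrier_mask = rng.random((ng, nt)) < config.carrier_rate
    cls_names = list(config.class_mix)
    cls_probs = np.array([config.class_mix[k] for k in cls_names])
    carrier_class = np.full((ng, nt), "", dtype=object)
    draw = rng.choice(cls_names, size=(ng, nt), p=cls_probs)
    carrier_class[carrier_mask] = draw[carrier_mask]

    # latent tumor matrices
    m = b_m[:, None] + config.noise_sd * rng.standard_normal((ng, nt))
    delta_m = np.zeros(ng)
    delta_p = np.zeros(ng)
    is_conc = effect_class == "concordant"
    is_mrna = effect_class == "mrna_only"
    is_prot = effect_class == "protein_only"
    delta_m[is_conc | is_mrna] = (sign * config.effect_size)[is_conc | is_mrna]
    delta_p[is_conc | is_prot] = (sign * config.effect_size)[is_conc | is_prot]
    m = m + carrier_mask * delta_m[:, None]

    eps_p = rng.standard_normal((ng, nt))
    p = (c_p[:, None] + rho[:, None] * (m - b_m[:, None])
         + np.sqrt(1.0 - rho[:, None] ** 2) * config.noise_sd * eps_p
         + tumor_boff[None, :])
    # top up protein so the realized carrier logFC equals the full delta:
    # concordant genes already inherit rho*delta through the mRNA term
    topup = np.where(is_conc, (1.0 - rho) * delta_p, delta_p)
    p = p + carrier_mask * topup[:, None]

    # paired normals: same gene baselines, no effects, no mutations
    nn = config.n_paired_normal
    if nn:
        m_n = b_m[:, None] + config.noise_sd * rng.standard_normal((ng, nn))
        p_n = (c_p[:, None] + rho[:, None] * (m_n - b_m[:, None])
               + np.sqrt(1.0 - rho[:, None] ** 2) * config.noise_sd
               * rng.standard_normal((ng, nn))
               + normal_boff[None, :])
    else:
        m_n = np.empty((ng, 0))
        p_n = np.empty((ng, 0))

    m_all = np.clip(np.concatenate([m, m_n], axis=1), 0.0, None)
    p_all = np.concatenate([p, p_n], axis=1)
    if config.missing_rate > 0:
        miss = rng.random(p_all.shape) < config.missing_rate
        p_all = np.where(miss, np.nan, p_all)

    all_samples = tumor_ids + normal_ids
    fpkm = pd.DataFrame(np.exp2(m_all) - 1.0, index=genes, columns=all_samples)
    protein = pd.DataFrame(p_all, index=genes, columns=all_samples)

    # mutation records and truth rows
    mut_rows = []
    truth_rows = []
    for gi, gene in enumerate(genes):
        cols = np.flatnonzero(carrier_mask[gi])
        if len(cols) == 0:
            continue
        per_class: dict[str, int] = {}
        for si in cols:
            fclass = carrier_class[gi, si]
            per_class[fclass] = per_class.get(fclass, 0) + 1
            pool = _VARIANT_POOL[fclass]
            vc = pool[int(rng.integers(0, len(pool)))]
            pchange = (f"p.{_AMINO[int(rng.integers(0, 20))]}"
                       f"{int(rng.integers(1, 500))}"
                       f"{_AMINO[int(rng.integers(0, 20))]}")
            mut_rows.append((tumor_ids[si], gene, vc, pchange))
        for fclass in sorted(per_class):
            truth_rows.append((gene, fclass, effect_class[gi],
                               delta_m[gi], delta_p[gi], rho[gi], per_class[fclass]))

    mutations = pd.DataFrame(
        mut_rows, columns=["sample_id", "gene", "variant_classification", "protein_change"])
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "functional_class", "effect_class",
                             "delta_mrna", "delta_protein", "rho", "n_carriers"])

    cohort = ProteogenomicCohort(mrna=fpkm, protein=protein, mutations=mutations,
                                 covariates=covariates, cancer_type="SYNTH")
    cohort.validate()
    return cohort, truth


def write_cohort(cohort: ProteogenomicCohort, truth: pd.DataFrame,
                 out_dir: str | Path, config: CohortConfig | None = None) -> None:
    """Write cohort TSVs plus truth table (and config YAML) to a directory."""
    out = Path(out_dir)
    cohort.write(out)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    if config is not None:
        config.to_yaml(out / "config.yaml")
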
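"""Calibration and recovery experiments on synthetic cohorts.

These routines run the full pipeline on simulated cohorts whose truth is
known and summarize how well it behaves: type-I error calibration on
null-only cohorts, sensitivity/specificity of the spsQTL recovery matrix,
directional concordance of effect sizes, and recovery of the variance-prior
hyperparameters from scaled-F draws. They back both the package's own
validation suite and reproducibility scripts.
"""

from __future__ import annotations

import numpy as np

from .models import SomaticQTLModel, SpsQTLModel
from .preprocess import preprocess_cohort
from .simulate import CohortConfig, generate_cohort
from .stats import fit_variance_prior


def _seed_for(base_seed: int, i: int) -> int:
    return (base_seed * 100_003 + 7919 * i + 1) % (2**31)


def null_calibration(n_seeds: int = 20, n_tumor: int = 150, n_genes: int = 300,
                     base_seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of both scans on cohorts with no injected effects.

    Single-class mutations at a carrier rate high enough that essentially
    every gene is testable, giving ~n_genes gene-class sets per seed.
    Returns pooled fractions of raw p < alpha and of BH discoveries at
    FDR < alpha per level, plus per-seed arrays.
    """
    per_seed: dict[str, list] = {f"{lv}_{k}": [] for lv in ("mrna", "protein")
                                 for k in ("p_frac", "bh_frac", "n")}
    for i in range(n_seeds):
        cfg = CohortConfig(
            n_tumor=n_tumor, n_genes=n_genes, n_paired_normal=0,
            carrier_rate=0.1,
            class_mix={"missense": 1.0, "truncating": 0.0, "synonymous": 0.0},
            effect_classes={"null": 1.0, "concordant": 0.0,
                            "mrna_only": 0.0, "protein_only": 0.0},
            seed=_seed_for(base_seed, i))
        cohort, _ = generate_cohort(cfg)
        proc, sets = preprocess_cohort(cohort)
        for level in ("mrna", "protein"):
            res = SomaticQTLModel(proc, sets, level, alpha=alpha).fit()
            tested = res.tested
            per_seed[f"{level}_p_frac"].append(float((tested["p_value"] < alpha).mean()))
            per_seed[f"{level}_bh_frac"].append(float((tested["fdr"] < alpha).mean()))
            per_seed[f"{level}_n"].append(int(len(tested)))
    out = {k: np.asarray(v) for k, v in per_seed.items()}
    for level in ("mrna", "protein"):
        n = out[f"{level}_n"]
        out[f"{level}_p_frac_pooled"] = float(
            (out[f"{level}_p_frac"] * n).sum() / n.sum())
        out[f"{level}_bh_frac_pooled"] = float(
            (out[f"{level}_bh_frac"] * n).sum() / n.sum())
        out[f"{level}_n_total"] = int(n.sum())
    return out


def recovery_config(seed: int, n_tumor: int = 150, n_genes: int = 120) -> CohortConfig:
    """Study conditions for the effect-class recovery experiments: strong
    effects (2 log2 units) over residual noise 0.5, carrier counts mostly
    >= 10 at a 10% carrier rate."""
    return CohortConfig(
        n_tumor=n_tumor, n_genes=n_genes, n_paired_normal=0, carrier_rate=0.1,
        effect_size=2.0, noise_sd=0.5, missing_rate=0.05,
        class_mix={"missense": 1.0, "truncating": 0.0, "synonymous": 0.0},
        effect_classes={"null": 0.4, "concordant": 0.2,
                        "mrna_only": 0.2, "protein_only": 0.2},
        seed=seed)


def effect_recovery(n_seeds: int = 20, base_seed: int = 0, alpha: float = 0.05,
                    min_truth_carriers: int = 10) -> dict:
    """Recovery matrix over synthetic cohorts with injected effects.

    For truth rows with at least ``min_truth_carriers`` carriers and a
    testable record at both levels, measures: concordant genes significant
    at both levels (and labeled concordant); protein-only genes called
    spsQTL; concordant and mRNA-only genes mislabeled spsQTL; the same-sign
    fraction among significant seQTLs; and the Pearson r of effect sizes
    across concordant pairs.
    """
    counts = {k: [0, 0] for k in  # [hits, n]
              ("concordant_both", "concordant_label", "protein_only_sps",
               "concordant_sps", "mrna_only_sps")}
    same_sign_hits, same_sign_n = 0, 0
    r_values = []
    for i in range(n_seeds):
        cohort, truth = generate_cohort(recovery_config(_seed_for(base_seed, 10_000 + i)))
        proc, sets = preprocess_cohort(cohort)
        se = SomaticQTLModel(proc, sets, "mrna", alpha=alpha).fit()
        sp = SomaticQTLModel(proc, sets, "protein", alpha=alpha).fit()
        sps = SpsQTLModel(proc, sets, se, sp, alpha=alpha).fit()
        merged = sps.table.merge(truth, on=["gene", "functional_class"])
        testable = merged[(merged["concordance"] != "untestable")
                          & (merged["n_carriers"] >= min_truth_carriers)]
        conc = testable[testable["effect_class"] == "concordant"]
        counts["concordant_both"][0] += int(((conc["seqtl_fdr"] < alpha)
                                             & (conc["spqtl_fdr"] < alpha)).sum())
        counts["concordant_both"][1] += len(conc)
        counts["concordant_label"][0] += int((conc["concordance"] == "concordant").sum())
        counts["concordant_label"][1] += len(conc)
        counts["concordant_sps"][0] += int(conc["is_spsqtl"].sum())
        counts["concordant_sps"][1] += len(conc)
        prot = testable[testable["effect_class"] == "protein_only"]
        counts["protein_only_sps"][0] += int(prot["is_spsqtl"].sum())
        counts["protein_only_sps"][1] += len(prot)
        mrna = testable[testable["effect_class"] == "mrna_only"]
        counts["mrna_only_sps"][0] += int(mrna["is_spsqtl"].sum())
        counts["mrna_only_sps"][1] += len(mrna)

        eff = sps.effects
        sig = eff[eff["fdr_rna"] < alpha]
        same_sign_hits += int(sig["same_sign"].sum())
        same_sign_n += len(sig)
        if not np.isnan(sps.pearson_r_concordant):
            r_values.append(sps.pearson_r_concordant)

    out = {}
    for k, (h, n) in counts.items():
        out[f"{k}_rate"] = h / n if n else np.nan
        out[f"{k}_n"] = n
    out["seqtl_same_sign_fraction"] = same_sign_hits / same_sign_n if same_sign_n else np.nan
    out["seqtl_same_sign_n"] = same_sign_n
    out["concordant_logfc_pearson_r"] = float(np.mean(r_values)) if r_values else np.nan
    out["n_seeds"] = n_seeds
    return out


def directional_concordance(n_seeds: int = 10, base_seed: int = 0,
                            alpha: float = 0.05) -> dict:
    """Same-sign fraction of protein vs mRNA effects among significant
    seQTLs, on cohorts whose injected effects are concordant.

    Mirrors the qualitative expectation that mutation effects found at the
    mRNA level point the same way at the protein level when the underlying
    biology is concordant; mRNA-only and protein-only effects are excluded
    from the generating mixture here by design.
    """
    hits, n = 0, 0
    r_values = []
    for i in range(n_seeds):
        cfg = CohortConfig(
            n_tumor=150, n_genes=120, n_paired_normal=0, carrier_rate=0.1,
            effect_size=2.0, noise_sd=0.5, missing_rate=0.05,
            class_mix={"missense": 1.0, "truncating": 0.0, "synonymous": 0.0},
            effect_classes={"null": 0.7, "concordant": 0.3,
                            "mrna_only": 0.0, "protein_only": 0.0},
            seed=_seed_for(base_seed, 20_000 + i))
        cohort, _ = generate_cohort(cfg)
        proc, sets = preprocess_cohort(cohort)
        se = SomaticQTLModel(proc, sets, "mrna", alpha=alpha).fit()
        sp = SomaticQTLModel(proc, sets, "protein", alpha=alpha).fit()
        from .spsqtl import concordance_effects

        eff = concordance_effects(se.table, sp.table, alpha=alpha)
        sig = eff[eff["fdr_rna"] < alpha]
        hits += int(sig["same_sign"].sum())
        n += len(sig)
        r = eff.attrs.get("pearson_r_concordant", np.nan)
        if not np.isnan(r):
            r_values.append(r)
    return {
        "same_sign_fraction": hits / n if n else np.nan,
        "n_significant_seqtls": n,
        "concordant_logfc_pearson_r": float(np.mean(r_values)) if r_values else np.nan,
        "n_seeds": n_seeds,
    }


def moderation_recovery(n_genes: int = 5000, d0_true: float = 4.0,
                        s0_true: float = 1.0, df_gene: float = 10.0,
                        seed: int = 0) -> dict:
    """Draw variances from the scaled-F marginal with known hyperparameters
    and measure the relative error of the moment-matching fit."""
    rng = np.random.default_rng(seed)
    chi_num = rng.chisquare(df_gene, size=n_genes) / df_gene
    chi_den = rng.chisquare(d0_true, size=n_genes) / d0_true
    s2 = s0_true * chi_num / chi_den
    d0_hat, s0_hat = fit_variance_prior(s2, np.full(n_genes, df_gene))
    return {
        "d0_hat": d0_hat, "s0_sq_hat": s0_hat,
        "d0_relative_error": abs(d0_hat - d0_true) / d0_true,
        "s0_sq_relative_error": abs(s0_hat - s0_true) / s0_true,
        "n_genes": n_genes,
    }
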
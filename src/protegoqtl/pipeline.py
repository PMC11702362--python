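"""End-to-end pipeline: preprocess -> scans -> spsQTL -> validation stages.

Writes every stage table as TSV plus a JSON manifest (config hash, row
counts, skip-reason tallies) so a run is fully reconstructable from its
output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import load_cohort_dir
from .correlation import correlation_stage
from .functional import (categorize_mutations, compare_functional_scores,
                         mutation_expression_percentile, read_functional_scores)
from .models import PairedDEModel, SomaticQTLModel, SpsQTLModel
from .preprocess import preprocess_cohort


@dataclass
class RunConfig:
    cohort_dir: str
    out_dir: str
    cancer_type: str = "SYNTH"
    alpha: float = 0.05
    min_carriers: int = 3
    min_controls: int = 3
    moderation: bool = True
    lrt_covariates: bool = True
    functional_scores_path: str | None = None
    functional_gene: str = "TP53"
    functional_level: str = "protein"
    top_fraction: float = 0.2
    percentile_ref: str = "samples"
    seed: int | None = None  # used only when the cohort is simulated upstream
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_carriers < 2:
            raise ValueError("min_carriers must be >= 2")


def _skip_counts(table: pd.DataFrame) -> dict:
    col = table.get("skipped_reason")
    if col is None:
        return {}
    return {k: int(v) for k, v in col[col != ""].value_counts().items()}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on one cohort directory; return the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    raw = load_cohort_dir(config.cohort_dir, cancer_type=config.cancer_type)
    cohort, carrier_sets = preprocess_cohort(raw, min_carriers=config.min_carriers)

    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "preprocess": dict(cohort.log),
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    def record(name: str, table: pd.DataFrame, fname: str) -> None:
        table.to_csv(out / fname, sep="\t", index=False)
        manifest["stages"][name] = {
            "file": fname, "rows": int(len(table)), "skips": _skip_counts(table)}

    common = dict(min_carriers=config.min_carriers, min_controls=config.min_controls,
                  moderation=config.moderation, alpha=config.alpha)
    seqtl = SomaticQTLModel(cohort, carrier_sets, "mrna", **common).fit()
    spqtl = SomaticQTLModel(cohort, carrier_sets, "protein", **common).fit()
    record("seqtl", seqtl.table, "seqtl.tsv")
    record("spqtl", spqtl.table, "spqtl.tsv")
    seqtl.volcano_table().to_csv(out / "seqtl_volcano.tsv", sep="\t", index=False)
    spqtl.volcano_table().to_csv(out / "spqtl_volcano.tsv", sep="\t", index=False)
    manifest["stages"]["seqtl"]["significant"] = int(len(seqtl.significant))
    manifest["stages"]["spqtl"]["significant"] = int(len(spqtl.significant))

    sps = SpsQTLModel(cohort, carrier_sets, seqtl, spqtl, alpha=config.alpha,
                      include_covariates=config.lrt_covariates,
                      min_carriers=config.min_carriers,
                      min_controls=config.min_controls).fit()
    record("spsqtl", sps.table, "spsqtl.tsv")
    record("concordance_effects", sps.effects, "concordance_effects.tsv")
    manifest["stages"]["spsqtl"]["n_spsqtl"] = int(sps.table["is_spsqtl"].sum())
    manifest["stages"]["spsqtl"]["pearson_r_concordant"] = (
        None if pd.isna(sps.pearson_r_concordant) else float(sps.pearson_r_concordant))

    if cohort.normal_samples:
        for level in ("mrna", "protein"):
            pde = PairedDEModel(cohort, carrier_sets, level,
                                moderation=config.moderation, alpha=config.alpha).fit()
            record(f"paired_de_{level}", pde.table, f"paired_de_{level}.tsv")
    else:
        manifest["stages"]["paired_de"] = {"skipped": "no normal samples"}

    corr, corr_tests = correlation_stage(cohort, sps.table)
    record("correlation", corr, "gene_correlations.tsv")
    record("correlation_tests", corr_tests, "correlation_tests.tsv")

    if config.functional_scores_path:
        scores = read_functional_scores(config.functional_scores_path)
        gene = config.functional_gene
        expr = cohort.protein if config.functional_level == "protein" else cohort.mrna
        if gene in expr.index:
            summaries = mutation_expression_percentile(
                expr.loc[gene, cohort.tumor_samples], cohort.mutations, gene,
                level=config.functional_level, cancer_type=config.cancer_type)
            observed = set(summaries["protein_change"])
            assayed = set(scores["protein_change"])
            partition = categorize_mutations(summaries, observed, assayed,
                                             top_fraction=config.top_fraction)
            tests = pd.concat([compare_functional_scores(partition, scores, sn)
                               for sn in sorted(scores["score_name"].unique())],
                              ignore_index=True)
            record("functional_summaries", summaries, "functional_summaries.tsv")
            record("functional_tests", tests, "functional_tests.tsv")
            manifest["stages"]["functional"] = {
                "gene": gene,
                "group_sizes": {k: len(v) for k, v in partition.items()}}
        else:
            manifest["stages"]["functional"] = {"skipped": f"gene {gene} has no "
                                                f"{config.functional_level} row"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
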
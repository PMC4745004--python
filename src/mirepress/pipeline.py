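"""End-to-end orchestration of the four-step repression workflow.

Steps, mirroring the per-sample-versus-control study design:

1. TPM-normalize every profile and average the control samples into a
   single comparator profile.
2. Apportion each sample's miRNA abundance over the interaction network
   into per-gene repression masses (and per-pair contributions).
3. Test every tumor sample against the averaged control with the pooled
   two-proportion z-test, at gene and interaction level.
4. Per sample, test the significant genes for pathway over-representation;
   intersect the enriched pathways across samples; restrict the
   differential tables to the overlapped pathways and collect the miRNAs
   and mRNAs recurrent in all samples.

Each tumor sample is deliberately compared on its own against the single
averaged control (no pooled test), and recurrence is taken across the
per-sample results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import io as mio
from .datatypes import (
    ContributionTable,
    DifferentialTable,
    EnrichmentResult,
    ExpressionProfile,
    InteractionTable,
    NormalizedProfile,
    PathwayCollection,
    RecurrenceSummary,
    RepressionResult,
)
from .differential import differential_interactions, differential_repression
from .normalization import average_controls, tpm_normalize
from .pathways import hypergeom_enrich, overlapped_pathways, recurrent_elements, restrict_to_pathways
from .repression import interaction_contributions, repression_scores, target_weights

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "analyze", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """File-based pipeline configuration (YAML-loadable)."""

    profiles: str
    interactions: str
    gene_sets: str
    control_samples: tuple[str, ...]
    test_samples: tuple[str, ...]
    outdir: str = "mirepress_out"
    alpha: float = 0.05
    enrich_alpha: float = 0.05
    adjust: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        control = tuple(self.control_samples)
        test = tuple(self.test_samples)
        if not control or not test:
            raise ValueError("control_samples and test_samples must be non-empty")
        if set(control) & set(test):
            raise ValueError("control and test sample sets must be disjoint")
        object.__setattr__(self, "control_samples", control)
        object.__setattr__(self, "test_samples", test)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass(frozen=True)
class PipelineResult:
    """In-memory results of every stage."""

    control_profile: NormalizedProfile
    tpm_profiles: tuple[NormalizedProfile, ...]
    control_repression: RepressionResult
    control_contributions: ContributionTable
    repression: Mapping[str, RepressionResult]
    contributions: Mapping[str, ContributionTable]
    diff_genes: Mapping[str, DifferentialTable]
    diff_interactions: Mapping[str, DifferentialTable]
    enrichment: Mapping[str, EnrichmentResult]
    overlapped: frozenset[str]
    recurrent_mrnas: RecurrenceSummary
    recurrent_mirnas: RecurrenceSummary
    universe: frozenset[str]

    def stage_counts(self) -> dict[str, object]:
        return {
            "n_test_samples": len(self.repression),
            "n_universe_genes": len(self.universe),
            "n_significant_genes": {
                s: int(t.rows["significant"].sum()) for s, t in self.diff_genes.items()
            },
            "n_significant_interactions": {
                s: int(t.rows["significant"].sum()) for s, t in self.diff_interactions.items()
            },
            "n_enriched_pathways": {
                s: len(r.enriched_ids) for s, r in self.enrichment.items()
            },
            "overlapped_pathways": sorted(self.overlapped),
            "n_recurrent_mrnas": len(self.recurrent_mrnas.intersection),
            "n_recurrent_mirnas": len(self.recurrent_mirnas.intersection),
        }


def analyze(
    profiles: Sequence[ExpressionProfile],
    interactions: InteractionTable,
    pathways: PathwayCollection,
    control_ids: Sequence[str],
    test_ids: Sequence[str],
    alpha: float = 0.05,
    enrich_alpha: float = 0.05,
    adjust: bool = False,
    universe: set[str] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory objects.

    The enrichment universe defaults to the genes of the interaction table
    that are annotated to at least one pathway.
    """
    by_id = {p.sample_id: p for p in profiles}
    missing = [s for s in list(control_ids) + list(test_ids) if s not in by_id]
    if missing:
        raise ValueError(f"sample id(s) not found in profiles: {missing}")

    tpm = {sid: tpm_normalize(by_id[sid]) for sid in by_id}
    control = average_controls([tpm[s] for s in control_ids])
    weights = target_weights(interactions)

    control_rep = repression_scores(control, weights)
    control_contrib = interaction_contributions(control, weights)
    repression = {s: repression_scores(tpm[s], weights) for s in test_ids}
    contributions = {s: interaction_contributions(tpm[s], weights) for s in test_ids}

    diff_genes = {
        s: differential_repression(control_rep, repression[s], alpha=alpha, adjust=adjust)
        for s in test_ids
    }
    diff_inter = {
        s: differential_interactions(control_contrib, contributions[s], alpha=alpha, adjust=adjust)
        for s in test_ids
    }

    if universe is None:
        universe = interactions.genes & pathways.all_genes()
    # hits = genes significantly MORE repressed in the tumor sample; the
    # two-sided test also flags genes whose share merely shrank because the
    # composition shifted, and those are not "repressed" genes
    enrichment = {
        s: hypergeom_enrich(
            set(diff_genes[s].repressed_keys) & universe,
            pathways,
            universe,
            alpha=enrich_alpha,
        )
        for s in test_ids
    }
    overlapped = frozenset(overlapped_pathways(enrichment))

    mrna_sets: dict[str, set[str]] = {}
    mirna_sets: dict[str, set[str]] = {}
    for s in test_ids:
        restricted_genes = restrict_to_pathways(diff_genes[s], pathways, overlapped)
        mrna_sets[s] = set(restricted_genes.repressed_keys)
        restricted_pairs = restrict_to_pathways(diff_inter[s], pathways, overlapped)
        mirna_sets[s] = {pair[0] for pair in restricted_pairs.significant_keys}

    return PipelineResult(
        control_profile=control,
        tpm_profiles=tuple(tpm[s] for s in by_id),
        control_repression=control_rep,
        control_contributions=control_contrib,
        repression=repression,
        contributions=contributions,
        diff_genes=diff_genes,
        diff_interactions=diff_inter,
        enrichment=enrichment,
        overlapped=overlapped,
        recurrent_mrnas=recurrent_elements(mrna_sets),
        recurrent_mirnas=recurrent_elements(mirna_sets),
        universe=frozenset(universe),
    )


def run_pipeline(config: RunConfig) -> dict:
    """File-based run: read inputs, analyze, write every intermediate table.

    Returns the run manifest (also written as ``manifest.json``).  On a
    stage failure, a manifest with a ``failed_stage`` marker is still
    written before the error propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "alpha": config.alpha,
            "enrich_alpha": config.enrich_alpha,
            "adjust": config.adjust,
            "seed": config.seed,
            "control_samples": list(config.control_samples),
            "test_samples": list(config.test_samples),
        },
        "inputs": {
            "profiles": config.profiles,
            "interactions": config.interactions,
            "gene_sets": config.gene_sets,
        },
        "outputs": {},
    }
    from . import __version__

    manifest["version"] = __version__

    stage = "read inputs"
    try:
        profiles = mio.read_profiles(config.profiles)
        interactions = mio.read_interactions(config.interactions)
        pathways = mio.read_gene_sets(config.gene_sets)

        stage = "analysis"
        result = analyze(
            profiles,
            interactions,
            pathways,
            control_ids=config.control_samples,
            test_ids=config.test_samples,
            alpha=config.alpha,
            enrich_alpha=config.enrich_alpha,
            adjust=config.adjust,
        )

        stage = "write outputs"
        out = manifest["outputs"]
        tpm_path = outdir / "tpm.tsv"
        mio.write_normalized_profiles(list(result.tpm_profiles), tpm_path)
        out["tpm"] = str(tpm_path)
        control_path = outdir / "control.tsv"
        mio.write_normalized_profiles([result.control_profile], control_path)
        out["control"] = str(control_path)
        for s in config.test_samples:
            for label, table in (
                ("diff_gene", result.diff_genes[s]),
                ("diff_interaction", result.diff_interactions[s]),
            ):
                path = outdir / f"{label}_{s}.tsv"
                mio.write_differential_table(table, path)
                out[f"{label}_{s}"] = str(path)
            path = outdir / f"enrich_{s}.tsv"
            mio.write_enrichment_result(result.enrichment[s], path)
            out[f"enrich_{s}"] = str(path)
        recur = {
            "overlapped_pathways": sorted(result.overlapped),
            "recurrent_mrnas": sorted(result.recurrent_mrnas.intersection),
            "recurrent_mirnas": sorted(result.recurrent_mirnas.intersection),
            "mrna_regions": {
                "|".join(region): count
                for region, count in sorted(result.recurrent_mrnas.region_counts.items())
            },
            "mirna_regions": {
                "|".join(region): count
                for region, count in sorted(result.recurrent_mirnas.region_counts.items())
            },
        }
        recur_path = outdir / "recurrence.json"
        mio.write_manifest(recur, recur_path)
        out["recurrence"] = str(recur_path)
        manifest["stages"] = result.stage_counts()
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        mio.write_manifest(manifest, outdir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    mio.write_manifest(manifest, outdir / "manifest.json")
    logger.info("pipeline complete: %s", manifest["stages"])
    return manifest
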
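"""Synthetic miRNA-profiling datasets with planted differential repression.

The generator emulates the structure of a tumor-versus-control miRNA
profiling study: a handful of control profiles (to be TPM-averaged into a
single comparator), several tumor profiles, a scored bipartite miRNA→mRNA
network, and disjoint pathway annotations in which a small number of
pathways carry a planted signal.  Planting works in two coupled moves:
the chosen miRNAs are rewired so that at least 80% of their targets lie
inside their pathway, and their expected expression in every tumor sample
is multiplied by ``fold_change``.  Ground truth (planted pathways, miRNAs
and the in-pathway genes they target) is recorded in the dataset so
recovery can be scored exactly.

Counts are negative-binomial (gamma–Poisson) around log-uniform baseline
means.  The default dispersion is small (sequencing-replicate scale)
because each tumor sample is compared individually against the averaged
control by a pooled-proportion test, whose sampling model is multinomial
counting noise; see the methods note for the power analysis behind the
defaults.

Three independent RNG streams (expression, network, planting) are spawned
from the master seed, so changing one configuration field perturbs only
its own component.  The same configuration and seed always reproduce the
dataset bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .datatypes import ExpressionProfile, InteractionTable, PathwayCollection
from . import io as mio

__all__ = ["SyntheticConfig", "SyntheticDataset", "simulate_dataset", "write_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic generator.

    Defaults emulate a deep miRNA-seq design: ~300 miRNAs at a mean of
    3000 counts (≈10^6 reads), 1000 annotated genes in 20 disjoint
    pathways, 4 control + 4 tumor samples, and 4 planted pathways each
    driven by 2 four-fold upregulated miRNAs.
    """

    n_mirnas: int = 300
    n_genes: int = 1000
    n_pathways: int = 20
    targets_per_mirna: tuple[int, int] = (10, 40)
    score_range: tuple[float, float] = (20.0, 200.0)
    n_control: int = 4
    n_test: int = 4
    baseline_mean: float = 3000.0
    dispersion: float = 0.001
    planted_pathways: int = 4
    planted_mirnas_per_pathway: int = 2
    fold_change: float = 4.0
    seed: int = 7
    #: fraction of a planted miRNA's targets rewired into its pathway
    planted_target_fraction: float = 0.8
    #: allow pathways to share genes (off by default so recovery is unambiguous)
    overlapping_pathways: bool = False

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_genes", "n_pathways", "n_control", "n_test",
                     "planted_pathways", "planted_mirnas_per_pathway"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        lo, hi = self.targets_per_mirna
        if not (1 <= lo <= hi):
            raise ValueError("targets_per_mirna must satisfy 1 ≤ lo ≤ hi")
        if hi > self.n_genes:
            raise ValueError("targets_per_mirna max exceeds n_genes")
        slo, shi = self.score_range
        if not (0 < slo <= shi):
            raise ValueError("score_range must be a positive interval")
        if self.planted_pathways > self.n_pathways:
            raise ValueError("planted_pathways exceeds n_pathways")
        n_planted = self.planted_pathways * self.planted_mirnas_per_pathway
        if n_planted > self.n_mirnas:
            raise ValueError("more planted miRNAs than miRNAs available")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")
        if not (0 < self.planted_target_fraction <= 1):
            raise ValueError("planted_target_fraction must be in (0, 1]")
        min_pathway = self.n_genes // self.n_pathways
        if math.ceil(self.planted_target_fraction * hi) > min_pathway:
            raise ValueError(
                "pathways too small to host the rewired targets of a planted miRNA; "
                "increase n_genes or decrease targets_per_mirna/n_pathways"
            )


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated profiles (controls first, then tumors), network, pathways, truth."""

    config: SyntheticConfig
    profiles: tuple[ExpressionProfile, ...]
    interactions: InteractionTable
    pathways: PathwayCollection
    planted_pathway_ids: frozenset[str]
    planted_mirna_ids: frozenset[str]
    planted_gene_ids: frozenset[str]

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(p.sample_id for p in self.profiles[: self.config.n_control])

    @property
    def test_ids(self) -> tuple[str, ...]:
        return tuple(p.sample_id for p in self.profiles[self.config.n_control:])


def _nb_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson draws: mean μ, variance μ + dispersion·μ²."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape=shape, scale=means * dispersion)
    return rng.poisson(lam).astype(float)


def simulate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a dataset with planted differentially repressed pathways."""
    config = config or SyntheticConfig()
    master = np.random.SeedSequence(config.seed)
    s_expr, s_net, s_plant = master.spawn(3)
    rng_expr = np.random.default_rng(s_expr)
    rng_net = np.random.default_rng(s_net)
    rng_plant = np.random.default_rng(s_plant)

    mirnas = [f"miR-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    genes = np.array([f"gene-{i:04d}" for i in range(1, config.n_genes + 1)])

    # --- pathway annotation: (near-)equal partition of the gene universe
    pathway_ids = [f"PW-{i:02d}" for i in range(1, config.n_pathways + 1)]
    assignment = np.arange(config.n_genes) % config.n_pathways
    pathway_genes: dict[str, set[str]] = {
        pid: set(genes[assignment == i]) for i, pid in enumerate(pathway_ids)
    }
    if config.overlapping_pathways:
        # optionally blur boundaries: each pathway additionally borrows a few
        # random genes, so membership is no longer a partition
        for pid in pathway_ids:
            extra = rng_net.choice(genes, size=max(1, config.n_genes // (10 * config.n_pathways)),
                                   replace=False)
            pathway_genes[pid] |= set(extra)

    # --- network: random target set with uniform scores per miRNA
    lo, hi = config.targets_per_mirna
    slo, shi = config.score_range
    target_sets: dict[str, np.ndarray] = {}
    for m in mirnas:
        size = int(rng_net.integers(lo, hi + 1))
        target_sets[m] = rng_net.choice(genes, size=size, replace=False)

    # --- planting: pick pathways and miRNAs, rewire targets into the pathway
    planted_pw = [str(p) for p in rng_plant.choice(pathway_ids, size=config.planted_pathways, replace=False)]
    n_planted = config.planted_pathways * config.planted_mirnas_per_pathway
    planted_mirnas = [str(m) for m in rng_plant.choice(mirnas, size=n_planted, replace=False)]
    planted_by_pw: dict[str, list[str]] = {
        pid: planted_mirnas[i * config.planted_mirnas_per_pathway:(i + 1) * config.planted_mirnas_per_pathway]
        for i, pid in enumerate(planted_pw)
    }
    planted_gene_ids: set[str] = set()
    for pid, pws_mirnas in planted_by_pw.items():
        pw_genes = np.array(sorted(pathway_genes[pid]))
        out_genes = np.array(sorted(set(genes) - pathway_genes[pid]))
        for m in pws_mirnas:
            size = len(target_sets[m])
            n_in = min(math.ceil(config.planted_target_fraction * size), len(pw_genes))
            n_out = size - n_in
            inside = rng_plant.choice(pw_genes, size=n_in, replace=False)
            outside = rng_plant.choice(out_genes, size=n_out, replace=False)
            target_sets[m] = np.concatenate([inside, outside])
            planted_gene_ids |= {str(g) for g in inside}

    records = []
    for m in mirnas:
        targets = target_sets[m]
        scores = rng_net.uniform(slo, shi, size=len(targets))
        for g, s in zip(targets, scores):
            records.append((m, str(g), float(s)))
    interactions = InteractionTable.from_records(records)

    # --- expression: log-uniform baseline means over one decade, NB counts
    means = config.baseline_mean * 10.0 ** rng_expr.uniform(-0.5, 0.5, size=config.n_mirnas)
    planted_mask = np.isin(np.array(mirnas), np.array(planted_mirnas))
    profiles: list[ExpressionProfile] = []
    for i in range(1, config.n_control + 1):
        counts = _nb_counts(rng_expr, means, config.dispersion)
        profiles.append(ExpressionProfile(f"normal_{i}", dict(zip(mirnas, counts))))
    test_means = np.where(planted_mask, means * config.fold_change, means)
    for i in range(1, config.n_test + 1):
        counts = _nb_counts(rng_expr, test_means, config.dispersion)
        profiles.append(ExpressionProfile(f"tumor_{i}", dict(zip(mirnas, counts))))

    pathways = PathwayCollection(
        {pid: (f"synthetic pathway {pid}", frozenset(gset)) for pid, gset in pathway_genes.items()}
    )
    return SyntheticDataset(
        config=config,
        profiles=tuple(profiles),
        interactions=interactions,
        pathways=pathways,
        planted_pathway_ids=frozenset(planted_pw),
        planted_mirna_ids=frozenset(planted_mirnas),
        planted_gene_ids=frozenset(planted_gene_ids),
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write profiles.tsv, interactions.tsv, pathways.gmt and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": str(outdir / "profiles.tsv"),
        "interactions": str(outdir / "interactions.tsv"),
        "pathways": str(outdir / "pathways.gmt"),
        "truth": str(outdir / "truth.json"),
    }
    mio.write_profiles(list(dataset.profiles), paths["profiles"])
    mio.write_interactions(dataset.interactions, paths["interactions"])
    mio.write_gene_sets(dataset.pathways, paths["pathways"])
    truth = {
        "config": asdict(dataset.config),
        "control_ids": list(dataset.control_ids),
        "test_ids": list(dataset.test_ids),
        "planted_pathways": sorted(dataset.planted_pathway_ids),
        "planted_mirnas": sorted(dataset.planted_mirna_ids),
        "planted_genes": sorted(dataset.planted_gene_ids),
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    return paths
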
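"""Pathway enrichment, cross-sample overlap and recurrence summaries.

Enrichment of a hit set within a pathway is the one-sided (upper tail)
hypergeometric test: drawing n = |hits| genes from a universe of N, with
K annotated to the pathway, the p-value is P(X ≥ k) for the observed
overlap k.  Pathways enriched in *every* tumor sample form the overlapped
set; differential tables can then be restricted to those pathways' genes,
and elements (miRNAs or mRNAs) significant in all samples are collected
with full Venn-region bookkeeping.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .datatypes import (
    DifferentialTable,
    EnrichmentResult,
    InteractionTable,
    PathwayCollection,
    RecurrenceSummary,
)

__all__ = [
    "hypergeom_enrich",
    "overlapped_pathways",
    "restrict_to_pathways",
    "recurrent_elements",
    "count_targets_per_pathway",
]


def hypergeom_enrich(
    hits: Iterable[str],
    pathways: PathwayCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation of ``hits`` per pathway.

    Every pathway is intersected with the universe before testing; a
    pathway with no universe genes is skipped.  ``enriched`` flags
    p < alpha (uncorrected).
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not hits <= universe:
        extra = sorted(hits - universe)[:5]
        raise ValueError(f"hits must be a subset of the universe; e.g. {extra}")
    n = len(hits)
    N = len(universe)
    rows = {}
    for pid in sorted(pathways.ids()):
        genes = pathways.genes_of(pid) & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        rows[pid] = {
            "overlap_count": k,
            "pathway_size": K,
            "hit_count": n,
            "universe_size": N,
            "p_value": p,
            "enriched": p < alpha,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=list(EnrichmentResult.COLUMNS))
    return EnrichmentResult(df)


def overlapped_pathways(per_sample: Mapping[str, EnrichmentResult]) -> set[str]:
    """Pathways flagged enriched in every sample."""
    if not per_sample:
        raise ValueError("need at least one sample's enrichment result")
    sets = [res.enriched_ids for res in per_sample.values()]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def restrict_to_pathways(
    diff: DifferentialTable,
    pathways: PathwayCollection,
    selected: Iterable[str],
) -> DifferentialTable:
    """Keep rows whose gene belongs to any selected pathway, order preserved.

    For interaction-level tables the gene is the second element of the key.
    """
    selected = set(selected)
    unknown = selected - pathways.ids()
    if unknown:
        raise ValueError(f"unknown pathway id(s): {sorted(unknown)}")
    allowed: set[str] = set()
    for pid in selected:
        allowed |= pathways.genes_of(pid)
    keys = diff.rows.index
    if isinstance(keys, pd.MultiIndex):
        mask = [g in allowed for g in keys.get_level_values(-1)]
    else:
        mask = [g in allowed for g in keys]
    return DifferentialTable(diff.rows.loc[mask])


def recurrent_elements(per_sample_sets: Mapping[str, Iterable[str]]) -> RecurrenceSummary:
    """Intersection across samples plus Venn-region counts.

    Each element of the union is keyed by the sorted tuple of samples that
    contain it; region counts therefore sum to |union|.
    """
    if not per_sample_sets:
        raise ValueError("need at least one sample set")
    sets = {sid: frozenset(s) for sid, s in per_sample_sets.items()}
    union: set[str] = set().union(*sets.values())
    intersection = frozenset(set.intersection(*(set(s) for s in sets.values())))
    region_counts: dict[tuple[str, ...], int] = {}
    for element in union:
        region = tuple(sorted(sid for sid, s in sets.items() if element in s))
        region_counts[region] = region_counts.get(region, 0) + 1
    return RecurrenceSummary(sets, intersection, region_counts)


def count_targets_per_pathway(
    mirnas: Iterable[str],
    interactions: InteractionTable,
    pathways: PathwayCollection,
    selected: Iterable[str],
) -> dict[str, dict[str, int]]:
    """Per selected pathway, how many of each miRNA's targets it contains."""
    selected = set(selected)
    unknown = selected - pathways.ids()
    if unknown:
        raise ValueError(f"unknown pathway id(s): {sorted(unknown)}")
    mirnas = sorted(set(mirnas))
    targets = {
        m: set(sub["gene_id"])
        for m, sub in interactions.records.groupby("mirna_id")
        if m in set(mirnas)
    }
    out: dict[str, dict[str, int]] = {}
    for pid in sorted(selected):
        genes = pathways.genes_of(pid)
        out[pid] = {m: len(targets.get(m, set()) & genes) for m in mirnas}
    return out
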
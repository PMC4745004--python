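"""Comprehensive repression: apportion miRNA abundance across targets.

The model treats each miRNA's TPM as a repression mass that is split
across its predicted targets in proportion to the interaction's repression
score (RS).  For miRNA *a* with targets t:

    weight(a, α) = RS(a, α) / Σ_t RS(a, t)

and the comprehensive repression received by mRNA α in a sample is the
abundance-weighted accumulation over every miRNA targeting it:

    R(α) = Σ_a TPM(a) · weight(a, α)

Mass is apportioned, never created: summing R over all genes returns the
total TPM of the miRNAs that carry at least one scored target, which is
the conservation property the tests rely on.  A miRNA whose scores sum to
zero predicts no repression and is dropped (with a logged warning) rather
than given uniform weights.
"""

from __future__ import annotations

import logging

import pandas as pd

from .datatypes import ContributionTable, InteractionTable, NormalizedProfile, RepressionResult, WeightTable

__all__ = ["target_weights", "repression_scores", "interaction_contributions"]

logger = logging.getLogger(__name__)


def target_weights(interactions: InteractionTable) -> WeightTable:
    """Normalize each miRNA's repression scores to apportionment weights."""
    df = interactions.records
    if df.empty:
        return WeightTable(pd.DataFrame(columns=["mirna_id", "gene_id", "weight"]))
    sums = df.groupby("mirna_id")["score"].transform("sum")
    zero = sums <= 0
    if zero.any():
        dropped = sorted(df.loc[zero, "mirna_id"].unique())
        logger.warning(
            "dropping %d miRNA(s) whose repression scores sum to zero: %s",
            len(dropped), ", ".join(dropped),
        )
    kept = df.loc[~zero].copy()
    kept["weight"] = kept["score"] / sums[~zero]
    return WeightTable(kept[["mirna_id", "gene_id", "weight"]])


def _contribution_frame(profile: NormalizedProfile, weights: WeightTable) -> pd.DataFrame:
    df = weights.weights
    if df.empty:
        return pd.DataFrame(columns=["mirna_id", "gene_id", "contribution"])
    tpm = df["mirna_id"].map(lambda m: profile.get(m)).astype(float)
    out = df[["mirna_id", "gene_id"]].copy()
    out["contribution"] = tpm.to_numpy() * df["weight"].to_numpy()
    return out


def repression_scores(profile: NormalizedProfile, weights: WeightTable) -> RepressionResult:
    """Accumulated repression R(α) per target gene for one sample.

    Every gene present in the weight table appears in the result, with an
    explicit 0 when none of its miRNAs are expressed; miRNAs in the
    profile with no scored targets contribute nothing.
    """
    contrib = _contribution_frame(profile, weights)
    if contrib.empty:
        return RepressionResult(profile.sample_id, pd.Series(dtype=float))
    rep = contrib.groupby("gene_id")["contribution"].sum()
    rep.index.name = None
    return RepressionResult(profile.sample_id, rep)


def interaction_contributions(profile: NormalizedProfile, weights: WeightTable) -> ContributionTable:
    """Per-(miRNA, gene) repression contributions TPM(a)·weight(a, α)."""
    contrib = _contribution_frame(profile, weights)
    if contrib.empty:
        empty = pd.Series(
            dtype=float,
            index=pd.MultiIndex.from_arrays([[], []], names=["mirna_id", "gene_id"]),
        )
        return ContributionTable(profile.sample_id, empty)
    series = contrib.set_index(["mirna_id", "gene_id"])["contribution"]
    series.name = None
    return ContributionTable(profile.sample_id, series)
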
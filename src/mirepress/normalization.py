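"""TPM normalization and construction of the averaged control profile.

TPM of miRNA *a* in a sample is ``counts(a) / total_counts × 1e6``, so a
normalized profile always sums to one million and is invariant to overall
library size.  The control comparator is the per-miRNA arithmetic mean of
the normal samples' TPM profiles: averaging on the TPM scale (not raw
counts) keeps unequal library sizes from biasing the control, and miRNAs
absent from a sample enter the mean as explicit zeros so downstream set
operations stay well defined.
"""

from __future__ import annotations

from typing import Sequence

from .datatypes import ExpressionProfile, NormalizedProfile, TPM_TOTAL

__all__ = ["tpm_normalize", "average_controls"]


def tpm_normalize(profile: ExpressionProfile) -> NormalizedProfile:
    """Scale a raw count profile to transcripts per million."""
    total = profile.total
    if total <= 0:
        raise ValueError(f"cannot normalize empty profile {profile.sample_id!r}")
    tpm = {mirna: count / total * TPM_TOTAL for mirna, count in profile.counts.items()}
    return NormalizedProfile(profile.sample_id, tpm)


def average_controls(
    profiles: Sequence[NormalizedProfile], sample_id: str = "control"
) -> NormalizedProfile:
    """Arithmetic per-miRNA mean of TPM profiles over the union of miRNA ids.

    miRNAs absent from a profile contribute 0 to the mean.  Because every
    input sums to 1e6, so does the average.
    """
    if not profiles:
        raise ValueError("average_controls requires at least one profile")
    ids: list[str] = []
    seen: set[str] = set()
    for p in profiles:
        for mirna in p.tpm:
            if mirna not in seen:
                seen.add(mirna)
                ids.append(mirna)
    n = len(profiles)
    mean = {mirna: sum(p.get(mirna) for p in profiles) / n for mirna in ids}
    return NormalizedProfile(sample_id, mean)
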
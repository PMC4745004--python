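"""Domain types for miRNA repression profiling.

The pipeline moves through a small set of validated containers: raw count
profiles, TPM-normalized profiles, a scored miRNA→mRNA interaction table,
per-gene repression masses, z-test tables, pathway collections and
enrichment/recurrence summaries.  Validation happens at construction so
that downstream operations can assume their invariants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionProfile",
    "NormalizedProfile",
    "InteractionTable",
    "PathwayCollection",
    "LiteratureTable",
    "WeightTable",
    "RepressionResult",
    "ContributionTable",
    "ZTestResult",
    "DifferentialTable",
    "EnrichmentResult",
    "RecurrenceSummary",
    "PanelMatrix",
    "ClusteringResult",
]

TPM_TOTAL = 1_000_000.0
#: relative tolerance on the TPM sum invariant
TPM_RTOL = 1e-9


class FormatError(ValueError):
    """An on-disk input violated the expected format or an invariant."""


def _check_counts(counts: Mapping[str, float], what: str) -> None:
    if not counts:
        raise ValueError(f"{what}: empty profile")
    for mirna, value in counts.items():
        v = float(value)
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{what}: count for {mirna!r} is {value!r}, must be a finite non-negative real")


@dataclass(frozen=True)
class ExpressionProfile:
    """Raw miRNA abundances (counts or intensities) for one sample."""

    sample_id: str
    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        _check_counts(self.counts, f"profile {self.sample_id!r}")
        if not any(float(v) > 0 for v in self.counts.values()):
            raise ValueError(f"profile {self.sample_id!r}: all counts are zero")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass(frozen=True)
class NormalizedProfile:
    """Transcripts-per-million abundances; values sum to 1e6."""

    sample_id: str
    tpm: Mapping[str, float]

    def __post_init__(self) -> None:
        _check_counts(self.tpm, f"normalized profile {self.sample_id!r}")
        total = float(sum(self.tpm.values()))
        if not math.isclose(total, TPM_TOTAL, rel_tol=TPM_RTOL):
            raise ValueError(
                f"normalized profile {self.sample_id!r}: TPM sums to {total!r}, expected {TPM_TOTAL}"
            )
        object.__setattr__(self, "tpm", dict(self.tpm))

    def get(self, mirna_id: str) -> float:
        return float(self.tpm.get(mirna_id, 0.0))


@dataclass(frozen=True)
class InteractionTable:
    """Scored miRNA→mRNA interactions.

    ``records`` has columns ``mirna_id``, ``gene_id``, ``score``; scores are
    non-negative repression scores (miRanda-style) and (miRNA, gene) pairs
    are unique.
    """

    records: pd.DataFrame

    COLUMNS = ("mirna_id", "gene_id", "score")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS)).copy()
        df["mirna_id"] = df["mirna_id"].astype(str)
        df["gene_id"] = df["gene_id"].astype(str)
        df["score"] = pd.to_numeric(df["score"], errors="raise").astype(float)
        if len(df) and ((df["score"] < 0) | ~np.isfinite(df["score"])).any():
            bad = df.loc[(df["score"] < 0) | ~np.isfinite(df["score"])].iloc[0]
            raise FormatError(
                f"interaction {bad['mirna_id']}→{bad['gene_id']} has score {bad['score']}, must be ≥ 0"
            )
        dup = df.duplicated(subset=["mirna_id", "gene_id"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise FormatError(f"duplicate interaction pair ({bad['mirna_id']}, {bad['gene_id']})")
        object.__setattr__(self, "records", df.reset_index(drop=True))

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str, float]]) -> "InteractionTable":
        return cls(pd.DataFrame(list(records), columns=list(cls.COLUMNS)))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mirnas(self) -> set[str]:
        return set(self.records["mirna_id"])

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene_id"])

    def targets_of(self, mirna_id: str) -> set[str]:
        sub = self.records[self.records["mirna_id"] == mirna_id]
        return set(sub["gene_id"])


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets (e.g. KEGG pathways), each with ≥ 1 member gene."""

    pathways: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for pid, (name, genes) in self.pathways.items():
            genes = frozenset(str(g) for g in genes)
            if not genes:
                raise FormatError(f"pathway {pid!r} has no genes")
            clean[str(pid)] = (str(name), genes)
        object.__setattr__(self, "pathways", clean)

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.pathways

    def ids(self) -> set[str]:
        return set(self.pathways)

    def genes_of(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def name_of(self, pathway_id: str) -> str:
        return self.pathways[pathway_id][0]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.pathways.values():
            out |= genes
        return out


@dataclass(frozen=True)
class LiteratureTable:
    """Per-miRNA literature report directions; empty list = no reports."""

    rows: Sequence[tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        clean: list[tuple[str, tuple[str, ...]]] = []
        for mirna, reports in self.rows:
            if mirna in seen:
                raise FormatError(f"duplicate miRNA id {mirna!r} in literature table")
            seen.add(mirna)
            reports = tuple(reports)
            for d in reports:
                if d not in ("up", "down"):
                    raise FormatError(f"literature direction {d!r} for {mirna!r}: must be 'up' or 'down'")
            clean.append((str(mirna), reports))
        object.__setattr__(self, "rows", tuple(clean))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class WeightTable:
    """Per-(miRNA, gene) apportionment weights; each miRNA's weights sum to 1."""

    weights: pd.DataFrame  # columns mirna_id, gene_id, weight

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.weights, columns=["mirna_id", "gene_id", "weight"]).copy()
        if len(df):
            sums = df.groupby("mirna_id")["weight"].sum()
            if not np.allclose(sums.to_numpy(), 1.0, rtol=0, atol=1e-12):
                bad = sums[~np.isclose(sums, 1.0, rtol=0, atol=1e-12)].index[0]
                raise ValueError(f"weights for miRNA {bad!r} sum to {sums[bad]!r}, expected 1")
        object.__setattr__(self, "weights", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class RepressionResult:
    """Accumulated repression mass per mRNA for one sample."""

    sample_id: str
    repression: pd.Series  # index gene_id, non-negative
    total: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        rep = pd.Series(self.repression, dtype=float)
        rep.index = rep.index.astype(str)
        if (rep < 0).any():
            raise ValueError(f"repression for sample {self.sample_id!r} contains negative values")
        total = float(rep.sum())
        if not math.isnan(self.total) and not math.isclose(total, self.total, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                f"stated total {self.total!r} disagrees with summed repression {total!r}"
            )
        object.__setattr__(self, "repression", rep)
        object.__setattr__(self, "total", total)


@dataclass(frozen=True)
class ContributionTable:
    """Per-(miRNA, gene) repression contributions for one sample."""

    sample_id: str
    contributions: pd.Series  # MultiIndex (mirna_id, gene_id), non-negative

    def __post_init__(self) -> None:
        contrib = pd.Series(self.contributions, dtype=float)
        if (contrib < 0).any():
            raise ValueError(f"contributions for sample {self.sample_id!r} contain negative values")
        object.__setattr__(self, "contributions", contrib)

    @property
    def total(self) -> float:
        return float(self.contributions.sum())

    def by_gene(self) -> pd.Series:
        """Sum contributions over miRNAs; reproduces the repression result."""
        if self.contributions.empty:
            return pd.Series(dtype=float)
        return self.contributions.groupby(level=1).sum()


class ZTestResult(NamedTuple):
    """Pooled two-proportion z-test result.

    ``z`` is NaN when the pooled proportion is degenerate (0 or 1), in which
    case ``p_value`` is 1.
    """

    p_hat_1: float
    p_hat_2: float
    p0: float
    z: float
    p_value: float


@dataclass(frozen=True)
class DifferentialTable:
    """Per-key z-test results with optional BH q-values.

    ``rows`` is indexed by gene id (gene-level) or (mirna_id, gene_id)
    tuples (interaction level), with columns p_hat_1, p_hat_2, p0, z,
    p_value, q_value, significant.
    """

    rows: pd.DataFrame

    COLUMNS = ("p_hat_1", "p_hat_2", "p0", "z", "p_value", "q_value", "significant")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows, columns=list(self.COLUMNS)).copy()
        object.__setattr__(self, "rows", df)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def significant_keys(self) -> list:
        return list(self.rows.index[self.rows["significant"].astype(bool)])

    @property
    def repressed_keys(self) -> list:
        """Keys significantly *more* repressed in the test group (p̂2 > p̂1)."""
        mask = self.rows["significant"].astype(bool) & (self.rows["p_hat_2"] > self.rows["p_hat_1"])
        return list(self.rows.index[mask])

    def genes(self) -> set[str]:
        """Gene universe of the table (second element for interaction keys)."""
        keys = self.rows.index
        if isinstance(keys, pd.MultiIndex):
            return set(keys.get_level_values(-1).astype(str))
        return set(keys.astype(str))


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation results per pathway."""

    rows: pd.DataFrame

    COLUMNS = (
        "overlap_count",
        "pathway_size",
        "hit_count",
        "universe_size",
        "p_value",
        "enriched",
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows, columns=list(self.COLUMNS)).copy()
        object.__setattr__(self, "rows", df)

    @property
    def enriched_ids(self) -> set[str]:
        return set(self.rows.index[self.rows["enriched"].astype(bool)].astype(str))


@dataclass(frozen=True)
class RecurrenceSummary:
    """Venn-style summary of element sets across samples."""

    per_sample_sets: Mapping[str, frozenset[str]]
    intersection: frozenset[str]
    region_counts: Mapping[tuple[str, ...], int]

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.per_sample_sets.values():
            out |= s
        return frozenset(out)


@dataclass(frozen=True)
class PanelMatrix:
    """sample × panel-miRNA matrix of log2(TPM + 1) values."""

    sample_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.mirna_ids)):
            raise ValueError(
                f"matrix shape {values.shape} inconsistent with {len(self.sample_ids)} samples × "
                f"{len(self.mirna_ids)} panel miRNAs"
            )
        if not np.isfinite(values).all():
            raise ValueError("panel matrix contains non-finite values")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "mirna_ids", tuple(self.mirna_ids))
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ClusteringResult:
    """Agglomerative merge tree plus flat labels at every cut 1..n."""

    sample_ids: tuple[str, ...]
    merge_tree: tuple[tuple[int, int, float], ...]
    labels_at_k: Mapping[int, Mapping[str, int]]

    def labels(self, k: int) -> dict[str, int]:
        return dict(self.labels_at_k[k])
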
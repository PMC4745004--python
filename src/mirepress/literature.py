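"""Literature-report tabulation for candidate biomarker miRNAs, plus qPCR math.

The package ships a curated table of colorectal-cancer literature reports
for the 21 recurrent miRNAs found by the pipeline's reference study
design: per miRNA, the reported expression directions (up/down) across
published studies, with ``NULL`` marking miRNAs without any report.  The
tabulation splits the panel into unreported / consistently reported /
inconsistently reported, with percentages on the conventional
denominators (unreported over all rows; consistency over reported rows),
rounded half-up to one decimal.

Also included is the standard relative-quantification fold change for
qRT-PCR, 2^(−ΔΔCt), where ΔΔCt = (Ct_target − Ct_reference)_test −
(Ct_target − Ct_reference)_control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

from .datatypes import FormatError, LiteratureTable

__all__ = [
    "LiteratureSummary",
    "CtMeasurement",
    "load_literature_table",
    "read_literature_table",
    "tabulate_literature",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class LiteratureSummary:
    n_total: int
    n_unreported: int
    n_reported: int
    n_consistent: int
    n_inconsistent: int
    pct_unreported: float
    pct_consistent: float
    pct_inconsistent: float


@dataclass(frozen=True)
class CtMeasurement:
    """Raw cycle thresholds for target and reference genes, test vs control."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal; 0 when the denominator is 0."""
    if denominator == 0:
        return 0.0
    exact = Decimal(numerator) * 100 / Decimal(denominator)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def read_literature_table(path: str | Path) -> LiteratureTable:
    """Read a 2-column TSV: mirna_id TAB comma-separated directions or NULL."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"literature table not found: {path}")
    rows: list[tuple[str, tuple[str, ...]]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["mirna_id", "reports"]:
            raise FormatError(f"{path}: expected header 'mirna_id\\treports'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}, line {lineno}: expected 2 fields")
            mirna, reports = fields
            if reports in ("", "NULL"):
                rows.append((mirna, ()))
            else:
                rows.append((mirna, tuple(reports.split(","))))
    return LiteratureTable(rows)


def load_literature_table() -> LiteratureTable:
    """The packaged 21-miRNA colorectal-cancer report table."""
    ref = resources.files("mirepress").joinpath("data/literature_reports.tsv")
    with resources.as_file(ref) as path:
        return read_literature_table(path)


def tabulate_literature(table: LiteratureTable) -> LiteratureSummary:
    """Split rows into unreported / consistent / inconsistent and percentage them.

    A reported miRNA is consistent when all its reported directions agree.
    """
    n_total = len(table)
    unreported = [m for m, reports in table.rows if not reports]
    reported = [(m, reports) for m, reports in table.rows if reports]
    consistent = [m for m, reports in reported if len(set(reports)) == 1]
    n_reported = len(reported)
    n_consistent = len(consistent)
    return LiteratureSummary(
        n_total=n_total,
        n_unreported=len(unreported),
        n_reported=n_reported,
        n_consistent=n_consistent,
        n_inconsistent=n_reported - n_consistent,
        pct_unreported=_pct(len(unreported), n_total),
        pct_consistent=_pct(n_consistent, n_reported),
        pct_inconsistent=_pct(n_reported - n_consistent, n_reported),
    )


def ddct_fold_change(m: CtMeasurement) -> float:
    """Relative expression fold change 2^(−ΔΔCt)."""
    ddct = (m.ct_target_test - m.ct_reference_test) - (
        m.ct_target_control - m.ct_reference_control
    )
    return float(2.0 ** (-ddct))
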
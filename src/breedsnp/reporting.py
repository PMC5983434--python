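"""Summary tables: per-breed filtration yield and cohort composition.

Both reports use half-up decimal rounding (the convention consistent
with the published tables they mirror): filtration percentages to three
decimals, composition percentages to two.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from breedsnp.vcf_io import BreedPanel

__all__ = [
    "FiltrationSummaryRow",
    "filtration_summary",
    "cohort_composition",
    "round_half_up",
]


def round_half_up(value: float | Decimal, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FiltrationSummaryRow:
    breed: str
    total_snps: int
    after_filtration: int
    percent: float  # 100 x after/total, 3 decimals, half-up

    def __post_init__(self) -> None:
        if not 0 <= self.after_filtration <= self.total_snps:
            raise ValueError(
                f"{self.breed}: filtered count {self.after_filtration} outside "
                f"[0, {self.total_snps}]"
            )


def filtration_summary(
    counts: Mapping[str, tuple[int, int]]
) -> list[FiltrationSummaryRow]:
    """Rows of (breed, total SNPs, SNPs after filtration, percent kept).

    ``counts`` maps breed -> (total, filtered); a zero total is an
    error since the percentage is undefined.
    """
    rows = []
    for breed, (total, filtered) in counts.items():
        if total == 0:
            raise ValueError(f"{breed}: total SNP count is zero")
        percent = round_half_up(Decimal(100 * filtered) / Decimal(total), 3)
        rows.append(FiltrationSummaryRow(breed, total, filtered, percent))
    return rows


def cohort_composition(panel: BreedPanel) -> dict[str, float]:
    """Percentage of cohort samples per breed (2 decimals, half-up)."""
    total = panel.n_samples
    return {
        breed: round_half_up(Decimal(100 * len(ids)) / Decimal(total), 2)
        for breed, ids in panel.samples.items()
    }


def filtration_summary_frame(
    counts: Mapping[str, tuple[int, int]]
) -> pd.DataFrame:
    rows = filtration_summary(counts)
    return pd.DataFrame(
        [
            {
                "breed": r.breed,
                "total_snps": r.total_snps,
                "after_filtration": r.after_filtration,
                "percent": r.percent,
            }
            for r in rows
        ]
    )
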
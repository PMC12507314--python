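"""Micro-costing of specialized burn care from a health-care perspective.

Costs are computed by multiplying per-patient healthcare-utilization volumes
with item-level unit prices, grouped into four categories: burn-center stay,
treatment, clinical consultation and outpatient burn care.  Prices carry a
price year and are updated to the analysis year (2023) by chained annual
inflation factors.  Readmission days are costed like ordinary stay days on the
patient who incurred them; in group reporting their pooled cost is therefore
automatically spread over the whole population (an average of per-patient
totals equals the category-pooled average).

Only the ICU-day and non-ICU-day unit prices are published figures; the
remaining entries of the shipped price table are replaceable placeholders
calibrated to reproduce realistic category averages.

All arithmetic is at full float precision; euro rounding happens only at the
presentation layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .indicators import PatientRecord

__all__ = [
    "COST_CATEGORIES",
    "UnitPriceEntry",
    "UnitPriceTable",
    "CostBreakdown",
    "default_price_table",
    "inflate_price",
    "patient_cost",
    "aggregate_costs",
    "category_shares",
    "bootstrap_mean_ci",
]

COST_CATEGORIES = (
    "burn_center_stay",
    "treatment",
    "clinical_consultation",
    "outpatient_burn_care",
)

PRICE_COLUMNS = ["item_code", "label", "category", "price_eur", "price_year", "unit"]
UNITS = ("day", "session", "procedure", "consultation", "item")


@dataclass(frozen=True)
class UnitPriceEntry:
    item_code: str
    label: str
    category: str
    price_eur: float
    price_year: int
    unit: str

    def __post_init__(self) -> None:
        if self.category not in COST_CATEGORIES:
            raise ValueError(f"unknown cost category {self.category!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.price_eur < 0:
            raise ValueError(f"negative unit price for {self.item_code}")


class UnitPriceTable:
    """Item-level price catalogue with CSV round-trip."""

    def __init__(self, entries: Iterable[UnitPriceEntry]):
        self._entries = {e.item_code: e for e in entries}
        if not self._entries:
            raise ValueError("price table is empty")

    def __contains__(self, item_code: str) -> bool:
        return item_code in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, item_code: str) -> UnitPriceEntry:
        try:
            return self._entries[item_code]
        except KeyError:
            raise KeyError(f"no unit price for item {item_code!r}") from None

    def inflated_to(self, year: int, index: Mapping[int, float]) -> "UnitPriceTable":
        """New table with every price carried to `year` by the inflation index."""
        return UnitPriceTable(
            UnitPriceEntry(
                e.item_code,
                e.label,
                e.category,
                inflate_price(e.price_eur, e.price_year, year, index),
                year,
                e.unit,
            )
            for e in self
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self], columns=PRICE_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.2f")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "UnitPriceTable":
        missing = set(PRICE_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"price table missing columns: {sorted(missing)}")
        return cls(
            UnitPriceEntry(
                str(r.item_code),
                str(r.label),
                str(r.category),
                float(r.price_eur),
                int(r.price_year),
                str(r.unit),
            )
            for r in frame.itertuples()
        )

    @classmethod
    def from_csv(cls, path) -> "UnitPriceTable":
        return cls.from_frame(pd.read_csv(path))


def default_price_table() -> UnitPriceTable:
    """The shipped 2023-euro price catalogue."""
    with resources.as_file(
        resources.files("bcqci.data").joinpath("unit_prices_2023.csv")
    ) as p:
        return UnitPriceTable.from_csv(p)


@dataclass(frozen=True)
class CostBreakdown:
    """Euro amounts by priced item and by cost category (2023 euros).

    The invariant ``total == sum(by_category) == sum(by_item)`` holds exactly
    at float precision; presentation rounding never feeds back into it.
    """

    by_item: Mapping[str, float]
    by_category: Mapping[str, float]

    @property
    def total_eur(self) -> float:
        return float(sum(self.by_category.values()))


def inflate_price(
    price: float, from_year: int, to_year: int, index: Mapping[int, float]
) -> float:
    """Carry a price from its price year to the target year.

    `index` maps a calendar year to that year's inflation factor (e.g. 1.04
    for 4% annual inflation); the price is multiplied by the chained factors
    of the years in ``(from_year, to_year]``.  Identity when the years match.
    """
    if to_year < from_year:
        raise ValueError("deflating to an earlier year is not supported")
    out = float(price)
    for year in range(from_year + 1, to_year + 1):
        if year not in index:
            raise KeyError(f"inflation index missing year {year}")
        out *= float(index[year])
    return out


def patient_cost(record: PatientRecord, prices: UnitPriceTable) -> CostBreakdown:
    """Volumes x unit prices for one patient, summed into categories."""
    by_item: dict = {}
    by_category = {c: 0.0 for c in COST_CATEGORIES}
    for item_code, volume in record.utilization.items():
        if item_code not in prices:
            raise KeyError(
                f"patient {record.patient_id}: utilization item {item_code!r} has no unit price"
            )
        entry = prices[item_code]
        amount = float(volume) * entry.price_eur
        by_item[item_code] = by_item.get(item_code, 0.0) + amount
        by_category[entry.category] += amount
    return CostBreakdown(by_item=by_item, by_category=by_category)


def aggregate_costs(
    cohort: Sequence[PatientRecord], prices: UnitPriceTable
) -> CostBreakdown:
    """Average cost per patient, by item and category, over a cohort.

    Pooled totals divided by the cohort size, so rarely used items (e.g.
    readmission days) are spread over all patients, not only their users.
    """
    if len(cohort) == 0:
        raise ValueError("cannot aggregate costs over an empty cohort")
    n = len(cohort)
    by_item: dict = {}
    by_category = {c: 0.0 for c in COST_CATEGORIES}
    for record in cohort:
        bd = patient_cost(record, prices)
        for k, v in bd.by_item.items():
            by_item[k] = by_item.get(k, 0.0) + v
        for k, v in bd.by_category.items():
            by_category[k] += v
    return CostBreakdown(
        by_item={k: v / n for k, v in by_item.items()},
        by_category={k: v / n for k, v in by_category.items()},
    )


def category_shares(breakdown: CostBreakdown) -> dict:
    """Fraction of the total in each cost category."""
    total = breakdown.total_eur
    if total <= 0:
        raise ValueError("cannot compute shares of a non-positive total")
    return {k: v / total for k, v in breakdown.by_category.items()}


def bootstrap_mean_ci(
    values: Sequence[float],
    B: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean.

    Resamples `values` with replacement B times and returns the empirical
    ``alpha/2`` and ``1 - alpha/2`` quantiles of the resampled means.
    Deterministic for a fixed seed.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(B, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
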
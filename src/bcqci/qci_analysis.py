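"""Cohort-level QCI analytics.

The QCI value expresses health outcome per unit cost:

    QCI value = (proportion of textbook outcome x 100)
                / (average total cost in thousands of euros)

computed per calendar quarter of the QCI date (start of specialized burn
care) to monitor outcome and cost over time.  Supporting analytics: case-mix
banding (age, %TBSA, etiology) with direct standardization to the
whole-cohort stratum mix, cost comparison between patients who achieved and
failed each outcome indicator (with a minimum-cell-size merge into an
'other' category), Kruskal-Wallis testing and bootstrap CIs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .costing import bootstrap_mean_ci
from .indicators import INDICATORS, PatientRecord

__all__ = [
    "QuarterSummary",
    "qci_value",
    "quarter_label",
    "quarterly_summaries",
    "pooled_proportion",
    "assign_case_mix",
    "case_mix_weights",
    "standardize_over_case_mix",
    "outcome_category_costs",
    "kruskal_wallis",
]

logger = logging.getLogger("bcqci")

AGE_BANDS = ("18-60", ">60")
TBSA_BANDS = ("0-5", "6-10", "11-20", ">20")
ETIOLOGY_GROUPS = ("flame", "other")

#: indicators pooled into 'other' when an arm is below the minimum cell size
DEFAULT_MERGE_SET = ("other_complications", "wound_infection", "predicted_mortality")


@dataclass(frozen=True)
class QuarterSummary:
    quarter: str
    n: int
    to_achieved: int
    to_failed: int
    to_proportion: float
    avg_total_cost: float
    qci_value: float


def qci_value(to_proportion: float, avg_cost: float) -> float:
    """Outcome per unit cost: ``(proportion * 100) / (avg_cost / 1000)``.

    Homogeneous of degree -1 in cost: doubling the average cost halves it.
    """
    if not (0.0 <= to_proportion <= 1.0):
        raise ValueError("to_proportion must be a fraction in [0, 1]")
    if avg_cost <= 0:
        raise ValueError("average total cost must be positive")
    return (to_proportion * 100.0) / (avg_cost / 1000.0)


def quarter_label(date) -> str:
    """Calendar quarter of a date as ``YYYY-Qn``."""
    p = pd.Period(pd.Timestamp(date), freq="Q")
    return f"{p.year}-Q{p.quarter}"


def _quarter_sequence(start, end) -> list:
    periods = pd.period_range(pd.Timestamp(start), pd.Timestamp(end), freq="Q")
    return [f"{p.year}-Q{p.quarter}" for p in periods]


def quarterly_summaries(
    cohort: Sequence[PatientRecord],
    total_costs: Sequence[float],
    to_flags: Sequence[bool],
    window: Optional[Tuple] = None,
) -> pd.DataFrame:
    """Per-quarter textbook-outcome counts, average cost and QCI value.

    Patients are assigned to the calendar quarter of their QCI date.  The
    study window defaults to the span of observed dates; quarters inside the
    window with no patients are reported with ``n = 0`` (never dropped), and a
    QCI date outside an explicit window raises.
    """
    if not (len(cohort) == len(total_costs) == len(to_flags)):
        raise ValueError("cohort, costs and TO flags must align")
    dates = [pd.Timestamp(r.qci_date) for r in cohort]
    if window is None:
        window = (min(dates), max(dates))
    w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    outside = [r.patient_id for r, d in zip(cohort, dates) if d < w0 or d > w1]
    if outside:
        raise ValueError(f"QCI date outside the study window for: {outside[:5]}")

    df = pd.DataFrame(
        {
            "quarter": [quarter_label(d) for d in dates],
            "cost": np.asarray(total_costs, dtype=float),
            "to": np.asarray(to_flags, dtype=bool),
        }
    )
    rows = []
    grouped = df.groupby("quarter")
    for q in _quarter_sequence(w0, w1):
        if q in grouped.groups:
            g = grouped.get_group(q)
            n = len(g)
            ach = int(g["to"].sum())
            avg = float(g["cost"].mean())
            rows.append(
                QuarterSummary(q, n, ach, n - ach, ach / n, avg,
                               qci_value(ach / n, avg) if avg > 0 else float("nan"))
            )
        else:
            rows.append(QuarterSummary(q, 0, 0, 0, float("nan"), float("nan"), float("nan")))
    return pd.DataFrame([vars(s) for s in rows])


def pooled_proportion(summaries: pd.DataFrame) -> float:
    """Patient-weighted pooled TO proportion over quarters."""
    n = summaries["n"].sum()
    if n == 0:
        raise ValueError("no patients in any quarter")
    return float(summaries["to_achieved"].sum() / n)


def assign_case_mix(record: PatientRecord) -> Tuple[str, str, str]:
    """Case-mix cell (age band, TBSA band, etiology group).

    Bands are right-closed as printed: age 60 falls in 18-60, TBSA 5 in 0-5,
    20 in 11-20.  Etiology is flame vs everything else.
    """
    age_band = AGE_BANDS[0] if record.age_years <= 60 else AGE_BANDS[1]
    t = record.tbsa_percent
    if t <= 5:
        tbsa_band = TBSA_BANDS[0]
    elif t <= 10:
        tbsa_band = TBSA_BANDS[1]
    elif t <= 20:
        tbsa_band = TBSA_BANDS[2]
    else:
        tbsa_band = TBSA_BANDS[3]
    etiology_group = "flame" if record.etiology == "flame" else "other"
    return (age_band, tbsa_band, etiology_group)


def case_mix_weights(cells: Sequence[Tuple[str, str, str]]) -> pd.Series:
    """Fraction of patients in each occupied case-mix cell (sums to 1)."""
    s = pd.Series(cells).value_counts(normalize=True).sort_index()
    s.index.name = "cell"
    return s


def standardize_over_case_mix(
    patient_df: pd.DataFrame,
    weights: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Directly standardized quarterly TO proportion and mean cost.

    `patient_df` needs columns ``quarter``, ``cell``, ``to``, ``cost``.  The
    reference weights default to the whole-cohort cell distribution.  For each
    quarter, stratum-specific means are re-weighted to the reference mix;
    cells absent from a quarter are excluded with weight renormalization (and
    logged).  Crude values are always reported alongside the adjusted ones.
    """
    required = {"quarter", "cell", "to", "cost"}
    if not required <= set(patient_df.columns):
        raise ValueError(f"patient_df must have columns {sorted(required)}")
    if weights is None:
        weights = case_mix_weights(list(patient_df["cell"]))
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("reference weights must sum to 1")

    rows = []
    for q, g in patient_df.groupby("quarter", sort=True):
        strata = g.groupby("cell", sort=False).agg(to=("to", "mean"), cost=("cost", "mean"))
        present = [c for c in weights.index if c in strata.index]
        missing = [c for c in weights.index if c not in strata.index]
        if missing:
            logger.info(
                "quarter %s: %d reference cell(s) empty, weights renormalized", q, len(missing)
            )
        w = weights.loc[present] / weights.loc[present].sum()
        rows.append(
            {
                "quarter": q,
                "n": len(g),
                "crude_to": float(g["to"].mean()),
                "adjusted_to": float((strata.loc[present, "to"] * w).sum()),
                "crude_cost": float(g["cost"].mean()),
                "adjusted_cost": float((strata.loc[present, "cost"] * w).sum()),
                "n_cells_excluded": len(missing),
            }
        )
    return pd.DataFrame(rows)


def _kw_statistic(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    offset = 0
    for g in groups:
        r = ranks[offset : offset + g.size]
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
        offset += g.size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0.0:
        return 0.0
    return h / tie


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "asymptotic"
) -> Tuple[float, float]:
    """Kruskal-Wallis rank test across cost groups.

    ``asymptotic`` (default) uses the chi-square approximation with k-1
    degrees of freedom; ``exact`` enumerates every assignment of the pooled
    observations to the observed group sizes (intended for n <= 10) and
    returns the permutation p-value.  Identical observations across all
    groups give ``(0.0, 1.0)``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size == 0 for a in arrs):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    if method == "asymptotic":
        h, p = stats.kruskal(*arrs)
        return float(h), float(p)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    h_obs = _kw_statistic(arrs)
    sizes = [a.size for a in arrs]
    n = pooled.size
    idx_all = range(n)

    def assignments(remaining, sizes_left):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(sorted(remaining), k):
            rest = remaining - set(combo)
            for tail in assignments(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    total = 0
    extreme = 0
    for assign in assignments(set(idx_all), sizes):
        total += 1
        h = _kw_statistic([pooled[ix] for ix in assign])
        if h >= h_obs - 1e-12:
            extreme += 1
    return float(h_obs), extreme / total


def outcome_category_costs(
    indicator_matrix: pd.DataFrame,
    total_costs: Sequence[float],
    min_cell: int = 5,
    merge_set: Sequence[str] = DEFAULT_MERGE_SET,
    B: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Average total cost of achieved vs failed patients per outcome category.

    `indicator_matrix` is a boolean patient x indicator achievement frame.
    Any indicator in `merge_set` whose achieved or failed arm holds fewer than
    `min_cell` patients is pooled into an ``other`` category (failed = failed
    at least one merged indicator).  Each reported arm carries a percentile
    bootstrap CI of its mean, and each category a Kruskal-Wallis comparison
    between arms.
    """
    if min_cell < 1:
        raise ValueError("min_cell must be >= 1")
    missing = set(INDICATORS) - set(indicator_matrix.columns)
    if missing:
        raise ValueError(f"indicator matrix missing columns: {sorted(missing)}")
    costs = np.asarray(total_costs, dtype=float)
    if costs.size != len(indicator_matrix):
        raise ValueError("costs and indicator matrix must align")

    merged = [
        ind
        for ind in merge_set
        if min(
            int(indicator_matrix[ind].sum()),
            int((~indicator_matrix[ind]).sum()),
        )
        < min_cell
    ]
    categories = {ind: indicator_matrix[ind].to_numpy() for ind in INDICATORS if ind not in merged}
    if merged:
        categories["other"] = indicator_matrix[merged].all(axis=1).to_numpy()

    rng = np.random.default_rng(seed)
    rows = []
    for name, achieved in categories.items():
        arm_a, arm_f = costs[achieved], costs[~achieved]
        row = {
            "category": name,
            "merged_from": ",".join(merged) if name == "other" else "",
            "n_achieved": int(arm_a.size),
            "n_failed": int(arm_f.size),
            "mean_achieved": float(arm_a.mean()) if arm_a.size else float("nan"),
            "mean_failed": float(arm_f.mean()) if arm_f.size else float("nan"),
        }
        for arm, tag in ((arm_a, "achieved"), (arm_f, "failed")):
            if arm.size >= 2:
                lo, hi = bootstrap_mean_ci(
                    arm, B=B, alpha=alpha, seed=int(rng.integers(0, 2**31 - 1))
                )
            else:
                lo = hi = float("nan")
            row[f"ci_lo_{tag}"], row[f"ci_hi_{tag}"] = lo, hi
        if arm_a.size and arm_f.size:
            h, p = kruskal_wallis([arm_a, arm_f])
        else:
            h, p = float("nan"), float("nan")
        row["kw_H"], row["kw_p"] = h, p
        rows.append(row)
    return pd.DataFrame(rows)
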
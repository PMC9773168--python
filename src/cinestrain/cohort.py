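"""Cohort assembly: inclusion filtering, stratification, selection, outliers.

Applies the study's eligibility rules (age 45–74, BMI 18.5–30, no diabetes,
never-smokers, qualifying ethnicity), partitions eligible subjects into the
12 sex × age-band × health cells, randomly selects fixed-size healthy
cells, removes whole individuals outside ±k SD on any analysis variable
within their group (single pass), and produces per-group summary tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline import ANALYSIS_VARIABLES
from .synthetic import AGE_BAND_RANGES, GroupSpec, all_groups

__all__ = [
    "InclusionCriteria",
    "OutlierRule",
    "apply_inclusion_filters",
    "age_band_of",
    "stratify",
    "select_random",
    "remove_outliers",
    "summarize",
]

# diagnoses that define the unhealthy stratum
CARDIOVASCULAR_FLAGS = ("stemi", "nstemi", "heart_failure")

VOLUME_VARIABLES = ("EDV", "ESV")


@dataclass(frozen=True)
class InclusionCriteria:
    """Eligibility windows and exclusion flags (closed intervals)."""

    bmi_range: tuple[float, float] = (18.5, 30.0)
    age_range: tuple[float, float] = (45.0, 74.0)
    exclude_diabetes: bool = True
    exclude_smokers: bool = True
    require_qualifying_ethnicity: bool = True

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("bmi_range", self.bmi_range), ("age_range", self.age_range)):
            if not lo < hi:
                raise ValueError(f"{name} must satisfy lower < upper, got ({lo}, {hi})")


@dataclass(frozen=True)
class OutlierRule:
    """±k·SD whole-individual removal, per variable within each group.

    ``unphysical_factor``: volumes beyond this multiple of the group median
    are treated as data-entry errors and removed before the SD rule.
    """

    k: float = 2.7
    variables: tuple = ANALYSIS_VARIABLES
    unphysical_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")


def apply_inclusion_filters(
    records: pd.DataFrame,
    criteria: InclusionCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into eligible and excluded, tagging the first failing rule.

    Returns ``(kept, excluded)``; ``excluded`` carries a ``reason`` column
    (missing-data, ethnicity, diabetes, smoker, bmi, age).  Input order is
    preserved in both outputs.
    """
    criteria = criteria or InclusionCriteria()
    reasons = []
    for _, row in records.iterrows():
        reason = None
        for col in ("age", "BMI"):
            if col not in row or pd.isna(row[col]):
                reason = "missing-data"
                break
        if reason is None and criteria.require_qualifying_ethnicity and not bool(
            row.get("qualifying_ethnicity", True)
        ):
            reason = "ethnicity"
        if reason is None and criteria.exclude_diabetes and bool(row.get("diabetes", False)):
            reason = "diabetes"
        if reason is None and criteria.exclude_smokers and bool(row.get("smoker", False)):
            reason = "smoker"
        if reason is None and not (criteria.bmi_range[0] <= row["BMI"] <= criteria.bmi_range[1]):
            reason = "bmi"
        if reason is None and not (
            criteria.age_range[0] <= row["age"] <= criteria.age_range[1]
        ):
            reason = "age"
        reasons.append(reason)
    reasons = pd.Series(reasons, index=records.index, dtype=object)
    kept = records[reasons.isna()].copy()
    excluded = records[reasons.notna()].copy()
    excluded["reason"] = reasons[reasons.notna()]
    return kept, excluded


def age_band_of(age: float) -> str | None:
    """Closed decade band containing the (floored) integer age, or None."""
    yr = float(np.floor(age))
    for band, (lo, hi) in AGE_BAND_RANGES.items():
        if lo <= yr <= hi:
            return band
    return None


def _health_of(row: pd.Series) -> str:
    if any(bool(row.get(flag, False)) for flag in CARDIOVASCULAR_FLAGS):
        return "unhealthy"
    if "health" in row and isinstance(row["health"], str):
        return row["health"]
    return "healthy"


def stratify(records: pd.DataFrame) -> dict[GroupSpec, pd.DataFrame]:
    """Partition eligible records into the 12 sex × age-band × health cells.

    Health is *unhealthy* iff any cardiovascular diagnosis flag (STEMI,
    NSTEMI, heart failure) is set; records may alternatively carry an
    explicit ``health`` column.  Every record lands in exactly one cell.
    """
    cells: dict[GroupSpec, list] = {g: [] for g in all_groups()}
    for idx, row in records.iterrows():
        band = age_band_of(row["age"])
        if band is None:
            raise ValueError(f"record {row.get('subject_id', idx)} has age outside all bands")
        g = GroupSpec(sex=row["sex"], age_band=band, health=_health_of(row))
        cells[g].append(idx)
    return {g: records.loc[ix] for g, ix in cells.items()}


def select_random(cell_records: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform without-replacement sample of ``n`` records, reproducibly.

    Cells smaller than ``n`` pass through whole with a warning (the
    situation of every unhealthy cell in the source design).
    """
    if n <= 0:
        raise ValueError(f"selection size must be positive, got {n}")
    if n >= len(cell_records):
        if n > len(cell_records):
            warnings.warn(
                f"requested {n} but cell has only {len(cell_records)}; keeping all",
                stacklevel=2,
            )
        return cell_records.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cell_records), size=n, replace=False)
    return cell_records.iloc[np.sort(idx)].copy()


def remove_outliers(
    group_table: pd.DataFrame,
    rule: OutlierRule | None = None,
) -> tuple[pd.DataFrame, list]:
    """Single-pass ±k·SD outlier removal within one group table.

    Volume values beyond ``unphysical_factor`` × the group median are
    removed first as data-entry errors; then any individual with any
    analysis variable outside mean ± k·SD (n−1 SD, computed on the
    remaining rows) is removed whole.  Returns (kept, removed subject ids).
    Groups with fewer than 3 rows are returned untouched with a warning.
    """
    rule = rule or OutlierRule()
    if len(group_table) < 3:
        warnings.warn("group too small for outlier screening; skipped", stacklevel=2)
        return group_table.copy(), []

    removed: list = []
    tbl = group_table
    # stage 1: unphysical volume entries
    bad = pd.Series(False, index=tbl.index)
    for var in VOLUME_VARIABLES:
        if var not in tbl.columns:
            continue
        vals = tbl[var]
        med = vals.median()
        if med > 0:
            bad |= vals > rule.unphysical_factor * med
    removed.extend(tbl.loc[bad, "subject_id"].tolist() if "subject_id" in tbl else list(tbl.index[bad]))
    tbl = tbl[~bad]

    # stage 2: one pass of the SD rule (statistics are not recomputed)
    flag = pd.Series(False, index=tbl.index)
    for var in rule.variables:
        if var not in tbl.columns:
            continue
        vals = tbl[var].astype(float)
        mean, sd = vals.mean(), vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        flag |= (vals - mean).abs() > rule.k * sd
    removed.extend(tbl.loc[flag, "subject_id"].tolist() if "subject_id" in tbl else list(tbl.index[flag]))
    return tbl[~flag].copy(), removed


def summarize(
    group_table: pd.DataFrame,
    variables: tuple = ANALYSIS_VARIABLES,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-variable mean, SD, median, t-based CI of the mean, and n.

    Missing entries reduce the per-variable n (summaries use pairwise
    deletion); an empty group yields an all-NaN table rather than an error.
    """
    rows = []
    for var in variables:
        vals = group_table[var].dropna().astype(float) if var in group_table.columns else pd.Series(dtype=float)
        n = len(vals)
        if n == 0:
            rows.append({"variable": var, "mean": np.nan, "sd": np.nan, "median": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "n": 0})
            continue
        mean = vals.mean()
        sd = vals.std(ddof=1) if n > 1 else 0.0
        if n > 1 and sd > 0:
            half = sps.t.ppf(0.5 + ci_level / 2, n - 1) * sd / np.sqrt(n)
        else:
            half = 0.0
        rows.append({"variable": var, "mean": mean, "sd": sd, "median": vals.median(),
                     "ci_lo": mean - half, "ci_hi": mean + half, "n": n})
    return pd.DataFrame(rows).set_index("variable")
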
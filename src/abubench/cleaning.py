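"""Exclusion, imputation and stratification rules.

Three stages turn a raw cohort into benchmarkable data:

1. prescription hygiene — exact duplicates collapse to one row, and rows
   with implausible values (therapy days outside ``(0, 365]``, animals
   treated outside ``[1, 10000]``) are dropped;
2. consultation eligibility — a pATI is computable for a practice ×
   species × year only if a usable NbConsult exists.  A practice that
   registered NbConsult for at least one year of the window gets missing
   years imputed as the *maximum* over its registered years (flagged
   ``corrected``); a practice with no registered year for a species is
   excluded outright, as is any year with fewer than 100 consultations;
3. stratification — mixed practices form their own stratum regardless of
   volume; companion practices/clinics split at 4500 consultations per
   year (strictly above → large), evaluated per species on the benchmark
   year's NbConsult.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import DeclaredType, ExclusionReason, PracticeType, Species

logger = logging.getLogger(__name__)

ELIGIBILITY_COLUMNS = [
    "practice_id",
    "species",
    "year",
    "nbconsult_raw",
    "nbconsult_used",
    "corrected",
    "eligible",
    "exclusion_reason",
]

MIN_CONSULTATIONS = 100  #: below this, a practice-year is not benchmarked
SIZE_SPLIT = 4500  #: companion practices: strictly more → large stratum


def deduplicate_prescriptions(prescriptions: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse rows that are identical in *every* field to one row."""
    out = prescriptions.drop_duplicates(keep="first").reset_index(drop=True)
    n_dropped = len(prescriptions) - len(out)
    if n_dropped:
        logger.info("deduplicate_prescriptions: dropped %d duplicate rows", n_dropped)
    return out, n_dropped


def filter_outliers(
    prescriptions: pd.DataFrame,
    max_therapy_days: float = 365.0,
    max_animals_treated: int = 10000,
) -> tuple[pd.DataFrame, int]:
    """Drop rows with non-positive or implausibly large values.

    Bounds are inclusive: ``therapy_days`` in ``(0, max_therapy_days]``,
    ``animals_treated`` in ``[1, max_animals_treated]``.
    """
    td = prescriptions["therapy_days"]
    at = prescriptions["animals_treated"]
    keep = (td > 0) & (td <= max_therapy_days) & (at >= 1) & (at <= max_animals_treated)
    out = prescriptions[keep].reset_index(drop=True)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_outliers: dropped %d rows", n_dropped)
    return out, n_dropped


def impute_consultations(
    consultations: pd.DataFrame,
    practices: pd.DataFrame,
    years: Sequence[int],
) -> pd.DataFrame:
    """Build the eligibility table for every practice × species × year.

    Missing years for a practice × species with at least one registered
    year get ``nbconsult_used`` = max over registered years and
    ``corrected = True``.  Exclusions: ``no_nbconsult_any_year`` when no
    year of the window is registered for that species, ``under_100``
    when the (possibly imputed) count is below 100.
    """
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("years must be non-empty")

    full = pd.MultiIndex.from_product(
        [practices["practice_id"].unique(), [s.value for s in Species], years],
        names=["practice_id", "species", "year"],
    )
    cons = consultations[consultations["year"].isin(years)]
    raw = (
        cons.set_index(["practice_id", "species", "year"])["n_consultations"]
        .astype(float)
        .reindex(full)
    )
    df = raw.rename("nbconsult_raw").reset_index()
    grp = df.groupby(["practice_id", "species"])["nbconsult_raw"]
    group_max = grp.transform("max")  # NaN iff no registered year
    registered_any = group_max.notna()

    df["nbconsult_used"] = df["nbconsult_raw"].where(df["nbconsult_raw"].notna(), group_max)
    df["corrected"] = df["nbconsult_raw"].isna() & registered_any
    df["eligible"] = df["nbconsult_used"] >= MIN_CONSULTATIONS
    reason = np.where(
        ~registered_any,
        ExclusionReason.NO_NBCONSULT_ANY_YEAR.value,
        np.where(df["eligible"], None, ExclusionReason.UNDER_100.value),
    )
    df["exclusion_reason"] = reason
    df = df[ELIGIBILITY_COLUMNS]

    n_corrected = int(df["corrected"].sum())
    n_excluded = int((~df["eligible"]).sum())
    logger.info(
        "impute_consultations: %d rows, %d corrected, %d ineligible",
        len(df), n_corrected, n_excluded,
    )
    return df


def assign_stratum(
    declared_type: Union[str, DeclaredType],
    nbconsult_used: Optional[float],
) -> PracticeType:
    """Stratum for one practice × species given the benchmark year's
    consultation count.  Declared mixed practices are always ``mixed``;
    companion practices/clinics are large only strictly above 4500."""
    declared = DeclaredType(declared_type)
    if declared is DeclaredType.MIXED_PRACTICE:
        return PracticeType.MIXED
    if nbconsult_used is not None and not np.isnan(nbconsult_used) and nbconsult_used > SIZE_SPLIT:
        return PracticeType.SMALL_GE4500
    return PracticeType.SMALL_LT4500


def assign_strata(
    practices: pd.DataFrame,
    eligibility: pd.DataFrame,
    benchmark_year: int,
) -> pd.DataFrame:
    """Per practice × species stratum, from the benchmark year's
    ``nbconsult_used``.  Returns columns practice_id, species,
    practice_type."""
    ref = eligibility[eligibility["year"] == benchmark_year][
        ["practice_id", "species", "nbconsult_used"]
    ]
    merged = ref.merge(practices[["practice_id", "declared_type"]], on="practice_id", how="left")
    merged["practice_type"] = [
        assign_stratum(d, n).value
        for d, n in zip(merged["declared_type"], merged["nbconsult_used"])
    ]
    return merged[["practice_id", "species", "practice_type"]]
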
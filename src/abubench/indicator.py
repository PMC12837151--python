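"""The practice-level antibiotic treatment indicator (pATI).

For one practice, species and year,

    pATI = sum_i TD_i * NbAS_i * AT_i / NbConsult

summed over all antibiotic prescriptions *i* of that practice, species
and year, where

* ``TD_i`` — therapy days: administered treatment days plus the longest
  carry-over (active-substance effective time) among the product's
  substances, taken from the substance catalog (default 0);
* ``NbAS_i`` — number of active substances in the product; under the
  ``critical`` scope, only critical substances are counted, so products
  without any critical substance contribute 0;
* ``AT_i`` — number of animals treated with the prescription;
* ``NbConsult`` — annual consultations of the practice for the species,
  the population at risk.  Practices below 100 consultations are never
  scored; the eligibility table decides which (practice, species, year)
  combinations get a value.

A pATI of 0 identifies a non-user (no antibiotic prescriptions despite
being eligible).
"""

from __future__ import annotations

from typing import Optional, Union

import pandas as pd

from .cleaning import MIN_CONSULTATIONS, assign_strata
from .records import PrescriptionRecord, Scope, SubstanceCatalog

PATI_COLUMNS = [
    "practice_id",
    "species",
    "year",
    "scope",
    "pati",
    "corrected",
    "practice_type",
]


def _substance_stats(substances: str, catalog: SubstanceCatalog) -> tuple[int, int, float]:
    """(n substances, n critical substances, max carry-over days) for a
    semicolon-joined substance list."""
    codes = [s for s in substances.split(";") if s]
    n_crit = sum(catalog.is_critical(c) for c in codes)
    max_carry = max(catalog.carryover_days(c) for c in codes)
    return len(codes), n_crit, max_carry


def therapy_days(
    record: Union[PrescriptionRecord, pd.Series, dict], catalog: SubstanceCatalog
) -> float:
    """TD_i: administered days plus the product's maximum carry-over."""
    if isinstance(record, PrescriptionRecord):
        subs = ";".join(record.substances)
        days = record.therapy_days
    else:
        subs = record["substances"]
        days = record["therapy_days"]
    _, _, carry = _substance_stats(subs, catalog)
    return float(days) + carry


def _as_frame(prescriptions) -> pd.DataFrame:
    if isinstance(prescriptions, pd.DataFrame):
        return prescriptions
    from .io import prescriptions_to_frame

    return prescriptions_to_frame(list(prescriptions))


def _with_contributions(presc: pd.DataFrame, catalog: SubstanceCatalog) -> pd.DataFrame:
    """Annotate prescriptions with per-row numerator terms for both scopes."""
    out = presc.copy()
    stats = {s: _substance_stats(s, catalog) for s in out["substances"].unique()}
    nbas_all = out["substances"].map(lambda s: stats[s][0])
    nbas_crit = out["substances"].map(lambda s: stats[s][1])
    carry = out["substances"].map(lambda s: stats[s][2])
    td_eff = out["therapy_days"].astype(float) + carry
    at = out["animals_treated"].astype(float)
    out["_contrib_all"] = td_eff * nbas_all * at
    out["_contrib_critical"] = td_eff * nbas_crit * at
    return out


def compute_pati(
    prescriptions,
    nbconsult_used: float,
    scope: Union[str, Scope],
    catalog: SubstanceCatalog,
) -> float:
    """pATI for one practice × species × year.

    ``prescriptions`` are the rows of that practice/species/year (a
    DataFrame or an iterable of records); an empty set gives 0.
    """
    if nbconsult_used < MIN_CONSULTATIONS:
        raise ValueError(
            f"nbconsult_used={nbconsult_used} < {MIN_CONSULTATIONS}: "
            "ineligible practice-years must be filtered upstream"
        )
    scope = Scope(scope)
    presc = _as_frame(prescriptions)
    if len(presc) == 0:
        return 0.0
    annotated = _with_contributions(presc, catalog)
    col = "_contrib_all" if scope is Scope.ALL else "_contrib_critical"
    return float(annotated[col].sum()) / float(nbconsult_used)


def compute_pati_table(
    prescriptions,
    eligibility: pd.DataFrame,
    practices: pd.DataFrame,
    catalog: SubstanceCatalog,
    benchmark_year: Optional[int] = None,
) -> pd.DataFrame:
    """One pATI value per eligible (practice, species, year) and scope.

    Eligible combinations with no prescriptions get pATI 0 (non-users);
    ineligible combinations are absent.  ``corrected`` is copied from
    the eligibility table; ``practice_type`` is the benchmark-year
    stratum of the practice × species (default: last year of the
    window).
    """
    if benchmark_year is None:
        benchmark_year = int(eligibility["year"].max())
    presc = _as_frame(prescriptions)
    elig = eligibility[eligibility["eligible"]][
        ["practice_id", "species", "year", "nbconsult_used", "corrected"]
    ].copy()

    if len(presc):
        annotated = _with_contributions(presc, catalog)
        sums = (
            annotated.groupby(["practice_id", "species", "year"], as_index=False)[
                ["_contrib_all", "_contrib_critical"]
            ].sum()
        )
        merged = elig.merge(sums, on=["practice_id", "species", "year"], how="left")
    else:
        merged = elig.assign(_contrib_all=0.0, _contrib_critical=0.0)
    merged[["_contrib_all", "_contrib_critical"]] = merged[
        ["_contrib_all", "_contrib_critical"]
    ].fillna(0.0)

    strata = assign_strata(practices, eligibility, benchmark_year)
    merged = merged.merge(strata, on=["practice_id", "species"], how="left")

    parts = []
    for scope in (Scope.ALL, Scope.CRITICAL):
        col = "_contrib_all" if scope is Scope.ALL else "_contrib_critical"
        part = merged[
            ["practice_id", "species", "year", "corrected", "practice_type"]
        ].copy()
        part["scope"] = scope.value
        part["pati"] = merged[col] / merged["nbconsult_used"]
        parts.append(part)
    table = pd.concat(parts, ignore_index=True)[PATI_COLUMNS]
    return (
        table.sort_values(["practice_id", "species", "year", "scope"], kind="mergesort")
        .reset_index(drop=True)
    )
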
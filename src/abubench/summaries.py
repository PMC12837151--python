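"""Per-practice and cohort-level summary statistics.

Covers the descriptive half of the benchmark report (treatment counts,
critical shares, antibiotic-class and indication breakdowns, top
products), the stratum overview table (medians/means/maxima per practice
type and species), the per-canton aggregation, and the cluster-bootstrap
comparison of group quantiles that replaces a quantile-regression fit:
practices contribute values to both species, so practice ids are
resampled with replacement as whole clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .indicator import therapy_days
from .records import SubstanceCatalog


def ratio_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-away-from-zero to one decimal — the
    convention behind printed shares like 686/989 → 69.4."""
    if denominator == 0:
        raise ZeroDivisionError("ratio_pct: zero denominator")
    frac = Decimal(int(numerator)) / Decimal(int(denominator)) * 100
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PracticeSummary:
    """Descriptive ABU statistics for one practice × species × year."""

    practice_id: str
    species: str
    year: int
    n_consultations: Optional[float]
    n_treatments: int
    n_critical_treatments: int
    pct_ab_treatments: Optional[float]  # treatments per 100 consultations
    pct_critical: float  # critical treatments per 100 treatments
    therapy_days_per_animal: float
    treatments_by_class: dict[str, int] = field(default_factory=dict)
    treatments_by_indication: dict[str, int] = field(default_factory=dict)
    top_vmps: list[tuple[str, int, Optional[float]]] = field(default_factory=list)


def summarize_practice(
    prescriptions: pd.DataFrame,
    practice_id: str,
    species: str,
    year: int,
    nbconsult_used: Optional[float],
    catalog: SubstanceCatalog,
    n_top_vmps: int = 10,
) -> PracticeSummary:
    """Summary of one practice × species × year from the raw rows.

    A treatment is one treated animal; a prescription with a product
    containing at least one critical substance counts as a critical
    treatment.  ``treatments_by_class`` attributes each treatment to
    the class of the product's first-listed (primary) substance so the
    class counts partition ``n_treatments``.  Top products are ranked
    by treatment count, ties broken by vmp_id; the modal dosage is the
    most frequent one, ties broken by the smallest value.
    """
    rows = prescriptions[
        (prescriptions["practice_id"] == practice_id)
        & (prescriptions["species"] == species)
        & (prescriptions["year"] == year)
    ]
    n_treat = int(rows["animals_treated"].sum())
    if n_treat == 0:
        return PracticeSummary(
            practice_id, species, year,
            nbconsult_used, 0, 0,
            None if nbconsult_used in (None,) or pd.isna(nbconsult_used)
            else 0.0,
            0.0, 0.0,
        )

    is_crit = rows["substances"].map(
        lambda s: any(catalog.is_critical(c) for c in s.split(";") if c)
    )
    n_crit = int(rows.loc[is_crit, "animals_treated"].sum())

    td_eff = rows.apply(lambda r: therapy_days(r, catalog), axis=1)
    td_per_animal = float((td_eff * rows["animals_treated"]).sum() / n_treat)

    by_class: dict[str, int] = {}
    by_indication: dict[str, int] = {}
    for _, r in rows.iterrows():
        at = int(r["animals_treated"])
        primary = r["substances"].split(";")[0]
        cls = catalog.ab_class(primary)
        by_class[cls] = by_class.get(cls, 0) + at
        ind = r["indication"] or "unspecified"
        by_indication[ind] = by_indication.get(ind, 0) + at

    vmp_counts = (
        rows.groupby("vmp_id")["animals_treated"].sum().astype(int).sort_index()
    )
    ranked = vmp_counts.sort_values(ascending=False, kind="mergesort")
    top = []
    for vmp in ranked.index[:n_top_vmps]:
        doses = rows.loc[rows["vmp_id"] == vmp, "dosage_mg_per_kg"].dropna()
        if len(doses):
            counts = doses.value_counts()
            best = counts.max()
            modal = float(min(d for d, c in counts.items() if c == best))
        else:
            modal = None
        top.append((vmp, int(ranked[vmp]), modal))

    has_nb = nbconsult_used is not None and not pd.isna(nbconsult_used)
    pct_ab = 100.0 * n_treat / float(nbconsult_used) if has_nb else None
    return PracticeSummary(
        practice_id=practice_id,
        species=species,
        year=year,
        n_consultations=float(nbconsult_used) if has_nb else None,
        n_treatments=n_treat,
        n_critical_treatments=n_crit,
        pct_ab_treatments=pct_ab,
        pct_critical=100.0 * n_crit / n_treat,
        therapy_days_per_animal=td_per_animal,
        treatments_by_class=dict(sorted(by_class.items())),
        treatments_by_indication=dict(sorted(by_indication.items())),
        top_vmps=top,
    )


def practice_species_stats(
    prescriptions: pd.DataFrame,
    eligibility: pd.DataFrame,
    catalog: SubstanceCatalog,
    year: int,
) -> pd.DataFrame:
    """Vectorised per practice × species counts for one year (eligible
    rows only): consultations, treatments, critical treatments, and the
    two percentage indicators."""
    elig = eligibility[(eligibility["year"] == year) & eligibility["eligible"]][
        ["practice_id", "species", "nbconsult_used"]
    ].copy()
    rows = prescriptions[prescriptions["year"] == year]
    if len(rows):
        is_crit = rows["substances"].map(
            lambda s: any(catalog.is_critical(c) for c in s.split(";") if c)
        )
        at = rows["animals_treated"].astype(int)
        counts = (
            pd.DataFrame(
                {
                    "practice_id": rows["practice_id"],
                    "species": rows["species"],
                    "n_treatments": at,
                    "n_critical_treatments": at.where(is_crit, 0),
                }
            )
            .groupby(["practice_id", "species"], as_index=False)
            .sum()
        )
        out = elig.merge(counts, on=["practice_id", "species"], how="left")
    else:
        out = elig.assign(n_treatments=0, n_critical_treatments=0)
    out[["n_treatments", "n_critical_treatments"]] = (
        out[["n_treatments", "n_critical_treatments"]].fillna(0).astype(int)
    )
    out["pct_ab_treatments"] = 100.0 * out["n_treatments"] / out["nbconsult_used"]
    out["pct_critical"] = np.where(
        out["n_treatments"] > 0,
        100.0 * out["n_critical_treatments"] / out["n_treatments"].replace(0, 1),
        0.0,
    )
    return out


COHORT_SUMMARY_COLUMNS = [
    "practice_type", "species",
    "consultations_median", "consultations_mean", "consultations_max",
    "treatments_median", "treatments_mean", "treatments_max",
    "critical_treatments_median", "critical_treatments_mean", "critical_treatments_max",
    "pct_ab_treatments_median", "pct_critical_median",
    "pati_median", "pati_critical_median",
    "n_practices",
]


def summarize_cohort(
    stats: pd.DataFrame,
    pati_table: pd.DataFrame,
    benchmark_year: Optional[int] = None,
) -> pd.DataFrame:
    """Stratum overview: medians/means/maxima of consultations and
    treatments, median treatment percentages and median pATI per
    practice type × species.

    ``stats`` is the output of :func:`practice_species_stats` for the
    benchmark year; strata and pATI values come from ``pati_table``.
    """
    if benchmark_year is None:
        benchmark_year = int(pati_table["year"].max())
    py = pati_table[pati_table["year"] == benchmark_year]
    pati_wide = py.pivot_table(
        index=["practice_id", "species", "practice_type"],
        columns="scope", values="pati", aggfunc="first",
    ).reset_index().rename(columns={"all": "pati_all", "critical": "pati_critical"})
    merged = stats.merge(pati_wide, on=["practice_id", "species"], how="inner")

    rows = []
    for (ptype, species), g in merged.groupby(["practice_type", "species"], sort=True):
        rows.append(
            {
                "practice_type": ptype,
                "species": species,
                "consultations_median": g["nbconsult_used"].median(),
                "consultations_mean": g["nbconsult_used"].mean(),
                "consultations_max": g["nbconsult_used"].max(),
                "treatments_median": g["n_treatments"].median(),
                "treatments_mean": g["n_treatments"].mean(),
                "treatments_max": g["n_treatments"].max(),
                "critical_treatments_median": g["n_critical_treatments"].median(),
                "critical_treatments_mean": g["n_critical_treatments"].mean(),
                "critical_treatments_max": g["n_critical_treatments"].max(),
                "pct_ab_treatments_median": g["pct_ab_treatments"].median(),
                "pct_critical_median": g["pct_critical"].median(),
                "pati_median": g["pati_all"].median(),
                "pati_critical_median": g["pati_critical"].median(),
                "n_practices": len(g),
            }
        )
    return pd.DataFrame(rows, columns=COHORT_SUMMARY_COLUMNS)


def canton_summary(
    practices: pd.DataFrame,
    categories: pd.DataFrame,
    prescriptions: pd.DataFrame,
    year: Optional[int] = None,
) -> pd.DataFrame:
    """Benchmarked practices and animal treatments per canton.

    ``n_practices`` counts practices with at least one classification;
    ``n_treatments`` sums treated animals over all prescriptions of the
    (benchmark) year.  ``share_*_pct`` columns use the printed-share
    rounding; ``share_*_raw`` are unrounded and sum to 100.
    """
    if year is None and len(prescriptions):
        year = int(prescriptions["year"].max())
    benchmarked = set(categories["practice_id"].unique())
    pr = practices.copy()
    pr["benchmarked"] = pr["practice_id"].isin(benchmarked)
    n_practices = (
        pr[pr["benchmarked"]].groupby("canton")["practice_id"].nunique()
    )
    rows = prescriptions[prescriptions["year"] == year] if len(prescriptions) else prescriptions
    treats = (
        rows.merge(practices[["practice_id", "canton"]], on="practice_id", how="left")
        .groupby("canton")["animals_treated"].sum()
        if len(rows)
        else pd.Series(dtype=int)
    )
    cantons = sorted(set(n_practices.index) | set(treats.index))
    out = pd.DataFrame(
        {
            "canton": cantons,
            "n_practices": [int(n_practices.get(c, 0)) for c in cantons],
            "n_treatments": [int(treats.get(c, 0)) for c in cantons],
        }
    )
    tot_p = out["n_practices"].sum()
    tot_t = out["n_treatments"].sum()
    out["share_practices_raw"] = 100.0 * out["n_practices"] / tot_p if tot_p else 0.0
    out["share_treatments_raw"] = 100.0 * out["n_treatments"] / tot_t if tot_t else 0.0
    out["share_practices_pct"] = [
        ratio_pct(n, tot_p) if tot_p else 0.0 for n in out["n_practices"]
    ]
    out["share_treatments_pct"] = [
        ratio_pct(n, tot_t) if tot_t else 0.0 for n in out["n_treatments"]
    ]
    return out


class BootstrapQuantileResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    q: float
    n_boot: int


def bootstrap_quantile_diff(
    values_a: Sequence[float],
    values_b: Sequence[float],
    q: float,
    clusters_a: Sequence,
    clusters_b: Sequence,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> BootstrapQuantileResult:
    """Cluster-bootstrap comparison of one quantile between two groups.

    The estimate is ``quantile(values_a, q) - quantile(values_b, q)``.
    Cluster ids (practices) are resampled with replacement from the
    union of both groups; a resampled cluster brings along *all* its
    values in either group, preserving the within-practice correlation
    of e.g. cat and dog values.  The two-sided p-value comes from the
    sign of the bootstrap distribution of the difference, with add-one
    smoothing so p is never exactly 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ca = np.asarray(clusters_a)
    cb = np.asarray(clusters_b)
    if len(a) != len(ca) or len(b) != len(cb):
        raise ValueError("values and cluster ids must have equal lengths")
    if len(a) < 10 or len(b) < 10:
        raise ValueError("each group needs at least 10 values (quantile unstable)")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")

    rng = np.random.default_rng(seed)
    estimate = float(np.quantile(a, q) - np.quantile(b, q))

    clusters = np.unique(np.concatenate([ca, cb]))
    k = len(clusters)
    pos = {c: i for i, c in enumerate(clusters)}
    codes_a = np.array([pos[c] for c in ca])
    codes_b = np.array([pos[c] for c in cb])
    counts_a = np.bincount(codes_a, minlength=k)
    counts_b = np.bincount(codes_b, minlength=k)

    samples = rng.integers(0, k, size=(n_boot, k))
    if counts_a.max() <= 1 and counts_b.max() <= 1:
        # one value per cluster per group: vectorised gather with NaN
        # for clusters absent from a group
        va = np.full(k, np.nan)
        va[codes_a] = a
        vb = np.full(k, np.nan)
        vb[codes_b] = b
        if counts_a.min() == 1 and counts_b.min() == 1:
            qa = np.quantile(va[samples], q, axis=1)
            qb = np.quantile(vb[samples], q, axis=1)
        else:
            with np.errstate(all="ignore"):
                qa = np.nanquantile(va[samples], q, axis=1)
                qb = np.nanquantile(vb[samples], q, axis=1)
        boot = qa - qb
        boot = boot[~np.isnan(boot)]
    else:
        vals_a = [a[codes_a == i] for i in range(k)]
        vals_b = [b[codes_b == i] for i in range(k)]
        boot_list = []
        for row in samples:
            sa = np.concatenate([vals_a[i] for i in row if counts_a[i]] or [np.empty(0)])
            sb = np.concatenate([vals_b[i] for i in row if counts_b[i]] or [np.empty(0)])
            if len(sa) == 0 or len(sb) == 0:
                continue
            boot_list.append(np.quantile(sa, q) - np.quantile(sb, q))
        boot = np.asarray(boot_list)
    if len(boot) == 0:
        raise ValueError("all bootstrap replicates degenerate (empty groups)")

    n_eff = len(boot)
    p_low = (1 + int((boot <= 0).sum())) / (n_eff + 1)
    p_high = (1 + int((boot >= 0).sum())) / (n_eff + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    ci_low, ci_high = np.quantile(boot, [0.025, 0.975])
    return BootstrapQuantileResult(estimate, float(ci_low), float(ci_high), p, q, n_boot)
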
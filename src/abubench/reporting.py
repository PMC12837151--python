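"""Pipeline orchestration and per-practice benchmark reports.

A report has two parts: (1) comparative data — the practice's own pATI
per year plotted against the anonymized pATI values of all comparable
practices (same stratum), with the signal/action threshold bands on a
log scale — and (2) a descriptive summary of the practice's antibiotic
use (treatment counts, critical share, class/indication breakdowns, top
products) next to the stratum medians.

Only the practice in question is identifiable in its own report; every
other practice appears as a bare number.  Practices without a pATI still
receive the cohort distribution, without their own point.

Because a pATI of 0 cannot be drawn on a log axis, null values are
plotted at half the smallest positive value of the panel and tagged
"no use" via the panel's ``zero_floor`` metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import NamedTuple, Optional

import pandas as pd

from . import cleaning, indicator, summaries
from .benchmarking import PercentileBenchmark
from .io import default_catalog
from .records import Scope, Species, SubstanceCatalog
from .simulate import CohortConfig, generate_cohort


class PipelineResult(NamedTuple):
    practices: pd.DataFrame
    consultations: pd.DataFrame
    prescriptions: pd.DataFrame  # cleaned
    eligibility: pd.DataFrame
    pati_table: pd.DataFrame
    benchmark: PercentileBenchmark
    categories: pd.DataFrame
    stats: pd.DataFrame
    cohort_summary: pd.DataFrame
    canton: pd.DataFrame
    counts: dict
    benchmark_year: int
    catalog: SubstanceCatalog


def run_pipeline(
    practices: pd.DataFrame,
    consultations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    catalog: Optional[SubstanceCatalog] = None,
    years: Optional[list[int]] = None,
    benchmark_year: Optional[int] = None,
    max_therapy_days: float = 365.0,
    signal_q: float = 0.75,
    action_q: float = 0.95,
) -> PipelineResult:
    """Clean → eligibility → pATI → thresholds → classification →
    summaries, on three in-memory tables."""
    catalog = catalog or default_catalog()
    if years is None:
        years = sorted(
            set(consultations["year"].unique()) | set(prescriptions["year"].unique())
        )
    years = [int(y) for y in years]
    if benchmark_year is None:
        benchmark_year = max(years)

    n_raw = len(prescriptions)
    presc, n_dup = cleaning.deduplicate_prescriptions(prescriptions)
    presc, n_out = cleaning.filter_outliers(presc, max_therapy_days=max_therapy_days)
    eligibility = cleaning.impute_consultations(consultations, practices, years)
    pati_table = indicator.compute_pati_table(
        presc, eligibility, practices, catalog, benchmark_year
    )
    bench = PercentileBenchmark(signal_q, action_q, benchmark_year).fit(pati_table)
    categories = bench.predict(pati_table)
    stats = summaries.practice_species_stats(presc, eligibility, catalog, benchmark_year)
    cohort_summary = summaries.summarize_cohort(stats, pati_table, benchmark_year)
    canton = summaries.canton_summary(practices, categories, presc, benchmark_year)
    counts = {
        "prescriptions_raw": n_raw,
        "prescriptions_duplicates_dropped": n_dup,
        "prescriptions_outliers_dropped": n_out,
        "prescriptions_kept": len(presc),
        "practices": len(practices),
        "eligibility_rows": len(eligibility),
        "eligible_rows": int(eligibility["eligible"].sum()),
        "pati_values": len(pati_table),
        "classified_values": len(categories),
        "benchmarked_practices": int(categories["practice_id"].nunique()),
    }
    return PipelineResult(
        practices, consultations, presc, eligibility, pati_table, bench,
        categories, stats, cohort_summary, canton, counts, benchmark_year, catalog,
    )


@dataclasses.dataclass(frozen=True)
class PracticeReport:
    practice_id: str
    benchmark_year: int
    panels: dict  # species -> scope -> panel dict
    summary: dict  # species -> practice summary (benchmark year)
    cohort_medians: dict  # species -> stratum medians

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _panel(
    result: PipelineResult, practice_id: str, species: str, scope: str
) -> dict:
    pt = result.pati_table
    own = pt[
        (pt["practice_id"] == practice_id)
        & (pt["species"] == species)
        & (pt["scope"] == scope)
    ]
    ptype = own["practice_type"].iloc[0] if len(own) else None

    cat_rows = result.categories[
        (result.categories["practice_id"] == practice_id)
        & (result.categories["species"] == species)
        & (result.categories["scope"] == scope)
    ]
    category = cat_rows["category"].iloc[0] if len(cat_rows) else None

    thr = None
    if ptype is not None:
        t = result.benchmark.thresholds_
        t = t[(t["practice_type"] == ptype) & (t["species"] == species) & (t["scope"] == scope)]
        if len(t):
            thr = {
                "signal": float(t["signal"].iloc[0]),
                "action": float(t["action"].iloc[0]),
                "n_contributing": int(t["n_contributing"].iloc[0]),
            }

    # comparable practices: same stratum, species, scope (no identifiers)
    if ptype is not None:
        comp = pt[
            (pt["species"] == species)
            & (pt["scope"] == scope)
            & (pt["practice_type"] == ptype)
        ]
    else:
        comp = pt[(pt["species"] == species) & (pt["scope"] == scope)]

    series = {}
    positive = comp[comp["pati"] > 0]["pati"]
    zero_floor = float(positive.min()) / 2.0 if len(positive) else None
    for year, g in comp.groupby("year"):
        others = g[g["practice_id"] != practice_id]["pati"]
        own_val = g[g["practice_id"] == practice_id]["pati"]
        series[int(year)] = {
            "values": sorted(round(float(v), 12) for v in others),
            "own": round(float(own_val.iloc[0]), 12) if len(own_val) else None,
        }
    return {
        "practice_type": ptype,
        "category": category,
        "thresholds": thr,
        "series": series,
        "display": {"scale": "log", "zero_floor": zero_floor, "zero_label": "no use"},
    }


def build_report(practice_id: str, result: PipelineResult) -> PracticeReport:
    """Assemble the full benchmark payload for one practice."""
    if practice_id not in set(result.practices["practice_id"]):
        raise KeyError(f"unknown practice {practice_id!r}")
    panels: dict = {}
    summary: dict = {}
    medians: dict = {}
    for species in (Species.DOG, Species.CAT):
        panels[species.value] = {
            scope.value: _panel(result, practice_id, species.value, scope.value)
            for scope in (Scope.ALL, Scope.CRITICAL)
        }
        elig = result.eligibility[
            (result.eligibility["practice_id"] == practice_id)
            & (result.eligibility["species"] == species.value)
            & (result.eligibility["year"] == result.benchmark_year)
        ]
        nb = elig["nbconsult_used"].iloc[0] if len(elig) else None
        ps = summaries.summarize_practice(
            result.prescriptions, practice_id, species.value,
            result.benchmark_year, nb, result.catalog,
        )
        summary[species.value] = dataclasses.asdict(ps)
        ptype = panels[species.value]["all"]["practice_type"]
        if ptype is not None:
            row = result.cohort_summary[
                (result.cohort_summary["practice_type"] == ptype)
                & (result.cohort_summary["species"] == species.value)
            ]
            medians[species.value] = (
                {k: float(v) for k, v in row.iloc[0].items() if isinstance(v, (int, float))}
                if len(row)
                else None
            )
        else:
            medians[species.value] = None
    return PracticeReport(practice_id, result.benchmark_year, panels, summary, medians)


def render_report(report: PracticeReport, format: str = "json") -> str:
    """Serialize a report deterministically as json, text or html."""
    data = report.to_dict()
    if format == "json":
        return json.dumps(data, sort_keys=True, indent=2)
    if format == "text":
        lines = [
            f"ABU benchmark report — practice {report.practice_id} "
            f"(benchmark year {report.benchmark_year})",
        ]
        for species in sorted(report.panels):
            for scope in sorted(report.panels[species]):
                p = report.panels[species][scope]
                lines.append(f"[{species} / {scope} antibiotics]")
                lines.append(f"  stratum: {p['practice_type'] or 'not benchmarked'}")
                lines.append(f"  category: {p['category'] or 'not classified'}")
                if p["thresholds"]:
                    lines.append(
                        "  signal (P75): {signal:.4g}  action (P95): {action:.4g}  "
                        "(n={n_contributing})".format(**p["thresholds"])
                    )
                for year in sorted(p["series"]):
                    s = p["series"][year]
                    own = "none" if s["own"] is None else f"{s['own']:.4g}"
                    lines.append(
                        f"  {year}: own pATI {own}, {len(s['values'])} comparable practices"
                    )
            summ = report.summary[species]
            lines.append(
                f"  {species} summary {report.benchmark_year}: "
                f"{summ['n_treatments']} treatments "
                f"({summ['n_critical_treatments']} critical)"
            )
        return "\n".join(lines) + "\n"
    if format == "html":
        payload = json.dumps(data, sort_keys=True)
        return (
            "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
            f"<title>ABU benchmark report {report.practice_id}</title></head>\n"
            "<body>\n"
            f"<h1>ABU benchmark report — practice {report.practice_id}</h1>\n"
            f"<p>Benchmark year: {report.benchmark_year}. "
            "pATI panels use a logarithmic axis; null values are drawn at the "
            "panel's zero floor and tagged “no use”.</p>\n"
            f"<script type=\"application/json\" id=\"report-data\">{payload}</script>\n"
            "</body></html>\n"
        )
    raise ValueError(f"unknown format {format!r}")


def extract_html_payload(html: str) -> dict:
    """Recover the embedded report data from a rendered HTML report."""
    start = html.index('id="report-data">') + len('id="report-data">')
    end = html.index("</script>", start)
    return json.loads(html[start:end])


def _config_hash(config: CohortConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_all(
    config: CohortConfig,
    out_dir,
    seed: Optional[int] = None,
    report_format: str = "json",
    write_reports: bool = True,
) -> dict:
    """Simulate a cohort, run the full pipeline, and write every output
    plus a run manifest under ``out_dir``.  Deterministic for a fixed
    seed: two runs produce byte-identical trees."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    used_seed = config.seed if seed is None else seed
    catalog = default_catalog()
    cohort = generate_cohort(config, seed=used_seed, catalog=catalog)
    cohort.practices.to_csv(out / "practices.csv", index=False)
    cohort.consultations.to_csv(out / "consultations.csv", index=False)
    cohort.prescriptions.to_csv(out / "prescriptions.csv", index=False)

    result = run_pipeline(
        cohort.practices, cohort.consultations, cohort.prescriptions,
        catalog=catalog, years=sorted(config.years),
    )
    result.eligibility.to_csv(out / "eligibility.csv", index=False)
    result.pati_table.to_csv(out / "pati.csv", index=False)
    result.benchmark.thresholds_.to_csv(out / "thresholds.csv", index=False)
    result.categories.to_csv(out / "categories.csv", index=False)
    result.cohort_summary.to_csv(out / "cohort_summary.csv", index=False)
    result.canton.to_csv(out / "canton_summary.csv", index=False)

    n_reports = 0
    if write_reports:
        rep_dir = out / "reports"
        rep_dir.mkdir(exist_ok=True)
        ext = {"json": "json", "html": "html", "text": "txt"}[report_format]
        for pid in sorted(result.categories["practice_id"].unique()):
            doc = render_report(build_report(pid, result), report_format)
            (rep_dir / f"{pid}.{ext}").write_text(doc, encoding="utf-8")
            n_reports += 1

    manifest = {
        "seed": used_seed,
        "config_sha256": _config_hash(config),
        "benchmark_year": result.benchmark_year,
        "counts": dict(result.counts, reports_written=n_reports),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    return manifest
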
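"""Seeded generator of a synthetic national prescription cohort.

The generator emulates the structure of a registry of companion-animal
antibiotic prescriptions: three practice-type strata, per-species annual
consultation counts (log-normal around a configured median), a binomial
number of treated animals per practice × species × year, one prescription
per treated animal, a configurable share of critical-antibiotic
prescriptions, plus the real-world blemishes the cleaning stage must
handle — withheld consultation counts, practices that never use
antibiotics for a species, and practices below 100 consultations.

Everything is driven by a single :class:`CohortConfig`; the default
configuration targets the stratum medians (consultations, treatment
percentages, critical shares) of the Swiss 2024 benchmarking cohort.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io import default_catalog
from .records import DeclaredType, PracticeType, Species, SubstanceCatalog

INDICATIONS = (
    "skin_infection",
    "urinary_tract",
    "respiratory",
    "gastrointestinal",
    "wound",
    "dental",
    "other",
)

#: Synthetic product palette: (vmp_id, semicolon-joined substances, weight).
#: Split into critical and non-critical products; the per-prescription
#: criticality flag selects the palette.
CRITICAL_PRODUCTS = (
    ("VMP-cefovecin", "cefovecin", 0.35),
    ("VMP-enrofloxacin", "enrofloxacin", 0.30),
    ("VMP-marbofloxacin", "marbofloxacin", 0.25),
    ("VMP-azithromycin", "azithromycin", 0.10),
)
NON_CRITICAL_PRODUCTS = (
    ("VMP-amoxiclav", "amoxicillin;clavulanic_acid", 0.40),
    ("VMP-amoxicillin", "amoxicillin", 0.20),
    ("VMP-cefalexin", "cefalexin", 0.15),
    ("VMP-doxycycline", "doxycycline", 0.10),
    ("VMP-metronidazole", "metronidazole", 0.05),
    ("VMP-clindamycin", "clindamycin", 0.05),
    ("VMP-tms", "trimethoprim;sulfadiazine", 0.05),
)

_CANTONS = (
    "AG AI AR BE BL BS FR GE GL GR JU LU NE NW OW SG SH SO SZ TG TI UR VD VS ZG ZH"
).split()
# the four most practice-dense cantons carry extra weight
_CANTON_WEIGHTS = np.array(
    [0.08 if c == "AG" else 0.16 if c == "BE" else 0.18 if c == "ZH" else 0.07 if c == "VD" else 0.0
     for c in _CANTONS]
)
_rest = (1.0 - _CANTON_WEIGHTS.sum()) / (_CANTON_WEIGHTS == 0).sum()
_CANTON_WEIGHTS = np.where(_CANTON_WEIGHTS == 0, _rest, _CANTON_WEIGHTS)


class CohortConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Maps are keyed by practice type, then species.  Probabilities are
    per consultation (``treatment_prob``), per prescription
    (``critical_frac``), per practice-year (``missing_nbconsult_prob``)
    or per practice (``zero_use_frac``, ``sub100_frac``).
    """

    model_config = ConfigDict(frozen=True)

    n_practices_per_type: dict[PracticeType, int]
    years: tuple[int, ...]
    median_consultations: dict[PracticeType, dict[Species, float]]
    treatment_prob: dict[PracticeType, dict[Species, float]]
    critical_frac: dict[PracticeType, dict[Species, float]]
    therapy_days_mean: float = Field(default=5.0, gt=0)
    consult_sigma: float = Field(default=0.8, ge=0)  # log-normal shape
    year_jitter_sigma: float = Field(default=0.15, ge=0)
    # per-practice multiplicative (log-normal, median 1) effects on the
    # treatment propensity and the critical share: between-practice
    # heterogeneity with the configured value kept as the median
    practice_effect_sigma: float = Field(default=0.3, ge=0)
    critical_effect_sigma: float = Field(default=0.3, ge=0)
    missing_nbconsult_prob: float = Field(default=0.15, ge=0, le=1)
    zero_use_frac: float = Field(default=0.05, ge=0, le=1)
    sub100_frac: float = Field(default=0.05, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not self.years:
            raise ValueError("years must be non-empty")
        for m in (self.treatment_prob, self.critical_frac):
            for by_species in m.values():
                for p in by_species.values():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"probability {p} outside [0, 1]")
        for n in self.n_practices_per_type.values():
            if n < 0:
                raise ValueError("practice counts must be >= 0")
        return self

    def to_yaml(self, path) -> None:
        data = self.model_dump(mode="json")
        data["years"] = list(self.years)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def default_swiss_like_config(
    n_per_type: int = 200, seed: int = 0
) -> CohortConfig:
    """Configuration whose stratum medians target the Swiss 2024 cohort:
    median annual consultations, share of consultations leading to an
    antibiotic treatment, and share of critical antibiotics among
    treatments, per practice type and species."""
    M, LT, GE = PracticeType.MIXED, PracticeType.SMALL_LT4500, PracticeType.SMALL_GE4500
    CAT, DOG = Species.CAT, Species.DOG
    return CohortConfig(
        n_practices_per_type={M: n_per_type, LT: n_per_type, GE: n_per_type},
        years=(2022, 2023, 2024),
        median_consultations={
            M: {DOG: 1481, CAT: 1602},
            LT: {DOG: 1612, CAT: 1671},
            GE: {DOG: 5812, CAT: 5545},
        },
        treatment_prob={
            M: {DOG: 0.120, CAT: 0.211},
            LT: {DOG: 0.098, CAT: 0.150},
            GE: {DOG: 0.098, CAT: 0.136},
        },
        critical_frac={
            M: {DOG: 0.052, CAT: 0.200},
            LT: {DOG: 0.068, CAT: 0.275},
            GE: {DOG: 0.068, CAT: 0.223},
        },
        seed=seed,
    )


class Cohort(NamedTuple):
    practices: pd.DataFrame
    consultations: pd.DataFrame
    prescriptions: pd.DataFrame


def generate_cohort(
    config: CohortConfig,
    seed: Optional[int] = None,
    catalog: Optional[SubstanceCatalog] = None,
) -> Cohort:
    """Draw one full cohort; deterministic for a fixed seed.

    ``seed`` overrides ``config.seed`` when given.  Returns the three
    tables as DataFrames with the documented CSV column layout.
    Consultation rows withheld by ``missing_nbconsult_prob`` are absent
    from the consultations table, but the underlying (true) counts still
    drive prescription generation.
    """
    if sum(config.n_practices_per_type.values()) == 0:
        raise ValueError("no practices configured")
    catalog = catalog or default_catalog()
    for vmp, subs, _w in CRITICAL_PRODUCTS + NON_CRITICAL_PRODUCTS:
        for s in subs.split(";"):
            if s not in catalog:
                raise ValueError(f"product {vmp}: substance {s!r} not in catalog")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    years = np.asarray(sorted(config.years))
    n_years = len(years)

    # --- practice registry -------------------------------------------------
    rows = []
    for ptype in (PracticeType.MIXED, PracticeType.SMALL_LT4500, PracticeType.SMALL_GE4500):
        n = config.n_practices_per_type.get(ptype, 0)
        for _ in range(n):
            rows.append(ptype)
    n_total = len(rows)
    ids = np.array([f"P{i:05d}" for i in range(1, n_total + 1)])
    target_type = np.array([p.value for p in rows])
    declared = np.where(
        target_type == PracticeType.MIXED.value,
        DeclaredType.MIXED_PRACTICE.value,
        rng.choice(
            [DeclaredType.COMPANION_PRACTICE.value, DeclaredType.COMPANION_CLINIC.value],
            size=n_total,
            p=[0.7, 0.3],
        ),
    )
    cantons = rng.choice(_CANTONS, size=n_total, p=_CANTON_WEIGHTS)
    # sim_stratum records the generator's target stratum (synthetic
    # provenance, ignored by the pipeline — real data has no such column)
    practices = pd.DataFrame(
        {
            "practice_id": ids,
            "declared_type": declared,
            "canton": cantons,
            "sim_stratum": target_type,
        }
    )

    sub100 = rng.random(n_total) < config.sub100_frac
    missing_year = rng.random((n_total, n_years)) < config.missing_nbconsult_prob

    crit_vmps = [p[0] for p in CRITICAL_PRODUCTS]
    crit_w = np.array([p[2] for p in CRITICAL_PRODUCTS])
    crit_w = crit_w / crit_w.sum()
    ncrit_vmps = [p[0] for p in NON_CRITICAL_PRODUCTS]
    ncrit_w = np.array([p[2] for p in NON_CRITICAL_PRODUCTS])
    ncrit_w = ncrit_w / ncrit_w.sum()
    vmp_substances = {p[0]: p[1] for p in CRITICAL_PRODUCTS + NON_CRITICAL_PRODUCTS}

    consult_parts = []
    presc_parts = []
    for ptype in (PracticeType.MIXED, PracticeType.SMALL_LT4500, PracticeType.SMALL_GE4500):
        mask = target_type == ptype.value
        n_p = int(mask.sum())
        if n_p == 0:
            continue
        p_ids = ids[mask]
        p_sub100 = sub100[mask]
        p_missing = missing_year[mask]
        for species in (Species.DOG, Species.CAT):
            median = config.median_consultations[ptype][species]
            treat_p = config.treatment_prob[ptype][species]
            crit_p = config.critical_frac[ptype][species]
            zero_use = rng.random(n_p) < config.zero_use_frac

            base = np.exp(rng.normal(np.log(median), config.consult_sigma, size=n_p))
            jitter = np.exp(rng.normal(0.0, config.year_jitter_sigma, size=(n_p, n_years)))
            nb = np.maximum(np.rint(base[:, None] * jitter), 1).astype(np.int64)
            nb_small = rng.integers(10, 100, size=(n_p, n_years))
            nb = np.where(p_sub100[:, None], nb_small, nb)

            treat_pi = np.clip(
                treat_p * np.exp(rng.normal(0.0, config.practice_effect_sigma, size=n_p)),
                0.0, 1.0,
            )
            crit_pi = np.clip(
                crit_p * np.exp(rng.normal(0.0, config.critical_effect_sigma, size=n_p)),
                0.0, 1.0,
            )
            n_treated = rng.binomial(nb, treat_pi[:, None])
            n_treated = np.where(zero_use[:, None], 0, n_treated)

            consult_parts.append(
                pd.DataFrame(
                    {
                        "practice_id": np.repeat(p_ids, n_years),
                        "species": species.value,
                        "year": np.tile(years, n_p),
                        "n_consultations": nb.ravel(),
                        "_withheld": p_missing.ravel(),
                    }
                )
            )

            # one prescription per treated animal
            counts = n_treated.ravel()
            total = int(counts.sum())
            if total == 0:
                continue
            rep_ids = np.repeat(np.repeat(p_ids, n_years), counts)
            rep_years = np.repeat(np.tile(years, n_p), counts)
            rep_crit_p = np.repeat(np.repeat(crit_pi, n_years), counts)
            is_crit = rng.random(total) < rep_crit_p
            vmps = np.empty(total, dtype=object)
            n_crit = int(is_crit.sum())
            if n_crit:
                vmps[is_crit] = rng.choice(crit_vmps, size=n_crit, p=crit_w)
            if total - n_crit:
                vmps[~is_crit] = rng.choice(ncrit_vmps, size=total - n_crit, p=ncrit_w)
            td = 1 + rng.poisson(max(config.therapy_days_mean - 1.0, 0.0), size=total)
            indication = rng.choice(INDICATIONS, size=total)
            dosage = np.round(np.exp(rng.normal(np.log(12.0), 0.4, size=total)), 2)
            presc_parts.append(
                pd.DataFrame(
                    {
                        "practice_id": rep_ids,
                        "year": rep_years,
                        "species": species.value,
                        "vmp_id": vmps,
                        "substances": pd.Series(vmps).map(vmp_substances).to_numpy(),
                        "therapy_days": td.astype(float),
                        "animals_treated": 1,
                        "indication": indication,
                        "dosage_mg_per_kg": dosage,
                    }
                )
            )

    consultations = pd.concat(consult_parts, ignore_index=True)
    consultations = (
        consultations[~consultations["_withheld"]]
        .drop(columns="_withheld")
        .sort_values(["practice_id", "species", "year"], kind="mergesort")
        .reset_index(drop=True)
    )
    if presc_parts:
        prescriptions = (
            pd.concat(presc_parts, ignore_index=True)
            .sort_values(["practice_id", "species", "year", "vmp_id"], kind="mergesort")
            .reset_index(drop=True)
        )
    else:
        prescriptions = pd.DataFrame(
            columns=[
                "practice_id", "year", "species", "vmp_id", "substances",
                "therapy_days", "animals_treated", "indication", "dosage_mg_per_kg",
            ]
        )
    return Cohort(practices, consultations, prescriptions)
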
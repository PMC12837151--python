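import pandas as pd
import pytest

from abubench import default_catalog, default_swiss_like_config, generate_cohort
from abubench.reporting import run_pipeline

YEARS = [2022, 2023, 2024]


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def tiny_cohort():
    """Three handcrafted practices covering the main eligibility cases.

    * A — mixed practice, complete consultation data;
    * B — companion practice, dog NbConsult missing in 2023 (imputed),
      cat NbConsult below 100 every year (ineligible);
    * C — companion clinic, >4500 dog consultations (large stratum) but
      3000 cat consultations (small stratum).
    """
    practices = pd.DataFrame(
        {
            "practice_id": ["A", "B", "C"],
            "declared_type": ["mixed_practice", "companion_practice", "companion_clinic"],
            "canton": ["BE", "ZH", "VD"],
        }
    )
    cons_rows = []
    for y in YEARS:
        cons_rows += [
            ("A", "dog", y, 1000),
            ("A", "cat", y, 1200),
            ("B", "cat", y, 99),
            ("C", "dog", y, 5000),
            ("C", "cat", y, 3000),
        ]
    cons_rows += [("B", "dog", 2022, 1200), ("B", "dog", 2024, 1500)]  # 2023 missing
    consultations = pd.DataFrame(
        cons_rows, columns=["practice_id", "species", "year", "n_consultations"]
    )
    presc_rows = [
        # practice A dogs: TD 10, 1 substance, 1 animal each year
        *[("A", y, "dog", "VMP-amoxicillin", "amoxicillin", 10.0, 1, "wound", 12.5) for y in YEARS],
        # practice A cats: one critical long-acting (cefovecin, carry-over 13)
        ("A", 2024, "cat", "VMP-cefovecin", "cefovecin", 1.0, 1, "skin_infection", 8.0),
        # practice C dogs: combination product, 2 substances, 3 animals
        ("C", 2024, "dog", "VMP-tms", "trimethoprim;sulfadiazine", 5.0, 3, "urinary_tract", 30.0),
        ("C", 2024, "dog", "VMP-amoxicillin", "amoxicillin", 7.0, 1, "wound", 11.0),
    ]
    prescriptions = pd.DataFrame(
        presc_rows,
        columns=[
            "practice_id", "year", "species", "vmp_id", "substances",
            "therapy_days", "animals_treated", "indication", "dosage_mg_per_kg",
        ],
    )
    return practices, consultations, prescriptions


@pytest.fixture(scope="session")
def small_cohort():
    cfg = default_swiss_like_config(n_per_type=40, seed=11)
    return generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort, catalog):
    return run_pipeline(*small_cohort, catalog=catalog)
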
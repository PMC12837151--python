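"""Percentile thresholds and four-category ABU classification.

Within every stratum (practice type × species × antibiotic scope) a
*signal* threshold is the 75th percentile and an *action* threshold the
95th percentile of the contributing practices' mean pATI.  A practice
contributes the mean of its year-level pATI values over the benchmark
window after dropping (1) years whose NbConsult was imputed
("corrected") and (2) null values (non-users); practices with no
surviving year contribute nothing — but corrected or null practices are
still *classified* against the thresholds.

Categories, with strict "above" at both boundaries:

* ``none`` — pATI = 0 (non-user);
* ``acceptable`` — 0 < pATI ≤ signal;
* ``high`` — signal < pATI ≤ action;
* ``very_high`` — pATI > action.

The fit/predict core is :class:`PercentileBenchmark`, a scikit-learn
style estimator; :func:`compute_thresholds` and :func:`classify_cohort`
are thin wrappers over it.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Optional, Sequence, Union

import pandas as pd
from sklearn.base import BaseEstimator

from .records import Category, PracticeType, Scope, Species, StratumKey

logger = logging.getLogger(__name__)

THRESHOLD_COLUMNS = ["practice_type", "species", "scope", "signal", "action", "n_contributing"]
CATEGORY_COLUMNS = ["practice_id", "species", "scope", "practice_type", "year", "pati", "category"]


class ThresholdPair(NamedTuple):
    stratum: StratumKey
    signal: float
    action: float
    n_contributing: int


def percentile(values: Sequence[float], q: float) -> float:
    """Quantile by linear interpolation between order statistics at
    position ``1 + q*(n-1)`` (the default convention of most statistical
    environments).  Implemented directly so that library quantile
    routines can serve as an independent cross-check."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q={q} outside [0, 1]")
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 0:
        raise ValueError("percentile of empty sequence")
    h = q * (n - 1)
    lo = math.floor(h)
    frac = h - lo
    if lo + 1 >= n:
        return xs[-1]
    return xs[lo] + frac * (xs[lo + 1] - xs[lo])


def mean_pati_contributions(pati_table: pd.DataFrame) -> pd.DataFrame:
    """Per practice × stratum mean of year-level pATI values, after the
    threshold-construction exclusions (corrected years, null values).

    Returns columns practice_id, practice_type, species, scope,
    mean_pati; practices with no surviving value are absent.
    """
    ok = pati_table[(~pati_table["corrected"].astype(bool)) & (pati_table["pati"] > 0)]
    out = (
        ok.groupby(["practice_id", "practice_type", "species", "scope"], as_index=False)[
            "pati"
        ]
        .mean()
        .rename(columns={"pati": "mean_pati"})
    )
    return out.sort_values(
        ["practice_type", "species", "scope", "practice_id"], kind="mergesort"
    ).reset_index(drop=True)


def categorize(
    pati: float, signal: float, action: float
) -> Category:
    """Four-category label for one pATI value against one threshold pair."""
    if pati < 0:
        raise ValueError("pati must be non-negative")
    if pati == 0:
        return Category.NONE
    if pati <= signal:
        return Category.ACCEPTABLE
    if pati <= action:
        return Category.HIGH
    return Category.VERY_HIGH


class PercentileBenchmark(BaseEstimator):
    """Percentile-threshold benchmark classifier.

    Parameters
    ----------
    signal_q, action_q : float
        Percentile levels of the signal and action thresholds
        (defaults 0.75 and 0.95).
    benchmark_year : int, optional
        Year whose pATI values are classified by :meth:`predict`.
        Defaults to the latest year seen during :meth:`fit`.  Earlier
        years can be classified retrospectively against the same
        thresholds by passing ``year=`` to :meth:`predict`.

    Attributes
    ----------
    contributions_ : DataFrame
        Mean pATI per contributing practice × stratum.
    thresholds_ : DataFrame
        Signal/action pair and contributor count per populated stratum.
    benchmark_year_ : int
        Default classification year.
    """

    def __init__(self, signal_q: float = 0.75, action_q: float = 0.95,
                 benchmark_year: Optional[int] = None):
        self.signal_q = signal_q
        self.action_q = action_q
        self.benchmark_year = benchmark_year

    def fit(self, X: pd.DataFrame, y=None) -> "PercentileBenchmark":
        """Learn the stratum thresholds from a pATI table (the output of
        :func:`abubench.indicator.compute_pati_table`)."""
        if not 0 <= self.signal_q <= self.action_q <= 1:
            raise ValueError("need 0 <= signal_q <= action_q <= 1")
        contributions = mean_pati_contributions(X)
        rows = []
        for (ptype, species, scope), grp in contributions.groupby(
            ["practice_type", "species", "scope"], sort=True
        ):
            vals = grp["mean_pati"].tolist()
            rows.append(
                {
                    "practice_type": ptype,
                    "species": species,
                    "scope": scope,
                    "signal": percentile(vals, self.signal_q),
                    "action": percentile(vals, self.action_q),
                    "n_contributing": len(vals),
                }
            )
        n_possible = len(PracticeType) * len(Species) * len(Scope)
        if len(rows) < n_possible:
            logger.warning(
                "thresholds computed for %d of %d possible strata "
                "(others have no contributors)", len(rows), n_possible,
            )
        self.contributions_ = contributions
        self.thresholds_ = pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)
        self.benchmark_year_ = (
            int(X["year"].max()) if self.benchmark_year is None else int(self.benchmark_year)
        )
        return self

    def predict(self, X: pd.DataFrame, year: Optional[int] = None) -> pd.DataFrame:
        """Classify the pATI values of one year of a pATI table.

        Corrected-NbConsult practices *are* classified (they were only
        excluded from threshold construction).  Rows whose stratum has
        no thresholds are dropped with a warning.
        """
        if not hasattr(self, "thresholds_"):
            raise ValueError("PercentileBenchmark is not fitted")
        year = self.benchmark_year_ if year is None else int(year)
        rows = X[X["year"] == year]
        merged = rows.merge(
            self.thresholds_, on=["practice_type", "species", "scope"], how="left"
        )
        missing = merged["signal"].isna()
        if missing.any():
            logger.warning(
                "dropping %d pATI values in strata without thresholds", int(missing.sum())
            )
            merged = merged[~missing]
        merged = merged.copy()
        merged["category"] = [
            categorize(p, s, a).value
            for p, s, a in zip(merged["pati"], merged["signal"], merged["action"])
        ]
        out = merged[CATEGORY_COLUMNS]
        return out.sort_values(
            ["practice_id", "species", "scope"], kind="mergesort"
        ).reset_index(drop=True)

    def threshold_pairs(self) -> list[ThresholdPair]:
        """The fitted thresholds as typed tuples."""
        return [
            ThresholdPair(
                StratumKey(PracticeType(r.practice_type), Species(r.species), Scope(r.scope)),
                float(r.signal),
                float(r.action),
                int(r.n_contributing),
            )
            for r in self.thresholds_.itertuples()
        ]


def compute_thresholds(
    pati_table: pd.DataFrame, signal_q: float = 0.75, action_q: float = 0.95
) -> pd.DataFrame:
    """Signal/action thresholds per populated stratum (wrapper over
    :class:`PercentileBenchmark`)."""
    return PercentileBenchmark(signal_q, action_q).fit(pati_table).thresholds_


def classify_cohort(
    pati_table: pd.DataFrame,
    thresholds: Union[pd.DataFrame, "PercentileBenchmark", None] = None,
    benchmark_year: Optional[int] = None,
) -> pd.DataFrame:
    """Classify every practice × species × scope of the benchmark year.

    ``thresholds`` may be a fitted estimator, a thresholds DataFrame, or
    None (fit on ``pati_table`` itself).
    """
    if isinstance(thresholds, PercentileBenchmark):
        est = thresholds
    else:
        est = PercentileBenchmark(benchmark_year=benchmark_year).fit(pati_table)
        if isinstance(thresholds, pd.DataFrame):
            est.thresholds_ = thresholds
    return est.predict(pati_table, year=benchmark_year)
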
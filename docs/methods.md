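# Methods

## The indicator

`abubench` benchmarks antibiotic use (ABU) at the level of a veterinary
practice, separately for cats and dogs, using a count-based treatment
indicator. For one practice, species and year,

```
pATI = Σ_i  TD_i · NbAS_i · AT_i  /  NbConsult
```

summed over all antibiotic prescriptions *i* of that practice, species
and year:

* **TD_i** — therapy days: administered treatment days plus the longest
  *carry-over* among the product's active substances. Carry-over models
  the active-substance effective time of long-acting formulations (e.g.
  a single cefovecin injection covers about two weeks) and is catalog
  data (`carryover_days`, default 0), not prescription data. The
  carry-over is added to TD before multiplication by NbAS.
* **NbAS_i** — number of active substances in the veterinary medicinal
  product (VMP). Under the *critical* scope only critical substances are
  counted, so a product without critical substances contributes zero;
  TD stays the product-level value in both scopes.
* **AT_i** — animals treated with the prescription.
* **NbConsult** — the practice's annual consultations for the species:
  the population at risk. pATI is therefore in units of therapy days per
  consultation.

Critical antibiotics are macrolides, fluoroquinolones and 3rd/4th
generation cephalosporins; the shipped substance catalog enforces that
the criticality flag follows the antibiotic class.

## Eligibility and cleaning

* Exact duplicate prescription rows collapse to one; rows with therapy
  days outside (0, 365] or animals treated outside [1, 10000] are
  dropped. These bounds are configurable; they concretise an "obvious
  error" rule that is inherently a policy choice.
* A pATI is computed only where a usable NbConsult exists. A practice ×
  species with at least one registered year gets missing years imputed
  as the **maximum** over its registered years and flagged *corrected*;
  a species with no registered year at all, or a (possibly imputed)
  count below 100 consultations, is excluded. The 100-consultation floor
  removes practices whose case mix (emergencies, specialities) would not
  reflect normal use.
* Eligibility is per species: a practice can be benchmarked for cats but
  not for dogs.

## Strata and thresholds

Practices are compared only within a stratum: practice type × species ×
antibiotic scope (all vs critical) — up to 12 strata. Declared mixed
practices always form their own stratum; companion practices and clinics
are split at 4500 consultations per year (strictly above → large),
evaluated **per species** on the benchmark year's NbConsult. Using the
benchmark year (rather than a mean or maximum over years) is a design
choice; the alternative definitions differ only for practices straddling
the cut-off.

Within each stratum, each practice contributes the **mean** of its
year-level pATI values over the benchmark window after dropping
(1) corrected years and (2) null values (non-users). The **signal**
threshold is the 75th percentile and the **action** threshold the 95th
percentile of these contributions. Percentiles interpolate linearly
between order statistics at position `1 + q·(n − 1)` (the default
convention of most statistical environments; implemented directly and
cross-checked against `numpy.quantile` in the tests).

Classification uses the benchmark year's pATI with strict "above":

| category | condition |
|---|---|
| none | pATI = 0 |
| acceptable | 0 < pATI ≤ signal |
| high | signal < pATI ≤ action |
| very_high | pATI > action |

A value exactly at a threshold takes the lower category; the published
wording ("above", "between", "below") does not fix the boundary, so the
convention is documented here and pinned by tests. Corrected-NbConsult
practices **are** classified — they are only barred from threshold
construction. This asymmetry is what lets the overall very-high share
exceed 5%: heavy users whose benchmark-year denominator was imputed sit
above an action threshold they never helped set. Earlier years can be
classified retrospectively against the same single threshold set.

The fit/predict core is the `PercentileBenchmark` estimator
(scikit-learn `BaseEstimator`): `fit` learns contributions and
thresholds from a pATI table, `predict` returns category labels.

## Quantile comparisons

Group contrasts (cat vs dog, practice types) compare a quantile (median,
P75, P95) between two sets of practice-level values. Because most
practices contribute values to both groups, plain bootstrap resampling
would break the within-practice correlation; `bootstrap_quantile_diff`
therefore resamples **practice ids** with replacement from the union of
both groups, carrying each sampled practice's values in both groups into
the replicate (a cluster bootstrap with the practice as the grouping
factor). The two-sided p-value comes from the sign of the bootstrap
distribution of the quantile difference, with add-one smoothing; the
95% CI is the percentile interval. Groups need ≥ 10 values and ≥ 200
replicates. Under a null simulation with shared practice effects
(200 clusters, 500 replicates) the empirical size at α = 0.05 is close
to nominal (the acceptance suite checks 5% ± 2 points over 200 runs).
This deliberately replaces a linear quantile mixed-model fit: the
quantity of interest is the quantile contrast, not the estimator.

## Synthetic cohort generator

Real registry data are confidential, so every stage runs against a
seeded synthetic cohort (`CohortConfig`, `generate_cohort`):

* three practice-type strata × three years (2022–2024);
* per practice × species, annual consultations are log-normal around the
  configured stratum median (shape σ = 0.8, chosen so the max/median
  ratio is on the order of the published spread) with mild year-to-year
  jitter (σ = 0.15);
* treated animals per practice × species × year are Binomial(NbConsult,
  p·e), where p is the configured per-consultation treatment probability
  and e a per-practice log-normal effect with median 1 (σ = 0.3) that
  creates realistic between-practice spread without moving the median;
* each treated animal becomes one prescription (companion animals are
  treated individually; group treatments appear only in unit fixtures):
  administered therapy days are shifted Poisson `1 + Pois(mean − 1)`
  with mean 5.0 days — chosen so the implied stratum median pATI
  (treatment probability × mean effective TD) lands on the order of the
  published medians (≈0.6 for dogs, ≈1.0–1.3 for cats); the product is
  critical with the configured probability (times a per-practice effect)
  and drawn from a small palette of common companion-animal products,
  including multi-substance combinations and the long-acting cefovecin;
* data blemishes: a per-(practice, year) probability of withholding the
  consultation rows (default 0.15), a share of practices that never use
  antibiotics for a species (default 0.05), and a share with fewer than
  100 consultations (default 0.05).

The default configuration (`default_swiss_like_config`) targets the
published 2024 stratum medians for consultations, treatment percentages
and critical shares. The generator targets **medians only**: the true
mixing structure behind the published mean ≫ median tails is unknowable,
so means and maxima of the synthetic cohort are not calibrated. It also
does not model seasonality, indication structure beyond a label, owner
behaviour, or practices that never report NbConsult in any year (the
withholding probability is per practice-year). Passing tests therefore
demonstrate the correctness of the pipeline's rules and the calibration
of its statistics on a cohort with these properties — not distributional
fidelity to the confidential registry beyond the targeted medians.

The practices table of a generated cohort carries a `sim_stratum`
column recording the generator's target stratum; it is synthetic
provenance used by calibration checks and ignored by the pipeline.

## Reports

A practice's report contains, per species × scope: its category, its
pATI per year, the stratum thresholds, and the anonymized pATI values of
all comparable practices per year — the practice's own point is the only
identified one, and reports of unbenchmarked practices show the cohort
without an own point. pATI panels are tagged for logarithmic display;
since 0 has no log, null values are drawn at half the smallest positive
pATI of the panel (`zero_floor`) and labelled "no use". The descriptive
part summarises treatments, critical share, class and indication
breakdowns (a treatment is attributed to the class of its first-listed
substance so counts partition), and the ten most prescribed VMPs with
modal dosage (ties: smaller dosage, lexicographic VMP id). JSON is the
canonical format; HTML embeds the identical JSON payload; all rendering
is byte-deterministic, and `run_all` writes a manifest (seed, config
hash, stage counts — no timestamps) so that two runs with the same seed
are byte-identical.

## Numerical and policy choices, in brief

* printed shares round half-away-from-zero to one decimal (`ratio_pct`);
* unknown substance codes reject the prescription row — defaulting to
  non-critical would silently undercount critical use;
* thresholds for strata without contributors are absent (logged), and
  pATI values in such strata are left unclassified rather than compared
  against another stratum's thresholds;
* duplication of the entire contributor set moves an interpolated
  percentile only within one order-statistic gap, so threshold
  "duplication invariance" is approximate by construction;
* problem sizes in tests and in `scripts/acceptance.py` (200 practices
  per stratum for calibration, 500–1000 bootstrap replicates, 200
  simulation runs for the size check) are chosen to make Monte-Carlo
  tolerances meaningful while keeping a full run in tens of seconds.

## Known limitations

* The outlier rule is a bound filter, not the full registry feedback
  loop that real data quality management relies on.
* Carry-over days ship with plausible defaults for a handful of
  substances; real pharmacokinetic tables would refine TD.
* The cluster bootstrap tests one quantile at a time and does not adjust
  for multiple quantiles or multiple strata.
* With very few contributors in a stratum the 95th percentile sits on
  the largest one or two observations; `n_contributing` is reported so
  downstream users can judge threshold stability.
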
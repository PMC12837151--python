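# abubench

Practice-level benchmarking of antibiotic use (ABU) in cats and dogs,
modelled on the Swiss national system for veterinary practices: a
registry collects every antibiotic prescription plus each practice's
annual consultation count per species, and every practice receives an
annual report comparing its use against all comparable practices.

The package is for epidemiologists and veterinary-authority analysts who
want to run, study or adapt such a benchmarking pipeline. Because the
real registry data are confidential, a seeded synthetic cohort generator
emulating the national data (three practice types, 2022–2024, realistic
consultation and treatment scales) makes every stage runnable and
testable end to end.

## The indicator

For one practice, species and year, the practice-level Antibiotic
Treatment Indicator is

```
pATI = Σ_i TD_i · NbAS_i · AT_i / NbConsult
```

summed over prescriptions *i*: therapy days (administered days plus the
carry-over of long-acting substances) × number of active substances in
the product × animals treated, normalised by the annual consultations
for that species (the population at risk). A second indicator,
*critical pATI*, counts only critical antibiotics (macrolides,
fluoroquinolones, 3rd/4th-generation cephalosporins).

Within each comparison stratum (mixed practices | companion practices
below 4500 consultations/year | above 4500; × species × scope) each
practice contributes the mean of its uncorrected, non-null yearly pATI
values; the **signal** threshold is that distribution's 75th percentile
and the **action** threshold its 95th. Practices are then classified for
the benchmark year: `none` (pATI = 0), `acceptable` (≤ signal), `high`
(≤ action), `very_high` (> action). Practices whose missing NbConsult
was imputed ("corrected") are classified but never shape the
thresholds. See `docs/methods.md` for the full rules.

## Worked example

```python
import abubench as ab
from abubench.reporting import run_pipeline

cfg = ab.default_swiss_like_config(n_per_type=50, seed=7)
cohort = ab.generate_cohort(cfg, seed=7)          # practices, consultations, prescriptions
res = run_pipeline(*cohort)

print(res.counts["benchmarked_practices"], "of", res.counts["practices"])
print(res.benchmark.thresholds_.query("scope == 'all'"))
```

prints (seed 7):

```
144 of 150
practice_type species scope   signal   action  n_contributing
        mixed     cat   all 2.100393 2.680585              46
        mixed     dog   all 1.146631 1.309687              44
 small_ge4500     cat   all 1.239240 1.512774              31
 small_ge4500     dog   all 0.875322 1.129092              24
 small_lt4500     cat   all 1.396726 1.855772              60
 small_lt4500     dog   all 0.866345 1.211387              67
```

144 of the 150 simulated practices could be benchmarked (the rest
withheld their consultation counts in every year or stayed below 100
consultations). Thresholds are in therapy days per consultation; cat
thresholds exceed dog thresholds in every practice type, and e.g. a
mixed-practice dog pATI above 1.31 would be classified `very_high`. The
dog all-antibiotics classification for this cohort comes out as 100
`acceptable`, 28 `high`, 7 `very_high`, 9 `none`. A single practice's
report payload:

```python
rep = ab.build_report("P00001", res)
panel = rep.panels["dog"]["all"]
panel["category"]                # 'acceptable'
panel["series"][2024]["own"]     # 0.774294670846  (its 2024 pATI)
panel["thresholds"]              # signal 1.147, action 1.310 (n=44)
```

`panel["series"]` also carries the anonymized pATI values of all
comparable practices per year for the report graphic (log scale, zeros
drawn at the documented floor); no other practice is identifiable.

The same pipeline is scriptable from the shell:

```
abu-bench run-all --n-per-type 50 --seed 7 --out out/
abu-bench report --in out/ --practice P00001 --format text
abu-bench compare --in out/ --q 0.5,0.95 --n-boot 1000 --seed 7
```

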
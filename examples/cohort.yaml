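consult_sigma: 0.8
critical_effect_sigma: 0.3
critical_frac:
  mixed:
    cat: 0.2
    dog: 0.052
  small_ge4500:
    cat: 0.223
    dog: 0.068
  small_lt4500:
    cat: 0.275
    dog: 0.068
median_consultations:
  mixed:
    cat: 1602.0
    dog: 1481.0
  small_ge4500:
    cat: 5545.0
    dog: 5812.0
  small_lt4500:
    cat: 1671.0
    dog: 1612.0
missing_nbconsult_prob: 0.15
n_practices_per_type:
  mixed: 50
  small_ge4500: 50
  small_lt4500: 50
practice_effect_sigma: 0.3
seed: 0
sub100_frac: 0.05
therapy_days_mean: 5.0
treatment_prob:
  mixed:
    cat: 0.211
    dog: 0.12
  small_ge4500:
    cat: 0.136
    dog: 0.098
  small_lt4500:
    cat: 0.15
    dog: 0.098
year_jitter_sigma: 0.15
years:
- 2022
- 2023
- 2024
zero_use_frac: 0.05
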
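# Cohort CSV data dictionary

One row per pregnancy; comma-separated UTF-8, `.` decimal, empty string =
missing. Missing values are only permitted in the variables marked below.

| Column | Type / levels | Unit | Missing allowed |
|---|---|---|---|
| `maternal_age_years` | float | years | no |
| `height_cm` | float | cm | no |
| `prepreg_weight_kg` | float | kg | no |
| `prepreg_bmi` | float; equals `prepreg_weight_kg / (height_cm/100)^2` | kg/m² | no |
| `gwg_kg` | float (pre-delivery minus pre-pregnancy weight) | kg | no |
| `parity` | int ≥ 0 (prior deliveries; 0 = primiparity) | count | no |
| `fetal_sex` | `son`, `daughter` | — | no |
| `gestational_age_weeks` | int, 25–42 (completed weeks) | weeks | no |
| `gdm` | `none`, `gdm1` (diet-treated), `gdm2` (insulin-treated) | — | no |
| `prior_macrosomia` | `yes`, `no` | — | no |
| `prior_gdm` | `yes`, `no` | — | no |
| `prior_cesarean` | `yes`, `no` | — | no |
| `family_dm_mother` | `parent`, `family_other`, `none` | — | no |
| `family_dm_father` | `parent`, `family_other`, `none` | — | no |
| `smoking` | `never`, `ex`, `current` | — | yes |
| `education` | `lt12`, `ge12` (years of schooling) | — | yes |
| `financial_status` | `lower`, `higher` | — | yes |
| `residence` | `village`, `small_town`, `large_city` | — | yes |
| `marital_status` | `married`, `divorced`, `unmarried` | — | yes |
| `folic_acid` | `yes`, `no` (first-trimester supplementation) | — | yes |
| `multivitamin` | `yes`, `no` (2nd–3rd-trimester supplementation) | — | yes |
| `interpregnancy_interval` | `primigravida`, `1y`, `2y`, `3_5y`, `6_10y`, `ge11y` | — | yes |
| `birthweight_g` | float > 0 | g | no |
| `macrosomia` | 0/1; 1 iff `birthweight_g` > 4000 | — | no |
| `weight_band` | `lt2500`, `2500_4000`, `gt4000` | — | no |
| `lga_band` | `lt10`, `10_90`, `gt90` (vs the reference growth grid) | — | no |
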
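# mortlink

A synthetic linked-mortality pipeline: simulate a 1940-style census-day
population with Gompertz proportional-hazards mortality, emit death registers
with configurable coverage windows and noise, link them back to the census
with a conservative deterministic matcher, build post-stratification weights
calibrated by iterative raking and trimming, and estimate mortality — both
extinct-cohort age-specific rates and maximum-likelihood Gompertz
differentials under doubly-truncated death observation.

No external data are required: the `synthetic` module generates every input,
and a truth map lets linkage and weighting be evaluated exactly.  The public
output files mirror flat person-level linked-mortality CSV layouts (a
`histid` crosswalk plus dates, death age and a statistical weight), so real
files could be substituted behind the same interfaces.

## Layout

| module | what it does |
| --- | --- |
| `mortlink.synthetic` | population/register/reference-table generation (`PopulationSpec`, `RegisterSpec`, `NoiseSpec`) |
| `mortlink.gompertz` | Gompertz PH closed forms, inverse-CDF sampling, life-expectancy quadrature |
| `mortlink.linkage` | conservative exact-key match with ±2-year age bands, surname rules for women, precision/recall + representativeness + middle-initial diagnostics |
| `mortlink.weighting` | ratio weights per death-year/age/sex/race/birth-state cell, fallback rules, raking (IPF) and trimming |
| `mortlink.mortality` | doubly-truncated Gompertz MLE, fixed-effects OLS on age at death, extinct-cohort rates, hazard-ratio conversions |
| `mortlink.pipeline` / `mortlink.cli` | stage orchestration (`generate → link → weight → estimate → report`), run manifest, demo fixture |

## CLI

```sh
mortlink run-all --seed 7 --outdir out/            # full pipeline, default config
mortlink generate --config cfg.yaml --outdir out/  # single stage, resumable
mortlink weight --config cfg.yaml --outdir out/    # re-runs from on-disk CSVs
mortlink make-demo --outdir demo/                  # ~5,000-person demo fixture
```

Every stage reads and writes headered CSV in `--outdir`; reruns with the same
config and seed reproduce stage outputs byte-for-byte (see `manifest.json`
for the config hash, seed and per-stage row counts).  A YAML config
(`PipelineConfig.to_yaml` / `from_yaml`) holds all rates, windows, thresholds
and the global seed; `mortlink.config.default_config()` documents the
defaults (numident-like register 1988–2005 with sex/birthplace/father's
surname; DMF-like register 1975–2005 with neither; reference totals lacking
birth state before 1979).

Key output files per register `<name>`:

- `census.csv`, `register_<name>.csv`, `truth_<name>.csv`,
  `totals_<name>.csv` (`dyear, death_age, sex, race, bstate, n_deaths`)
- `crosswalk_<name>.csv` (`histid, rec_id, band`), `exclusions_<name>.csv`
  (reason-coded), `linkage_summary_<name>.csv`, `linkage_report_<name>.csv`
  (stratum shares matched vs census with differences)
- `weighted_<name>.csv` (linked records + `weight`, `weight_rule`),
  `cells_<name>.csv`, `weight_diagnostics_<name>.csv`
- `censoc_<name>.csv` — public schema: `histid, byear, bmonth, dyear,
  dmonth, death_age, weight` (numident-like adds `sex, race_first,
  race_last, bpl, socstate, age_first_application, zip_residence`, with
  unmodelled fields left empty)
- `fit_<name>.csv`, `ols_<name>.csv`, `rates_<name>.csv`,
  `plotdata_log_mortality.csv`

## Conventions worth knowing

- Integer record ages use completed years; the census-day age treats
  birthdays in the census month as not yet reached, and register death ages
  come from month arithmetic on (possibly misstated) birth dates, so age
  noise propagates realistically.
- Name keys are opaque pool identifiers; typos resample to fresh keys,
  nickname noise emits a `NICK:`-prefixed alias that `standardize_name`
  collapses (a custom equivalence table can be supplied as data).
- Middle initials are never used for matching — they are reserved for the
  post-hoc agreement diagnostic that upper-bounds the false-match rate.
- Truncation windows for the likelihood are per cohort:
  `x_l = max(65, window_start − birth_year)`,
  `x_r = min(max_age, window_end + 1 − birth_year)`, with integer ages
  jittered to age + 0.5 (switchable to uniform jitter).
- The trim ceiling is anchored to 5× the mean *unadjusted* ratio weight and
  held fixed while raking and trimming alternate.
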
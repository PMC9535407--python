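# vertraits

Toolkit for specimen-level vertebrate trait data: a Darwin Core-flavoured
measurement template (one measurement event per row), trait-term and unit
standardization, a flag-never-delete cleaning routine that infers probable
adults among records with unknown life stage, dynamically derived species
trait summaries compared against literature means, and log-log allometric
body-mass reconstruction with propagated prediction errors.

## Package layout

- `vertraits.records` — `TraitRecord` data model, template CSV read/write,
  required-column validation, wide-to-long conversion, synonym-to-canonical
  trait-term mapping (`vertraits/data/trait_terms.csv`) and unit
  canonicalization (`vertraits/data/units.yaml`; canonical units are g and
  mm). Verbatim fields are never modified.
- `vertraits.cleaning` — per species x trait: minimum-record gate (default
  10), univariate squared-standardized-distance outlier screen on known
  adults (chi-square(1) quantile cutoff), normal / log-normal / non-normal
  classification, +/-3 sigma (or 5%/95% quantile) limits, and annotation of
  unknown-life-stage records as `possible adult; possibly good`,
  `possible juvenile`, or `outlier`. Output row count always equals input
  row count.
- `vertraits.summaries` — species summaries over a configurable status
  keep-set; one-sample t comparison against a literature mean table with
  Benjamini-Hochberg adjustment; tallies of species outside +/-3 se by
  body-mass class; diagnostic regressions of |mean difference| on sample
  size and on mass.
- `vertraits.allometry` — OLS of log10(mass) on log10(length), prediction
  with `se = sqrt(se_resid^2/n + (se_slope*(log10 x - mean_log_x))^2)`
  (an `eq3_as_printed` switch computes the literal `(se_resid/n)^2`
  variant), 2-se intervals back-transformed from log space, and
  application/interval-checking of published legacy constants.
- `vertraits.synthetic` — seeded generators: mixed-life-stage populations
  with optional gross contamination (truth in a separate sidecar), paired
  length/mass datasets under a known power law, and messy wide-format
  tables with synonym headers and mixed units.
- `vertraits.cli` — command-line workflow.

## CLI

```bash
vertraits validate input.csv
vertraits clean input.csv -o cleaned.csv --report report.csv [--config cfg.yaml]
vertraits summarize cleaned.csv -o summaries.csv
vertraits compare cleaned.csv reference.csv -o comparisons.csv --tally tally.csv
vertraits allometry fit pairs.csv -o fit.json
vertraits allometry predict fit.json lengths.csv -o predictions.csv \
    --legacy-intercept -6.79 --legacy-slope 5.29 --legacy-unit kg
vertraits simulate --kind population --seed 17 -o fixture.csv --truth truth.csv
```

Exit codes: 0 success, 1 validation failure, 2 usage error. Logs go to
stderr, data to files.

## External data (optional)

To run the full deer case study, convert the published supplementary
spreadsheets to CSV and place them at:

- `data/deer/mmc1_modern.csv` — columns `gllMm` (astragalus lateral
  length, mm) and `massKg` (live body mass, kg) for the modern specimens;
- `data/deer/mmc3_zooarch.csv` — columns `gllMm` and, optionally,
  `legacyMassKg` for the zooarchaeological specimens.
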
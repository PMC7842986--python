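# File formats

All CSV files are UTF-8, comma-separated, "." decimal, header row
mandatory. Every writer's output round-trips through the matching reader
with exact value preservation. Monetary columns are constant 2020 USD
("USD2020").

## Woman-level microdata (CSV)

`io.write_microdata` / `io.read_microdata`. One row per woman:

| column | type | meaning |
|---|---|---|
| `woman_id` | int | unique within the file |
| `community_id` | int | survey cluster / community |
| `age` | int 15–49 | age in years |
| `wealth` | int 1–5 | wealth quintile |
| `education` | int 0–3 | ordinal education level |
| `urban` | 0/1 | urban residence |
| `religion` | str | categorical level |
| `supports_fgm` | float [0,1] | support indicator; fractional after an expectation-mode attitude shift |
| `daughter_cut` | 0/1 | outcome of the norms regression |

A sidecar `<name>.meta.json` records the generating seed.

## Incidence / prevalence surfaces (CSV, long format)

`io.write_surface` / `io.read_incidence` / `io.read_prevalence`:
columns `age`, `year`, and a value column (default `value`); one row per
(age, year) cell, grid complete.

## Country profile (JSON or YAML by extension)

`io.write_profile` / `io.read_profile`. Keys: `name`,
`population_by_age` (total persons, single ages from 0), `gdp_ppp`
(per-capita international $), `legislation_present`, `type3_share`,
`health_providers`, `legal_personnel`, `first_births_per_year`,
`historic_trend`, `n_communities`, `region`, `conflict`.

## Unit costs (CSV)

`io.write_unit_costs` / `io.read_unit_costs`: columns `intervention`
(must name a known intervention), `reference_cost` (USD2020 per unit),
`reference_gdp_ppp`.

## Cost ledger (CSV)

`io.write_ledger`: columns `country`, `region`, `year`, `intervention`,
`category`, `number_reached`, `service_cost`, `support_cost`,
`total_cost` (all money USD2020; `total = service + support`).

## Run configuration (YAML)

`io.load_config` applies documented defaults (see `io.DEFAULT_CONFIG`).
Keys: `seed`; `countries` (`n_countries`, `n_communities`,
`women_per_community`); `scenario` (`name`, `coverage_target`,
`effects` {`direct`, `indirect`, `indirect_ratio`},
`planning_indirect_ratio`, `persistence`, `spillover`,
`covid_delay_years`, optional horizon overrides); `unit_costs` (path or
null for package defaults); `sensitivity_rows` (list or null for all).
Unknown keys are rejected with the offending field path.

## Run metadata (JSON)

Written with every output set: `config_hash` (SHA-256 of canonical
JSON), `seed`, `timestamp`, `version`, `input_digests`.
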
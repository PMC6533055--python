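# Survey table column dictionary

`thalmap.geodb.load_survey_table` reads UTF-8 CSV files with a header row.

| column | required | type | meaning |
|---|---|---|---|
| `survey_id` | yes | string | unique identifier of the population sample |
| `source_id` | no | string | citation key of the source publication |
| `country` | yes | string | country name (e.g. `Thailand`, `Lao PDR`) |
| `location_name` | no | string | free-text place name |
| `latitude`, `longitude` | yes* | float | WGS84 decimal degrees of the survey centroid; empty for national-level surveys |
| `national_level` | yes* | bool | `True` when the survey can only be located at the national level; such rows must have empty coordinates |
| `year` | no | int | survey calendar year |
| `group` | no | string | population sampled (community, newborns, pregnant women, ethnic group, ...) |
| `n_individuals` | yes | int ≥ 1 | sample size in individuals; the chromosome denominator is `2 * n_individuals` |
| `freq_a0`, `freq_aplus`, `freq_and` | no | float | allele frequency of the double-deletion, single-deletion and non-deletional forms. Proportions in [0, 1] by default; pass `percent=True` if the file stores percentages in [0, 100] — the unit is never guessed. Empty = form not tested |
| `count_a0`, `count_aplus`, `count_and` | no | int | alternative to `freq_*`: chromosome counts, normalised by `2n` at load |
| `var:<label>` | no | int | chromosome count for one typed variant; empty = variant not tested (distinct from an observed count of 0) |

*Either point coordinates or `national_level=True` must be present.

Recognised variant labels: `-a3.7`, `-a4.2`, `--SEA`, `--THAI`, `--MED`,
`--FIL`, `-(a)20.5`, `Hb Adana`, `Hb CS`, `Hb Pakse`, `Hb Quong Sze`,
`Other`. Unknown labels are folded into `Other` with a warning.
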
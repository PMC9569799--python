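# File formats

All outputs are tab-separated text with a single header row, or JSON.

## Damage set (`damage.tsv`)

Simplified SDD-like exchange format. First line is a `#` comment with
exposure metadata (`dose_gy`, `dsb_yield`, `complex_fraction`,
`hc_fraction`, `nucleus_radius_nm`, `seed`), then:

| column | meaning |
|---|---|
| `id` | integer DSB identifier |
| `x_nm`, `y_nm`, `z_nm` | position inside the spherical nucleus (nm) |
| `complexity` | `simple` or `complex` (extra break within 10 bp) |
| `chromatin` | `EC` (euchromatin) or `HC` (heterochromatin) |
| `pathway` | `fast`, `slow`, or `unassigned` |

## Repair curve (`repair_curve.tsv`)

`time_s`, `unrepaired_fraction` (or `unrepaired_count` when not
normalized); piecewise-constant, monotone non-increasing.

## Repair event log (`repair_events.tsv`)

`dsb_id`, `pathway`, `completion_time_s`, `correct_partner`
(`true`/`false`; `false` marks a wrong-partner joining).

## Network parameter file (`p53_params.tsv`)

`name`, `value`, `unit`, `source` — one rate constant or Hill constant
per row; `source` tags provenance (`calibrated`, `base-model`,
`standard-yield`). Every constant referenced by the reaction list must
be present.

## Trajectory (`trajectory_<engine>.tsv`)

`time_h` followed by one column per species (copy numbers); the `DSB`
column is the external forcing.

## Fate / sweep tables

`fate.tsv`: `apoptotic`, `apoptosis_time_h`, `arrest_duration_h`,
`tgfb_cumulative`. `sweep.tsv`: one row per condition with `dose_gy`,
`f_slow`, `m_gy_equiv`, `n_cells`, `n_failed`, `apoptosis_pct(_se)`,
`mean_arrest_h`, `se_arrest_h`, `mean_tgfb`, `se_tgfb`.

## Manifests

Every CLI run writes `manifest.json`: package version, command, full
validated configuration (including the master seed). Sweeps add
`sweep_manifest.json` with the parameter-file SHA-256 and the
counter-based seeding scheme; a manifest plus the package version
reproduces a run bit-exactly.

## Reaction audit (`reactions.json`)

Full serialized reaction list: per channel the rate-constant name and
value, reactants, products, catalysts, and any Hill modifier
(species, K, exponent, activation/repression).
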
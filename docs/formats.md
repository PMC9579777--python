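# File formats

All tabular output is comma-separated UTF-8 with a header row, `.` decimal
separator, no index column, and floats printed at 17 significant digits
(`%.17g`), which round-trips IEEE doubles losslessly (re-read with
`pandas.read_csv(..., float_precision="round_trip")` for exact recovery).
No file carries a timestamp, so identical invocations are byte-identical.

## Run configuration (TOML, read by `abilitygame evolve --config`)

A single flat document; see `examples/sim.toml` and
`examples/sim_sexual_scaled.toml`.

| key | type | meaning | default |
| --- | --- | --- | --- |
| `p` | float | cost exponent, > 1 | required |
| `mode` | string | `"sexual"` or `"asexual"` | required |
| `n_individuals` | int | population size (even) | 1000 |
| `n_generations` | int | generations to simulate | 10001 |
| `initial_ability` | float | founder ability in [0, 1] | 1.0 |
| `segregation_sd` | float | infinitesimal-model segregation SD (sexual) | 0.05 |
| `mutation_prob` | float | per-offspring mutation probability (asexual) | 0.01 |
| `mutation_sd` | float | mutation effect SD (asexual) | 0.05 |
| `record_every` | int | quantile-series thinning interval | 10 |
| `seed` | int | RNG seed | 0 |

Unknown keys are rejected with an error naming the key.

## CSV schemas

* gradient curve (`gradient`, `figures --figure fig2`):
  `ability, gradient`
* PIP long format (`pip`, `figures --figure fig2`):
  `resident, mutant, delta, invades` — `delta` is
  V(mutant, resident) − V(resident, resident); `invades` is 0/1.
* quantile series (`evolve --series`, `figures --figure fig3/fig4`):
  `generation, q025, median, q975`
* final histogram (`figures --figure fig3/fig4`):
  `bin_left, bin_right, count` — 20 equal bins on [0, 1].
* mutant sweep (`figures --figure fig1`):
  `mutant_ability, mutant_effort, partner_effort, total_effort, benefit,
  cost, net_payoff, resident_payoff`

## JSON schemas

* `nash --json`: `{a1, a2, p, e1, e2, w1, w2, converged, iterations}`.
* `singular --json`: list of `{location, gradient_at,
  second_deriv_invasion, convergence_stable, evolutionarily_stable, label}`
  with `label` one of `boundary_attractor_low`, `boundary_attractor_high`,
  `css`, `branching_point`, `repeller`.
* `evolve --out`: `{config: {...}, p, final_median,
  final_histogram: {bin_edges, counts}}`.
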
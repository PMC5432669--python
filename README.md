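# parwire

A parallel construction kernel for spiking neuronal networks, as a testable
library and CLI. It models how a multi-process / multi-thread simulator
builds a network in memory:

- **topology** — 0-based global identifiers (gids) distributed round-robin
  over `VP = M × T` virtual processes (`vp = gid mod VP`); en-bloc
  registration of node populations so registry cost is independent of
  population size.
- **rng_streams** — one Philox stream per virtual process, seeded from
  `(master_seed, vp)` only, so construction results are identical for a
  fixed VP count regardless of the process/thread factorization.
- **connection_store** — per-VP adjacency: a sparse source table plus
  adaptive per-source connectors (fixed-size below a cutoff of 3,
  capacity-doubling dynamic containers above it, heterogeneous containers
  for multiple synapse types), with a ledger counting every modeled
  allocation/free event.
- **connection_rules** — fixed in-degree wiring in two loop orders
  (scan-all-targets-and-skip vs scan-local-nodes-and-test-membership) that
  produce identical networks, plus all-to-all; per-phase operation counters
  replace wall-clock phase timings.
- **predictions** — closed-form expected connector sizes (`εK/VP`,
  `(1−ε)K/VP`, `K/VP`), allocation-count formulas
  (`(4+⌈log₂(k/3)⌉)·S` allocs / `(3+⌈log₂(k/3)⌉)·S` frees in the dense
  regime, `2·N1c` / `N1c` in the sparse regime), Poisson occupancy classes
  per VP, and a Monte-Carlo occupancy oracle.
- **benchmark_model** — builder for the balanced random network benchmark
  (80% excitatory / 20% inhibitory, fixed in-degree, plastic E→E synapses)
  with a single-rank dryrun mode and a vectorized counting mode.
- **dynamics** — minimal leaky integrate-and-fire loop with delayed spike
  delivery through the stores and an additive pair-based plasticity rule,
  demonstrating partition-invariant state propagation.
- **allocator_model** — guarded-interaction counts for serialized vs
  thread-local-pool allocator regimes over the per-VP event ledgers.
- **cli_io** — `parwire` command-line front end and deterministic
  micro-fixtures.

## CLI

```sh
# closed-form predictions for a 25,000-neuron benchmark on 48 VPs
parwire predict --N 25000 --K 2500 --epsilon 0.8 --vp 48

# build a small network deterministically; writes edges.tsv + report.json
parwire build --N 1000 --K 100 --vp 4 --seed 1 --loop-order local-scan \
    --out-dir out/

# build one rank of an emulated 4-process x 2-thread run
parwire build --N 1000 --K 100 --processes 4 --threads 2 --rank 0 --out-dir out/

# build + simulate, writing spikes.gdf (one "time_ms<TAB>gid" per line)
parwire simulate --N 1000 --K 100 --vp 4 --duration-ms 100 --out-dir out/

# allocator-contention counts from a build report
parwire contention --report out/report.json --refill-size 64

# deterministic micro-networks for regression tests
parwire fixture indeg2_ring --out-dir out/
```

Options may also be given in a flat YAML/JSON file via `--config`;
command-line flags override file keys. Any two of `--vp`, `--processes`,
`--threads` determine the third; an inconsistent triple is a validation
error.

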
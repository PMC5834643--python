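# mirlearn

Small-RNA-seq differential expression and accessibility-aware miRNA target
scoring, with a fully synthetic test bench.

The package chains five analysis capabilities, plus a generator that
simulates every input the chain consumes with known ground truth:

1. **Read processing** — 3' adapter trimming (bounded mismatch fraction,
   partial adapter at the read end), length/quality filtering (≥ 15 nt,
   every base above Q20), and size-class histograms (20–23 nt mature
   miRNAs, 26–28 nt piRNAs, the minor 41 nt class).
2. **Quantification** — assignment of inserts to hairpin references by
   fewest-mismatch substring match (ties discarded as ambiguous), count
   tables, counts-per-million.
3. **Differential expression** — the Audic–Claverie exact test for count
   data from unreplicated libraries, with Benjamini–Hochberg FDR control.
4. **Target prediction** — seed-match scanning of 3'UTRs (perfect
   Watson–Crick seed, G–U wobbles counted in the 3' supplementary region)
   scored by `ddG = dG_duplex + dG_open`: a nearest-neighbor duplex
   minimum free energy plus the cost of opening the site's local secondary
   structure, computed from McCaskill partition functions.
5. **qPCR quantification** — the comparative-CT method (2^−ΔΔCT) with
   per-group mean ± SEM.

A `pipeline` module and the `mirlearn` CLI orchestrate
`simulate → process → quantify → detest → target → qpcr` as a configured,
logged, checksummed run.

## Quick start

```python
from mirlearn import (SimulationConfig, generate_hairpin_set, generate_library,
                      map_reads, build_count_table, call_differential)
from mirlearn.reads import process_library

cfg = SimulationConfig(rng_seed=3, n_mirnas=60,
                       library_depths={"naive": 100_000, "1h": 100_000},
                       planted_effects={"Lym-sim-miR-001": ("1h", 1.5)})
hairpins = generate_hairpin_set(cfg)
assignments = {}
for lib in cfg.library_depths:
    sim = generate_library(cfg, hairpins, lib)
    kept, tally = process_library(sim.reads, cfg.adapter3p)
    assignments[lib] = map_reads(kept, hairpins)
table = build_count_table(assignments, [h.name for h in hairpins], ["naive", "1h"])
for r in call_differential(table, ("naive", "1h"), alpha=0.01)[:1]:
    print(r.mirna, r.x, "->", r.y, f"fold {r.fold_change:.3f}", f"p_adj {r.p_adj:.2e}")
```

prints (deterministically, for this seed):

```
Lym-sim-miR-001 1727 -> 2652 fold 1.512 p_adj 8.93e-40
```

The planted 1.5-fold effect is recovered at adjusted p < 0.01; the
processing step is lossless at these settings, so the count table equals
the generator's ground truth exactly.

Or run everything from a config file:

```bash
mirlearn run --config run.yaml          # full pipeline
mirlearn simulate --config run.yaml     # one stage
mirlearn detest --config run.yaml --seed 42 --outdir other_run
```

A minimal `run.yaml`:

```yaml
run_id: demo
rng_seed: 1
outdir: demo_run
library_depths: {naive: 100000, "1h": 100000, "6h": 100000}
planted_effects:
  Lym-miR-137: ["1h", 1.5]
```

Each run writes per-stage TSV/FASTA/FASTQ outputs plus `manifest.json`
with a SHA-256 checksum of every file; re-running with the same config is
byte-identical, and partial runs resume against checksummed outputs.

## Examples

`examples/` holds one narrative script per capability:

| script | shows |
| --- | --- |
| `01_simulate_small_rna_study.py` | synthetic three-library study with ground truth |
| `02_process_and_quantify.py` | trimming, filtering, size classes, exact count recovery |
| `03_differential_expression.py` | Audic–Claverie test + BH, power of a 1.5-fold effect |
| `04_target_prediction.py` | seed scan, pairing map, dG_duplex / dG_open / ddG |
| `05_qpcr_quantification.py` | 2^−ΔΔCT with and without CT noise |
| `06_full_pipeline.py` | config-driven run, manifest, byte-reproducibility |

## Tests and acceptance

```bash
python -m pytest tests/            # unit + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite validates the numerical core against independent
brute-force oracles: exhaustive structure enumeration for the duplex DP
and the partition function, and direct log-space tail summation for the
exact test. Two optional tests compare target scores on a published 3'UTR
(GenBank AB083656); they run only if you place that sequence at
`tests/data/AB083656.fasta` (it is not redistributed here).

The acceptance script recomputes the headline quantities — mapped-read
fraction, null calibration of the exact test, planted-effect recovery,
oracle deviations, round-trip checks — and writes them as JSON.

## Documentation

`docs/methods.md` describes the statistical model, the energy model and
its declared simplifications, all defaults and units, and the generator's
scope and limits.
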
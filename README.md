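# priosc

Prioritized LC-MS/MS acquisition simulation and single-cell proteomics
quantification, as a desk-scale Python toolkit.

## The problem

Shotgun (topN) data-dependent acquisition fragments the *n* most abundant
precursors in each duty cycle. For single-cell proteomics this is doubly
costly: peptide selection is stochastic (poor data completeness across cells),
biased toward abundant proteins, and much of the cycle is spent on precursors
that will never be identified. Multi-tier *prioritized* acquisition fixes the
selection, not the chemistry: a large inclusion list of identifiable
precursors keeps every duty cycle full, and integer priority levels decide who
gets the limited MS2 slots — an entry with priority *p* always outranks
anything with priority < *p*, with intensity and m/z breaking ties. After
each in-tolerance fragmentation the entry's priority is decremented (floored
at 0), so a tier's members rotate through the available slots. Low-abundance
peptides of interest can additionally be given longer ion-accumulation (fill)
times: 1000/750/500 ms for the bottom/middle/top intensity tertile of the
high-priority level.

`priosc` implements that acquisition logic as an in-silico duty-cycle
simulator, plus everything around it that such a campaign needs:

* **`priosc.acquisition`** — DDA duty-cycle simulator (topN and prioritized
  modes), sliding-median real-time RT alignment, per-tier MS1/MS2/ID rate
  metrics, percent-gain arithmetic.
* **`priosc.inclusion`** — tiered inclusion-list construction from PSM tables:
  decoy-based FDR at the largest PEP cutoff with decoy fraction <= 1%,
  PIF and carrier-ratio filters, charge-state deduplication, declarative tier
  rules, intensity-tertile fill times.
* **`priosc.merops`** — semi-tryptic FASTA augmentation from protease-cleavage
  annotations: split at the P1|P1' bond, in-silico tryptic digestion of both
  halves, neo-C/neo-N fragments >= 6 residues appended as annotated entries.
* **`priosc.quant`** — single-cell reporter-ion processing: CV-based cell QC
  (threshold 0.4), 99% missingness filter, column-median/row-mean
  normalization, log2, median protein aggregation; no imputation.
* **`priosc.stats`** — intensity-binned (15 equal-count bins) replicate-null
  differential abundance with z-scores t-tested against a 10,000-value
  standard-normal draw and BH correction; protein-set enrichment on PC
  loadings (two-tailed rank-sum, set-size filters 5/10%/200); marker-panel
  permutation tests (10,000 label permutations, q floored at 1e-5 when p = 0);
  spike-in accuracy regression through the origin over a 16-fold, five-level
  design.
* **`priosc.fixtures`** — seeded synthetic generators for every input above,
  each with a ground-truth table.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Three 500-entry priority tiers compete for one 500-ms MS2 slot per 5-second
duty cycle over a 60-minute gradient — about half the detected load — first
prioritized, then topN with identical parameters:

```python
import numpy as np
from priosc.fixtures import FixtureSpec, make_lcms_population
from priosc.acquisition import AcquisitionConfig, simulate_run, run_metrics, percent_gain

spec = FixtureSpec(seed=11, n_peptides=1500, drift_magnitude=0.0)
peptides, entries, _ = make_lcms_population(spec)
rng = np.random.default_rng(12)
priorities = np.repeat([2, 1, 0], 500)
rng.shuffle(priorities)
for e, p in zip(entries, priorities):
    e.priority = int(p)

config = AcquisitionConfig(
    cycle_time_s=5.0, survey_cost_s=4.0, ms2_overhead_s=0.05,
    default_fill_ms=500.0, rt_tolerance_min=0.5, noise_floor=1.0,
    topn_n=10, dyn_exclusion_s=1e9, id_threshold_ions=1.0, gradient_min=60.0,
)

for mode in ("prioritized", "topn"):
    log = simulate_run(peptides, entries, config, mode=mode, seed=1)
    print(f"--- {mode} ---")
    print(run_metrics(log, entries).round(1))

print("consistency gain:", percent_gain(18, 59), "%")
```

Output:

```
--- prioritized ---
        n  detection_pct  send_pct  id_pct
tier
0     500          100.0       1.0     1.0
1     500          100.0      32.2    32.2
2     500          100.0      98.0    98.0
--- topn ---
        n  detection_pct  send_pct  id_pct
tier
0     500          100.0      44.0    44.0
1     500          100.0      42.8    42.8
2     500          100.0      44.2    44.2
consistency gain: 228 %
```

Every tier is detected in survey scans equally (detection ~100%), but under
prioritization the MS2 slots go to the top tier first: 98% of tier-2 entries
are fragmented, 32% of tier-1, 1% of tier-0. topN, blind to tiers, spreads the
same capacity evenly (~43–44% everywhere). The final line is the percent-gain
arithmetic on a benchmark pair of all-run identification rates (18% without,
59% with prioritization → a 228% gain in consistency).

## Command line

A thin CLI wraps the library:

```sh
priosc make-fixtures --seed 3 --out fx/                 # synthetic inputs + truth
priosc build-list --psms fx/psms.tsv --spec tiers.json --seed 4 --out list.tsv
priosc sim --mode prioritized --inclusion list.tsv --peptides fx/peptides.tsv \
       --seed 5 --out simout/
priosc augment-fasta --fasta db.fasta --cleavages sites.tsv --out db_aug.fasta
priosc quantify --matrix fx/quant_matrix.tsv --cell-meta fx/cell_meta.tsv \
       --protein-map fx/protein_map.tsv --out quant/
priosc diffexp / psea / permtest / spikein / report ...
```

Each subcommand writes a `manifest.json` (inputs, parameters, seed, version)
sufficient to replay it.

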
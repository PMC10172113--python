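# Methods

## Scope and model of the instrument

`priosc` models data-dependent LC-MS/MS acquisition at the level of the duty
cycle, not the spectrum. A run is a sequence of cycles of fixed wall-clock
length (`cycle_time_s`); each cycle spends `survey_cost_s` on the MS1 survey
scan and packs MS2 scans into the remainder. An MS2 scan costs its allotted
maximum fill (ion-accumulation) time plus a fixed per-scan overhead
(`ms2_overhead_s`). Real instruments stop accumulating when an AGC ion target
is reached, so actual fill times are data-dependent; the fixed-cost model
deliberately ignores this because scheduling behaviour — which precursor is
analyzed when time is limiting — depends on the budgeted, not the realized,
cost.

Ground-truth precursors elute as Gaussians: intensity at time *t* is
`max_intensity * exp(-(t - apex)^2 / (2 sigma^2))`, with a per-run additive
retention-time drift. A survey scan at *t* detects an inclusion-list entry iff
*t* lies within `rt_tolerance_min` of the entry's offset-corrected predicted
apex and the Gaussian intensity is at or above `noise_floor`.

### Precursor selection

Two modes share one greedy packer:

* **topN** — candidates ordered by intensity (descending), at most `topn_n`
  selections, each costing the default fill time. This is the shotgun
  heuristic and the package's baseline.
* **prioritized** — candidates ordered by (priority descending, intensity
  descending, m/z ascending) and packed first-fit: an entry that does not fit
  the remaining budget is skipped and the walk continues, keeping duty cycles
  full. Priorities are non-negative integers from the inclusion list (default
  0). After each fragmentation that occurred within the RT tolerance of the
  peptide's true apex, the stored priority is decremented by one, floored at
  zero — an entry already analyzed stops outcompeting its tier until the rest
  catch up. Fragmentations outside tolerance (wrong target) do not decrement.

Tie-breaking (intensity, then m/z) is a package choice: some deterministic
total order is required for reproducible runs, and intensity-then-m/z is the
natural instrument-flavoured one. Selected entries enter dynamic exclusion for
`dyn_exclusion_s` (default 30 s, standard DDA practice; set effectively
infinite to model analyze-once campaigns). Priorities reset between runs and
are never re-incremented within a run.

### Retention-time alignment

The real-time offset estimate is the median of (observed − predicted) apex
times over the most recent `calib_window` calibration observations, zero when
none exist. One observation is contributed per entry, at its first detection.
A sliding median tracks slow drift robustly and is trivially testable; the
proprietary aligner it stands in for is not specified anywhere reproducible.

### Identification model

`ions_sampled = intensity x fill_ms`; an MS2 event is identified iff
`ions_sampled >= id_threshold_ions`. This deterministic threshold captures the
one mechanism the scheduler can exploit — more ion copies through longer fills
or better timing — without simulating spectra or search engines.

## Inclusion-list construction

Candidates come from evidence-style PSM tables. The FDR filter finds the
largest PEP cutoff at which decoys are at most the target fraction (default
1%) of all entries at or below the cutoff; decoys and contaminants are then
removed. Spectral-purity (PIF) and carrier-ratio filters mirror single-cell
practice: PSMs with PIF < 0.5 are dropped, as are PSMs whose mean single-cell
reporter intensity exceeds a configurable fraction of the carrier channel
(0.10 in the human cell-line pipeline, 0.02 in the macrophage pipeline; no
single default is privileged and the CLI takes it explicitly). Charge states
of a modified sequence are condensed to the lowest-PEP row, ties broken by
higher precursor intensity. "Spectral confidence" is read as PEP throughout
(lower = more confident).

Tiers are declarative rule sets evaluated highest-priority-first on the pool
of unassigned precursors, so tiers are disjoint by construction. Supported
rules: PEP and PIF thresholds, top-k-per-protein by PEP, identified-run
fraction bounds (counting runs with at least one qualifying PSM), seeded
sampling without replacement, and a size cap. Precursors left over after all
tiers become RT-calibration-only entries (MS2 disabled). The sampling seed is
recorded in the list header.

Fill times: under the tertile policy, tertile boundaries are computed across
the full filtered candidate intensity pool; high-priority entries in the
bottom/middle/top tertile receive 1000/750/500 ms and everything else 500 ms.
Boundary ties fall into the lower-intensity bin (a determinism choice); on
distinct intensities the three bins differ in size by at most one.

## Semi-tryptic FASTA augmentation

Protease cleavage annotations give the P1 residue position; the scissile bond
is between P1 and P1'. Records with K or R at P1 are indistinguishable from
tryptic background and are removed. For each remaining site the parent
sequence is split after P1 and each half digested in silico with trypsin
(cleave after K/R; an optional switch blocks cleavage before proline — both
conventions are used by common search engines, and the plain rule is the
default). The tryptic fragment abutting the cut on the N-terminal side
carries the neo-C terminus; the fragment starting at the cut carries the
neo-N terminus. Fragments shorter than 6 residues are suppressed (below the
practical identification floor). Fragments are appended to the FASTA as
separate entries headed
`{protein}|MEROPS|{enzyme}|pos{P1}|{neo_C|neo_N}`; the original entries are
untouched. Whole halves are *not* added — the emitted entries are peptides,
which is what the 6-residue digest constraint presupposes.

## Single-cell quantification

Quality control: for every cell and every protein with at least two observed
peptides, the CV (sd/mean) of the peptide relative abundances is computed;
the cell's aggregate is the mean of protein CVs (median available — reports
of this procedure use both, so it is a flag with the mean as default) and
cells above 0.4 are removed. Negative controls (reagent-only droplets) carry
uncorrelated reporter noise, so their aggregate CV is large; they are
reported alongside cells but never enter downstream statistics.

Normalization (order fixed and documented since upstream conventions vary):
optional division by the reference channel per precursor; column (cell)
division by the median over observed entries; row (precursor) division by the
mean; log2; protein abundance = median over the protein's observed peptides.
Missing values propagate — there is no imputation anywhere in the package;
imputation and batch correction are identity pass-through hooks by design.
One column/row normalization pass is not an exact fixed point on finite
matrices: a second pass perturbs values at the order of
1/sqrt(n features) (about 7% on a 500 x 120 matrix), vanishing only in the
infinite-data limit. The missingness filter drops cells, then features, whose
missing fraction reaches 99% (strict threshold: 98.9% missing is kept).

Completeness is reported per cell and per priority tier as the percent of
tier features observed, plus per-feature rates across cells. The sensitivity
contrast splits each run's log10 intensity range into 30 equal-width bins and
summarizes per-bin identification counts by median and s.d. across the runs
of each platform (s.d. flagged 0 for a single run).

## Statistics

**Intensity-binned null differential abundance.** Replicate injections of one
sample define null log2 fold changes; because quantification noise shrinks
with intensity, pairs are split into 15 equal-count bins over average
intensity, storing each bin's mean and s.d. Fold changes between conditions
are z-scored through their bin; bins with zero s.d. (identical replicates)
raise an error rather than silently inflating z-scores. Per protein, the
precursor z-scores are tested against one seeded draw of 10,000
standard-normal values with a Welch two-sample t-test (a pooled-variance test
when a single precursor leaves the group variance undefined; such proteins
are flagged, not dropped), and BH correction is applied across proteins. The
z-conversion uses bin mean/s.d. rather than an empirical quantile map — the
simpler model, adequate when the binned null is roughly Gaussian, which the
held-out calibration test checks (|mean| < 0.1, |s.d. − 1| < 0.1 at n =
5,000). Note the small-n ceiling: with 5 precursors the Welch test has ~4
degrees of freedom, bounding attainable significance regardless of effect
size. Marker panels additionally require |log2 fold change| >= 1.

**PSEA on PC loadings.** A set is tested when at least 5 members are present,
those members are at least 10% of the set, and the set has fewer than 200
entries. Member loadings are compared to all non-member loadings with a
two-tailed Wilcoxon rank-sum test (exact for small untied samples). The
reported per-set z is the set's median loading standardized across all tested
sets — the most direct reading of "median loading as a z-score"; a
resampling-based reference population would be an alternative, heavier
choice.

**Marker-panel permutation test.** On the cells x proteins matrix restricted
to targets and panel members, the observed statistic per target is the median
Pearson correlation with panel A minus the median with panel B. The null
permutes the protein-column labels (the literal reading of the procedure;
cell-label permutation is the more common null and is deliberately not the
default here), p is the fraction of |null| >= |observed| over 10,000
permutations, BH is applied across targets, and an empirical p of exactly 0
receives a q floor of 1e-5. Swapping the panels flips the statistic's sign
and leaves p unchanged.

**Spike-in regression.** Reporter intensities are normalized per experiment
and precursor by the median of the 1x channels, charge states are collapsed
per sequence by the median, and log2 normalized intensity is regressed on
log2 relative level through the origin. With a single predictor, the
through-origin least-squares slope coincides with a one-component
through-origin projection (partial-least-squares) fit, so plain least squares
is used; R^2 is the uncentered coefficient of determination, as appropriate
without an intercept. Experiments lacking 1x anchors are excluded with a
reason.

**BH correction** is `statsmodels` `multipletests(method="fdr_bh")`; the test
suite checks it against a hand-coded step-up oracle.

## Synthetic study conditions

All generators derive every stream from one integer seed via spawned
`SeedSequence` substreams, so any downstream number is reproducible from one
integer, and every generator emits a ground-truth table.

Defaults emulate the structure of prioritized single-cell experiments:
log-normal precursor intensities (log-sd 1.5); Gaussian elution with sigma
0.08–0.25 min over a 60-min gradient; per-run RT drift, constant or linear;
PSM tables with an exact decoy count whose PEPs are stochastically larger
than targets (so a 1% decoy-fraction threshold is informative); carrier and
reference reporter channels about 200x and 5x over single cells; 12
single-cell channels per run across 6 runs; cells x peptides matrices with
8 protein modules of 10 proteins, within-module correlation 0.6, 4 peptides
per protein, multiplicative log-normal measurement noise (log-sd 0.10 for
cells, 0.80 for reagent-only controls — the contrast that makes the 0.4 CV
threshold discriminate), and 20% uniform missingness; replicate pairs with
log2 noise s.d. 0.3, optionally shrinking with intensity rank to mimic more
precise quantification of abundant precursors; spike-in sets of 4 sequences
x 2 charge states at levels 1/2/4/8/16x over 8 experiments.

What the generators do **not** emulate — and hence what passing tests do not
establish about real data: chromatographic co-elution and isolation
interference, charge-state-dependent response, peptide-specific ionization
efficiency, batch structure, missingness that depends on abundance, and
search-engine score distributions. The fixtures validate the *logic* of the
procedures (ordering, budgets, thresholds, calibration under the stated
noise model), not instrument realism.

### Problem sizes in the shipped checks

The acceptance script and test suite run the scheduler contrast on 1,500
inclusion entries (three 500-entry tiers) over a 60-min simulated gradient
with one 500-ms MS2 slot per 5-s cycle and unbounded dynamic exclusion —
total MS2 capacity about half the detected load, which is the regime where
prioritization matters; the differential-testing calibration uses 200 null
simulations of 60 proteins x 5 precursors against a null fitted on 1,500
replicate pairs; PSEA null behaviour uses 100 shuffles of 150 loadings
against 15 sets; spike-in recovery uses 200 repeats of 8 experiments. These
sizes were chosen as the smallest at which the contrasts are unambiguous.

## Numerical choices and degenerate inputs

* FDR threshold: evaluated at every distinct observed PEP (ties included);
  returns NaN and an empty retention when no cutoff achieves the target.
* Equal-count binning uses stable argsort + `array_split`, so bin counts
  differ by at most one.
* Zero-length gradients yield empty logs; empty tiers report NaN rates, not
  zero; empty calibration lists yield zero offset.
* Scheduler randomness: the seed perturbs only optional per-run RT/intensity
  jitter (both default 0); scheduling itself is deterministic, and identical
  seeds give byte-identical logs.
* Permutation q-floor applies only when the empirical p is exactly 0.

## Known limitations

* The fixed-cost MS2 model cannot capture AGC-driven fill-time truncation, so
  absolute throughput numbers are not comparable to a real instrument; only
  relative scheduling behaviour is.
* The identification threshold has no false positives by construction; decoy
  behaviour exists only in the PSM-table generator, not in the simulator.
* The through-origin spike-in regression assumes multiplicative noise; with
  additive noise at low levels the slope biases low.
* Protein-column label permutation preserves each cell's expression profile
  but breaks protein identities; if panels share strong global structure with
  most of the matrix, this null is conservative.
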
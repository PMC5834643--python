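# Methods

This note documents the models implemented in `mirlearn`, every default
that affects results, the numerical choices, and what the synthetic
generator does and does not simulate. Units: free energies in kcal/mol at
37 °C; coordinates 0-based half-open internally (mature-miRNA positions in
pairing maps are 1-based, matching convention).

## 1. Read processing (`mirlearn.reads`)

Reads carry Phred+33 qualities. Processing is: trim the 3' ligation
adapter, then filter.

**Adapter trimming.** The adapter may start at any read position,
including partially running off the read end. A candidate occurrence at
position *k* is accepted when its Hamming mismatch fraction over the
overlapping bases is ≤ `max_error_rate` (default **0.1**, the cutadapt
convention); the leftmost accepted occurrence wins, which gives the
shortest-insert interpretation priority, as a semi-global trimmer does.
End overlaps shorter than **3 nt** are ignored (`min_overlap`). A read
with no acceptable occurrence is rejected ("no adapter"); an occurrence at
position 0 is an adapter dimer, also rejected. Rejection is a value, not
an exception. A vectorized batch path (`process_library`) implements
identical semantics; a property test asserts batch == scalar on random
reads.

**Filtering.** Retained reads need insert length ≥ `min_len` (default
**15 nt**) and every base quality strictly above `min_q` (default
**Q20** — a base at exactly Q20 rejects). An optional blacklist removes
contaminants by exact sequence match. Rejections are tallied per reason.

**Size classes.** Closed intervals: mature miRNA 20–23 nt, piRNA
26–28 nt, minor class exactly 41 nt, everything else "other".

## 2. Quantification (`mirlearn.quantify`)

Inserts are assigned to hairpin precursors (sense strand) by ungapped
substring match with at most `max_mismatches` ∈ {0, 1, 2} mismatches
(default **0**). The fewest-mismatch hit wins; a best-hit tie across
distinct miRNA names discards the read as ambiguous. Exact matching uses
one substring search over a concatenated reference (separator-joined);
the mismatch path scans per-hairpin sliding windows in numpy. Count-table
column sums (reads assigned per library) are the library totals N1, N2
used by the exact test; CPM rescales columns to 10⁶.

## 3. Differential expression (`mirlearn.diffexpr`)

**Audic–Claverie exact test.** For a tag with counts *x*, *y* in two
libraries of totals N1, N2, the probability of *y* given *x* under Poisson
sampling with a flat prior on the common rate is

    p(y | x) = (N2/N1)^y · (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is the negative-binomial predictive distribution with r = x + 1 and
success probability N1/(N1+N2). `ac_probability` evaluates the mass in
log space (log-gamma); `ac_test` takes tails from the same distribution's
CDF/SF (scipy). One-sided p-values include the observed point once; the
two-sided p-value is `min(1, 2·min(lower, upper))`. p-values are floored
at the smallest positive double rather than returned as 0.

Tests compare the tails against an independent log-space summation of the
mass recurrence. Agreement is at double precision wherever the p-value
exceeds 1e−30; in astronomically deep tails (~1e−286) the incomplete-beta
evaluation carries ~3e−9 relative error (verified against 60-digit
arithmetic), which is statistically irrelevant and declared in the test
tolerance.

**Multiple testing.** Benjamini–Hochberg step-up adjusted p-values
(delegated to statsmodels `fdr_bh`; unit-tested against the step-up
formula). A miRNA is called significant when adjusted p < `alpha`
(default **0.01**, strict). Fold change is the rate ratio
(y/N2)/(x/N1): `inf` when x = 0 < y, `NaN` when both counts are 0
(rendered `Inf`/`NA` in TSV output).

**Calibration and power.** Under a Poisson null (200 tags, equal
expected totals), the measured two-sided rejection rate at 0.05 is at or
below nominal (the test is conservative for discrete counts), and BH at
0.01 flags ≈ 0% of null tags. Note the test conditions on library totals,
which are themselves sums of the counts: planting a large amount of
differential mass shifts the totals and biases every other tag's test
(compositional effect). The power checks therefore plant few (≤ 3)
moderate-abundance effects per run — baseline expectation 500–2500 reads
out of 10⁵, chosen from the generator's abundance vector *before* any
counts are drawn — keeping the planted mass ≤ ~3% of the library. At
those baselines a 1.5-fold effect is recovered at adjusted p < 0.01 in
≥ 90% of seeded runs (observed: 100%).

## 4. Thermodynamics (`mirlearn.thermo`)

A simplified Turner-style nearest-neighbor model at 37 °C, shipped as
versioned package data (`data/nn_params_37C.json`): Watson–Crick + G–U
stacking energies (published 37 °C values), hairpin/bulge/internal loop
size penalties with Jacobson–Stockmayer extrapolation
(1.75·RT·ln(n/n_max) beyond the tabulated sizes, capped at total loop
size 30), duplex initiation **+4.09**, terminal AU/GU penalty **+0.45**,
affine multiloop cost (closing 3.4, per branch 0.4, per unpaired 0.0),
RT = **0.61633** kcal/mol. Declared simplifications: no
dangling ends or terminal mismatches, no special 1×1/1×2/2×2 loop
tables, no coaxial stacking, no loop-asymmetry penalty. The parameter
file is a swappable artifact.

**Duplex MFE** (`duplex_energy`): dynamic programming over non-crossing
intermolecular pairs (antiparallel); consecutive pairs contribute a stack
when adjacent on both strands, otherwise a bulge/internal-loop penalty;
initiation and the two terminal penalties are added once. "No favorable
duplex" returns 0.0 with an empty trace (keeps downstream ddG finite and
flags the case). Equals brute-force enumeration on hundreds of random
pairs (≤ 8 nt); the one-off cross-check against an external duplex folder
(full Turner model) gave rank correlation ρ ≈ 0.86 with a ~1 kcal/mol
offset, consistent with the declared simplifications.

**Partition function** (`partition_function`): McCaskill-style recursions
(Zb / ZM1 / ZM plus exterior loop) over WC+GU pairs with hairpin loops
≥ 3 nt and the loop decomposition above; returns ln Z. Positions can be
constrained unpaired. Matches Boltzmann-weighted exhaustive enumeration
to ~1e−13 relative on random windows.

**Opening cost**: `dG_open = G_constrained − G_free ≥ 0` with
G = −RT·ln Z, the site forced single-stranded within a window of site
± `flank` (default **70 nt**); clipped at 0 against roundoff.

## 5. Target prediction (`mirlearn.targets`)

Seed = mature positions **2–8** (7-mer, configurable 6–8 nt). A candidate
site is a UTR window exactly Watson–Crick complementary to the seed; G–U
is forbidden in the seed and allowed (and counted) in the 3'
supplementary region. The pairing map extends antiparallel across the
full mature length. Sites are scored

    ddG = dG_duplex + dG_open

where dG_open is stored as the non-negative opening cost, so this equals
ΔGduplex − ΔGopen in the convention where ΔGopen = G_free − G_constrained
≤ 0. Lower ddG = stronger predicted interaction; an occluded site scores
strictly worse than the same site with unstructured flanks (tested).
Multi-site aggregation across a UTR, conservation and 3'-compensatory
site classes are out of scope.

## 6. qPCR (`mirlearn.qpcr`)

Comparative CT: ΔCT = CT(target) − CT(reference) per sample; relative
quantity = 2^−(ΔCT − ΔCT_cal). The calibrator is either a single
designated sample (`single`) or the mean ΔCT of the flagged group
(`group_mean`, default). Group summaries report mean ± SEM (sd/√n);
a single-sample group reports SEM 0 with a warning. Amplification
efficiency correction and melt curves are out of scope.

## 7. Synthetic data (`mirlearn.simulate`)

Everything is a pure function of an integer seed (independent named RNG
streams per artifact, so changing e.g. the qPCR table never perturbs the
libraries).

* **Hairpins**: n (default 100) precursors, 20 nt arm + mature (20–23 nt)
  + 25 nt arm; the first record is always the miRNA of interest with its
  fixed 22-nt mature sequence; matures are pairwise distinct and guarded
  against cross-hairpin collisions.
* **Abundances**: log-uniform over three orders of magnitude, normalized;
  shared across libraries so the only between-library differences are
  planted effects and counting noise.
* **Counts**: Poisson with mean depth × mapped_fraction × abundance ×
  planted fold (default depths 10⁵; mapped_fraction **0.74**); optional
  negative-binomial overdispersion (gamma-mixed Poisson).
* **Reads**: insert + 3' adapter (`AGATCGGAAGAGCACACGTCT`), truncated to
  the 50 nt machine read length; non-miRNA size classes (piRNA 15%,
  41-mer 2%, other 5%, plus 20–23 nt decoys making the mature class 78%)
  are random sequence; per-base qualities drawn from a distribution that
  is entirely above Q20 by default, so processing is lossless and count
  recovery is exact — quality-failure behavior is exercised by setting a
  distribution with sub-Q20 mass.
* **Planted UTR**: the exact reverse complement of the mature with up to
  2 G–U wobbles introduced in the 3' supplementary region (never the
  seed), inside random flanks re-drawn until no spurious seed match
  exists.
* **qPCR tables**: CT_target = CT_ref + base_delta − log2(fold) + noise,
  so the noiseless table returns planted folds exactly.

Not simulated, deliberately: sequencing errors, ligation/GC bias, real
miRBase content, isomiRs, multi-mapping families, and biological
replicate variability beyond the overdispersion switch.

## 8. Reproducibility and problem sizes

All stages are deterministic given the config; the pipeline manifest
records a SHA-256 checksum per output and re-runs are byte-identical.
Typical costs on one CPU: a 3 × 10⁵-read study end-to-end ≈ 30 s; a
partition function on a 160 nt window (22 nt site + 2 × 70 nt flank)
< 1 s; the full test suite ≈ 3 min; `scripts/acceptance.py` ≈ 1.5 min.
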
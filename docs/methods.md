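# Methods

## Scope and model

`hotspotcnv` implements CNV discovery for hotspot-targeted aCGH: probes
report log2 intensity ratios of a test genome against a single two-copy
reference, a heterozygous deletion shifts covered probes by
log2(1/2) = −1 and a single-copy duplication by log2(3/2) ≈ +0.585, and
the analysis task is to recover contiguous shifted probe runs from noisy
per-probe measurements, reduce them to rare events against control
catalogs, and compare carrier burden between cohorts.

## Coordinates

Internal coordinates are 1-based inclusive (the convention in which
aCGH calls are printed, e.g. chr16:73,290,945–73,626,825 → 335,881 bp);
every BED-style file boundary converts to/from 0-based half-open.
Chromosome names are normalized to the `chr` prefix on read. Readers
reject records that violate type invariants (duplicate probe ids,
inverted intervals, missing ratio values — no imputation) rather than
repairing them; the one exception is sort order, repaired with a logged
warning. Missing values are an error because the pipeline assumes
complete hybridization vectors for samples that passed DNA quality
control.

## Synthetic arrays and cohorts

`generate_design` places a configurable number of hotspot regions
uniformly at random (seeded) across a given genome and lays probes with
independent exponential inter-probe gaps. The exponential's **mean** is
set to the nominal spacing (2.6 kbp in hotspots, 36 kbp in the
backbone), so the expected probe count of a region is its length divided
by the nominal spacing and the total lands within ~5% of the probe
target; the realized *median* gap is then spacing × ln 2. Hotspot region
length is derived from the probe target: each hotspot converts backbone
spacing to hotspot spacing over its span, so
`hotspot_len = (target − genome/backbone_spacing) / (n_hotspots ×
(1/hotspot_spacing − 1/backbone_spacing))`. Heavy-tailed exponential
gaps deliberately stress the distance-based merge rules: backbone gaps
exceed the 50-kbp split threshold with probability e^(−50/36) ≈ 25%,
so backbone CNVs fragment — as they would on a sparse real backbone —
while hotspot CNVs do not.

The default simulation genome is reduced (3 chromosomes × 30 Mbp,
~10,000 probes, 30 hotspots) so full-cohort experiments run in seconds;
full-scale geometry (135,000 probes, 107 hotspots) is available by
passing hg18-scale chromosome sizes. Default noise is Gaussian:
per-probe sd 0.2 (a conventional aCGH magnitude; the true platform noise
is data-set specific and is exposed in config) plus a per-sample
whole-genome baseline offset (sd 0.05) modelling reference/dye effects.
The simulator models neither GC/dye waves, probe-specific affinity,
mosaicism nor homozygous losses, and does not simulate sex chromosomes
by default; passing tests therefore demonstrate correctness of the
calling logic under idealized independent Gaussian noise, not
performance on real hybridizations.

`simulate_cohort` draws each sample's carrier status independently per
CNV spec at that spec's carrier frequency and returns the exact truth.
A probe counts as inside a CNV if its interval overlaps the CNV
interval; overlapping truth CNVs of opposite sign in one sample are an
error, and for same-sign overlap the first covering spec's shift
applies. `place_cnvs_in_hotspots` assigns size-specified CNVs to unused
hotspot regions, spreading across chromosomes (least-loaded first): if
embedded CNVs are allowed to stack on one desk-scale chromosome they
cover a large fraction of its probes, and per-chromosome z-scoring then
absorbs part of the signal (mean shifts toward the CNV, sd inflates).
This is a real property of chromosome-wise standardization that the
desk-scale genome amplifies; at full scale a CNV covers a negligible
probe fraction.

## Calling

**Normalization.** Per chromosome, z = (x − mean)/sd with the sample
standard deviation (n − 1). Chromosomes with < 2 probes or zero variance
are an error naming the chromosome. After the transform every
chromosome has mean 0 and sd 1 to 1e-9, and any whole-sample baseline
shift cancels up to float rounding.

**HMM.** Three states (decreased/normal/increased), Gaussian emissions
in z units, homogeneous transitions. Parameters are not derivable from
first principles and are fixed defaults, all exposed in config: state
means (−2.5, 0, +2.0) reflect that a heterozygous deletion at noise sd
0.2–0.4 lands near z = −2.5 to −5 while duplications are attenuated
(+0.585 shift); unit emission sds; shared self-transition 0.999 with the
off-diagonal mass split evenly; normal-heavy initial distribution
(0.998/0.001/0.001). Decoding is Viterbi (single best path) — the
standard reading of per-probe state assignment — computed entirely in
log space (no underflow for |z| ≤ 50); ties break toward normal, then
decreased, implemented by scanning states in that preference order with
strict improvement. The transition matrix is genomic-distance-
independent on purpose: all distance handling lives in the explicit
post-hoc merge rules, keeping them isolated and testable. A sticky
chain has a boundary effect worth knowing: at a chromosome edge a
non-normal run can absorb one or two weak trailing probes, because
returning to normal costs a switch (ln 0.0005 ≈ −7.6) that emitting
≤ 2 z≈0 probes from the non-normal state (≈ −3.1 each) does not repay.

**Merging.** Stage one scans each chromosome's decoded path for maximal
runs of identical non-normal state and splits a run wherever consecutive
probe starts are ≥ 50 kbp apart (start-to-start; "less than 50 kbp
apart" merges). Stage two fuses adjacent same-state segments whose
intervening probes number ≤ 5 **and** whose intervening span (bases
strictly between the segments) is ≤ 10 kbp, counting the intervening
probes into the variant and recomputing mean z over all covered probes,
iterated to a fixed point (the operation is idempotent). An alternative
reading of the 50-kbp rule — re-checking internal gaps after fusion —
would be a different operator; the start-to-start reading is
implemented.

**Sex chromosomes.** chrX/chrY are excluded from calling by default: a
single male reference makes chrX ratios track subject sex rather than
CNV state. An `include_sex_chroms` override exists.

## Filtering

Threshold filter: size > 50 kbp (strict), ≥ 5 probes, |mean z| ≥ 1.5.
The size cuts are strict inequalities as printed in the conventions they
encode; the probe-count and z cutoffs are field conventions (such
filters are standard but their exact values are a tuning choice) and
are config-exposed. Large calls are size > 500 kbp (strict). Rarity:
a call's frequency in a catalog is the sum of carrier counts of records
matching at ≥ 50% reciprocal overlap (the standard event-matching
convention) divided by cohort size, capped at 1; a call is kept only if
rare (< 1% by default) in *every* supplied catalog, mirroring dual
reporting against both a large external catalog and a platform-matched
control cohort. All filters are monotone and threshold+rarity commute.
`catalog_from_calls` builds a catalog from a called cohort by greedy
reciprocal-overlap clustering against each cluster's founding interval —
adequate for recurrent hotspot events, coarse for nested/partial
overlaps.

## Burden testing and summaries

A cohort member is a carrier if it has ≥ 1 call strictly above the size
threshold (each sample counted once); rosters must cover all assayed
samples so zero-call samples count as non-carriers. Fisher's exact test
computes the hypergeometric mass with log-gamma factorials (stable to
cohort sizes ~1e5). One-sided (greater) p is P(X ≥ observed) for
case enrichment; two-sided p sums outcome probabilities ≤ the observed
outcome's (with the usual 1+1e-7 relative slack against float ties);
degenerate margins return p = 1 with a flag; the odds ratio is the
sample ad/bc (infinite when bc = 0). Published burden p-values do not
always state sidedness: for the carrier table 6/113 vs 6/306 the
one-sided value is 0.0727 and the two-sided 0.0944, so a printed
"0.072" corresponds to the one-sided test (truncated at the third
decimal); both are always reported. Summary percentages round half-up
to one decimal and render exact 0 and 100 without a decimal.

## Problem sizes and determinism

Every stochastic component is a pure function of its spec and an
explicit integer seed; identical config + seed reproduces outputs
byte-for-byte (provenance headers carry version, seed and key
parameters and no timestamps). The test suite and the acceptance script
use the desk-scale genome (~10,000 probes, 20-sample cohorts, 20-probe
embedded CNVs at |shift|/noise ≥ 3 — noise sd 0.15 so the duplication
shift +0.585 clears the ratio), chosen so the full suite runs in tens
of seconds while leaving each stage's behavior measurable. Fisher and
Viterbi implementations are verified against exhaustive enumeration
oracles (all 3^n paths for n ≤ 8; the full hypergeometric support for
N ≤ 60) and cross-checked against scipy.

## Known limitations

- Call boundaries are probe-supported spans; true breakpoints inside
  flanking segmental duplications (outside probe coverage) are not
  extended, so sizes underestimate events whose breakpoints lie in
  untiled repeats.
- Per-chromosome z-scoring assumes CNVs cover a small fraction of each
  chromosome's probes; very large events (or small simulated
  chromosomes) attenuate their own signal.
- HMM parameters are fixed, not re-fit per sample (no Baum–Welch); a
  platform with very different noise needs re-configured state means.
- The simulator's independent-Gaussian noise omits spatial artifacts
  (waves, dye bias), so simulated recovery rates are upper bounds on
  real-array performance.
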
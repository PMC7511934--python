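# Methods

This note records the models and procedures capcraft implements, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Coordinates and file dialects

All in-memory coordinates are 0-based half-open. BED output is native.
UCSC-style gene tables (`txStart`/`txEnd`) are consumed as 0-based half-open.
The rmap and baitmap design files are emitted 1-based inclusive, the dialect
the established interaction-calling ecosystem expects; reading them converts
back, and write→read round-trips are bit-exact (tested).

## Digestion and promoter windows

Cut positions are the first base of each recognition-site occurrence
(DpnII cuts `^GATC`); overhang chemistry is irrelevant to an in-silico map
and is ignored. Overlapping site occurrences all cut; `N` never matches.
Fragment boundaries are `{0} ∪ cuts ∪ {length}` with zero-length fragments
suppressed, so fragments tile each chromosome exactly (a tested invariant,
together with re-digestion stability).

Promoter windows are strand-aware: TSS = `txStart` (+) or `txEnd` (−),
window = 1,000 bp away from the gene plus 500 bp into it, clipped at
chromosome edges. One window per input row; TSS deduplication (transcript
vs gene level) is deliberately left to the caller, since annotation
granularity is a data-preparation decision.

## Probe selection

Fragments overlapping a promoter window are ranked by overlap length
(ties: leftmost first, for determinism). Both ends of each fragment are
tried until at least two probes accumulate (a configurable target);
probes accumulate **across** fragments — the alternative reading (two probes
must come from a single fragment) would leave promoters whose best fragment
has one usable end under-covered for no benefit.

The 40-bp end rule is read as: the probe's **outer** end lies within 40 bp of
the targeted fragment end. The literal both-ends reading is geometrically
impossible for a 140-bp probe on a ≥ 300-bp fragment. The search scans
offsets 0..40 inward in ascending order and takes the first window passing
the GC ([0.25, 0.65], bounds inclusive — "no less/no more than" is
inclusive) and repeat (≤ 30 masked bases) rules; anchoring as close to the
fragment end as possible maximises the chance that a sequenced read pair
spans a ligation junction. Repeat content comes from FASTA soft masking by
default; an explicit RepeatMasker-style interval list overrides it. A
fragment end is never given a second probe, including across promoters that
share fragments; the losing promoter's failure is tallied
(`fragment_end_already_used`).

Probe sequences are reported on the forward strand: dsDNA probes hybridise
either strand. Synthesis oligos are `5'-adapter + probe + 3'-adapter`
(15 + 140 + 15 = 170 nt); each 21-nt PCR primer extends its adapter by 6 nt,
so the amplified dsDNA probe is 182 bp.

## Binning, baits and chinput

Bins are fixed 2-kb tiles (final partial bin kept). A bin is probe-bearing
if a probe overlaps it by ≥ 1 bp (a probe straddling a boundary targets both
bins); maximal runs of adjacent probe-bearing bins merge into one bait,
named by the promoters of its probes.

Anchors are assigned to bins by their mapped position (fragment-midpoint
assignment would require the fragment map at counting time and changes
nothing at 2-kb resolution). Duplicates are identical anchor-coordinate
pairs after canonical ordering, strand-insensitive — the natural definition
when upstream read-level deduplication is out of scope. Bait–bait products
produce one row per bait anchor (two rows), mirroring the established
chinput convention; library-level "reads falling in baits" QC counts each
product once, so the two notions are kept in separate code paths.
Distances are signed midpoint differences (other end − bait); trans rows
carry NA.

## The PIR-calling background

The full established caller builds a two-component convolution background
(Brownian + technical noise) with distance-dependent p-value reweighting.
capcraft deliberately does **not** reimplement it; the stand-in keeps the
printed decision semantics — a `−log10` score with threshold 5, non-bait
other ends only, a 1-Mb distance filter — behind a pluggable interface
(`attach_external_scores`) so scores from an external caller can be dropped
in. Within the stand-in:

* Strata: 20 log-spaced distance bins from the smallest candidate distance
  to 1 Mb. The candidate universe is every cis (bait, bin) pair in range;
  unobserved pairs count as zeros.
* Per-bait scaling: baits are captured with different efficiencies, so the
  expected count for a pair is `s_bait × μ(d)` with
  `s_bait = (bait's count rate) / (global rate)`, clipped to [0.05, 20].
* μ(d): per-stratum mean of scale-normalised counts, smoothed by isotonic
  regression (monotone non-increasing, weighted by candidate counts), then
  log-log interpolated between stratum midpoints when evaluated — a step
  function would under-estimate the mean at the near edge of each stratum
  and mis-calibrate the tail test there.
* Dispersion: one pooled negative-binomial α from per-stratum moments of
  scale-normalised counts, combined by the **median** across strata so a few
  loop-rich strata cannot inflate it; α is floored at 0 (Poisson).
* Score: `−log10 P(X ≥ N)` under NB(μ, α) (Poisson when α ≈ 0), capped at
  350 where the tail underflows.

The threshold comparison is `score ≥ 5` (configurable); the source
literature uses "≥ 5" and "higher than 5" interchangeably and both cannot
be honoured at once — at float resolution the choice is immaterial. No
multiple-testing reweighting is applied: the score threshold is the sole
decision rule.

Calibration is tested, not assumed: on a pure-background simulation the
fraction of candidate pairs reaching score 5 must stay within 10× the
nominal 1e-5 tail.

## Loop annotation and statistics

Any ≥ 1-bp overlap between a PIR bin and a feature yields a candidate loop;
duplicates (same bait and element via different PIR bins) collapse to the
first in genomic order, making annotation idempotent. Enrichment draws
`n_sets = 100` random bin sets matching the PIR multiset of bait–bin
distances per stratum (same log-spaced strata as the decay profile;
"distance-matched" is otherwise unspecified), sampling non-bait candidate
pairs without replacement within a stratum and widening a too-small stratum
to its neighbours with a warning. Reported: observed count, mean and s.d.
over the random sets, log2(observed/expected).

TAD boundaries are consumed as points (BED intervals collapse to
midpoints). A loop is inter-TAD iff a boundary lies strictly between its
anchor midpoints; trans loops are excluded. The expected inter-TAD count
re-places each loop's PIR at bait ± distance with equal probability
(positions clipped to the chromosome), 100 repetitions, median reported;
for ≤ 10 loops the test suite checks the median against exhaustive
enumeration of all 2^L orientation assignments.

The CTCF convergence test selects, per anchor, the best-scoring motif
inside the anchor interval; loops lacking a motif on either anchor are
discarded. With anchors in genomic order, a pair is convergent iff the left
motif is `+` and the right is `−`. The null probability is 0.25 — one of
four equiprobable strand configurations — with a one-sided upper tail;
this choice reproduces the published example (42 convergent of 65 pairs →
p = 1.906e-11) while a 0.5 null does not, and it is configurable. The
implementation is cross-checked against a log-space brute-force tail
summation up to n = 1,000.

## Downsampling

Subsampling operates on the multiset of unique ligation products: each
bait's rows are a count vector, and a level-`t` draw is a multivariate
hypergeometric sample (uniform, without replacement) summing to exactly
`t`. Presets: `blood` (per-replicate start 10,000, 29 rounds of −333;
3 replicates × 333 = 999 ≈ the 1,000-step combined description — a
1-in-1,000 discrepancy the per-replicate form resolves), `hela` (start
15,000, step 1,000 — the step is not specified by the source protocol and
is a package default), `chesi` (combined start 20,000 down to 1,000).

Bait selection requires coverage **strictly above** the threshold in every
replicate (the default threshold is the schedule start); random subsets are
seeded, and the three repetitions sample independently (overlapping subsets
allowed). The standard pool is the (bait, element) intersection of loops
called on the full data and on the start-level downsample — loops gained by
subsampling are apparent false positives and are excluded. Retention per
level and loop class is `|calls ∩ pool| / |pool|`. One master seed spawns
per-repetition, per-level, per-replicate generators (`numpy.random.
SeedSequence`), so any round is reproducible in isolation.

## The synthetic scenario

Defaults (all configurable on `SyntheticScenario`): two 2-Mb chromosomes of
uniform random sequence (natural GATC spacing ~256 bp; extra sites are
planted only if a denser target spacing is requested); 5% of the genome
soft-masked in ~400-bp stretches; 50 promoters on a jittered 25-kb grid,
100 kb from chromosome edges; TAD boundaries every 250 kb; 40 planted
promoter–enhancer and 30 promoter–CTCF loops at 50–300 kb plus background
enhancer/CTCF/DHS elements; contact decay `P(d) ∝ (d + d0)^(−α)` with
α = 1 and d0 = 5 kb (standard polymer-contact phenomenology; the offset
prevents divergence at d → 0); 10% trans contacts; 10,000 products per
promoter (the coverage regime the saturation analysis identifies as
sufficient, and the regime the recovery guarantees are stated for); 10-fold
count enrichment at planted loop bins; 10% PCR duplicates; capture
retention `logistic(3 − 3·meanGC)` per bait (GC-dependent efficiency; the
coefficient sign is configurable to emulate either hybridisation-protocol
variant) with a 2% off-target rate. 65% of planted CTCF loops carry
convergent motifs, so the convergence test is exercised in its realistic
regime.

Two deliberate idealisations: cis partners are never drawn from bins within
5 kb of **another** baited promoter (products joining two baits are excluded
from PIR calling anyway, and a partially-baited anchor bin would otherwise
carry concentrated reciprocal signal that no background model without a
technical-noise component can absorb); and each planted element sits fully
inside one 2-kb bin, ≥ 5 kb from every TSS, giving unambiguous ground truth.

What passing tests show — and do not. The generator reproduces the
statistical structure the analyses assume: power-law distance decay,
bait-specific capture efficiency, trans noise, duplicates, planted signal.
It does **not** model read-level artefacts (mapping, di-tag filtering),
restriction-site density biases within bins, chromatin-state-dependent
background, or the reciprocal-signal and technical-noise structure of real
libraries; recall/precision measured here therefore characterise the
implementation, not expected performance on real data.

## Problem sizes

The test suite and the acceptance script run the default scenario (4-Mb
genome, 50 promoters, ~500k products over three replicates), a 50,000-
product decay-recovery simulation, and a 6-level retention schedule
(3,000 → 500 products per bait, 3 repetitions) — sizes chosen so the whole
suite completes in well under a minute per analysis while every statistic
retains enough events to be meaningful.

## Known limitations

* The background model is a stand-in: scores are not comparable numerically
  to the established caller's, only the decision semantics match.
* Per-bait scaling is a single multiplicative factor; real capture bias has
  sequence- and distance-dependent structure.
* `select_covered_baits` top-n mode ranks by the worst experiment, which is
  one of several defensible conventions.
* The promoter-window reader reconstructs the TSS from the window and
  strand, which is only exact for unclipped windows.
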
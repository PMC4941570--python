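# Methods

This note records the model behind each pipeline stage, the defaults and
why they were chosen, what the simulator does and does not emulate, and
the numerical decisions that were genuinely open.

## Sequence identity — one definition everywhere

Every threshold in the pipeline (97% reliability/clustering/cross-
reference, 75% nonspecific, the chimera two-segment score) consumes the
same quantity: `identity = 100 × matches / scored_columns` of a
semi-global pairwise alignment in which terminal gaps are excluded from
the scored columns, internal gaps count as non-match columns, and `N`
matches nothing (including another `N`). The semi-global (free end gap)
policy is required so that a ~250 nt V4 profile fragment contained
exactly in a near-full-length 16S sequence scores 100, and so that reads
slightly longer or shorter than a reference are not penalised at their
ends.

The alignment engine is unit-cost edit-distance alignment (edlib) in
infix mode with the shorter sequence as the query; matches and columns
are read off the alignment path. A minimum-edit path is not guaranteed to
maximise `matches/columns`, but at the divergences this pipeline operates
at (reads within a few percent of their templates, thresholds at 97% and
75%) the two criteria select the same alignments; the choice buys two to
three orders of magnitude in speed over an affine-gap dynamic program in
Python, which the all-against-all reliability stage requires.

Thresholded searches are accelerated losslessly in two ways, both
verified against exhaustive scans in the test suite:

* a bounded-distance screen — identity ≥ *t* implies edit distance
  ≤ `|q|·(1−t)/t`, so candidates are first screened with edlib's banded
  mode and the exact path is computed only for front-runners (the front
  is widened by a distance margin so the exact pass is conclusive);
* a shared-12-mer prescreen (inverted index for the within-run dataset
  search), applied only when the pigeonhole bound
  `|q| − k + 1 − k·d_max ≥ 1` guarantees that no record at or above the
  threshold can be discarded, and only when the database is large enough
  for the index to pay for itself.

Ties in best-hit search are broken by database input order, for
determinism.

## Demultiplexing

Anchors (forward transposase 14 nt, reverse transposase 15 nt, universal
reverse primer 16 nt) are searched ungapped on both strands with ≤3
mismatches; the strand with more anchors found wins (tie → plus). Each
barcode class is predicted to abut its flanking anchor — row barcode
immediately upstream of the forward transposase, plate barcode
immediately after the universal reverse primer, column barcode after the
reverse transposase — which makes the prediction immune to indels
elsewhere in the read. When a class's own anchor is missing, its position
is reconstructed from the construct's global coordinates shifted by the
nearest found anchor; this fallback maximises well recovery at the cost
of some indel sensitivity.

Barcodes are called only as exact (0-mismatch) matches. The whole
oriented read is scanned; the call is the match closest to the predicted
start, and it is *position-consistent* only within ±4 nt of the
prediction (the tolerance absorbs indel drift; config-exposed). Two
distinct barcodes matching inside the window is ambiguous — no call. A
read is assigned only when all three classes are called and consistent;
everything else is unassigned, never guessed. Under this rule a
misassignment requires ≥3 coordinated substitutions inside one barcode
converting it into another valid barcode (the bundled manifest enforces
pairwise Hamming distance ≥3 within a class; validation requires ≥2),
with probability far below one event per run.

Assigned reads are re-oriented to construct plus strand and trimmed to
the 16S insert (forward-transposase end → universal-primer start).
The trim matters: ~70 nt of barcode/anchor overhead would otherwise cap
identity against any clean reference near 95% and silently defeat every
97% threshold downstream. Coverage is computed on the untrimmed read.

## Coverage

`coverage = round(total subread nucleotides / consensus length)`, ties
rounded half away from zero (the rounding direction was unspecified in
the source material for this quantity; half-away-from-zero is recorded
here and in config so it is auditable). Reads below 2× are never
admitted; the low/high accuracy classes split at 10×.

## QC cascade

Order: length → chimera → nonspecific → reliability, each stage seeing
only the survivors of the previous one; a parallel ≥10× coverage filter
is computed for comparison but removes nothing.

* **Length**: discard strictly above 1,600 nt — amplicons that long are
  themselves likely concatemeric/chimeric artifacts.
* **Chimera**: for each read, per-parent boolean match profiles (in read
  coordinates) are computed against candidate references — the top 4 by
  shared 12-mers; every ordered parent pair and crossover point is then
  scored from cumulative sums of those profiles. A read is chimeric when
  the best two-segment identity beats the best single-parent identity by
  ≥2.0 points *and* reaches ≥97%. Scoring both quantities over read
  coordinates (parent insertions ignored) keeps the gain comparable. The
  2-point gain is a decision threshold, config-exposed; the heuristic
  parent search is checked against exhaustive all-pairs search in the
  tests. Crossovers very close to the read ends are undetectable in
  principle (either segment explains almost everything), which is why
  the simulator places crossovers in the middle 60% of the insert.
* **Nonspecific**: discard reads strictly below 75% best identity to the
  curated 16S set — off-target amplification.
* **Reliability**: stage 1 keeps reads ≥97% identical to a curated
  reference (database hit); stage 2, run only on stage-1 misses, keeps
  reads ≥97% identical to any *other* read in the run, self excluded
  (dataset hit) — redundancy across (or within) wells corroborates a
  sequence that no database knows. The rest are error-prone and
  discarded. Same-well reads count as corroboration by default
  (config-exposed), since the rule is "any other sequence within the
  dataset". Coverage plays no role: a 2× read with a database hit is
  kept, which is the point of the filter.

The ledger enforces three conservation identities after every run:
assembled = demultiplexed + non-demultiplexed; usable-before-filtering =
reliable + error-prone; reliable = database hits + dataset hits.

## OTU clustering

Greedy centroid clustering at ≥97% identity, first within each well,
then over well centroids across the collection (redundancy map). Reads
are processed in a fixed total order — coverage descending, then length
descending, then id — so clustering is deterministic under any input
file order; coverage is the abundance surrogate standing in for the
size ordering of conventional greedy clustering pipelines. Each read
joins the first centroid at ≥97% or founds an OTU, so every new centroid
is <97% to all earlier centroids at founding time. No chimera re-check
happens here (already filtered upstream), keeping ledger accounting
single-counted.

## Taxonomy

A word-presence (Bernoulli) naive-Bayes classifier over 8-mers:
`p(w|g) = (m_wg + P_w)/(n_g + 1)` with word prior
`P_w = (n_w + 0.5)/(N + 1)`, where `m_wg` counts genus-g training
sequences containing `w`. The prior also serves as an explicit
*background class*: in each of the 100 bootstrap subsamples (⌊L/k⌋ words
drawn with replacement from the query's words), a genus receives a vote
only if its score beats the background score of the same sample. Without
this null, chance k-mer matches on a sequence unrelated to every genus
can accumulate into a consistently-winning genus and a spuriously
confident call. Confidence at higher ranks is the sum of votes for
genera within that rank's taxon, so it is monotone non-decreasing up the
lineage. A genus is reported only at confidence >0.95; queries shorter
than 8·k are unassigned at zero confidence. The bootstrap generator is
seeded from the run seed and a CRC of the query sequence, so results are
bit-reproducible and independent of call order. `k = 8` and 100
bootstraps are the standard choices for this classifier family; all are
config-exposed.

## Recovery estimation

Profile representatives (short V4-region fragments) are the alignment
queries, scored over their own length inside the near-full-length
collection sequences; pairs at ≥97% are hits. Per compartment, recovery
= Σ relative abundance of profile OTUs with ≥1 hit; an OTU hit by many
collection sequences counts once, so the estimate is monotone in the
collection and bounded by 100%.

## The simulator

The generator's defaults are the study conditions the pipeline is
validated under: 5 plates; 93 sample wells per plate with community
sizes 1–4 (P = 0.45/0.30/0.15/0.10, so just over half of multi-read
wells hold ≥2 members); an H10 positive-control well seeded with a
designated control taxon and empty H11/H12 negative controls; 3–6 reads
per well (≈2,100 reads per run — large enough for the binomial checks on
the 12.3% chimera and 0.14% off-target injection rates while keeping a
full run in tens of seconds on one core); a reference pool of 24 taxa in
8 genera (≥97% within, ≤90% between — in practice random ancestors sit
near 60%); inserts of 1,250–1,450 nt; coverage drawn from 2–40× with
74.7% of mass above 9×; per-base error rates 2.3%/0.7%/0.3% by coverage
class, applied i.i.d. with an 80/20 substitution/indel mix (the mix is a
modelling decision — only aggregate rates are known); chimeras at 12.3%
built from two parents of *different genera* on the same plate with the
crossover uniform in the middle 60% of the insert (within-genus bimeras
are indistinguishable from their parents by any reference-based method,
and a chimera is by definition a fusion of different templates);
off-target random inserts at 0.14%; 2% of reads with one barcode
corrupted in 1–2 positions; ~50% of reads reverse-complemented; subread
totals = coverage × read length ± uniform jitter below 0.4× read length,
so recomputed coverage is exact. All draws come from one seeded
generator; runs are reproducible bit for bit. The bundled manifest uses
the public Nextera transposase sequences, a non-degenerate 16-nt suffix
of the 1492r universal primer, and deterministically generated
distance-checked barcodes.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: 16S sequence conservation (random genera
are far more separable than real ones, so taxonomy accuracy here is an
upper bound); PCR abundance bias and per-well depth structure; quality
scores; raw polymerase reads (the CCS+sidecar interface is the
contract); chimera formation mechanisms beyond clean two-parent single
crossovers; and reference databases with taxa missing from the pool —
on the default runs nearly every read finds a database hit, so the
dataset-hit arm of the reliability filter is exercised by dedicated
tests that withhold taxa from the curated set rather than by the
default simulation.

## Numerical choices and degenerate inputs

Empty wells cluster to empty OTU lists; an empty read set produces valid
empty outputs and an all-zero ledger; an empty reference database is a
configuration error, never silently ignored. Boundary semantics are
strict as specified: ≥97 reliable, >1,600 discarded, <75 discarded,
≥10× high-coverage, >0.95 reported. Barcode-position tolerance ±4 nt;
anchor mismatch budget 3. Chimera candidates top-k = 4. All thresholds
live in `PipelineConfig`, which fully serialises a run.

## Problem sizes

The default test and acceptance runs use the 5-plate, ≈2,100-read
configuration above; the brute-force oracles (optimal 97% star
partition, all-pairs chimera search, exhaustive database scans) run on
wells of ≤10 reads, databases of ≤100 records and read subsamples, the
sizes at which exact enumeration is meaningful.

## Known limitations

The chimera score is a two-parent single-crossover model; multi-parent
or near-terminal-crossover chimeras are out of reach (as they are for
reference-based detectors generally). The reliability filter inherits
the curated database's blind spots: a lone, novel, low-coverage organism
in a single well is indistinguishable from an error-prone read. Taxonomy
confidence calibration on real, conserved 16S genera will be less sharp
than on simulated pools. The recovery estimate counts presence, not
abundance, in the collection.
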
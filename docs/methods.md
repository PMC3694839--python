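# Methods

## The measurement

Bisulfite treatment deaminates unmethylated cytidine to uridine; 5-methylcytidine
(m⁵C) resists.  After reverse transcription and sequencing, an unmethylated
reference C is read as T while a methylated one is still read as C.  For every
reference cytosine, in both orientations, the pipeline counts `n` qualifying
reads covering the position and `k` reads in which the C was retained, and
reports

* the **methylation level** `100·k/n` (one decimal place) — an estimate of the
  fraction of transcript molecules methylated at that position (stoichiometry);
* a **p-value** from a two-sided Fisher's exact test of the 2×2 table
  `[[k, n−k], [0, n]]`, i.e. the observed counts against an all-converted
  pseudo-sample of equal depth, under the minimum-likelihood two-sided rule
  (the sum of hypergeometric probabilities no larger than the observed
  table's).  This table construction reproduces published worked examples to
  three significant figures, e.g. (k=7, n=10) → 0.003096 and
  (k=17, n=30) → 6.19e-07, and is fixed; a one-sided variant sits behind a
  flag.  The test itself is delegated to `scipy.stats.fisher_exact`; the test
  suite cross-checks it against an independent hypergeometric enumeration for
  all n ≤ 60.

Sites with `n = 0` are never emitted.  Internally all coordinates are 0-based
half-open; every report is 1-based inclusive.

## Alignment

Reads are mapped with a three-letter strategy so conversion status can never
penalize a placement: the read and the reference are both collapsed (C→T on
the forward conversion, G→A on the reverse) before matching.  Because the
library is non-directional double-stranded cDNA, each read is tried in four
states — {C→T, G→A} × {as sequenced, reverse complement} — against the
matching strand conversion; the winning state fixes the transcript strand on
which conversion states are read out.  Matching uses exact k-mer seeding
(default k = 12, three seed offsets so two mismatches can never eliminate
every seed — the seeds are disjoint for reads ≥ 36 nt) followed by ungapped
extension with at most `max_mismatches` (default 2) mismatches on the
converted alphabet.  Reads failing at full length are trimmed 2 nt from the
3′ end (qualities in lockstep) and retried while their length is ≥ 35 nt; no
attempt is made below the floor.  Reads whose best score is shared by several
placements (multi-copy genes) are assigned uniformly at random to one of
them from a seeded generator, after sorting candidates by reference id and
coordinate so the choice is reproducible.  The aligner is validated against
an exhaustive all-offsets, all-states oracle on small genomes, and emits
minimal SAM; external SAM can be imported, with conversion states rebuilt
against the original reference.

Two reference modes exist.  *Genome* mode converts whole chromosomes, both
strands.  *Transcriptome* mode aligns against one representative per unique
mature tRNA/rRNA sequence, so reads from identical multi-copy genes are not
diluted and intron-containing genomic copies do not shed reads; collapsed
copies keep a membership list so calls can be attributed to every source
gene.

## Artifact filters

1. **PCR duplicates** (genome mode only): reads with an identical full
   sequence string collapse to one representative (first by coordinate, then
   read id).  The filter is off in transcriptome mode, where identical reads
   from highly expressed structural RNAs are genuine coverage.
2. **Conversion failures**: reads with ≥ 3 unconverted cytosines are removed —
   molecules insufficiently exposed to bisulfite leave stretches of
   unconverted Cs.  Unconverted states are counted on the read's resolved
   strand and only at bases passing the quality gate, so a quality-failed
   base cannot mask the molecule-level signal it never contributes to.
3. **Base quality**: only bases with Phred quality > 20 are counted in the
   pileup.

After significance gating (p < 0.01), sites within 10 nt of another site are
discarded — both members of a close pair, since the wording of the rule is
symmetric and clustered calls are a hallmark of local conversion artifacts.
Significant sites sharing an identical 31-nt flanking context
(strand-oriented, site at the center) are collapsed into one call with `n`
and `k` summed and level/p recomputed from the sums; contexts truncated by a
sequence edge are grouped by the available context and flagged.  Calls are
binned at level band edges {10, 20, 50}%, inclusive upward.  The global
conversion rate is computed from the raw alignments before any filtering.

## Motif analysis

The consensus ATCGANGT (RNA: AUCGANGU), anchor C at offset 2, is scanned
over the coding strand of annotated genes; occurrences are deduplicated by
genomic anchor position and kept when the anchor C is covered by ≥ 5 reads
(regardless of p-value).  A coverage threshold of 3 and a degenerate variant
spelling of the pattern are available in configuration.  The control set
contains covered cytosines whose context violates the consensus at all three
constrained offsets (−2 ≠ A, −1 ≠ T, +1 ≠ G), guaranteeing disjointness from
the motif set.  Enrichment is reported as the fraction of sites methylated
above each level cut (10%, 20%) in motif vs control sets — rounded to integer
percent, e.g. 31/75 → 41% — with a two-sided Fisher comparison.  A position
frequency matrix over site flanks yields an IUPAC consensus: a fixed base at
≥ 90% frequency, a two-base degenerate symbol when the top two jointly reach
90%, else N.

## Comparative statistics

Relative position of a site within its gene is `(site − 5′ end)/(length − 1)`,
strand-aware, so both ends are attainable (0 and 1 exactly); the denominator
choice is the package's own, as either convention fits the definition.
Location shifts between two position sets use a Welch two-sample t-test
computed from its defining formulas (means, variances, Welch–Satterthwaite
degrees of freedom).  Level shifts between two site sets use a Mann-Whitney U
test: exact enumeration over all C(na+nb, na) assignments when both samples
are ≤ 8, otherwise the tie-corrected normal approximation with a 0.5
continuity correction.  Both are cross-validated against scipy and a
permutation oracle in the test suite.

## RIP-seq cross-validation

Antibody pulldown of ~100-nt fragments enriches modified RNA with ~100 bp
resolution.  Per-base coverage is profiled over each displayed feature; all
libraries are rescaled so their median over the feature matches the IP
library's median, and coverage is expressed as fold enrichment over that
reference point — a normalization invariant to rescaling any library by a
positive constant (a zero median falls back to the mean with a warning).  A
candidate site is *supported* when the IP fold enrichment within ± 50 nt
exceeds `min_fold` (default 5 — conservative relative to reported 10–35-fold
peaks) while no control library exceeds it.  The analysis is deliberately
descriptive; there is no statistical peak model.

## Synthetic data generator

The generator emulates the study conditions end to end with known truth:

| parameter | default | rationale |
| --- | --- | --- |
| conversion probability per unmethylated C | 0.985 | matches the >98% observed conversion of real libraries |
| whole-molecule failure fraction | 0.02 | small population of under-converted molecules |
| conversion probability inside a failure molecule | 0.2 | stretches of unconverted Cs, the artifact the ≥3-unconverted filter targets |
| read length | 40 nt | matches the sequenced library design |
| sequencing error rate | 0.002/base | typical short-read error |
| PCR duplication rate | 0.05 | moderate library duplication |
| sub-Phred-20 base fraction | 0.02 | exercises the quality gate |
| RIP fragment length | ~N(100, 10) nt | chemical fragmentation to ~100 bp |

Conversion failure is modeled at the molecule level — one low conversion
probability shared by all Cs of the molecule — matching the proposed artifact
mechanism, not independent per-base failure.  Planted m⁵C sites retain their
C with probability equal to the site's stoichiometry, independently per
molecule; motif-embedded sites have the full consensus written on the coding
strand.  Reads are emitted in either cDNA orientation with equal probability
(non-directional library).  Spike templates are ~200 nt, unmethylated, each
embedding one consensus variant (ATCGAGGT / ATCGAAGG) exactly once.  Every
stochastic outcome — failure flags, duplicate provenance, per-C conversion —
is logged to a truth table, so each filter's removal set is exactly
predictable when noise terms are switched off (a property the suite asserts).

What the generator does **not** model: RNA-structure-dependent conversion
resistance, reverse-transcriptase drop-off at bulky modifications, polyA
selection, variable read lengths, or modifications other than m⁵C that also
resist conversion (e.g. N4-methylcytidine).  Passing tests therefore show the
*computational* pipeline recovers what the noise model hides, not that the
chemistry is free of such confounders; distinguishing m⁵C from other
bisulfite-resistant modifications is explicitly out of scope, as is rescuing
sites below 10% stoichiometry, which cannot be separated from artifacts at
these conversion rates.

## Recovery benchmarks and their yardstick

End-to-end recovery is measured on a 50 kb genome at 100× coverage with 20
planted sites at stoichiometries {0.25, 0.5, 0.9, 1.0}.  Sites are scored
against the **realized** methylation fraction — the per-site k/n tallied from
the truth table over unique, non-failure molecules — rather than the nominal
stoichiometry: at 100× coverage the binomial sampling deviation of a
0.5-stoichiometry site is ~5 points by itself, so the realized fraction is
the quantity a perfect pipeline could report, and deviations from it isolate
pipeline-induced error (quality gating, filtering, collapsing).  The nominal
deviation is reported alongside in the acceptance output.

A known limitation surfaces here: with fixed 40-nt reads at 100× coverage,
distinct molecules regularly share an identical sequence, and the duplicate
filter — keyed on the full sequence string — cannot tell them from PCR
duplicates.  Methylated reads at a high-stoichiometry site are less diverse
than the site's minority reads, so collapsing them biases levels at
sub-unity high stoichiometry downward by ~3–5 points.  This is a property of
the method (and the reason the filter is disabled for high-coverage
structural RNA), not of the implementation; the acceptance script reports
the measured error honestly.

## Problem sizes and numerical choices

The shipped benchmarks use a 50 kb genome at 100× (~90k reads) for recovery
and filter metrics, a 5 kb genome and 100 reads for the brute-force aligner
equivalence, ~60k spike reads for the non-conversion check (±0.3-point
resolution at a 0.6% rate), and ~20k RIP fragments per library — sizes chosen
so every property is measured well inside its sampling error.  All
randomness flows from explicit seeds; per-stage independent streams are
spawned from them, so the genome, reads, spikes and RIP libraries are
individually reproducible and a rerun with the same configuration is
byte-identical.  Ties in multi-mapper assignment are broken only among
equal-best placements; mixed-score candidate sets are rejected loudly.
Degenerate cases follow one rule: impossible quantities (level at n = 0,
variance-free t-test) raise errors rather than return sentinels.
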
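# Methods

## Model and procedure

`consite` scores every base of a reference genome for evolutionary
constraint and ranks SpCas9 target sites by that score. The computation has
four stages.

**Conserved-element scan.** Pairwise alignments (AXT) of each query species
against the reference are scanned with reference-anchored sliding windows.
A "W-bp window" always means W consecutive *reference* bases: query
insertions (gaps in the reference row) occupy no reference coordinate and
are skipped, while a reference base aligned to a gap or to/through N counts
as a mismatch — a deliberately conservative identity. Defaults are two
scans, 30 bp with thresholds {0.90, 0.97, 1.00} and 50 bp with
{0.70, 0.90, 0.96, 0.98, 1.00}, and a global floor of 0.70. Within one
(window, threshold) scan, overlapping qualifying windows are merged into
maximal runs; a merged element carries the maximum window identity inside
it. Windows never span two alignment blocks: abutting net blocks are not
stitched, so cross-block conservation is never synthesised. All scans are
pooled by projecting elements onto a per-base matrix with a pointwise
maximum, which makes the final matrix insensitive to the per-scan merge
rule — the reason that rule could be chosen freely.

**Phylogenetic weighting.** Each species' identity row is multiplied by its
patristic distance to the reference leaf (sum of branch lengths on the
connecting path, in substitutions/site). Of the two readings of a
matrix-times-distance-vector normalisation, row-wise multiplication is the
one that gives *more* weight to the same identity in more distant species —
division would do the opposite — so multiplication is used. A global
rescaling of all distances cancels in the final MinMax step, so only
relative distances matter. When no tree is supplied, JC69 distances
d = −(3/4)·ln(1 − 4p̂/3) are estimated from the alignments' mismatch
fraction p̂ (error above the p̂ ≥ 0.75 saturation bound); a supplied tree
always wins over the fallback.

**Score assembly.** With σ the SNP density (fraction of variant positions
in a 20-bp window centred on each base, truncated windows divided by their
actual span) and p the per-site selection score (phyloP CONACC sign
convention), the raw score is

    cs_raw[n] = mean_i(Ĩ[i, n]) · (1 − σ[n])/(1 + σ[n]) · 2^{p[n]}

The mean runs over all *m* configured species with absent alignments
contributing identity 0, keeping scores comparable across positions and
penalising unalignable sequence: no alignment ⇒ no conservation signal.
The SNP factor is 1 at σ = 0, 0 at σ = 1 and strictly decreasing; the
selection factor 2^p is 1 at p = 0 and strictly increasing, so conserved
(CONACC-positive) sites are boosted and accelerated sites damped. Raw
scores are MinMax-scaled per chromosome arm; a constant arm (no contrast)
maps to all zeros with a warning rather than an arbitrary constant.
Genome-wide scaling over the concatenated arms is available behind a flag.

**Target sites.** A site is the canonical 23-bp unit: 20-nt protospacer +
NGG PAM, enumerated on both strands (minus-strand sites appear as CCN… on
the forward sequence). Sites containing N are dropped; sites overlapping
the accessibility mask are *flagged*, not removed — a high score in a
masked region is a warning, not a hidden result. Ranking is by mean scaled
score over the 23 bases, ties by minimum score, then by coordinates, making
the order invariant under input permutation. Percentiles are computed
against the positive-score positions of the arm only. The printed table
uses 1-based inclusive coordinates (a site [s, e) prints as s+1..e, a
23-bp span), the convention used for published Cas9 site coordinates;
internally everything is 0-based half-open, converted only at file
boundaries.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| scan windows | 30, 50 | bp | short window catches short perfect cores, long window tolerates isolated mismatches |
| identity thresholds | 30 bp: 90/97/100%; 50 bp: 70/90/96/98/100% | fraction | ladder of stringencies pooled by max-projection |
| minimum identity | 0.70 | fraction | floor below which "conservation" is noise at these window lengths |
| SNP-density window | 20 | bp | matches the Cas9 site scale; one variant contributes σ = 0.05 across 20 positions |
| scaling domain | arm | — | arms differ in alignability; per-arm scaling keeps 1 meaningful locally |
| site length | 23 (20 + NGG) | bp | canonical SpCas9 protospacer + PAM |

## Synthetic fixtures: what they emulate, what they do not

The generator emulates the *structure* of the real inputs at desk scale:
one 100-kb chromosome arm (default), six query species diverged from the
reference under JC69 at branch lengths 0.05–0.5 substitutions/site
(spanning close congeners to deeply diverged outgroups), three embedded
ultraconserved blocks (600–1000 bp) copied verbatim into every species with
zero SNP rate, population SNPs placed i.i.d. Bernoulli at 2% per base
outside blocks (a deliberately high density evoking a hyperdiverse wild
population), a selection track of +1.5 inside blocks and 0 outside, and a
~5% accessibility mask of 100–400-bp intervals avoiding the blocks. Species
sequences substitute each non-block site independently with probability
p(t) = (3/4)(1 − e^{−4t/3}), so the realised mismatch fraction is an
unbiased estimate of p(t) and JC69 recovery can be asserted within
sampling error. The emitted tree is a star with a zero-length reference
branch, making each species' patristic distance exactly its simulated
branch length (so the tree and JC69 routes agree by construction).

Deliberately absent: rearrangements and indels (alignments are collinear
single blocks — the scan operates within blocks, so synteny modelling adds
no test power), rate heterogeneity and richer substitution models (REV),
linkage and demographic structure in the population variants, and base
composition bias. Passing tests therefore demonstrate the *computation* is
correct and well-calibrated on data satisfying its assumptions; they do not
validate biological conclusions on real genomes, where alignment quality
and model misspecification dominate.

## Numerical choices

- Window qualification uses `count ≥ ceil(threshold·W − 1e−9)`, so 49/50
  qualifies at 0.98 exactly and float representation of thresholds cannot
  flip a boundary case.
- bedGraph writing run-length-encodes every value including zeros; reading
  back with fill 0 is an exact inverse (values printed with `%.17g`).
- Overlapping score-track records: last record wins, with a warning —
  deterministic and detectable.
- VCF: multi-allelic and duplicate records contribute one position; indels
  are excluded by default (`snps_only=True`) since the density track models
  point variation.
- Constant-domain MinMax → all zeros (warned): a flat arm carries no
  evidence of conservation contrast.
- Tie-breaks in ranking end with (chrom, start, strand) so output order is
  a pure function of the input set.
- All fixture randomness flows through `numpy` Generators seeded from the
  single configured seed (per-component substreams), giving byte-identical
  bundles per seed.

## Known limitations

- The scan consumes alignments; it does not produce them. Aligner choice
  and chaining/netting upstream determine what can ever be detected.
- Selection scores are consumed, not computed: the package does not fit
  neutral substitution models or compute likelihood-ratio site statistics.
- The 2^p selection factor is unbounded above; extreme positive scores can
  dominate an arm's scaling. Real CONACC tracks are bounded in practice,
  and MinMax absorbs overall magnitude.
- `percentile_of` and the ranking treat each base/site independently; no
  multiple-testing or spatial correlation correction is attempted.
- JC69 fallback distances are downward-biased when ultraconserved regions
  are included in the estimate (they are part of the alignment), which is
  visible in the recovery tests as a small dilution term at deep branches.
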
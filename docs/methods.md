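# Methods

This note documents the models, parameters, and numerical choices behind
`dualvar`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic diploid genomes

`dualvar.simulate` generates a single random chromosome (default 1 Mb,
uniform base composition) and plants, non-overlapping with ≥ 50 bp
separation:

- **VNTR loci** (default 50): tandem repeats of a random unit (default
  25 bp, 8–16 copies) written into the reference. The first
  `min(n_vntrs, n_svs)` structural variants are realized as whole-unit
  copy-number changes (|Δ| of 2–4 units, i.e. 50–100 bp) anchored at the
  repeat start. These are the loci where alignment ambiguity naturally
  decomposes one allele into several sub-50 bp indels — the failure mode
  the VNTR grouping addresses.
- **Generic SVs**: insertions/deletions of 50–2000 bp (inversions
  available but off by default), 20 % homozygous, the rest heterozygous
  on a random haplotype.
- **Heterozygous SNPs** at 10⁻³ per bp and **small indels** at 2×10⁻⁴ per
  bp (geometric lengths, mean 3, capped at 49 bp).

Variants are kept `max(500, read_len_mean/4)` bp away from the chromosome
ends. This mirrors confident-region benchmarking: coverage necessarily
thins toward sequence ends, and variants placed there would measure the
coverage profile rather than the methods.

Haplotypes are built by applying each variant's allele; the truth VCF is
sorted, left-anchored, and reproduces both haplotypes byte-exactly by
construction (tested).

**Reads.** Lognormal lengths (mean 20 kb, shape 0.4, minimum 1 kb),
clipped-uniform start positions (so coverage stays flat out to the ends;
edge reads are truncated), half of the reads reverse-complemented, total
coverage 30× (15× per haplotype). Errors are injected per base at 1 %
(half substitutions, the rest split between 1 bp insertions and
deletions), with the error probability multiplied by 3 inside
homopolymers ≥ 4 bp — indel errors concentrating in homopolymers is the
salient feature of nanopore data for consensus polishing. The exact true
alignment of every read to the reference is produced by composing the
read-to-fragment error CIGAR with the haplotype-to-reference variant
CIGAR; reads crossing an inversion are emitted as strand-split records.
Reads falling entirely inside an inserted sequence have no reference
placement and are emitted unaligned.

**Methylation.** CpG sites are enumerated on both strands of the
reference inside randomly placed regions (default 200 regions of 2 kb).
Each region draws a baseline from a bimodal prior (~0.1 or ~0.9); in a
configurable fraction of regions one haplotype is shifted by Δ = 0.5
toward the opposite pole. Per-site fractions add Gaussian noise
(SD 0.05, truncated to [0,1]); coverage is Poisson (mean 15). The
methylation layer is simulated in reference coordinates independently of
the variant layer — it exercises the regional summarization and the
differential caller, not coordinate lifting through variants.

All draws come from labelled sub-streams of one seeded generator, so
adding a feature does not shift unrelated draws and identical configs
give byte-identical outputs.

*What this does not emulate:* real base-caller error profiles and quality
strings, mapping ambiguity in segmental duplications, reference bias,
chimeric reads, CpG-island structure, or methylation changes caused by the
variants themselves. Passing the synthetic benchmarks shows the
algorithms are correct under their stated model, not that real-genome
accuracy numbers transfer.

## Read filtering and divergence

Reads are dropped if shorter than 5 kb, aligned over less than 5 kb,
more than 20 % unaligned, or with gap-compressed divergence above 0.09;
rules are applied per read (pooled over its alignment records) in that
order, and each removal is tagged with the first failing rule. The
unaligned-fraction threshold (0.20) is a package choice exposed in
`ReadFilterConfig`; the others are standard long-read QC values.

Divergence is **gap-compressed** — (mismatches + gap opens) / (aligned
columns + gap opens), the aligner `de:` tag convention — not per-column.
Counting indel columns individually would push every read spanning a
≥ 2 kb SV above the 0.09 threshold and silently delete coverage exactly
where SV evidence is needed; gap-compression scores an SV as one event.
For CIGARs using `M` (match-or-mismatch), mismatches are unavailable and
the value is a documented lower bound.

## Dual assembly

Heterozygous SNP candidates need both alleles at frequency ≥ 0.25 and
coverage ≥ 8; columns where a single non-draft base dominates are kept
separately as homozygous draft corrections. Haplotagging is a majority
vote over the phased alleles a read covers; ties and zero-vote reads stay
untagged and are excluded from polishing (conservative: a wrongly included
read harms the consensus more than a missing one).

Polishing is a per-column plurality vote over the haplotype's pileup
(deletion is a votable symbol; insertions at a junction are accepted when
carried by more than half of the covering reads, and the inserted
sequence is a medoid-plus-column-vote consensus of the carried strings,
so long insertions survive read errors). Chunks are nominally 10 kb;
boundaries are shifted off "inconsistent-indel regions" — maximal
intervals where ≥ 2 reads carry ≥ 5 bp indels at coordinates differing by
≥ 10 bp whose 10 bp-padded intervals chain together. Chunks containing
such regions are rebuilt reference-free: read segments spanning the chunk
are extracted by alignment-column projection, a medoid backbone is chosen
by total edit distance, and all segments are column-voted against it.
This keeps VNTR alleles coherent even when the aligner places their
indels inconsistently across reads. Zero-coverage chunks are returned
unchanged and flagged; coordinate maps through complex chunks are
interpolated (exact at chunk boundaries).

Inversion signatures are minority-strand segments of strand-mixed split
reads, clustered within 500 bp; clusters with ≥ 3 supporting reads are
applied (reverse-complemented) to the haplotype(s) of their supporting
reads' tags. Signatures supported only by untagged reads are applied to
both haplotypes — the conservative reading when phase evidence is absent.

## SV calling and VNTR grouping

Variants come from three signal classes: CIGAR operations (X runs, I, D),
junctions between consecutive collinear split-alignment segments of one
contig, and minority-strand segments (inversions). Junction gap pairs are
realigned globally with affine gap scoring (match +1, mismatch −3, gap
open −30, extend −0.1 via Biopython's `PairwiseAligner`) before variant
extraction: with unit edit costs, two unrelated DNA stretches align at
~52 % identity, so a clean insertion-plus-deletion junction would smear
into mismatch runs; cheap gap extension restores the contiguous indel
structure and lets two nearby SVs fused into one junction come apart.
Junctions larger than 8 kb × 8 kb are emitted as single replacement
records instead of realigned.

Grouping replaces all indels of one haplotype anchored inside one VNTR
interval by a single record spanning first-to-last affected base, with
the alt allele built by applying the members to the reference window; a
replacement record (rather than a pure INS or DEL) is used because mixed
indels in one repeat have no faithful single-type representation. The
SVTYPE follows the sign of the net length change; a net-zero group stays
a non-SV indel. The simulator pads emitted VNTR BED intervals by one
repeat unit so left-shifted insertion anchors still fall inside.

Diploid merging pairs same-type calls within 500 bp at size ratio ≥ 0.7
(insertions additionally at sequence similarity ≥ 0.7, computed between
locally reconstructed haplotype windows — substituting each alt into a
shared reference window ± 100 bp — which is invariant to equivalent
representations inside repeats, e.g. cyclic rotations of inserted units).
Remaining single-haplotype calls colliding at (nearly) one anchor are
re-anchored on the union span as multiallelic 1|2.

## Joint phasing

The emission model follows the reference-expansion design: window
expansion 12 bp for small variants, 64 bp for variants whose allele
length difference reaches 50 bp; read subsequences are selected by
projecting alignment columns into the window, and reads that do not span
the full window contribute nothing at that locus (scoring a truncated
read against full-length alleles would bias toward shorter alleles).
Likelihoods are `eps^d (1−eps)^(L−d)`; the default `eps` = 0.10 reflects
~90 % read identity and is exposed in `PhasingConfig` (newer chemistries
warrant ~0.01).

The phasing objective is the exact read log-likelihood of a two-haplotype
partition, `Σ_r log(0.5 Π p(hap1) + 0.5 Π p(hap2))`. Search: linkage
components are formed over pairs sharing ≥ 2 reads; each component is
initialized by orienting a maximum spanning forest of pairwise cis/trans
log-odds and refined by best-improvement hill climbing over single-site
flips and suffix flips (suffix flips capture switch-type errors cheaply);
components of ≤ 30 sites additionally try paired flips and 8 seeded
random restarts, which removed every residual local-optimum failure in
6000 randomized trials against exhaustive enumeration. Cross-component
read couplings (below the linkage threshold) are deliberately ignored —
that is what splitting into phase sets means. Output is canonicalized
(first site of each set lists its smaller allele first; PS = position of
the component's first site), making results deterministic.

## Methylation

Strand collapsing merges the + site at p with the − site at p+1,
coverage-weighted, conserving methylated-read mass. Regional summaries
use sites with coverage ≥ 5 on both haplotypes (the read threshold used
for methylation concordance checks) and drop regions with fewer than 5
usable CpGs. The differential call flags |Δ| more than 3 robust
deviations above the median |Δ|. The deviation scale is 1.4826 × MAD of
Δ around its median (or the SD of Δ with `scale="sd"`). Estimating the
scale from Δ itself, rather than from the folded |Δ|, is what keeps the
test calibrated: the MAD of a folded Gaussian is small relative to its
tail, and a |Δ|-based scale flags ~1.4 % of null regions at z > 3,
whereas the Δ-based scale flags ≲ 0.1 % while leaving power at Δ = 0.5
unchanged (precision and recall 1.0 in the seeded benchmark). A scale
floor of 10⁻³ keeps the degenerate all-identical case from flagging
everything.

## Evaluation

SV matching requires same chromosome and type class, anchor distance
≤ 2000 bp, size ratio ≥ 0.7, and (insertions) sequence similarity ≥ 0.7;
assignment is greedy one-to-one by combined distance+size score with
deterministic tie-breaks. This keeps the headline semantics of
established SV benchmarking (the distance bound, size ratio and sequence
similarity) without replicating a specific tool's full scoring. The 10 %
catalog overlap rule is read as reciprocal overlap for span variants;
insertions, spanless on the reference, match by anchor distance and size
ratio — both choices are configurable. Small-variant comparison is exact
normalized-allele plus unordered-genotype matching within confident
regions; this is stricter than haplotype-aware comparison and may
undercount matches at complex loci where equivalent representations
differ.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 1 Mb /
30× (about half a minute), consensus checks at 300 kb, the methylation
benchmarks on 1000 regions over 3 Mb, and the oracles on 200–500
randomized instances each — sizes chosen so the whole validation runs in
minutes on one CPU while every property is still measured on hundreds of
independent events.

## Known limitations

- The polisher is a plurality-vote consensus, not a maximum-likelihood
  polisher; it is exact on clean data and corrects 1 % read error fully
  at 15× per haplotype, but has no explicit error model.
- Only inversions are handled among balanced rearrangements; duplications
  and translocations are out of scope.
- Multi-chromosome genomes are supported by the formats and metrics, but
  the simulator emits a single chromosome.
- The methylation layer is positioned on the reference; haplotype-specific
  coordinates (e.g. CpGs created or destroyed by variants) are not
  modelled.
- Breakend (BND) notation and gVCF are not supported.
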
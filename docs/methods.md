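# Methods

This note documents the models and procedures implemented in `redc`,
the parameters that matter, the design choices made where the procedure
admitted more than one reading, and what the synthetic validation does
and does not establish.

## Chimera model and read demultiplexing

A library molecule is `DNA—bridge—RNA`: an NlaIII-digested, MmeI-trimmed
DNA fragment ligated through a 37-nt biotinylated bridge adapter
(`AGTCGGAGCGTTGCCTATCGCATTGATGGTGCTAGGA` in forward-read orientation) to
the 3' end of an RNA, reverse-transcribed with a template switch that
prepends `GGG` to the RNA 5' end on the reverse read.  The forward read
therefore carries the DNA part, the bridge, and the RNA read *from its
3' end* (reverse-complemented); the reverse read carries `GGG` and the
RNA read from its 5' end.  When the RNA fragment is shorter than the
remaining cycles, both mates read through into adapter sequence.

Parsing parameters (all exposed on `redc parse`):

| parameter | default | meaning |
|---|---|---|
| dedup key length | 50 nt | both mates cut to 50 nt; exact-duplicate groups keep the first pair |
| quality window / threshold | 5 / Q26 | leftmost window with mean < threshold truncates parts; a mate with zero passing bases rejects the pair |
| bridge mismatches | ≤ 1 | substitutions only; the terminal `GA` (protected suffix) must match exactly; N counts as mismatch |
| probe length | 14 nt | switch-oligo probe `CCCAGATCGGAAGA`, mate bridge probe `TCCTAGCACCATCA`, complementarity probes |

Decisions taken where the procedure was open:

* **Oligo scanning is substitution-only** (Hamming); indels are not
  modelled.  Scanning runs on full-length reads; the quality position is
  applied afterwards as a right-truncation inside each extracted part.
* **Multiple complete-bridge hits**: the leftmost is used.
* **Complementarity trimming keeps the matched region.**  To remove
  sub-probe-length read-through stubs, the 14 nt adjoining the landmark
  in the mate are reverse-complemented and located in the read; the cut
  is placed at the *end* of the rightmost exact occurrence, removing
  only what lies beyond it.  This is the only reading consistent with
  exact part recovery: the complementary region *is* genuine RNA (it is
  the mate's view of the same fragment), and trimming it would truncate
  every fully-read RNA fragment by 14 nt.  Partial (< 14 nt) end-anchored
  matches are deliberately not trimmed — a chance ≥ 4-nt suffix
  coincidence would otherwise clip real RNA in roughly 0.4% of reads.
* Zero-length parts are representable but never written to part files.

## Contact filters

All coordinates are 0-based half-open; the single-bp position of the
RNA 3' end (bridge-adjoining) and 5' end (GGG-adjoining) is the part's
first sequenced base: the lower coordinate of the first alignment block
on `+`, `end − 1` of the last block on `−`.  The DNA anchor used for
chromatin-state lookup and background normalization is the midpoint of
the mapped (CATG-supplemented) DNA interval.

The three per-contact predicates — pairing (same chromosome, opposite
strands, lower-coordinate distance ≤ 10 kb), restriction-site exclusion
and chromatin retention (states 1–13) — are pure functions of one
contact and therefore commute; the pipeline applies them in that order
but order is verified immaterial by test.

The restriction-site rule excludes RNA ends inside any genomic `CATG`
± 1 bp.  "MmeI digestion site" is ambiguous, so two modes exist:
`cutsite` (default) excludes 5' ends 17–22 bp downstream of a `TCCRAC`
recognition sequence in the enzyme's cutting direction on either strand;
`recognition` excludes the recognition sequence ± 1 bp.

## Annotation

Gene assignment is two-pass: pass 1 counts, for every gene, all
strand-compatible (antisense) intersecting RNA 3' parts — a part
overlapping several genes counts once per gene — and forms the coverage
density count/length; pass 2 assigns each part to its densest candidate
(ties: shorter gene, then lexicographic id).  For spliced parts only the
bridge-adjoining block intersects.  This keeps abundant small RNAs
(snRNA-class genes nested in hosts) from being swallowed by their hosts.

X-RNA discovery chains unassigned parts per strand while the gap between
consecutive parts (end-to-start; 0 if overlapping) is ≤ 100 bp, keeps
chains of ≥ 100 parts, discards a chain when a gene within 100 bp of
either boundary carries more assigned parts than the chain (both flanks
tested), and merges surviving same-strand chains closer than 1 kb.
Cluster bounds are the min start / max end of member parts.  Increasing
the merge distance can only decrease the cluster count (tested).

Every chromatin-state interval of states 4–7 is an individual enhancer;
parts on either strand are assigned to it independently of gene
assignment (double counting is intentional), and enhancers with ≥ 100
parts form the reported eRNA set.  A part touching two adjacent
enhancers goes to the larger overlap.

## Background, normalization, enrichment

The ligation background at 500-bp bins sums DNA anchors of contacts
whose source RNA is protein-coding and encoded on a different
chromosome, smoothed per chromosome with a Gaussian of σ = 10 bins
(5 kb; the kernel width is a package choice — only the kernel family is
prescribed), reflected at ends and rescaled to preserve mass exactly.
Weights are `1/(B + p)` with pseudocount `p = 0.1 × min nonzero B`,
rescaled so Σ weights = Σ raw contacts; a constant background yields
unit weights to machine precision, and conservation holds to 1e-9
relative everywhere.

Contact frequencies divide summed weights by the *analysable* length of
a region: segments in states 14/15 or outside the annotation are
subtracted from the denominator and their anchors discarded.  With a
chromatin-type filter the denominator is the type's total length in the
region.

Fold-enrichment profiles use raw counts (the bin-level background is
built and mean-normalized inside the procedure): RNA signal / own mean,
background / own mean then 10-bin moving average, per-bin ratio, mask
below fold 2, require ≥ 3 enriched bins in the centered 11-bin window,
final 10-bin moving average.  Moving averages are centered with left
bias (−5..+4), truncated at chromosome ends, and means (scale-free in a
ratio).  The mean over "all bins" includes empty bins of annotated
chromosomes.  Two consequences worth knowing: (i) the double
mean-normalization deflates a planted fold-f block of k bins on an
N-bin genome to `f·N/(N + k(f−1))` (≈ 3.8 for f = 4, k = 10, N = 600),
which is inherent to the procedure; (ii) recovered fold is measured on
the masked ratio *before* the final smoothing, because that smoothing
deliberately bleeds peak edges toward masked neighbours.

## Genomic-distribution ranking

Intervals per gene: G (body), S (0–50 kb flanks), M (50–500 kb),
SM = S∪M, L (0.5–5 Mb), R (> 5 Mb cis), T (other chromosomes), clipped
to chromosome bounds and mutually disjoint.  Eligible RNAs have ≥ 500
contacts and ≥ 1 raw contact in each of L, R, T.  Ratios SM/L, L/R, R/T
are computed on frequencies (zero numerators/denominators surviving
eligibility are floored at half the RNA's minimal positive frequency),
log-transformed and z-scored within contact-count strata (500–1500,
1500–10 000, > 10 000; strata with < 5 RNAs are refused with a warning),
pooled, and cut into five equal-count quantiles with quantile 1 holding
the *lowest* values.  The orientation is forced by group C
("distributed throughout the genome"): a genome-uniform RNA has all
three ratios near 1, the low end of each scale, so C = Q1/Q1/Q1,
B (chromosome-wide) = Q1/Q1/Q5 and A (proximal ± 5 Mb plateau) =
Q1/Q5/Q5.  The z-transform is on log ratios (the raw ratios are heavily
right-skewed); since the transform is monotone within a stratum, only
the stratum pooling depends on it.

Because every group requires first-quantile SM/L membership, archetyped
RNAs can only be grouped when embedded in a realistic cohort whose bulk
(ordinary mRNAs with steep proximal decay, SM/L ≫ 1) fills the upper
quantiles.  The validation cohort therefore contains 100 RNAs per
archetype plus 1200 decay-profile filler RNAs, mirroring the
composition of a real library.

## Transcription dynamics

Part classes derive from the 5'-end and 3'-end positions against the
gene model: same exon, same intron, exon–adjacent-intron (either order
along transcription), or consecutive exons with a reported splice
junction (> 1 alignment block).  Everything else — including ends
outside the gene span — is unclassified.  Gene-body bins (12) are
assigned from the 3'-end position, reversed for minus-strand genes.

Metagene profiles use 24 bins of identical length gene_length/12 —
6 upstream flank, 12 body, 6 downstream flank — over protein-coding
genes with ≥ 1 contact in the gene ± half-gene flanks, averaged
position-wise and scaled to max 1 (strand-mirrored; verified invariant).

Directional asymmetry takes the transcription site of a part as its
3'-end position, bins DNA-anchor offsets into distance bands
(0–10, 10–50, 50–100, 100–500 kb by default) and reports the
downstream/upstream weight ratio, folded by transcript strand when
oriented.  Scaling curves use 100-kb bins, sources restricted to
occupied bins, zeros counted, means taken over bin pairs of equal cis
separation and normalized by the total pair count including trans; the
bin-pair count is non-increasing with distance for separations ≥ 1 bin
(distance 0 has one self-pair per source where distance 1 has up to
two neighbours).

## Synthetic data: what it emulates and what it does not

The sequence-level simulator draws i.i.d. uniform ACGT genomes (three
chromosomes, 1–1.5 Mb by default), places non-overlapping 2–6-exon
genes, tiles chromatin states 1–15 (5% repetitive, 2% unannotated), and
emits contacts whose DNA parts end at genomic CATG sites with the
experimentally observed length pattern ({18: 0.05, 19: 0.40, 20: 0.55}
— the cutter's 60/40 preference at 20/21 bp shifted 1 bp by the bridge,
with a few percent shorter) and whose RNA fragments (20–40 nt, 10%
junction-spanning) avoid the restriction-site exclusion zones — i.e.
the generator plants the *detectable* contact population, so pipeline
recovery isolates algorithmic loss from the designed filter loss.
Template-switch artifacts pair RNA 3'/5' fragments from different
chromosomes; duplicates are exact copies; RNase mode emits 1–3-nt
purine RNA stubs; ligase-minus mode emits 0–1-nt DNA parts.  Reads are
constant-length Q37 with optional uniform substitution errors.

Coordinate-level scenario builders plant archetype contact
distributions, X-RNA clusters with gene-tail and sub-threshold decoys,
enrichment blocks/spikes over a trans background, co-transcriptional
metagene geometry (first-exon parts travel to the TES, first-intron
parts stay in their bin), a downstream drag factor of 1.5 within
100 kb, and power-law cis decay P(s) ∝ s⁻¹ between 0.2 and 10 Mb with
interior sources so bin-pair counts stay flat over the fitted range.

Not emulated: sequencing indels and quality-dependent errors, PCR bias
beyond flat duplication, real base composition and repeats (so mapping
uniqueness is far easier than on a real genome), isoform diversity
(one transcript per gene), and chromatin-state correlation with genes.
Passing tests therefore demonstrate correctness of the computations and
filters under the stated models, not robustness to real-library noise
or alignment ambiguity.  Alignment itself is out of scope: the bundled
exact mapper (14-mer seed + verification, splice-aware via annotated
junction windows, zero mismatches) is a test oracle standing in for an
external spliced aligner.

## Problem sizes used in validation

Parser/end-to-end runs use 10 000 contacts (plus 2% template-switch
artifacts and 5% duplicates); control modes 500; X-RNA discovery plants
20 transcripts of 110–150 parts with 5 gene-tail decoys and one 99-part
decoy; enrichment uses 120 000 background and 10 000 RNA contacts on a
600-bin genome; classification 1500 RNAs at 700–1400 contacts each;
asymmetry 30 000 contacts; scaling 200 000 pairs.  These sizes put
simple binomial noise well inside every stated tolerance while keeping
the whole validation under a minute.
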
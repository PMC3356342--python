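# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reading was defensible.

## Coordinates and formats

All on-disk formats and public dataclasses use 1-based inclusive
coordinates (GFF3 convention). Internal arithmetic is 0-based half-open;
the conversion lives in exactly one pair of functions
(`core_model.to_slice` / `from_slice`) and is covered by a symmetry
test. BED input is converted to 1-based inclusive at read time. FASTA
input is uppercased and U is mapped to T, so one canonical alphabet
{A,C,G,T,N} holds everywhere downstream. GFF3 handling is flat (one
feature per line, gene-style features only); multi-level gene/mRNA/CDS
hierarchies are out of scope.

Similarity hits arrive as 12-column tabular output. Multiple HSP rows
per (query, subject) pair are aggregated by the reader: e-value is the
minimum over HSPs and `hsp_total_length` the sum of alignment lengths.
The tabular dialect carries no sequence lengths, so the reader accepts
an optional lengths side table; coverage is `hsp_total_length` over the
**shorter** of the two sequences — the symmetric choice standard in
ortholog calling.

## Gene-model consensus

Candidate models must span fewer than 10 consecutive Ns and encode at
least 60 aa (≥ 180 nt). "Common" genes are models identical in contig,
strand, start and end — the strictest reading of agreement on strand
direction and transcriptional initiation/termination sites. Remaining
single-predictor models survive unless they partially overlap a
same-strand model from the other predictor with a higher
annotation-accuracy class; ties go to the longer model, then to
predictor A, making the output deterministic.

The four accuracy classes are monotone in homology evidence:
*conserved* (best e ≤ 1e-10), *slightly conserved* (1e-10 < e ≤ 1e-5),
*hypothetical* (no qualifying hit, both predictors agree), *predicted*
(no hit, single predictor). Only the two e-value anchors are
published; the band structure between them is this package's choice.

## Frame-shift artifacts

An *interrupted* pair is two same-contig, same-strand genes sharing a
best-homolog subject, whose intergenic gap (stop-of-upstream to
start-of-downstream, exclusive) is under 600 bp, and whose mutual
e-value exceeds 1e-5 (or which have no mutual hit): two halves of one
protein do not align to each other, which separates a split gene from a
genuine tandem paralog pair. An *overlapping* pair shares a best
homolog and intersects. Rates are reported over homolog-bearing genes
— the only genes the detector can see, since it is defined on shared
best homologs.

## Protein families

Edges require e ≤ 1e-20 in either direction and coverage strictly
above 50%. A family seed is a true 3-clique (all three pairwise edges);
a two-edge "triangle" is a star and over-merges, so it does not count.
Clusters sharing **≥ 2** members are merged iteratively to a fixpoint
("shared 2" is read as at-least-2). The fixpoint is computed by
union-find over cluster ids with a registry of member pairs; the result
provably equals naive repeated merging and is order-invariant, which
the suite checks against a brute-force oracle on 100 random graphs and
20 edge-order shuffles.

## Tag mapping

The contract: a 50-bp tag is split into 5′ and 3′ 25-bp halves;
placement is decided by the 5′ half with at most two substitutions and
no indels; acceptance requires exactly one candidate locus genome-wide;
the 3′ half's contiguous agreement is recorded but not required (its
role in the original vendor pipeline is unstated, so it does not gate
acceptance here). Multi-mapped tags are dropped entirely, never placed
randomly. Candidate enumeration seeds on three exact sub-seeds of the
5′ half (8 + 9 + 8 bp): two mismatches cannot hit all three seeds, so
enumeration is complete — note that *two* exact halves would not
suffice, since two mismatches can hit one half each. Candidates require
the full 50-bp footprint inside a contig. Equivalence with an
exhaustive scan of every offset is property-tested on 10⁴ reads.

Alignments report the leftmost footprint base. A tag is assigned to the
gene whose span contains that base — sense if strands agree, antisense
otherwise; same-strand genes take precedence when both strands overlap,
and assignment is by start position rather than fractional overlap
(with 50-bp tags against ≥ 180-bp genes the boundary effect is
negligible). rRNA filtering removes alignments starting inside an rRNA
interval before counting.

## Normalization, HEGs, fold changes

The per-sample upper quartile is the 75th percentile of sense counts
over genes that are nonzero in at least one sample; all-zero genes are
excluded from the quartile but still reported (normalized value 0).
Percentiles use linear interpolation between order statistics — the
numpy/pandas default — fixed explicitly because the convention is
material at a few hundred genes. Antisense counts share the sample's
sense-derived quartile: one per-sample factor is the only choice that
keeps sense and antisense values comparable on a single scale.

HEG status is strict: uq value > 10. Pathway reporting is strict:
fraction of HEG members > 0.10. Cross-phase fold changes are ratios of
normalized values; within-phase antisense:sense comparisons are ratios
of raw tag counts — mirroring which numbers each kind of published
ratio was formed from. Ratios are computed from full-precision values;
a ratio of the rounded table values 81.83/0.88 gives 93.0, and the
package never asserts the alternative printed figure.

## Transcript discovery

"Significant expression" is per-base depth ≥ `min_expressed_depth`
(default 2) on one strand, with no bridging across sub-threshold bases;
runs longer than 180 bp are kept. Classification: ≥ 1 bp overlap with a
same-strand gene → genic_sense (precedence, conservative against false
antisense); overlap only with opposite-strand genes → antisense; no
overlap → intergenic. The "non-coding" tally is intergenic + antisense.
Genome expression coverage counts the two strands separately against
single-strand length, so its ceiling is 200%. The antisense report
flags a gene when sense expression falls and antisense rises between
the two phases while an antisense contig overlaps it.

## Synthetic data: what it emulates, and what it does not

The generator emulates: an intronless yeast-like genome at 45 ± 2% GC
(non-coding GC is solved for after coding sequence is generated);
ATG…stop genes, multiples of 3, 60–120 codons, on both strands with
≥ 200 bp intergenic gaps (~54% coding at the default 200 genes /
100 kb); an A/T-third-position codon bias strong enough for the usage
tabulator to recover (e.g. TTT preferred over TTC); homopolymer
single-base deletions (inside a forced AAA-AAA run) that break the
reading frame of a configurable gene fraction (default 10%) — the
deletion is physically applied to the genome and downstream coordinates
shift; two predictors that each miss 8% of genes and jitter 20% of
boundaries by ≤ 15 bp in-frame, while both emit the indel-broken genes
as two ≥ 180 bp fragments with a short gap (the break is in the
assembly, so both predictors see it); a reference-proteome hit table in
which split fragments share a best homolog but have no mutual hit, 55%
of genes are homolog-bearing (matching the roughly half observed in the
real study), and planted paralog families (3–5 members) hit each other;
expression with log-normal means across genes (σ = 1.7, placing ≈ 2%
of genes above ten times the upper quartile — the HEG regime) and
Poisson counts; 10% of genes ≥ 300 bp carrying stationary-phase-only
antisense transcription with sense expression reduced six-fold (the
ADH1 pattern); always-on intergenic transcripts; ~2% rRNA tags from
designated intervals; and 2% of reads carrying 1–3 substitutions.

It does **not** emulate: color-space encoding or quality scores, paired
ends, indel sequencing errors in reads (indels live in the assembly, per
the mapping contract), introns or splice junctions, UTRs (so sense
contigs end at gene boundaries and genome coverage is far below a real
transcriptome's ~97%/200%), repeat structure (so multi-mapping is rare
and alignment rates are near 100% rather than ~60%), or cross-species
proteomes (family recovery is exercised on planted within-proteome
paralog families and on abstract graphs). Passing tests therefore
demonstrate the correctness of the rules and their boundary behaviour,
not performance on repeat-rich, UTR-bearing real data.

## Problem sizes and determinism

The end-to-end suite runs the full pipeline at 100 kb / 200 genes /
20 planted antisense genes / 20× depth for three seeds (~40 k tags per
seed); recall denominators are planted genes present in the merged
annotation (antisense) and planted split genes with homology evidence
(frameshift), since genes invisible to a stage by construction cannot
be recalled by it. Calibration checks (upper quartile, HEG fraction)
use a genome-free expression simulation at 2,000 genes. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
pipeline reruns with the same seed and configuration are byte-identical,
and the run manifest records the seed, the configuration and its hash,
and per-stage row counts.

## Known limitations

* The triangle-merge fixpoint is computed exactly but quadratically in
  cluster pairs in the worst case; fine at proteome scale with
  e ≤ 1e-20 edges, not tuned for dense million-edge graphs.
* The mapper's seed index is an in-memory Python dict (~25 × genome
  size entries); built for desk-scale genomes (≤ a few Mb), not for
  mammalian references.
* Gap bridging, fractional-overlap tag assignment and the role of the
  3′ half are all exposed as configuration or documented fixed choices;
  sensitivity to them can be swept but no automatic selection is done.
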
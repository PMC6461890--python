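# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `picevo`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and read weighting

All internal coordinates are 0-based half-open. GFF3 and RepeatMasker
`.out` (both 1-based closed) are converted at the parsing boundary; BED
and pysam-reported SAM coordinates are native. A single convention
eliminates off-by-one drift between stages.

Mapped small-RNA reads are collapsed by exact sequence identity. A
sequence observed `c` times with `h` genomic placements contributes
weight `c/h` at each placement ("reads/hits" fractionation), so
multi-mappers are never over-counted. Collapsed SAM carries the copy
count in the integer tag `XC` (one line per placement); the BED dialect
encodes it in the name field as `seq:<sequence>|n:<count>`. Mapping
itself is out of scope: placements are consumed as given.

## Ping-pong statistics

5′-overlap geometry: a plus-strand 5′ end at `p` and a minus-strand 5′
end at `q` overlap by `k = q − p + 1`; ping-pong pairs have `k = 10`.
Scores `s(k)`, k = 1..20, accumulate the product of the two placements'
fractionated weights (product weighting is a documented choice; the
field also uses min- or unweighted counts, and the original tooling does
not state its formula). `z₁₀` uses the mean and the *sample* standard
deviation (n − 1) of the 19 background bins — the more conservative
convention. A signature is significant when the argmax over k is
*uniquely* at 10 (ties are not "unambiguous" and fail) and `z₁₀` >
2.3264, the minimal 4-decimal z with upper-tail normal probability
≤ 0.01.

Degenerate cases: an all-zero score vector has undefined `z₁₀` and is
not significant. When every pair overlaps by exactly 10 nt (possible in
small transcript-space fixtures) the background standard deviation is 0
with `s(10) > 0`; this is the cleanest possible signal and is reported
significant with `z₁₀ = ∞`.

`partner_share` is the fraction of distinct 24–32 nt sequences with at
least one exact 10-nt-overlap partner; it depends only on distinct
sequences, not copy counts.

## Cluster calling

Reads are filtered to 24–32 nt. The genome is tiled at 1 kb (well below
the minimum cluster size); a candidate region is a maximal run of tiles
whose fractionated read density exceeds the `(1 − P)` quantile of the
genome-wide distribution of *nonzero* tile densities, extended to the
outermost read boundaries in the run. The density quantile is our
reproducible, seedless operationalization of the original tool's density
P value, whose internals are unpublished.

Emitted loci must pass, in this order: size ≥ `min_size`; composition —
weighted fraction of reads with 1U *or* 10A ≥ threshold, else the rescue
condition that the 1U fraction *and* the 10A fraction each be ≥ 0.33 (a
literal per-read AND would reject canonical 1U-dominated clusters);
main-strand fraction ≥ 0.5 (an exact tie reports '+' with a warning);
and the diversity rule — the top `ceil(0.01 × n)` distinct sequences
(minimum 1) may hold at most 90% of the locus weight. Presets:
strict (5000, 0.01, 0.75), lenient (2500, 0.05, 0.50); both share
rescue 0.33, strand 0.5, top-1% 90%, merge 10 kb.

Loci closer than 10 kb merge transitively; merged attributes are
recomputed from the union of reads, and merging is idempotent.
`rpm = weight × 10⁶ / library`, `rpkm = rpm / (kb)`, with the library
defined as total weighted 24–32 nt mapped reads. Leaning: 26 when the
25–27 nt weight strictly exceeds the 29–31 nt weight, else 30 — ties
lean 30, the majority class in real testis data.

## Similarity engine

Both homology and pseudogene search go through one adapter
(`picevo.engine`). The built-in engine seeds exact k-mers (11 nt
default; 9 nt in the sensitive preset used for diverged non-coding
sequence), groups seeds on alignment diagonals (seed gaps ≤ 200 nt),
requires ≥ 2 seeds per run (isolated single seeds are overwhelmingly
chance matches at these word sizes), and extends each run ungapped with
an x-drop criterion under +1/−2 scoring, trimming to matching ends.
Extension is clipped to 800 nt beyond the seeded span: with an expected
score slope of about −1.25/nt in non-homologous sequence, an x-drop of
20–30 cannot plausibly travel further. Hits below 30 aligned nt or 60%
(55% sensitive) identity are dropped; e-values use rough ungapped
Karlin–Altschul constants (λ = 1.28, K = 0.46) and serve only for
ranking. Lowercase (repeat-masked) and N subject positions never seed;
extension through them counts mismatches.

The engine is ungapped by design: the synthetic genomes evolve by
substitutions only, so homologous sequences stay colinear. For gapped or
low-identity work the `BlastnEngine` adapter shells out to `blastn`
(`dc-megablast` by default) and parses standard 12-column tabular
output into the same hit records; a test cross-checks the two engines on
a diverged pair.

## Synteny-based homology

Per query cluster, the exons of up to ten protein-coding genes up- and
downstream (lncRNAs never anchor synteny) are searched against the
masked subject genome. Hits of one gene within 200 kb merge into a gene
locus; gene loci within 2 Mb group into candidate flanks (both distances
are our choices — they exceed typical gene spacing while bounding the
search); the best flank by (gene count, mean identity) wins and must
hold ≥ 4 genes. The cluster sequence is then searched in the flank
(padded by 50 kb) with the sensitive engine; hit groups (gap ≤ query
length) are accepted when query coverage ≥ 5%, total aligned ≥ 1.5 kb,
and subject span ≥ 15% of the *query* length ("relative size" is read on
the query; the alternative reading is unstated in the source protocol).
A homolog counts as expressed when it overlaps any lenient-preset
cluster of the subject species by ≥ 1 bp.

Pairwise links chain into groups as connected components; a component
holding two loci of one species resolves to the higher-coverage link
with a warning. Categories: 1 = present and expressed in every species,
2 = present in every genome but not expressed in all, 3 = homolog
missing in ≥ 1 genome.

Identity-versus-split-time tables take engine alignments for the cluster
category; for the gene and whole-genome categories the generator
guarantees colinearity, so orthologous CDS pairs and sampled 5-kb
windows are globally aligned with edlib and identity is
1 − edits/length. Default split times mirror the primate calibration
points: 1, 25, 40, 58 and 65 My.

## Pseudogene annotation

The prediction pipeline searches the CDS catalog against the
repeat-masked genome, then: drops hits overlapping annotated gene exons
(this also removes each gene's self-hit); merges genomically overlapping
hits into blocks — a block is a pseudo-exon, the natural
operationalization of an otherwise undefined count; joins adjacent
blocks of the same parent into a unit when the gap ≤ max(1.5 × largest
parent intron, 30 kb); resolves competing parents over one locus by
identity × coverage (ties by best e-value, then lexicographic id);
discards units with span < 300 bp or query coverage < 10%; and
classifies processed ⇔ pseudo-exons ≤ ½ × (coverage × parent exon
count). Identity to parent is the alignment-length-weighted mean over a
unit's hits; unit strand is the weight-majority strand of its hits.

Two intrinsic properties of the classification rule worth knowing: a
full-length single-exon retrocopy is classified unprocessed (1 > 0.5),
and a strongly 5′-truncated processed copy of a 3-exon gene can fall on
the unprocessed side (1 > 0.5 × cov × 3 when cov < ⅔). Both follow from
the rule as stated, and the generator's planted mixtures include such
edge cases; classification accuracy on the default study is measured by
the tests rather than asserted here.

In-cluster units are parallel/reverse relative to the cluster's main
strand; intron-inserted units are labeled relative to the host gene.
Cross-species pseudogene matches inside homologous cluster regions keep
alignments ≥ 150 bp with coverage ≥ 30%. Window scans slide 32-nt
windows (step 1) along a unit, computing identity-to-parent from the
unit's own alignment and antisense read density in rpm; Pearson r is 0
with a flag when either profile has zero variance, and |r| ≤ 0.3 is
considered negligible.

## Target genes

Reads are matched to cDNAs ungapped and end-to-end via a
seed-and-verify index (8-mer seeds; with ≤ 2 mismatches over a 24–32 nt
read, three seeds guarantee one exact hit by pigeonhole). Sense
placements (read = cDNA substring) are kept only mismatch-free;
antisense placements (reverse complement of the read matches the cDNA)
tolerate two. Per-gene weights fractionate copies over transcript
placements only — the transcript mapping is a standalone step, not
reconciled with genomic placements. Gene length for RPKM is the
representative (longest) cDNA; the pass threshold is 5 RPKM. Per-gene
ping-pong re-uses the genomic overlap statistic on transcript-space
pseudo-reads (sense = plus strand; an antisense placement's 5′ end sits
at position + length − 1).

Pseudogene-derived targets: reads overlapping reverse in-cluster units
on the strand antisense to the parent mRNA are mapped to the cDNA
catalog on their own; resulting genes carry their source unit ids.
Cross-species overlap counts ortholog groups targeted in exactly k
species; genes absent from the ortholog table count as
species-specific.

## Genomic environments

Fixed 1-Mb tiling from position 0; terminal partial windows are kept
with length-normalized per-Mb features (discarding them would bias small
fixture genomes). Genes, pseudogenes and ChIP peaks are assigned to the
window containing their midpoint (no double counting); repeat shares are
covered bp / window bp and divergence is the length-weighted mean.
GC ignores ambiguous bases and raises on all-N input. Windows
overlapping centromere intervals are excluded from comparisons. A
cluster is intergenic iff it overlaps no gene span and no pseudogene by
even 1 bp.

Cluster-containing windows are compared with the rest by the two-sided
Wilcoxon–Mann–Whitney test (scipy; exact null distribution for small
tie-free samples, asymptotic with tie correction otherwise); constant
features report p = 1 with a flag. The null-calibration check in the
test suite deliberately works in the small-sample regime (4 windows per
side) where the exact, discrete null applies: there the achieved level
is conservative (≈3% at nominal 5%), so the calibration bound is a
meaningful correctness check rather than a coin flip on Monte-Carlo
noise — at large n the rejection count over 100 simulations is simply
Binomial(100, 0.05). Peak densities use the midpoint rule; the
enrichment ratio is region density over genome-wide density, undefined
(flagged) for empty peak sets.

## Comparative synthesis

The expression matrix holds rpm per homolog group × species, 0 for
absent or non-expressed members. Hierarchical clustering is average
linkage (UPGMA, scipy) on Pearson distance d = 1 − r; items are
pre-sorted by label for deterministic tie-breaks, and zero-variance
profiles get d = 1 with a warning rather than a crash. A brute-force
UPGMA oracle in the tests verifies cophenetic distances to 1e-9.

HECs (highly expressed clusters): a group member is an HEC at fold f in
species s iff its rpm is ≥ f × the *maximum* rpm among the other species
of the group (the strictest reading of "f-fold versus the remaining
species") and > 0; HEC sets are monotone decreasing in f by
construction. The ping-pong ratio compares partner shares of pooled HEC
reads versus all remaining cluster reads. Per-category transposon
divergence is the length-weighted mean over repeats inside each member
locus, compared across categories with the paired Wilcoxon signed-rank
test over species; clusters without repeats are excluded with a flag.

## Synthetic data generator

The generator is the package's study-conditions definition, not a
tuning surface. One ancestral genome (default 5 Mb, one chromosome) is
laid out with 160 genes (3–8 exons of 150–400 nt, introns 200–2000 nt,
8% lncRNA, 12% paralogs at 0.10 subst/site), 20 clusters of 6–12 kb
interleaved so every cluster has ≥ 7 protein-coding flank genes per
side, 60 pseudogenes (60% processed, of which 30% 5′-truncated; half
inside clusters with a 60/40 reverse/parallel mix; 20% of the rest in
gene introns; divergence 0.02–0.10), ~300 repeats from three families
with per-family divergence normals (Alu 12 ± 3%, L1 18 ± 4%, ERVL
15 ± 3.5%) written as mutated copies of per-family consensus sequences
and lowercase-masked, a 100-kb feature-free centromere, and GC varying
by 100-kb blocks (0.42 ± 0.05). Placement is deterministic given the
seed; infeasible packings raise before writing.

Species evolve from the root by Jukes–Cantor substitutions at
`subst_rate × time` (default 0.002/site/My; per-site change probability
¾(1 − e^(−4d/3)), so multiple hits are collapsed and the closed-form
expected identity ¼ + ¾e^(−4d/3) is testable). The species list is a
ladder: pairwise split time = max of the two divergence-from-root times.
Per species, a deterministic round(fraction × n) number of clusters is
*lost* (sequence replaced by random DNA; fraction = 1 − e^(−0.0105 t),
chosen so retention falls from ~99% at 1 My to ~50% at 65 My, the
qualitative shape reported for primate cluster retention) and a smaller
number is *silenced* (present but no reads; rate 0.004/My). Deterministic
counts make retention-versus-time monotone by construction, so the
homology experiments measure detection, not sampling luck.

Expression: each cluster has a base log₁₀ level (σ = 0.25) shared by all
species plus independent per-species drift with σ = 0.04·√t — so
between-species expression correlation decays with divergence time and
clustering the matrix recovers the species ladder. Reads (default 100k
per species, 20% uniform background, 2% of background planted as exact
two-placement multi-mappers) are drawn per expressed cluster
proportionally to these levels: lengths from a 26/30 normal mixture
(σ = 0.9, truncated to 24–32; mixture 75/25 or 25/75 by the cluster's
planted leaning), primary reads start with U with probability 0.75
(position rejection sampling against the actual genome sequence), 25% of
cluster reads form ping-pong pairs with exact 10-nt 5′ overlaps on
opposite strands — responder 10A then follows automatically from
complementarity — and 85% of non-pair reads sit on the main strand.
Reads are emitted pre-mapped at their true coordinates; no aligner runs.

What the generator does **not** emulate: insertions/deletions and
rearrangements (homology stays colinear — the built-in ungapped engine
is sufficient *because* of this, and real data would need the blastn
adapter); transposition dynamics (repeats are annotations plus mutated
consensus copies, not active elements); isoforms (cDNA = spliced exons =
CDS); sequencing error and adapter artifacts; chromosome structure
beyond one centromere gap. Passing tests therefore demonstrate the
correctness of each algorithm under clean, colinear, substitution-only
conditions — not performance on real degraded genomes.

## Problem sizes in validation

The validation experiments use the default 3-species/5-Mb/100k-read
study for cluster, pseudogene, target and comparative checks; a compact
1.2-Mb/6-cluster study per seed (10 seeds) for homolog retention across
0.01–0.15 subst/site; and a 10-Mb single-species genome for the window
recount oracle. These sizes keep every truth-table quantity at
measurable counts while each stage runs in seconds to a few minutes on
one CPU.
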
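# Methods

## Scope and model of the data

The package operates on four annotated genomes with designated roles:
a reference ingroup species, its close ingroup relative, a third, more
distant ingroup species, and an outgroup used for rooting (the canonical
configuration is mouse / rat / guinea pig / human). All coordinates are
held 0-based half-open internally; GFF3 I/O uses the format's native
1-based inclusive convention, and every sequence attached to an intron
record is transcript-oriented (reverse-complemented for minus-strand
genes). When a gene has several annotated transcripts, one canonical
structure is chosen: the transcript with the longest CDS span, then the
longest exon span, ties broken by lexicographic transcript id. This choice
is a stand-in — sources rarely document which transcript underlies an
ortholog table — and is isolated in one function.

## Filter cascade

Thresholds live in `FilterConfig`, defaults: length window [200, 1600] bp
on the reference species (closed interval — "between x and y" is read
inclusively); tiered length-difference fractions 0.90 / 0.80 / 0.70 with
strict bounds ("lower than"); at most 9 ambiguous bases per intron; flanks
≥ 40 bp; extraction cap 50 kb (strict); E-value 10⁻⁴; scaling factor < 0.8
and K tree score < 0.09 (both strict). Two readings of the
length-difference tiers are possible; the implementation uses the tier's
named species as denominator (outgroup length for the 90% rule, third
rodent for 80%, reference for 70%), by analogy with the explicit wording
of the outgroup tier. Redundancy means an exactly identical
reference-species genomic interval — the observable meaning of "annotated
more than once"; overlapping but distinct intervals are both kept. An
ambiguous base is any character outside {A,C,G,T}, case-insensitive,
counted on the intron only (not the flanks). Rejections are attributed to
the first failing stage only; the per-marker predicates (length window,
ambiguity, flank) are order-independent in membership and the whole
cascade is idempotent, both of which are asserted by tests.

## Single-copy screen

Flanking exons — never the intron — are the queries, searched against the
same species' whole genome. The built-in search is a word-seeded
(default word size 11), ungapped, X-dropoff extension with +1/−2 scoring
and Karlin–Altschul E-values `E = K·m·n·e^(−λS)` using the ungapped DNA
constants λ = 1.28, K = 0.46 for that scoring scheme (configurable).
A significant hit (E ≤ 10⁻⁴) counts as a duplicate when it lies outside
the source gene's span padded by 1 kb on its own chromosome — the padding
tolerates coordinate slop; the self-hit never triggers rejection. A
duplicate in *any* of the four species rejects the marker (the
conservative reading: one multi-band species spoils the marker). Externally
computed hits in the 12-column tabular dialect can replace the built-in
search per species; tests assert the verdict is identical on equivalent
inputs.

## Alignment and block cleaning

The aligner is pluggable via a command template (`"mafft --auto {in} >
{out}"` style). The built-in fallback is a progressive aligner — global
pairwise alignment (match +1, mismatch −1, linear gap −2, via Biopython's
PairwiseAligner, cross-checked against an exhaustive DP oracle in tests)
with a greedy similarity-ranked join order and consensus-based profile
joins — so the test suite and default pipeline never shell out. Its only
guaranteed contract is that each aligned row degaps back to its input.

Column cleaning is a relaxed Gblocks-style block filter: a column is
*conserved* when its most frequent residue occurs in at least
⌊N/2⌋+1 rows, runs of more than 8 nonconserved columns are cut and break
blocks, block ends are trimmed back to conserved columns, trimmed blocks
shorter than 5 columns are dropped, and a kept column may be gapped in at
most half the taxa. The classification is iterated to a fixed point so the
operation is idempotent. All five parameters are exposed; the defaults
follow the "relaxed" convention (small blocks and half-gap columns
allowed) because no canonical numeric setting exists for this use.

## Trees and the divergence statistics

Built-in trees are neighbor joining on Jukes–Cantor distances
`d = −(3/4)·ln(1 − 4p/3)` computed over gap-free shared columns per pair;
saturated pairs (p ≥ 0.75) receive a configurable cap (default d = 5) and
negative NJ branch estimates are clamped to zero. Externally inferred
newick trees (e.g. maximum likelihood) can be supplied per marker; ML/
Bayesian inference itself is out of scope. The reference tree is built
from the concatenated cleaned alignments of every marker that reaches the
phylogenetic stage.

Tree comparison pairs branches of the two trees by the leaf bipartition
each branch induces; a bipartition present in only one tree pairs with
length 0, which keeps the comparison defined when single-marker topologies
disagree with the reference. The scaling factor is the closed-form
least-squares multiplier `K = Σtᵢrᵢ / Σtᵢ²` and the K tree score is
`sqrt(Σ(K·tᵢ − rᵢ)² / n)`. The normalization count `n` is the *union*
partition count — the source method does not document whether union,
reference or comparison count is meant; union is symmetric in the
mismatched partitions and is asserted in tests against an independent
1-D numerical minimizer. `K < 1` marks a tree more divergent than the
reference. Bipartition lengths are accumulated over root-adjacent edges,
making the statistics invariant to root placement.

## Primer design

Candidate primers are IUPAC consensus windows (observed ambiguity codes
expanded before taking the union) of 20–25 columns inside a search window
(default 120 columns) at the intron-proximal end of each flanking-exon
alignment. Windows containing any gapped column are disqualified — a
primer cannot span an indel. Degeneracy is the product of per-position
base-set sizes and must be strictly below 48. Melting temperature uses
`Tm = 64.9 + 41·(GC − 16.4)/L`, evaluated on the AT-most and GC-most
expansions of degenerate positions to give a (min, max) range; pairs must
have mean-Tm difference within 5 °C. Ranking favors low degeneracy, then
intron proximity — a documented stand-in for "most conserved region"
selection, which the source does not specify numerically. The predicted
amplicon is the reference intron length plus each window's offset from the
intron (the between-primer span). Note the degeneracy of one published
reverse primer in the packaged table sits exactly on the 48 bound; the
designer keeps the strict inequality.

## Variability and validation statistics

For a pair of sequenced alleles, a column counts toward divergence only
when both residues are non-gap and their IUPAC base sets are disjoint, so
a heterozygous position (a two-fold ambiguity code: R,Y,S,W,K,M) sharing
an allele with the other sequence never inflates divergence; a
strict-mismatch rule is available as an option. Heterozygosity counts
two-fold codes only — N and three-fold codes are treated as sequencing
ambiguity, not allelic evidence. Indels are maximal gap runs per row after
dropping columns gapped in both rows. The pooled mean divergence is total
differences over total aligned positions (a length-weighted mean).
Validation grids over {65-55, 65-60, 65-50, fail} touch-down PCR outcomes
are summarized into success totals, integer percentages (rounded half away
from zero, matching how such rates are conventionally printed), per-ramp
counts, and per-species / per-marker breakdowns.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes. Root
genes (exon counts 2–8, exon lengths 30–240 bp, intron lengths 80–2200 bp
— wide enough that the length and flank filters have genuine work) evolve
down a fixed four-taxon species tree with exon-scale branch lengths
(ingroup tips 0.025/0.030, +0.040 to the third rodent at 0.100, outgroup
0.170 substitutions/site). Introns evolve faster by a per-intron rate
multiplier drawn from a gamma distribution with mean 3 and CV 0.5 —
across-intron rate heterogeneity is the premise of the rate filter, so it
is part of the default conditions. Indels (0.1 events per substitution,
lengths 1–10) apply to introns only, so exon structure is conserved;
ambiguous bases are injected at 2×10⁻³ per intron site; 40% of genes sit
on the minus strand to exercise orientation code; with probability 0.05 a
gene carries an unannotated duplicate copy on a dedicated `chr_dup`
chromosome, making locus-overlap logic unambiguous. A truth table records
each marker's expected first failing stage from generation-time knowledge;
tests require ≥ 95% agreement with the cascade's actual verdicts (slack
for stochastic boundary effects). Substitution is Jukes–Cantor; identical
seeds give byte-identical outputs.

What the generator does **not** emulate: isochore/GC structure, codon
models and selection on exons, rate variation among sites within an
intron, lineage-specific rate shifts, assembly or annotation error beyond
injected Ns, and recent segmental duplications that are themselves
diverged. Passing tests therefore demonstrate the correctness of the
pipeline's logic under its own assumptions, not the biological yield of a
real genome comparison — the published genome-scale survivor counts
require the original genome snapshots and are deliberately out of scope.

## Problem sizes and numerical choices

Default test and demonstration runs use 15–30 genes (≈50–130 candidate
introns), chosen as comfortable desk-scale sizes for the pure-Python
search and alignment paths. The rate-filter recovery check simulates 25
markers at twice the reference rate (600 bp each) against a reference
concatenated from 15 baseline markers: expected scaling factor ≈ 0.5 with
sampling noise well inside the 0.09 score threshold, and ≥ 90% of the
fast markers must pass. Ties in redundancy resolution go to the
lexicographically smallest marker id; NJ ties follow the distance-matrix
order; all randomness flows from a single integer seed.
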
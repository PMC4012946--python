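# epicmarkers

Discovery of rapidly evolving, single-copy, PCR-amplifiable intron markers
(EPIC markers: *exon-primed, intron-crossing*) from annotated genomes.

Studies of closely related species — species trees under the coalescent,
speciation, phylogeography — need nuclear markers with as much sequence
variability as possible. Introns evolve much faster than the exons that
flank them, and those conserved flanking exons are ideal real estate for
degenerate PCR primers that work across a whole clade. `epicmarkers`
implements the full mining pipeline for a four-species genome comparison
(two closely related ingroup rodents, a third rodent, and an outgroup used
for rooting): intron extraction, one-to-one ortholog crossing, a cascade of
quality filters, a single-copy screen, tree-based selection of the fastest
clock-like introns, and degenerate primer design — plus a synthetic-genome
generator so every stage is testable without genome downloads.

## The filter cascade

Orthologous intron sets (named `<gene>-<intron index>`, e.g. `Dhcr24-7`)
pass through, in order:

1. **Length window** — reference-species intron length in [200, 1600] bp
   (amplifiable by standard PCR).
2. **Length difference** — tiered pairwise length similarity to avoid
   unalignable introns: each rodent within 90% of the outgroup intron
   length (an outgroup intron of 1000 bp admits rodent introns strictly
   between 100 and 1900 bp), the ingroup rodents within 80% of the third
   rodent, and within 70% of each other. All bounds strict.
3. **Redundancy** — introns annotated more than once (identical
   reference-genome interval) are collapsed.
4. **Ambiguity** — more than nine non-ACGT bases in any species rejects.
5. **Flank length** — both flanking exons ≥ 40 bp in every species
   (primer real estate).
6. **Single copy** — each flanking exon is searched against its own
   species' genome (built-in seed-and-extend ungapped search with
   Karlin–Altschul E-values, threshold 10⁻⁴, or externally computed
   tabular hits); any significant hit outside the source locus rejects
   the marker.
7. **Phylogenetic** — each intron alignment (cleaned with a relaxed
   Gblocks-style block filter) yields a tree; against the reference tree
   from the concatenated supermatrix the scaling factor
   `K = Σtᵢrᵢ / Σtᵢ²` (least-squares branch-length multiplier, branches
   paired by leaf bipartition) and the K tree score
   `k = sqrt(Σ(K·tᵢ − rᵢ)² / n)` are computed. Markers with `K < 0.8`
   (more divergent than average) and `k < 0.09` (clock-like) survive.

Surviving markers are cataloged with their alignments, trees, divergence
statistics (including the summed ingroup terminal branch lengths, a proxy
for recent divergence) and, where feasible, degenerate primer pairs
(consensus windows of 20–25 bp in the intron-proximal exon ends,
degeneracy < 48, matched melting temperatures).

## Worked example

Simulate a small four-species dataset and run the cascade:

```
$ epicmarkers simulate --seed 4 --n-genes 15 demo/sim
wrote simulated dataset to demo/sim
$ epicmarkers run --config demo/pipeline.yaml demo/catalog
length_window          48 ->     31
length_difference      31 ->     31
redundancy             31 ->     31
ambiguity              31 ->     31
flank                  31 ->     23
single_copy            23 ->     23
phylogenetic           23 ->     10
catalog: 10 markers -> demo/catalog
```

(`demo/pipeline.yaml` lists the written FASTA/GFF3/ortholog-table paths and
the anchor order; see `PipelineConfig`.) Of the 48 extracted orthologous
introns, 31 fall in the reference length window, 23 also have long enough
flanks, and 10 are both fast-evolving and clock-like. The catalog index
records, per marker:

```
marker_id    chromosome  start  end   scaling_factor  k_score   ...
g0000_mus-5  chr1        6557   7552  0.669353        0.017854
g0000_mus-7  chr1        9075   9278  0.583379        0.046775
```

A scaling factor of 0.67 means this intron's tree is ~1.5× as divergent as
the reference; a K tree score of 0.018 means its relative branch lengths
closely track the reference, i.e. the rate acceleration is uniform across
lineages.

The validation/variability reporting side works from per-locus tables:

```
$ epicmarkers report --validation .../rodent_validation.tsv \
                     --variability .../microtus_variability.tsv
PCR validation: 87/110 positive reactions (79%)
  per ramp: 65-55: 80, 65-60: 2, 65-50: 5
  per-species success rate: 30% - 90%
Sequenced-locus variability: 28 differences over 3720 aligned positions (0.75%)
  heterozygous sequence loci: 7
```

## Layout

- `genome_io` — FASTA/GFF3/GenBank reading, strand-aware intron extraction
- `orthology` — pairwise ortholog-table crossing into one-to-one quartets
- `intron_filters` — the deterministic filter cascade and its trace
- `homology_search` — seed-and-extend search and the single-copy screen
- `msa_clean` — pluggable alignment plus the relaxed block filter
- `treekit` — NJ/JC trees, concatenation, scaling factor and K tree score
- `primer_design` — degenerate consensus-window primer pairs
- `variability_report` — divergence/heterozygosity/indel and PCR summaries
- `simdata` — synthetic four-species genomes with known ground truth
- `pipeline`, `cli` — orchestration and the `epicmarkers` command
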
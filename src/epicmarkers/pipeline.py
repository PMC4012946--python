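"""End-to-end orchestration: genomes + annotations + ortholog tables in,
filtered marker catalog with trees, divergence statistics and primers out.

Stage order: length window -> length difference -> redundancy -> ambiguity
-> flank length -> single copy -> phylogenetic (rate/clock) filter.  The
reference tree for the phylogenetic stage is built from the concatenated
cleaned alignments of every marker surviving the single-copy screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .genome_io import (
    GeneModel,
    GenomeSet,
    IntronRecord,
    extract_introns,
    parse_annotation,
)
from .homology_search import GenomeHitSource, HitSource, TabularHitSource, single_copy_stage
from .intron_filters import (
    DEFAULT_STAGE_ORDER,
    FilterConfig,
    FilterTrace,
    OrthologousIntronSet,
    build_intron_sets,
    run_cascade,
)
from .msa_clean import Alignment, BlockParams, align_set, clean_blocks
from .orthology import OrthologTable, cross_tables, equal_exon_count_filter
from .primer_design import PrimerConstraints, PrimerPair, design_pair
from .treekit import (
    MarkerDivergenceStats,
    build_nj_tree,
    concatenate,
    marker_stats,
    phylo_filter,
    read_newick,
    write_newick,
)

logger = logging.getLogger(__name__)


@dataclass
class MarkerCatalogEntry:
    marker_id: str
    reference_location: tuple[str, int, int]
    records: Mapping[str, IntronRecord]
    alignment: Alignment
    stats: MarkerDivergenceStats
    tree_newick: str
    annotation: str = ""
    primers: "PrimerPair | None" = None


@dataclass
class PipelineResult:
    catalog: list[MarkerCatalogEntry]
    trace: FilterTrace
    reference_tree_newick: str
    n_quartets: int


@dataclass
class PipelineConfig:
    """File-level pipeline configuration (YAML-loadable)."""

    genomes: dict[str, str]
    annotations: dict[str, str]
    ortholog_tables: list[tuple[str, str, str]]
    filters: FilterConfig = field(default_factory=FilterConfig)
    aligner: "str | None" = None
    external_hits: "dict[str, str] | None" = None
    external_trees: "dict[str, str] | None" = None  # marker_id -> newick path
    design_primers: bool = True

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        filters = data.pop("filters", None)
        cfg = cls(
            genomes=data["genomes"],
            annotations=data["annotations"],
            ortholog_tables=[tuple(t) for t in data["ortholog_tables"]],
            aligner=data.get("aligner"),
            external_hits=data.get("external_hits"),
            external_trees=data.get("external_trees"),
            design_primers=data.get("design_primers", True),
        )
        if filters:
            if "anchor_order" in filters:
                filters["anchor_order"] = tuple(filters["anchor_order"])
            if "tier_fractions" in filters:
                filters["tier_fractions"] = dict(filters["tier_fractions"])
            cfg.filters = FilterConfig(**filters)
        return cfg


def run_pipeline_data(
    genomes: GenomeSet,
    models: Mapping[str, Sequence[GeneModel]],
    tables: Sequence[OrthologTable],
    cfg: FilterConfig,
    aligner: "str | None" = None,
    hit_source: "HitSource | None" = None,
    external_trees: "Mapping[str, object] | None" = None,
    block_params: "BlockParams | None" = None,
    design_primers: bool = True,
    primer_constraints: "PrimerConstraints | None" = None,
) -> PipelineResult:
    """Run the full cascade on in-memory inputs."""
    models_index = {
        (sp, m.gene_id): m for sp, ms in models.items() for m in ms
    }
    records: dict[tuple[str, str, int], IntronRecord] = {}
    for (sp, gid), model in models_index.items():
        for rec in extract_introns(model, genomes, cfg.max_extract_len):
            records[(sp, gid, rec.intron_index)] = rec

    quartets = cross_tables(tables, cfg.anchor_order, cfg.one2one_label)
    logger.info("crossed ortholog tables: %d one-to-one quartets", len(quartets))
    quartets, _ = equal_exon_count_filter(quartets, models_index)
    logger.info("equal-exon-count filter: %d quartets remain", len(quartets))

    sets = build_intron_sets(quartets, records)
    logger.info("orthologous intron sets: %d", len(sets))

    stages: list = list(DEFAULT_STAGE_ORDER)
    src = hit_source or GenomeHitSource(genomes)
    stages.append(("single_copy", single_copy_stage(src)))
    survivors, trace = run_cascade(sets, cfg, stages)

    # phylogenetic stage: align, clean, tree, compare to the concatenated
    # reference, filter
    aligned: list[tuple[OrthologousIntronSet, Alignment]] = []
    trees: dict[str, object] = {}
    n_in = len(survivors)
    for iset in survivors:
        seqs = {sp: rec.intron_seq for sp, rec in iset.records.items()}
        aln = align_set(seqs, engine=aligner)
        cleaned, _ = clean_blocks(aln, block_params)
        if external_trees and iset.marker_id in external_trees:
            src_tree = external_trees[iset.marker_id]
            tree = src_tree if hasattr(src_tree, "tips") else read_newick(src_tree)
        else:
            try:
                tree = build_nj_tree(cleaned)
            except ValueError as exc:
                trace.rejections.setdefault(iset.marker_id, "phylogenetic")
                logger.warning("marker %s: %s", iset.marker_id, exc)
                continue
        aligned.append((iset, cleaned))
        trees[iset.marker_id] = tree

    catalog: list[MarkerCatalogEntry] = []
    ref_newick = ""
    if aligned:
        concat, _ = concatenate(
            [a for _, a in aligned], list(cfg.anchor_order)
        )
        ref_tree = build_nj_tree(concat)
        ref_newick = write_newick(ref_tree)
        ingroup = [cfg.reference_species, cfg.ingroup2_species]
        for iset, cleaned in aligned:
            stats = marker_stats(
                iset.marker_id, trees[iset.marker_id], ref_tree, ingroup
            )
            if not phylo_filter(stats, cfg):
                trace.rejections.setdefault(iset.marker_id, "phylogenetic")
                continue
            ref_rec = iset.records[cfg.reference_species]
            primers = None
            if design_primers:
                primers = _design_marker_primers(
                    iset, cfg, aligner, primer_constraints
                )
            catalog.append(
                MarkerCatalogEntry(
                    marker_id=iset.marker_id,
                    reference_location=ref_rec.genomic_interval,
                    records=iset.records,
                    alignment=cleaned,
                    stats=stats,
                    tree_newick=write_newick(trees[iset.marker_id]),
                    primers=primers,
                )
            )
    trace.record_stage("phylogenetic", n_in, len(catalog))
    return PipelineResult(
        catalog=catalog,
        trace=trace,
        reference_tree_newick=ref_newick,
        n_quartets=len(quartets),
    )


def _design_marker_primers(
    iset: OrthologousIntronSet,
    cfg: FilterConfig,
    aligner: "str | None",
    constraints: "PrimerConstraints | None",
) -> "PrimerPair | None":
    up = {sp: rec.upstream_exon_seq for sp, rec in iset.records.items()}
    down = {sp: rec.downstream_exon_seq for sp, rec in iset.records.items()}
    try:
        up_aln = align_set(up, engine=aligner)
        down_aln = align_set(down, engine=aligner)
        result = design_pair(
            up_aln,
            down_aln,
            constraints,
            intron_length_ref=iset.records[cfg.reference_species].intron_length,
        )
    except ValueError:
        return None
    if not result.pairs:
        logger.info(
            "marker %s: no primer pair (%s)", iset.marker_id, result.diagnostic
        )
        return None
    return result.pairs[0]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-level wrapper: load inputs, run, return the result."""
    genomes = GenomeSet()
    for sp, path in config.genomes.items():
        genomes.add_fasta(path, sp)
    models = {
        sp: parse_annotation(path, genomes, sp)
        for sp, path in config.annotations.items()
    }
    tables = [
        OrthologTable.from_tsv(path, (a, b))
        for a, b, path in config.ortholog_tables
    ]
    hit_source = (
        TabularHitSource(config.external_hits) if config.external_hits else None
    )
    external_trees = (
        {m: read_newick(p) for m, p in config.external_trees.items()}
        if config.external_trees
        else None
    )
    return run_pipeline_data(
        genomes,
        models,
        tables,
        config.filters,
        aligner=config.aligner,
        hit_source=hit_source,
        external_trees=external_trees,
        design_primers=config.design_primers,
    )


def write_catalog(result: PipelineResult, outdir: "str | Path") -> None:
    """Per-marker directories plus a global index TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for entry in result.catalog:
        mdir = outdir / entry.marker_id
        mdir.mkdir(exist_ok=True)
        entry.alignment.to_fasta(mdir / "alignment.fasta")
        (mdir / "tree.nwk").write_text(entry.tree_newick + "\n")
        s = entry.stats
        (mdir / "stats.tsv").write_text(
            "marker_id\tscaling_factor\tk_score\ttotal_branch_length\t"
            "ingroup_terminal_sum\n"
            f"{s.marker_id}\t{s.scaling_factor:.6f}\t{s.k_score:.6f}\t"
            f"{s.total_branch_length:.6f}\t{s.ingroup_terminal_sum:.6f}\n"
        )
        if entry.primers is not None:
            p = entry.primers
            (mdir / "primers.tsv").write_text(
                "forward\treverse\tdegeneracy_fwd\tdegeneracy_rev\t"
                "predicted_amplicon\n"
                f"{p.forward_seq}\t{p.reverse_seq}\t{p.degeneracies[0]}\t"
                f"{p.degeneracies[1]}\t{p.predicted_amplicon}\n"
            )
        chrom, start, end = entry.reference_location
        index_rows.append(
            {
                "marker_id": entry.marker_id,
                "chromosome": chrom,
                "start": start,
                "end": end,
                "scaling_factor": round(s.scaling_factor, 6),
                "k_score": round(s.k_score, 6),
                "total_branch_length": round(s.total_branch_length, 6),
                "ingroup_terminal_sum": round(s.ingroup_terminal_sum, 6),
                "has_primers": entry.primers is not None,
            }
        )
    pd.DataFrame(
        index_rows,
        columns=[
            "marker_id", "chromosome", "start", "end", "scaling_factor",
            "k_score", "total_branch_length", "ingroup_terminal_sum",
            "has_primers",
        ],
    ).to_csv(outdir / "index.tsv", sep="\t", index=False)
    result.trace.to_tsv(outdir / "filter_trace.tsv")
    if result.reference_tree_newick:
        (outdir / "reference_tree.nwk").write_text(
            result.reference_tree_newick + "\n"
        )
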
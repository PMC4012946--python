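"""Seed-and-extend search, tabular hit ingestion and the single-copy screen."""

import pytest

from epicmarkers.genome_io import GenomeSet, GenomicSequence
from epicmarkers.homology_search import (
    GenomeHitSource,
    GenomeSearcher,
    TabularHitSource,
    flank_query_id,
    karlin_altschul_evalue,
    read_tabular_hits,
    seed_extend_search,
    single_copy_filter,
    write_tabular_hits,
)

from conftest import ANCHORS, make_set


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_exact_substring_yields_full_length_self_hit(rng):
    genome_seq = _random_seq(rng, 5000)
    query = genome_seq[1000:1100]
    hits = seed_extend_search(
        query, [GenomicSequence("sp", "chr1", genome_seq)], evalue_max=1e-4
    )
    assert hits
    best = hits[0]
    s, e = best.subject_interval
    assert s <= 1000 and e >= 1100
    assert best.raw_score >= 100
    assert best.strand == "+"


def test_reverse_strand_copy_found(rng):
    from epicmarkers._iupac import revcomp

    genome_seq = _random_seq(rng, 3000)
    query = revcomp(genome_seq[500:580])
    hits = seed_extend_search(
        query, [GenomicSequence("sp", "chr1", genome_seq)], evalue_max=1e-4
    )
    assert any(
        h.strand == "-" and h.subject_interval[0] <= 500 < h.subject_interval[1]
        for h in hits
    )


def test_every_exact_repeat_at_least_word_size_is_found(rng):
    """Completeness on exact copies: a planted repeat is always reported."""
    core = _random_seq(rng, 40)
    genome_seq = _random_seq(rng, 1000) + core + _random_seq(rng, 1000) + core
    hits = seed_extend_search(
        core, [GenomicSequence("sp", "chr1", genome_seq)], evalue_max=10.0
    )
    starts = {h.subject_interval[0] for h in hits}
    assert any(abs(s - 1000) <= 5 for s in starts)
    assert any(abs(s - 2040) <= 5 for s in starts)


def test_query_shorter_than_word_size_is_hard_error():
    with pytest.raises(ValueError, match="word size"):
        seed_extend_search("ACGTACGT", [GenomicSequence("sp", "c", "A" * 100)])


def test_raising_evalue_threshold_never_removes_hits(rng):
    genome = [GenomicSequence("sp", "chr1", _random_seq(rng, 4000))]
    searcher = GenomeSearcher(genome)
    query = genome[0].residues[100:160]
    strict = searcher.search(query, evalue_max=1e-6)
    loose = searcher.search(query, evalue_max=10.0)
    strict_keys = {(h.subject_chromosome, h.subject_interval, h.strand) for h in strict}
    loose_keys = {(h.subject_chromosome, h.subject_interval, h.strand) for h in loose}
    assert strict_keys <= loose_keys


def test_evalue_strictly_decreases_with_score():
    e1 = karlin_altschul_evalue(50, 100, 1_000_000)
    e2 = karlin_altschul_evalue(100, 100, 1_000_000)
    assert e2 < e1


def test_random_query_has_no_significant_hits(rng):
    """A 60-mer unrelated to a 100 kb random genome clears the 1e-4 E-value
    threshold in (essentially) every replicate."""
    genome = [GenomicSequence("sp", "chr1", _random_seq(rng, 100_000))]
    searcher = GenomeSearcher(genome)
    n_with_hits = sum(
        bool(searcher.search(_random_seq(rng, 60), evalue_max=1e-4))
        for _ in range(50)
    )
    assert n_with_hits == 0


# ---------------------------------------------------------------------------
# tabular hits
# ---------------------------------------------------------------------------


def test_read_tabular_hits_minus_strand_normalization(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("q1\tchr2\t98.5\t50\t1\t0\t1\t50\t200\t151\t1e-05\t90.1\n")
    (hit,) = read_tabular_hits(p)
    assert hit.strand == "-"
    assert hit.subject_interval == (150, 200)
    assert hit.evalue == pytest.approx(1e-5)
    assert hit.subject_chromosome == "chr2"


def test_read_tabular_hits_empty_file(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    assert read_tabular_hits(p) == []


def test_read_tabular_hits_malformed_row_names_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("q1\tchr2\t98.5\t50\n")
    with pytest.raises(ValueError, match="bad.tsv:1"):
        read_tabular_hits(p)


# ---------------------------------------------------------------------------
# single-copy screen
# ---------------------------------------------------------------------------


def _single_copy_genomes(rng, plant_duplicate_in=None):
    """Four species, each genome holding the gene's two flanks at a fixed
    locus; optionally plant a copy of the upstream exon elsewhere."""
    genomes = GenomeSet()
    iset = None
    up = _random_seq(rng, 120)
    down = _random_seq(rng, 110)
    intron = _random_seq(rng, 400)
    records = {}
    from epicmarkers.genome_io import IntronRecord

    for sp in ANCHORS:
        left = _random_seq(rng, 800)
        right = _random_seq(rng, 800)
        gene_seq = up + intron + down
        chrom_seq = left + gene_seq + right
        genomes.add(GenomicSequence(sp, "chr1", chrom_seq))
        gstart = len(left)
        gend = gstart + len(gene_seq)
        records[sp] = IntronRecord(
            gene_id="gX",
            species=sp,
            intron_index=1,
            intron_seq=intron,
            upstream_exon_seq=up,
            downstream_exon_seq=down,
            genomic_interval=("chr1", gstart + len(up), gstart + len(up) + len(intron)),
            gene_span=("chr1", gstart, gend),
        )
        if plant_duplicate_in == sp:
            genomes.add(
                GenomicSequence(sp, "chr_dup", _random_seq(rng, 200) + up)
            )
    from epicmarkers.intron_filters import OrthologousIntronSet

    return genomes, OrthologousIntronSet(
        marker_id="gX-1", records=records, intron_index=1
    )


def test_source_gene_only_is_kept(rng, filter_cfg):
    genomes, iset = _single_copy_genomes(rng)
    ok, reason = single_copy_filter(iset, GenomeHitSource(genomes), filter_cfg)
    assert ok, reason


def test_planted_duplicate_exon_rejects_marker(rng, filter_cfg):
    genomes, iset = _single_copy_genomes(rng, plant_duplicate_in="cavia")
    ok, reason = single_copy_filter(iset, GenomeHitSource(genomes), filter_cfg)
    assert not ok and reason == "single_copy"


def test_duplicate_in_single_species_rejects_whole_marker(rng, filter_cfg):
    """Duplication in any one of the four species suffices for rejection."""
    for sp in ANCHORS:
        genomes, iset = _single_copy_genomes(rng, plant_duplicate_in=sp)
        ok, _ = single_copy_filter(iset, GenomeHitSource(genomes), filter_cfg)
        assert not ok


def test_missing_genome_rejects_with_distinct_reason(rng, filter_cfg):
    genomes, iset = _single_copy_genomes(rng)
    partial = GenomeSet(
        [c for c in genomes if c.species != "homo"]
    )
    ok, reason = single_copy_filter(iset, GenomeHitSource(partial), filter_cfg)
    assert not ok and reason == "missing_genome"


def test_builtin_and_tabular_hit_sources_agree(rng, filter_cfg, tmp_path):
    """The verdict is identical whether hits come from the built-in search
    or from an equivalent tabular file."""
    for plant in (None, "rat"):
        genomes, iset = _single_copy_genomes(rng, plant_duplicate_in=plant)
        builtin = GenomeHitSource(genomes)
        files = {}
        for sp in ANCHORS:
            rows = []
            qlens = {}
            rec = iset.records[sp]
            for side, seq in (("up", rec.upstream_exon_seq),
                              ("down", rec.downstream_exon_seq)):
                qid = flank_query_id(rec, side)
                qlens[qid] = len(seq)
                rows.extend(
                    builtin.hits(sp, seq, qid, filter_cfg.evalue_threshold)
                )
            path = tmp_path / f"hits_{plant}_{sp}.tsv"
            write_tabular_hits(rows, qlens, path)
            files[sp] = path
        tabular = TabularHitSource(files)
        v1 = single_copy_filter(iset, builtin, filter_cfg)
        v2 = single_copy_filter(iset, tabular, filter_cfg)
        assert v1 == v2
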
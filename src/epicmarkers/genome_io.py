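"""Genome and annotation I/O: gene models, intron extraction, flanking exons.

Coordinates are stored 0-based half-open internally; GFF3 input/output uses
the format's native 1-based inclusive convention.  All sequences attached to
an :class:`IntronRecord` are in transcript orientation, i.e. reverse
complemented for minus-strand genes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._iupac import revcomp

logger = logging.getLogger(__name__)

DEFAULT_MAX_EXTRACT_LEN = 50_000


@dataclass(frozen=True)
class GenomicSequence:
    """One chromosome (or scaffold) of one species, residues uppercase."""

    species: str
    chromosome: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def length(self) -> int:
        return len(self.residues)


class GenomeSet:
    """Collection of chromosome sequences, keyed by (species, chromosome)."""

    def __init__(self, sequences: Iterable[GenomicSequence] = ()) -> None:
        self._seqs: dict[tuple[str, str], GenomicSequence] = {}
        for seq in sequences:
            self.add(seq)

    def add(self, seq: GenomicSequence) -> None:
        self._seqs[(seq.species, seq.chromosome)] = seq

    def get(self, species: str, chromosome: str) -> GenomicSequence:
        try:
            return self._seqs[(species, chromosome)]
        except KeyError:
            raise KeyError(
                f"no sequence for chromosome {chromosome!r} of species {species!r}"
            ) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._seqs

    def __iter__(self) -> Iterator[GenomicSequence]:
        return iter(self._seqs.values())

    def __len__(self) -> int:
        return len(self._seqs)

    def species(self) -> list[str]:
        return sorted({sp for sp, _ in self._seqs})

    def chromosomes(self, species: str) -> list[GenomicSequence]:
        return [s for (sp, _), s in self._seqs.items() if sp == species]

    def add_fasta(self, path: str | Path, species: str) -> None:
        for rec in SeqIO.parse(str(path), "fasta"):
            self.add(GenomicSequence(species, rec.id, str(rec.seq)))

    @classmethod
    def from_fasta(cls, path: str | Path, species: str) -> "GenomeSet":
        gs = cls()
        gs.add_fasta(path, species)
        return gs

    def write_fasta(self, species: str, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(c.residues), id=c.chromosome, description="")
            for c in self.chromosomes(species)
        ]
        SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene (its canonical transcript), strand-aware.

    ``exons`` are (start, end) 0-based half-open genomic intervals listed in
    transcript (5'->3') order: ascending genomic coordinates on '+', reversed
    on '-'.
    """

    gene_id: str
    transcript_id: str
    species: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-" or len(self.strand) != 1:
            raise ValueError(
                f"unknown strand {self.strand!r} for gene {self.gene_id}"
            )
        ivs = sorted(self.exons)
        if any(a[1] > b[0] for a, b in zip(ivs, ivs[1:])):
            raise ValueError(f"overlapping exons in gene {self.gene_id}")
        expected = ivs if self.strand == "+" else ivs[::-1]
        if tuple(expected) != tuple(self.exons):
            raise ValueError(
                f"exons of gene {self.gene_id} not in transcript order"
            )
        if any(s < 0 or e <= s for s, e in self.exons):
            raise ValueError(f"invalid exon interval in gene {self.gene_id}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole gene, 0-based half-open."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass(frozen=True)
class IntronRecord:
    """An intron plus its two flanking exons in one species.

    Sequences are transcript-oriented; ``intron_index`` counts 1..n_exons-1
    from the 5' end of the transcript.  ``genomic_interval`` is
    (chromosome, start, end) in genomic coordinates.
    """

    gene_id: str
    species: str
    intron_index: int
    intron_seq: str
    upstream_exon_seq: str
    downstream_exon_seq: str
    genomic_interval: tuple[str, int, int]
    gene_span: tuple[str, int, int] = field(default=("", 0, 0))

    @property
    def intron_length(self) -> int:
        return len(self.intron_seq)

    @property
    def flank_lengths(self) -> tuple[int, int]:
        return len(self.upstream_exon_seq), len(self.downstream_exon_seq)

    @property
    def marker_suffix(self) -> str:
        return f"intron{self.intron_index}"


# ---------------------------------------------------------------------------
# annotation parsing
# ---------------------------------------------------------------------------


def _check_bounds(chrom_len: int, start: int, end: int, label: str) -> None:
    if start < 0 or end > chrom_len:
        raise ValueError(
            f"exon of {label} at [{start}, {end}) lies outside its "
            f"chromosome (length {chrom_len})"
        )


def _canonical(transcripts: dict[str, dict]) -> str:
    """Pick the canonical transcript: longest CDS span, then longest exon
    span, ties broken by lexicographic transcript id."""

    def key(tid: str) -> tuple[int, int, str]:
        t = transcripts[tid]
        exon_span = max(e for _, e in t["exons"]) - min(s for s, _ in t["exons"])
        return (-t["cds_span"], -exon_span, tid)

    return min(transcripts, key=key)


def parse_gff3(
    path: str | Path, genomes: GenomeSet, species: str
) -> list[GeneModel]:
    """Read a GFF3 file into one :class:`GeneModel` per gene.

    Genes with several transcripts are collapsed to a canonical one (longest
    CDS span, ties by transcript id).  Input coordinates are 1-based
    inclusive and converted on the fly.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in "+-":
            raise ValueError(
                f"unknown strand {gene.strand!r} on gene {gene.id}"
            )
        transcripts: dict[str, dict] = {}
        mrnas = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        if mrnas:
            for mrna in mrnas:
                exons = [
                    (f.start - 1, f.end)
                    for f in db.children(mrna, featuretype="exon", order_by="start")
                ]
                cds = [
                    (f.start - 1, f.end)
                    for f in db.children(mrna, featuretype="CDS", order_by="start")
                ]
                cds_span = (
                    max(e for _, e in cds) - min(s for s, _ in cds) if cds else 0
                )
                if exons:
                    transcripts[mrna.id] = {"exons": exons, "cds_span": cds_span}
        else:  # exons attached directly to the gene
            exons = [
                (f.start - 1, f.end)
                for f in db.children(gene, featuretype="exon", order_by="start")
            ]
            if exons:
                transcripts[gene.id] = {"exons": exons, "cds_span": 0}
        if not transcripts:
            logger.warning("gene %s has no exon features; skipped", gene.id)
            continue
        tid = _canonical(transcripts)
        exons = sorted(transcripts[tid]["exons"])
        chrom = genomes.get(species, gene.seqid)
        for s, e in exons:
            _check_bounds(chrom.length, s, e, f"gene {gene.id} ({tid})")
        if gene.strand == "-":
            exons = exons[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                transcript_id=tid,
                species=species,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
            )
        )
    return models


def parse_genbank(
    path: str | Path, genomes: GenomeSet, species: str
) -> list[GeneModel]:
    """Read gene models from a GenBank flat file (gene/mRNA features; a
    join() location of an mRNA supplies the exon list)."""
    models: list[GeneModel] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        chrom_id = rec.id
        chrom = genomes.get(species, chrom_id)
        mrnas_by_gene: dict[str, list] = {}
        for feat in rec.features:
            if feat.type != "mRNA":
                continue
            gene_id = feat.qualifiers.get(
                "gene", feat.qualifiers.get("locus_tag", ["?"])
            )[0]
            mrnas_by_gene.setdefault(gene_id, []).append(feat)
        for gene_id, feats in mrnas_by_gene.items():
            transcripts: dict[str, dict] = {}
            for i, feat in enumerate(feats):
                if feat.location.strand not in (1, -1):
                    raise ValueError(
                        f"unknown strand on mRNA of gene {gene_id}"
                    )
                tid = feat.qualifiers.get("transcript_id", [f"{gene_id}.t{i+1}"])[0]
                exons = sorted(
                    (int(p.start), int(p.end)) for p in feat.location.parts
                )
                transcripts[tid] = {"exons": exons, "cds_span": 0, "feat": feat}
            tid = _canonical(transcripts)
            feat = transcripts[tid]["feat"]
            exons = transcripts[tid]["exons"]
            for s, e in exons:
                _check_bounds(chrom.length, s, e, f"gene {gene_id} ({tid})")
            strand = "+" if feat.location.strand == 1 else "-"
            if strand == "-":
                exons = exons[::-1]
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tid,
                    species=species,
                    chromosome=chrom_id,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
    return models


def parse_annotation(
    path: str | Path, genomes: GenomeSet, species: str, fmt: str | None = None
) -> list[GeneModel]:
    """Dispatch to the GFF3 or GenBank reader by ``fmt`` or file extension."""
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "genbank" if ext in {".gb", ".gbk", ".genbank"} else "gff3"
    if fmt == "gff3":
        return parse_gff3(path, genomes, species)
    if fmt == "genbank":
        return parse_genbank(path, genomes, species)
    raise ValueError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------
# intron extraction
# ---------------------------------------------------------------------------


def extract_introns(
    model: GeneModel,
    genomes: GenomeSet,
    max_extract_len: int = DEFAULT_MAX_EXTRACT_LEN,
) -> list[IntronRecord]:
    """Extract every intron of a gene together with its flanking exons.

    Introns of length >= ``max_extract_len`` are dropped; zero-length gaps
    between annotated exons are skipped with a warning.  A single-exon gene
    yields an empty list.
    """
    if model.n_exons < 2:
        return []
    chrom = genomes.get(model.species, model.chromosome)
    residues = chrom.residues
    minus = model.strand == "-"

    def oriented(s: int, e: int) -> str:
        seq = residues[s:e]
        return revcomp(seq) if minus else seq

    gspan = model.span
    records: list[IntronRecord] = []
    for i in range(model.n_exons - 1):
        up, down = model.exons[i], model.exons[i + 1]
        if minus:
            istart, iend = down[1], up[0]
        else:
            istart, iend = up[1], down[0]
        ilen = iend - istart
        if ilen == 0:
            logger.warning(
                "gene %s: zero-length gap between exons %d and %d; skipped",
                model.gene_id, i + 1, i + 2,
            )
            continue
        if ilen >= max_extract_len:
            continue
        records.append(
            IntronRecord(
                gene_id=model.gene_id,
                species=model.species,
                intron_index=i + 1,
                intron_seq=oriented(istart, iend),
                upstream_exon_seq=oriented(*up),
                downstream_exon_seq=oriented(*down),
                genomic_interval=(model.chromosome, istart, iend),
                gene_span=(model.chromosome, gspan[0], gspan[1]),
            )
        )
    return records


def transcript_sequence(model: GeneModel, genomes: GenomeSet) -> str:
    """Concatenated exon+intron sequence of the gene span, transcript-oriented."""
    chrom = genomes.get(model.species, model.chromosome)
    s, e = model.span
    seq = chrom.residues[s:e]
    return revcomp(seq) if model.strand == "-" else seq


def write_records_fasta(records: Iterable[IntronRecord], path: str | Path) -> None:
    """Write intron records as multi-FASTA, headers ``species|gene|intronN``."""
    recs = [
        SeqRecord(
            Seq(r.intron_seq),
            id=f"{r.species}|{r.gene_id}|intron{r.intron_index}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_records_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA written by :func:`write_records_fasta`."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
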
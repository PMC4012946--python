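"""Single-copy screening: search flanking exons against whole genomes.

A built-in seed-and-extend ungapped search (word seeds, +1/-2 scoring,
X-drop extension, Karlin-Altschul E-values) stands in for an external
search tool; externally computed hits in 12-column tabular format can be
substituted.  A marker is rejected when either flanking exon of any species
has a significant hit outside its own gene's padded genomic span.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from ._iupac import revcomp
from .genome_io import GenomicSequence, GenomeSet
from .intron_filters import FilterConfig, OrthologousIntronSet

logger = logging.getLogger(__name__)

DEFAULT_WORD_SIZE = 11
# ungapped DNA Karlin-Altschul constants for +1/-2 scoring
DEFAULT_LAMBDA = 1.28
DEFAULT_KAPPA = 0.46
DEFAULT_XDROP = 20
#: slop around the source gene span inside which a hit counts as the self-hit
SELF_PAD = 1000


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    subject_chromosome: str
    subject_interval: tuple[int, int]  # 0-based half-open
    strand: str
    raw_score: float
    evalue: float


def karlin_altschul_evalue(
    score: float, m: int, n: int,
    lam: float = DEFAULT_LAMBDA, kappa: float = DEFAULT_KAPPA,
) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return kappa * m * n * math.exp(-lam * score)


class GenomeSearcher:
    """Word index over one species' chromosomes with ungapped extension."""

    def __init__(
        self,
        chromosomes: Iterable[GenomicSequence],
        word_size: int = DEFAULT_WORD_SIZE,
        lam: float = DEFAULT_LAMBDA,
        kappa: float = DEFAULT_KAPPA,
        xdrop: float = DEFAULT_XDROP,
    ) -> None:
        self.word_size = word_size
        self.lam = lam
        self.kappa = kappa
        self.xdrop = xdrop
        self.chromosomes = {c.chromosome: c.residues for c in chromosomes}
        self.total_length = sum(len(s) for s in self.chromosomes.values())
        self._index: dict[str, list[tuple[str, int]]] = {}
        w = word_size
        for chrom, seq in self.chromosomes.items():
            for i in range(len(seq) - w + 1):
                word = seq[i : i + w]
                if "N" in word:
                    continue
                self._index.setdefault(word, []).append((chrom, i))

    def _extend(
        self, query: str, subject: str, qpos: int, spos: int
    ) -> tuple[int, int, float]:
        """Ungapped X-drop extension of a seed; returns the subject interval
        and the score of the best-scoring extension."""
        w = self.word_size
        score = float(w)  # seed is an exact match, +1 per position

        def run(direction: int, q0: int, s0: int) -> tuple[int, float]:
            best, cur, off = 0, 0.0, 0
            i = 1
            while True:
                q, s = q0 + direction * i, s0 + direction * i
                if not (0 <= q < len(query) and 0 <= s < len(subject)):
                    break
                cur += 1.0 if query[q] == subject[s] else -2.0
                if cur > best:
                    best, off = cur, i
                if best - cur > self.xdrop:
                    break
                i += 1
            return off, best

        left_off, left_gain = run(-1, qpos, spos)
        right_off, right_gain = run(+1, qpos + w - 1, spos + w - 1)
        score += left_gain + right_gain
        return spos - left_off, spos + w + right_off, score

    def search(
        self,
        query: str,
        query_id: str = "query",
        evalue_max: float = 10.0,
    ) -> list[SearchHit]:
        """Seed on both strands, extend ungapped, merge overlaps, filter by E."""
        w = self.word_size
        query = query.upper()
        if len(query) < w:
            raise ValueError(
                f"query {query_id!r} shorter than word size ({len(query)} < {w})"
            )
        m = len(query)
        best: dict[tuple[str, str, int, int], float] = {}
        for strand, q in (("+", query), ("-", revcomp(query))):
            for i in range(m - w + 1):
                for chrom, j in self._index.get(q[i : i + w], ()):
                    subject = self.chromosomes[chrom]
                    s, e, score = self._extend(q, subject, i, j)
                    key = (chrom, strand, s, e)
                    if best.get(key, -1.0) < score:
                        best[key] = score
        # merge overlapping hits on the same chromosome/strand, keep the best
        hits: list[SearchHit] = []
        by_cs: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
        for (chrom, strand, s, e), score in best.items():
            by_cs.setdefault((chrom, strand), []).append((s, e, score))
        for (chrom, strand), ivs in by_cs.items():
            ivs.sort()
            merged: list[list[float]] = []
            for s, e, score in ivs:
                if merged and s < merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                    merged[-1][2] = max(merged[-1][2], score)
                else:
                    merged.append([s, e, score])
            for s, e, score in merged:
                ev = karlin_altschul_evalue(
                    score, m, self.total_length, self.lam, self.kappa
                )
                if ev <= evalue_max:
                    hits.append(
                        SearchHit(
                            query_id=query_id,
                            subject_chromosome=chrom,
                            subject_interval=(int(s), int(e)),
                            strand=strand,
                            raw_score=score,
                            evalue=ev,
                        )
                    )
        hits.sort(key=lambda h: h.evalue)
        return hits


def seed_extend_search(
    query: str,
    genome: Iterable[GenomicSequence],
    word_size: int = DEFAULT_WORD_SIZE,
    evalue_max: float = 10.0,
    **kwargs,
) -> list[SearchHit]:
    """One-shot convenience wrapper around :class:`GenomeSearcher`."""
    return GenomeSearcher(genome, word_size=word_size, **kwargs).search(
        query, evalue_max=evalue_max
    )


def read_tabular_hits(path: str | Path) -> list[SearchHit]:
    """Read 12-column tabular hits (query, subject, pident, length, mismatch,
    gapopen, qstart, qend, sstart, send, evalue, bitscore); coordinates are
    normalized to 0-based half-open, strand inferred from sstart/send order."""
    hits: list[SearchHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                qid, subj = fields[0], fields[1]
                sstart, send = int(fields[8]), int(fields[9])
                evalue, bitscore = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if sstart <= send:
                strand, lo, hi = "+", sstart, send
            else:
                strand, lo, hi = "-", send, sstart
            hits.append(
                SearchHit(
                    query_id=qid,
                    subject_chromosome=subj,
                    subject_interval=(lo - 1, hi),
                    strand=strand,
                    raw_score=bitscore,
                    evalue=evalue,
                )
            )
    return hits


def write_tabular_hits(hits: Sequence[SearchHit], query_lengths: Mapping[str, int],
                       path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (inverse of the reader)."""
    lines = []
    for h in hits:
        lo, hi = h.subject_interval
        sstart, send = (lo + 1, hi) if h.strand == "+" else (hi, lo + 1)
        qlen = query_lengths.get(h.query_id, hi - lo)
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    h.query_id, h.subject_chromosome, 100.0, hi - lo, 0, 0,
                    1, qlen, sstart, send, f"{h.evalue:.3g}", h.raw_score,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# hit sources and the single-copy verdict
# ---------------------------------------------------------------------------


class HitSource(Protocol):
    def hits(self, species: str, query_seq: str, query_id: str,
             evalue_max: float) -> "list[SearchHit] | None":
        """Significant hits of one flank in one species' genome; None when
        the species' genome (or hit file) is unavailable."""


class GenomeHitSource:
    """Built-in search of each species' own genome, indexed once."""

    def __init__(self, genomes: GenomeSet, word_size: int = DEFAULT_WORD_SIZE,
                 **kwargs) -> None:
        self._genomes = genomes
        self._word_size = word_size
        self._kwargs = kwargs
        self._searchers: dict[str, GenomeSearcher] = {}

    def _searcher(self, species: str) -> "GenomeSearcher | None":
        if species not in self._searchers:
            chroms = self._genomes.chromosomes(species)
            if not chroms:
                return None
            self._searchers[species] = GenomeSearcher(
                chroms, word_size=self._word_size, **self._kwargs
            )
        return self._searchers[species]

    def hits(self, species, query_seq, query_id, evalue_max):
        searcher = self._searcher(species)
        if searcher is None:
            return None
        return searcher.search(query_seq, query_id=query_id, evalue_max=evalue_max)


class TabularHitSource:
    """Externally computed hits, one tabular file per species; queries are
    matched by the ``species|gene|intronN|up`` / ``...|down`` id scheme."""

    def __init__(self, files: Mapping[str, "str | Path"]) -> None:
        self._hits: dict[str, dict[str, list[SearchHit]]] = {}
        for species, path in files.items():
            per_query: dict[str, list[SearchHit]] = {}
            for h in read_tabular_hits(path):
                per_query.setdefault(h.query_id, []).append(h)
            self._hits[species] = per_query

    def hits(self, species, query_seq, query_id, evalue_max):
        if species not in self._hits:
            return None
        return [
            h for h in self._hits[species].get(query_id, []) if h.evalue <= evalue_max
        ]


def flank_query_id(rec, side: str) -> str:
    return f"{rec.species}|{rec.gene_id}|intron{rec.intron_index}|{side}"


def single_copy_filter(
    iset: OrthologousIntronSet,
    hit_source: HitSource,
    cfg: FilterConfig,
    self_pad: int = SELF_PAD,
) -> tuple[bool, str | None]:
    """Reject the marker when any flanking exon of any species hits the
    genome significantly outside the source gene's padded span.

    Exon sequences (never the intron) are the queries; the self-hit at the
    gene's own locus does not count as a duplicate.
    """
    for species, rec in iset.records.items():
        chrom, gstart, gend = rec.gene_span
        for side, seq in (
            ("up", rec.upstream_exon_seq),
            ("down", rec.downstream_exon_seq),
        ):
            qid = flank_query_id(rec, side)
            found = hit_source.hits(species, seq, qid, cfg.evalue_threshold)
            if found is None:
                return False, "missing_genome"
            for h in found:
                if h.subject_chromosome == chrom:
                    s, e = h.subject_interval
                    if s < gend + self_pad and e > gstart - self_pad:
                        continue  # self locus
                return False, "single_copy"
    return True, None


def single_copy_stage(hit_source: HitSource, self_pad: int = SELF_PAD):
    """Cascade stage wrapping :func:`single_copy_filter`."""

    def stage(sets, cfg):
        kept, rejections = [], {}
        for s in sets:
            ok, reason = single_copy_filter(s, hit_source, cfg, self_pad=self_pad)
            if ok:
                kept.append(s)
            else:
                rejections[s.marker_id] = reason
        return kept, rejections

    return stage
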
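"""Multiple alignment of orthologous intron sets and block-based cleaning.

The aligner is pluggable: an external command template ("mafft-style") can
be supplied, and a built-in progressive aligner (match +1 / mismatch -1 /
gap -2, similarity-ranked join order) keeps the package self-contained.
Poorly aligned columns are discarded with a relaxed Gblocks-style block
filter.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._iupac import GAP

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows over an ordered taxon list."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)

    def select_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(
            taxa=self.taxa,
            rows=tuple("".join(r[i] for i in cols) for r in self.rows),
        )

    def degap(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(r), id=t, description="")
            for t, r in zip(self.taxa, self.rows)
        ]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa=tuple(taxa), rows=tuple(rows))


@dataclass(frozen=True)
class BlockMap:
    """Columns kept by the block filter, as ascending original indices."""

    kept_columns: tuple[int, ...]
    n_columns: int

    def __post_init__(self) -> None:
        if any(a >= b for a, b in zip(self.kept_columns, self.kept_columns[1:])):
            raise ValueError("kept_columns must be strictly increasing")

    @property
    def removed_fraction(self) -> float:
        if self.n_columns == 0:
            return 1.0
        return 1.0 - len(self.kept_columns) / self.n_columns

    def to_tsv(self, path: str | Path) -> None:
        lines = ["original_column\tkept_rank"]
        lines += [f"{c}\t{i}" for i, c in enumerate(self.kept_columns)]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

MATCH, MISMATCH, GAP_SCORE = 1.0, -1.0, -2.0


def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_SCORE
    al.extend_gap_score = GAP_SCORE
    return al


def pairwise_align(a: str, b: str) -> tuple[str, str, float]:
    """Global Needleman-Wunsch under the built-in scores."""
    al = _aligner()
    best = al.align(a, b)[0]
    return str(best[0]), str(best[1]), best.score


def _profile_consensus(rows: Sequence[str]) -> str:
    cols = []
    for i in range(len(rows[0])):
        counts: dict[str, int] = {}
        for r in rows:
            ch = r[i]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        cols.append(max(sorted(counts), key=counts.get) if counts else "N")
    return "".join(cols)


def _project(rows: list[str], gapped_consensus: str) -> list[str]:
    """Insert gap columns into profile rows wherever the aligned consensus
    acquired a gap."""
    out = [""] * len(rows)
    j = 0
    for ch in gapped_consensus:
        if ch == GAP:
            for k in range(len(rows)):
                out[k] += GAP
        else:
            for k in range(len(rows)):
                out[k] += rows[k][j]
            j += 1
    return out


def align_set(
    seqs: Mapping[str, str], engine: "str | None" = None
) -> Alignment:
    """Align one orthologous set.

    ``engine`` is an external command template with ``{in}`` and ``{out}``
    placeholders (e.g. ``"mafft --auto {in} > {out}"``); ``None`` selects the
    built-in progressive aligner.
    """
    if len(seqs) < 2:
        raise ValueError("align_set requires at least 2 sequences")
    taxa = list(seqs)
    if engine is not None:
        return _align_external(seqs, engine)

    cleaned = {t: seqs[t].upper().replace(GAP, "") for t in taxa}
    # similarity-ranked join order: greedy, seeded with the best-scoring pair
    scores: dict[tuple[str, str], float] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            scores[(a, b)] = scores[(b, a)] = pairwise_align(
                cleaned[a], cleaned[b]
            )[2]
    if len(taxa) == 2:
        a, b = taxa
        ra, rb, _ = pairwise_align(cleaned[a], cleaned[b])
        return Alignment(taxa=tuple(taxa), rows=(ra, rb))

    first, second = max(
        ((a, b) for (a, b) in scores if a < b), key=lambda p: scores[p]
    )
    ra, rb, _ = pairwise_align(cleaned[first], cleaned[second])
    profile_taxa, profile_rows = [first, second], [ra, rb]
    remaining = [t for t in taxa if t not in (first, second)]
    remaining.sort(
        key=lambda t: -max(scores[(t, p)] for p in profile_taxa)
    )
    while remaining:
        t = remaining.pop(0)
        cons = _profile_consensus(profile_rows)
        gc, gt, _ = pairwise_align(cons, cleaned[t])
        profile_rows = _project(profile_rows, gc)
        profile_taxa.append(t)
        profile_rows.append(gt)
    order = [profile_taxa.index(t) for t in taxa]
    return Alignment(
        taxa=tuple(taxa), rows=tuple(profile_rows[i] for i in order)
    )


def _align_external(seqs: Mapping[str, str], engine: str) -> Alignment:
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        recs = [
            SeqRecord(Seq(s.replace(GAP, "")), id=t, description="")
            for t, s in seqs.items()
        ]
        SeqIO.write(recs, str(fin), "fasta")
        cmd = engine.replace("{in}", shlex.quote(str(fin))).replace(
            "{out}", shlex.quote(str(fout))
        )
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"external aligner failed (exit {proc.returncode}): {proc.stderr}"
            )
        if not fout.exists() or fout.stat().st_size == 0:
            fout.write_text(proc.stdout)
        aln = Alignment.from_fasta(fout)
    by_taxon = dict(zip(aln.taxa, aln.rows))
    return Alignment(
        taxa=tuple(seqs), rows=tuple(by_taxon[t] for t in seqs)
    )


# ---------------------------------------------------------------------------
# block cleaning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockParams:
    """Relaxed block-filter settings.

    ``conserved_min``/``flank_min`` default to floor(N/2)+1 identical
    residues; a kept column may be gapped in up to ``max_gap_frac`` of the
    taxa; runs of more than ``max_contiguous`` nonconserved columns are cut;
    trimmed blocks shorter than ``min_block_len`` are dropped.
    """

    conserved_min: "int | None" = None
    flank_min: "int | None" = None
    max_contiguous: int = 8
    min_block_len: int = 5
    max_gap_frac: float = 0.5

    def resolve(self, n_taxa: int) -> tuple[int, int, int]:
        default = n_taxa // 2 + 1
        cons = self.conserved_min if self.conserved_min is not None else default
        flank = self.flank_min if self.flank_min is not None else default
        gap_allowed = int(n_taxa * self.max_gap_frac)
        return cons, flank, gap_allowed


def _classify(column: str, cons: int, flank: int, gap_allowed: int) -> str:
    """'bad' (gap rule), 'flank' (highly conserved), 'cons', or 'non'."""
    gaps = column.count(GAP)
    if gaps > gap_allowed:
        return "bad"
    counts: dict[str, int] = {}
    for ch in column:
        if ch != GAP:
            counts[ch] = counts.get(ch, 0) + 1
    top = max(counts.values(), default=0)
    if top >= flank:
        return "flank"
    if top >= cons:
        return "cons"
    return "non"


def _clean_pass(
    aln: Alignment, cols: list[int], params: BlockParams
) -> list[int]:
    n_taxa = len(aln.taxa)
    cons, flank, gap_allowed = params.resolve(n_taxa)
    status = [
        _classify(aln.column(c), cons, flank, gap_allowed) for c in cols
    ]
    # cut runs of > max_contiguous nonconserved columns, splitting blocks
    segments: list[list[int]] = []
    current: list[int] = []
    run: list[int] = []
    for pos, st in enumerate(status):
        if st in ("non", "bad"):
            run.append(pos)
        else:
            if len(run) > params.max_contiguous:
                if current:
                    segments.append(current)
                current = []
            else:
                current.extend(run)
            run = []
            current.append(pos)
    if len(run) <= params.max_contiguous:
        current.extend(run)
    if current:
        segments.append(current)
    kept: list[int] = []
    for seg in segments:
        # trim ends to flank-quality columns
        while seg and status[seg[0]] != "flank":
            seg.pop(0)
        while seg and status[seg[-1]] != "flank":
            seg.pop()
        if len(seg) < params.min_block_len:
            continue
        kept.extend(p for p in seg if status[p] != "bad")
    return [cols[p] for p in kept]


def clean_blocks(
    aln: Alignment, params: BlockParams | None = None
) -> tuple[Alignment, BlockMap]:
    """Discard poorly aligned columns with the relaxed block filter.

    Iterates the column classification to a fixed point so that the result
    is idempotent.
    """
    if len(aln.taxa) < 2:
        raise ValueError("clean_blocks requires an alignment of >= 2 taxa")
    params = params or BlockParams()
    cols = list(range(aln.n_columns))
    while True:
        new = _clean_pass(aln, cols, params)
        if new == cols:
            break
        cols = new
        if not cols:
            break
    return (
        aln.select_columns(cols),
        BlockMap(kept_columns=tuple(cols), n_columns=aln.n_columns),
    )
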
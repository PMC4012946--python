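"""Degenerate, exon-anchored primer design from flanking-exon alignments.

Primers are taken from consensus windows of the exon alignments at the
intron-proximal ends: the forward primer from the upstream exon (reported
as the consensus itself) and the reverse primer from the downstream exon
(reported reverse-complemented).  Constraints follow EPIC practice: length
20-25 bp, degeneracy (number of encoded unambiguous sequences) strictly
below 48, and similar melting temperatures within a pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from ._iupac import GAP, base_set, revcomp, set_code
from .msa_clean import Alignment


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 20
    max_len: int = 25
    max_degeneracy: int = 48  # exclusive bound
    max_pair_tm_gap: float = 5.0  # degC between pair mean Tm's
    search_window: int = 120  # alignment columns from the intron-proximal exon end

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.max_degeneracy < 1:
            raise ValueError("max_degeneracy must be >= 1")


@dataclass(frozen=True)
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    degeneracies: tuple[int, int]
    tm_ranges: tuple[tuple[float, float], tuple[float, float]]
    window_positions: tuple[tuple[int, int], tuple[int, int]]
    predicted_amplicon: int

    @property
    def lengths(self) -> tuple[int, int]:
        return len(self.forward_seq), len(self.reverse_seq)


@dataclass(frozen=True)
class PrimerDesignResult:
    pairs: tuple[PrimerPair, ...]
    diagnostic: "str | None" = None


def iupac_consensus(column: Sequence[str]) -> str:
    """Minimal IUPAC code covering the bases observed in one column.

    Observed ambiguity codes are expanded before taking the union; a column
    of only gaps yields the gap code.
    """
    if not column:
        raise ValueError("empty column")
    bases: set[str] = set()
    for ch in column:
        if ch == GAP:
            continue
        bases |= base_set(ch)
    if not bases:
        return GAP
    return set_code(frozenset(bases))


def degeneracy(seq: str) -> int:
    """Number of unambiguous sequences a degenerate primer encodes."""
    total = 1
    for ch in seq:
        total *= len(base_set(ch))
    return total


def melting_temp(seq: str) -> tuple[float, float]:
    """(min, max) Wallace-like Tm = 64.9 + 41*(GC - 16.4)/L over the AT-most
    and GC-most expansions of each degenerate position."""
    if len(seq) < 14:
        raise ValueError("melting_temp requires length >= 14")
    L = len(seq)
    gc_min = gc_max = 0
    for ch in seq:
        bases = base_set(ch)
        gc_min += 1 if bases <= {"G", "C"} else 0
        gc_max += 1 if bases & {"G", "C"} else 0
    tm = lambda gc: 64.9 + 41.0 * (gc - 16.4) / L
    return tm(gc_min), tm(gc_max)


@dataclass(frozen=True)
class _Window:
    consensus: str
    start: int  # alignment column of the window start
    end: int
    distance_to_intron: int
    deg: int
    tm_range: tuple[float, float]


def _enumerate_windows(
    aln: Alignment, constraints: PrimerConstraints, side: str
) -> tuple[list[_Window], "str | None"]:
    """All feasible consensus windows at the intron-proximal end of one exon
    alignment.  ``side`` is 'upstream' (intron at the right edge) or
    'downstream' (intron at the left edge)."""
    ncol = aln.n_columns
    if ncol < constraints.min_len:
        return [], "window too short"
    if side == "upstream":
        region_lo, region_hi = max(0, ncol - constraints.search_window), ncol
    else:
        region_lo, region_hi = 0, min(ncol, constraints.search_window)
    consensus_cols = [iupac_consensus(aln.column(i)) for i in range(ncol)]
    windows: list[_Window] = []
    saw_gap = saw_deg = False
    for length in range(constraints.min_len, constraints.max_len + 1):
        for start in range(region_lo, region_hi - length + 1):
            end = start + length
            cols = consensus_cols[start:end]
            if GAP in cols or any(
                GAP in aln.column(i) for i in range(start, end)
            ):
                saw_gap = True
                continue
            cons = "".join(cols)
            deg = degeneracy(cons)
            if deg >= constraints.max_degeneracy:
                saw_deg = True
                continue
            dist = (ncol - end) if side == "upstream" else start
            windows.append(
                _Window(
                    consensus=cons,
                    start=start,
                    end=end,
                    distance_to_intron=dist,
                    deg=deg,
                    tm_range=melting_temp(cons),
                )
            )
    if windows:
        return windows, None
    if saw_deg:
        return [], "degeneracy"
    if saw_gap:
        return [], "gap columns"
    return [], "window too short"


def design_pair(
    upstream_aln: Alignment,
    downstream_aln: Alignment,
    constraints: PrimerConstraints | None = None,
    intron_length_ref: int = 0,
    max_pairs: int = 10,
) -> PrimerDesignResult:
    """Enumerate, score and pair consensus windows from the two exon
    alignments.

    Windows are ranked by (degeneracy ascending, distance to the intron
    ascending); a pair additionally requires the mean-Tm gap to be within
    ``constraints.max_pair_tm_gap``.  The reverse primer is the
    reverse-complemented downstream consensus.  The predicted amplicon is
    the reference intron length plus each window's offset from the intron.
    """
    constraints = constraints or PrimerConstraints()
    if not upstream_aln.rows or not downstream_aln.rows:
        raise ValueError("both exon alignments must be nonempty")
    fwd, fdiag = _enumerate_windows(upstream_aln, constraints, "upstream")
    rev, rdiag = _enumerate_windows(downstream_aln, constraints, "downstream")
    if not fwd or not rev:
        parts = []
        if fdiag:
            parts.append(f"forward: {fdiag}")
        if rdiag:
            parts.append(f"reverse: {rdiag}")
        return PrimerDesignResult(pairs=(), diagnostic="; ".join(parts))
    key = lambda w: (w.deg, w.distance_to_intron)
    fwd.sort(key=key)
    rev.sort(key=key)
    pairs: list[PrimerPair] = []
    for f in fwd:
        for r in rev:
            mean_f = sum(f.tm_range) / 2
            mean_r = sum(r.tm_range) / 2
            if abs(mean_f - mean_r) > constraints.max_pair_tm_gap:
                continue
            pairs.append(
                PrimerPair(
                    forward_seq=f.consensus,
                    reverse_seq=revcomp(r.consensus),
                    degeneracies=(f.deg, r.deg),
                    tm_ranges=(f.tm_range, r.tm_range),
                    window_positions=((f.start, f.end), (r.start, r.end)),
                    predicted_amplicon=(
                        intron_length_ref
                        + f.distance_to_intron
                        + r.distance_to_intron
                    ),
                )
            )
            if len(pairs) >= max_pairs * 4:
                break
        if len(pairs) >= max_pairs * 4:
            break
    if not pairs:
        return PrimerDesignResult(pairs=(), diagnostic="pair Tm gap")
    pairs.sort(
        key=lambda p: (
            p.degeneracies[0] * p.degeneracies[1],
            p.predicted_amplicon,
        )
    )
    return PrimerDesignResult(pairs=tuple(pairs[:max_pairs]), diagnostic=None)


def write_primers_tsv(
    entries: Sequence[tuple[str, int, PrimerPair]], path: "str | Path"
) -> None:
    """Write a primer table: marker, reference intron length, primers."""
    lines = ["marker\tintron_length_ref\tforward\treverse\tdegeneracy_fwd\tdegeneracy_rev"]
    for marker, ilen, pair in entries:
        lines.append(
            f"{marker}\t{ilen}\t{pair.forward_seq}\t{pair.reverse_seq}\t"
            f"{pair.degeneracies[0]}\t{pair.degeneracies[1]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
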
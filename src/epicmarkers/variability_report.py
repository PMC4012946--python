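"""Divergence, heterozygosity and indel statistics for amplified loci, and
summaries of a PCR validation matrix (species x marker amplification
outcomes of a touch-down protocol).

The difference rule for a pair of sequenced alleles treats a column as a
difference only when the two residues' IUPAC base sets are disjoint, so a
heterozygous position sharing an allele with the other species never
inflates divergence.  A strict-mismatch alternative is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._iupac import GAP, TWOFOLD, base_set
from .msa_clean import Alignment

logger = logging.getLogger(__name__)

RAMPS = ("65-55", "65-60", "65-50")
FAIL = "fail"


@dataclass(frozen=True)
class LocusVariability:
    marker_id: str
    het_positions: tuple[int, ...]  # per species, in matrix species order
    alignment_length: int
    n_differences: int
    indels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_differences > self.alignment_length:
            raise ValueError("n_differences exceeds alignment_length")
        if any(h < 0 for h in self.het_positions):
            raise ValueError("negative heterozygous-position count")
        if any(l < 1 for l in self.indels):
            raise ValueError("indel lengths must be >= 1")


@dataclass(frozen=True)
class ValidationMatrix:
    species: tuple[str, ...]
    markers: tuple[str, ...]
    outcome: tuple[tuple[str, ...], ...]  # rows = species

    def __post_init__(self) -> None:
        if len(self.outcome) != len(self.species) or any(
            len(r) != len(self.markers) for r in self.outcome
        ):
            raise ValueError("outcome grid does not match species x markers")
        bad = {c for row in self.outcome for c in row} - set(RAMPS) - {FAIL}
        if bad:
            raise ValueError(f"unknown outcome labels {sorted(bad)}")


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------


def pairwise_divergence(
    aln: Alignment, rule: str = "disjoint"
) -> tuple[int, int, float]:
    """(n_differences, alignment_length, rate) for a two-sequence alignment.

    Under the default ``disjoint`` rule a column counts as a difference iff
    both residues are non-gap and their IUPAC sets share no base; ``strict``
    counts any non-gap character mismatch.
    """
    if len(aln.rows) != 2:
        raise ValueError("pairwise_divergence requires exactly 2 rows")
    a, b = aln.rows
    n_diff = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        if rule == "disjoint":
            if not (base_set(x) & base_set(y)):
                n_diff += 1
        elif rule == "strict":
            if x != y:
                n_diff += 1
        else:
            raise ValueError(f"unknown difference rule {rule!r}")
    length = aln.n_columns
    return n_diff, length, (n_diff / length if length else 0.0)


def heterozygous_sites(seq: str) -> int:
    """Count of two-fold ambiguity codes (R,Y,S,W,K,M); N and three-fold
    codes are not evidence of heterozygosity."""
    return sum(1 for ch in seq.upper() if ch in TWOFOLD)


def indel_tally(aln: Alignment) -> list[int]:
    """Lengths of maximal gap runs in either row of a 2-sequence alignment;
    columns gapped in both rows are dropped first (with a warning)."""
    if len(aln.rows) != 2:
        raise ValueError("indel_tally requires exactly 2 rows")
    a, b = aln.rows
    keep = [i for i in range(aln.n_columns) if not (a[i] == GAP and b[i] == GAP)]
    if len(keep) != aln.n_columns:
        logger.warning(
            "dropped %d columns gapped in both rows before indel tally",
            aln.n_columns - len(keep),
        )
    a = "".join(a[i] for i in keep)
    b = "".join(b[i] for i in keep)
    lengths: list[int] = []
    for row in (a, b):
        run = 0
        for ch in row + "#":  # sentinel flushes a trailing run
            if ch == GAP:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
    return lengths


# ---------------------------------------------------------------------------
# cross-locus and validation summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossLocusSummary:
    total_length: int
    total_differences: int
    mean_rate: float
    n_het_loci: int


def cross_locus_summary(loci: Sequence[LocusVariability]) -> CrossLocusSummary:
    """Pooled divergence and heterozygosity over a set of sequenced loci.

    ``n_het_loci`` counts (marker, species) sequence loci with at least one
    heterozygous position.
    """
    if not loci:
        raise ValueError("cross_locus_summary requires at least one locus")
    total_length = sum(l.alignment_length for l in loci)
    total_diff = sum(l.n_differences for l in loci)
    n_het = sum(1 for l in loci for h in l.het_positions if h >= 1)
    return CrossLocusSummary(
        total_length=total_length,
        total_differences=total_diff,
        mean_rate=total_diff / total_length if total_length else 0.0,
        n_het_loci=n_het,
    )


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ValidationSummary:
    n_reactions: int
    n_success: int
    success_rate_pct: int
    ramp_counts: dict[str, int]
    per_species_rate_pct: dict[str, int]
    per_marker_species_count: dict[str, int]
    min_species_rate_pct: int
    max_species_rate_pct: int


def summarize_validation(matrix: ValidationMatrix) -> ValidationSummary:
    """Success totals, per-ramp counts, per-species rates and per-marker
    species counts of a PCR validation grid."""
    n_reactions = len(matrix.species) * len(matrix.markers)
    ramp_counts = {r: 0 for r in RAMPS}
    per_species_success = {sp: 0 for sp in matrix.species}
    per_marker = {m: 0 for m in matrix.markers}
    for sp, row in zip(matrix.species, matrix.outcome):
        for m, cell in zip(matrix.markers, row):
            if cell == FAIL:
                continue
            ramp_counts[cell] += 1
            per_species_success[sp] += 1
            per_marker[m] += 1
    n_success = sum(ramp_counts.values())
    n_markers = len(matrix.markers)
    per_species_rate = {
        sp: _round_half_away(100.0 * k / n_markers)
        for sp, k in per_species_success.items()
    }
    return ValidationSummary(
        n_reactions=n_reactions,
        n_success=n_success,
        success_rate_pct=_round_half_away(100.0 * n_success / n_reactions),
        ramp_counts=ramp_counts,
        per_species_rate_pct=per_species_rate,
        per_marker_species_count=per_marker,
        min_species_rate_pct=min(per_species_rate.values()),
        max_species_rate_pct=max(per_species_rate.values()),
    )


# ---------------------------------------------------------------------------
# TSV I/O and packaged fixtures (transcriptions of published validation and
# variability tables for two Microtus sister species)
# ---------------------------------------------------------------------------


def read_variability_tsv(path: "str | Path") -> list[LocusVariability]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    het_cols = [c for c in df.columns if c.startswith("het_")]
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        indels = tuple(
            int(x) for x in str(d.get("indels", "")).split(";") if x
        )
        out.append(
            LocusVariability(
                marker_id=d["marker_id"],
                het_positions=tuple(int(d[c]) for c in het_cols),
                alignment_length=int(d["alignment_length"]),
                n_differences=int(d["n_differences"]),
                indels=indels,
            )
        )
    return out


def write_variability_tsv(
    loci: Sequence[LocusVariability], species: Sequence[str], path: "str | Path"
) -> None:
    cols = ["marker_id"] + [f"het_{sp}" for sp in species] + [
        "alignment_length", "n_differences", "indels",
    ]
    lines = ["\t".join(cols)]
    for l in loci:
        lines.append(
            "\t".join(
                [l.marker_id]
                + [str(h) for h in l.het_positions]
                + [str(l.alignment_length), str(l.n_differences),
                   ";".join(str(x) for x in l.indels)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_validation_tsv(path: "str | Path") -> ValidationMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    markers = tuple(df.columns[1:])
    species = tuple(df.iloc[:, 0])
    outcome = tuple(tuple(df.iloc[i, 1:]) for i in range(len(df)))
    return ValidationMatrix(species=species, markers=markers, outcome=outcome)


def write_validation_tsv(matrix: ValidationMatrix, path: "str | Path") -> None:
    lines = ["species\t" + "\t".join(matrix.markers)]
    for sp, row in zip(matrix.species, matrix.outcome):
        lines.append(sp + "\t" + "\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("epicmarkers").joinpath("data", name)))


def load_microtus_variability() -> list[LocusVariability]:
    """Packaged per-locus variability table for the two Microtus sister
    species (nine sequenced introns)."""
    return read_variability_tsv(_data_path("microtus_variability.tsv"))


def load_rodent_validation() -> ValidationMatrix:
    """Packaged PCR validation grid: 10 intron markers x 11 rodent species."""
    return read_validation_tsv(_data_path("rodent_validation.tsv"))


def load_marker_primers() -> pd.DataFrame:
    """Packaged table of the ten designed marker primer pairs."""
    return pd.read_csv(_data_path("marker_primers.tsv"), sep="\t", dtype=str)


def format_report(summary: ValidationSummary, cross: CrossLocusSummary) -> str:
    """Human-readable combined report."""
    lines = [
        f"PCR validation: {summary.n_success}/{summary.n_reactions} positive "
        f"reactions ({summary.success_rate_pct}%)",
        "  per ramp: "
        + ", ".join(f"{r}: {summary.ramp_counts[r]}" for r in RAMPS),
        f"  per-species success rate: {summary.min_species_rate_pct}%"
        f" - {summary.max_species_rate_pct}%",
        f"Sequenced-locus variability: {cross.total_differences} differences "
        f"over {cross.total_length} aligned positions "
        f"({100 * cross.mean_rate:.2f}%)",
        f"  heterozygous sequence loci: {cross.n_het_loci}",
    ]
    return "\n".join(lines)
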
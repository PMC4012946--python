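"""Crossing pairwise ortholog tables into one-to-one four-species quartets.

The anchor order is (reference rodent, second rodent, third rodent,
outgroup).  A quartet is emitted iff the reference gene has exactly one
one-to-one partner in each of the three pairwise tables, and no partner gene
is claimed by two different reference genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import GeneModel

logger = logging.getLogger(__name__)

ONE2ONE = "ortholog_one2one"


@dataclass(frozen=True)
class OrthologTable:
    """Pairwise homology rows (gene_a, gene_b, homology_type) between two species."""

    species_pair: tuple[str, str]
    rows: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        pairs = [(a, b) for a, b, _ in self.rows]
        if len(pairs) != len(set(pairs)):
            raise ValueError(
                f"duplicate (gene_a, gene_b) rows in table {self.species_pair}"
            )

    @classmethod
    def from_tsv(cls, path: str | Path, species_pair: tuple[str, str]) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_a", "gene_b", "homology_type"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        rows = tuple(
            (r.gene_a, r.gene_b, r.homology_type) for r in df.itertuples()
        )
        return cls(species_pair=species_pair, rows=rows)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(list(self.rows), columns=["gene_a", "gene_b", "homology_type"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class OrthologQuartet:
    """One-to-one gene mapping across the four anchor species."""

    genes: tuple[tuple[str, str], ...]  # ((species, gene_id), ...) in anchor order
    n_exons: int | None = None  # shared exon count, set by the exon filter

    def gene(self, species: str) -> str:
        for sp, g in self.genes:
            if sp == species:
                return g
        raise KeyError(f"species {species!r} not in quartet")

    @property
    def reference_gene(self) -> str:
        return self.genes[0][1]

    def as_dict(self) -> dict[str, str]:
        return dict(self.genes)


def _one2one_map(
    table: OrthologTable,
    ref: str,
    other: str,
    label: str,
) -> dict[str, str]:
    """ref-gene -> partner map from the one-to-one rows of one table,
    dropping reference genes with several partners and partners claimed by
    several reference genes."""
    if table.species_pair == (ref, other):
        rows = [(a, b) for a, b, t in table.rows if t == label]
    elif table.species_pair == (other, ref):
        rows = [(b, a) for a, b, t in table.rows if t == label]
    else:
        raise ValueError(
            f"table for pair {table.species_pair} does not link {ref!r} and {other!r}"
        )
    partners: dict[str, set[str]] = {}
    claimed: dict[str, set[str]] = {}
    for a, b in rows:
        partners.setdefault(a, set()).add(b)
        claimed.setdefault(b, set()).add(a)
    return {
        a: next(iter(bs))
        for a, bs in partners.items()
        if len(bs) == 1 and len(claimed[next(iter(bs))]) == 1
    }


def cross_tables(
    tables: Sequence[OrthologTable],
    anchor_order: Sequence[str],
    one2one_label: str = ONE2ONE,
) -> list[OrthologQuartet]:
    """Intersect the three reference-anchored tables into quartets."""
    if len(anchor_order) != 4:
        raise ValueError(f"anchor_order must name 4 species, got {len(anchor_order)}")
    ref = anchor_order[0]
    maps: dict[str, dict[str, str]] = {}
    for other in anchor_order[1:]:
        table = next(
            (
                t
                for t in tables
                if set(t.species_pair) == {ref, other}
            ),
            None,
        )
        if table is None:
            raise ValueError(f"no ortholog table for species pair ({ref}, {other})")
        maps[other] = _one2one_map(table, ref, other, one2one_label)
    quartets = []
    for gene in sorted(set.intersection(*(set(m) for m in maps.values()))):
        genes = ((ref, gene),) + tuple(
            (other, maps[other][gene]) for other in anchor_order[1:]
        )
        quartets.append(OrthologQuartet(genes=genes))
    return quartets


def equal_exon_count_filter(
    quartets: Iterable[OrthologQuartet],
    models: Mapping[tuple[str, str], GeneModel],
) -> tuple[list[OrthologQuartet], dict[str, str]]:
    """Keep quartets whose four genes all have the same exon count.

    ``models`` is keyed by (species, gene_id).  Quartets with a gene lacking
    a model are dropped with a warning and reported separately from genuine
    filter rejections.  Survivors carry the shared exon count.

    Returns (survivors, rejections) where rejections maps the reference gene
    id to either ``"exon_count"`` or ``"missing_model"``.
    """
    kept: list[OrthologQuartet] = []
    rejections: dict[str, str] = {}
    for q in quartets:
        counts = []
        missing = False
        for sp, g in q.genes:
            m = models.get((sp, g))
            if m is None:
                logger.warning(
                    "quartet %s: gene %s (%s) has no gene model; quartet dropped",
                    q.reference_gene, g, sp,
                )
                missing = True
                break
            counts.append(m.n_exons)
        if missing:
            rejections[q.reference_gene] = "missing_model"
        elif len(set(counts)) != 1:
            rejections[q.reference_gene] = "exon_count"
        else:
            kept.append(OrthologQuartet(genes=q.genes, n_exons=counts[0]))
    return kept, rejections


def write_quartets_tsv(quartets: Sequence[OrthologQuartet], path: str | Path) -> None:
    if not quartets:
        Path(path).write_text("")
        return
    species = [sp for sp, _ in quartets[0].genes]
    df = pd.DataFrame(
        [[q.gene(sp) for sp in species] + [q.n_exons] for q in quartets],
        columns=species + ["n_exons"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_quartets_tsv(path: str | Path) -> list[OrthologQuartet]:
    df = pd.read_csv(path, sep="\t", dtype={"n_exons": "Int64"})
    species = [c for c in df.columns if c != "n_exons"]
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        n = d.pop("n_exons", None)
        out.append(
            OrthologQuartet(
                genes=tuple((sp, str(d[sp])) for sp in species),
                n_exons=None if pd.isna(n) else int(n),
            )
        )
    return out
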
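"""Synthetic four-species genomes with known ground truth.

Emulates the statistical structure the marker-discovery pipeline assumes:
genes with exon/intron structure evolve along a species tree under
Jukes-Cantor substitution, introns evolve faster than exons (a per-intron
rate multiplier, heterogeneous across introns), indels accumulate in
introns only, a fraction of genes carries an unannotated duplicated copy on
a dedicated extra chromosome, and occasional ambiguous bases are injected.
Each simulated marker's expected filter fate is recorded in a truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._iupac import revcomp
from .genome_io import GeneModel, GenomicSequence, GenomeSet
from .intron_filters import FilterConfig
from .orthology import ONE2ONE, OrthologTable
from .treekit import read_newick

BASES = np.array(list("ACGT"))

DEFAULT_SPECIES_TREE = (
    "((mus:0.025,rat:0.030):0.040,cavia:0.100,homo:0.170);"
)
DEFAULT_ANCHORS = ("mus", "rat", "cavia", "homo")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator; the defaults are the package's
    standing desk-scale emulation of a 4-genome rodent comparison."""

    species_tree: str = DEFAULT_SPECIES_TREE
    anchor_order: tuple[str, str, str, str] = DEFAULT_ANCHORS
    n_genes: int = 30
    n_exons_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (30, 240)
    intron_length_range: tuple[int, int] = (80, 2200)
    intron_rate_multiplier: float = 3.0
    intron_rate_cv: float = 0.5  # gamma heterogeneity of per-intron rates
    indel_rate: float = 0.1  # indel events per substitution, introns only
    indel_length_range: tuple[int, int] = (1, 10)
    duplication_prob: float = 0.05
    ambiguous_inject_rate: float = 2e-3
    minus_strand_prob: float = 0.4
    spacer_length_range: tuple[int, int] = (200, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (
            self.n_exons_range, self.exon_length_range,
            self.intron_length_range, self.indel_length_range,
            self.spacer_length_range,
        ):
            if not 0 < lo <= hi:
                raise ValueError(f"invalid distribution bounds ({lo}, {hi})")
        if self.intron_rate_multiplier < 1:
            raise ValueError("intron_rate_multiplier must be >= 1")
        for r in (self.indel_rate, self.ambiguous_inject_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not 0 <= self.duplication_prob <= 1:
            raise ValueError("duplication_prob must lie in [0, 1]")


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def jc_p_changed(d: float) -> float:
    """Expected proportion of changed sites at JC distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def evolve_sequence(seq: str, branch_length: float, model: str = "JC",
                    seed=None) -> str:
    """Per-site substitution along one branch under Jukes-Cantor."""
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    if model != "JC":
        raise ValueError(f"unsupported model {model!r}")
    if branch_length == 0 or not seq:
        return seq
    rng = _as_rng(seed)
    p = jc_p_changed(branch_length)
    # map residues to 0..3 (non-ACGT characters are left untouched)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = lut[raw]
    hit = (rng.random(len(raw)) < p) & (codes >= 0)
    idx = np.nonzero(hit)[0]
    if idx.size:
        # uniform over the three other bases: shift by 1..3 mod 4
        shift = rng.integers(1, 4, size=idx.size)
        codes = codes.astype(np.int16)
        new_codes = (codes[idx] + shift) % 4
        out = raw.copy()
        base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
        out[idx] = base_bytes[new_codes]
        return out.tobytes().decode()
    return seq


def _apply_indels(seq: str, d_intron: float, cfg: SimulationConfig,
                  rng: np.random.Generator) -> str:
    lam = cfg.indel_rate * d_intron * len(seq)
    n_events = rng.poisson(lam) if lam > 0 else 0
    for _ in range(n_events):
        length = int(rng.integers(cfg.indel_length_range[0],
                                  cfg.indel_length_range[1] + 1))
        if len(seq) == 0:
            break
        pos = int(rng.integers(0, len(seq) + 1))
        if rng.random() < 0.5:  # deletion
            seq = seq[:pos] + seq[pos + length:]
        else:  # insertion of random bases
            ins = "".join(rng.choice(BASES, size=length))
            seq = seq[:pos] + ins + seq[pos:]
    return seq


# ---------------------------------------------------------------------------
# whole-genome simulation
# ---------------------------------------------------------------------------


@dataclass
class _GeneStructure:
    """One gene's parts at one tree node, transcript orientation."""
    exons: list[str]
    introns: list[str]


@dataclass
class SimulatedDataset:
    """In-memory simulation output; ``write`` materializes the file layout
    the pipeline reads (FASTA + GFF3 per species, ortholog TSVs, truth TSV)."""

    config: SimulationConfig
    genomes: GenomeSet
    models: dict[str, list[GeneModel]]  # per species
    tables: list[OrthologTable]
    truth: pd.DataFrame  # per marker: expected first failing stage

    def models_index(self) -> dict[tuple[str, str], GeneModel]:
        return {
            (sp, m.gene_id): m for sp, ms in self.models.items() for m in ms
        }

    def write(self, outdir: "str | Path") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in self.config.anchor_order:
            self.genomes.write_fasta(sp, outdir / f"{sp}.fasta")
            _write_gff3(self.models[sp], outdir / f"{sp}.gff3")
        for t in self.tables:
            a, b = t.species_pair
            t.to_tsv(outdir / f"orthologs_{a}_{b}.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _write_gff3(models: Sequence[GeneModel], path: Path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        s, e = m.span
        lines.append(
            f"{m.chromosome}\tsim\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
            f"ID={m.gene_id}"
        )
        lines.append(
            f"{m.chromosome}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
            f"ID={m.transcript_id};Parent={m.gene_id}"
        )
        for es, ee in sorted(m.exons):
            lines.append(
                f"{m.chromosome}\tsim\texon\t{es + 1}\t{ee}\t.\t{m.strand}\t.\t"
                f"Parent={m.transcript_id}"
            )
    path.write_text("\n".join(lines) + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _evolve_gene(struct: _GeneStructure, d: float, mult: Sequence[float],
                 cfg: SimulationConfig, rng: np.random.Generator) -> _GeneStructure:
    exons = [evolve_sequence(e, d, seed=rng) for e in struct.exons]
    introns = []
    for i, intr in enumerate(struct.introns):
        di = d * mult[i]
        evolved = evolve_sequence(intr, di, seed=rng)
        evolved = _apply_indels(evolved, di, cfg, rng)
        introns.append(evolved)
    return _GeneStructure(exons=exons, introns=introns)


def _expected_fate(cfg: SimulationConfig, fcfg: FilterConfig,
                   lengths: Mapping[str, int],
                   ambig: Mapping[str, int],
                   flank_min: int, duplicated: bool) -> str:
    """First failing stage predicted from generation-time knowledge; the
    arithmetic mirrors the published filter rules directly."""
    ref, ing2, mid, out = cfg.anchor_order
    if not fcfg.min_len <= lengths[ref] <= fcfg.max_len:
        return "length_window"
    f = fcfg.tier_fractions
    tiers = [
        (out, [ref, ing2, mid], f["outgroup_tier"]),
        (mid, [ref, ing2], f["mid_tier"]),
        (ref, [ing2], f["ingroup_tier"]),
    ]
    for denom_sp, others, frac in tiers:
        denom = lengths[denom_sp]
        if denom == 0:
            return "length_difference"
        for sp in others:
            if not abs(lengths[sp] - denom) < frac * denom:
                return "length_difference"
    if any(a > fcfg.max_ambiguous for a in ambig.values()):
        return "ambiguity"
    if flank_min < fcfg.min_flank:
        return "flank"
    if duplicated:
        return "single_copy"
    return "candidate"


def simulate_genomes(cfg: SimulationConfig,
                     filter_config: FilterConfig | None = None) -> SimulatedDataset:
    """Simulate genomes, annotations, ortholog tables and a truth table."""
    rng = np.random.default_rng(cfg.seed)
    tree = read_newick(cfg.species_tree)
    leaves = {l.name for l in tree.tips()}
    missing = set(cfg.anchor_order) - leaves
    if missing:
        raise ValueError(f"species tree lacks anchor species {sorted(missing)}")
    fcfg = filter_config or FilterConfig(anchor_order=cfg.anchor_order)

    n_genes = cfg.n_genes
    gene_names = [f"g{i:04d}" for i in range(n_genes)]
    roots: list[_GeneStructure] = []
    multipliers: list[np.ndarray] = []
    strands: list[str] = []
    duplicated = rng.random(n_genes) < cfg.duplication_prob
    shape = 1.0 / (cfg.intron_rate_cv ** 2) if cfg.intron_rate_cv > 0 else None
    for _ in range(n_genes):
        n_ex = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        exons = [
            _random_seq(rng, int(rng.integers(cfg.exon_length_range[0],
                                              cfg.exon_length_range[1] + 1)))
            for _ in range(n_ex)
        ]
        introns = [
            _random_seq(rng, int(rng.integers(cfg.intron_length_range[0],
                                              cfg.intron_length_range[1] + 1)))
            for _ in range(n_ex - 1)
        ]
        roots.append(_GeneStructure(exons=exons, introns=introns))
        if shape is not None:
            mult = cfg.intron_rate_multiplier * rng.gamma(shape, 1.0 / shape,
                                                          size=n_ex - 1)
        else:
            mult = np.full(n_ex - 1, cfg.intron_rate_multiplier)
        multipliers.append(np.maximum(mult, 1.0))
        strands.append("-" if rng.random() < cfg.minus_strand_prob else "+")

    # evolve every gene down the tree
    leaf_structs: dict[str, list[_GeneStructure]] = {}

    def descend(node, structs: list[_GeneStructure]) -> None:
        if node.is_tip():
            leaf_structs[node.name] = structs
            return
        for child in node.children:
            evolved = [
                _evolve_gene(structs[g], child.length or 0.0,
                             multipliers[g], cfg, rng)
                for g in range(n_genes)
            ]
            descend(child, evolved)

    descend(tree, roots)

    genomes = GenomeSet()
    models: dict[str, list[GeneModel]] = {}
    ambig_counts: dict[tuple[str, str, int], int] = {}
    lengths: dict[tuple[str, str, int], int] = {}

    for sp in cfg.anchor_order:
        structs = leaf_structs[sp]
        chrom_parts: list[str] = []
        dup_parts: list[str] = []
        sp_models: list[GeneModel] = []
        pos = 0
        for g, name in enumerate(gene_names):
            st = structs[g]
            # inject ambiguous bases into introns
            introns = []
            for i, intr in enumerate(st.introns):
                if cfg.ambiguous_inject_rate > 0 and intr:
                    arr = list(intr)
                    hits = np.nonzero(
                        rng.random(len(arr)) < cfg.ambiguous_inject_rate
                    )[0]
                    for h in hits:
                        arr[h] = "N"
                    intr = "".join(arr)
                    n_amb = len(hits)
                else:
                    n_amb = 0
                ambig_counts[(sp, name, i + 1)] = n_amb
                lengths[(sp, name, i + 1)] = len(intr)
                introns.append(intr)
            parts = [st.exons[0]]
            for i, intr in enumerate(introns):
                parts.append(intr)
                parts.append(st.exons[i + 1])
            gene_seq = "".join(parts)
            spacer = _random_seq(
                rng, int(rng.integers(cfg.spacer_length_range[0],
                                      cfg.spacer_length_range[1] + 1))
            )
            chrom_parts.append(spacer)
            pos += len(spacer)
            gstart = pos
            strand = strands[g]
            # transcript-orientation exon offsets within the gene
            offsets = []
            off = 0
            for i, ex in enumerate(st.exons):
                offsets.append((off, off + len(ex)))
                off += len(ex)
                if i < len(introns):
                    off += len(introns[i])
            glen = len(gene_seq)
            if strand == "+":
                exon_ivs = [(gstart + s, gstart + e) for s, e in offsets]
                chrom_parts.append(gene_seq)
            else:
                # genomic sequence is the reverse complement; transcript
                # offset [s, e) maps to genomic [gstart+glen-e, gstart+glen-s)
                exon_ivs = [
                    (gstart + glen - e, gstart + glen - s) for s, e in offsets
                ]
                chrom_parts.append(revcomp(gene_seq))
            pos += glen
            gene_id = f"{name}_{sp}"
            sp_models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=f"{gene_id}.t1",
                    species=sp,
                    chromosome="chr1",
                    strand=strand,
                    exons=tuple(exon_ivs),
                )
            )
            if duplicated[g]:
                dup_parts.append(_random_seq(rng, 100))
                dup_parts.append(gene_seq)
        genomes.add(GenomicSequence(sp, "chr1", "".join(chrom_parts)))
        if dup_parts:
            genomes.add(GenomicSequence(sp, "chr_dup", "".join(dup_parts)))
        models[sp] = sp_models

    ref = cfg.anchor_order[0]
    tables = [
        OrthologTable(
            species_pair=(ref, other),
            rows=tuple(
                (f"{name}_{ref}", f"{name}_{other}", ONE2ONE)
                for name in gene_names
            ),
        )
        for other in cfg.anchor_order[1:]
    ]

    truth_rows = []
    for g, name in enumerate(gene_names):
        n_introns = len(roots[g].introns)
        for idx in range(1, n_introns + 1):
            per_len = {sp: lengths[(sp, name, idx)] for sp in cfg.anchor_order}
            per_amb = {sp: ambig_counts[(sp, name, idx)] for sp in cfg.anchor_order}
            # exon lengths are invariant under substitution-only evolution,
            # so the root lengths are the flank lengths in every species
            flank_min = min(
                len(roots[g].exons[idx - 1]), len(roots[g].exons[idx])
            )
            fate = _expected_fate(cfg, fcfg, per_len, per_amb, flank_min,
                                  bool(duplicated[g]))
            truth_rows.append(
                {
                    "marker_id": f"{name}_{ref}-{idx}",
                    "gene": name,
                    "intron_index": idx,
                    "duplicated": bool(duplicated[g]),
                    "intron_rate_multiplier": float(multipliers[g][idx - 1]),
                    "expected_fate": fate,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        config=cfg, genomes=genomes, models=models, tables=tables, truth=truth
    )
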
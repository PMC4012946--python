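"""The deterministic filter cascade over orthologous intron sets.

Stages (default order, mirroring the discovery pipeline):

1. ``length_window`` — reference-species intron length within [200, 1600] bp
   (closed interval).
2. ``length_difference`` — tiered pairwise length-similarity rule: every
   rodent within 90% of the outgroup intron length, the two ingroup rodents
   within 80% of the mid-tier rodent, and the two ingroup rodents within 70%
   of each other (strict "<" bounds throughout).
3. ``redundancy`` — drop introns annotated more than once (identical
   reference-species genomic interval).
4. ``ambiguity`` — at most 9 non-ACGT residues per intron in every species.
5. ``flank`` — both flanking exons >= 40 bp in every species.

The single-copy and phylogenetic stages are pluggable: any callable with
the stage signature can be appended (the pipeline wires in the homology
screen and the tree-based filter this way).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import yaml

from ._iupac import count_ambiguous
from .genome_io import IntronRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Every numeric threshold of the cascade, defaults as used for rodents."""

    anchor_order: tuple[str, str, str, str] = ("mouse", "rat", "guinea_pig", "human")
    min_len: int = 200
    max_len: int = 1600
    tier_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "outgroup_tier": 0.90,
            "mid_tier": 0.80,
            "ingroup_tier": 0.70,
        }
    )
    max_ambiguous: int = 9
    min_flank: int = 40
    max_extract_len: int = 50_000
    evalue_threshold: float = 1e-4
    sf_max: float = 0.8
    k_max: float = 0.09
    one2one_label: str = "ortholog_one2one"

    def __post_init__(self) -> None:
        if not 0 < self.min_len < self.max_len:
            raise ValueError("require 0 < min_len < max_len")
        if any(not 0 < f < 1 for f in self.tier_fractions.values()):
            raise ValueError("tier fractions must lie in (0, 1)")

    @property
    def reference_species(self) -> str:
        return self.anchor_order[0]

    @property
    def ingroup2_species(self) -> str:
        return self.anchor_order[1]

    @property
    def mid_species(self) -> str:
        return self.anchor_order[2]

    @property
    def outgroup_species(self) -> str:
        return self.anchor_order[3]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "anchor_order" in data:
            data["anchor_order"] = tuple(data["anchor_order"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "anchor_order": list(self.anchor_order),
            "min_len": self.min_len,
            "max_len": self.max_len,
            "tier_fractions": dict(self.tier_fractions),
            "max_ambiguous": self.max_ambiguous,
            "min_flank": self.min_flank,
            "max_extract_len": self.max_extract_len,
            "evalue_threshold": self.evalue_threshold,
            "sf_max": self.sf_max,
            "k_max": self.k_max,
            "one2one_label": self.one2one_label,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class OrthologousIntronSet:
    """One orthologous intron across the four anchor species."""

    marker_id: str
    records: Mapping[str, IntronRecord]
    intron_index: int

    def __post_init__(self) -> None:
        for sp, rec in self.records.items():
            if rec.intron_index != self.intron_index:
                raise ValueError(
                    f"marker {self.marker_id}: record for {sp} has intron index "
                    f"{rec.intron_index}, expected {self.intron_index}"
                )


@dataclass
class FilterTrace:
    """Per-stage survivor counts and first-fail rejection reasons."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    rejections: dict[str, str] = field(default_factory=dict)

    def record_stage(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: n_out {n_out} > n_in {n_in}")
        self.stages.append((name, n_in, n_out))
        logger.info("stage %-18s %6d -> %6d introns", name, n_in, n_out)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["stage\tn_in\tn_out"]
        lines += [f"{s}\t{i}\t{o}" for s, i, o in self.stages]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# per-marker predicates
# ---------------------------------------------------------------------------


def length_window_filter(
    iset: OrthologousIntronSet, cfg: FilterConfig
) -> tuple[bool, str | None]:
    """Keep iff the reference-species intron length lies in [min_len, max_len]."""
    rec = iset.records.get(cfg.reference_species)
    if rec is None:
        return False, "missing_reference_record"
    if cfg.min_len <= rec.intron_length <= cfg.max_len:
        return True, None
    return False, "length_window"


def length_difference_filter(
    iset: OrthologousIntronSet, cfg: FilterConfig
) -> tuple[bool, str | None]:
    """Tiered length-similarity rule; all bounds strict ("lower than")."""
    lengths = {}
    for sp in cfg.anchor_order:
        rec = iset.records.get(sp)
        if rec is None:
            return False, "missing_record"
        lengths[sp] = rec.intron_length
    f = cfg.tier_fractions
    tiers = [
        # (denominator species, compared species, fraction)
        (cfg.outgroup_species,
         [cfg.reference_species, cfg.ingroup2_species, cfg.mid_species],
         f["outgroup_tier"]),
        (cfg.mid_species,
         [cfg.reference_species, cfg.ingroup2_species],
         f["mid_tier"]),
        (cfg.reference_species, [cfg.ingroup2_species], f["ingroup_tier"]),
    ]
    for denom_sp, others, frac in tiers:
        denom = lengths[denom_sp]
        if denom == 0:
            return False, "zero_length_denominator"
        for sp in others:
            if not abs(lengths[sp] - denom) < frac * denom:
                return False, "length_difference"
    return True, None


def ambiguity_filter(
    iset: OrthologousIntronSet, cfg: FilterConfig
) -> tuple[bool, str | None]:
    """Keep iff no species' intron has more than max_ambiguous non-ACGT bases."""
    for rec in iset.records.values():
        if count_ambiguous(rec.intron_seq) > cfg.max_ambiguous:
            return False, "ambiguity"
    return True, None


def flank_length_filter(
    iset: OrthologousIntronSet, cfg: FilterConfig
) -> tuple[bool, str | None]:
    """Keep iff both flanking exons are >= min_flank bp in every species."""
    for rec in iset.records.values():
        if min(rec.flank_lengths) < cfg.min_flank:
            return False, "flank"
    return True, None


# ---------------------------------------------------------------------------
# set-level stages and the cascade
# ---------------------------------------------------------------------------

Predicate = Callable[[OrthologousIntronSet, FilterConfig], tuple[bool, "str | None"]]
StageFn = Callable[
    [Sequence[OrthologousIntronSet], FilterConfig],
    tuple[list[OrthologousIntronSet], dict[str, str]],
]


def _predicate_stage(pred: Predicate, default_reason: str) -> StageFn:
    def stage(sets, cfg):
        kept, rejections = [], {}
        for s in sets:
            ok, reason = pred(s, cfg)
            if ok:
                kept.append(s)
            else:
                rejections[s.marker_id] = reason or default_reason
        return kept, rejections

    return stage


def redundancy_filter(
    sets: Sequence[OrthologousIntronSet],
    cfg: FilterConfig | None = None,
) -> tuple[list[OrthologousIntronSet], dict[str, str]]:
    """Among markers whose reference-species genomic interval coincides
    exactly, keep the one with the lowest marker_id."""
    ref = cfg.reference_species if cfg is not None else None
    by_interval: dict[tuple, list[OrthologousIntronSet]] = {}
    orphans: list[OrthologousIntronSet] = []
    for s in sets:
        rec = s.records.get(ref) if ref else next(iter(s.records.values()))
        if rec is None:
            orphans.append(s)
            continue
        by_interval.setdefault(rec.genomic_interval, []).append(s)
    kept, rejections = [], {}
    for group in by_interval.values():
        group = sorted(group, key=lambda s: s.marker_id)
        kept.append(group[0])
        for dup in group[1:]:
            rejections[dup.marker_id] = "redundancy"
    kept.extend(orphans)
    kept.sort(key=lambda s: s.marker_id)
    return kept, rejections


STAGES: dict[str, StageFn] = {
    "length_window": _predicate_stage(length_window_filter, "length_window"),
    "length_difference": _predicate_stage(
        length_difference_filter, "length_difference"
    ),
    "redundancy": redundancy_filter,
    "ambiguity": _predicate_stage(ambiguity_filter, "ambiguity"),
    "flank": _predicate_stage(flank_length_filter, "flank"),
}

DEFAULT_STAGE_ORDER = (
    "length_window",
    "length_difference",
    "redundancy",
    "ambiguity",
    "flank",
)


def run_cascade(
    sets: Sequence[OrthologousIntronSet],
    cfg: FilterConfig,
    stages: Sequence["str | tuple[str, StageFn]"] | None = None,
) -> tuple[list[OrthologousIntronSet], FilterTrace]:
    """Apply the filter stages in order, recording a :class:`FilterTrace`.

    ``stages`` may mix registered stage names with (name, callable) pairs
    for extra stages such as the single-copy screen or the phylogenetic
    filter.  A marker is attributed to its first failing stage only.
    """
    if stages is None:
        stages = DEFAULT_STAGE_ORDER
    resolved: list[tuple[str, StageFn]] = []
    for s in stages:
        if isinstance(s, str):
            if s not in STAGES:
                raise ValueError(f"unknown filter stage {s!r}")
            resolved.append((s, STAGES[s]))
        else:
            resolved.append(s)
    trace = FilterTrace()
    current = list(sets)
    for name, fn in resolved:
        kept, rejections = fn(current, cfg)
        trace.record_stage(name, len(current), len(kept))
        for marker, reason in rejections.items():
            trace.rejections.setdefault(marker, reason)
        current = kept
    return current, trace


def build_intron_sets(
    quartets,
    records: Mapping[tuple[str, str, int], IntronRecord],
) -> list[OrthologousIntronSet]:
    """Group extracted intron records into orthologous sets, one per shared
    intron index of each quartet, named ``<refgene>-<index>``.

    ``records`` is keyed by (species, gene_id, intron_index).  An index is
    included only when a record exists for all four species.
    """
    sets: list[OrthologousIntronSet] = []
    for q in quartets:
        n = q.n_exons
        if n is None or n < 2:
            continue
        for idx in range(1, n):
            per_species = {}
            for sp, gene in q.genes:
                rec = records.get((sp, gene, idx))
                if rec is None:
                    break
                per_species[sp] = rec
            else:
                sets.append(
                    OrthologousIntronSet(
                        marker_id=f"{q.reference_gene}-{idx}",
                        records=per_species,
                        intron_index=idx,
                    )
                )
    return sets
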
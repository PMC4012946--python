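"""Trees per intron, concatenated reference trees, and the rate filter.

The comparison statistic follows the Ktreedist definitions: branches of two
trees on the same leaf set are paired by leaf bipartition (a bipartition
present in only one tree pairs with length 0), the scaling factor K
minimizes sum((K*t_i - r_i)^2) in closed form K = sum(t_i*r_i)/sum(t_i^2),
and the K tree score is the RMS residual sqrt(sum((K*t_i - r_i)^2)/n) over
the union partition count.  K < 1 means the comparison tree is more
divergent than the reference.

Built-in tree inference is neighbor joining on Jukes-Cantor distances; any
externally computed newick (e.g. maximum likelihood) can be ingested
instead.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._iupac import GAP
from .intron_filters import FilterConfig
from .msa_clean import Alignment

DEFAULT_SATURATION_CAP = 5.0  # JC distance assigned to saturated pairs (p >= 0.75)


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------


def read_newick(source: "str | Path") -> TreeNode:
    """Parse a newick tree from a string or file path."""
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    return TreeNode.read(io.StringIO(text), convert_underscores=False)


def write_newick(tree: TreeNode, path: "str | Path | None" = None) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue().strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def scale_tree(tree: TreeNode, factor: float) -> TreeNode:
    """Copy of the tree with every branch length multiplied by ``factor``."""
    out = tree.copy()
    for node in out.traverse():
        if node.length is not None:
            node.length *= factor
    return out


# ---------------------------------------------------------------------------
# distances and NJ
# ---------------------------------------------------------------------------


def jc_distance(p: float, saturation_cap: float = DEFAULT_SATURATION_CAP) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); capped when saturated."""
    if p < 0:
        raise ValueError("mismatch proportion must be >= 0")
    if p >= 0.75:
        return saturation_cap
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def alignment_distance_matrix(
    aln: Alignment, saturation_cap: float = DEFAULT_SATURATION_CAP
) -> DistanceMatrix:
    """Pairwise JC distances over gap-free shared columns of every pair."""
    n = len(aln.taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.rows[i], aln.rows[j]
            shared = mismatch = 0
            for x, y in zip(a, b):
                if x == GAP or y == GAP:
                    continue
                shared += 1
                if x != y:
                    mismatch += 1
            if shared == 0:
                raise ValueError(
                    f"no gap-free shared columns between {aln.taxa[i]!r} "
                    f"and {aln.taxa[j]!r}"
                )
            mat[i, j] = mat[j, i] = jc_distance(mismatch / shared, saturation_cap)
    return DistanceMatrix(mat, ids=list(aln.taxa))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining; negative branch estimates are clamped to zero."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_nj_tree(
    aln: Alignment,
    model: str = "JC",
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> TreeNode:
    """NJ tree from an alignment under JC distances."""
    if model != "JC":
        raise ValueError(f"unsupported distance model {model!r}")
    if len(aln.taxa) < 3:
        raise ValueError("tree building requires at least 3 taxa")
    return nj_tree(alignment_distance_matrix(aln, saturation_cap))


def concatenate(
    alignments: Sequence[Alignment], taxa: Sequence[str]
) -> tuple[Alignment, list[tuple[int, int]]]:
    """Append alignments column-wise over a shared taxon list.

    Taxa absent from a partition are padded with gaps there; the returned
    partition list holds (start, end) column intervals.
    """
    if not alignments:
        raise ValueError("cannot concatenate an empty list of alignments")
    rows = {t: [] for t in taxa}
    partitions: list[tuple[int, int]] = []
    offset = 0
    for aln in alignments:
        extra = set(aln.taxa) - set(taxa)
        if extra:
            raise ValueError(f"partition contains unknown taxa {sorted(extra)}")
        width = aln.n_columns
        for t in taxa:
            rows[t].append(aln.row(t) if t in aln.taxa else GAP * width)
        partitions.append((offset, offset + width))
        offset += width
    return (
        Alignment(taxa=tuple(taxa), rows=tuple("".join(rows[t]) for t in taxa)),
        partitions,
    )


# ---------------------------------------------------------------------------
# tree comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeComparison:
    scaling_factor: float
    k_score: float
    n_partitions: int


@dataclass(frozen=True)
class MarkerDivergenceStats:
    marker_id: str
    scaling_factor: float
    k_score: float
    total_branch_length: float
    ingroup_terminal_sum: float


def bipartition_lengths(tree: TreeNode) -> dict[frozenset, float]:
    """Branch lengths keyed by the leaf bipartition each branch induces.

    Keys are frozensets {side, complement}; the two root edges of a rooted
    binary tree induce the same bipartition and their lengths are summed,
    which makes the map invariant to root placement.
    """
    leaves = frozenset(l.name for l in tree.tips())
    out: dict[frozenset, float] = {}
    for node in tree.traverse(include_self=False):
        side = frozenset(
            (l.name for l in node.tips()) if not node.is_tip() else (node.name,)
        )
        if not side or side == leaves:
            continue
        key = frozenset((side, leaves - side))
        out[key] = out.get(key, 0.0) + (node.length or 0.0)
    return out


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=False))


def compare_trees(tree: TreeNode, ref: TreeNode) -> TreeComparison:
    """Scaling factor and K tree score of ``tree`` against ``ref``."""
    leaves_t = {l.name for l in tree.tips()}
    leaves_r = {l.name for l in ref.tips()}
    if leaves_t != leaves_r:
        raise ValueError(
            "leaf sets differ: only in comparison tree "
            f"{sorted(leaves_t - leaves_r)}, only in reference "
            f"{sorted(leaves_r - leaves_t)}"
        )
    bt = bipartition_lengths(tree)
    br = bipartition_lengths(ref)
    keys = sorted(bt.keys() | br.keys(), key=lambda k: sorted(map(sorted, k)))
    t = np.array([bt.get(k, 0.0) for k in keys])
    r = np.array([br.get(k, 0.0) for k in keys])
    st2 = float(np.dot(t, t))
    if st2 == 0.0:
        raise ValueError("comparison tree has zero total branch length")
    K = float(np.dot(t, r)) / st2
    n = len(keys)
    k_score = float(np.sqrt(np.sum((K * t - r) ** 2) / n))
    return TreeComparison(scaling_factor=K, k_score=k_score, n_partitions=n)


def clade_terminal_sum(tree: TreeNode, taxa_subset: Iterable[str]) -> float:
    """Sum of the pendant branch lengths of the named taxa."""
    tips = {l.name: l for l in tree.tips()}
    total = 0.0
    for t in taxa_subset:
        if t not in tips:
            raise KeyError(f"taxon {t!r} not in tree")
        total += tips[t].length or 0.0
    return total


def marker_stats(
    marker_id: str, tree: TreeNode, ref: TreeNode, ingroup_taxa: Sequence[str]
) -> MarkerDivergenceStats:
    cmpres = compare_trees(tree, ref)
    return MarkerDivergenceStats(
        marker_id=marker_id,
        scaling_factor=cmpres.scaling_factor,
        k_score=cmpres.k_score,
        total_branch_length=total_branch_length(tree),
        ingroup_terminal_sum=clade_terminal_sum(tree, ingroup_taxa),
    )


def phylo_filter(stats: MarkerDivergenceStats, cfg: FilterConfig) -> bool:
    """Keep iff scaling_factor < sf_max and k_score < k_max (both strict)."""
    for v in (stats.scaling_factor, stats.k_score):
        if not math.isfinite(v):
            raise ValueError(f"marker {stats.marker_id}: non-finite statistic")
    return stats.scaling_factor < cfg.sf_max and stats.k_score < cfg.k_max


def write_stats_tsv(
    stats: Sequence[MarkerDivergenceStats], path: "str | Path"
) -> None:
    lines = [
        "marker_id\tscaling_factor\tk_score\ttotal_branch_length\tingroup_terminal_sum"
    ]
    for s in stats:
        lines.append(
            f"{s.marker_id}\t{s.scaling_factor:.6f}\t{s.k_score:.6f}\t"
            f"{s.total_branch_length:.6f}\t{s.ingroup_terminal_sum:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
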
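"""Dated ultrametric trees: parsing, validation, pruning, rescaling,
branching times and lineage-through-time (LTT) series.

All ages are measured backward from the present (tips at age 0) in the
time units of the input tree (Myr for a dated phylogeny).  Branching
times are the sufficient statistic consumed by every diversification
model in :mod:`divrate.models`: ``x_2 >= x_3 >= ... >= x_n`` where
``x_i`` is the age at which the reconstructed tree first has ``i``
lineages and ``x_2`` is the crown age.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "NewickParseError",
    "NotUltrametricError",
    "UltrametricTree",
    "BranchingTimes",
    "LTTSeries",
    "parse_tree",
    "write_newick",
    "check_ultrametric",
    "prune_to_clade",
    "rescale_root_age",
    "branching_times",
    "ltt",
]

DEFAULT_REL_TOL = 1e-6


class NewickParseError(ValueError):
    """Malformed Newick input (position information from the parser is kept)."""


class NotUltrametricError(ValueError):
    """Root-to-tip distances disagree beyond the stated tolerance."""


@dataclass
class UltrametricTree:
    """A rooted binary dated phylogeny.

    Wraps a :class:`dendropy.Tree`.  ``crown_age`` is the maximum
    root-to-tip path length; ultrametricity is *checked*, not assumed,
    so a freshly parsed tree may carry unequal tip depths until
    validated by :func:`check_ultrametric` / :func:`branching_times`.
    """

    _tree: dendropy.Tree = field(repr=False)

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                raise ValueError(
                    f"missing branch length on edge above "
                    f"{node.taxon.label if node.taxon else 'an internal node'}"
                )
            if node.parent_node is not None and node.edge.length < 0:
                raise ValueError("negative branch length")
            nchild = len(node.child_nodes())
            if nchild > 2:
                raise ValueError(
                    f"polytomy ({nchild} children) at an internal node; "
                    "resolve multifurcations before analysis"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def _depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    @property
    def crown_age(self) -> float:
        depths = self._depths()
        return max(d for n, d in depths.items() if n.is_leaf())

    def clone(self) -> "UltrametricTree":
        return UltrametricTree(self._tree.clone(depth=1))


def parse_tree(newick_text: str) -> UltrametricTree:
    """Parse a single Newick tree.

    Unquoted and single-quoted labels are accepted, square-bracket
    comments are ignored, internal node labels are ignored.  Missing
    branch lengths and polytomies raise :class:`ValueError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return UltrametricTree(tree)


def write_newick(tree: UltrametricTree, digits: int | None = None) -> str:
    """Serialize to Newick with a trailing newline.

    By default branch lengths are written at full precision so that
    write -> parse preserves branching times exactly; pass ``digits``
    (e.g. 10) for fixed-significant-digit output.
    """
    out = io.StringIO()
    kwargs = {}
    if digits is not None:
        kwargs["real_value_format_specifier"] = f".{digits}g"
    tree._tree.write(file=out, schema="newick", suppress_rooting=True, **kwargs)
    return out.getvalue()


def check_ultrametric(tree: UltrametricTree, rel_tol: float = DEFAULT_REL_TOL) -> bool:
    """True iff all root-to-tip distances agree within ``rel_tol * crown_age``."""
    depths = tree._depths()
    tip_depths = [d for n, d in depths.items() if n.is_leaf()]
    crown = max(tip_depths)
    return (crown - min(tip_depths)) <= rel_tol * crown


def _max_deviation(tree: UltrametricTree) -> float:
    depths = tree._depths()
    tip_depths = [d for n, d in depths.items() if n.is_leaf()]
    return max(tip_depths) - min(tip_depths)


def prune_to_clade(tree: UltrametricTree, keep: set[str]) -> UltrametricTree:
    """Induced subtree on ``keep``; crown age becomes the age of MRCA(keep).

    Unary internal nodes created by pruning are suppressed with branch
    lengths summed; the root stem above the MRCA is dropped.
    """
    keep = set(keep)
    labels = set(tree.tip_labels)
    missing = sorted(keep - labels)
    if missing:
        raise KeyError(f"labels not in tree: {missing}")
    if len(keep) < 3:
        raise ValueError(f"need >= 3 tips to analyse a clade, got {len(keep)}")
    sub = tree._tree.clone(depth=1)
    sub.retain_taxa_with_labels(sorted(keep))
    sub.suppress_unifurcations()
    # drop any residual stem path above the MRCA of the kept tips
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        child.parent_node = None
        sub.seed_node = child
    sub.seed_node.edge.length = None
    return UltrametricTree(sub)


def rescale_root_age(tree: UltrametricTree, target_age: float) -> UltrametricTree:
    """Multiply every branch length by ``target_age / crown_age``."""
    if not target_age > 0:
        raise ValueError(f"target_age must be > 0, got {target_age}")
    factor = target_age / tree.crown_age
    out = tree.clone()
    for edge in out._tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


@dataclass(frozen=True)
class BranchingTimes:
    """Ordered internal-node ages ``x_2 >= ... >= x_n`` (Myr before present)."""

    n_tips: int
    ages: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        if len(ages) != self.n_tips - 1:
            raise ValueError(
                f"expected {self.n_tips - 1} branching times, got {len(ages)}"
            )
        if np.any(np.diff(ages) > 0):
            raise ValueError("branching times must be sorted non-increasing")
        if not np.all(ages > 0):
            raise ValueError("branching times must be strictly positive")

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])

    def durations(self) -> np.ndarray:
        """Interval lengths ``d_i = x_i - x_{i+1}`` for ``i = 2..n`` (``x_{n+1} = 0``)."""
        ext = np.append(self.ages, 0.0)
        return ext[:-1] - ext[1:]

    def lineage_counts(self) -> np.ndarray:
        """Lineage count ``i`` carried by each interval, ``2..n``."""
        return np.arange(2, self.n_tips + 1)

    def rescaled(self, factor: float) -> "BranchingTimes":
        if not factor > 0:
            raise ValueError("scale factor must be > 0")
        return BranchingTimes(self.n_tips, self.ages * factor)


def branching_times(
    tree: UltrametricTree, rel_tol: float = DEFAULT_REL_TOL
) -> BranchingTimes:
    """Extract sorted internal-node ages from an ultrametric tree."""
    n = tree.n_tips
    if n < 3:
        raise ValueError(f"need >= 3 tips for branching-time analysis, got {n}")
    depths = tree._depths()
    crown = max(d for nd, d in depths.items() if nd.is_leaf())
    if not check_ultrametric(tree, rel_tol):
        raise NotUltrametricError(
            f"tree is not ultrametric: max root-to-tip deviation "
            f"{_max_deviation(tree):.6g} exceeds {rel_tol:g} x crown age {crown:.6g}"
        )
    ages = [crown - d for nd, d in depths.items() if not nd.is_leaf()]
    ages = np.sort(np.asarray(ages))[::-1]
    ages[0] = crown  # the root age is the crown age by definition
    return BranchingTimes(n, ages)


@dataclass(frozen=True)
class LTTSeries:
    """Step series of reconstructed lineage count against age before present."""

    ages: np.ndarray
    counts: np.ndarray

    @property
    def log_counts(self) -> np.ndarray:
        return np.log(self.counts)

    @property
    def n_tips(self) -> int:
        return int(self.counts[-1])

    def to_tsv(self) -> str:
        lines = ["age\tcount\tlog_count"]
        for a, c, lc in zip(self.ages, self.counts, self.log_counts):
            lines.append(f"{a:.10g}\t{c:d}\t{lc:.10g}")
        return "\n".join(lines) + "\n"


def ltt(bt: BranchingTimes) -> LTTSeries:
    """LTT series: count ``k`` applies on the age interval ``(x_k, x_{k+1}]``;
    the final segment down to age 0 carries ``n_tips`` lineages."""
    ages = np.append(bt.ages, 0.0)
    counts = np.append(np.arange(2, bt.n_tips + 1), bt.n_tips)
    return LTTSeries(ages=ages, counts=counts)
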
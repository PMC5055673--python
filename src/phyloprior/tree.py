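"""Rooted, dated phylogeny container and its branch incidence table.

All evolutionary-history metrics in this package are sums over branches of
``length × weight``, where the weight of a branch depends only on the set of
tips that descend from it (extinction probabilities for Expected PD-loss and
HED/HEDGE, range unions for BED, tip counts for fair-proportion ED).  The
:class:`BranchTable` materializes exactly that structure — one row per branch
with its length and a boolean tip-incidence vector — so the metric modules are
plain vectorized numpy over it.

Tree I/O, MRCA lookup and pruning are delegated to dendropy; this module owns
validation and the incidence representation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "BranchTable",
    "PhylogenyError",
    "parse_newick",
    "graft_polytomy",
]


class PhylogenyError(ValueError):
    """Malformed tree input (parse failure, duplicate labels, bad lengths)."""


@dataclass(frozen=True)
class BranchTable:
    """Branch × tip incidence for a :class:`Phylogeny`.

    Attributes
    ----------
    lengths : (B,) float array of branch lengths.
    memb : (B, S) boolean array; ``memb[b, i]`` is True iff tip ``i`` descends
        from branch ``b``.  Row ``b`` therefore also encodes the root path:
        branch ``b`` lies on the root path of tip ``i`` iff ``memb[b, i]``.
    tips : tip labels in column order.
    """

    lengths: np.ndarray
    memb: np.ndarray
    tips: tuple[str, ...]
    tip_index: dict[str, int] = field(repr=False)

    @property
    def n_branches(self) -> int:
        return self.lengths.shape[0]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def indices_of(self, species) -> np.ndarray:
        """Column indices of the given species labels (error on unknowns)."""
        try:
            return np.array([self.tip_index[s] for s in species], dtype=int)
        except KeyError as exc:
            raise PhylogenyError(f"species not a tip of the tree: {exc.args[0]!r}") from None

    def tip_mask(self, species) -> np.ndarray:
        mask = np.zeros(self.n_tips, dtype=bool)
        mask[self.indices_of(species)] = True
        return mask


class Phylogeny:
    """A single rooted tree with branch lengths in time units.

    Invariants enforced at construction: unique tip labels, finite
    non-negative branch lengths, a single root from which every tip is
    reachable.  A zero-length (or absent) root edge is tolerated and ignored;
    a positive root edge is kept as a branch subtending all tips so that
    ``PD(all tips) == total_branch_length`` always holds.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._branch_table: BranchTable | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise PhylogenyError(f"Newick parse error: {exc}") from exc
        tree.is_rooted = True
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        leaves = self._tree.leaf_node_iter()
        labels = []
        for leaf in leaves:
            if leaf.taxon is None or not leaf.taxon.label:
                raise PhylogenyError("unlabelled tip in tree")
            labels.append(leaf.taxon.label)
        if not labels:
            raise PhylogenyError("tree has no tips")
        seen = set()
        for lab in labels:
            if lab in seen:
                raise PhylogenyError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge: None or >= 0 tolerated
                if edge.length is not None and (
                    not np.isfinite(edge.length) or edge.length < 0
                ):
                    raise PhylogenyError(f"invalid root edge length {edge.length!r}")
                continue
            if edge.length is None:
                raise PhylogenyError(
                    f"missing branch length on edge above {_node_label(edge.head_node)}"
                )
            if not np.isfinite(edge.length) or edge.length < 0:
                raise PhylogenyError(
                    f"invalid branch length {edge.length!r} above {_node_label(edge.head_node)}"
                )

    # -- basic properties --------------------------------------------------

    @property
    def tips(self) -> tuple[str, ...]:
        return self.branch_table().tips

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_table().lengths.sum())

    def distance_to_root(self, tip: str) -> float:
        bt = self.branch_table()
        i = bt.indices_of([tip])[0]
        return float(bt.lengths[bt.memb[:, i]].sum())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = [self.distance_to_root(t) for t in self.tips]
        span = max(depths) - min(depths)
        scale = max(max(depths), 1e-12)
        return span <= rel_tol * scale

    # -- branch table ------------------------------------------------------

    def branch_table(self) -> BranchTable:
        if self._branch_table is None:
            self._branch_table = self._build_branch_table()
        return self._branch_table

    def _build_branch_table(self) -> BranchTable:
        leaves = list(self._tree.leaf_node_iter())
        tips = tuple(leaf.taxon.label for leaf in leaves)
        tip_index = {lab: i for i, lab in enumerate(tips)}
        n = len(tips)

        lengths: list[float] = []
        rows: list[np.ndarray] = []
        # postorder so each node's tip set is the union of its children's
        below: dict[int, np.ndarray] = {}
        root = self._tree.seed_node
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(n, dtype=bool)
                mask[tip_index[node.taxon.label]] = True
            else:
                mask = np.zeros(n, dtype=bool)
                for child in node.child_nodes():
                    mask |= below[id(child)]
            below[id(node)] = mask
            if node is root:
                if node.edge.length:  # positive root edge kept as a branch
                    lengths.append(float(node.edge.length))
                    rows.append(mask)
            else:
                lengths.append(float(node.edge.length))
                rows.append(mask)
        return BranchTable(
            lengths=np.asarray(lengths, dtype=float),
            memb=np.vstack(rows),
            tips=tips,
            tip_index=tip_index,
        )

    # -- structural operations --------------------------------------------

    def prune_to(self, keep) -> "Phylogeny":
        """Return the tree restricted to the given tips (unifurcations merged)."""
        keep = set(keep)
        unknown = keep - set(self.tips)
        if unknown:
            raise PhylogenyError(f"cannot keep unknown tips: {sorted(unknown)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(clone)

    def mrca_tips(self, species) -> frozenset[str]:
        """Tip set of the most recent common ancestor of the given species."""
        node = self._mrca_node(self._tree, species)
        return frozenset(l.taxon.label for l in node.leaf_iter())

    @staticmethod
    def _mrca_node(tree: dendropy.Tree, species):
        """Minimal node whose leaf set covers ``species`` (plain upward walk)."""
        wanted = set(species)
        by_label = {
            l.taxon.label: l for l in tree.leaf_node_iter() if l.taxon is not None
        }
        missing = sorted(wanted - set(by_label))
        if missing:
            raise PhylogenyError(f"species not in tree: {missing}")
        node = by_label[next(iter(wanted))]
        while True:
            below = {l.taxon.label for l in node.leaf_iter()}
            if wanted <= below:
                return node
            if node.parent_node is None:
                return node
            node = node.parent_node


def _node_label(node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return "<internal>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def _mean_depth_below(node) -> float:
    """Mean root-path length from ``node`` to its descendant tips."""
    total, count = 0.0, 0
    stack = [(node, 0.0)]
    while stack:
        nd, depth = stack.pop()
        if nd.is_leaf():
            total += depth
            count += 1
        else:
            for child in nd.child_nodes():
                stack.append((child, depth + child.edge.length))
    return total / count


def graft_polytomy(
    tree: Phylogeny,
    species: str,
    genus_members,
    mode: str = "mrca_polytomy",
    seed: int = 0,
) -> Phylogeny:
    """Attach a missing species onto the subtree spanned by its congeners.

    ``mrca_polytomy`` attaches the new tip directly at the MRCA of
    ``genus_members`` with terminal length equal to the mean depth below that
    node, preserving ultrametricity of dated trees.  ``random_within_genus``
    attaches at a uniformly chosen node of the genus subtree (seeded), used by
    the placement-sensitivity analysis.  When the attachment point is itself a
    tip (single-member genus, or a random draw landing on a leaf) the terminal
    edge is split at its midpoint and the new species becomes that tip's
    sister, again keeping tip depths equal.
    """
    genus_members = sorted(set(genus_members))
    if not genus_members:
        raise PhylogenyError("genus_members must be non-empty")
    if species in tree.tips:
        raise PhylogenyError(f"species {species!r} already in tree")
    if mode not in ("mrca_polytomy", "random_within_genus"):
        raise PhylogenyError(f"unknown graft mode {mode!r}")

    clone = tree._tree.clone(depth=1)
    anchor = Phylogeny._mrca_node(clone, genus_members)
    if mode == "random_within_genus":
        rng = random.Random(seed)
        candidates = [nd for nd in anchor.preorder_iter()]
        anchor = rng.choice(candidates)

    taxon = clone.taxon_namespace.new_taxon(label=species)
    if anchor.is_leaf():
        # midpoint split of the terminal edge; new tip is the sister
        old_len = anchor.edge.length
        parent = anchor.parent_node
        mid = dendropy.Node(edge_length=old_len / 2.0)
        parent.remove_child(anchor)
        parent.add_child(mid)
        anchor.edge.length = old_len / 2.0
        mid.add_child(anchor)
        mid.new_child(taxon=taxon, edge_length=old_len / 2.0)
    else:
        anchor.new_child(taxon=taxon, edge_length=_mean_depth_below(anchor))
    return Phylogeny(clone)
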
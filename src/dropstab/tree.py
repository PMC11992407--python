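"""Cell-type relationship trees.

A :class:`CellTypeTree` is a rooted tree whose leaves are cell types (or
cell states nested under types). Branch weights encode divergence: the
variance of the per-gene log-fold effects accumulated along an edge during
simulation is proportional to the edge's weight. Leaf ``cell_fractions``
give the expected proportion of cells per type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["CellTypeTree", "preset_tree", "PRESET_DESIGNS"]

PRESET_DESIGNS = ("separate3", "nested8")


@dataclass
class CellTypeTree:
    """Rooted tree over cell types/states with divergence branch weights.

    Parameters
    ----------
    parent
        Mapping node -> parent node; the root maps to ``None``.
    branch_weight
        Mapping node -> nonnegative weight of the edge from its parent.
        The root's entry is ignored (conventionally 0).
    cell_fractions
        Mapping leaf -> expected fraction of cells; must sum to 1.
        If empty, uniform fractions over the leaves are filled in.
    """

    parent: dict[str, str | None]
    branch_weight: dict[str, float]
    cell_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for n, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"parent {p!r} of node {n!r} is not a tree node")
        for n, w in self.branch_weight.items():
            if w < 0:
                raise ValueError(f"negative branch weight on node {n!r}")
        # every node must reach the root (no cycles, no orphans)
        for n in self.parent:
            seen = set()
            cur: str | None = n
            while cur is not None:
                if cur in seen:
                    raise ValueError("cycle detected in tree")
                seen.add(cur)
                cur = self.parent[cur]
        if not self.cell_fractions:
            leaves = self.leaves
            self.cell_fractions = {leaf: 1.0 / len(leaves) for leaf in leaves}
        total = sum(self.cell_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell_fractions sum to {total}, expected 1")
        if set(self.cell_fractions) != set(self.leaves):
            raise ValueError("cell_fractions keys must be exactly the leaves")

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent.items() if p is None)

    @property
    def leaves(self) -> list[str]:
        parents = set(p for p in self.parent.values() if p is not None)
        return [n for n in self.parent if n not in parents]

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def children(self, node: str) -> list[str]:
        return [n for n, p in self.parent.items() if p == node]

    def path_to_root(self, node: str) -> list[str]:
        """Nodes from ``node`` up to (and including) the root."""
        out = [node]
        while self.parent[out[-1]] is not None:
            out.append(self.parent[out[-1]])  # type: ignore[arg-type]
        return out

    def depth(self, node: str) -> int:
        return len(self.path_to_root(node)) - 1

    def group_of(self, leaf: str) -> str:
        """The child-of-root ancestor of a leaf (its top-level type)."""
        path = self.path_to_root(leaf)
        return path[-2] if len(path) >= 2 else leaf

    def to_newick(self) -> str:
        """Serialize topology and branch weights as a Newick string."""

        def render(node: str) -> str:
            kids = sorted(self.children(node))
            label = node
            if kids:
                inner = ",".join(
                    f"{render(k)}:{self.branch_weight.get(k, 0.0):g}" for k in kids
                )
                return f"({inner}){label}"
            return label

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str,
                    cell_fractions: dict[str, float] | None = None) -> "CellTypeTree":
        """Parse a Newick string (branch lengths become branch weights)."""
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=False)
        parent: dict[str, str | None] = {}
        weight: dict[str, float] = {}
        counter = [0]

        def name_of(nd) -> str:
            if nd.taxon is not None and nd.taxon.label:
                return nd.taxon.label
            if nd.label:
                return nd.label
            counter[0] += 1
            nd.label = f"node{counter[0]}"
            return nd.label

        for nd in dt.preorder_node_iter():
            name = name_of(nd)
            if nd.parent_node is None:
                parent[name] = None
                weight[name] = 0.0
            else:
                parent[name] = name_of(nd.parent_node)
                weight[name] = float(nd.edge.length or 0.0)
        return cls(parent=parent, branch_weight=weight,
                   cell_fractions=cell_fractions or {})


def preset_tree(design: str) -> CellTypeTree:
    """Return one of the two built-in cell-type tree designs.

    ``separate3`` is a star tree of 3 well-separated cell types (equal deep
    branches). ``nested8`` nests 8 cell states under 3 type nodes in groups
    of (3, 3, 2): deep branches between groups, shallow branches within, so
    states of one type form sub-populations of a common profile.
    """
    if design == "separate3":
        parent: dict[str, str | None] = {"root": None}
        weight = {"root": 0.0}
        for t in ("typeA", "typeB", "typeC"):
            parent[t] = "root"
            weight[t] = 1.0
        return CellTypeTree(parent=parent, branch_weight=weight)
    if design == "nested8":
        parent = {"root": None}
        weight = {"root": 0.0}
        groups = {"typeA": ("A1", "A2", "A3"),
                  "typeB": ("B1", "B2", "B3"),
                  "typeC": ("C1", "C2")}
        for g, states in groups.items():
            parent[g] = "root"
            weight[g] = 1.0
            for s in states:
                parent[s] = g
                weight[s] = 0.02
        return CellTypeTree(parent=parent, branch_weight=weight)
    raise ValueError(
        f"unknown design {design!r}; valid designs: {', '.join(PRESET_DESIGNS)}"
    )
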
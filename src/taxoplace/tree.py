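"""Rooted region tree with branch lengths, tip lineages, and cached
per-node tip diameters (max cophenetic distance among descendant tips).

Wraps a scikit-bio :class:`~skbio.TreeNode`. Every node gets a unique,
stable name (internal nodes are auto-named ``N1, N2, ...`` in preorder),
so downstream artefacts (node label tables, placements) can refer to
nodes by name.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from skbio import TreeNode

from .taxonomy import TaxonomyTable


class UnknownTipError(KeyError):
    pass


@dataclass
class NodeInfo:
    name: str
    is_tip: bool
    parent: str | None
    length: float          # branch length of the edge above this node
    depth: float           # path length from the root
    tips: tuple[str, ...]  # descendant tip names (self if a tip)
    diameter: float        # max cophenetic distance among descendant tips


@dataclass
class RegionTree:
    """A rooted, named, taxonomy-annotated tree over region sequences."""

    tree: TreeNode
    taxonomy: TaxonomyTable
    nodes: dict[str, NodeInfo] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._name_nodes()
        self._index()
        missing = [t for t in self.tip_names if t not in self.taxonomy]
        if missing:
            raise UnknownTipError(
                f"tips without taxonomy entries: {sorted(missing)[:10]}"
            )

    # -- construction helpers -------------------------------------------

    def _name_nodes(self) -> None:
        seen: set[str] = set()
        counter = 0
        for node in self.tree.preorder():
            if node.name is None or node.name == "" or node.name in seen:
                if not node.is_tip():
                    counter += 1
                    while f"N{counter}" in seen:
                        counter += 1
                    node.name = f"N{counter}"
                else:
                    raise ValueError("duplicate or empty tip name in tree")
            seen.add(node.name)

    def _index(self) -> None:
        self.nodes.clear()
        self._skbio: dict[str, TreeNode] = {}
        # postorder: tips first, so diameters/tip sets compose upward
        down: dict[str, float] = {}  # max root-ward distance to a tip below
        for node in self.tree.postorder():
            length = float(node.length or 0.0)
            if node.is_tip():
                tips = (node.name,)
                diam = 0.0
                down[node.name] = 0.0
            else:
                tips = tuple(
                    t for c in node.children for t in self.nodes[c.name].tips
                )
                reach = sorted(
                    (down[c.name] + float(c.length or 0.0) for c in node.children),
                    reverse=True,
                )
                down[node.name] = reach[0]
                diam = max(
                    [self.nodes[c.name].diameter for c in node.children]
                    + ([reach[0] + reach[1]] if len(reach) > 1 else [])
                )
            self.nodes[node.name] = NodeInfo(
                name=node.name,
                is_tip=node.is_tip(),
                parent=None,  # filled below
                length=length,
                depth=0.0,    # filled below
                tips=tips,
                diameter=diam,
            )
            self._skbio[node.name] = node
        for node in self.tree.preorder():
            info = self.nodes[node.name]
            if node.parent is not None:
                info.parent = node.parent.name
                info.depth = self.nodes[node.parent.name].depth + info.length

    # -- queries ---------------------------------------------------------

    @property
    def root_name(self) -> str:
        return self.tree.name

    @property
    def tip_names(self) -> tuple[str, ...]:
        return self.nodes[self.root_name].tips

    @property
    def diameter(self) -> float:
        return self.nodes[self.root_name].diameter

    def node(self, name: str) -> NodeInfo:
        try:
            return self.nodes[name]
        except KeyError:
            raise UnknownTipError(f"unknown node {name!r}") from None

    def ancestors(self, name: str):
        """Yield node names from `name`'s parent up to the root."""
        cur = self.nodes[name].parent
        while cur is not None:
            yield cur
            cur = self.nodes[cur].parent

    def lca(self, a: str, b: str) -> str:
        if a == b:
            return a
        seen = {a}
        seen.update(self.ancestors(a))
        if b in seen:
            return b
        for anc in self.ancestors(b):
            if anc in seen:
                return anc
        raise UnknownTipError(f"no common ancestor of {a!r} and {b!r}")

    def cophenetic(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two tips (or nodes)."""
        na, nb = self.node(a), self.node(b)
        lca = self.lca(a, b)
        return na.depth + nb.depth - 2.0 * self.nodes[lca].depth

    def node_to_tip_distance(self, node_name: str, tip: str) -> float:
        return self.cophenetic(node_name, tip)

    # -- IO ---------------------------------------------------------------

    def write_newick(self, path) -> None:
        self.tree.write(str(path), format="newick")

    @classmethod
    def from_newick(cls, source, taxonomy: TaxonomyTable,
                    validate_tips=None) -> "RegionTree":
        """Parse a Newick tree; with `validate_tips`, reject trees whose
        tip names are not a subset of the given IDs, listing offenders."""
        kwargs = {"format": "newick", "convert_underscores": False}
        if hasattr(source, "read"):
            tree = TreeNode.read(source, **kwargs)
        elif isinstance(source, str) and source.lstrip().startswith("("):
            tree = TreeNode.read(io.StringIO(source), **kwargs)
        else:
            tree = TreeNode.read(str(source), **kwargs)
        if validate_tips is not None:
            allowed = set(validate_tips)
            unknown = [t.name for t in tree.tips() if t.name not in allowed]
            if unknown:
                from .refprep import ReferencePrepError
                raise ReferencePrepError(
                    f"external tree has tips absent from the region slice: "
                    f"{sorted(unknown)[:10]}"
                )
        return cls(tree=tree, taxonomy=taxonomy)
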
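"""Shared domain types and file formats.

The package models geographic ranges as subsets of a small ordered set of
biogeographic realms.  A :class:`RealmSet` fixes the canonical realm order,
which doubles as the bit order of every :class:`RangeState` bitmask; dated
phylogenies are handled by a light array-friendly :class:`Phylogeny` built on
top of dendropy's newick parser.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "RealmSet",
    "RangeState",
    "Node",
    "Phylogeny",
    "CladeDataset",
    "ModelParams",
    "read_newick",
    "parse_newick",
    "write_newick",
    "read_geography",
    "write_geography",
    "read_geography_csv",
    "split_into_clades",
]

#: Realm codes of the nine global marine realms, in canonical bit order.
MARINE_REALMS = ("NC", "CI", "CP", "EA", "EP", "SC", "WA", "WI", "NP")


@dataclass(frozen=True)
class RealmSet:
    """Ordered collection of realm codes; the order is the bitmask order."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a RealmSet needs at least 2 realms")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("realm labels must be unique")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def count(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @classmethod
    def marine(cls) -> "RealmSet":
        """The nine marine realms (NC CI CP EA EP SC WA WI NP)."""
        return cls(MARINE_REALMS)


@dataclass(frozen=True)
class RangeState:
    """A subset of realms encoded as a bitmask over a RealmSet's order."""

    bits: int
    n_realms: int

    def __post_init__(self) -> None:
        if not 0 <= self.bits < (1 << self.n_realms):
            raise ValueError(f"bits {self.bits} out of range for {self.n_realms} realms")

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    @property
    def is_empty(self) -> bool:
        return self.bits == 0

    def indices(self) -> Iterator[int]:
        bits = self.bits
        while bits:
            low = bits & -bits
            yield low.bit_length() - 1
            bits ^= low

    def labels(self, realms: RealmSet) -> tuple[str, ...]:
        return tuple(realms.labels[i] for i in self.indices())

    def __contains__(self, realm_index: int) -> bool:
        return bool(self.bits >> realm_index & 1)

    @classmethod
    def from_labels(cls, labels: Iterable[str], realms: RealmSet) -> "RangeState":
        bits = 0
        for lab in labels:
            bits |= 1 << realms.index(lab)
        return cls(bits, realms.count)

    @classmethod
    def from_binary(cls, s: str) -> "RangeState":
        """Decode a lagrange-style presence string such as ``101``."""
        if set(s) - {"0", "1"}:
            raise ValueError(f"invalid presence string {s!r}")
        bits = 0
        for i, c in enumerate(s):
            if c == "1":
                bits |= 1 << i
        return cls(bits, len(s))

    def to_binary(self) -> str:
        return "".join("1" if i in self else "0" for i in range(self.n_realms))


class Node:
    """One node of a rooted dated tree."""

    __slots__ = ("label", "length", "children", "parent", "age", "index")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.age = 0.0  # time before present (Ma); filled by Phylogeny
        self.index = -1

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted ultrametric tree with branch lengths in Myr.

    Node ages (time before present) are computed from root-to-tip paths; the
    tree is validated to be ultrametric within ``tol_rel`` times the root age.
    """

    def __init__(self, root: Node, tol_rel: float = 1e-6, allow_nonultrametric: bool = False):
        self.root = root
        self._index_nodes()
        self._assign_ages(tol_rel, allow_nonultrametric)

    def _index_nodes(self) -> None:
        self._postorder: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                self._postorder.append(node)
            else:
                stack.append((node, True))
                for child in node.children:
                    stack.append((child, False))
        for i, node in enumerate(self._postorder):
            node.index = i
        self._tips = [n for n in self._postorder if n.is_leaf]

    def _assign_ages(self, tol_rel: float, allow: bool) -> None:
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node is not self.root:
                if node.length <= 0:
                    raise ValueError(f"non-positive branch length on {node.label or 'internal node'}")
                depth[id(node)] = depth[id(node.parent)] + node.length
        tip_depths = [depth[id(t)] for t in self._tips]
        max_depth = max(tip_depths)
        spread = max_depth - min(tip_depths)
        if spread > tol_rel * max(max_depth, 1e-12):
            msg = f"tree is not ultrametric: tip depth spread {spread:g} vs root age {max_depth:g}"
            if not allow:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=3)
        self.root_age = max_depth
        for node in self._postorder:
            node.age = max(self.root_age - depth[id(node)], 0.0)
        # snap tip ages to exactly zero for downstream binning
        for t in self._tips:
            if abs(t.age) <= tol_rel * max(self.root_age, 1e-12):
                t.age = 0.0

    # -- traversal -----------------------------------------------------------
    def postorder(self) -> list[Node]:
        return list(self._postorder)

    def preorder(self) -> list[Node]:
        return list(reversed(self._postorder))

    @property
    def tips(self) -> list[Node]:
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self._tips]

    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node is self.root:
                return f"({inner})"
            return f"({inner}):{node.length:.10g}"

        return fmt(self.root) + ";"


def parse_newick(text: str, allow_nonultrametric: bool = False) -> Phylogeny:
    """Parse a newick string into a Phylogeny (dendropy does the parsing)."""
    dt = dendropy.Tree.get(data=text, schema="newick")
    return _from_dendropy(dt, allow_nonultrametric)


def read_newick(path, allow_nonultrametric: bool = False) -> Phylogeny:
    dt = dendropy.Tree.get(path=str(path), schema="newick")
    return _from_dendropy(dt, allow_nonultrametric)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def _from_dendropy(dt: dendropy.Tree, allow_nonultrametric: bool) -> Phylogeny:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label.replace(" ", "_")
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dt.seed_node)
    root.length = 0.0
    return Phylogeny(root, allow_nonultrametric=allow_nonultrametric)


@dataclass
class CladeDataset:
    """A dated clade plus the realm range of each tip."""

    tree: Phylogeny
    ranges: dict[str, RangeState]
    group: str = ""
    below_minimum: bool = False

    def __post_init__(self) -> None:
        labels = set(self.tree.tip_labels)
        missing = labels - set(self.ranges)
        if missing:
            raise ValueError(f"tips without a range: {sorted(missing)[:5]}")
        for name in labels:
            if self.ranges[name].is_empty:
                raise ValueError(f"empty range for tip {name}")

    @property
    def n_realms(self) -> int:
        return next(iter(self.ranges.values())).n_realms


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the DEC-family models.

    d : anagenetic dispersal rate (events/Myr, scaled by the realm-pair
        multiplier); e : per-realm extirpation rate (events/Myr); j :
        founder-event weight; y, s, v : cladogenetic per-event weights for
        narrow sympatry, subset sympatry and vicariance (dimensionless,
        fixed at 1 by convention).
    """

    d: float = 0.0
    e: float = 0.0
    j: float = 0.0
    y: float = 1.0
    s: float = 1.0
    v: float = 1.0

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("d and e must be >= 0")
        if not 0 <= self.j < 3:
            raise ValueError("j must be in [0, 3)")
        if min(self.y, self.s, self.v) < 0:
            raise ValueError("y, s, v must be >= 0")


# -- geography files ---------------------------------------------------------

def read_geography(path, realms: RealmSet | None = None) -> tuple[RealmSet, dict[str, RangeState]]:
    """Read a lagrange/PHYLIP-style geography file.

    Format: header ``ntaxa nareas (L1 L2 ...)`` then one ``name  binarystring``
    row per taxon.  Returns the realm set (from the header, or the one
    supplied) and a taxon -> RangeState map.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    header = lines[0]
    try:
        left, _, label_part = header.partition("(")
        ntaxa_s, nareas_s = left.split()
        ntaxa, nareas = int(ntaxa_s), int(nareas_s)
        labels = label_part.rstrip(")").split()
    except ValueError as exc:
        raise ValueError(f"malformed geography header: {header!r}") from exc
    if labels:
        file_realms = RealmSet(tuple(labels))
        if realms is not None and realms.labels != file_realms.labels:
            raise ValueError("realm labels in file disagree with supplied RealmSet")
        realms = file_realms
    if realms is None:
        raise ValueError("geography header lists no realm labels and none were supplied")
    if realms.count != nareas:
        raise ValueError(f"header declares {nareas} areas but {realms.count} labels")

    ranges: dict[str, RangeState] = {}
    for line in lines[1:]:
        name, _, bitstr = line.partition("\t") if "\t" in line else line.partition(" ")
        name, bitstr = name.strip(), bitstr.strip()
        if len(bitstr) != nareas:
            raise ValueError(f"range string for {name} has length {len(bitstr)}, expected {nareas}")
        if name in ranges:
            raise ValueError(f"duplicate taxon {name}")
        state = RangeState.from_binary(bitstr)
        if state.is_empty:
            raise ValueError(f"empty range for taxon {name}")
        ranges[name] = state
    if len(ranges) != ntaxa:
        raise ValueError(f"header declares {ntaxa} taxa but {len(ranges)} rows found")
    return realms, ranges


def write_geography(path, realms: RealmSet, ranges: Mapping[str, RangeState]) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(ranges)} {realms.count} ({' '.join(realms.labels)})\n")
        for name in sorted(ranges):
            fh.write(f"{name}\t{ranges[name].to_binary()}\n")


def read_geography_csv(path, realms: RealmSet) -> dict[str, RangeState]:
    """Long-format alternative: one ``taxon,realm`` pair per line (with header)."""
    import csv

    by_taxon: dict[str, set[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:2]] != ["taxon", "realm"]:
            raise ValueError("expected header 'taxon,realm'")
        for row in reader:
            if not row:
                continue
            by_taxon.setdefault(row[0].strip(), set()).add(row[1].strip())
    return {
        name: RangeState.from_labels(labs, realms) for name, labs in by_taxon.items()
    }


# -- clade splitting ---------------------------------------------------------

def split_into_clades(
    tree: Phylogeny, min_tips: int = 10, max_tips: int = 100
) -> list[Phylogeny]:
    """Partition a large tree into monophyletic clades of ``<= max_tips`` tips.

    Greedy deepest-first rule: a clade is extracted at every node whose tip
    count is at most ``max_tips`` while its parent's exceeds it, so the clade
    tip sets partition the tree's tips.  Clades smaller than ``min_tips``
    are returned with ``below_minimum`` set.  The stem branch leading to each
    clade's MRCA is retained on the subtree root.
    """
    if min_tips < 2 or max_tips < min_tips:
        raise ValueError("need min_tips >= 2 and max_tips >= min_tips")

    counts: dict[int, int] = {}
    for node in tree.postorder():
        counts[id(node)] = 1 if node.is_leaf else sum(counts[id(c)] for c in node.children)

    roots: list[Node] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if counts[id(node)] <= max_tips:
            roots.append(node)
        else:
            stack.extend(node.children)

    clades = []
    for sub in roots:
        copy = _copy_subtree(sub)
        phylo = Phylogeny(copy)
        phylo.below_minimum = counts[id(sub)] < min_tips  # type: ignore[attr-defined]
        clades.append(phylo)
    return clades


def _copy_subtree(node: Node) -> Node:
    copy = Node(label=node.label, length=node.length)
    for child in node.children:
        copy.add_child(_copy_subtree(child))
    return copy
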
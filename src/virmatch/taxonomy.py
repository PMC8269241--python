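"""Strain lineage store with lowest-common-ancestor queries.

Every host-prediction method reduces a set of candidate strains to a single
taxonomic call by taking the lowest (deepest) common ancestor of their
lineages.  Lineages are loaded from a plain TSV (one row per strain, named
ranks phylum through species); identical lineage prefixes share nodes, so the
store is a rooted tree and LCA is path intersection.

Missing intermediate ranks are permitted: blank cells are collapsed and a
strain simply attaches to the deepest named rank, so an LCA is always reported
at the nearest named rank rather than at a placeholder.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species", "strain")
_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}

#: column order expected in a lineage TSV, after the leading ``strain_id``
LINEAGE_COLUMNS = ("phylum", "class", "order", "family", "genus", "species")


class TaxonomyError(ValueError):
    """Raised for malformed lineage tables or unknown strain identifiers."""


@dataclass(eq=False)
class TaxonNode:
    """A single taxon: an opaque id, a display name and a rank."""

    taxon_id: str
    name: str
    rank: str
    parent: "TaxonNode | None" = None
    children: list["TaxonNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rank not in _RANK_DEPTH:
            raise TaxonomyError(f"unknown rank {self.rank!r}")

    @property
    def depth(self) -> int:
        return _RANK_DEPTH[self.rank]

    def path(self) -> list["TaxonNode"]:
        """Root-to-self path, root first."""
        out: list[TaxonNode] = []
        node: TaxonNode | None = self
        while node is not None:
            out.append(node)
            node = node.parent
        out.reverse()
        return out

    def ancestor_at(self, rank: str) -> "TaxonNode | None":
        """The ancestor (or self) at *rank*, or None if the path skips it."""
        want = _RANK_DEPTH[rank]
        node: TaxonNode | None = self
        while node is not None:
            if node.depth == want:
                return node
            if node.depth < want:
                return None
            node = node.parent
        return None

    def is_ancestor_of(self, other: "TaxonNode") -> bool:
        node: TaxonNode | None = other
        while node is not None:
            if node is self:
                return True
            node = node.parent
        return False

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonNode({self.rank}:{self.name})"


class TaxonomyTree:
    """Rooted rank-labelled lineage store supporting LCA queries.

    The root is a synthetic domain-rank node named ``root``; an LCA that
    resolves to it means the query spanned the whole table and callers should
    treat the result as unresolved.
    """

    def __init__(self) -> None:
        self.root = TaxonNode(taxon_id="root", name="root", rank="domain")
        self._strains: dict[str, TaxonNode] = {}
        self._lineages: dict[str, tuple[tuple[str, str], ...]] = {}
        self._by_name: dict[tuple[str, str], TaxonNode | None] = {}

    # -- construction ------------------------------------------------------

    def add_strain(self, strain_id: str, lineage: Sequence[tuple[str, str]]) -> TaxonNode:
        """Attach *strain_id* under the (rank, name) pairs of *lineage*.

        Blank names must already be removed; ranks must be strictly ordered.
        A strain seen twice with an identical lineage is a no-op; a
        conflicting lineage is a hard error naming the strain.
        """
        strain_id = strain_id.strip()
        if not strain_id:
            raise TaxonomyError("empty strain id")
        key = tuple(lineage)
        if strain_id in self._strains:
            if self._lineages[strain_id] != key:
                raise TaxonomyError(
                    f"strain {strain_id!r} listed twice with conflicting lineages"
                )
            return self._strains[strain_id]
        prev_depth = _RANK_DEPTH["domain"]
        node = self.root
        for rank, name in lineage:
            if rank not in _RANK_DEPTH:
                raise TaxonomyError(f"unknown rank {rank!r}")
            if _RANK_DEPTH[rank] <= prev_depth:
                raise TaxonomyError(
                    f"ranks out of order for strain {strain_id!r}: {rank}"
                )
            prev_depth = _RANK_DEPTH[rank]
            node = self._child(node, rank, name)
        leaf = self._child(node, "strain", strain_id)
        self._strains[strain_id] = leaf
        self._lineages[strain_id] = key
        return leaf

    def _child(self, node: TaxonNode, rank: str, name: str) -> TaxonNode:
        for child in node.children:
            if child.rank == rank and child.name == name:
                return child
        new = TaxonNode(
            taxon_id=f"{node.taxon_id}/{rank}:{name}", name=name, rank=rank, parent=node
        )
        node.children.append(new)
        key = (rank, name)
        # a name reused under different parents becomes ambiguous for lookup
        self._by_name[key] = None if key in self._by_name else new
        return new

    # -- queries -----------------------------------------------------------

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self._strains)

    def strain_node(self, strain_id: str) -> TaxonNode:
        try:
            return self._strains[strain_id]
        except KeyError:
            raise TaxonomyError(f"unknown strain id {strain_id!r}") from None

    def node(self, name: str, rank: str) -> TaxonNode:
        """Look a node up by (name, rank); errors if absent or ambiguous."""
        if name == "root":
            return self.root
        hit = self._by_name.get((rank, name))
        if hit is None:
            raise TaxonomyError(f"taxon {name!r} at rank {rank!r} absent or ambiguous")
        return hit

    def lca(self, strain_ids: Iterable[str]) -> TaxonNode:
        """Deepest node ancestral to every strain in *strain_ids*.

        Order and duplication of the input do not matter.  A result equal to
        the tree root means the query could not be resolved below the table's
        implicit single domain.
        """
        ids = list(strain_ids)
        if not ids:
            raise TaxonomyError("lca() requires at least one strain id")
        paths = [self.strain_node(s).path() for s in set(ids)]
        shortest = min(len(p) for p in paths)
        lca_node = self.root
        for i in range(shortest):
            first = paths[0][i]
            if all(p[i] is first for p in paths):
                lca_node = first
            else:
                break
        return lca_node


def lca_nodes(nodes: Sequence[TaxonNode]) -> TaxonNode:
    """Deepest node ancestral to (or equal to) every node in *nodes*."""
    if not nodes:
        raise TaxonomyError("lca_nodes() requires at least one node")
    paths = [n.path() for n in nodes]
    shortest = min(len(p) for p in paths)
    result = paths[0][0]
    for i in range(shortest):
        first = paths[0][i]
        if all(p[i] is first for p in paths):
            result = first
        else:
            break
    return result


def load_taxonomy(path: str | Path) -> TaxonomyTree:
    """Load a lineage TSV into a :class:`TaxonomyTree`.

    Expected header: ``strain_id`` followed by phylum, class, order, family,
    genus, species (tab-separated, UTF-8).  Blank cells mark missing ranks and
    are collapsed.  Names are matched case-sensitively after whitespace
    trimming.
    """
    tree = TaxonomyTree()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "strain_id" not in reader.fieldnames:
            raise TaxonomyError(f"{path}: missing header with strain_id column")
        for row in reader:
            lineage = [
                (rank, row[rank].strip())
                for rank in LINEAGE_COLUMNS
                if rank in row and row[rank] is not None and row[rank].strip()
            ]
            tree.add_strain(row["strain_id"], lineage)
    return tree


def write_taxonomy(rows: Iterable[dict[str, str]], path: str | Path) -> None:
    """Write lineage rows (dicts keyed strain_id + rank names) as TSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["strain_id", *LINEAGE_COLUMNS], delimiter="\t"
        )
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in writer.fieldnames})
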
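"""Ranked taxonomy: nodes, lineages and lowest-common-ancestor queries.

The assignment rule of the pipeline collapses multi-taxon hits to the lowest
Linnaean level shared by all candidate taxa, so the taxonomy is the backbone
of every downstream call.  Trees are held as flat ``taxon_id -> TaxonNode``
maps (NCBI-style node records) and loaded from a small hand-writable TSV.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class Rank(enum.IntEnum):
    """Linnaean ladder, ordered from the root down.

    Comparison follows depth: ``Rank.species > Rank.genus`` means species is
    the *lower* (more resolved) level.  ``NO_RANK`` marks unranked
    intermediate clades; these are legal in trees but are skipped when the
    achieved rank of an assignment is reported.
    """

    ROOT = 0
    SUPERKINGDOM = 1
    KINGDOM = 2
    PHYLUM = 3
    CLASS = 4
    ORDER = 5
    FAMILY = 6
    GENUS = 7
    SPECIES = 8
    NO_RANK = 99  # unranked; never reported

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        label = label.strip().lower().replace(" ", "_")
        aliases = {"no_rank": "NO_RANK", "norank": "NO_RANK", "clade": "NO_RANK"}
        name = aliases.get(label, label.upper())
        try:
            return cls[name]
        except KeyError as exc:
            raise ValueError(f"unknown rank label: {label!r}") from exc

    @property
    def label(self) -> str:
        return "no rank" if self is Rank.NO_RANK else self.name.lower()


#: Standard ladder used for reporting (no unranked levels).
STANDARD_RANKS = tuple(r for r in Rank if r is not Rank.NO_RANK)


@dataclass(frozen=True)
class TaxonNode:
    taxon_id: str
    name: str
    rank: Rank
    parent_id: str | None  # None only for the root


class UnknownTaxonError(KeyError):
    def __init__(self, taxon_id: str):
        super().__init__(taxon_id)
        self.taxon_id = taxon_id

    def __str__(self) -> str:  # KeyError quotes args; keep the message plain
        return f"unknown taxon_id: {self.taxon_id!r}"


@dataclass
class TaxonomyTree:
    """Rooted ranked tree keyed by taxon_id.

    Invariants checked at construction: exactly one root, every parent_id
    resolves, no cycles, and a parent's rank is strictly higher (closer to
    the root) than its child's — rank gaps are allowed, inversions are not.
    Unranked (``no rank``) nodes are exempt from the rank-order check against
    equally-unranked neighbours but may not sit below a species.
    """

    nodes: dict[str, TaxonNode] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nodes:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_nodes(cls, nodes: Iterable[TaxonNode]) -> "TaxonomyTree":
        return cls(nodes={n.taxon_id: n for n in nodes})

    def validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for node in self.nodes.values():
            if node.parent_id is None:
                continue
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                raise ValueError(
                    f"node {node.taxon_id!r} has unresolved parent {node.parent_id!r}"
                )
            if node.rank is not Rank.NO_RANK and parent.rank is not Rank.NO_RANK:
                if parent.rank >= node.rank:
                    raise ValueError(
                        f"rank inversion: {parent.taxon_id!r} ({parent.rank.label}) "
                        f"is parent of {node.taxon_id!r} ({node.rank.label})"
                    )
        # cycle check: every node must reach the root
        root_id = roots[0].taxon_id
        for node in self.nodes.values():
            seen = set()
            cur: TaxonNode | None = node
            while cur is not None and cur.parent_id is not None:
                if cur.taxon_id in seen:
                    raise ValueError(f"cycle through node {cur.taxon_id!r}")
                seen.add(cur.taxon_id)
                cur = self.nodes[cur.parent_id]
            if cur is not None and cur.taxon_id != root_id:
                raise ValueError(f"node {node.taxon_id!r} does not reach the root")

    # -- queries -----------------------------------------------------------

    @property
    def root(self) -> TaxonNode:
        return next(n for n in self.nodes.values() if n.parent_id is None)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxon_id: str) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise UnknownTaxonError(taxon_id) from None

    def children(self, taxon_id: str) -> list[TaxonNode]:
        self.node(taxon_id)
        return sorted(
            (n for n in self.nodes.values() if n.parent_id == taxon_id),
            key=lambda n: n.taxon_id,
        )

    def leaves(self, taxon_id: str | None = None) -> list[TaxonNode]:
        """Leaf nodes of the subtree under ``taxon_id`` (whole tree if None)."""
        has_child = {n.parent_id for n in self.nodes.values() if n.parent_id}
        leaves = [n for n in self.nodes.values() if n.taxon_id not in has_child]
        if taxon_id is not None:
            self.node(taxon_id)
            leaves = [
                n for n in leaves
                if any(a.taxon_id == taxon_id for a in self.lineage(n.taxon_id))
            ]
        return sorted(leaves, key=lambda n: n.taxon_id)

    def species(self) -> list[TaxonNode]:
        return sorted(
            (n for n in self.nodes.values() if n.rank is Rank.SPECIES),
            key=lambda n: n.taxon_id,
        )

    def find_by_name(self, name: str) -> list[TaxonNode]:
        """All nodes with the given name; names are not unique, ids are."""
        return sorted(
            (n for n in self.nodes.values() if n.name == name),
            key=lambda n: n.taxon_id,
        )

    def lineage(self, taxon_id: str) -> list[TaxonNode]:
        """Root-first chain of nodes from the root down to ``taxon_id``."""
        chain = [self.node(taxon_id)]
        while chain[-1].parent_id is not None:
            chain.append(self.node(chain[-1].parent_id))
        chain.reverse()
        return chain

    def ancestor_at(self, taxon_id: str, rank: Rank) -> TaxonNode | None:
        """Ancestor-or-self of ``taxon_id`` at exactly ``rank``, if any."""
        for node in self.lineage(taxon_id):
            if node.rank is rank:
                return node
        return None

    def reported_rank(self, taxon_id: str) -> Rank:
        """Nearest standard rank at or above the node (unranked nodes skipped)."""
        for node in reversed(self.lineage(taxon_id)):
            if node.rank is not Rank.NO_RANK:
                return node.rank
        return Rank.ROOT

    def lca(self, taxa: Iterable[str]) -> TaxonNode:
        """Lowest common ancestor of a non-empty set of taxa.

        Walks root-first lineages in parallel and returns the deepest node
        shared by all of them — "the lowest taxonomic level shared by all
        taxa" of the assignment rule.
        """
        ids = sorted(set(taxa))
        if not ids:
            raise ValueError("lca of an empty taxon set is undefined")
        lineages = [self.lineage(t) for t in ids]
        shared = lineages[0][0]
        for level in range(min(len(ln) for ln in lineages)):
            ids_at_level = {ln[level].taxon_id for ln in lineages}
            if len(ids_at_level) == 1:
                shared = lineages[0][level]
            else:
                break
        return shared

    # -- serialization -----------------------------------------------------

    TSV_HEADER = ("taxon_id", "parent_id", "rank", "name", "notes")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(self.TSV_HEADER)]
        for tid in sorted(self.nodes):
            n = self.nodes[tid]
            lines.append(
                "\t".join([n.taxon_id, n.parent_id or "", n.rank.label, n.name, ""])
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        nodes = []
        text = Path(path).read_text(encoding="utf-8")
        rows = [
            ln for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        header = rows[0].split("\t")
        if [h.strip().lower() for h in header[:4]] != list(cls.TSV_HEADER[:4]):
            raise ValueError(
                f"taxonomy TSV must start with columns {cls.TSV_HEADER[:4]}, got {header}"
            )
        for ln in rows[1:]:
            fields = ln.split("\t")
            tid, pid, rank, name = (fields + ["", "", "", ""])[:4]
            nodes.append(
                TaxonNode(
                    taxon_id=tid.strip(),
                    name=name.strip(),
                    rank=Rank.from_label(rank),
                    parent_id=pid.strip() or None,
                )
            )
        return cls.from_nodes(nodes)


def lineage(tree: TaxonomyTree, taxon_id: str) -> list[TaxonNode]:
    """Functional alias for :meth:`TaxonomyTree.lineage`."""
    return tree.lineage(taxon_id)


def lca(tree: TaxonomyTree, taxa: Iterable[str]) -> TaxonNode:
    """Functional alias for :meth:`TaxonomyTree.lca`."""
    return tree.lca(taxa)


def name_table(tree: TaxonomyTree) -> Mapping[str, str]:
    """taxon_id -> display name, convenience for report writers."""
    return {tid: n.name for tid, n in tree.nodes.items()}
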
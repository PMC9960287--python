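"""Minimal NCBI-style taxonomy store.

Holds a rooted tree of taxa with ranks and names and answers the queries the
profiling and evaluation stages need: lineage walks, projection of a taxon to
a requested rank (``ancestor_at_rank``), lowest common ancestor, and
bacteriophage labelling by family/order membership.

The on-disk format is a four-column tab-separated file (``taxid``,
``parent_taxid``, ``rank``, ``name``) with a header row, a deliberately
hand-writable simplification of the NCBI ``nodes.dmp``/``names.dmp`` pair.
The root is the single row whose ``parent_taxid`` equals its own ``taxid``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "RANKS",
    "TaxonomyError",
    "TaxonNode",
    "TaxonomyStore",
    "PhageLabelSet",
    "load_taxonomy",
    "write_taxonomy",
    "default_phage_labels",
]

#: Recognised rank labels. ``no_rank`` nodes are transparent to rank
#: projection: they are skipped and never returned by ``ancestor_at_rank``.
RANKS = frozenset(
    {
        "no_rank",
        "strain",
        "subspecies",
        "species",
        "subgenus",
        "genus",
        "subfamily",
        "family",
        "suborder",
        "order",
        "class",
        "phylum",
        "kingdom",
        "superkingdom",
        "clade",
    }
)


class TaxonomyError(ValueError):
    """Structural or lookup error in a taxonomy store or its input file."""


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: id, parent id, rank label and scientific name."""

    taxid: int
    parent_taxid: int
    rank: str
    name: str

    def __post_init__(self) -> None:
        if self.taxid <= 0 or self.parent_taxid <= 0:
            raise TaxonomyError(f"taxids must be positive, got {self.taxid}/{self.parent_taxid}")
        if self.rank not in RANKS:
            raise TaxonomyError(f"unknown rank {self.rank!r} for taxid {self.taxid}")


class TaxonomyStore:
    """Validated rooted taxid tree.

    Construction checks that there is exactly one root, that every
    ``parent_taxid`` exists, and that following parents from any node reaches
    the root (no cycles).
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        if not self.nodes:
            raise TaxonomyError("empty taxonomy")
        roots = [t for t, n in self.nodes.items() if n.parent_taxid == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}: {sorted(roots)}")
        self.root: int = roots[0]
        for taxid, node in self.nodes.items():
            if node.parent_taxid not in self.nodes:
                raise TaxonomyError(f"taxid {taxid} has missing parent {node.parent_taxid}")
        # Cycle check: every node must reach the root within |nodes| steps.
        limit = len(self.nodes)
        for taxid in self.nodes:
            cur, steps = taxid, 0
            while cur != self.root:
                cur = self.nodes[cur].parent_taxid
                steps += 1
                if steps > limit:
                    raise TaxonomyError(f"cycle detected walking parents from taxid {taxid}")

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def lineage(self, taxid: int) -> list[TaxonNode]:
        """Nodes from ``taxid`` (inclusive) up to and including the root."""
        out = [self.node(taxid)]
        while out[-1].taxid != self.root:
            out.append(self.nodes[out[-1].parent_taxid])
        return out

    def depth(self, taxid: int) -> int:
        return len(self.lineage(taxid)) - 1

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """Nearest ancestor (inclusive) whose rank equals ``rank``.

        ``no_rank`` nodes are skipped and never returned. Returns ``None``
        when the lineage has no node at the requested rank.
        """
        for node in self.lineage(taxid):
            if node.rank == "no_rank":
                continue
            if node.rank == rank:
                return node.taxid
        return None

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of taxids."""
        taxids = set(taxids)
        if not taxids:
            raise ValueError("lca of an empty taxid set is undefined")
        paths = [
            [n.taxid for n in reversed(self.lineage(t))]  # root .. leaf
            for t in sorted(taxids)
        ]
        lca = self.root
        for level in zip(*paths):
            if len(set(level)) != 1:
                break
            lca = level[0]
        return lca

    def superkingdom_name(self, taxid: int) -> Optional[str]:
        anc = self.ancestor_at_rank(taxid, "superkingdom")
        return self.nodes[anc].name if anc is not None else None

    def is_phage(self, taxid: int, labels: "PhageLabelSet") -> bool:
        """True iff any family- or order-ranked ancestor is on the phage list."""
        if not labels.family_names and not labels.order_names:
            raise ValueError("phage labelling requested with an empty label set")
        for node in self.lineage(taxid):
            if node.rank == "family" and labels.matches("family", node.name):
                return True
            if node.rank == "order" and labels.matches("order", node.name):
                return True
        return False


@dataclass(frozen=True)
class PhageLabelSet:
    """Family and order names whose members infect exclusively bacteria or archaea.

    Name comparison is case-insensitive after whitespace trimming. The list
    file holds one name per line; ``#`` starts a comment. A line may carry an
    explicit ``family:`` or ``order:`` prefix; an unprefixed name matches at
    either rank.
    """

    family_names: frozenset[str]
    order_names: frozenset[str]

    @staticmethod
    def _norm(name: str) -> str:
        return name.strip().casefold()

    def matches(self, rank: str, name: str) -> bool:
        pool = self.family_names if rank == "family" else self.order_names
        return self._norm(name) in pool

    @classmethod
    def from_names(cls, families: Iterable[str] = (), orders: Iterable[str] = ()) -> "PhageLabelSet":
        return cls(
            family_names=frozenset(cls._norm(n) for n in families),
            order_names=frozenset(cls._norm(n) for n in orders),
        )

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "PhageLabelSet":
        fams, orders = set(), set()
        for raw in lines:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            low = line.casefold()
            if low.startswith("family:"):
                fams.add(cls._norm(line.split(":", 1)[1]))
            elif low.startswith("order:"):
                orders.add(cls._norm(line.split(":", 1)[1]))
            else:
                fams.add(cls._norm(line))
                orders.add(cls._norm(line))
        return cls(family_names=frozenset(fams), order_names=frozenset(orders))

    @classmethod
    def from_file(cls, path: str | Path) -> "PhageLabelSet":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_lines(fh)


_COLUMNS = ("taxid", "parent_taxid", "rank", "name")


def load_taxonomy(path: str | Path) -> TaxonomyStore:
    """Load and validate a taxonomy from the four-column TSV format."""
    rows: list[TaxonNode] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header: Optional[dict[str, int]] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if header is None:
                names = [fields[0].lstrip("#").strip()] + [f.strip() for f in fields[1:]]
                missing = [c for c in _COLUMNS if c not in names]
                if missing:
                    raise TaxonomyError(f"{path}: header missing columns {missing}")
                header = {name: i for i, name in enumerate(names)}
                continue
            try:
                rows.append(
                    TaxonNode(
                        taxid=int(fields[header["taxid"]]),
                        parent_taxid=int(fields[header["parent_taxid"]]),
                        rank=fields[header["rank"]].strip(),
                        name=fields[header["name"]].strip(),
                    )
                )
            except (IndexError, ValueError) as exc:
                if isinstance(exc, TaxonomyError):
                    raise
                raise TaxonomyError(f"{path}:{lineno}: malformed row: {line!r}") from exc
    return TaxonomyStore(rows)


def write_taxonomy(store: TaxonomyStore, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for taxid in sorted(store.nodes):
            n = store.nodes[taxid]
            fh.write(f"{n.taxid}\t{n.parent_taxid}\t{n.rank}\t{n.name}\n")


def default_phage_labels() -> PhageLabelSet:
    """Bacteriophage/archaeal-virus family and order names shipped with the package."""
    text = resources.files("viroprof").joinpath("data/phage_labels.txt").read_text("utf-8")
    return PhageLabelSet.from_lines(text.splitlines())
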
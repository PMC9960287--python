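"""Taxonomic profiling: host filtering, best-hit assignment, abundance,
percentile pruning and contig splitting.

The profiling model is contig-first: contigs are assigned a taxon by their
best database hit, assembled reads inherit the taxid of their contig, and
only unassembled reads are assigned from read-level hits. Per-rank abundance
counts individual reads (mates counted separately) under their rank-level
ancestor, and the least abundant taxa jointly accounting for the last *t*
percent of binned reads are pruned as noise (default t=1 for viruses, t=5
for bacteria). Contigs are finally split into eukaryotic-virus, bacteriophage
and unmapped collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .simulate import ReadPair
from .taxonomy import PhageLabelSet, TaxonomyStore
from .toymap import Hit, HitTable, MinimizerIndex, map_queries

__all__ = [
    "ReadToContigMap",
    "Assignment",
    "AbundanceTable",
    "PruneConfig",
    "DEFAULT_PRUNE_T",
    "host_filter",
    "best_hit",
    "assign_taxa",
    "abundance",
    "percentile_prune",
    "pruned_taxids",
    "subtable_by_superkingdom",
    "split_contigs",
]

logger = logging.getLogger(__name__)

#: Default prune percentile per superkingdom: the last percentile of the read
#: distribution for viruses, the last five percentiles for bacteria.
DEFAULT_PRUNE_T = {"Viruses": 1.0, "Bacteria": 5.0}


@dataclass
class ReadToContigMap:
    """Assembler output carrier: read id -> contig id, plus unassembled reads.

    Read ids are mate-level (``pair/1``, ``pair/2``); the dict form enforces
    that a read belongs to at most one contig.
    """

    mapping: dict[str, str]
    unassembled: set[str] = field(default_factory=set)

    def contigs(self) -> set[str]:
        return set(self.mapping.values())

    def restrict(self, read_ids: set[str]) -> "ReadToContigMap":
        """Map restricted to surviving reads; survivors without a contig
        become unassembled."""
        mapping = {r: c for r, c in self.mapping.items() if r in read_ids}
        return ReadToContigMap(mapping, {r for r in read_ids if r not in mapping})


@dataclass(frozen=True)
class Assignment:
    """Taxon call for one query (contig or read). ``taxid`` is None iff the
    query had no surviving hit."""

    query_id: str
    taxid: Optional[int]
    ambiguous: bool
    source: str  # contig_hit | read_hit | inherited_from_contig

    def __post_init__(self) -> None:
        if self.source not in ("contig_hit", "read_hit", "inherited_from_contig"):
            raise ValueError(f"unknown assignment source {self.source!r}")


@dataclass
class AbundanceTable:
    """Per-taxon read counts at one rank. ``total_reads`` is the library-wide
    read count entering profiling (post host-filter), so row counts sum to at
    most that."""

    rank: str
    counts: dict[int, int]
    total_reads: int

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("abundance rows must have positive read counts")
        if sum(self.counts.values()) > self.total_reads:
            raise ValueError("abundance rows exceed the library read count")

    def rows(self) -> list[tuple[int, int]]:
        """(taxid, readn) sorted by descending readn, ties by ascending taxid."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    @property
    def binned_reads(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class PruneConfig:
    """Percentile-pruning threshold t in [0, 100]."""

    t: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= 100.0):
            raise ValueError(f"prune percentile must lie in [0, 100], got {self.t}")


def host_filter(
    pairs: Sequence[ReadPair],
    host_index: MinimizerIndex,
    min_identity: float = 0.90,
    min_aln: int = 100,
    min_chain: int = 3,
) -> tuple[list[ReadPair], list[str]]:
    """Remove read pairs that map to the host genome set.

    A pair is removed when either mate has a host hit with identity >=
    ``min_identity`` over at least ``min_aln`` aligned bases. Returns the
    surviving pairs and the sorted removal log of pair ids (kept for error
    auditing).
    """
    queries = []
    for p in pairs:
        queries.append((p.r1.id, p.r1.sequence))
        queries.append((p.r2.id, p.r2.sequence))
    hits = map_queries(queries, host_index, min_chain=min_chain, min_identity=min_identity)
    removed = {
        h.query_id.rsplit("/", 1)[0]
        for h in hits.hits
        if h.aln_length >= min_aln and h.identity >= min_identity
    }
    kept = [p for p in pairs if p.pair_id not in removed]
    return kept, sorted(removed)


def best_hit(hits: HitTable) -> dict[str, tuple[Hit, bool]]:
    """Per-query best hit with deterministic tie-breaking.

    The winner is the maximum-score hit; ties on score are broken by higher
    identity, then lower taxid, then subject id. The ambiguous flag is set
    when two or more distinct taxids share the winning (score, identity),
    which is how shared identical regions between references surface.
    """
    out: dict[str, tuple[Hit, bool]] = {}
    for query_id, qhits in hits.by_query().items():
        winner = min(qhits, key=lambda h: (-h.score, -h.identity, h.subject_taxid, h.subject_id))
        tied_taxids = {
            h.subject_taxid
            for h in qhits
            if h.score == winner.score and h.identity == winner.identity
        }
        out[query_id] = (winner, len(tied_taxids) > 1)
    return out


def assign_taxa(
    contig_hits: HitTable,
    read_hits: HitTable,
    r2c: ReadToContigMap,
) -> list[Assignment]:
    """Assign taxa contig-first.

    Contigs are assigned by their best hit; assembled reads inherit the
    contig's taxid; unassembled reads are assigned by their own best hit.
    Queries with no surviving hit get ``taxid=None``. A read that is both
    assembled and present in the read-level hit table keeps its contig
    inheritance (the read hit is ignored and logged).
    """
    contig_best = best_hit(contig_hits)
    read_best = best_hit(read_hits)
    assignments: list[Assignment] = []

    contig_ids = sorted(r2c.contigs() | set(contig_best))
    contig_assign: dict[str, Assignment] = {}
    for cid in contig_ids:
        entry = contig_best.get(cid)
        a = (
            Assignment(cid, entry[0].subject_taxid, entry[1], "contig_hit")
            if entry
            else Assignment(cid, None, False, "contig_hit")
        )
        contig_assign[cid] = a
        assignments.append(a)

    overridden = 0
    for read_id in sorted(r2c.mapping):
        ca = contig_assign[r2c.mapping[read_id]]
        if read_id in read_best:
            overridden += 1
        assignments.append(Assignment(read_id, ca.taxid, ca.ambiguous, "inherited_from_contig"))
    if overridden:
        logger.info("%d assembled reads had read-level hits; contig inheritance wins", overridden)

    for read_id in sorted(r2c.unassembled):
        entry = read_best.get(read_id)
        if entry:
            assignments.append(Assignment(read_id, entry[0].subject_taxid, entry[1], "read_hit"))
        else:
            assignments.append(Assignment(read_id, None, False, "read_hit"))
    return assignments


def abundance(
    assignments: Iterable[Assignment],
    store: TaxonomyStore,
    rank: str,
    total_reads: Optional[int] = None,
) -> AbundanceTable:
    """Count each assigned read once under its rank-level ancestor.

    Reads whose taxid has no ancestor at the requested rank fall into an
    unranked bucket that is excluded from the rows; unassigned reads
    contribute to ``total_reads`` only. Contig-level assignments are not
    counted (their reads are, via inheritance).
    """
    counts: dict[int, int] = {}
    n_reads = 0
    for a in assignments:
        if a.source == "contig_hit":
            continue
        n_reads += 1
        if a.taxid is None:
            continue
        anc = store.ancestor_at_rank(a.taxid, rank)
        if anc is not None:
            counts[anc] = counts.get(anc, 0) + 1
    return AbundanceTable(rank, counts, total_reads if total_reads is not None else n_reads)


def percentile_prune(table: AbundanceTable, cfg: PruneConfig) -> AbundanceTable:
    """Drop the least abundant taxa accounting for the last t% of binned reads.

    Rows are sorted by descending readn (ties: ascending taxid); a row is
    kept iff the cumulative readn of strictly better rows is below
    (1 - t/100) of the binned-read total. Equivalently the dropped rows are
    the maximal suffix of taxa lying entirely within the last t% of binned
    reads; a taxon straddling the boundary is kept. The comparison is done
    in integer arithmetic scaled by 100 so the boundary is exact.
    """
    rows = table.rows()
    total = sum(readn for _, readn in rows)
    kept: dict[int, int] = {}
    cum_before = 0
    for taxid, readn in rows:
        if cum_before * 100.0 < (100.0 - cfg.t) * total:
            kept[taxid] = readn
        cum_before += readn
    return AbundanceTable(table.rank, kept, table.total_reads)


def pruned_taxids(table: AbundanceTable, cfg: PruneConfig) -> set[int]:
    """Taxids removed by pruning; the prune log used by the error audit."""
    return set(table.counts) - set(percentile_prune(table, cfg).counts)


def subtable_by_superkingdom(
    table: AbundanceTable, store: TaxonomyStore, superkingdom: str
) -> AbundanceTable:
    """Rows whose lineage passes through the named superkingdom; the
    library-wide total is retained."""
    want = superkingdom.casefold()
    counts = {
        taxid: n
        for taxid, n in table.counts.items()
        if (store.superkingdom_name(taxid) or "").casefold() == want
    }
    return AbundanceTable(table.rank, counts, table.total_reads)


def split_contigs(
    assignments: Iterable[Assignment],
    store: TaxonomyStore,
    labels: PhageLabelSet,
) -> tuple[set[str], set[str], set[str]]:
    """Split contigs into (eukaryotic-viral, bacteriophage, unmapped) id sets.

    Virus-superkingdom contigs go to the phage set when a listed family or
    order appears in their lineage, otherwise to the viral set; contigs with
    no hit are unmapped. Contigs of other superkingdoms (e.g. bacteria) fall
    into none of the three sets.
    """
    viral: set[str] = set()
    phage: set[str] = set()
    unmapped: set[str] = set()
    for a in assignments:
        if a.source != "contig_hit":
            continue
        if a.taxid is None:
            unmapped.add(a.query_id)
        elif (store.superkingdom_name(a.taxid) or "") == "Viruses":
            if store.is_phage(a.taxid, labels):
                phage.add(a.query_id)
            else:
                viral.add(a.query_id)
    return viral, phage, unmapped
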
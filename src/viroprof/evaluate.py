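"""Benchmarking of taxon calling against simulated-metagenome ground truth.

Implements the scoring used throughout the benchmark: rank-level confusion
counts (TP/FP/FN with precision, recall and F1 reported as percentages
rounded half-up to one decimal), read-binning recall/precision by read-id
set comparison, horizontal (breadth-of) genome coverage as an interval
union, and a rule-cascade error audit that attributes each false call to
the pipeline stage that produced it (host filtering, chimeric assembly,
shared identical regions, dropped hits, abundance pruning).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .profile import (
    AbundanceTable,
    Assignment,
    PruneConfig,
    ReadToContigMap,
    best_hit,
    percentile_prune,
)
from .simulate import TruthTable
from .taxonomy import TaxonomyStore
from .toymap import HitTable

__all__ = [
    "ConfusionResult",
    "BinningRecord",
    "CoverageResult",
    "ErrorAuditEntry",
    "AUDIT_CAUSES",
    "confusion",
    "confusion_from_counts",
    "read_binning_eval",
    "horizontal_coverage",
    "error_audit",
]


def _pct(num: int, den: int) -> float:
    """num/den as a percentage rounded half-up to one decimal (0.0 for den=0)."""
    if den == 0:
        return 0.0
    return float((Decimal(num) * 100 / Decimal(den)).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionResult:
    """Taxon-set confusion at one rank. Percentages are rounded half-up to
    one decimal; F1 is computed from the counts (2TP / (2TP + FP + FN), the
    harmonic mean of precision and recall) before rounding."""

    rank: str
    true_count: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def confusion_from_counts(true_count: int, tp: int, fp: int, fn: int, rank: str = "species") -> ConfusionResult:
    """Confusion metrics from raw counts (the arithmetic behind every report row)."""
    return ConfusionResult(
        rank=rank,
        true_count=true_count,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=_pct(tp, tp + fp),
        recall=_pct(tp, tp + fn),
        f1=_pct(2 * tp, 2 * tp + fp + fn),
    )


def confusion(
    truth_taxa: Iterable[int],
    predicted: AbundanceTable,
    store: TaxonomyStore,
    rank: str,
    cfg: Optional[PruneConfig] = None,
    superkingdom: Optional[str] = None,
) -> ConfusionResult:
    """Score predicted taxa against a truth set at one rank.

    Truth taxids are projected to the rank and de-duplicated (the reported
    ``true_count`` is the projected size actually used). Predictions are
    pruned first when ``cfg`` is given, then projected likewise; pruning is
    never applied to the truth. ``superkingdom`` restricts the predictions
    scored (e.g. ``"Viruses"`` when scoring a virus report that shares its
    abundance table with bacterial calls).
    """
    truth_taxa = set(truth_taxa)
    if not truth_taxa:
        raise ValueError("truth taxon set is empty")
    truth_proj: set[int] = set()
    for t in sorted(truth_taxa):
        anc = store.ancestor_at_rank(t, rank)
        if anc is None:
            raise ValueError(f"truth taxid {t} has no ancestor at rank {rank!r}")
        truth_proj.add(anc)

    table = percentile_prune(predicted, cfg) if cfg is not None else predicted
    pred_proj: set[int] = set()
    for t in table.counts:
        anc = store.ancestor_at_rank(t, rank)
        if anc is None:
            continue
        if superkingdom is not None:
            sk = store.superkingdom_name(anc)
            if sk is None or sk.casefold() != superkingdom.casefold():
                continue
        pred_proj.add(anc)

    tp = len(truth_proj & pred_proj)
    fp = len(pred_proj - truth_proj)
    fn = len(truth_proj - pred_proj)
    return confusion_from_counts(len(truth_proj), tp, fp, fn, rank)


def confusion_sets(
    truth_taxa: Iterable[int],
    predicted: AbundanceTable,
    store: TaxonomyStore,
    rank: str,
    cfg: Optional[PruneConfig] = None,
    superkingdom: Optional[str] = None,
) -> tuple[set[int], set[int]]:
    """The (FP, FN) rank-level taxid sets behind a confusion result."""
    truth_proj = {store.ancestor_at_rank(t, rank) for t in truth_taxa}
    table = percentile_prune(predicted, cfg) if cfg is not None else predicted
    pred_proj = set()
    for t in table.counts:
        anc = store.ancestor_at_rank(t, rank)
        if anc is None:
            continue
        if superkingdom is not None:
            sk = store.superkingdom_name(anc)
            if sk is None or sk.casefold() != superkingdom.casefold():
                continue
        pred_proj.add(anc)
    return pred_proj - truth_proj, truth_proj - pred_proj


@dataclass(frozen=True)
class BinningRecord:
    """Read-binning accuracy for one truth genome.

    ``taxid`` is the genome's rank-level taxon. Recall is computed against
    the genome's own simulated read ids; precision pools the truth reads of
    all genomes sharing the taxid, so that several assemblies collapsing to
    one taxon (the parvovirus situation) are not penalised.
    """

    genome_id: str
    taxid: int
    truth_reads: int
    predicted_reads: int
    intersection: int
    recall: float
    precision: float


def read_binning_eval(
    truth: TruthTable,
    assignments: Iterable[Assignment],
    store: TaxonomyStore,
    rank: str = "species",
) -> list[BinningRecord]:
    """Compare simulated read ids with pipeline-assigned read ids per genome."""
    predicted: dict[int, set[str]] = {}
    for a in assignments:
        if a.source == "contig_hit" or a.taxid is None:
            continue
        anc = store.ancestor_at_rank(a.taxid, rank)
        if anc is not None:
            predicted.setdefault(anc, set()).add(a.query_id.rsplit("/", 1)[0])

    genome_reads: dict[str, set[str]] = {}
    genome_taxid: dict[str, int] = {}
    for rec in truth.records:
        genome_reads.setdefault(rec.genome_id, set()).add(rec.read_id)
        anc = store.ancestor_at_rank(rec.taxid, rank)
        if anc is None:
            raise ValueError(f"truth genome {rec.genome_id} has no rank-{rank} taxon")
        genome_taxid[rec.genome_id] = anc

    pooled: dict[int, set[str]] = {}
    for gid, taxid in genome_taxid.items():
        pooled.setdefault(taxid, set()).update(genome_reads[gid])

    out = []
    for gid in sorted(genome_reads):
        taxid = genome_taxid[gid]
        T = genome_reads[gid]
        P = predicted.get(taxid, set())
        inter = len(T & P)
        out.append(
            BinningRecord(
                genome_id=gid,
                taxid=taxid,
                truth_reads=len(T),
                predicted_reads=len(P),
                intersection=inter,
                recall=inter / len(T),
                precision=(len(pooled[taxid] & P) / len(P)) if P else 0.0,
            )
        )
    return out


@dataclass(frozen=True)
class CoverageResult:
    genome_id: str
    genome_length: int
    covered_bases: int
    covered_fraction: float


def horizontal_coverage(
    intervals: Iterable[tuple[int, int]], genome_length: int, genome_id: str = ""
) -> CoverageResult:
    """Breadth of coverage: length of the union of half-open intervals over
    the genome, as bases and as a fraction of the genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    ivs = sorted(intervals)
    covered = 0
    cur_start: Optional[int] = None
    cur_end = 0
    for start, end in ivs:
        if not (0 <= start < end <= genome_length):
            raise ValueError(f"interval ({start}, {end}) out of bounds for length {genome_length}")
        if cur_start is None or start > cur_end:
            if cur_start is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        covered += cur_end - cur_start
    return CoverageResult(genome_id, genome_length, covered, covered / genome_length)


AUDIT_CAUSES = (
    "host_filtered",
    "shared_region_tie",
    "chimeric_assembly",
    "decoy_homolog",
    "dropped_hits",
    "pruned_low_abundance",
    "unexplained",
)


@dataclass(frozen=True)
class ErrorAuditEntry:
    taxid: int
    kind: str  # "FP" | "FN"
    cause: str
    evidence: str

    def __post_init__(self) -> None:
        if self.kind not in ("FP", "FN"):
            raise ValueError("kind must be FP or FN")
        if self.cause not in AUDIT_CAUSES:
            raise ValueError(f"unknown audit cause {self.cause!r}")


def error_audit(
    fn_taxids: Iterable[int],
    fp_taxids: Iterable[int],
    *,
    truth: TruthTable,
    assignments: Sequence[Assignment],
    removal_log: Iterable[str],
    contig_hits: HitTable,
    read_hits: HitTable,
    r2c: ReadToContigMap,
    store: TaxonomyStore,
    rank: str,
    pre_prune: AbundanceTable,
    post_prune: AbundanceTable,
) -> list[ErrorAuditEntry]:
    """Attribute each FP/FN taxon to a cause by a fixed rule cascade.

    False negatives, first matching rule wins:

    1. at least half of the taxon's truth read pairs were removed by host
       filtering -> ``host_filtered``;
    2. its reads inherited a contig whose reads span two or more truth taxa
       -> ``chimeric_assembly``;
    3. its queries' best hits were ambiguous ties -> ``shared_region_tie``;
    4. its queries are absent from both hit tables -> ``dropped_hits``;
    5. present before pruning, absent after -> ``pruned_low_abundance``;
    6. otherwise ``unexplained``.

    False positives: the winner of an ambiguous tie is ``shared_region_tie``;
    a taxon introduced by an injected decoy hit is ``decoy_homolog``;
    otherwise ``unexplained``. All stage logs from one pipeline run are
    required; a missing one raises naming the absent stage.
    """
    stage_args = {
        "truth": truth,
        "assignments": assignments,
        "removal_log": removal_log,
        "contig_hits": contig_hits,
        "read_hits": read_hits,
        "read-to-contig map": r2c,
        "pre_prune": pre_prune,
        "post_prune": post_prune,
    }
    for stage, value in stage_args.items():
        if value is None:
            raise ValueError(f"error audit requires the {stage} log")

    removed = set(removal_log)
    project = lambda t: store.ancestor_at_rank(t, rank)

    truth_by_taxon: dict[int, list] = {}
    read_truth_taxon: dict[str, int] = {}
    for rec in truth.records:
        anc = project(rec.taxid)
        if anc is None:
            continue
        truth_by_taxon.setdefault(anc, []).append(rec)
        read_truth_taxon[rec.read_id] = anc

    contig_truth_span: dict[str, set[int]] = {}
    contig_of_taxon: dict[int, set[str]] = {}
    for read_id, cid in r2c.mapping.items():
        t = read_truth_taxon.get(read_id.rsplit("/", 1)[0])
        if t is None:
            continue
        contig_truth_span.setdefault(cid, set()).add(t)
        contig_of_taxon.setdefault(t, set()).add(cid)

    contig_best = best_hit(contig_hits)
    read_best = best_hit(read_hits)

    entries: list[ErrorAuditEntry] = []
    fn_causes: dict[int, str] = {}
    for taxid in sorted(set(fn_taxids)):
        recs = truth_by_taxon.get(taxid, [])
        pair_ids = {r.read_id for r in recs}
        mate_ids = {p + suf for p in pair_ids for suf in ("/1", "/2")}
        n_removed = len(pair_ids & removed)
        contigs = contig_of_taxon.get(taxid, set())
        queries = contigs | mate_ids

        if pair_ids and n_removed * 2 >= len(pair_ids):
            cause, ev = "host_filtered", f"{n_removed}/{len(pair_ids)} truth read pairs in host removal log"
        elif any(len(contig_truth_span.get(c, set())) >= 2 for c in contigs):
            bad = sorted(c for c in contigs if len(contig_truth_span.get(c, set())) >= 2)
            cause, ev = "chimeric_assembly", f"reads co-assembled with another taxon in contig(s) {', '.join(bad)}"
        elif any(contig_best[q][1] for q in contigs if q in contig_best) or any(
            read_best[q][1] for q in mate_ids if q in read_best
        ):
            cause, ev = "shared_region_tie", "best hit tied between multiple taxa at equal score and identity"
        elif not any(q in contig_best for q in contigs) and not any(q in read_best for q in mate_ids):
            cause, ev = "dropped_hits", "no hits recorded for any query of this taxon"
        elif taxid in pre_prune.counts and taxid not in post_prune.counts:
            cause, ev = "pruned_low_abundance", (
                f"readn {pre_prune.counts[taxid]} fell in the pruned tail of the read distribution"
            )
        else:
            cause, ev = "unexplained", "no audit rule matched"
        fn_causes[taxid] = cause
        entries.append(ErrorAuditEntry(taxid, "FN", cause, ev))

    # winners of ambiguous ties, projected to rank
    ambiguous_winners: set[int] = set()
    for a in assignments:
        if a.ambiguous and a.taxid is not None:
            anc = project(a.taxid)
            if anc is not None:
                ambiguous_winners.add(anc)
    injected_decoys: set[int] = set()
    for table in (contig_hits, read_hits):
        for h in table.hits:
            if "decoy" in h.note:
                anc = project(h.subject_taxid)
                if anc is not None:
                    injected_decoys.add(anc)

    tie_fns = {t for t, c in fn_causes.items() if c == "shared_region_tie"}
    for taxid in sorted(set(fp_taxids)):
        if taxid in ambiguous_winners and tie_fns:
            cause, ev = "shared_region_tie", (
                f"won an ambiguous tie paired with FN taxon(s) {sorted(tie_fns)}"
            )
        elif taxid in injected_decoys:
            cause, ev = "decoy_homolog", "called from an injected decoy hit"
        else:
            cause, ev = "unexplained", "no audit rule matched"
        entries.append(ErrorAuditEntry(taxid, "FP", cause, ev))
    return entries
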
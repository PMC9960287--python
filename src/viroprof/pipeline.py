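"""Deterministic end-to-end orchestration of the profiling workflow.

One run executes: host filtering -> minimizer mapping of contigs and of
unassembled reads against the reference set -> optional hit-table fault
injections -> contig-first taxon assignment -> per-rank abundance ->
per-superkingdom percentile pruning -> contig splitting -> reports. Every
intermediate (removal log, hit tables, pre/post-prune tables) is retained on
the run object so that errors can be audited stage by stage, and identical
configuration plus seed yields byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io_utils as io
from .evaluate import (
    ConfusionResult,
    ErrorAuditEntry,
    confusion,
    confusion_sets,
    error_audit,
)
from .profile import (
    DEFAULT_PRUNE_T,
    AbundanceTable,
    Assignment,
    PruneConfig,
    ReadToContigMap,
    abundance,
    assign_taxa,
    host_filter,
    percentile_prune,
    split_contigs,
    subtable_by_superkingdom,
)
from .scenarios import Contig, Fixture, ScenarioSpec
from .simulate import inject_hit_errors
from .taxonomy import PhageLabelSet, TaxonomyStore, load_taxonomy
from .toymap import HitTable, build_index, map_queries

__all__ = [
    "MapperParams",
    "RunConfig",
    "PipelineRun",
    "StageError",
    "run_pipeline",
    "load_fixture",
    "virus_confusion",
    "audit_run",
]


@dataclass(frozen=True)
class MapperParams:
    k: int = 15
    w: int = 10
    min_chain: int = 3
    min_identity: float = 0.80


@dataclass
class RunConfig:
    """Stage toggles and thresholds for one pipeline run.

    ``prune_t`` maps superkingdom name to the prune percentile applied to
    that report (defaults: last percentile for viruses, last five for
    bacteria); unlisted superkingdoms are not pruned. Host filtering can be
    switched off entirely, which is the documented remedy for endogenous
    viral elements being removed with the host reads.
    """

    rank: str = "species"
    host_filter_on: bool = True
    host_min_identity: float = 0.90
    host_min_aln: int = 100
    prune_t: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PRUNE_T))
    mapper: MapperParams = field(default_factory=MapperParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineRun:
    """All intermediates and results of one run."""

    config: RunConfig
    kept_pairs: list
    removed_ids: list[str]
    r2c: ReadToContigMap
    contig_hits: HitTable
    read_hits: HitTable
    assignments: list[Assignment]
    table_all: AbundanceTable
    sk_tables: dict[str, tuple[AbundanceTable, AbundanceTable]]  # pre-, post-prune
    splits: tuple[set[str], set[str], set[str]]
    total_reads: int
    outdir: Optional[Path] = None


def run_pipeline(
    fixture: Fixture, cfg: Optional[RunConfig] = None, outdir: Optional[str | Path] = None
) -> PipelineRun:
    """Run the full workflow on a fixture; optionally write reports to ``outdir``."""
    cfg = cfg or RunConfig()
    mp = cfg.mapper

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(name, exc) from exc

    if cfg.host_filter_on and fixture.host_genomes:
        def _host():
            idx = build_index(fixture.host_genomes, k=mp.k, w=mp.w)
            return host_filter(
                fixture.reads, idx, cfg.host_min_identity, cfg.host_min_aln, mp.min_chain
            )
        kept, removed = stage("host_filter", _host)
    else:
        kept, removed = list(fixture.reads), []

    surviving = {p.pair_id + suffix for p in kept for suffix in ("/1", "/2")}
    r2c = fixture.r2c.restrict(surviving)

    def _map():
        ref_idx = build_index(fixture.ref_genomes, k=mp.k, w=mp.w)
        contig_hits = map_queries(
            [(c.contig_id, c.sequence) for c in fixture.contigs],
            ref_idx, min_chain=mp.min_chain, min_identity=mp.min_identity,
        )
        mate_seq = {}
        for p in kept:
            mate_seq[p.r1.id] = p.r1.sequence
            mate_seq[p.r2.id] = p.r2.sequence
        read_hits = map_queries(
            [(rid, mate_seq[rid]) for rid in sorted(r2c.unassembled) if rid in mate_seq],
            ref_idx, min_chain=mp.min_chain, min_identity=mp.min_identity,
        )
        return contig_hits, read_hits

    contig_hits, read_hits = stage("mapping", _map)

    def _edits():
        ch, rh = contig_hits, read_hits
        for which, mode, params in fixture.hit_edits:
            if which == "contig":
                ch = inject_hit_errors(ch, mode, params, seed=cfg.seed)
            elif which == "read":
                rh = inject_hit_errors(rh, mode, params, seed=cfg.seed)
            else:
                raise ValueError(f"hit edit targets unknown table {which!r}")
        return ch, rh

    if fixture.hit_edits:
        contig_hits, read_hits = stage("hit_injection", _edits)

    assignments = stage("assignment", lambda: assign_taxa(contig_hits, read_hits, r2c))
    total_reads = 2 * len(kept)
    table_all = stage(
        "abundance", lambda: abundance(assignments, fixture.store, cfg.rank, total_reads)
    )

    def _prune():
        out: dict[str, tuple[AbundanceTable, AbundanceTable]] = {}
        for sk in ("Viruses", "Bacteria", "Eukaryota"):
            sub = subtable_by_superkingdom(table_all, fixture.store, sk)
            if not sub.counts:
                continue
            t = cfg.prune_t.get(sk, 0.0)
            out[sk] = (sub, percentile_prune(sub, PruneConfig(t)))
        return out

    sk_tables = stage("pruning", _prune)
    splits = stage(
        "contig_splitting", lambda: split_contigs(assignments, fixture.store, fixture.labels)
    )

    run = PipelineRun(
        config=cfg,
        kept_pairs=kept,
        removed_ids=list(removed),
        r2c=r2c,
        contig_hits=contig_hits,
        read_hits=read_hits,
        assignments=assignments,
        table_all=table_all,
        sk_tables=sk_tables,
        splits=splits,
        total_reads=total_reads,
    )
    if outdir is not None:
        stage("reporting", lambda: _write_reports(run, fixture, Path(outdir)))
        run.outdir = Path(outdir)
    return run


def _write_reports(run: PipelineRun, fixture: Fixture, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_paf(run.contig_hits, outdir / "contig_hits.paf")
    io.write_paf(run.read_hits, outdir / "read_hits.paf")
    io.write_tsv(
        pd.DataFrame({"read_id": run.removed_ids}), outdir / "host_removal_log.tsv"
    )
    for sk, (pre, post) in sorted(run.sk_tables.items()):
        io.write_abundance(pre, fixture.store, outdir / f"abundance_{sk.lower()}_preprune.tsv")
        io.write_abundance(post, fixture.store, outdir / f"abundance_{sk.lower()}.tsv")
    viral, phage, unmapped = run.splits
    for name, ids in (("vi", viral), ("phages", phage), ("un", unmapped)):
        io.write_tsv(pd.DataFrame({"contig_id": sorted(ids)}), outdir / f"contigs_{name}.tsv")

    checksums = {}
    for path in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.paf")):
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    log = {
        "config": run.config.to_dict(),
        "n_input_pairs": len(fixture.reads),
        "n_kept_pairs": len(run.kept_pairs),
        "n_removed_pairs": len(run.removed_ids),
        "n_contigs": len(fixture.contigs),
        "checksums": checksums,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


def load_fixture(fixture_dir: str | Path) -> Fixture:
    """Rebuild a fixture from a directory written by ``Fixture.write``."""
    d = Path(fixture_dir)
    host_genomes = io.read_genomes(d / "host.fasta")
    ref_genomes = io.read_genomes(d / "reference.fasta")
    with open(d / "manifest.json", "rt", encoding="utf-8") as fh:
        doc = json.load(fh)
    contig_sources = doc.get("contig_sources", {})
    contigs = [
        Contig(g.genome_id, g.sequence, tuple(contig_sources.get(g.genome_id, ())))
        for g in io.read_genomes(d / "contigs.fasta")
    ]
    reads = io.read_fastq_pairs(d / "reads_R1.fastq.gz", d / "reads_R2.fastq.gz")
    truth = io.read_truth(d / "truth.tsv")
    r2c = io.read_r2c(d / "r2c.tsv")
    store = load_taxonomy(d / "taxonomy.tsv")
    labels = PhageLabelSet.from_file(d / "phage_labels.txt")
    design = io.read_design(d / "design.yaml", host_genomes + ref_genomes)
    manifest = doc.get("manifest", {})
    hit_edits = [tuple(e) for e in doc.get("hit_edits", [])]
    spec = ScenarioSpec(name=manifest.get("scenario", "clean"))
    return Fixture(
        spec=spec,
        design=design,
        host_genomes=host_genomes,
        ref_genomes=ref_genomes,
        contigs=contigs,
        r2c=r2c,
        reads=reads,
        truth=truth,
        store=store,
        labels=labels,
        hit_edits=[(a, b, c) for a, b, c in hit_edits],
        manifest=manifest,
    )


def virus_confusion(
    run: PipelineRun, fixture: Fixture, rank: str = "species"
) -> tuple[ConfusionResult, set[int], set[int]]:
    """Score the pruned virus report against the designed virus taxa.

    Returns the confusion result plus the FP and FN rank-level taxid sets.
    """
    pre, post = run.sk_tables.get("Viruses", (None, None))
    if post is None:
        post = AbundanceTable(rank, {}, run.total_reads)
    conf = confusion(
        fixture.virus_truth_taxa, post, fixture.store, rank, cfg=None, superkingdom="Viruses"
    )
    fp, fn = confusion_sets(
        fixture.virus_truth_taxa, post, fixture.store, rank, cfg=None, superkingdom="Viruses"
    )
    return conf, fp, fn


def audit_run(
    run: PipelineRun, fixture: Fixture, rank: str = "species"
) -> tuple[ConfusionResult, list[ErrorAuditEntry]]:
    """Virus-report confusion plus the stage-attribution audit of its errors."""
    conf, fp, fn = virus_confusion(run, fixture, rank)
    pre, post = run.sk_tables.get(
        "Viruses",
        (AbundanceTable(rank, {}, run.total_reads), AbundanceTable(rank, {}, run.total_reads)),
    )
    entries = error_audit(
        fn,
        fp,
        truth=fixture.truth,
        assignments=run.assignments,
        removal_log=run.removed_ids,
        contig_hits=run.contig_hits,
        read_hits=run.read_hits,
        r2c=run.r2c,
        store=fixture.store,
        rank=rank,
        pre_prune=pre,
        post_prune=post,
    )
    return conf, entries
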
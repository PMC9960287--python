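"""Readers and writers for the toolkit's on-disk formats.

FASTA/FASTQ go through Biopython (gzip-aware on both ends); homology hits
round-trip through PAF with taxid/identity/score tags and can also be read
from BLAST tabular output (outfmt 6 plus a subject-taxid column); tabular
reports are tab-separated with a ``#``-prefixed header row.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .profile import AbundanceTable, ReadToContigMap
from .simulate import (
    FastqRecord,
    GenomeRecord,
    MetagenomeDesign,
    ReadPair,
    ReadSimParams,
    ReadTruthRecord,
    TruthTable,
)
from .taxonomy import TaxonomyStore
from .toymap import Hit, HitTable

__all__ = [
    "xopen",
    "read_genomes",
    "write_genomes",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_truth",
    "write_truth",
    "read_r2c",
    "write_r2c",
    "read_paf",
    "write_paf",
    "read_blast_tab",
    "write_tsv",
    "read_tsv",
    "write_abundance",
    "write_design",
    "read_design",
]


def xopen(path: str | Path, mode: str = "rt") -> IO:
    """Open a path, transparently gzipped when it ends in ``.gz``."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ

def write_genomes(path: str | Path, genomes: Iterable[GenomeRecord]) -> None:
    """FASTA with ``taxid=`` and ``role=`` key-value pairs in the description."""
    records = (
        SeqRecord(Seq(g.sequence), id=g.genome_id, description=f"taxid={g.taxid} role={g.role}")
        for g in genomes
    )
    with xopen(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_genomes(path: str | Path) -> list[GenomeRecord]:
    out = []
    with xopen(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            meta = dict(
                token.split("=", 1) for token in rec.description.split() if "=" in token
            )
            out.append(
                GenomeRecord(
                    genome_id=rec.id,
                    taxid=int(meta.get("taxid", 0) or 0),
                    role=meta.get("role", "virus"),
                    sequence=str(rec.seq).upper(),
                )
            )
    return out


def write_fastq_pairs(r1_path: str | Path, r2_path: str | Path, pairs: Iterable[ReadPair]) -> None:
    pairs = list(pairs)

    def _records(which: str):
        for p in pairs:
            mate = p.r1 if which == "r1" else p.r2
            rec = SeqRecord(Seq(mate.sequence), id=mate.id, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in mate.quality]
            yield rec

    with xopen(r1_path, "wt") as fh:
        SeqIO.write(_records("r1"), fh, "fastq")
    with xopen(r2_path, "wt") as fh:
        SeqIO.write(_records("r2"), fh, "fastq")


def _read_fastq(path: str | Path) -> list[FastqRecord]:
    out = []
    with xopen(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(FastqRecord(rec.id, str(rec.seq), qual))
    return out


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    r1 = _read_fastq(r1_path)
    r2 = _read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError("R1 and R2 files hold different numbers of records")
    pairs = []
    for a, b in zip(r1, r2):
        pid_a, pid_b = a.id.rsplit("/", 1)[0], b.id.rsplit("/", 1)[0]
        if pid_a != pid_b:
            raise ValueError(f"unpaired records {a.id} / {b.id}")
        pairs.append(ReadPair(pid_a, a, b))
    return pairs


# ------------------------------------------------------------------ TSV plumbing

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated with a '#'-prefixed header row."""
    with xopen(path, "wt") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with xopen(path, "rt") as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", names=header)


_TRUTH_COLS = ["read_id", "genome_id", "taxid", "role", "start", "end", "strand"]


def write_truth(truth: TruthTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.read_id, r.genome_id, r.taxid, r.role, r.fragment_start, r.fragment_end, r.strand)
            for r in truth.records
        ],
        columns=_TRUTH_COLS,
    )
    write_tsv(df, path)


def read_truth(path: str | Path) -> TruthTable:
    df = read_tsv(path)
    records = [
        ReadTruthRecord(
            read_id=row.read_id,
            genome_id=row.genome_id,
            taxid=int(row.taxid),
            role=row.role,
            fragment_start=int(row.start),
            fragment_end=int(row.end),
            strand=row.strand,
        )
        for row in df.itertuples()
    ]
    return TruthTable(records)


def write_r2c(r2c: ReadToContigMap, path: str | Path) -> None:
    rows = [(r, c) for r, c in sorted(r2c.mapping.items())]
    rows += [(r, "") for r in sorted(r2c.unassembled)]
    write_tsv(pd.DataFrame(rows, columns=["read_id", "contig_id"]), path)


def read_r2c(path: str | Path) -> ReadToContigMap:
    df = read_tsv(path)
    mapping: dict[str, str] = {}
    unassembled: set[str] = set()
    for row in df.itertuples():
        cid = "" if pd.isna(row.contig_id) else str(row.contig_id)
        if cid:
            mapping[str(row.read_id)] = cid
        else:
            unassembled.add(str(row.read_id))
    return ReadToContigMap(mapping, unassembled)


# ----------------------------------------------------------------------- hits

def write_paf(table: HitTable, path: str | Path) -> None:
    """Standard 12-column PAF plus ``ti`` (taxid), ``sc`` (score), ``id``
    (identity) and optional ``nt`` (note) tags."""
    with xopen(path, "wt") as fh:
        for h in table.hits:
            cols = [
                h.query_id,
                str(h.query_len),
                str(h.query_start),
                str(h.query_end),
                h.strand,
                h.subject_id,
                str(h.subject_len),
                str(h.subject_start),
                str(h.subject_end),
                str(h.matches),
                str(h.aln_length),
                "255",
                f"ti:i:{h.subject_taxid}",
                f"sc:i:{h.score}",
                f"id:f:{h.identity:.6f}",
            ]
            if h.note:
                cols.append(f"nt:Z:{h.note}")
            fh.write("\t".join(cols) + "\n")


def read_paf(path: str | Path) -> HitTable:
    hits = []
    with xopen(path, "rt") as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tags = {t.split(":", 1)[0]: t.split(":", 2)[2] for t in f[12:] if t.count(":") >= 2}
            matches, aln = int(f[9]), int(f[10])
            hits.append(
                Hit(
                    query_id=f[0],
                    query_start=int(f[2]),
                    query_end=int(f[3]),
                    subject_id=f[5],
                    subject_taxid=int(tags.get("ti", 0)),
                    subject_start=int(f[7]),
                    subject_end=int(f[8]),
                    strand=f[4],
                    matches=matches,
                    aln_length=aln,
                    score=int(tags.get("sc", 2 * matches - aln)),
                    query_len=int(f[1]),
                    subject_len=int(f[6]),
                    note=tags.get("nt", ""),
                )
            )
    return HitTable(hits, provenance="external-PAF")


def read_blast_tab(path: str | Path) -> HitTable:
    """BLAST outfmt 6 with a 13th ``staxids`` column.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore staxids. BLAST coordinates are 1-based inclusive
    with sstart > send on the minus strand; they are converted to 0-based
    half-open here. Score is matches - mismatches for consistency with the
    internal mapper.
    """
    hits = []
    with xopen(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            pident, length, mismatch = float(f[2]), int(f[3]), int(f[4])
            sstart, send = int(f[8]), int(f[9])
            strand = "+" if send >= sstart else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            matches = int(round(pident / 100.0 * length))
            taxid = int(f[12].split(";")[0])
            hits.append(
                Hit(
                    query_id=f[0],
                    query_start=int(f[6]) - 1,
                    query_end=int(f[7]),
                    subject_id=f[1],
                    subject_taxid=taxid,
                    subject_start=lo - 1,
                    subject_end=hi,
                    strand=strand,
                    matches=matches,
                    aln_length=length,
                    score=matches - mismatch,
                )
            )
    return HitTable(hits, provenance="external-BLAST")


# -------------------------------------------------------------------- reports

def write_abundance(table: AbundanceTable, store: TaxonomyStore, path: str | Path) -> None:
    rows = []
    total = table.total_reads or 1
    for taxid, readn in table.rows():
        node = store.nodes.get(taxid)
        rows.append(
            (taxid, node.name if node else "", table.rank, readn, round(100.0 * readn / total, 4))
        )
    write_tsv(
        pd.DataFrame(rows, columns=["taxid", "name", "rank", "readn", "readn_pct"]), path
    )


# --------------------------------------------------------------------- design

def write_design(design: MetagenomeDesign, path: str | Path) -> None:
    doc = {
        "params": {
            "read_length": design.params.read_length,
            "insert_mean": design.params.insert_mean,
            "insert_sd": design.params.insert_sd,
            "error_rate_start": design.params.error_rate_start,
            "error_rate_end": design.params.error_rate_end,
            "seed": design.params.seed,
        },
        "components": [
            {"genome_id": g.genome_id, "taxid": g.taxid, "role": g.role, "coverage": cov}
            for g, cov in design.components
        ],
    }
    with xopen(path, "wt") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_design(path: str | Path, genomes: Iterable[GenomeRecord]) -> MetagenomeDesign:
    """Rebuild a design from its YAML file plus the genome sequences."""
    with xopen(path, "rt") as fh:
        doc = yaml.safe_load(fh)
    by_id = {g.genome_id: g for g in genomes}
    components = []
    for comp in doc["components"]:
        gid = comp["genome_id"]
        if gid not in by_id:
            raise ValueError(f"design references unknown genome {gid!r}")
        components.append((by_id[gid], float(comp["coverage"])))
    return MetagenomeDesign(components, ReadSimParams(**doc["params"]))
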
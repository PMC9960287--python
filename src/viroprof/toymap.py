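"""Minimizer-seeded, ungapped-extension read/contig mapper.

A deliberately small seed-and-extend mapper that fills the nucleotide
homology-search slot of the pipeline without external aligners. Canonical
k-mer minimizers (invertible 64-bit mixing hash, leftmost tie-break within a
window) are indexed over the reference set; query minimizers are chained per
(subject, strand, diagonal) and chains with enough seeds are extended
without gaps, which is exact here because the read simulator emits
substitutions only. Output is a hit table with the quantities profiling
consumes: subject taxid, identity, aligned length and score
(matches - mismatches).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["Hit", "HitTable", "MinimizerIndex", "build_index", "map_queries"]

_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """2-bit encode a DNA string (non-ACGT characters collapse to A)."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _mix64(x: np.ndarray) -> np.ndarray:
    # Murmur3 finalizer: invertible mixing of the canonical k-mer code.
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xFF51AFD7ED558CCD)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xC4CEB9FE1A85EC53)
    x ^= x >> np.uint64(33)
    return x


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement integer codes of every k-mer."""
    n = len(codes) - k + 1
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    pw_fwd = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    pw_rc = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
    fwd = (win * pw_fwd).sum(axis=1)
    rc = ((np.uint64(3) - win) * pw_rc).sum(axis=1)
    return fwd, rc


def minimizers(codes: np.ndarray, k: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hash, position, strand) of the canonical (k, w)-minimizers of a sequence.

    Strand is +1 when the forward k-mer is canonical, -1 otherwise. Ties
    within a window go to the leftmost position.
    """
    if len(codes) < k:
        return np.empty(0, np.uint64), np.empty(0, np.int64), np.empty(0, np.int8)
    fwd, rc = _kmer_codes(codes, k)
    canonical = np.where(fwd <= rc, fwd, rc)
    strand = np.where(fwd <= rc, 1, -1).astype(np.int8)
    h = _mix64(canonical)
    n = len(h)
    if n <= w:
        pos = np.array([int(np.argmin(h))], dtype=np.int64)
    else:
        wins = np.lib.stride_tricks.sliding_window_view(h, w)
        pos = wins.argmin(axis=1) + np.arange(n - w + 1)
        keep = np.ones(len(pos), dtype=bool)
        keep[1:] = pos[1:] != pos[:-1]
        pos = np.unique(pos[keep])
    return h[pos], pos, strand[pos]


@dataclass(frozen=True)
class Hit:
    """One ungapped homology hit (0-based half-open coordinates)."""

    query_id: str
    query_start: int
    query_end: int
    subject_id: str
    subject_taxid: int
    subject_start: int
    subject_end: int
    strand: str
    matches: int
    aln_length: int
    score: int
    query_len: int = 0
    subject_len: int = 0
    note: str = ""

    @property
    def identity(self) -> float:
        return self.matches / self.aln_length if self.aln_length else 0.0

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start:
            raise ValueError(f"hit {self.query_id}: query_end must exceed query_start")
        if self.matches > self.aln_length:
            raise ValueError(f"hit {self.query_id}: matches exceed alignment length")


@dataclass
class HitTable:
    """Hits sorted by (query_id, descending score); the interchange object
    between mapping and profiling. ``provenance`` records the producer
    (toymap / external-PAF / external-BLAST); ``edits`` logs fault injections."""

    hits: list[Hit]
    provenance: str = "toymap"
    edits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits = sorted(
            self.hits,
            key=lambda h: (h.query_id, -h.score, -h.identity, h.subject_taxid, h.subject_id),
        )

    def __len__(self) -> int:
        return len(self.hits)

    def queries(self) -> set[str]:
        return {h.query_id for h in self.hits}

    def by_query(self) -> dict[str, list[Hit]]:
        out: dict[str, list[Hit]] = {}
        for h in self.hits:
            out.setdefault(h.query_id, []).append(h)
        return out


@dataclass
class _Reference:
    genome_id: str
    taxid: int
    codes: np.ndarray

    @property
    def length(self) -> int:
        return len(self.codes)


class MinimizerIndex:
    """Canonical-minimizer index over a reference genome set."""

    def __init__(self, references: Iterable, k: int = 15, w: int = 10):
        if k < 1 or w < 1:
            raise ValueError("k and w must be positive")
        self.k = k
        self.w = w
        self.refs: list[_Reference] = []
        self.registry: dict[str, tuple[int, int]] = {}  # genome_id -> (taxid, length)
        self.table: dict[int, list[tuple[int, int, int]]] = {}
        for ref in references:
            seq = ref.sequence
            if len(seq) < k:
                warnings.warn(
                    f"reference {ref.genome_id} shorter than k={k}; skipped", stacklevel=2
                )
                continue
            ridx = len(self.refs)
            codes = encode(seq)
            self.refs.append(_Reference(ref.genome_id, ref.taxid, codes))
            self.registry[ref.genome_id] = (ref.taxid, len(seq))
            hashes, positions, strands = minimizers(codes, k, w)
            for h, p, s in zip(hashes.tolist(), positions.tolist(), strands.tolist()):
                self.table.setdefault(h, []).append((ridx, p, s))

    def __len__(self) -> int:
        return len(self.refs)


def build_index(references: Sequence, k: int = 15, w: int = 10) -> MinimizerIndex:
    """Index reference genomes (objects with genome_id, taxid, sequence)."""
    return MinimizerIndex(references, k=k, w=w)


def _extend(
    qcodes: np.ndarray,
    rcq: np.ndarray,
    ref: _Reference,
    rel_strand: int,
    diag: int,
    k: int,
) -> Optional[tuple[int, int, int, int, int, int]]:
    """Ungapped comparison of the full query placed on the reference at ``diag``.

    Returns (matches, aln_len, qstart, qend, sstart, send) or None when the
    placement falls outside the reference.
    """
    qlen = len(qcodes)
    r0 = diag if rel_strand == 1 else diag + k - qlen
    s = max(r0, 0)
    e = min(r0 + qlen, ref.length)
    if e <= s:
        return None
    refseg = ref.codes[s:e]
    if rel_strand == 1:
        qseg = qcodes[s - r0 : e - r0]
        qstart, qend = s - r0, e - r0
    else:
        qseg = rcq[s - r0 : e - r0]
        qstart, qend = qlen - (e - r0), qlen - (s - r0)
    matches = int((qseg == refseg).sum())
    return matches, e - s, qstart, qend, s, e


def map_queries(
    queries: Iterable[tuple[str, str]],
    index: MinimizerIndex,
    min_chain: int = 3,
    min_identity: float = 0.80,
) -> HitTable:
    """Map queries against the index; returns at most one hit per (query, subject).

    Seeds are grouped per (subject, relative strand, diagonal); for each
    subject/strand the best-supported diagonal with at least ``min_chain``
    seeds is extended without gaps over the whole query placement, and hits
    below ``min_identity`` are discarded. Unmappable queries are simply
    absent from the output. Equally scoring hits on different subjects are
    all reported, which is what lets downstream best-hit selection detect
    ambiguous ties.
    """
    k, w = index.k, index.w
    hits: list[Hit] = []
    for query_id, seq in queries:
        qcodes = encode(seq)
        qlen = len(qcodes)
        hashes, positions, strands = minimizers(qcodes, k, w)
        if len(hashes) == 0:
            continue
        anchors: dict[tuple[int, int, int], int] = {}
        for h, qpos, qstrand in zip(hashes.tolist(), positions.tolist(), strands.tolist()):
            entries = index.table.get(h)
            if not entries:
                continue
            for ridx, rpos, rstrand in entries:
                rel = 1 if qstrand == rstrand else -1
                diag = rpos - qpos if rel == 1 else rpos + qpos
                key = (ridx, rel, diag)
                anchors[key] = anchors.get(key, 0) + 1
        if not anchors:
            continue
        # best-supported diagonal per (subject, strand)
        best_diag: dict[tuple[int, int], tuple[int, int]] = {}
        for (ridx, rel, diag), count in anchors.items():
            cur = best_diag.get((ridx, rel))
            if cur is None or count > cur[0] or (count == cur[0] and diag < cur[1]):
                best_diag[(ridx, rel)] = (count, diag)
        rcq = (3 - qcodes)[::-1]
        per_ref: dict[int, Hit] = {}
        for (ridx, rel), (count, diag) in sorted(best_diag.items()):
            if count < min_chain:
                continue
            ref = index.refs[ridx]
            ext = _extend(qcodes, rcq, ref, rel, diag, k)
            if ext is None:
                continue
            matches, aln, qs, qe, ss, se = ext
            if aln == 0 or matches / aln < min_identity:
                continue
            hit = Hit(
                query_id=query_id,
                query_start=qs,
                query_end=qe,
                subject_id=ref.genome_id,
                subject_taxid=ref.taxid,
                subject_start=ss,
                subject_end=se,
                strand="+" if rel == 1 else "-",
                matches=matches,
                aln_length=aln,
                score=2 * matches - aln,
                query_len=qlen,
                subject_len=ref.length,
            )
            prev = per_ref.get(ridx)
            if prev is None or (hit.score, hit.identity) > (prev.score, prev.identity):
                per_ref[ridx] = hit
        hits.extend(per_ref.values())
    return HitTable(hits, provenance="toymap")
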
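"""Synthetic genomes, Illumina-like paired-end reads and composed metagenomes.

The simulator stands in for a short-read simulator such as ART at desk
scale. It produces 2x150 nt paired-end libraries with a two-parameter,
position-dependent substitution error model (error probability interpolated
linearly from the start to the end of each read, with Phred qualities
consistent with the local rate) and no indels. Fragment lengths are normal,
fragment starts uniform over the linear genome, and every read pair carries a
truth record (source genome, taxid, coordinates, strand) so that downstream
taxon calls and read binning can be scored exactly.

It also builds the error-inducing constructs used for fault injection:
shared identical regions between two genomes, endogenous elements spliced
into a host genome, and doctored homology-hit tables (decoy homologs,
dropped queries, tied best hits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ROLES",
    "GenomeRecord",
    "FastqRecord",
    "ReadPair",
    "ReadSimParams",
    "ReadTruthRecord",
    "TruthTable",
    "MetagenomeDesign",
    "generate_genome",
    "revcomp",
    "plant_shared_region",
    "insert_element",
    "simulate_reads",
    "compose_metagenome",
    "inject_hit_errors",
    "pair_count",
]

ROLES = ("host", "bacteria", "virus")

_ALPHABET = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A reference sequence with its taxon id and role in the metagenome."""

    genome_id: str
    taxid: int
    role: str
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FastqRecord:
    id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class ReadPair:
    """A mate pair; mate record ids carry ``/1`` and ``/2`` suffixes."""

    pair_id: str
    r1: FastqRecord
    r2: FastqRecord


@dataclass(frozen=True)
class ReadSimParams:
    """Read simulation settings for a 2x150-style paired-end library.

    ``error_rate_start``/``error_rate_end`` are per-base substitution
    probabilities at the first and last read position; intermediate positions
    interpolate linearly, mimicking the quality drop along Illumina reads.
    """

    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 35.0
    error_rate_start: float = 0.001
    error_rate_end: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be at least read_length")
        for rate in (self.error_rate_start, self.error_rate_end):
            if not (0.0 <= rate < 0.5):
                raise ValueError(f"error rates must lie in [0, 0.5), got {rate}")


@dataclass(frozen=True)
class ReadTruthRecord:
    """Ground truth for one simulated read pair (0-based half-open coords)."""

    read_id: str
    genome_id: str
    taxid: int
    role: str
    fragment_start: int
    fragment_end: int
    strand: str


@dataclass
class TruthTable:
    """All truth records of a composed metagenome plus per-role pair totals."""

    records: list[ReadTruthRecord]

    @property
    def role_pairs(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.role] = out.get(rec.role, 0) + 1
        return out

    @property
    def role_proportions(self) -> dict[str, float]:
        total = len(self.records)
        return {role: n / total for role, n in self.role_pairs.items()} if total else {}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MetagenomeDesign:
    """Genome components with fold coverages plus global read parameters."""

    components: list[tuple[GenomeRecord, float]]
    params: ReadSimParams = field(default_factory=ReadSimParams)

    def __post_init__(self) -> None:
        for genome, coverage in self.components:
            if coverage < 0:
                raise ValueError(f"coverage must be >= 0, got {coverage} for {genome.genome_id}")


def generate_genome(
    length: int,
    gc: float,
    taxid: int,
    role: str,
    seed: int,
    genome_id: Optional[str] = None,
) -> GenomeRecord:
    """I.i.d. random genome with expected GC content ``gc``; deterministic per seed."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must lie strictly between 0 and 1, got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    seq = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)[codes].tobytes().decode()
    return GenomeRecord(genome_id or f"g{taxid}", taxid, role, seq)


def plant_shared_region(
    a: GenomeRecord,
    b: GenomeRecord,
    region_length: int,
    identity: float,
    seed: int = 0,
    a_start: Optional[int] = None,
    b_start: Optional[int] = None,
) -> tuple[GenomeRecord, GenomeRecord, dict[str, int]]:
    """Overwrite a region of ``b`` with a (mutated) copy of a region of ``a``.

    The copied segment is mutated so that its expected identity to the source
    is ``identity``. Returns ``a`` unchanged, the modified ``b`` and the
    planted coordinates (0-based half-open on both genomes).
    """
    if region_length < 0 or region_length > min(len(a), len(b)):
        raise ValueError("region_length must fit inside both genomes")
    if not (0.0 < identity <= 1.0):
        raise ValueError("identity must lie in (0, 1]")
    if region_length == 0:
        return a, b, {}
    rng = np.random.default_rng(seed)
    if a_start is None:
        a_start = int(rng.integers(0, len(a) - region_length + 1))
    if b_start is None:
        b_start = int(rng.integers(0, len(b) - region_length + 1))
    seg = np.frombuffer(a.sequence[a_start : a_start + region_length].encode(), dtype=np.uint8).copy()
    enc = np.zeros(256, dtype=np.uint8)
    for i, base in enumerate(_ALPHABET):
        enc[ord(base)] = i
    codes = enc[seg]
    mask = rng.random(region_length) < (1.0 - identity)
    codes[mask] = (codes[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    planted = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)[codes].tobytes().decode()
    new_seq = b.sequence[:b_start] + planted + b.sequence[b_start + region_length :]
    coords = {
        "a_start": a_start,
        "a_end": a_start + region_length,
        "b_start": b_start,
        "b_end": b_start + region_length,
    }
    return a, replace(b, sequence=new_seq), coords


def insert_element(
    host: GenomeRecord, element: GenomeRecord, position: int
) -> tuple[GenomeRecord, tuple[int, int]]:
    """Splice ``element`` into ``host`` at ``position``; returns the new genome
    and the element coordinates on it."""
    if not (0 <= position <= len(host)):
        raise ValueError(f"position {position} out of range for genome of length {len(host)}")
    new_seq = host.sequence[:position] + element.sequence + host.sequence[position:]
    return replace(host, sequence=new_seq), (position, position + len(element))


def pair_count(coverage: float, genome_length: int, read_length: int) -> int:
    """Number of read pairs for a fold coverage: round(coverage * L / (2 * read_length)),
    rounding half away from zero."""
    return int(math.floor(coverage * genome_length / (2 * read_length) + 0.5))


def _quality_string(rates: np.ndarray) -> str:
    phred = np.rint(-10.0 * np.log10(np.maximum(rates, 1e-4))).astype(int)
    phred = np.clip(phred, 2, 41)
    return "".join(chr(33 + q) for q in phred)


def simulate_reads(
    genome: GenomeRecord,
    coverage: float,
    params: ReadSimParams,
    id_prefix: Optional[str] = None,
) -> tuple[list[ReadPair], list[ReadTruthRecord]]:
    """Simulate paired-end reads from a linear genome at the given fold coverage.

    Pair count is ``round(coverage * L / (2 * read_length))``. Fragment
    lengths are drawn from a normal distribution clamped to
    ``[read_length, L]``; starts are uniform over valid positions; the
    sequenced strand of each fragment is chosen uniformly. Substitution
    errors are drawn per base at the linearly interpolated rate and qualities
    reflect that rate. Deterministic for a fixed ``params.seed``.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    L = len(genome)
    rl = params.read_length
    if L < rl:
        raise ValueError(f"genome {genome.genome_id} shorter than read length")
    n = pair_count(coverage, L, rl)
    if n == 0:
        return [], []

    rng = np.random.default_rng(params.seed)
    rates = np.linspace(params.error_rate_start, params.error_rate_end, rl)
    qual = _quality_string(rates)

    enc_lut = np.zeros(256, dtype=np.uint8)
    for i, base in enumerate(_ALPHABET):
        enc_lut[ord(base)] = i
    genome_codes = enc_lut[np.frombuffer(genome.sequence.encode(), dtype=np.uint8)]
    dec_lut = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)

    inserts = np.rint(rng.normal(params.insert_mean, params.insert_sd, size=n)).astype(int)
    inserts = np.clip(inserts, rl, L)
    starts = (rng.random(n) * (L - inserts + 1)).astype(int)
    strands = rng.integers(0, 2, size=n)  # 0 -> '+', 1 -> '-'

    prefix = id_prefix or genome.genome_id
    pairs: list[ReadPair] = []
    truth: list[ReadTruthRecord] = []
    for i in range(n):
        s = int(starts[i])
        e = s + int(inserts[i])
        fwd = genome_codes[s : s + rl].copy()          # 5' mate on the + strand
        rev = (3 - genome_codes[e - rl : e])[::-1].copy()  # 5' mate on the - strand
        if strands[i] == 0:
            m1, m2, strand = fwd, rev, "+"
        else:
            m1, m2, strand = rev, fwd, "-"
        for mate in (m1, m2):
            err = rng.random(rl) < rates
            k = int(err.sum())
            if k:
                mate[err] = (mate[err] + rng.integers(1, 4, size=k)) % 4
        pid = f"{prefix}:{i:07d}"
        pairs.append(
            ReadPair(
                pid,
                FastqRecord(pid + "/1", dec_lut[m1].tobytes().decode(), qual),
                FastqRecord(pid + "/2", dec_lut[m2].tobytes().decode(), qual),
            )
        )
        truth.append(
            ReadTruthRecord(pid, genome.genome_id, genome.taxid, genome.role, s, e, strand)
        )
    return pairs, truth


def compose_metagenome(design: MetagenomeDesign) -> tuple[list[ReadPair], TruthTable]:
    """Simulate all components and interleave their read pairs.

    Each component gets a child seed derived from the design seed; the final
    pair order is a seeded Fisher-Yates shuffle so that host, bacterial and
    viral reads are interleaved as in a real library. Deterministic for a
    fixed design and seed.
    """
    if not design.components:
        raise ValueError("metagenome design has no components")
    ss = np.random.SeedSequence(design.params.seed)
    children = ss.spawn(len(design.components) + 1)
    all_pairs: list[ReadPair] = []
    all_truth: list[ReadTruthRecord] = []
    for (genome, coverage), child in zip(design.components, children[:-1]):
        comp_seed = int(child.generate_state(1)[0] % (2**31))
        comp_params = replace(design.params, seed=comp_seed)
        pairs, truth = simulate_reads(genome, coverage, comp_params)
        all_pairs.extend(pairs)
        all_truth.extend(truth)
    order = np.random.default_rng(children[-1]).permutation(len(all_pairs))
    shuffled = [all_pairs[i] for i in order]
    return shuffled, TruthTable([all_truth[i] for i in order])


def inject_hit_errors(hits, mode: str, params: dict, seed: int = 0):
    """Doctor a homology hit table to emulate annotation-stage failure modes.

    ``decoy_homolog``
        add, for each named query, a winning high-identity hit to a decoy
        taxid (params: ``queries``, ``decoy_taxid``, optional ``decoy_subject_id``,
        ``identity`` (default 1.0), ``score_margin`` (default 1),
        ``aln_length`` fallback for queries with no prior hits).
    ``drop_query``
        remove every hit of the named queries (params: ``queries``).
    ``tie_pair``
        duplicate each named query's best hit onto a second taxid with
        identical score and identity (params: ``queries``, ``partner_taxid``,
        optional ``partner_subject_id``).

    Returns a new hit table; injected hits carry a ``note`` tag and the edit
    is recorded in the table's ``edits`` log for downstream error auditing.
    """
    from .toymap import Hit, HitTable  # local import: toymap does not import simulate

    if mode not in ("decoy_homolog", "drop_query", "tie_pair"):
        raise ValueError(f"unknown hit-error mode {mode!r}")
    queries = set(params.get("queries", ()))
    if not queries:
        raise ValueError(f"{mode}: params must name the affected queries")

    by_query: dict[str, list[Hit]] = {}
    for h in hits.hits:
        by_query.setdefault(h.query_id, []).append(h)

    new_hits = list(hits.hits)
    edits = list(hits.edits)

    if mode == "drop_query":
        new_hits = [h for h in new_hits if h.query_id not in queries]
        edits.append(f"drop_query:{','.join(sorted(queries))}")
    elif mode == "decoy_homolog":
        taxid = int(params["decoy_taxid"])
        subject = params.get("decoy_subject_id", f"decoy_{taxid}")
        identity = float(params.get("identity", 1.0))
        margin = int(params.get("score_margin", 1))
        for q in sorted(queries):
            prior = by_query.get(q, [])
            if prior:
                best = max(prior, key=lambda h: h.score)
                aln = best.aln_length
                qs, qe = best.query_start, best.query_end
                score = best.score + margin
            else:
                aln = int(params.get("aln_length", 500))
                qs, qe = 0, aln
                score = 2 * int(round(identity * aln)) - aln
            matches = int(round(identity * aln))
            new_hits.append(
                Hit(q, qs, qe, subject, taxid, 0, aln, "+", matches, aln, score,
                    note="injected:decoy")
            )
        edits.append(f"decoy_homolog:{taxid}:{','.join(sorted(queries))}")
    else:  # tie_pair
        taxid = int(params["partner_taxid"])
        subject = params.get("partner_subject_id", f"tie_{taxid}")
        for q in sorted(queries):
            prior = by_query.get(q)
            if not prior:
                raise ValueError(f"tie_pair: query {q!r} has no hits to duplicate")
            best = max(prior, key=lambda h: (h.score, h.identity))
            new_hits.append(replace(best, subject_id=subject, subject_taxid=taxid,
                                    note="injected:tie"))
        edits.append(f"tie_pair:{taxid}:{','.join(sorted(queries))}")

    return HitTable(new_hits, provenance=hits.provenance, edits=edits)
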
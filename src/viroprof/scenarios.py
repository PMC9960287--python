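"""Named benchmark scenarios: self-contained synthetic fixtures.

Each scenario packages genomes, a metagenome design, simulated reads with
truth, perfect contigs with a read-to-contig map, a matching toy taxonomy
and phage label list, optional hit-table fault injections, and a manifest
predicting the false calls the scenario should produce:

``clean``
    host + bacteria background with viruses at the designed coverage and no
    injected errors; every designed virus species should be recovered.
``host_endogenous``
    a viral element is spliced into the host genome and also spiked as its
    own library; host filtering removes its reads -> FN (host_filtered).
``shared_region``
    a decoy reference genome carries an identical copy of one spiked virus;
    best-hit ties resolve away from the truth -> FN/FP pair
    (shared_region_tie).
``chimeric``
    two viruses are mis-assembled into one contig -> FN for the minor
    partner (chimeric_assembly).
``decoy``
    an injected high-identity hit to an absent taxon wins one contig ->
    FP (decoy_homolog).
``drop_query``
    all hits of one virus's queries are removed -> FN (dropped_hits).
``pruned``
    one virus is spiked so low that abundance pruning removes it ->
    FN (pruned_low_abundance).
``low_coverage``
    a series of clean designs differing only in virus coverage (5X down to
    1X), for recall-versus-depth curves.

Contigs are "perfect assemblies": genome substrings with known read
membership, standing in for an assembler, which is outside the scope of
this toolkit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .simulate import (
    GenomeRecord,
    MetagenomeDesign,
    ReadPair,
    ReadSimParams,
    TruthTable,
    compose_metagenome,
    generate_genome,
    insert_element,
    plant_shared_region,
)
from .profile import ReadToContigMap
from .taxonomy import PhageLabelSet, TaxonNode, TaxonomyStore, default_phage_labels, write_taxonomy

__all__ = ["SCENARIOS", "ScenarioSpec", "Contig", "Fixture", "make_fixture"]

SCENARIOS = (
    "clean",
    "host_endogenous",
    "shared_region",
    "chimeric",
    "decoy",
    "drop_query",
    "pruned",
    "low_coverage",
)

HOST_TAXID = 9615
VIRUS_BASE = 5000
BACTERIA_BASE = 3000
SHARED_DECOY_TAXID = 4999   # below VIRUS_BASE so the tie-break favours it
HIT_DECOY_TAXID = 4990
TINY_VIRUS_TAXID = 5998
ENDO_ELEMENT_TAXID = 5999

_PHAGE_FAMILY_NAMES = ("Microviridae", "Inoviridae")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one fixture scenario; defaults are desk-scale."""

    name: str
    seed: int = 0
    n_virus: int = 5
    virus_length: tuple[int, int] = (10_000, 30_000)
    virus_coverage: float = 5.0
    host_length: int = 120_000
    host_coverage: float = 5.0
    n_bacteria: int = 2
    bacteria_length: int = 60_000
    bacteria_coverage: float = 5.0
    include_phage: bool = True
    read_params: ReadSimParams = field(default_factory=ReadSimParams)
    coverage_series: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0, 1.0)

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")


@dataclass(frozen=True)
class Contig:
    """A perfect-assembly contig with the genomes its reads came from."""

    contig_id: str
    sequence: str
    sources: tuple[str, ...]


@dataclass
class Fixture:
    """Everything one pipeline run needs, plus the expected-outcome manifest."""

    spec: ScenarioSpec
    design: MetagenomeDesign
    host_genomes: list[GenomeRecord]
    ref_genomes: list[GenomeRecord]
    contigs: list[Contig]
    r2c: ReadToContigMap
    reads: list[ReadPair]
    truth: TruthTable
    store: TaxonomyStore
    labels: PhageLabelSet
    hit_edits: list[tuple[str, str, dict]]
    manifest: dict

    @property
    def virus_truth_taxa(self) -> list[int]:
        return sorted({g.taxid for g, _ in self.design.components if g.role == "virus"})

    @property
    def bacteria_truth_taxa(self) -> list[int]:
        return sorted({g.taxid for g, _ in self.design.components if g.role == "bacteria"})

    def write(self, outdir: str | Path) -> Path:
        """Write the fixture as a self-describing directory of text files."""
        from . import io_utils as io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_genomes(outdir / "host.fasta", self.host_genomes)
        io.write_genomes(outdir / "reference.fasta", self.ref_genomes)
        io.write_genomes(
            outdir / "contigs.fasta",
            [GenomeRecord(c.contig_id, 1, "virus", c.sequence) for c in self.contigs],
        )
        io.write_fastq_pairs(outdir / "reads_R1.fastq.gz", outdir / "reads_R2.fastq.gz", self.reads)
        io.write_truth(self.truth, outdir / "truth.tsv")
        io.write_r2c(self.r2c, outdir / "r2c.tsv")
        write_taxonomy(self.store, outdir / "taxonomy.tsv")
        with open(outdir / "phage_labels.txt", "wt", encoding="utf-8") as fh:
            for name in sorted(self.labels.family_names):
                fh.write(f"family:{name}\n")
            for name in sorted(self.labels.order_names):
                fh.write(f"order:{name}\n")
        io.write_design(self.design, outdir / "design.yaml")
        contig_sources = {c.contig_id: list(c.sources) for c in self.contigs}
        with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
            json.dump(
                {
                    "manifest": self.manifest,
                    "hit_edits": self.hit_edits,
                    "contig_sources": contig_sources,
                    "virus_truth_taxa": self.virus_truth_taxa,
                    "bacteria_truth_taxa": self.bacteria_truth_taxa,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        return outdir


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(seed).spawn(n)]


def build_scenario_taxonomy(
    bacteria_taxids: list[int],
    virus_taxids: list[int],
    phage_taxids: frozenset[int] = frozenset(),
) -> TaxonomyStore:
    """Toy tree: root, three superkingdoms, host lineage, and family/genus
    chains for every species. Phage species get families named on the
    default phage label list; one no-rank clade node is inserted so rank
    projection has something to skip."""
    nodes = [
        TaxonNode(1, 1, "no_rank", "root"),
        TaxonNode(2, 1, "superkingdom", "Bacteria"),
        TaxonNode(2759, 1, "superkingdom", "Eukaryota"),
        TaxonNode(10239, 1, "superkingdom", "Viruses"),
        TaxonNode(9608, 2759, "family", "Hostidae"),
        TaxonNode(9611, 9608, "genus", "Hostus"),
        TaxonNode(HOST_TAXID, 9611, "species", "Hostus domesticus"),
    ]
    seen: set[int] = {n.taxid for n in nodes}

    def add(node: TaxonNode) -> None:
        if node.taxid not in seen:
            nodes.append(node)
            seen.add(node.taxid)

    for i, t in enumerate(sorted(bacteria_taxids)):
        fam, gen = 70000 + i // 4, 60000 + i // 2
        add(TaxonNode(fam, 2, "family", f"Bacterfam{i // 4}aceae"))
        add(TaxonNode(gen, fam, "genus", f"Bactergenus{i // 2}"))
        add(TaxonNode(t, gen, "species", f"Bacterium sp{t}"))

    phage_i = 0
    nonphage_i = 0
    for t in sorted(virus_taxids):
        if t in phage_taxids:
            fam_name = _PHAGE_FAMILY_NAMES[phage_i % len(_PHAGE_FAMILY_NAMES)]
            fam, gen = 95000 + phage_i, 85000 + phage_i
            add(TaxonNode(fam, 10239, "family", fam_name))
            add(TaxonNode(gen, fam, "genus", f"Phagegenus{phage_i}"))
            add(TaxonNode(t, gen, "species", f"Phagevirus {t}"))
            phage_i += 1
        else:
            fam, gen = 90000 + nonphage_i // 4, 80000 + nonphage_i // 2
            add(TaxonNode(fam, 10239, "family", f"Virofam{nonphage_i // 4}viridae"))
            add(TaxonNode(gen, fam, "genus", f"Virogenus{nonphage_i // 2}"))
            if nonphage_i == 0:
                # transparent clade between the first species and its genus
                add(TaxonNode(99998, gen, "no_rank", "unclassified Virogenus0 clade"))
                add(TaxonNode(t, 99998, "species", f"Simulavirus {t}"))
            else:
                add(TaxonNode(t, gen, "species", f"Simulavirus {t}"))
            nonphage_i += 1
    return TaxonomyStore(nodes)


def make_fixture(spec: ScenarioSpec, outdir: Optional[str | Path] = None):
    """Build the fixture for a scenario (a list of fixtures for ``low_coverage``)."""
    if spec.name == "low_coverage":
        fixtures = []
        for cov in spec.coverage_series:
            sub = replace(spec, name="clean", virus_coverage=cov)
            fx = make_fixture(sub)
            fx.manifest["series_coverage"] = cov
            if outdir is not None:
                fx.write(Path(outdir) / f"vi{cov:g}X")
            fixtures.append(fx)
        return fixtures

    seeds = _child_seeds(spec.seed, 4 + spec.n_bacteria + spec.n_virus)
    host_seed, extra_seed, read_seed, shuffle_unused = seeds[:4]
    bact_seeds = seeds[4 : 4 + spec.n_bacteria]
    virus_seeds = seeds[4 + spec.n_bacteria :]

    host = generate_genome(spec.host_length, 0.41, HOST_TAXID, "host", host_seed, "host1")
    bacteria = [
        generate_genome(
            spec.bacteria_length, 0.45 + 0.05 * (i % 3), BACTERIA_BASE + 1 + i, "bacteria",
            bact_seeds[i], f"bac{i + 1:02d}",
        )
        for i in range(spec.n_bacteria)
    ]
    len_rng = np.random.default_rng(extra_seed)
    viruses = []
    phage_taxids: set[int] = set()
    for i in range(spec.n_virus):
        length = int(len_rng.integers(spec.virus_length[0], spec.virus_length[1] + 1))
        gc = float(len_rng.uniform(0.35, 0.55))
        taxid = VIRUS_BASE + 1 + i
        viruses.append(generate_genome(length, gc, taxid, "virus", virus_seeds[i], f"vir{i + 1:02d}"))
        if spec.include_phage and i == spec.n_virus - 1 and spec.n_virus > 1:
            phage_taxids.add(taxid)

    host_genomes = [host]
    components: list[tuple[GenomeRecord, float]] = [(host, spec.host_coverage)]
    components += [(b, spec.bacteria_coverage) for b in bacteria]
    components += [(v, spec.virus_coverage) for v in viruses]
    ref_genomes: list[GenomeRecord] = list(bacteria) + list(viruses)
    hit_edits: list[tuple[str, str, dict]] = []
    manifest: dict = {"scenario": spec.name, "expected_fn": {}, "expected_fp": {}}
    extra_virus_taxids: list[int] = []
    chimera_sources: Optional[tuple[str, str]] = None
    decoy_split_genome: Optional[str] = None
    decoy_split_at = 0

    if spec.name == "host_endogenous":
        element = generate_genome(4_000, 0.50, ENDO_ELEMENT_TAXID, "virus", extra_seed + 1, "endo1")
        host_mod, _coords = insert_element(host, element, spec.host_length // 2)
        host_genomes = [host_mod]
        components[0] = (host_mod, spec.host_coverage)
        components.append((element, spec.virus_coverage))
        ref_genomes.append(element)
        extra_virus_taxids.append(ENDO_ELEMENT_TAXID)
        manifest["expected_fn"][str(ENDO_ELEMENT_TAXID)] = "host_filtered"
    elif spec.name == "shared_region":
        target = viruses[0]
        decoy = generate_genome(
            len(target) + 4_000, 0.45, SHARED_DECOY_TAXID, "virus", extra_seed + 2, "decoy_shared"
        )
        _, decoy, _coords = plant_shared_region(
            target, decoy, len(target), identity=1.0, seed=extra_seed + 3, a_start=0, b_start=2_000
        )
        ref_genomes.append(decoy)
        extra_virus_taxids.append(SHARED_DECOY_TAXID)
        manifest["expected_fn"][str(target.taxid)] = "shared_region_tie"
        manifest["expected_fp"][str(SHARED_DECOY_TAXID)] = "shared_region_tie"
    elif spec.name == "chimeric":
        a, b = viruses[0], viruses[1]
        chimera_sources = (a.genome_id, b.genome_id)
        manifest["expected_fn"][str(b.taxid)] = "chimeric_assembly"
    elif spec.name == "decoy":
        decoy_split_genome = viruses[0].genome_id
        decoy_split_at = len(viruses[0]) // 2
        extra_virus_taxids.append(HIT_DECOY_TAXID)
        hit_edits.append(
            (
                "contig",
                "decoy_homolog",
                {
                    "queries": [f"ctg_{decoy_split_genome}_2"],
                    "decoy_taxid": HIT_DECOY_TAXID,
                    "score_margin": 5,
                },
            )
        )
        manifest["expected_fp"][str(HIT_DECOY_TAXID)] = "decoy_homolog"
    elif spec.name == "drop_query":
        target = viruses[0]
        hit_edits.append(("contig", "drop_query", {"queries": [f"ctg_{target.genome_id}"]}))
        manifest["expected_fn"][str(target.taxid)] = "dropped_hits"
    elif spec.name == "pruned":
        tiny = generate_genome(8_000, 0.45, TINY_VIRUS_TAXID, "virus", extra_seed + 4, "tinyvir")
        components.append((tiny, 0.15))
        ref_genomes.append(tiny)
        extra_virus_taxids.append(TINY_VIRUS_TAXID)
        manifest["expected_fn"][str(TINY_VIRUS_TAXID)] = "pruned_low_abundance"

    virus_taxids = sorted(
        {g.taxid for g in ref_genomes if g.role == "virus"} | set(extra_virus_taxids)
    )
    store = build_scenario_taxonomy(
        [b.taxid for b in bacteria], virus_taxids, frozenset(phage_taxids)
    )
    labels = default_phage_labels()

    design = MetagenomeDesign(components, replace(spec.read_params, seed=read_seed))
    reads, truth = compose_metagenome(design)

    # perfect contigs + read-to-contig map from the truth table
    contigs: list[Contig] = []
    by_id = {g.genome_id: g for g, _ in components}
    non_host = [g for g, _ in components if g.role != "host"]
    if chimera_sources is not None:
        a, b = by_id[chimera_sources[0]], by_id[chimera_sources[1]]
        chim_seq = a.sequence[: int(0.9 * len(a))] + b.sequence[: max(600, len(b) // 10)]
        contigs.append(Contig("ctg_chimera", chim_seq, chimera_sources))
        for g in non_host:
            if g.genome_id not in chimera_sources:
                contigs.append(Contig(f"ctg_{g.genome_id}", g.sequence, (g.genome_id,)))
    elif decoy_split_genome is not None:
        for g in non_host:
            if g.genome_id == decoy_split_genome:
                contigs.append(
                    Contig(f"ctg_{g.genome_id}_1", g.sequence[:decoy_split_at], (g.genome_id,))
                )
                contigs.append(
                    Contig(f"ctg_{g.genome_id}_2", g.sequence[decoy_split_at:], (g.genome_id,))
                )
            else:
                contigs.append(Contig(f"ctg_{g.genome_id}", g.sequence, (g.genome_id,)))
    else:
        contigs = [Contig(f"ctg_{g.genome_id}", g.sequence, (g.genome_id,)) for g in non_host]

    def contig_for(rec) -> Optional[str]:
        if rec.role == "host":
            return None
        if chimera_sources is not None and rec.genome_id in chimera_sources:
            return "ctg_chimera"
        if decoy_split_genome is not None and rec.genome_id == decoy_split_genome:
            suffix = "_1" if rec.fragment_start < decoy_split_at else "_2"
            return f"ctg_{rec.genome_id}{suffix}"
        return f"ctg_{rec.genome_id}"

    mapping: dict[str, str] = {}
    unassembled: set[str] = set()
    for rec in truth.records:
        cid = contig_for(rec)
        for suffix in ("/1", "/2"):
            if cid is None:
                unassembled.add(rec.read_id + suffix)
            else:
                mapping[rec.read_id + suffix] = cid
    r2c = ReadToContigMap(mapping, unassembled)

    fixture = Fixture(
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
        hit_edits=hit_edits,
        manifest=manifest,
    )
    if outdir is not None:
        fixture.write(outdir)
    return fixture
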
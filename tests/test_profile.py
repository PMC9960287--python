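"""Profiling core: host filtering, best-hit selection, assignment,
abundance, percentile pruning and contig splitting."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from viroprof.profile import (
    AbundanceTable,
    Assignment,
    PruneConfig,
    ReadToContigMap,
    abundance,
    assign_taxa,
    best_hit,
    host_filter,
    percentile_prune,
    split_contigs,
    subtable_by_superkingdom,
)
from viroprof.simulate import ReadSimParams, generate_genome, simulate_reads
from viroprof.taxonomy import PhageLabelSet
from viroprof.toymap import Hit, HitTable, build_index

ERROR_FREE = ReadSimParams(error_rate_start=0.0, error_rate_end=0.0, seed=8)


def _hit(q, taxid, score, identity=1.0, aln=150, note=""):
    matches = int(round(identity * aln))
    return Hit(q, 0, aln, f"s{taxid}", taxid, 0, aln, "+", matches, aln, score, note=note)


@pytest.fixture(scope="module")
def host_index():
    host = generate_genome(30_000, 0.41, 9615, "host", 1, "host1")
    return host, build_index([host])


class TestHostFilter:

    def test_error_free_host_reads_are_all_removed(self, host_index):
        host, idx = host_index
        pairs, _ = simulate_reads(host, 1.0, ERROR_FREE)
        kept, removed = host_filter(pairs, idx)
        assert kept == []
        assert len(removed) == len(pairs)

    def test_noisy_host_reads_nearly_all_removed(self, host_index):
        host, idx = host_index
        pairs, _ = simulate_reads(host, 1.0, ReadSimParams(seed=2))
        kept, removed = host_filter(pairs, idx)
        assert len(removed) / len(pairs) >= 0.99

    def test_dissimilar_virus_reads_pass_untouched(self, host_index):
        _, idx = host_index
        virus = generate_genome(10_000, 0.45, 5001, "virus", 3, "v")
        pairs, _ = simulate_reads(virus, 2.0, ERROR_FREE)
        kept, removed = host_filter(pairs, idx)
        assert removed == [] and len(kept) == len(pairs)


class TestBestHit:
    def test_single_hit_wins_unambiguously(self):
        table = HitTable([_hit("q", 500, 100)])
        winner, ambiguous = best_hit(table)["q"]
        assert winner.subject_taxid == 500 and not ambiguous

    def test_score_tie_breaks_to_lower_taxid_and_flags_ambiguity(self):
        table = HitTable([_hit("q", 900, 100), _hit("q", 80, 100)])
        winner, ambiguous = best_hit(table)["q"]
        assert winner.subject_taxid == 80 and ambiguous

    def test_higher_identity_breaks_score_tie_without_ambiguity(self):
        table = HitTable([_hit("q", 900, 100, identity=1.0, aln=100),
                          _hit("q", 80, 100, identity=0.9, aln=200)])
        winner, ambiguous = best_hit(table)["q"]
        assert winner.subject_taxid == 900 and not ambiguous


class TestAssignTaxa:
    def test_assembled_reads_inherit_contig_taxon(self):
        r2c = ReadToContigMap({f"p{i}/1": "C" for i in range(10)}, set())
        out = assign_taxa(HitTable([_hit("C", 500, 300)]), HitTable([]), r2c)
        reads = [a for a in out if a.source == "inherited_from_contig"]
        assert len(reads) == 10 and all(a.taxid == 500 for a in reads)

    def test_unassembled_read_without_hit_is_unassigned(self):
        r2c = ReadToContigMap({}, {"lone/1"})
        out = assign_taxa(HitTable([]), HitTable([]), r2c)
        assert [a for a in out if a.query_id == "lone/1"][0].taxid is None

    def test_contig_inheritance_overrides_read_hit(self):
        r2c = ReadToContigMap({"p0/1": "C"}, set())
        out = assign_taxa(
            HitTable([_hit("C", 500, 300)]), HitTable([_hit("p0/1", 999, 150)]), r2c
        )
        read = [a for a in out if a.query_id == "p0/1"][0]
        assert read.taxid == 500 and read.source == "inherited_from_contig"


class TestAbundance:
    def _assignments(self, spec):
        return [Assignment(f"r{i}", t, False, "read_hit") for i, t in enumerate(spec)]

    def test_single_species_single_row(self, chain_store):
        table = abundance(self._assignments([300] * 100), chain_store, "species")
        assert table.counts == {300: 100} and table.total_reads == 100

    def test_two_species_aggregate_at_genus(self, chain_store):
        table = abundance(self._assignments([300] * 60 + [301] * 40), chain_store, "genus")
        assert table.counts == {200: 100}

    def test_unassigned_reads_enter_total_but_not_rows(self, chain_store):
        table = abundance(self._assignments([300] * 5 + [None] * 5), chain_store, "species")
        assert table.counts == {300: 5} and table.total_reads == 10

    def test_strain_counts_under_its_species(self, chain_store):
        table = abundance(self._assignments([320, 320, 300]), chain_store, "species")
        assert table.counts == {300: 3}

    def test_unranked_taxa_excluded_from_rows(self, chain_store):
        # taxid 501 has no genus in its lineage
        table = abundance(self._assignments([501, 300]), chain_store, "genus")
        assert table.counts == {200: 1} and table.total_reads == 2


def _prune_oracle(counts: dict[int, int], t: float) -> dict[int, int]:
    """Enumerate suffixes of the sorted rows; drop the maximal suffix lying
    entirely within the last t percent of binned reads."""
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(c for _, c in rows)
    for j in range(len(rows) + 1):
        if sum(c for _, c in rows[j:]) * 100 <= t * total:
            return dict(rows[:j])
    return dict(rows)


class TestPercentilePrune:
    def test_worked_example(self):
        table = AbundanceTable("species", {1: 90, 2: 6, 3: 3, 4: 1}, 100)
        assert percentile_prune(table, PruneConfig(5)).counts == {1: 90, 2: 6}

    def test_t_zero_is_identity(self):
        table = AbundanceTable("species", {1: 90, 2: 6, 3: 3, 4: 1}, 100)
        assert percentile_prune(table, PruneConfig(0)).counts == table.counts

    def test_t_hundred_drops_everything(self):
        table = AbundanceTable("species", {1: 90, 2: 6}, 96)
        assert percentile_prune(table, PruneConfig(100)).counts == {}

    def test_straddling_taxon_is_kept(self):
        # tail {B:10} straddles the 5% boundary of S=100 -> kept
        table = AbundanceTable("species", {1: 90, 2: 10}, 100)
        assert percentile_prune(table, PruneConfig(5)).counts == {1: 90, 2: 10}

    @given(
        counts=st.lists(st.integers(1, 500), min_size=1, max_size=12),
        t1=st.sampled_from([0, 1, 5, 20, 50, 100]),
        t2=st.sampled_from([0, 1, 5, 20, 50, 100]),
    )
    def test_monotone_in_t_and_keeps_a_prefix(self, counts, t1, t2):
        table = AbundanceTable("species", dict(enumerate(counts, 1)), sum(counts))
        lo, hi = sorted((t1, t2))
        kept_hi = set(percentile_prune(table, PruneConfig(hi)).counts)
        kept_lo = set(percentile_prune(table, PruneConfig(lo)).counts)
        assert kept_hi <= kept_lo
        # what survives is always a prefix of the abundance-sorted rows
        rows = [t for t, _ in table.rows()]
        kept = [t for t, _ in percentile_prune(table, PruneConfig(t1)).rows()]
        assert kept == rows[: len(kept)]
        assert percentile_prune(table, PruneConfig(0)).counts == table.counts

    def test_reapplication_redefines_the_percentile_base(self):
        # pruning is one-shot over the full read distribution: applying it
        # again to an already pruned table rescales S and can drop more
        table = AbundanceTable("species", {1: 75, 2: 15, 3: 10}, 100)
        once = percentile_prune(table, PruneConfig(20))
        assert once.counts == {1: 75, 2: 15}
        twice = percentile_prune(once, PruneConfig(20))
        assert twice.counts == {1: 75}

    @given(counts=st.lists(st.integers(1, 20), min_size=1, max_size=6),
           t=st.sampled_from([0, 1, 5, 20, 100]))
    def test_matches_suffix_enumeration_oracle(self, counts, t):
        table = AbundanceTable("species", dict(enumerate(counts, 1)), sum(counts))
        assert percentile_prune(table, PruneConfig(t)).counts == _prune_oracle(
            dict(enumerate(counts, 1)), t
        )


class TestSplitContigs:
    labels = PhageLabelSet.from_names(orders=["Tubulavirales"])

    def _split(self, chain_store, taxid):
        assignments = [Assignment("C", taxid, False, "contig_hit")]
        return split_contigs(assignments, chain_store, self.labels)

    def test_phage_lineage_contig_goes_to_phage_set(self, chain_store):
        viral, phage, unmapped = self._split(chain_store, 302)
        assert phage == {"C"} and not viral and not unmapped

    def test_eukaryotic_virus_contig_goes_to_viral_set(self, chain_store):
        viral, phage, unmapped = self._split(chain_store, 300)
        assert viral == {"C"} and not phage

    def test_unmapped_contig(self, chain_store):
        viral, phage, unmapped = self._split(chain_store, None)
        assert unmapped == {"C"} and not viral and not phage

    def test_bacterial_contig_belongs_to_no_set(self, chain_store):
        viral, phage, unmapped = self._split(chain_store, 400)
        assert not viral and not phage and not unmapped

    def test_superkingdom_subtable(self, chain_store):
        table = AbundanceTable("species", {300: 10, 400: 5}, 20)
        sub = subtable_by_superkingdom(table, chain_store, "Viruses")
        assert sub.counts == {300: 10} and sub.total_reads == 20
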
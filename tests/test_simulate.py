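"""Read simulator: genome generation, fault constructs, read/metagenome
simulation and hit-table fault injection."""

import numpy as np
import pytest

from viroprof.simulate import (
    GenomeRecord,
    MetagenomeDesign,
    ReadSimParams,
    compose_metagenome,
    generate_genome,
    inject_hit_errors,
    insert_element,
    pair_count,
    plant_shared_region,
    revcomp,
    simulate_reads,
)
from viroprof.toymap import Hit, HitTable

ERROR_FREE = ReadSimParams(error_rate_start=0.0, error_rate_end=0.0, seed=5)


class TestGenerateGenome:
    def test_deterministic_per_seed(self):
        a = generate_genome(10_000, 0.5, 7, "virus", seed=1)
        b = generate_genome(10_000, 0.5, 7, "virus", seed=1)
        c = generate_genome(10_000, 0.5, 7, "virus", seed=2)
        assert a.sequence == b.sequence
        assert a.sequence != c.sequence

    def test_gc_content_matches_request(self):
        g = generate_genome(100_000, 0.7, 7, "virus", seed=3)
        gc = sum(g.sequence.count(b) for b in "GC") / len(g)
        assert abs(gc - 0.7) < 0.01  # ~3 binomial sigma at this length

    @pytest.mark.parametrize("length, gc", [(0, 0.5), (100, 0.0), (100, 1.0), (-5, 0.5)])
    def test_invalid_arguments(self, length, gc):
        with pytest.raises(ValueError):
            generate_genome(length, gc, 7, "virus", seed=1)


class TestFaultConstructs:
    def test_identity_one_plants_a_byte_identical_region(self):
        a = generate_genome(5_000, 0.5, 1, "virus", 1, "a")
        b = generate_genome(5_000, 0.5, 2, "virus", 2, "b")
        _, b2, c = plant_shared_region(a, b, 1_000, identity=1.0, seed=3)
        assert (
            b2.sequence[c["b_start"]:c["b_end"]] == a.sequence[c["a_start"]:c["a_end"]]
        )

    def test_partial_identity_within_binomial_bound(self):
        a = generate_genome(8_000, 0.5, 1, "virus", 1, "a")
        b = generate_genome(8_000, 0.5, 2, "virus", 2, "b")
        _, b2, c = plant_shared_region(a, b, 2_000, identity=0.95, seed=4)
        sa = a.sequence[c["a_start"]:c["a_end"]]
        sb = b2.sequence[c["b_start"]:c["b_end"]]
        ident = sum(x == y for x, y in zip(sa, sb)) / len(sa)
        assert abs(ident - 0.95) < 0.02

    def test_zero_length_region_leaves_genomes_unchanged(self):
        a = generate_genome(1_000, 0.5, 1, "virus", 1, "a")
        b = generate_genome(1_000, 0.5, 2, "virus", 2, "b")
        _, b2, coords = plant_shared_region(a, b, 0, identity=1.0)
        assert b2.sequence == b.sequence and coords == {}

    def test_insert_at_zero_is_concatenation_and_conserves_length(self):
        host = generate_genome(2_000, 0.4, 9, "host", 1, "h")
        element = generate_genome(300, 0.5, 10, "virus", 2, "e")
        merged, (s, e) = insert_element(host, element, 0)
        assert merged.sequence == element.sequence + host.sequence
        assert (s, e) == (0, 300)
        assert len(merged) == len(host) + len(element)

    def test_insert_position_out_of_range(self):
        host = generate_genome(1_000, 0.4, 9, "host", 1, "h")
        with pytest.raises(ValueError):
            insert_element(host, host, 5_000)


class TestSimulateReads:
    def test_zero_coverage_yields_nothing(self):
        g = generate_genome(30_000, 0.5, 7, "virus", 1)
        pairs, truth = simulate_reads(g, 0.0, ERROR_FREE)
        assert pairs == [] and truth == []

    @pytest.mark.parametrize(
        "coverage, length, expected",
        [(5, 30_000, 500), (1, 10_000, 33), (2.5, 9_999, 83), (0.15, 8_000, 4)],
    )
    def test_pair_count_is_rounded_coverage_formula(self, coverage, length, expected):
        g = generate_genome(length, 0.5, 7, "virus", 1)
        pairs, truth = simulate_reads(g, coverage, ERROR_FREE)
        assert len(pairs) == len(truth) == pair_count(coverage, length, 150) == expected

    def test_error_free_reads_are_genome_substrings(self):
        g = generate_genome(20_000, 0.5, 7, "virus", 2)
        pairs, truth = simulate_reads(g, 2.0, ERROR_FREE)
        for p, t in zip(pairs, truth):
            frag = g.sequence[t.fragment_start:t.fragment_end]
            fwd5, rev5 = frag[:150], revcomp(frag[-150:])
            if t.strand == "+":
                assert p.r1.sequence == fwd5 and p.r2.sequence == rev5
            else:
                assert p.r1.sequence == rev5 and p.r2.sequence == fwd5
            assert t.fragment_end - t.fragment_start >= 150

    def test_substitution_rate_recovery_within_3_sigma(self):
        e = 0.01
        params = ReadSimParams(error_rate_start=e, error_rate_end=e, seed=9)
        g = generate_genome(20_000, 0.5, 7, "virus", 3)
        pairs, truth = simulate_reads(g, 10.0, params)
        mism = total = 0
        for p, t in zip(pairs, truth):
            frag = g.sequence[t.fragment_start:t.fragment_end]
            fwd5, rev5 = frag[:150], revcomp(frag[-150:])
            expected = (fwd5, rev5) if t.strand == "+" else (rev5, fwd5)
            for obs, exp in zip((p.r1.sequence, p.r2.sequence), expected):
                mism += sum(a != b for a, b in zip(obs, exp))
                total += 150
        assert total >= 100_000
        sigma = (e * (1 - e) / total) ** 0.5
        assert abs(mism / total - e) < 3 * sigma

    def test_quality_tracks_local_error_rate(self):
        params = ReadSimParams(error_rate_start=0.001, error_rate_end=0.01, seed=1)
        g = generate_genome(5_000, 0.5, 7, "virus", 1)
        pairs, _ = simulate_reads(g, 0.5, params)
        quals = [ord(c) - 33 for c in pairs[0].r1.quality]
        assert quals[0] == 30 and quals[-1] == 20  # -10 log10 of the end rates
        assert all(a >= b for a, b in zip(quals, quals[1:]))

    def test_negative_coverage_rejected(self):
        g = generate_genome(1_000, 0.5, 7, "virus", 1)
        with pytest.raises(ValueError):
            simulate_reads(g, -1.0, ERROR_FREE)


class TestComposeMetagenome:
    def _design(self, seed=0, virus_cov=5.0):
        host = generate_genome(100_000, 0.41, 9615, "host", 1, "h")
        bact = generate_genome(25_000, 0.5, 3001, "bacteria", 2, "b")
        virus = generate_genome(9_000, 0.45, 5001, "virus", 3, "v")
        return MetagenomeDesign(
            [(host, 5.0), (bact, 5.0), (virus, virus_cov)],
            ReadSimParams(seed=seed),
        )

    def test_single_component_proportions(self):
        g = generate_genome(10_000, 0.5, 5001, "virus", 1, "v")
        _, truth = compose_metagenome(MetagenomeDesign([(g, 3.0)], ReadSimParams(seed=1)))
        assert truth.role_proportions == {"virus": 1.0}

    def test_read_count_conservation_and_formula(self):
        reads, truth = compose_metagenome(self._design(seed=4))
        per_comp = [pair_count(c, L, 150) for c, L in ((5, 100_000), (5, 25_000), (5, 9_000))]
        assert len(reads) == len(truth) == sum(per_comp)
        # per-role counts within one pair of the lengths x coverage formula
        total = len(reads)
        shares = {"host": 5 * 100_000, "bacteria": 5 * 25_000, "virus": 5 * 9_000}
        denom = sum(shares.values())
        for role, share in shares.items():
            assert abs(truth.role_pairs[role] - share / denom * total) <= 1

    def test_virus_proportion_scales_with_coverage(self):
        _, t5 = compose_metagenome(self._design(seed=4, virus_cov=5.0))
        _, t1 = compose_metagenome(self._design(seed=4, virus_cov=1.0))
        assert abs(t5.role_pairs["virus"] - 5 * t1.role_pairs["virus"]) <= 3

    def test_deterministic_and_interleaved(self):
        r1, t1 = compose_metagenome(self._design(seed=6))
        r2, t2 = compose_metagenome(self._design(seed=6))
        assert r1 == r2 and t1.records == t2.records
        roles_of = {rec.read_id: rec.role for rec in t1.records}
        head_roles = {roles_of[p.pair_id] for p in r1[:200]}
        assert len(head_roles) >= 2  # shuffled, not blocked by component

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            compose_metagenome(MetagenomeDesign([], ReadSimParams()))


class TestInjectHitErrors:
    def _table(self):
        h = Hit("q1", 0, 500, "s1", 500, 0, 500, "+", 500, 500, 500, note="")
        g = Hit("q2", 0, 400, "s1", 500, 0, 400, "+", 400, 400, 400, note="")
        return HitTable([h, g])

    def test_drop_query_removes_all_hits_of_query(self):
        out = inject_hit_errors(self._table(), "drop_query", {"queries": ["q1"]})
        assert out.queries() == {"q2"}
        assert any(e.startswith("drop_query") for e in out.edits)

    def test_decoy_homolog_adds_winning_tagged_hit(self):
        out = inject_hit_errors(
            self._table(), "decoy_homolog", {"queries": ["q1"], "decoy_taxid": 42}
        )
        best = out.by_query()["q1"][0]
        assert best.subject_taxid == 42 and "decoy" in best.note
        assert best.score > 500

    def test_tie_pair_duplicates_best_hit_at_equal_score(self):
        out = inject_hit_errors(
            self._table(), "tie_pair", {"queries": ["q2"], "partner_taxid": 77}
        )
        q2 = out.by_query()["q2"]
        assert {h.subject_taxid for h in q2} == {500, 77}
        assert len({(h.score, h.identity) for h in q2}) == 1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            inject_hit_errors(self._table(), "swap_all", {"queries": ["q1"]})
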
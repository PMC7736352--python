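"""The N-terminal extension screen: filtering, calling, conservation, paralogs."""

import numpy as np
import pytest

from atriscan.align import search
from atriscan.nte import (
    NteCall,
    ScreenParams,
    call_nte,
    cluster_families,
    conservation_scan,
    filter_and_rank,
    paralog_nte_pairs,
)
from atriscan.seq_io import HomologHit, ProteinRecord
from atriscan.simulate import FamilySpec, make_family

from oracles import brute_force_filter


def _hit(sid, similarity=90.0, coverage=90.0, qstart=1, score=100.0, qid="q", sstart=1):
    return HomologHit(
        query_id=qid,
        subject_id=sid,
        similarity_pct=similarity,
        coverage_pct=coverage,
        query_start=qstart,
        query_end=qstart + 49,
        rank_score=score,
        subject_start=sstart,
    )


def _random_hits(rng, n, qid="q"):
    return [
        _hit(
            f"s{i:04d}",
            similarity=float(rng.uniform(0, 100)),
            coverage=float(rng.uniform(0, 100)),
            qstart=int(rng.integers(1, 40)),
            score=float(rng.choice([50.0, 75.0, 100.0, 125.0])),  # many ties
            qid=qid,
        )
        for i in range(n)
    ]


class TestFilterAndRank:
    def test_boundary_hits_excluded_by_strict_inequality(self):
        at_similarity = _hit("s1", similarity=30.0, coverage=90.0)
        above = _hit("s2", similarity=30.1, coverage=90.0)
        at_coverage = _hit("s3", similarity=90.0, coverage=70.0)
        retained = filter_and_rank([at_similarity, above, at_coverage])
        assert [h.subject_id for h in retained] == ["s2"]

    def test_top_k_caps_at_250_under_defaults(self):
        hits = [_hit(f"s{i:03d}", score=float(i)) for i in range(300)]
        retained = filter_and_rank(hits)
        assert len(retained) == 250
        # the best-scoring hits are the ones kept
        assert min(h.rank_score for h in retained) == 50.0

    def test_matches_brute_force_oracle_on_randomized_hits(self):
        params = ScreenParams()
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            hits = _random_hits(rng, 1000)
            expected = brute_force_filter(hits, 30.0, 70.0, 250)
            assert filter_and_rank(hits, params) == expected

    def test_idempotent_on_its_own_output(self, rng):
        hits = _random_hits(rng, 400)
        once = filter_and_rank(hits)
        assert filter_and_rank(once) == once

    def test_mixed_query_ids_and_score_scales_rejected(self):
        with pytest.raises(ValueError, match="mix query ids"):
            filter_and_rank([_hit("s1", qid="q1"), _hit("s2", qid="q2")])
        raw = HomologHit(
            query_id="q", subject_id="s9", similarity_pct=90, coverage_pct=90,
            query_start=1, query_end=50, rank_score=100, score_scale="raw",
        )
        with pytest.raises(ValueError, match="scales"):
            filter_and_rank([_hit("s1"), raw])


class TestCallNte:
    QUERY = ProteinRecord(protein_id="q", sequence="M" * 300, genome_id="g")

    def test_all_homologs_starting_downstream_yield_an_nte(self):
        hits = [_hit(f"s{i}", qstart=26) for i in range(12)]
        call = call_nte(self.QUERY, hits)
        assert call.nte_length == 25 and call.is_nte and call.status == "ok"

    def test_single_full_n_terminus_hit_vetoes_uniqueness(self):
        hits = [_hit(f"s{i}", qstart=26) for i in range(11)] + [_hit("s11", qstart=1)]
        call = call_nte(self.QUERY, hits)
        assert call.nte_length == 0 and not call.is_nte

    def test_insufficient_support_is_a_status_not_an_error(self):
        hits = [_hit(f"s{i}", qstart=26) for i in range(5)]
        call = call_nte(self.QUERY, hits)
        assert not call.is_nte and call.status == "insufficient-support"
        assert call.nte_length == 25  # overhang still measured
        empty = call_nte(self.QUERY, [])
        assert empty.min_query_start is None and empty.status == "insufficient-support"

    def test_truncation_guard_downgrades_large_subject_starts(self):
        hits = [_hit(f"s{i}", qstart=26, sstart=8) for i in range(12)]
        call = call_nte(self.QUERY, hits)
        assert not call.is_nte and call.status == "subject-start-uncertain"
        relaxed = call_nte(self.QUERY, hits, ScreenParams(check_subject_start=False))
        assert relaxed.is_nte and relaxed.nte_length == 18  # 26 - 8

    def test_subject_overhang_discounts_trimmed_boundary_columns(self):
        # alignments trimmed by one boundary mismatch on both sequences:
        # query_start 27 / subject_start 2 still measures a 25-residue NTE
        hits = [_hit(f"s{i}", qstart=27, sstart=2) for i in range(12)]
        call = call_nte(self.QUERY, hits)
        assert call.is_nte and call.nte_length == 25

    def test_out_of_range_calls_are_flagged_but_reported(self):
        hits = [_hit(f"s{i}", qstart=100) for i in range(12)]
        call = call_nte(self.QUERY, hits, ScreenParams(max_nte_len=73))
        assert call.is_nte and call.status == "out-of-range" and call.nte_length == 99

    def test_adding_a_retained_hit_never_increases_nte_length(self, rng):
        hits = [_hit(f"s{i}", qstart=int(rng.integers(5, 40))) for i in range(15)]
        call = call_nte(self.QUERY, hits, ScreenParams(min_nte_len=1))
        more = hits + [_hit("s_extra", qstart=int(rng.integers(1, 40)))]
        call2 = call_nte(self.QUERY, more, ScreenParams(min_nte_len=1))
        assert call2.nte_length <= call.nte_length

    @pytest.mark.parametrize("planted", [10, 42, 73])
    def test_planted_extension_recovered_from_synthetic_family(self, planted):
        fam = make_family(FamilySpec(seed=1, nte_lengths={0: planted}))
        query = fam.proteome.records[0]
        hits = search(query.protein_id, query.sequence, fam.proteome)
        call = call_nte(query, filter_and_rank(hits))
        assert call.nte_length == planted and call.is_nte

    def test_every_positive_call_satisfies_its_invariant_chain(self, rng):
        params = ScreenParams(min_nte_len=10, min_support=10)
        for _ in range(50):
            hits = [
                _hit(f"s{i}", qstart=int(rng.integers(1, 60)))
                for i in range(int(rng.integers(1, 30)))
            ]
            call = call_nte(self.QUERY, hits, params)
            assert call.nte_length >= 0
            if call.is_nte:
                assert call.nte_length >= params.min_nte_len
                assert call.n_hits_retained >= params.min_support


def _call(qid, nte_length, is_nte):
    return NteCall(
        query_id=qid, query_length=200, n_hits_retained=12,
        min_query_start=nte_length + 1, nte_length=nte_length, is_nte=is_nte,
    )


class TestConservationScan:
    def test_two_genomes_with_shared_nte_list_each_other(self):
        calls = {
            "gA": {"a1": _call("a1", 20, True)},
            "gB": {"b1": _call("b1", 20, True)},
        }
        pairs = [("gA", "a1", "gB", "b1")]
        out = conservation_scan(calls, pairs)
        assert out["gA"]["a1"].conserved_in == ("gB",)
        assert out["gB"]["b1"].conserved_in == ("gA",)

    def test_ortholog_without_nte_gives_empty_conservation(self):
        calls = {
            "gA": {"a1": _call("a1", 20, True)},
            "gB": {"b1": _call("b1", 0, False)},
        }
        out = conservation_scan(calls, [("gA", "a1", "gB", "b1")])
        assert out["gA"]["a1"].conserved_in == ()

    def test_four_genome_fixture_with_nte_in_three(self):
        genomes = ["g1", "g2", "g3", "g4"]
        calls = {
            g: {f"{g}_p": _call(f"{g}_p", 20 if g != "g4" else 0, g != "g4")}
            for g in genomes
        }
        pairs = [
            (ga, f"{ga}_p", gb, f"{gb}_p")
            for i, ga in enumerate(genomes)
            for gb in genomes[i + 1:]
        ]
        out = conservation_scan(calls, pairs)
        for g in ("g1", "g2", "g3"):
            assert out[g][f"{g}_p"].conserved_in == tuple(
                sorted(set(("g1", "g2", "g3")) - {g})
            )
        assert out["g4"]["g4_p"].conserved_in == ()


class TestParalogPairs:
    def test_conventional_plus_nte_family_reported_once(self):
        families = {"famA": {"ftsZ1", "ftsZ2"}}
        calls = {"ftsZ1": _call("ftsZ1", 0, False), "ftsZ2": _call("ftsZ2", 17, True)}
        assert paralog_nte_pairs(families, calls) == [("ftsZ1", "ftsZ2", "famA")]

    def test_family_without_conventional_member_not_reported(self):
        families = {"famA": {"x1", "x2"}}
        calls = {"x1": _call("x1", 15, True), "x2": _call("x2", 20, True)}
        assert paralog_nte_pairs(families, calls) == []

    def test_three_planted_dual_paralog_families_give_three_pairs(self):
        families = {f"fam{i}": {f"c{i}", f"n{i}"} for i in range(3)}
        calls = {}
        for i in range(3):
            calls[f"c{i}"] = _call(f"c{i}", 0, False)
            calls[f"n{i}"] = _call(f"n{i}", 30, True)
        pairs = paralog_nte_pairs(families, calls)
        assert len(pairs) == 3
        assert {fam for _, _, fam in pairs} == {"fam0", "fam1", "fam2"}


def test_cluster_families_single_linkage_over_filtered_hits(rng):
    """Two planted families in one proteome cluster into two components."""
    fam_a = make_family(FamilySpec(seed=10, n_homologs=3, core_length=120), genome_id="g")
    fam_b = make_family(FamilySpec(seed=11, n_homologs=3, core_length=120), genome_id="g")
    records = list(fam_a.proteome.records) + list(fam_b.proteome.records)
    from atriscan.seq_io import Proteome

    prot = Proteome(genome_id="g", records=records)
    hits_by_query = {
        r.protein_id: search(r.protein_id, r.sequence, prot) for r in records
    }
    families = cluster_families(hits_by_query, ScreenParams())
    assert len(families) == 2
    member_sets = sorted(families.values(), key=min)
    assert member_sets[0] == {r.protein_id for r in fam_a.proteome}
    assert member_sets[1] == {r.protein_id for r in fam_b.proteome}
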
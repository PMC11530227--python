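"""Search engine: aligner-vs-oracle equivalence, prefilter, E-values, policies."""

import math
import random

import numpy as np
import pytest

from annopipe import fixtures, search
from annopipe.errors import ConfigError
from annopipe.refdb import build_profile, build_sequence_db, calibrate_profile
from annopipe.scoring import AA, AA_INDEX, blosum62
from annopipe.search import (
    SearchParams,
    align_local,
    align_profile,
    evalue_sequence,
    prefilter,
    read_m8,
    search_profile_db,
    search_sequence_db,
    write_m8,
)
from annopipe.seqio import SequenceRecord

import oracles

_MAT = blosum62()


def _lookup(a, b):
    return int(_MAT[AA_INDEX.get(a, 20), AA_INDEX.get(b, 20)])


def _random_protein(rnd, lo, hi):
    return "".join(rnd.choice(AA) for _ in range(rnd.randint(lo, hi)))


class TestAlignLocal:
    def test_self_alignment_diagonal_sum(self):
        # BLOSUM62 self scores: M5 K5 V4 L4 Y7 A4 -> 29
        raw, qi, ti, pid, pairs = align_local("MKVLYA", "MKVLYA")
        assert raw == 29
        assert qi == (0, 6) and ti == (0, 6)
        assert pid == 100.0
        assert pairs == tuple((i, i) for i in range(6))

    def test_no_positive_pair_is_no_hit(self):
        assert align_local("AAAA", "CCCC") is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "MKV")

    def test_gap_cost_is_open_plus_k_extend(self):
        # deletion of one residue relative to an exact copy: the optimal
        # alignment either pays open+extend once or splits into two locals
        q = "WWWWYYYYWWWW"
        t = "WWWWYYYYYWWWW"
        raw, _, _, _, _ = align_local(q, t)
        self_score = sum(_lookup(c, c) for c in q)
        assert raw == self_score - (11 + 1) or raw > 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_dp(self, seed):
        """Raw scores equal an independent quadratic DP oracle exactly."""
        rnd = random.Random(seed)
        for _ in range(30):
            q = _random_protein(rnd, 20, 120)
            t = _random_protein(rnd, 20, 120)
            want = int(oracles.sw_score_sequences(q, t, _lookup))
            res = align_local(q, t)
            got = res[0] if res is not None else 0
            assert got == want


class TestEvalueSequence:
    def test_zero_bit_gives_search_space(self):
        # raw score such that lambda*S = ln K -> bit = 0 -> E = m*n
        lam, K = 0.267, 0.041
        raw = math.log(K) / lam
        bit, ev = evalue_sequence(raw, 300, 10**5, lam, K)
        assert bit == pytest.approx(0.0)
        assert ev == pytest.approx(300 * 10**5)

    def test_one_bit_halves_evalue(self):
        bit1, e1 = evalue_sequence(100, 300, 10**5)
        bit2, e2 = evalue_sequence(100 + math.log(2) / 0.267, 300, 10**5)
        assert bit2 == pytest.approx(bit1 + 1)
        assert e2 == pytest.approx(e1 / 2)

    def test_closed_form(self):
        lam, K, S, m, n = 0.267, 0.041, 100, 300, 10**5
        bit, ev = evalue_sequence(S, m, n, lam, K)
        assert bit == pytest.approx((lam * S - math.log(K)) / math.log(2))
        assert ev == pytest.approx(m * n * 2 ** (-bit))

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            evalue_sequence(100, 0, 10**5)


class TestSearchParams:
    def test_gap_ordering_enforced(self):
        with pytest.raises(ConfigError):
            SearchParams(gap_open=1, gap_extend=5)

    def test_nonpositive_evalue_rejected(self):
        with pytest.raises(ConfigError):
            SearchParams(max_evalue=0.0)


@pytest.fixture(scope="module")
def small_seq_db(tmp_path_factory):
    root = tmp_path_factory.mktemp("searchdb")
    fx = fixtures.make_sequence_db_fixture(root, n_targets=50,
                                           len_range=(80, 160), seed=21)
    return build_sequence_db(fx.fasta_path, fx.metadata_path, "sdb"), fx


class TestPrefilter:
    def test_identical_query_is_top_candidate(self, small_seq_db):
        db, fx = small_seq_db
        target = fx.records[7]
        query = SequenceRecord("q", "", target.residues, "protein")
        cands = prefilter(query, db)
        assert cands[0] == target.id

    def test_foreign_query_has_no_candidates(self, small_seq_db):
        db, _ = small_seq_db
        query = SequenceRecord("q", "", "WYWYWYWYWYWYWYWY", "protein")
        assert prefilter(query, db) == []

    def test_matches_brute_force_diagonal_counting(self, small_seq_db):
        """Prefilter candidate sets equal an exhaustive diagonal k-mer count."""
        db, fx = small_seq_db
        params = SearchParams()
        rng = np.random.default_rng(3)
        for i in range(10):
            src = fx.records[int(rng.integers(len(fx.records)))]
            query = SequenceRecord(f"q{i}", "",
                                   fixtures.mutate(src.residues, 0.7, rng),
                                   "protein")
            got = prefilter(query, db, params)
            want = self._brute_force(query.residues, fx.records, params)
            assert sorted(got) == sorted(want)

    @staticmethod
    def _brute_force(query, targets, params):
        k = params.kmer_len
        out = []
        for rec in targets:
            diags = []
            for qp in range(len(query) - k + 1):
                kmer = query[qp:qp + k]
                tp = -1
                while True:
                    tp = rec.residues.find(kmer, tp + 1)
                    if tp < 0:
                        break
                    diags.append(tp - qp)
            best = 0
            for d in diags:
                cnt = sum(1 for e in diags if d <= e <= d + 8)
                best = max(best, cnt)
            if best >= params.min_diag_kmers:
                out.append(rec.id)
        return out

    def test_planted_homolog_survives_prefilter(self, sequence_db, default_fixture):
        """Full-length homologs at >=60% identity pass the prefilter.

        Uses the default fixture database (targets of 150-400 residues);
        much shorter targets can lack two conserved co-diagonal k-mers at
        this identity, which is the sensitivity cost of exact k-mer
        matching."""
        seq_fx, _, _, _ = default_fixture
        rng = np.random.default_rng(9)
        for i in range(15):
            src = seq_fx.records[int(rng.integers(len(seq_fx.records)))]
            query = SequenceRecord(f"q{i}", "",
                                   fixtures.mutate(src.residues, 0.6, rng),
                                   "protein")
            assert src.id in prefilter(query, sequence_db)


class TestSearchSequenceDb:
    def test_planted_queries_recover_sources(self, small_seq_db):
        db, fx = small_seq_db
        rng = np.random.default_rng(17)
        queries, sources = [], {}
        for i in range(10):
            src = fx.records[int(rng.integers(len(fx.records)))]
            qid = f"q{i}"
            queries.append(SequenceRecord(
                qid, "", fixtures.mutate(src.residues, 0.7, rng), "protein"))
            sources[qid] = src.id
        hits = search_sequence_db(queries, db)
        tops = {}
        for h in hits:
            if h.query_id not in tops or h.bit_score > tops[h.query_id].bit_score:
                tops[h.query_id] = h
        for qid, src_id in sources.items():
            assert tops[qid].target_id == src_id

    def test_self_hit_dominates(self, small_seq_db):
        db, fx = small_seq_db
        target = fx.records[0]
        query = SequenceRecord("q", "", target.residues, "protein")
        hits = search_sequence_db([query], db)
        best = max(hits, key=lambda h: h.bit_score)
        assert best.target_id == target.id
        assert best.pct_identity == 100.0

    def test_no_hit_at_or_above_threshold(self, small_seq_db):
        db, fx = small_seq_db
        rng = np.random.default_rng(23)
        queries = [SequenceRecord(f"q{i}", "",
                                  fixtures.mutate(fx.records[i].residues, 0.7, rng),
                                  "protein") for i in range(8)]
        params = SearchParams(max_evalue=1e-5)
        hits = search_sequence_db(queries, db, params)
        assert hits and all(h.e_value < params.max_evalue for h in hits)

    def test_tightening_threshold_gives_subset(self, small_seq_db):
        db, fx = small_seq_db
        rng = np.random.default_rng(29)
        queries = [SequenceRecord(f"q{i}", "",
                                  fixtures.mutate(fx.records[i].residues, 0.7, rng),
                                  "protein") for i in range(8)]
        loose = search_sequence_db(queries, db, SearchParams(max_evalue=1e-3))
        tight = search_sequence_db(queries, db, SearchParams(max_evalue=1e-8))
        key = lambda h: (h.query_id, h.target_id)
        assert {key(h) for h in tight} <= {key(h) for h in loose}

    def test_shuffled_queries_rarely_hit(self, small_seq_db):
        """Random queries against the db: >=99% have no hit at E<1e-5."""
        db, _ = small_seq_db
        rng = np.random.default_rng(31)
        queries = [SequenceRecord(f"r{i}", "", fixtures.random_protein(rng, 150),
                                  "protein") for i in range(100)]
        hits = search_sequence_db(queries, db)
        hit_queries = {h.query_id for h in hits}
        assert len(hit_queries) <= 1


@pytest.fixture(scope="module")
def two_profiles():
    rng = np.random.default_rng(41)
    out = []
    for i in range(2):
        master = fixtures.random_protein(rng, 70)
        rows = [SequenceRecord("m", "", master, "protein")] + [
            SequenceRecord(f"c{j}", "", fixtures.mutate(master, 0.9, rng),
                           "protein") for j in range(7)]
        p = build_profile(rows, f"PF{i}")
        calibrate_profile(p, 150, 80, seed=41 + i)
        out.append(p)
    return out


class _FakeProfileDb:
    def __init__(self, profiles):
        self.name = "pdb"
        self.profiles = profiles


class TestAlignProfile:
    def test_consensus_aligns_full_length_with_max_scores(self, two_profiles):
        p = two_profiles[0]
        raw, qi, ti, pid, pairs = align_profile(p.consensus, p)
        assert ti == (0, p.length)
        assert pid == 100.0
        assert raw == pytest.approx(sum(p.pssm[i].max() for i in range(p.length)))

    def test_all_x_query_no_hit(self, two_profiles):
        assert align_profile("X" * 50, two_profiles[0]) is None

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_pssm_dp(self, two_profiles, seed):
        """Profile alignment scores equal a brute-force PSSM DP oracle."""
        rnd = random.Random(seed)
        p = two_profiles[seed]
        rows = [list(map(float, r)) for r in p.pssm]
        for _ in range(25):
            q = _random_protein(rnd, 20, 120)
            want = oracles.sw_score_profile(q, rows, AA)
            res = align_profile(q, p)
            got = res[0] if res is not None else 0.0
            assert got == pytest.approx(want, abs=1e-9)


class TestSearchProfileDb:
    def test_two_domain_query_gets_both_profiles(self, two_profiles, rng):
        pa, pb = two_profiles
        linker = fixtures.random_protein(rng, 20)
        query = SequenceRecord(
            "q", "", pa.consensus + linker + pb.consensus, "protein")
        hits = search_profile_db([query], _FakeProfileDb(two_profiles))
        by_profile = {h.target_id: h for h in hits}
        assert set(by_profile) == {"PF0", "PF1"}
        ha, hb = by_profile["PF0"], by_profile["PF1"]
        assert ha.q_end <= len(pa.consensus)
        assert hb.q_start >= len(pa.consensus) + len(linker) - 2

    def test_tandem_repeat_found_by_masked_realignment(self, two_profiles, rng):
        p = two_profiles[0]
        linker = fixtures.random_protein(rng, 15)
        query = SequenceRecord("q", "", p.consensus + linker + p.consensus,
                               "protein")
        hits = [h for h in search_profile_db([query], _FakeProfileDb([p]))
                if h.target_id == "PF0"]
        assert len(hits) >= 2
        a, b = sorted(hits, key=lambda h: h.q_start)[:2]
        assert a.q_end <= b.q_start  # disjoint query intervals

    def test_x_only_query_no_hits(self, two_profiles):
        query = SequenceRecord("q", "", "X" * 80, "protein")
        assert search_profile_db([query], _FakeProfileDb(two_profiles)) == []

    def test_evalue_filter_holds(self, two_profiles, rng):
        query = SequenceRecord("q", "", two_profiles[0].consensus, "protein")
        hits = search_profile_db([query], _FakeProfileDb(two_profiles))
        assert hits and all(h.e_value < 1e-5 for h in hits)


class TestM8:
    def test_round_trip_and_one_based_coordinates(self, tmp_path, small_seq_db):
        db, fx = small_seq_db
        query = SequenceRecord("q", "", fx.records[0].residues, "protein")
        hits = search_sequence_db([query], db)
        path = tmp_path / "hits.m8"
        write_m8(hits, path)
        rows = read_m8(path)
        assert len(rows) == len(hits)
        top = rows[0]
        assert top["qstart"] == 1 and top["sstart"] == 1  # 1-based inclusive
        assert top["qend"] == len(fx.records[0].residues)
        # writing the parsed rows back reproduces the file byte-for-byte
        rehits = [
            search.SearchHit(
                query_id=r["qseqid"], target_id=r["sseqid"], db_name="sdb",
                db_role="sequence", q_start=r["qstart"] - 1, q_end=r["qend"],
                t_start=r["sstart"] - 1, t_end=r["send"], raw_score=0,
                bit_score=r["bitscore"], e_value=r["evalue"],
                pct_identity=r["pident"], aln_len=r["length"],
                mismatches=r["mismatch"], gap_opens=r["gapopen"])
            for r in rows
        ]
        path2 = tmp_path / "hits2.m8"
        write_m8(rehits, path2)
        assert path.read_bytes() == path2.read_bytes()
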
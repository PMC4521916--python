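"""Seed-and-extend search: contracts, strand symmetry, oracle equivalence.

The independent oracle is a full local-alignment scan: Biopython's
PairwiseAligner run over every record and strand with the same scoring,
with no seeding or extension heuristics.  Discrepancies are only tolerated
for alignments that contain no exact word-size match -- the documented
miss class of any word-seeded search.
"""

import math
import random

import pytest
from Bio import Align

from riboseek.search import (
    SearchDatabase,
    SearchParams,
    SimilarityHit,
    build_db,
    has_hits,
    read_tabular,
    revcomp,
    search,
    write_tabular,
)
from riboseek.structures import RnaSequence


def rand_dna(n, rng):
    return "".join(rng.choice("ACGT") for _ in range(n))


def sw_aligner(p: SearchParams):
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = p.match
    a.mismatch_score = p.mismatch
    a.open_gap_score = p.gap_open + p.gap_extend
    a.extend_gap_score = p.gap_extend
    return a


def oracle_hit_keys(query: str, db: SearchDatabase, p: SearchParams):
    """(record, strand) pairs with a full-scan alignment under the cutoff."""
    aligner = sw_aligner(p)
    n_db = db.total_length
    out = set()
    for ri, (rid, seq) in enumerate(db.records):
        for strand in "+-":
            subject = seq if strand == "+" else revcomp(seq)
            score = aligner.score(query, subject)
            if p.e_value(score, len(query), n_db) <= p.e_cutoff:
                out.add((rid, strand))
    return out


def alignment_has_seed(query: str, subject: str, p: SearchParams) -> bool:
    """Does the full-scan best alignment contain >= word_size consecutive
    matches (i.e. a stretch a word-seeded search could have found)?"""
    aln = sw_aligner(p).align(query, subject)[0]
    qb, sb = aln.aligned
    for (qa, qe), (sa, _se) in zip(qb, sb):
        run = 0
        for k in range(qe - qa):
            if query[qa + k] == subject[sa + k]:
                run += 1
                if run >= p.word_size:
                    return True
            else:
                run = 0
    return False


class TestBuildDb:
    def test_forward_posting_count_single_record(self):
        db = build_db([("r", "ACGTACGTACGT")], word_size=7)
        n_fwd = sum(
            1
            for posts in db.word_index.values()
            for (_ri, _off, strand) in posts
            if strand == "+"
        )
        assert n_fwd == 12 - 7 + 1

    def test_short_record_retained_without_postings(self):
        db = build_db([("r", "ACGT")], word_size=7)
        assert db.records == [("r", "ACGT")]
        assert not db.word_index

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            build_db([("r", "ACGTACGT"), ("r", "TTTTAAAA")])

    def test_empty_and_illegal_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_db([])
        with pytest.raises(ValueError, match="bad_rec"):
            build_db([("bad_rec", "ACGTNNN")])

    def test_rna_input_normalized_to_dna(self):
        db = build_db([("r", "ACGUACGUACGU")])
        assert db.records[0][1] == "ACGTACGTACGT"


class TestSearch:
    @pytest.fixture(scope="class")
    @classmethod
    def planted(cls):
        rng = random.Random(71)
        query = rand_dna(60, rng)
        rec1 = rand_dna(900, rng) + query + rand_dna(900, rng)
        rec2 = rand_dna(400, rng) + revcomp(query) + rand_dna(400, rng)
        db = build_db([("r1", rec1), ("r2", rec2), ("r3", rand_dna(1200, rng))])
        return query, db

    def test_exact_plant_is_top_hit_full_identity(self, planted):
        query, db = planted
        hits = search(query, db, SearchParams(e_cutoff=1e-3))
        top = hits[0]
        assert top.record_id in ("r1", "r2")
        assert top.identities == top.alignment_length == 60
        assert (top.query_start, top.query_end) == (0, 60)
        plus = [h for h in hits if h.record_id == "r1"][0]
        assert (plus.subject_start, plus.subject_end, plus.strand) == (900, 960, "+")

    def test_strand_symmetry(self, planted):
        query, db = planted
        p = SearchParams(e_cutoff=1e-3)
        fwd = {(h.record_id, h.strand, h.subject_start, h.subject_end)
               for h in search(query, db, p)}
        rev = {(h.record_id, "-" if h.strand == "+" else "+",
                h.subject_start, h.subject_end)
               for h in search(revcomp(query), db, p)}
        assert fwd == rev

    def test_scores_identical_on_both_strands(self, planted):
        query, db = planted
        hits = search(query, db, SearchParams(e_cutoff=1e-3))
        scores = {h.record_id: h.raw_score for h in hits}
        assert scores["r1"] == scores["r2"] == 120.0  # 60 matches * +2

    def test_e_cutoff_monotonicity(self, planted):
        query, db = planted
        rng = random.Random(73)
        mutated = list(query)
        for i in rng.sample(range(60), 12):
            mutated[i] = rng.choice([c for c in "ACGT" if c != mutated[i]])
        mutated = "".join(mutated)
        keys = lambda p: {
            (h.record_id, h.strand, h.subject_start) for h in search(mutated, db, p)
        }
        loose = keys(SearchParams(e_cutoff=10))
        tight = keys(SearchParams(e_cutoff=1e-6))
        assert tight <= loose

    def test_query_shorter_than_word_rejected(self, planted):
        _query, db = planted
        with pytest.raises(ValueError):
            search("ACGT", db)

    def test_has_hits_matches_search(self, planted):
        query, db = planted
        p = SearchParams(e_cutoff=1e-3)
        assert has_hits(query, db, p)
        assert not has_hits(rand_dna(60, random.Random(79)), db, p)

    def test_karlin_evalue_and_bitscore_formulas(self):
        p = SearchParams()
        s = 50
        assert p.e_value(s, 69, 10000) == pytest.approx(
            0.41 * 69 * 10000 * math.exp(-0.625 * s)
        )
        assert p.bit_score(s) == pytest.approx(
            (0.625 * s - math.log(0.41)) / math.log(2)
        )

    def test_gapped_alignment_bridges_an_insertion(self):
        rng = random.Random(83)
        left, right = rand_dna(30, rng), rand_dna(30, rng)
        query = left + right
        subject = rand_dna(200, rng) + left + "ACGT" + right + rand_dna(200, rng)
        hits = search(query, build_db([("r", subject)]), SearchParams(e_cutoff=1e-6))
        assert hits and hits[0].gap_opens >= 1
        assert hits[0].identities == 60
        # gapped score: 60 matches, one 4-nt gap (open 5 + 4 * extend 2)
        assert hits[0].raw_score == 120 - (5 + 4 * 2)


class TestOracleEquivalence:
    def test_agreement_with_full_alignment_scan(self):
        """Seeded search reproduces the full-scan verdicts; any miss must
        lack an exact word seed."""
        rng = random.Random(89)
        query0 = rand_dna(69, rng)
        db = build_db(
            [("g1", rand_dna(4000, rng) + query0 + rand_dna(4000, rng))]
            + [(f"g{i}", rand_dna(6000, rng)) for i in range(2, 4)]
        )
        p = SearchParams(e_cutoff=1e-2)
        agree = total = 0
        for t in range(25):
            q = list(query0)
            for i in rng.sample(range(69), rng.randint(0, 30)):
                q[i] = rng.choice([c for c in "ACGT" if c != q[i]])
            q = "".join(q)
            mine = {(h.record_id, h.strand) for h in search(q, db, p)}
            oracle = oracle_hit_keys(q, db, p)
            total += 1
            if mine == oracle:
                agree += 1
            else:
                for rid, strand in oracle - mine:
                    subject = next(s for r, s in db.records if r == rid)
                    if strand == "-":
                        subject = revcomp(subject)
                    assert not alignment_has_seed(q, subject, p)
                assert not (mine - oracle)  # never report what the scan rejects
        assert agree / total >= 0.95


class TestTabular:
    def test_outfmt6_roundtrip(self, tmp_path):
        rng = random.Random(97)
        query = rand_dna(60, rng)
        db = build_db(
            [
                ("r1", rand_dna(300, rng) + query + rand_dna(300, rng)),
                ("r2", rand_dna(200, rng) + revcomp(query) + rand_dna(200, rng)),
            ]
        )
        hits = search(RnaSequence("q", query), db, SearchParams(e_cutoff=1e-3))
        path = tmp_path / "hits.tsv"
        write_tabular(hits, path)
        back = read_tabular(path)
        assert len(back) == len(hits)
        for a, b in zip(hits, back):
            assert (a.record_id, a.strand) == (b.record_id, b.strand)
            assert (a.subject_start, a.subject_end) == (b.subject_start, b.subject_end)
            assert (a.query_start, a.query_end) == (b.query_start, b.query_end)
            assert b.e_value == pytest.approx(a.e_value, rel=0.01)
            assert b.identities == a.identities

    def test_minus_strand_prints_reversed_coordinates(self, tmp_path):
        hit = SimilarityHit(
            record_id="r", query_id="q", query_start=0, query_end=10,
            subject_start=100, subject_end=110, strand="-", raw_score=20,
            bit_score=19.3, e_value=1e-5, identities=10, alignment_length=10,
        )
        path = tmp_path / "one.tsv"
        write_tabular([hit], path)
        fields = path.read_text().split("\t")
        assert (fields[8], fields[9]) == ("110", "101")
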
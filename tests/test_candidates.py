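"""Window extraction and structural vetting of hits."""

import random

import pytest

from riboseek.candidates import (
    CandidateReport,
    assess,
    extract_window,
    rank_candidates,
)
from riboseek.folding import fold_mfe
from riboseek.search import SimilarityHit, revcomp
from riboseek.structures import MotifConstraint, RnaSequence
from riboseek.synthetic import diverge_covariant


def make_hit(**kw):
    base = dict(
        record_id="r", query_id="q", query_start=0, query_end=69,
        subject_start=100, subject_end=169, strand="+", raw_score=138,
        bit_score=120.0, e_value=1e-30, identities=69, alignment_length=69,
    )
    base.update(kw)
    return SimilarityHit(**base)


class TestExtractWindow:
    def setup_method(self):
        rng = random.Random(7)
        self.record = "".join(rng.choice("ACGT") for _ in range(400))

    def test_full_length_hit_is_subject_interval(self):
        (lo, hi), win = extract_window(self.record, make_hit(), 69)
        assert (lo, hi) == (100, 169)
        assert win == self.record[100:169]

    def test_partial_hit_anchored_by_query_offset(self):
        hit = make_hit(query_start=10, query_end=40, subject_start=150,
                       subject_end=180, identities=30, alignment_length=30)
        (lo, hi), _ = extract_window(self.record, hit, 69)
        # 10 aligned-query positions precede the hit: extend 10 upstream
        assert (lo, hi) == (140, 209)

    def test_clipped_at_record_start_keeps_length(self):
        hit = make_hit(query_start=10, query_end=40, subject_start=3,
                       subject_end=33, identities=30, alignment_length=30)
        (lo, hi), win = extract_window(self.record, hit, 69)
        assert (lo, hi) == (0, 69)
        assert len(win) == 69

    def test_minus_strand_window_is_reverse_complemented(self):
        hit = make_hit(strand="-")
        (lo, hi), win = extract_window(self.record, hit, 69)
        assert (lo, hi) == (100, 169)
        assert win == revcomp(self.record[100:169])

    def test_record_shorter_than_aptamer_rejected(self):
        with pytest.raises(ValueError):
            extract_window("ACGT" * 10, make_hit(), 69)


class TestAssess:
    def test_query_window_is_accepted_known_at_zero_distance(
        self, vienna_engine, xpt, xpt_ref
    ):
        report = assess(xpt, xpt, xpt_ref, vienna_engine)
        assert report.verdict
        assert report.is_known
        assert report.bp_distance_to_query == 0
        assert report.shapiro_distance_to_query == 0
        assert report.preserved_positions == frozenset(range(69))

    def test_unstructured_window_rejected(self, vienna_engine, xpt, xpt_ref):
        window = RnaSequence("w", "AC" * 34 + "A")
        report = assess(window, xpt, xpt_ref, vienna_engine)
        assert not report.verdict
        assert report.shapiro_distance_to_query > 2

    def test_covariant_homolog_accepted_with_preserved_positions(
        self, vienna_engine, xpt, xpt_ref
    ):
        rng = random.Random(19)
        hom = diverge_covariant(xpt, xpt_ref, 15, rng, vienna_engine)
        report = assess(hom, xpt, xpt_ref, vienna_engine)
        assert report.verdict and not report.is_known
        assert report.shapiro_distance_to_query == 0
        assert report.bp_distance_to_query == 0
        n_mut = sum(a != b for a, b in zip(hom.residues, xpt.residues))
        assert len(report.preserved_positions) == 69 - n_mut

    def test_verdict_invariant_under_covariant_mutation(
        self, vienna_engine, xpt, xpt_ref
    ):
        # metamorphic: a structure-preserving substitution of the window
        # cannot change the verdict (it depends on the fold only)
        rng = random.Random(23)
        window = diverge_covariant(xpt, xpt_ref, 5, rng, vienna_engine)
        before = assess(window, xpt, xpt_ref, vienna_engine).verdict
        mutated = diverge_covariant(window, xpt_ref, 3, rng, vienna_engine)
        after = assess(mutated, xpt, xpt_ref, vienna_engine).verdict
        assert before == after

    def test_motif_region_check(self, vienna_engine, xpt, xpt_ref):
        # protect the multibranch core of the aptamer
        labels_region = (20, 45)
        constraint = MotifConstraint(
            region=labels_region,
            required_substructure=xpt_ref.dotbracket[slice(*labels_region)],
        )
        ok = assess(xpt, xpt, xpt_ref, vienna_engine, constraint=constraint)
        assert ok.verdict

    def test_large_bp_distance_alone_does_not_reject(self, builtin_engine):
        # a window whose stem is shifted relative to the reference: every
        # individual pair moves (large bp distance) but the coarse shape is
        # intact, and the shapiro distance drives the verdict
        from riboseek.structures import parse_dotbracket

        query = RnaSequence("q", "GGGGAAACCCCAA")
        reference = parse_dotbracket("((((...))))..")
        window = RnaSequence("w", "AAGGGGAAACCCC")  # folds to ..((((...))))
        report = assess(window, query, reference, builtin_engine)
        assert report.bp_distance_to_query == 8
        assert report.shapiro_distance_to_query <= 2
        assert report.verdict

    def test_length_mismatch_rejected(self, vienna_engine, xpt, xpt_ref):
        with pytest.raises(ValueError):
            assess(RnaSequence("w", "ACGU"), xpt, xpt_ref, vienna_engine)


class TestRankCandidates:
    def _report(self, verdict, shapiro, bp, ev, rid="r"):
        return CandidateReport(
            record_id=rid, start=0, end=10, strand="+",
            window_sequence=RnaSequence("w", "ACGUACGUAC"),
            predicted_structure=None, bp_distance_to_query=bp,
            shapiro_distance_to_query=shapiro, preserved_positions=frozenset(),
            verdict=verdict, e_value=ev,
        )

    def test_accepted_before_rejected_regardless_of_distances(self):
        rejected = self._report(False, 0, 0, 1e-30)
        accepted = self._report(True, 2, 39, 1.0)
        assert rank_candidates([rejected, accepted])[0] is accepted

    def test_ordering_and_stability(self):
        a = self._report(True, 1, 5, 1e-3, rid="a")
        b = self._report(True, 1, 5, 1e-3, rid="b")
        c = self._report(True, 0, 20, 1e-2, rid="c")
        ranked = rank_candidates([a, b, c])
        assert [r.record_id for r in ranked] == ["c", "a", "b"]

    def test_single_report_unchanged(self):
        r = self._report(True, 0, 0, 1e-5)
        assert rank_candidates([r]) == [r]
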
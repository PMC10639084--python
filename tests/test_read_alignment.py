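"""Local alignment, decoys and the specificity cutoff.

The affine-gap kernel is checked exactly against an independently written
brute-force dynamic program over random sequence pairs.
"""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qtrna.read_alignment import (
    AlignmentRecord,
    ScoringScheme,
    align_to_references,
    compute_cutoff,
    filter_significant,
    local_align,
    make_decoy,
    cigar_consumed_lengths,
)
from qtrna.read_simulator import ErrorModel, simulate_read

SEQ = st.text(alphabet="ACGT", min_size=0, max_size=40)


def sw_score_bruteforce(a: str, b: str, scheme: ScoringScheme) -> int:
    """Independent three-matrix affine-gap DP, score only."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + scheme.gap_open, E[i][j - 1] + scheme.gap_extend)
            F[i][j] = max(H[i - 1][j] + scheme.gap_open, F[i - 1][j] + scheme.gap_extend)
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAlign:
    def test_identity(self):
        rec = local_align("ACGTACGT", "ACGTACGT", ScoringScheme(2, -3, -5, -2))
        assert rec.score == 16 and rec.cigar == "8="

    def test_all_mismatch_single_best_base(self):
        rec = local_align("ACGT", "TTTT", ScoringScheme(2, -3, -5, -2))
        assert rec.score == 2
        assert rec.score == sw_score_bruteforce("ACGT", "TTTT", ScoringScheme(2, -3, -5, -2))

    def test_empty_read(self):
        rec = local_align("", "ACGT")
        assert rec.score == 0 and rec.ref_end == rec.ref_start == 0

    def test_empty_reference(self):
        rec = local_align("ACGT", "")
        assert rec.score == 0

    def test_oracle_equivalence_200_random_pairs(self):
        rng = np.random.default_rng(1)
        scheme = ScoringScheme()
        matches = 0
        for _ in range(200):
            a = "".join("ACGT"[k] for k in rng.integers(0, 4, rng.integers(1, 41)))
            b = "".join("ACGT"[k] for k in rng.integers(0, 4, rng.integers(1, 41)))
            if local_align(a, b, scheme).score == sw_score_bruteforce(a, b, scheme):
                matches += 1
        assert matches == 200

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=SEQ, b=SEQ)
    def test_score_symmetric_under_symmetric_scheme(self, a, b):
        scheme = ScoringScheme()
        assert local_align(a, b, scheme).score == local_align(b, a, scheme).score

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=SEQ.filter(bool), b=SEQ.filter(bool))
    def test_cigar_consistent_with_intervals(self, a, b):
        rec = local_align(a, b)
        read_len, ref_len = cigar_consumed_lengths(rec.cigar)
        assert ref_len == rec.ref_end - rec.ref_start
        assert read_len == rec.read_end - rec.read_start
        # soft clips + consumed read bases account for the whole read
        total = sum(int(n) for n, _ in re.findall(r"(\d+)([MX=IS])", rec.cigar))
        assert total == len(a)


class TestDecoy:
    def test_reversal(self):
        assert make_decoy("AACG") == "GCAA"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(s=SEQ)
    def test_involution_and_composition(self, s):
        assert make_decoy(make_decoy(s)) == s
        assert sorted(make_decoy(s)) == sorted(s)


class TestCutoff:
    def test_uniform_decoys(self):
        model = compute_cutoff([], range(1, 101), level=0.95)
        assert model.cutoff == 96
        assert model.realized_specificity == pytest.approx(0.95)

    def test_all_zero_decoys(self):
        model = compute_cutoff([10, 20], [0] * 100, level=0.95)
        assert model.cutoff == 1 and model.realized_specificity == 1.0

    def test_level_zero_keeps_everything(self):
        model = compute_cutoff([5, 7], [3, 4, 9], level=0.0)
        assert model.cutoff == min([5, 7, 3, 4, 9])

    def test_empty_decoys_error(self):
        with pytest.raises(ValueError):
            compute_cutoff([1], [])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        decoys=st.lists(st.integers(0, 60), min_size=1, max_size=80),
        level=st.floats(0.0, 0.99),
    )
    def test_realized_specificity_at_least_level(self, decoys, level):
        model = compute_cutoff([], decoys, level)
        assert model.realized_specificity >= level


class TestRankingAndFiltering:
    def test_ranks_and_default_retention(self, ten_refs):
        read = ten_refs[0].full_sequence  # exact copy of one reference
        hits = align_to_references("r", read, ten_refs, keep_all_ranks=True)
        assert hits[0].rank == 1 and hits[0].ref_name == ten_refs[0].name
        assert all(
            h1.rank <= h2.rank for h1, h2 in zip(hits, hits[1:])
        )
        top_only = align_to_references("r", read, ten_refs)
        assert all(h.rank == 1 for h in top_only)

    def test_tied_top_scores_share_rank_one(self):
        from qtrna.reference_curation import TRNAReference

        body = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTA"
        refs = [
            TRNAReference("a", body, "", "", 10),
            TRNAReference("b", body, "", "", 10),
        ]
        hits = align_to_references("r", body, refs)
        assert len(hits) == 2 and {h.rank for h in hits} == {1}

    def test_simulated_read_maps_back_to_source(self, ten_refs):
        rng = np.random.default_rng(3)
        for ref in ten_refs[:3]:
            read = simulate_read(
                ref, ErrorModel(0, 0, 0, p_truncation=0), rng=rng
            )
            hits = align_to_references("r", read, ten_refs)
            assert [h.ref_name for h in hits] == [ref.name]

    def test_filter_significant(self):
        def rec(rid, ref, score, rank=1, decoy=False):
            return AlignmentRecord(rid, ref, score, 0, 4, 0, 4, "4=", rank, decoy)

        model = compute_cutoff([], [9] * 100, level=0.95)  # cutoff 10
        alns = [
            rec("a", "r1", 9),
            rec("b", "r1", 10),
            rec("c", "r1", 15),
            rec("d", "r1", 15),
            rec("d", "r2", 15),  # multimapped
            rec("e", "r1", 50, decoy=True),
            rec("f", "r1", 50, rank=2),
        ]
        kept = filter_significant(alns, model)
        assert sorted(a.read_id for a in kept) == ["b", "c"]
        kept_mm = filter_significant(alns, model, keep_multimapped=True)
        assert sorted(a.read_id for a in kept_mm) == ["b", "c", "d", "d"]

    def test_error_rate_degrades_mean_score(self, single_ref):
        ref = single_ref[0]
        means = []
        for p in (0.0, 0.08, 0.2):
            scores = []
            for seed in range(3):
                rng = np.random.default_rng(100 + seed)
                model = ErrorModel(p, p / 2, p / 4, p_truncation=0)
                for _ in range(30):
                    read = simulate_read(ref, model, rng=rng)
                    scores.append(align_to_references("r", read, single_ref)[0].score)
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]
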
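"""Local alignment similarity, recognition probability and TIS aggregation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neoscreen.tcr import (
    EpitopePool,
    identity_lookup,
    local_align_score,
    pair_score,
    pool_similarities,
    recognition_probability,
    tis,
)
from oracles import brute_force_local_score


class TestLocalAlignScore:
    @pytest.mark.parametrize(
        "s, e, expected",
        [
            ("AAAAAAAAA", "AAAAAAAAA", 36.0),   # 9 x BLOSUM62(A,A)=4
            ("KLVVVGAGG", "KLVVVGAGG", 43.0),   # sum of diagonal entries
            ("AAAA", "AACA", 12.0),             # full-length 4+4+0+4 beats any block
        ],
    )
    def test_frozen_examples(self, s, e, expected):
        assert local_align_score(s, e) == expected

    def test_gap_costs_open_plus_extend(self):
        # forced single-residue gap: 8 x W(11) - (11 + 1) = 76
        assert local_align_score("WWWWAWWWW", "WWWWWWWW") == 76.0

    def test_non_canonical_residue_rejected(self):
        with pytest.raises(ValueError):
            local_align_score("AAXAA", "AAAAA")

    def test_matches_brute_force_on_short_peptides(self):
        rng = np.random.default_rng(11)
        alphabet = "ACDEG"
        for _ in range(40):
            s = "".join(rng.choice(list(alphabet), size=rng.integers(1, 7)))
            e = "".join(rng.choice(list(alphabet), size=rng.integers(1, 7)))
            assert local_align_score(s, e) == brute_force_local_score(s, e), (s, e)

    def test_matches_biotite_on_random_9mers(self):
        biotite_align = pytest.importorskip("biotite.sequence.align")
        import biotite.sequence as bseq

        matrix = biotite_align.SubstitutionMatrix.std_protein_matrix()
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(60):
            s = "".join(rng.choice(aas, size=9))
            e = "".join(rng.choice(aas, size=rng.integers(8, 16)))
            # biotite charges |open| for a length-1 gap, so (-12, -1) matches
            # the open-11-plus-1-per-residue convention used here
            ref = biotite_align.align_optimal(
                bseq.ProteinSequence(s), bseq.ProteinSequence(e), matrix,
                gap_penalty=(-12, -1), local=True,
            )[0].score
            assert local_align_score(s, e) == ref, (s, e)

    @given(st.text("ACDEFGHIKL", min_size=1, max_size=9),
           st.text("ACDEFGHIKL", min_size=1, max_size=9))
    def test_self_similarity_dominates(self, s, e):
        assert local_align_score(s, s) >= local_align_score(s, e)
        assert local_align_score(s, e) >= 0.0

    def test_bit_score_scale_is_monotone_rescale(self):
        raw = local_align_score("KLVVVGAGG", "KLVVVGAGG")
        bit = local_align_score("KLVVVGAGG", "KLVVVGAGG", score_kind="bit")
        assert bit == pytest.approx((0.267 * raw - math.log(0.041)) / math.log(2))


class TestRecognitionProbability:
    def test_empty_pool_gives_zero(self):
        assert recognition_probability("AAAAAAAAA", EpitopePool(())) == 0.0

    def test_half_probability_at_displacement(self):
        r = recognition_probability("x", EpitopePool(()), a=26, k=1,
                                    similarities=[26.0])
        assert r == pytest.approx(0.5)

    def test_one_unit_above_displacement(self):
        r = recognition_probability("x", EpitopePool(()), a=26, k=1,
                                    similarities=[27.0])
        assert r == pytest.approx(math.e / (1 + math.e))

    def test_numerically_stable_for_huge_similarity(self):
        r = recognition_probability("x", EpitopePool(()), similarities=[1e4])
        assert 0.0 <= r < 1.0 and r == pytest.approx(1.0)

    @given(st.lists(st.floats(-50, 80), min_size=1, max_size=20),
           st.integers(0, 19), st.floats(0.1, 10.0))
    def test_monotone_in_similarities_and_pool_growth(self, sims, idx, bump):
        base = recognition_probability("x", EpitopePool(()), similarities=sims)
        assert 0.0 <= base < 1.0
        bumped = list(sims)
        bumped[idx % len(sims)] += bump
        assert recognition_probability("x", EpitopePool(()),
                                       similarities=bumped) >= base
        grown = sims + [0.0]
        assert recognition_probability("x", EpitopePool(()),
                                       similarities=grown) >= base

    def test_pool_similarities_use_alignment(self):
        pool = EpitopePool.from_sequences(["AAAAAAAAA", "KLVVVGAGG"])
        sims = pool_similarities("AAAAAAAAA", pool)
        assert sims[0] == 36.0


class TestEpitopePool:
    def test_hygiene_casefold_dedup_drop_noncanonical(self):
        pool = EpitopePool.from_sequences(
            [" siinfekl ", "SIINFEKL", "AAXBBAA", "KLVVVGAGG"]
        )
        assert pool.entries == ("SIINFEKL", "KLVVVGAGG")

    @pytest.mark.parametrize(
        "query, expected",
        [("SIINFEKL", True), ("siinfekl", True), ("SIINFEKM", False),
         ("SIINFEK", False)],
    )
    def test_identity_lookup_is_full_length_exact(self, query, expected):
        pool = EpitopePool.from_sequences(["SIINFEKL", "KLVVVGAGG"])
        found, matches = identity_lookup(query, pool)
        assert found is expected
        assert bool(matches) is expected


class TestPairScoreAndTis:
    @pytest.mark.parametrize(
        "calls, expected",
        [((True, True, True), 1.0), ((True, True, False), 0.75),
         ((True, False, False), 0.25), ((False, False, False), 0.0)],
    )
    def test_pair_score_counts_positives(self, calls, expected):
        for perm in set(itertools.permutations(calls)):
            assert pair_score(perm) == expected

    def test_pair_score_requires_three_calls(self):
        with pytest.raises(ValueError):
            pair_score((True, True))

    @pytest.mark.parametrize(
        "scores, expected",
        [([1, 1, 0, 0], 0.5), ([1, 0.75, 0.75, 1], 1.0), ([0.25, 0, 0.25, 0], 0.0)],
    )
    def test_tis_fraction_above_threshold(self, scores, expected):
        assert tis(scores, threshold=0.75) == pytest.approx(expected)

    def test_tis_mean_reading_available_explicitly(self):
        assert tis([1, 0.5, 0], method="mean_pair_score") == pytest.approx(0.5)

    def test_tis_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            tis([])
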
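"""Pair-HMM posteriors, partition-function pairing, homology weights."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dagalign.posterior import (
    NumericModelError,
    PairHmmParams,
    PairingModel,
    SparseProbMatrix,
    align_posteriors,
    homology_probability,
    log_likelihood,
    mea_pairwise,
    pairing_posteriors,
)
from dagalign.seqio import RnaSequence

from .conftest import random_hmm_params, random_sequence
from .oracles import enum_pair_hmm_posterior, enum_pairing_posterior


def match_biased_params() -> PairHmmParams:
    me = np.full((4, 4), 0.004)
    np.fill_diagonal(me, 0.238)
    me /= me.sum()
    return PairHmmParams(me, np.full(4, 0.25), 0.02, 0.5)


class TestPairHmmParams:
    def test_emission_sum_validated(self):
        with pytest.raises(ValueError, match="sum"):
            PairHmmParams(np.full((4, 4), 0.1), np.full(4, 0.25), 0.1, 0.5)

    def test_gap_probabilities_validated(self):
        me = np.full((4, 4), 1 / 16)
        with pytest.raises(ValueError, match="gap_open"):
            PairHmmParams(me, np.full(4, 0.25), 0.6, 0.5)


class TestAlignPosteriors:
    @pytest.mark.parametrize("draw", range(12))
    def test_matches_exhaustive_enumeration(self, draw):
        """Forward-backward equals the sum over all alignment paths."""
        rng = np.random.default_rng(1000 + draw)
        params = random_hmm_params(rng)
        x = random_sequence(rng, int(rng.integers(1, 5)), "x")
        y = random_sequence(rng, int(rng.integers(1, 5)), "y")
        mine = align_posteriors(x, y, params, threshold=0.0).toarray()
        ref = enum_pair_hmm_posterior(x.residues, y.residues, params)
        assert np.abs(mine - ref).max() < 1e-10

    def test_forward_backward_totals_agree(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            params = random_hmm_params(rng)
            x = random_sequence(rng, int(rng.integers(10, 51)), "x")
            y = random_sequence(rng, int(rng.integers(10, 51)), "y")
            zf, zb = log_likelihood(x, y, params)
            assert zf == pytest.approx(zb, abs=1e-8)

    def test_identical_sequences_favour_diagonal(self):
        x = RnaSequence("x", "ACGU")
        post = align_posteriors(x, x, match_biased_params(), threshold=0.0).toarray()
        assert (post.argmax(axis=1) == np.arange(4)).all()

    def test_row_and_column_sums_bounded(self):
        rng = np.random.default_rng(21)
        params = random_hmm_params(rng)
        x = random_sequence(rng, 30, "x")
        y = random_sequence(rng, 25, "y")
        post = align_posteriors(x, y, params, threshold=0.0).toarray()
        assert post.sum(axis=1).max() <= 1 + 1e-9
        assert post.sum(axis=0).max() <= 1 + 1e-9

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(31)
        params = random_hmm_params(rng)
        x = random_sequence(rng, 12, "x")
        y = random_sequence(rng, 9, "y")
        pxy = align_posteriors(x, y, params, threshold=0.0).toarray()
        pyx = align_posteriors(y, x, params, threshold=0.0).toarray()
        assert np.abs(pxy - pyx.T).max() < 1e-12

    def test_degenerate_parameters_raise(self):
        me = np.zeros((4, 4))
        me[1, 1] = 1.0  # only C~C emits
        params = PairHmmParams(me, np.array([0.0, 1 / 3, 1 / 3, 1 / 3]), 0.1, 0.5)
        with pytest.raises(NumericModelError, match="partition"):
            align_posteriors(RnaSequence("x", "A"), RnaSequence("y", "A"), params)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_threshold_monotonicity(self, seed):
        """Raising the threshold removes entries without changing the rest."""
        rng = np.random.default_rng(seed)
        params = random_hmm_params(rng)
        x = random_sequence(rng, 10, "x")
        y = random_sequence(rng, 10, "y")
        lo = align_posteriors(x, y, params, threshold=0.001)
        hi = align_posteriors(x, y, params, threshold=0.05)
        lo_map = {(i, j): v for i, j, v in lo.items()}
        for i, j, v in hi.items():
            assert lo_map[(i, j)] == pytest.approx(v, abs=0)


class TestPairingPosteriors:
    @pytest.mark.parametrize("draw", range(8))
    def test_matches_structure_enumeration(self, draw):
        """Inside-outside equals enumeration over all nested structures."""
        rng = np.random.default_rng(2000 + draw)
        model = PairingModel(
            {"GC": 3.0, "CG": 3.0, "AU": 2.0, "UA": 2.0, "GU": 1.0, "UG": 1.0},
            min_hairpin=3,
            stack_bonus=float(rng.uniform(1.0, 30.0)),
        )
        x = random_sequence(rng, int(rng.integers(5, 13)), "x")
        mine = pairing_posteriors(x, model, threshold=0.0).toarray()
        ref = enum_pairing_posterior(x.residues, model)
        assert np.abs(mine - ref).max() < 1e-10

    def test_no_canonical_pairs_gives_empty_matrix(self):
        pm = pairing_posteriors(RnaSequence("x", "AAAAAA"), threshold=0.0)
        assert pm.nnz == 0

    def test_single_partner_normalization(self):
        rng = np.random.default_rng(3)
        x = random_sequence(rng, 40, "x")
        arr = pairing_posteriors(x, threshold=0.0).toarray()
        per_base = arr.sum(axis=0) + arr.sum(axis=1)
        assert per_base.max() <= 1 + 1e-9

    def test_hairpin_constraint_respected(self):
        pm = pairing_posteriors(RnaSequence("x", "GGGAAACCC"), threshold=0.0)
        for i, j, _ in pm.items():
            assert j - i - 1 >= pm.min_hairpin

    def test_n_never_pairs(self):
        pm = pairing_posteriors(RnaSequence("x", "GNGAAACNC"), threshold=0.0)
        for i, j, _ in pm.items():
            assert "N" not in ("GNGAAACNC"[i], "GNGAAACNC"[j])


class TestHomologyProbability:
    def test_identical_sequences_score_high(self):
        x = RnaSequence("x", "ACGUACGUACGU")
        post = align_posteriors(x, x, match_biased_params(), threshold=0.0)
        assert homology_probability(x, x, post) >= 0.9

    def test_zero_posterior_gives_zero(self):
        x = RnaSequence("x", "ACGU")
        empty = SparseProbMatrix.from_dense(np.zeros((4, 4)), 0.01)
        assert homology_probability(x, x, empty) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        params = random_hmm_params(rng)
        x = random_sequence(rng, 15, "x")
        y = random_sequence(rng, 11, "y")
        pxy = align_posteriors(x, y, params, threshold=0.0)
        pyx = align_posteriors(y, x, params, threshold=0.0)
        assert homology_probability(x, y, pxy) == pytest.approx(
            homology_probability(y, x, pyx), abs=1e-12
        )


def test_mea_pairwise_recovers_clear_path():
    post = np.zeros((3, 3))
    post[0, 0] = post[1, 1] = post[2, 2] = 0.9
    matches, score = mea_pairwise(post)
    assert matches == [(0, 0), (1, 1), (2, 2)]
    assert score == pytest.approx(2.7)
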
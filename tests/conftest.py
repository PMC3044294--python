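"""Shared fixtures and synthetic-instance builders."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from dagalign.consistency import ProbabilitySet
from dagalign.posterior import PairHmmParams, PairingMatrix, SparseProbMatrix
from dagalign.seqio import RnaSequence

BASES = "ACGU"


def random_sequence(rng: np.random.Generator, length: int, sid: str = "x") -> RnaSequence:
    return RnaSequence(sid, "".join(rng.choice(list(BASES), length)))


def random_hmm_params(rng: np.random.Generator) -> PairHmmParams:
    me = rng.random((4, 4)) + 0.05
    me = (me + me.T) / 2
    me /= me.sum()
    ie = rng.random(4) + 0.1
    ie /= ie.sum()
    return PairHmmParams(
        me, ie, float(rng.uniform(0.01, 0.4)), float(rng.uniform(0.1, 0.9))
    )


def random_probability_set(
    rng: np.random.Generator,
    m: int = 3,
    min_len: int = 6,
    max_len: int = 10,
    threshold: float = 0.01,
) -> ProbabilitySet:
    """A synthetic ProbabilitySet with random (valid) sparse matrices.

    Row/column sums of the alignment matrices and per-base pairing sums
    are kept below 1, as the posterior semantics require.
    """
    seqs = [
        random_sequence(rng, int(rng.integers(min_len, max_len + 1)), f"s{k}")
        for k in range(m)
    ]
    align = {}
    homology = {}
    for a in range(m):
        for b in range(a + 1, m):
            La, Lb = len(seqs[a]), len(seqs[b])
            arr = rng.random((La, Lb)) * (rng.random((La, Lb)) < 0.4)
            # scale rows and columns so sums stay <= 1
            arr /= np.maximum(arr.sum(axis=1, keepdims=True), 1.0)
            arr /= np.maximum(arr.sum(axis=0, keepdims=True), 1.0)
            align[(a, b)] = SparseProbMatrix.from_dense(arr, threshold)
            homology[(a, b)] = float(rng.uniform(0.05, 1.0))
    pairing = {}
    h = 3
    for x in range(m):
        L = len(seqs[x])
        arr = np.zeros((L, L))
        ii, jj = np.triu_indices(L, k=h + 1)
        if len(ii):
            vals = rng.random(len(ii)) * (rng.random(len(ii)) < 0.5)
            arr[ii, jj] = vals
            tot = arr.sum(axis=0) + arr.sum(axis=1)
            scale = max(tot.max(), 1.0)
            arr /= scale
        pairing[x] = PairingMatrix.from_dense(arr, threshold, h)
    return ProbabilitySet(seqs, align, pairing, homology, threshold)


def diagonal_dominant_pair(
    rng: np.random.Generator, max_len: int = 20, threshold: float = 0.01
) -> ProbabilitySet:
    """Two sequences whose alignment posterior follows one strong
    monotone path (plus weak off-path noise)."""
    Lx = int(rng.integers(5, max_len + 1))
    Ly = int(rng.integers(5, max_len + 1))
    seqs = [random_sequence(rng, Lx, "s0"), random_sequence(rng, Ly, "s1")]
    # sparse, weak off-path noise: the diagonal path must stay dominant
    arr = rng.random((Lx, Ly)) * 0.04 * (rng.random((Lx, Ly)) < 0.15)
    i = j = 0
    while i < Lx and j < Ly:
        step = rng.random()
        if step < 0.75:  # match step: high posterior, then advance both
            arr[i, j] = rng.uniform(0.7, 0.95)
            i, j = i + 1, j + 1
        elif step < 0.875:  # gap in y
            i += 1
        else:  # gap in x
            j += 1
    align = {(0, 1): SparseProbMatrix.from_dense(arr, threshold)}
    pairing = {
        0: PairingMatrix.from_dense(np.zeros((Lx, Lx)), threshold, 3),
        1: PairingMatrix.from_dense(np.zeros((Ly, Ly)), threshold, 3),
    }
    return ProbabilitySet(seqs, align, pairing, {(0, 1): 0.9}, threshold)


@pytest.fixture(scope="session")
def small_family():
    from dagalign.simulate import sample_family

    return sample_family(m=4, length=50, seed=11)


@pytest.fixture(scope="session")
def small_family_probs(small_family):
    return ProbabilitySet.compute(small_family.sequences)
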
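"""Probabilistic consistency transformations.

Three sparse transformations sharpen the posterior probabilities before
the alignment graph is built:

* **inter-sequence** — re-estimates each pairwise base-alignment matrix
  as a homology-weighted average of relay products through every
  sequence ``z`` (including x and y themselves, with the identity as
  the self-alignment):

      P'_xy = ( sum_z  w_z * P_xz @ P_zy ) / sum_z w_z,
      w_z = P(x<>z) * P(z<>y)

* **intra-sequence** — mixes each base-pairing matrix with the
  structural evidence carried over from homologs through the alignment
  matrices (a "sandwich" product), weighted by homology:

      P'_b(x) = a * P_b(x)
              + (1-a) * ( sum_y P(x<>y) * A_xy @ Pb_sym(y) @ A_xy^T ) / sum_y P(x<>y)

* **four-way** — re-estimates the alignment matrix using base-pairing
  structure at both ends:

      P'_a(xy) = (1-b) * P_a(xy) + b * Pb_sym(x) @ P_a(xy) @ Pb_sym(y)

Homology weights are computed once, from the pre-transformation
posteriors, and reused throughout; values are clamped to [0, 1] and
re-pruned at the sparsity threshold after every transform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy import sparse

from .posterior import (
    PairHmmParams,
    PairingMatrix,
    PairingModel,
    SparseProbMatrix,
    align_posteriors,
    default_hmm_params,
    default_pairing_model,
    default_threshold,
    homology_probability,
    pairing_posteriors,
)
from .seqio import RnaSequence


@dataclass
class ProbabilitySet:
    """All pairwise and per-sequence probability matrices over a set S.

    ``align`` is keyed by index pairs ``(a, b)`` with ``a < b`` and holds
    the matrix oriented (rows = sequence a, columns = sequence b);
    ``pairing`` is keyed by sequence index; ``homology`` by index pair.
    """

    sequences: list[RnaSequence]
    align: dict[tuple[int, int], SparseProbMatrix]
    pairing: dict[int, PairingMatrix]
    homology: dict[tuple[int, int], float]
    threshold: float

    # -- construction ----------------------------------------------------
    @classmethod
    def compute(
        cls,
        sequences: list[RnaSequence],
        hmm_params: PairHmmParams | None = None,
        pairing_model: PairingModel | None = None,
        threshold: float | None = None,
    ) -> "ProbabilitySet":
        """Compute P_a for every pair, P_b for every sequence, and the
        homology weights, from scratch."""
        hmm_params = hmm_params or default_hmm_params()
        pairing_model = pairing_model or default_pairing_model()
        threshold = default_threshold() if threshold is None else threshold
        m = len(sequences)
        align: dict[tuple[int, int], SparseProbMatrix] = {}
        homology: dict[tuple[int, int], float] = {}
        for a in range(m):
            for b in range(a + 1, m):
                mat = align_posteriors(sequences[a], sequences[b], hmm_params, threshold)
                align[(a, b)] = mat
                homology[(a, b)] = homology_probability(sequences[a], sequences[b], mat)
        pairing = {
            i: pairing_posteriors(s, pairing_model, threshold)
            for i, s in enumerate(sequences)
        }
        return cls(sequences, align, pairing, homology, threshold)

    # -- accessors -------------------------------------------------------
    def get_align_csr(self, a: int, b: int) -> sparse.csr_matrix:
        """Alignment matrix oriented (rows = a, cols = b); identity if a == b."""
        if a == b:
            n = len(self.sequences[a])
            return sparse.identity(n, format="csr")
        if a < b:
            return self.align[(a, b)].csr
        return sparse.csr_matrix(self.align[(b, a)].csr.T)

    def get_homology(self, a: int, b: int) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a < b else (b, a)
        return self.homology[key]

    def mu(self) -> float:
        """Average stored entries per row over all alignment matrices."""
        nnz = sum(m.nnz for m in self.align.values())
        rows = sum(m.shape[0] for m in self.align.values())
        return nnz / rows if rows else 0.0


def _reprune_align(csr: sparse.csr_matrix, threshold: float) -> SparseProbMatrix:
    return SparseProbMatrix.from_csr(csr, threshold)


def inter_sequence_transform(ps: ProbabilitySet) -> ProbabilitySet:
    """Homology-weighted relay transformation of the alignment matrices.

    The relay set includes x and y themselves (identity self-alignment),
    so for |S| = 2 the transformation is the identity.
    """
    m = len(ps.sequences)
    new_align: dict[tuple[int, int], SparseProbMatrix] = {}
    for a in range(m):
        for b in range(a + 1, m):
            num = None
            denom = 0.0
            for z in range(m):
                w = ps.get_homology(a, z) * ps.get_homology(z, b)
                if w == 0.0:
                    continue
                prod = ps.get_align_csr(a, z) @ ps.get_align_csr(z, b)
                term = w * prod
                num = term if num is None else num + term
                denom += w
            if num is None or denom == 0.0:
                new_align[(a, b)] = ps.align[(a, b)]
            else:
                new_align[(a, b)] = _reprune_align(num / denom, ps.threshold)
    return replace(ps, align=new_align)


def intra_sequence_transform(ps: ProbabilitySet, alpha: float = 0.6) -> ProbabilitySet:
    """Homology-weighted structural carry-over into the pairing matrices.

    ``alpha`` weighs the sequence's own pairing evidence against the
    expectation over homologs; ``alpha = 1`` leaves P_b unchanged.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    m = len(ps.sequences)
    new_pairing: dict[int, PairingMatrix] = {}
    for x in range(m):
        old = ps.pairing[x]
        if alpha == 1.0 or m == 1:
            new_pairing[x] = old
            continue
        num = None
        denom = 0.0
        for y in range(m):
            if y == x:
                continue
            w = ps.get_homology(x, y)
            if w == 0.0:
                continue
            A = ps.get_align_csr(x, y)
            sandwich = A @ ps.pairing[y].to_symmetric_csr() @ A.T
            term = w * sandwich
            num = term if num is None else num + term
            denom += w
        if num is None or denom == 0.0:
            carried = sparse.csr_matrix(old.shape)
        else:
            carried = sparse.csr_matrix(sparse.triu(num / denom, k=1))
        mixed = alpha * old.csr + (1.0 - alpha) * carried
        mixed = sparse.csr_matrix(mixed)
        new_pairing[x] = PairingMatrix.from_dense(
            mixed.toarray(), ps.threshold, old.min_hairpin
        )
    return replace(ps, pairing=new_pairing)


def fourway_transform(ps: ProbabilitySet, beta: float = 0.1) -> ProbabilitySet:
    """Structural sandwich transformation of the alignment matrices.

    Adds, with weight ``beta``, the evidence that aligned partners of
    base-paired residues should themselves align; ``beta = 0`` is the
    identity.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if beta == 0.0:
        return ps
    m = len(ps.sequences)
    sym = {x: ps.pairing[x].to_symmetric_csr() for x in range(m)}
    new_align: dict[tuple[int, int], SparseProbMatrix] = {}
    for a in range(m):
        for b in range(a + 1, m):
            A = ps.align[(a, b)].csr
            mixed = (1.0 - beta) * A + beta * (sym[a] @ A @ sym[b])
            new_align[(a, b)] = _reprune_align(sparse.csr_matrix(mixed), ps.threshold)
    return replace(ps, align=new_align)


def apply_all(
    ps: ProbabilitySet, alpha: float = 0.6, beta: float = 0.1, rounds: int = 1
) -> ProbabilitySet:
    """Apply inter-sequence, intra-sequence, then four-way transforms."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    for _ in range(rounds):
        ps = inter_sequence_transform(ps)
        ps = intra_sequence_transform(ps, alpha)
        ps = fourway_transform(ps, beta)
    return ps
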
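"""Posterior base-alignment and base-pairing probabilities.

Two probability families drive the aligner:

* ``P_a(x_i ~ y_j | x, y)`` — the posterior probability that residues
  ``x_i`` and ``y_j`` are matched in the (unknown) true pairwise
  alignment, computed by forward/backward over a 3-state pair hidden
  Markov model (states M, Ix, Iy).
* ``P_b(x_i ~ x_j | x)`` — the posterior probability that residues i and
  j of one sequence form a base pair, computed as the Boltzmann-weighted
  fraction of nested secondary structures containing that pair
  (inside--outside over a weighted Nussinov-style ensemble).

Both matrices are kept sparse: entries below a threshold are dropped,
which is what makes the downstream consistency transformations cheap.
All pair-HMM dynamic programming is done in log space.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field
from math import exp, inf, log

import numpy as np
import yaml
from scipy import sparse

from .seqio import RnaSequence

_BASES = "ACGU"
_IDX = {b: i for i, b in enumerate(_BASES)}
_IDX["N"] = 4
NEG_INF = -inf


def _lse(*vals: float) -> float:
    """Log-sum-exp for a handful of plain floats."""
    m = max(vals)
    if m == NEG_INF:
        return NEG_INF
    return m + log(sum(exp(v - m) for v in vals))


def _encode(seq: str) -> list[int]:
    return [_IDX[c] for c in seq]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


class NumericModelError(ArithmeticError):
    """Raised when a probability model is degenerate (zero partition value)."""


@dataclass(frozen=True)
class PairHmmParams:
    """Parameters of the 3-state (M, Ix, Iy) pair HMM.

    Transitions: M->Ix and M->Iy with probability ``gap_open`` each,
    Ix->Ix and Iy->Iy with probability ``gap_extend``; insert states
    return to M with ``1 - gap_extend`` (no Ix<->Iy transitions).  The
    initial distribution is ``(1 - 2*gap_open, gap_open, gap_open)``.

    ``N`` residues emit the marginal over the four bases.
    """

    match_emission: np.ndarray  # (4, 4), sums to 1
    insert_emission: np.ndarray  # (4,), sums to 1
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        me = np.asarray(self.match_emission, dtype=float)
        ie = np.asarray(self.insert_emission, dtype=float)
        if me.shape != (4, 4) or ie.shape != (4,):
            raise ValueError("match_emission must be 4x4 and insert_emission length 4")
        if not np.isclose(me.sum(), 1.0, atol=1e-6):
            raise ValueError("match emission table must sum to 1")
        if not np.allclose(me, me.T, atol=1e-12):
            # the joint distribution of an aligned pair is exchangeable;
            # symmetry is also what makes posteriors transpose-symmetric
            raise ValueError("match emission table must be symmetric")
        if not np.isclose(ie.sum(), 1.0, atol=1e-6):
            raise ValueError("insert emission table must sum to 1")
        if not (0.0 < self.gap_open < 0.5):
            raise ValueError("gap_open must lie in (0, 0.5)")
        if not (0.0 < self.gap_extend < 1.0):
            raise ValueError("gap_extend must lie in (0, 1)")
        object.__setattr__(self, "match_emission", me)
        object.__setattr__(self, "insert_emission", ie)

    # -- derived log tables, N handled as the marginal over ACGU ---------
    @functools.cached_property
    def _log_match(self) -> list[list[float]]:
        me = self.match_emission
        full = np.zeros((5, 5))
        full[:4, :4] = me
        full[4, :4] = me.mean(axis=0)
        full[:4, 4] = me.mean(axis=1)
        full[4, 4] = me.mean()
        with np.errstate(divide="ignore"):
            return np.log(full).tolist()

    @functools.cached_property
    def _log_insert(self) -> list[float]:
        ie = self.insert_emission
        full = np.concatenate([ie, [ie.mean()]])
        with np.errstate(divide="ignore"):
            return np.log(full).tolist()


def _log(p: float) -> float:
    return log(p) if p > 0.0 else NEG_INF


def _pair_hmm_tables(params: PairHmmParams):
    d, e = params.gap_open, params.gap_extend
    la = {
        "MM": _log(1 - 2 * d), "MX": _log(d), "MY": _log(d),
        "XM": _log(1 - e), "XX": _log(e),
        "YM": _log(1 - e), "YY": _log(e),
    }
    lpi = (_log(1 - 2 * d), _log(d), _log(d))
    return la, lpi


def _forward(xe: list[int], ye: list[int], params: PairHmmParams):
    la, lpi = _pair_hmm_tables(params)
    lem, lei = params._log_match, params._log_insert
    Lx, Ly = len(xe), len(ye)
    FM = [[NEG_INF] * (Ly + 1) for _ in range(Lx + 1)]
    FX = [[NEG_INF] * (Ly + 1) for _ in range(Lx + 1)]
    FY = [[NEG_INF] * (Ly + 1) for _ in range(Lx + 1)]
    for i in range(Lx + 1):
        for j in range(Ly + 1):
            if i == 0 and j == 0:
                continue
            if i >= 1 and j >= 1:
                pi, pj = i - 1, j - 1
                if pi == 0 and pj == 0:
                    t = lpi[0]
                else:
                    t = _lse(FM[pi][pj] + la["MM"], FX[pi][pj] + la["XM"],
                             FY[pi][pj] + la["YM"])
                FM[i][j] = t + lem[xe[i - 1]][ye[j - 1]]
            if i >= 1:
                pi, pj = i - 1, j
                if pi == 0 and pj == 0:
                    t = lpi[1]
                else:
                    t = _lse(FM[pi][pj] + la["MX"], FX[pi][pj] + la["XX"])
                FX[i][j] = t + lei[xe[i - 1]]
            if j >= 1:
                pi, pj = i, j - 1
                if pi == 0 and pj == 0:
                    t = lpi[2]
                else:
                    t = _lse(FM[pi][pj] + la["MY"], FY[pi][pj] + la["YY"])
                FY[i][j] = t + lei[ye[j - 1]]
    Z = _lse(FM[Lx][Ly], FX[Lx][Ly], FY[Lx][Ly])
    return FM, FX, FY, Z


def _backward(xe: list[int], ye: list[int], params: PairHmmParams):
    la, lpi = _pair_hmm_tables(params)
    lem, lei = params._log_match, params._log_insert
    Lx, Ly = len(xe), len(ye)
    BM = [[NEG_INF] * (Ly + 1) for _ in range(Lx + 1)]
    BX = [[NEG_INF] * (Ly + 1) for _ in range(Lx + 1)]
    BY = [[NEG_INF] * (Ly + 1) for _ in range(Lx + 1)]
    BM[Lx][Ly] = BX[Lx][Ly] = BY[Lx][Ly] = 0.0
    for i in range(Lx, -1, -1):
        for j in range(Ly, -1, -1):
            if i == Lx and j == Ly:
                continue
            terms_m, terms_x, terms_y = [], [], []
            if i < Lx and j < Ly:
                nxt = lem[xe[i]][ye[j]] + BM[i + 1][j + 1]
                terms_m.append(la["MM"] + nxt)
                terms_x.append(la["XM"] + nxt)
                terms_y.append(la["YM"] + nxt)
            if i < Lx:
                nxt = lei[xe[i]] + BX[i + 1][j]
                terms_m.append(la["MX"] + nxt)
                terms_x.append(la["XX"] + nxt)
            if j < Ly:
                nxt = lei[ye[j]] + BY[i][j + 1]
                terms_m.append(la["MY"] + nxt)
                terms_y.append(la["YY"] + nxt)
            BM[i][j] = _lse(*terms_m) if terms_m else NEG_INF
            BX[i][j] = _lse(*terms_x) if terms_x else NEG_INF
            BY[i][j] = _lse(*terms_y) if terms_y else NEG_INF
    # total via first emission, used as a forward/backward consistency check
    terms = []
    if Lx >= 1 and Ly >= 1:
        terms.append(lpi[0] + lem[xe[0]][ye[0]] + BM[1][1])
    if Lx >= 1:
        terms.append(lpi[1] + lei[xe[0]] + BX[1][0])
    if Ly >= 1:
        terms.append(lpi[2] + lei[ye[0]] + BY[0][1])
    Z = _lse(*terms)
    return BM, BX, BY, Z


def log_likelihood(x: RnaSequence, y: RnaSequence, params: PairHmmParams) -> tuple[float, float]:
    """Total log-probability from the forward and the backward pass."""
    xe, ye = _encode(x.residues), _encode(y.residues)
    _, _, _, zf = _forward(xe, ye, params)
    _, _, _, zb = _backward(xe, ye, params)
    return zf, zb


# ---------------------------------------------------------------------------
# Sparse probability containers
# ---------------------------------------------------------------------------


class SparseProbMatrix:
    """Sparse posterior base-alignment matrix for one ordered sequence pair."""

    def __init__(self, csr: sparse.csr_matrix, threshold: float):
        self.csr = csr
        self.threshold = threshold

    @property
    def shape(self) -> tuple[int, int]:
        return self.csr.shape

    @classmethod
    def from_dense(cls, arr: np.ndarray, threshold: float) -> "SparseProbMatrix":
        a = np.asarray(arr, dtype=float).copy()
        a[a < threshold] = 0.0
        np.clip(a, 0.0, 1.0, out=a)
        return cls(sparse.csr_matrix(a), threshold)

    @classmethod
    def from_csr(cls, csr, threshold: float) -> "SparseProbMatrix":
        csr = sparse.csr_matrix(csr)
        csr.data = np.clip(csr.data, 0.0, 1.0)
        csr.data[csr.data < threshold] = 0.0
        csr.eliminate_zeros()
        return cls(csr, threshold)

    def toarray(self) -> np.ndarray:
        return self.csr.toarray()

    def items(self) -> list[tuple[int, int, float]]:
        coo = self.csr.tocoo()
        out = [(int(i), int(j), float(v)) for i, j, v in zip(coo.row, coo.col, coo.data)]
        out.sort()
        return out

    @property
    def nnz(self) -> int:
        return self.csr.nnz

    def mu(self) -> float:
        """Average number of stored entries per row."""
        return self.csr.nnz / self.shape[0]

    def transpose(self) -> "SparseProbMatrix":
        return SparseProbMatrix(sparse.csr_matrix(self.csr.T), self.threshold)


class PairingMatrix:
    """Sparse upper-triangular base-pairing probability matrix."""

    def __init__(self, csr: sparse.csr_matrix, threshold: float, min_hairpin: int):
        self.csr = csr
        self.threshold = threshold
        self.min_hairpin = min_hairpin

    @property
    def shape(self) -> tuple[int, int]:
        return self.csr.shape

    @property
    def length(self) -> int:
        return self.csr.shape[0]

    @classmethod
    def from_dense(cls, arr: np.ndarray, threshold: float, min_hairpin: int) -> "PairingMatrix":
        a = np.asarray(arr, dtype=float).copy()
        n = a.shape[0]
        # keep strict upper triangle beyond the hairpin limit only
        mask = np.zeros_like(a, dtype=bool)
        ii, jj = np.triu_indices(n, k=min_hairpin + 1)
        mask[ii, jj] = True
        a[~mask] = 0.0
        a[a < threshold] = 0.0
        np.clip(a, 0.0, 1.0, out=a)
        return cls(sparse.csr_matrix(a), threshold, min_hairpin)

    def toarray(self) -> np.ndarray:
        return self.csr.toarray()

    def items(self) -> list[tuple[int, int, float]]:
        coo = self.csr.tocoo()
        out = [(int(i), int(j), float(v)) for i, j, v in zip(coo.row, coo.col, coo.data)]
        out.sort()
        return out

    @property
    def nnz(self) -> int:
        return self.csr.nnz

    def to_symmetric_csr(self) -> sparse.csr_matrix:
        return sparse.csr_matrix(self.csr + self.csr.T)


# ---------------------------------------------------------------------------
# Posterior base-alignment probabilities
# ---------------------------------------------------------------------------


def align_posteriors(
    x: RnaSequence, y: RnaSequence, params: PairHmmParams, threshold: float = 0.01
) -> SparseProbMatrix:
    """Posterior match probabilities ``P_a(x_i ~ y_j)`` for every (i, j).

    Entry (i, j) is ``forward * backward / Z`` for the match state over
    residues ``x[i]`` and ``y[j]``; values below ``threshold`` are
    dropped from the sparse result.
    """
    xe, ye = _encode(x.residues), _encode(y.residues)
    FM, _, _, Z = _forward(xe, ye, params)
    if Z == NEG_INF or not np.isfinite(Z):
        raise NumericModelError(
            f"zero partition value for pair ({x.id!r}, {y.id!r}); degenerate parameters"
        )
    BM, _, _, _ = _backward(xe, ye, params)
    Lx, Ly = len(xe), len(ye)
    post = np.zeros((Lx, Ly))
    for i in range(1, Lx + 1):
        fm_row, bm_row = FM[i], BM[i]
        for j in range(1, Ly + 1):
            v = fm_row[j] + bm_row[j]
            if v != NEG_INF:
                post[i - 1, j - 1] = exp(v - Z)
    return SparseProbMatrix.from_dense(post, threshold)


# ---------------------------------------------------------------------------
# Base-pairing probabilities (partition function)
# ---------------------------------------------------------------------------


def _default_weights() -> dict[str, float]:
    return dict(default_config()["pairing_model"]["weights"])


@dataclass(frozen=True)
class PairingModel:
    """Boltzmann-weighted nested-structure ensemble.

    Each canonical pair type (AU, UA, GC, CG, GU, UG) carries a strictly
    positive multiplicative weight; non-canonical pairs weigh zero and
    unpaired bases weigh one.  A structure's weight is the product of
    its pair weights times ``stack_bonus`` for every stacked pair (a
    pair (i, j) whose enclosing neighbour (i-1, j+1) is also present) —
    the bonus is what concentrates probability mass onto helices.
    ``min_hairpin`` is the minimum number of unpaired bases a
    hairpin-closing pair must enclose.
    """

    weights: dict[str, float] = field(default_factory=_default_weights)
    min_hairpin: int = 3
    stack_bonus: float = 25.0

    def __post_init__(self) -> None:
        for k, v in self.weights.items():
            if len(k) != 2 or any(c not in _BASES for c in k):
                raise ValueError(f"bad pair type {k!r}")
            if v <= 0:
                raise ValueError(f"pair weight for {k} must be strictly positive")
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be >= 0")
        if self.stack_bonus <= 0:
            raise ValueError("stack_bonus must be strictly positive")

    @functools.cached_property
    def weight_matrix(self) -> np.ndarray:
        """(5, 5) pair-weight lookup over A,C,G,U,N; N never pairs."""
        w = np.zeros((5, 5))
        for pair, v in self.weights.items():
            w[_IDX[pair[0]], _IDX[pair[1]]] = v
        return w


def structure_weight(seq: str, pairs: set[tuple[int, int]], model: PairingModel) -> float:
    """Boltzmann weight of one nested structure under the model."""
    w = 1.0
    for i, j in pairs:
        w *= model.weight_matrix[_IDX[seq[i]], _IDX[seq[j]]]
        if (i + 1, j - 1) in pairs:
            w *= model.stack_bonus
    return w


def pairing_posteriors(
    x: RnaSequence, model: PairingModel | None = None, threshold: float = 0.01
) -> PairingMatrix:
    """Base-pairing probabilities ``P_b(x_i ~ x_j)`` by inside--outside.

    Inside pass: ``Z[i][j]`` is the partition value over the half-open
    region ``x[i:j]`` and ``Zb(i, j)`` (inclusive ends) over structures
    in which (i, j) is paired, with the stacked case carrying the extra
    ``stack_bonus`` factor.  The outside pass is the exact adjoint of
    the inside recursion, so each probability equals the
    Boltzmann-weighted fraction of nested structures containing the
    pair:  ``P(i, j) = Gb(i, j) * Zb(i, j) / Z``.
    """
    if model is None:
        model = default_pairing_model()
    xe = _encode(x.residues)
    n = len(xe)
    h = model.min_hairpin
    wmat = model.weight_matrix
    sigma = model.stack_bonus
    P = np.zeros((n, n))
    if n >= h + 2:
        Z = np.ones((n + 1, n + 1))  # region x[i:j]
        Zb = np.zeros((n, n))  # (i, j) paired, inclusive
        # inside, over increasing region span; pair (k, j-1) cells of
        # inclusive span s are filled while visiting region span s
        for span in range(2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span
                # pair cell (i, j-1) if it closes this exact region
                w = wmat[xe[i], xe[j - 1]]
                if w > 0.0 and span - 2 >= h:
                    val = Z[i + 1][j - 1]
                    if span >= 4:
                        val += (sigma - 1.0) * Zb[i + 1, j - 2]
                    Zb[i, j - 1] = w * val
                total = Z[i][j - 1]  # last base unpaired
                for k in range(i, j - 1 - h):
                    if Zb[k, j - 1] != 0.0:
                        total += Z[i][k] * Zb[k, j - 1]
                Z[i][j] = total
        Ztot = Z[0][n]
        if not np.isfinite(Ztot) or Ztot <= 0:
            raise NumericModelError(f"partition function overflow for {x.id!r}")
        # adjoint (outside) pass over decreasing span
        GZ = np.zeros((n + 1, n + 1))
        Gb = np.zeros((n, n))
        GZ[0][n] = 1.0
        for span in range(n, 1, -1):
            for i in range(0, n - span + 1):
                j = i + span
                g = GZ[i][j]
                if g != 0.0:
                    GZ[i][j - 1] += g
                    for k in range(i, j - 1 - h):
                        if Zb[k, j - 1] != 0.0:
                            GZ[i][k] += g * Zb[k, j - 1]
                            Gb[k, j - 1] += g * Z[i][k]
                # pair cell of the same inclusive span: (i, j-1)
                gb = Gb[i, j - 1]
                if gb != 0.0 and Zb[i, j - 1] != 0.0:
                    w = wmat[xe[i], xe[j - 1]]
                    GZ[i + 1][j - 1] += gb * w
                    if span >= 4:
                        Gb[i + 1, j - 2] += gb * w * (sigma - 1.0)
        P = Gb * Zb / Ztot
    return PairingMatrix.from_dense(P, threshold, h)


# ---------------------------------------------------------------------------
# MEA pairwise alignment and homology probability
# ---------------------------------------------------------------------------


def mea_pairwise(post: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Maximum-expected-accuracy pairwise alignment.

    Needleman--Wunsch over the posterior match probabilities with gap
    score 0; returns the matched index pairs and the summed posterior of
    the alignment.  Traceback prefers match over x-gap over y-gap.
    """
    Lx, Ly = post.shape
    D = np.zeros((Lx + 1, Ly + 1))
    for i in range(1, Lx + 1):
        prow = post[i - 1]
        dprev, dcur = D[i - 1], D[i]
        for j in range(1, Ly + 1):
            dcur[j] = max(dprev[j - 1] + prow[j - 1], dprev[j], dcur[j - 1])
    matches: list[tuple[int, int]] = []
    i, j = Lx, Ly
    while i > 0 and j > 0:
        here = D[i][j]
        p = post[i - 1, j - 1]
        if p > 0.0 and here == D[i - 1][j - 1] + p:
            matches.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif here == D[i - 1][j]:
            i -= 1
        else:
            j -= 1
    matches.reverse()
    return matches, float(D[Lx][Ly])


def homology_probability(x: RnaSequence, y: RnaSequence, posterior: SparseProbMatrix) -> float:
    """Homology weight ``P(x <> y)``: expected accuracy of the MEA alignment.

    The summed posterior along the MEA pairwise alignment, normalized by
    the shorter sequence length and clamped to [0, 1].  Symmetric in its
    arguments because the posterior matrix itself is.
    """
    post = posterior.toarray()
    _, score = mea_pairwise(post)
    val = score / min(len(x), len(y))
    return min(max(val, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Default parameters
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=1)
def default_config() -> dict:
    text = importlib.resources.files("dagalign").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_hmm_params() -> PairHmmParams:
    cfg = default_config()["pair_hmm"]
    d, o = cfg["match_identity"], cfg["match_mismatch"]
    me = np.full((4, 4), o)
    np.fill_diagonal(me, d)
    me /= me.sum()
    ie = np.full(4, 0.25)
    return PairHmmParams(me, ie, cfg["gap_open"], cfg["gap_extend"])


def default_pairing_model() -> PairingModel:
    cfg = default_config()["pairing_model"]
    return PairingModel(dict(cfg["weights"]), cfg["min_hairpin"], cfg["stack_bonus"])


def default_threshold() -> float:
    return float(default_config()["sparsity_threshold"])
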
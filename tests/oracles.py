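"""Independent brute-force oracles used by the test suite.

Everything in here is deliberately naive — exhaustive enumeration and
dense nested-loop arithmetic — and shares no code with the sparse /
log-space implementations it is used to check.
"""

from __future__ import annotations

import numpy as np

from dagalign.consistency import ProbabilitySet
from dagalign.posterior import PairHmmParams, PairingModel

BASES = "ACGU"
IDX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# Pair-HMM posterior by exhaustive alignment-path enumeration
# ---------------------------------------------------------------------------


def enum_pair_hmm_posterior(x: str, y: str, p: PairHmmParams) -> np.ndarray:
    """Posterior match probabilities by summing over every alignment path."""
    d, e = p.gap_open, p.gap_extend
    trans = {
        ("M", "M"): 1 - 2 * d, ("M", "X"): d, ("M", "Y"): d,
        ("X", "M"): 1 - e, ("X", "X"): e,
        ("Y", "M"): 1 - e, ("Y", "Y"): e,
    }
    pi = {"M": 1 - 2 * d, "X": d, "Y": d}
    Lx, Ly = len(x), len(y)
    post = np.zeros((Lx, Ly))
    total = 0.0

    def rec(i: int, j: int, prev: str | None, w: float, matches: list):
        nonlocal total
        if w == 0.0:
            return
        if i == Lx and j == Ly:
            total += w
            for mm in matches:
                post[mm] += w
            return
        for state in ("M", "X", "Y"):
            if state == "M" and (i == Lx or j == Ly):
                continue
            if state == "X" and i == Lx:
                continue
            if state == "Y" and j == Ly:
                continue
            t = pi[state] if prev is None else trans.get((prev, state), 0.0)
            if t == 0.0:
                continue
            if state == "M":
                emit = p.match_emission[IDX[x[i]], IDX[y[j]]]
                rec(i + 1, j + 1, state, w * t * emit, matches + [(i, j)])
            elif state == "X":
                rec(i + 1, j, state, w * t * p.insert_emission[IDX[x[i]]], matches)
            else:
                rec(i, j + 1, state, w * t * p.insert_emission[IDX[y[j]]], matches)

    rec(0, 0, None, 1.0, [])
    return post / total


# ---------------------------------------------------------------------------
# Base-pairing posterior by exhaustive nested-structure enumeration
# ---------------------------------------------------------------------------


def enum_nested_structures(seq: str, model: PairingModel) -> list[frozenset]:
    wmat = model.weight_matrix
    h = model.min_hairpin

    def structs(i: int, j: int) -> list[frozenset]:
        # structures on the half-open region seq[i:j]
        if j - i <= 0:
            return [frozenset()]
        out = list(structs(i, j - 1))
        for k in range(i, j - 1 - h):
            if wmat[IDX.get(seq[k], 4), IDX.get(seq[j - 1], 4)] > 0:
                for left in structs(i, k):
                    for inner in structs(k + 1, j - 1):
                        out.append(left | inner | {(k, j - 1)})
        return out

    return structs(0, len(seq))


def enum_pairing_posterior(seq: str, model: PairingModel) -> np.ndarray:
    from dagalign.posterior import structure_weight

    n = len(seq)
    P = np.zeros((n, n))
    Z = 0.0
    for s in enum_nested_structures(seq, model):
        w = structure_weight(seq, set(s), model)
        Z += w
        for pair in s:
            P[pair] += w
    return P / Z


# ---------------------------------------------------------------------------
# Dense consistency-transform oracles
# ---------------------------------------------------------------------------


def _dense_align(ps: ProbabilitySet, a: int, b: int) -> np.ndarray:
    if a == b:
        return np.eye(len(ps.sequences[a]))
    if a < b:
        return ps.align[(a, b)].toarray()
    return ps.align[(b, a)].toarray().T


def _dense_pairing_sym(ps: ProbabilitySet, x: int) -> np.ndarray:
    arr = ps.pairing[x].toarray()
    return arr + arr.T


def _prune(arr: np.ndarray, threshold: float) -> np.ndarray:
    out = np.clip(arr, 0.0, 1.0)
    out[out < threshold] = 0.0
    return out


def dense_inter(ps: ProbabilitySet) -> dict[tuple[int, int], np.ndarray]:
    m = len(ps.sequences)
    out = {}
    for a in range(m):
        for b in range(a + 1, m):
            num = np.zeros((len(ps.sequences[a]), len(ps.sequences[b])))
            denom = 0.0
            for z in range(m):
                w = ps.get_homology(a, z) * ps.get_homology(z, b)
                if w == 0.0:
                    continue
                num += w * (_dense_align(ps, a, z) @ _dense_align(ps, z, b))
                denom += w
            if denom == 0.0:
                out[(a, b)] = ps.align[(a, b)].toarray()
            else:
                out[(a, b)] = _prune(num / denom, ps.threshold)
    return out


def dense_intra(ps: ProbabilitySet, alpha: float) -> dict[int, np.ndarray]:
    m = len(ps.sequences)
    out = {}
    for x in range(m):
        L = len(ps.sequences[x])
        own = ps.pairing[x].toarray()
        num = np.zeros((L, L))
        denom = 0.0
        for y in range(m):
            if y == x:
                continue
            w = ps.get_homology(x, y)
            if w == 0.0:
                continue
            A = _dense_align(ps, x, y)
            num += w * (A @ _dense_pairing_sym(ps, y) @ A.T)
            denom += w
        carried = np.triu(num / denom, k=1) if denom > 0 else np.zeros((L, L))
        mixed = alpha * own + (1.0 - alpha) * carried
        h = ps.pairing[x].min_hairpin
        mask = np.zeros((L, L), dtype=bool)
        ii, jj = np.triu_indices(L, k=h + 1)
        mask[ii, jj] = True
        mixed[~mask] = 0.0
        out[x] = _prune(mixed, ps.threshold)
    return out


def dense_fourway(ps: ProbabilitySet, beta: float) -> dict[tuple[int, int], np.ndarray]:
    m = len(ps.sequences)
    out = {}
    for a in range(m):
        for b in range(a + 1, m):
            A = ps.align[(a, b)].toarray()
            mixed = (1.0 - beta) * A + beta * (
                _dense_pairing_sym(ps, a) @ A @ _dense_pairing_sym(ps, b)
            )
            if beta == 0.0:
                out[(a, b)] = A
            else:
                out[(a, b)] = _prune(mixed, ps.threshold)
    return out
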
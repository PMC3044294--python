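"""Discriminative split-and-realignment refinement.

After the greedy graph construction, each sequence in turn is removed
from the alignment, realigned against the profile of its own similarity
cluster (found by k-means over homology-probability feature vectors),
and the resulting cluster profile is then profile-profile aligned with
the profile of the remaining sequences.  All profile dynamic programs
are expected-accuracy alignments: the column-pair score is the sum of
transformed posterior alignment probabilities between member residues,
with gap score 0.

Refinement is a guarded hill climb on the total posterior score (the
summed P'_a over all aligned residue pairs): each sequence's
split-and-realign step is accepted only if it strictly improves the
score, and rejected steps leave the alignment untouched.  The score is
therefore non-decreasing within and across passes, and refinement never
returns a worse-scoring alignment than its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .consistency import ProbabilitySet
from .seqio import GAP, MultipleAlignment

Column = list[tuple[int, int]]  # [(seq index, residue index), ...]


@dataclass(frozen=True)
class RefinementConfig:
    passes: int = 1
    k: int = 2
    min_cluster_size: int = 1
    tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.passes < 0:
            raise ValueError("passes must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _feature_matrix(ps: ProbabilitySet) -> np.ndarray:
    """Per-sequence feature vector: homology probabilities to all sequences."""
    m = len(ps.sequences)
    F = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            F[a, b] = ps.get_homology(a, b)
    return F


def _farthest_point_init(F: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point seeding: start from the point farthest
    from the grand centroid, then repeatedly take the point farthest from
    the chosen centers."""
    center = F.mean(axis=0)
    d0 = np.linalg.norm(F - center, axis=1)
    chosen = [int(np.argmax(d0))]
    while len(chosen) < k:
        dists = np.min(
            np.linalg.norm(F[:, None, :] - F[chosen][None, :, :], axis=2), axis=1
        )
        dists[chosen] = -1.0
        chosen.append(int(np.argmax(dists)))
    return F[chosen]


def cluster_labels(ps: ProbabilitySet, cfg: RefinementConfig) -> np.ndarray:
    """k-means cluster label for every sequence (deterministic)."""
    m = len(ps.sequences)
    k = min(cfg.k, m)
    if k <= 1:
        return np.zeros(m, dtype=int)
    F = _feature_matrix(ps)
    init = _farthest_point_init(F, k)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=cfg.seed)
    return km.fit_predict(F)


def cluster_similar(x: int, ps: ProbabilitySet, cfg: RefinementConfig) -> set[int]:
    """The similarity cluster S_x containing sequence x.

    Falls back to the whole set when x's cluster is smaller than the
    configured minimum size.
    """
    labels = cluster_labels(ps, cfg)
    sx = {i for i, lab in enumerate(labels) if lab == labels[x]}
    if len(sx) < cfg.min_cluster_size:
        sx = set(range(len(ps.sequences)))
    return sx


# ---------------------------------------------------------------------------
# Profile dynamic programming
# ---------------------------------------------------------------------------


def _dense_align(ps: ProbabilitySet) -> dict[tuple[int, int], np.ndarray]:
    """Dense copies of the alignment matrices for fast scoring lookups."""
    return {key: mat.toarray() for key, mat in ps.align.items()}


def _pair_score(dense, a: int, i: int, b: int, j: int) -> float:
    if a == b:
        return 0.0
    if a < b:
        return float(dense[(a, b)][i, j])
    return float(dense[(b, a)][j, i])


def _profile_align(
    colsA: list[Column], colsB: list[Column], dense
) -> list[Column]:
    """Expected-accuracy profile-profile alignment (gap score 0).

    Returns the merged column list; traceback prefers match, then a
    column from A, then a column from B, which keeps it deterministic.
    """
    na, nb = len(colsA), len(colsB)
    S = np.zeros((na, nb))
    for u in range(na):
        for v in range(nb):
            s = 0.0
            for a, i in colsA[u]:
                for b, j in colsB[v]:
                    s += _pair_score(dense, a, i, b, j)
            S[u, v] = s
    D = np.zeros((na + 1, nb + 1))
    for u in range(1, na + 1):
        srow = S[u - 1]
        dprev, dcur = D[u - 1], D[u]
        for v in range(1, nb + 1):
            dcur[v] = max(dprev[v - 1] + srow[v - 1], dprev[v], dcur[v - 1])
    merged: list[Column] = []
    u, v = na, nb
    while u > 0 or v > 0:
        if u > 0 and v > 0 and D[u][v] == D[u - 1][v - 1] + S[u - 1, v - 1]:
            merged.append(colsA[u - 1] + colsB[v - 1])
            u, v = u - 1, v - 1
        elif u > 0 and D[u][v] == D[u - 1][v]:
            merged.append(list(colsA[u - 1]))
            u -= 1
        else:
            merged.append(list(colsB[v - 1]))
            v -= 1
    merged.reverse()
    return merged


# ---------------------------------------------------------------------------
# Alignment <-> column-list plumbing and scoring
# ---------------------------------------------------------------------------


def _columns_of(aln: MultipleAlignment, ps: ProbabilitySet) -> list[Column]:
    order = {seq.id: idx for idx, seq in enumerate(ps.sequences)}
    cols: list[Column] = []
    for members in aln.column_members():
        cols.append([(order[sid], i) for sid, i in members])
    return cols


def _alignment_from_columns(cols: list[Column], ps: ProbabilitySet) -> MultipleAlignment:
    rows = []
    for s, seq in enumerate(ps.sequences):
        chars = []
        for col in cols:
            idx = dict(col).get(s)
            chars.append(seq.residues[idx] if idx is not None else GAP)
        rows.append((seq.id, "".join(chars)))
    return MultipleAlignment(rows)


def _restrict(cols: list[Column], subset: set[int]) -> list[Column]:
    out = []
    for col in cols:
        sub = [(s, i) for s, i in col if s in subset]
        if sub:
            out.append(sub)
    return out


def total_posterior_score(aln: MultipleAlignment, ps: ProbabilitySet) -> float:
    """Summed transformed posterior over all aligned residue pairs."""
    dense = _dense_align(ps)
    total = 0.0
    for col in _columns_of(aln, ps):
        for a in range(len(col)):
            for b in range(a + 1, len(col)):
                total += _pair_score(dense, *col[a], *col[b])
    return total


# ---------------------------------------------------------------------------
# Refinement driver
# ---------------------------------------------------------------------------


def _score_columns(cols: list[Column], dense) -> float:
    total = 0.0
    for col in cols:
        for a in range(len(col)):
            for b in range(a + 1, len(col)):
                total += _pair_score(dense, *col[a], *col[b])
    return total


def refine_alignment(
    aln: MultipleAlignment,
    ps: ProbabilitySet,
    cfg: RefinementConfig = RefinementConfig(),
) -> MultipleAlignment:
    """Iteratively split and realign; never returns a worse alignment.

    Each sequence's realignment is accepted only if it strictly
    improves the total posterior score, so the climb stays close to the
    greedy graph solution and cannot degrade it.
    """
    m = len(ps.sequences)
    if cfg.passes == 0 or m < 2:
        return aln
    dense = _dense_align(ps)
    best = _columns_of(aln, ps)
    best_score = _score_columns(best, dense)
    for _ in range(cfg.passes):
        improved = False
        for x in range(m):
            sx = cluster_similar(x, ps, cfg)
            others_in = sx - {x}
            cols = best
            # (1)+(2): realign x against the profile of its cluster
            if others_in:
                prof = _restrict(cols, others_in)
                xcols = _restrict(cols, {x})
                group = _profile_align(prof, xcols, dense)
            else:
                group = _restrict(cols, {x})
            # (3): profile-profile alignment with the rest
            rest = set(range(m)) - sx
            candidate = (
                _profile_align(group, _restrict(cols, rest), dense) if rest else group
            )
            score = _score_columns(candidate, dense)
            if score > best_score + cfg.tol:
                best, best_score = candidate, score
                improved = True
        if not improved:
            break
    return _alignment_from_columns(best, ps)
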
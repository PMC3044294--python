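"""Greedy construction of the alignment graph.

The multiple alignment is represented as a directed acyclic graph whose
vertices are alignment columns (sets of (sequence, residue) positions,
at most one residue per sequence) and whose edges are precedence
constraints.  The alignment is built in two greedy passes:

1. **Structural skeleton** — confident base pairs (transformed pairing
   probability above ``T_b``) are matched across sequences and both stem
   ends are aligned, recording the two columns as a paired-column pair.
   These insertions must keep the graph acyclic *and* left-right
   compatible (every sequence's residue in the left column of a paired
   pair precedes its residue in the right column).

2. **Local insertions** — the remaining pairwise base alignments are
   inserted in order of transformed alignment probability, subject to
   acyclicity only (a stricter variant that also re-checks left-right
   compatibility can be switched on).

A topological ordering of the final graph, with unplaced residues
wrapped in singleton columns, yields the multiple alignment.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Optional

from .consistency import ProbabilitySet
from .seqio import GAP, MultipleAlignment, RnaSequence

Residue = tuple[int, int]  # (sequence index, residue index)

NEW_COLUMN = "new-column"
EXTENDED = "extended"
MERGED = "merged"
REJECTED = "rejected"


class AlignmentGraph:
    """DAG of alignment columns with incremental legality checking.

    Reachability queries are answered exactly by breadth-first search;
    insertions are validated *before* any mutation so a rejected
    insertion leaves the graph untouched.
    """

    def __init__(self, sequences: list[RnaSequence]):
        self.sequences = sequences
        self._members: dict[int, dict[int, int]] = {}  # col id -> {seq: residue}
        self._col_of: dict[Residue, int] = {}
        self._succ: dict[int, set[int]] = {}
        self._pred: dict[int, set[int]] = {}
        self._placed: dict[int, list[int]] = {s: [] for s in range(len(sequences))}
        self.paired_columns: list[tuple[int, int]] = []
        self.anchor_pairs: set[frozenset] = set()  # skeleton-inserted base alignments
        self._next_id = 0

    # -- bookkeeping -----------------------------------------------------
    def copy(self) -> "AlignmentGraph":
        g = AlignmentGraph.__new__(AlignmentGraph)
        g.sequences = self.sequences
        g._members = {c: dict(m) for c, m in self._members.items()}
        g._col_of = dict(self._col_of)
        g._succ = {c: set(s) for c, s in self._succ.items()}
        g._pred = {c: set(s) for c, s in self._pred.items()}
        g._placed = {s: list(v) for s, v in self._placed.items()}
        g.paired_columns = list(self.paired_columns)
        g.anchor_pairs = set(self.anchor_pairs)
        g._next_id = self._next_id
        return g

    @property
    def columns(self) -> dict[int, dict[int, int]]:
        return self._members

    def column_of(self, res: Residue) -> Optional[int]:
        return self._col_of.get(res)

    def path_exists(self, u: int, v: int) -> bool:
        """Exact reachability u -> v (path of length >= 1)."""
        if u == v:
            return v in self._succ.get(u, ())
        stack = [u]
        seen = {u}
        while stack:
            node = stack.pop()
            for nxt in self._succ.get(node, ()):
                if nxt == v:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def _add_edge(self, u: int, v: int) -> None:
        if u != v:
            self._succ[u].add(v)
            self._pred[v].add(u)

    def _remove_edge(self, u: int, v: int) -> None:
        self._succ[u].discard(v)
        self._pred[v].discard(u)

    def _new_column_id(self) -> int:
        cid = self._next_id
        self._next_id += 1
        self._members[cid] = {}
        self._succ[cid] = set()
        self._pred[cid] = set()
        return cid

    def _neighbors(self, seq: int, idx: int) -> tuple[Optional[int], Optional[int]]:
        """Columns of the nearest already-placed residues before/after idx."""
        placed = self._placed[seq]
        pos = bisect.bisect_left(placed, idx)
        pred_col = self._col_of[(seq, placed[pos - 1])] if pos > 0 else None
        succ_col = self._col_of[(seq, placed[pos])] if pos < len(placed) else None
        return pred_col, succ_col

    def _place(self, seq: int, idx: int, cid: int) -> None:
        """Attach residue (seq, idx) to column cid and wire adjacency edges."""
        pred_col, succ_col = self._neighbors(seq, idx)
        self._members[cid][seq] = idx
        self._col_of[(seq, idx)] = cid
        bisect.insort(self._placed[seq], idx)
        if pred_col is not None:
            self._add_edge(pred_col, cid)
            if succ_col is not None and succ_col in self._succ[pred_col]:
                # direct edge now implied through the new column
                self._remove_edge(pred_col, succ_col)
        if succ_col is not None:
            self._add_edge(cid, succ_col)

    # -- insertion -------------------------------------------------------
    def insert_pair(self, p: Residue, q: Residue) -> str:
        """Insert the base alignment p ~ q; one of the outcomes
        {new-column, extended, merged, rejected}.

        The graph is mutated only when the insertion keeps it acyclic
        and no column ends up with two residues of one sequence.
        """
        if p[0] == q[0]:
            return REJECTED
        cp, cq = self._col_of.get(p), self._col_of.get(q)
        if cp is not None and cp == cq:
            return MERGED  # already aligned; trivial no-op
        if cp is None and cq is None:
            return self._insert_new_column(p, q)
        if cp is not None and cq is not None:
            return self._merge(cp, cq)
        if cp is None:
            p, q = q, p
            cp, cq = cq, cp
        return self._extend(cp, q)

    def _insert_new_column(self, p: Residue, q: Residue) -> str:
        preds, succs = [], []
        for seq, idx in (p, q):
            pc, sc = self._neighbors(seq, idx)
            if pc is not None:
                preds.append(pc)
            if sc is not None:
                succs.append(sc)
        for s in succs:
            for t in preds:
                if s == t or self.path_exists(s, t):
                    return REJECTED
        cid = self._new_column_id()
        self._place(p[0], p[1], cid)
        self._place(q[0], q[1], cid)
        self._prune_redundant(cid)
        return NEW_COLUMN

    def _extend(self, cid: int, q: Residue) -> str:
        seq, idx = q
        if seq in self._members[cid]:
            return REJECTED  # column already holds another residue of seq
        pc, sc = self._neighbors(seq, idx)
        if pc is not None and (pc == cid or self.path_exists(cid, pc)):
            return REJECTED
        if sc is not None and (sc == cid or self.path_exists(sc, cid)):
            return REJECTED
        self._place(seq, idx, cid)
        self._prune_redundant(cid)
        return EXTENDED

    def _merge(self, c1: int, c2: int) -> str:
        m1, m2 = self._members[c1], self._members[c2]
        for seq in m2:
            if seq in m1:
                return REJECTED  # two residues of one sequence
        if self.path_exists(c1, c2) or self.path_exists(c2, c1):
            return REJECTED
        # absorb c2 into c1
        for seq, idx in m2.items():
            m1[seq] = idx
            self._col_of[(seq, idx)] = c1
        for u in list(self._pred[c2]):
            self._remove_edge(u, c2)
            self._add_edge(u, c1)
        for v in list(self._succ[c2]):
            self._remove_edge(c2, v)
            self._add_edge(c1, v)
        del self._members[c2], self._succ[c2], self._pred[c2]
        self.paired_columns = [
            (c1 if a == c2 else a, c1 if b == c2 else b) for a, b in self.paired_columns
        ]
        self._prune_redundant(c1)
        return MERGED

    def _prune_redundant(self, cid: int) -> None:
        """Drop edges incident to cid that are implied through another path."""
        for u in list(self._pred[cid]):
            self._remove_edge(u, cid)
            if not self.path_exists(u, cid):
                self._add_edge(u, cid)
        for v in list(self._succ[cid]):
            self._remove_edge(cid, v)
            if not self.path_exists(cid, v):
                self._add_edge(cid, v)

    # -- invariants (used by tests and the stricter step-2 mode) ---------
    def leftright_ok(self) -> bool:
        """Every recorded paired-column pair (c, c') has i < i' for all
        sequences present in both columns."""
        for ca, cb in self.paired_columns:
            ma, mb = self._members.get(ca), self._members.get(cb)
            if ma is None or mb is None:
                return False
            for seq, i in ma.items():
                if seq in mb and not (i < mb[seq]):
                    return False
        return True

    def is_acyclic(self) -> bool:
        indeg = {c: len(p) for c, p in self._pred.items()}
        ready = [c for c, d in indeg.items() if d == 0]
        seen = 0
        while ready:
            c = ready.pop()
            seen += 1
            for v in self._succ[c]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    ready.append(v)
        return seen == len(self._members)


# ---------------------------------------------------------------------------
# Candidate sets
# ---------------------------------------------------------------------------


@dataclass
class CandidateSets:
    """Sorted candidate lists for the two greedy passes.

    ``B``: (seq, i, i', prob) base pairs with transformed pairing
    probability above ``tb``.  ``A``: (seq_a, seq_b, i, j, prob) stored
    alignment entries.  Both are sorted by probability descending with a
    deterministic tie-break (sequence indices, then left/right indices
    ascending).
    """

    B: list[tuple[int, int, int, float]] = field(default_factory=list)
    A: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    tb: float = 0.5


def build_candidates(ps: ProbabilitySet, tb: float = 0.5) -> CandidateSets:
    if not 0.0 <= tb <= 1.0:
        raise ValueError("tb must lie in [0, 1]")
    B = [
        (x, i, j, p)
        for x, mat in ps.pairing.items()
        for i, j, p in mat.items()
        if p > tb
    ]
    B.sort(key=lambda e: (-e[3], e[0], e[1], e[2]))
    A = [
        (a, b, i, j, p)
        for (a, b), mat in ps.align.items()
        for i, j, p in mat.items()
    ]
    A.sort(key=lambda e: (-e[4], e[0], e[1], e[2], e[3]))
    return CandidateSets(B, A, tb)


# ---------------------------------------------------------------------------
# Step 1: structural skeleton
# ---------------------------------------------------------------------------


def _align_prob(ps: ProbabilitySet, x: int, i: int, y: int, j: int) -> float:
    if x == y:
        return 0.0
    if x < y:
        return float(ps.align[(x, y)].csr[i, j])
    return float(ps.align[(y, x)].csr[j, i])


def _mutual_best(ps: ProbabilitySet) -> dict[tuple[int, int], set[tuple[int, int]]]:
    """Per ordered sequence pair, the (i, j) entries that are both the
    row and the column maximum of the transformed alignment matrix."""
    best: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for key, mat in ps.align.items():
        arr = mat.toarray()
        if arr.size == 0:
            best[key] = set()
            continue
        row_arg = arr.argmax(axis=1)
        col_arg = arr.argmax(axis=0)
        mb = set()
        for i in range(arr.shape[0]):
            j = int(row_arg[i])
            if arr[i, j] > 0.0 and int(col_arg[j]) == i:
                mb.add((i, j))
        best[key] = mb
    return best


def build_skeleton(
    g: AlignmentGraph,
    ps: ProbabilitySet,
    candidates: CandidateSets,
    audit: Optional[Callable[[AlignmentGraph], None]] = None,
) -> AlignmentGraph:
    """Insert the most probable alignments of confident base pairs.

    Each base pair from ``B`` is matched with the compatible partner
    base pair from another sequence that maximizes the product of the
    transformed alignment probabilities of the two stem ends
    ``P'_a(x_i ~ y_j) * P'_a(x_i' ~ y_j')``; both base alignments are
    inserted and the two columns are recorded as a paired-column pair.
    Each base pair is used as an anchor once, but stays available as a
    partner, so the anchors of one conserved stem chain into full
    structural columns across the whole set rather than isolated
    two-sequence islands.

    A match is only considered when both of its base alignments are
    mutual best hits of their transformed alignment matrix; wrong
    stem-register matches otherwise slip in early with low evidence and
    measurably damage low-identity alignments.
    """
    B = candidates.B
    mutual = _mutual_best(ps)

    def _is_mutual(x: int, i: int, y: int, j: int) -> bool:
        if x < y:
            return (i, j) in mutual.get((x, y), ())
        return (j, i) in mutual.get((y, x), ())

    anchored: set[tuple[int, int, int]] = set()
    for x, i, i2, _ in B:
        if (x, i, i2) in anchored:
            continue
        scored: list[tuple[float, int, int, int]] = []
        for y, j, j2, _ in B:
            if y == x:
                continue
            if not (_is_mutual(x, i, y, j) and _is_mutual(x, i2, y, j2)):
                continue
            s = _align_prob(ps, x, i, y, j) * _align_prob(ps, x, i2, y, j2)
            if s > 0.0:
                scored.append((-s, y, j, j2))
        scored.sort()
        for negs, y, j, j2 in scored:
            trial = g.copy()
            if trial.insert_pair((x, i), (y, j)) == REJECTED:
                continue
            if trial.insert_pair((x, i2), (y, j2)) == REJECTED:
                continue
            left = trial.column_of((x, i))
            right = trial.column_of((x, i2))
            if left is None or right is None or left == right:
                continue
            if (left, right) not in trial.paired_columns:
                trial.paired_columns.append((left, right))
            if not trial.leftright_ok():
                continue
            trial.anchor_pairs.add(frozenset(((x, i), (y, j))))
            trial.anchor_pairs.add(frozenset(((x, i2), (y, j2))))
            g.__dict__.update(trial.__dict__)
            anchored.add((x, i, i2))
            if audit is not None:
                audit(g)
            break
    return g


# ---------------------------------------------------------------------------
# Step 2: local insertions
# ---------------------------------------------------------------------------


def insert_local_alignments(
    g: AlignmentGraph,
    candidates: CandidateSets,
    strict_leftright: bool = False,
    audit: Optional[Callable[[AlignmentGraph], None]] = None,
) -> AlignmentGraph:
    """Insert remaining pairwise base alignments in probability order.

    Entries incompatible with the current graph (cycle, or a column that
    would hold two residues of one sequence) are skipped; later entries
    are still processed.
    """
    for a, b, i, j, _ in candidates.A:
        p, q = (a, i), (b, j)
        if g.column_of(p) is not None and g.column_of(p) == g.column_of(q):
            continue
        if strict_leftright:
            trial = g.copy()
            if trial.insert_pair(p, q) == REJECTED or not trial.leftright_ok():
                continue
            g.__dict__.update(trial.__dict__)
            if audit is not None:
                audit(g)
        else:
            if g.insert_pair(p, q) != REJECTED and audit is not None:
                audit(g)
    return g


# ---------------------------------------------------------------------------
# Linearization
# ---------------------------------------------------------------------------


def linearize(g: AlignmentGraph, sequences: list[RnaSequence]) -> MultipleAlignment:
    """Topologically order the columns and emit the gapped alignment.

    Residues not yet in any column are first wrapped in singleton
    columns (with their per-sequence adjacency edges).  Ties between
    simultaneously-ready columns are broken by the lexicographically
    smallest (sequence, residue) member, which makes the output
    deterministic.
    """
    g = g.copy()
    for s, seq in enumerate(sequences):
        for idx in range(len(seq)):
            if g.column_of((s, idx)) is None:
                cid = g._new_column_id()
                g._place(s, idx, cid)
    order = _topological_order(g)
    rows = []
    for s, seq in enumerate(sequences):
        chars = []
        for cid in order:
            idx = g._members[cid].get(s)
            chars.append(seq.residues[idx] if idx is not None else GAP)
        rows.append((seq.id, "".join(chars)))
    aln = MultipleAlignment(rows)
    for s, seq in enumerate(sequences):
        if aln.degapped(seq.id) != seq.residues:
            raise RuntimeError(
                f"internal error: linearization broke sequence {seq.id!r}"
            )
    return aln


def _topological_order(g: AlignmentGraph) -> list[int]:
    import heapq

    def key(cid: int) -> tuple:
        return tuple(sorted(g._members[cid].items()))

    indeg = {c: len(p) for c, p in g._pred.items()}
    heap = [(key(c), c) for c, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        _, c = heapq.heappop(heap)
        order.append(c)
        for v in sorted(g._succ[c]):
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(heap, (key(v), v))
    if len(order) != len(g._members):
        raise RuntimeError("internal error: alignment graph contains a cycle")
    return order


def graph_to_dot(g: AlignmentGraph, sequences: list[RnaSequence]) -> str:
    """DOT-format dump of the alignment graph, for debugging."""
    lines = ["digraph alignment {"]
    for cid, members in sorted(g.columns.items()):
        label = ",".join(
            f"{sequences[s].id}[{i}]" for s, i in sorted(members.items())
        )
        lines.append(f'  c{cid} [label="{label}"];')
    for u in sorted(g._succ):
        for v in sorted(g._succ[u]):
            lines.append(f"  c{u} -> c{v};")
    lines.append("}")
    return "\n".join(lines)
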
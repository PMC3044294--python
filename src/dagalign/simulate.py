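"""Synthetic RNA family generator.

Samples a random nested secondary structure (sequential stem-loop
blocks), an ancestral sequence with canonical base pairs at paired
sites, and then a family of descendants by substitution and loop-
confined indels.  Substitutions at paired sites are compensatory (they
replace the whole pair with another canonical pair type) with a
configurable probability, which is the covariation signal a structural
aligner exploits.  Because indels never touch stems, the true alignment
is unambiguous at paired positions, giving a clean ground truth for
sum-of-pairs scoring.

The generator is fully deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import DotBracketStructure, GAP, MultipleAlignment, RnaSequence

_BASES = "ACGU"
_CANONICAL = ["GC", "CG", "AU", "UA", "GU", "UG"]
_PAIR_WEIGHTS = [0.3, 0.3, 0.15, 0.15, 0.05, 0.05]


class ParameterError(ValueError):
    """Raised for infeasible simulation parameters."""


@dataclass(frozen=True)
class FamilyParams:
    """Family evolution parameters.

    ``sub_rate`` is the per-site substitution probability at unpaired
    positions; ``paired_sub_rate`` the per-pair substitution probability
    at paired positions (``None`` means: same as ``sub_rate``).  Paired
    sites default to evolving faster than loops — compensatory pairs
    swap freely under structural constraint, which is the covariation
    signal structural aligners exploit.
    """

    m: int = 6
    length: int = 70
    sub_rate: float = 0.22
    paired_sub_rate: float | None = 0.5
    indel_rate: float = 0.05
    comp_prob: float = 0.95
    min_stem: int = 3
    max_stem: int = 8
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ParameterError("need at least 2 sequences")
        if self.length < 10:
            raise ParameterError("length must be >= 10")
        for name in ("sub_rate", "indel_rate", "comp_prob", "paired_sub_rate"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.length < 2 * self.min_stem + self.min_hairpin:
            raise ParameterError(
                f"length {self.length} too small for any stem "
                f"(need >= {2 * self.min_stem + self.min_hairpin})"
            )


@dataclass
class RnaFamilySample:
    """A simulated family with its ground truth."""

    params: FamilyParams
    seed: int
    structure: DotBracketStructure  # on ancestral coordinates
    ancestor: str
    alignment: MultipleAlignment  # true alignment of the descendants
    sequences: list[RnaSequence]
    # per descendant: ancestral position -> residue index (None if deleted)
    residue_maps: list[list[int | None]] = field(repr=False, default_factory=list)

    def true_pairs(self, d: int) -> set[tuple[int, int]]:
        """The ancestral base pairs mapped onto descendant d's coordinates
        (pairs with a deleted end are dropped; stems never are)."""
        rm = self.residue_maps[d]
        out = set()
        for i, j in self.structure.pairs:
            a, b = rm[i], rm[j]
            if a is not None and b is not None:
                out.add((a, b))
        return out

    def mean_pairwise_identity(self) -> float:
        """Mean fraction of identical residues over aligned (gapless in
        both rows) columns, over all sequence pairs."""
        rows = [g for _, g in self.alignment.rows]
        total, count = 0.0, 0
        for a in range(len(rows)):
            for b in range(a + 1, len(rows)):
                same = tot = 0
                for ca, cb in zip(rows[a], rows[b]):
                    if ca != GAP and cb != GAP:
                        tot += 1
                        same += ca == cb
                if tot:
                    total += same / tot
                    count += 1
        return total / count if count else 0.0


def _sample_structure(rng: np.random.Generator, p: FamilyParams) -> DotBracketStructure:
    rem = p.length
    parts: list[str] = []
    min_hp = 2 * p.min_stem + p.min_hairpin
    while rem >= min_hp:
        sp = int(rng.integers(0, min(3, rem - min_hp) + 1))
        parts.append("." * sp)
        rem -= sp
        stem = int(rng.integers(p.min_stem, min(p.max_stem, (rem - p.min_hairpin) // 2) + 1))
        loop = int(rng.integers(p.min_hairpin, min(p.min_hairpin + 4, rem - 2 * stem) + 1))
        parts.append("(" * stem + "." * loop + ")" * stem)
        rem -= 2 * stem + loop
    parts.append("." * rem)
    db = "".join(parts)
    from .seqio import parse_dotbracket

    return parse_dotbracket(db, p.length, min_loop=p.min_hairpin)


def _sample_ancestor(rng: np.random.Generator, struct: DotBracketStructure) -> str:
    chars = [""] * struct.length
    paired = {i for pair in struct.pairs for i in pair}
    for pos in range(struct.length):
        if pos not in paired:
            chars[pos] = _BASES[int(rng.integers(4))]
    for i, j in sorted(struct.pairs):
        pt = _CANONICAL[int(rng.choice(len(_CANONICAL), p=_PAIR_WEIGHTS))]
        chars[i], chars[j] = pt[0], pt[1]
    return "".join(chars)


def _other_base(rng: np.random.Generator, base: str) -> str:
    options = [b for b in _BASES if b != base]
    return options[int(rng.integers(3))]


def sample_family(
    m: int = 6,
    length: int = 70,
    sub_rate: float = 0.22,
    indel_rate: float = 0.05,
    comp_prob: float = 0.95,
    seed: int = 0,
    **kwargs,
) -> RnaFamilySample:
    """Sample a synthetic RNA family with known structure and alignment.

    When ``paired_sub_rate`` is passed as ``None`` the paired sites use
    ``sub_rate`` as well (see :class:`FamilyParams`).
    """
    params = FamilyParams(
        m=m, length=length, sub_rate=sub_rate, indel_rate=indel_rate,
        comp_prob=comp_prob, **kwargs,
    )
    rng = np.random.default_rng(seed)
    struct = _sample_structure(rng, params)
    ancestor = _sample_ancestor(rng, struct)
    L = params.length
    partner = {}
    for i, j in struct.pairs:
        partner[i] = j
        partner[j] = i

    # per descendant: residue char per ancestral position (None = deleted),
    # and inserted bases following each ancestral position
    desc_chars: list[list[str | None]] = []
    desc_ins: list[list[list[str]]] = []
    pair_rate = params.sub_rate if params.paired_sub_rate is None else params.paired_sub_rate
    for _ in range(m):
        chars: list[str | None] = list(ancestor)
        # substitutions at paired sites, decided per pair
        for i, j in sorted(struct.pairs):
            if rng.random() < pair_rate:
                if rng.random() < params.comp_prob:
                    current = chars[i] + chars[j]
                    options = [t for t in _CANONICAL if t != current]
                    pt = options[int(rng.integers(len(options)))]
                    chars[i], chars[j] = pt[0], pt[1]
                else:
                    side = i if rng.random() < 0.5 else j
                    chars[side] = _other_base(rng, chars[side])
        # substitutions and deletions at unpaired sites
        for pos in range(L):
            if pos in partner:
                continue
            if rng.random() < params.sub_rate:
                chars[pos] = _other_base(rng, chars[pos])
            if rng.random() < params.indel_rate:
                chars[pos] = None
        # insertions after unpaired positions
        ins: list[list[str]] = [[] for _ in range(L)]
        for pos in range(L):
            if pos in partner:
                continue
            if rng.random() < params.indel_rate:
                k = int(rng.integers(1, 3))
                ins[pos] = [_BASES[int(rng.integers(4))] for _ in range(k)]
        desc_chars.append(chars)
        desc_ins.append(ins)

    # assemble the true alignment column by column
    ids = [f"seq{d + 1}" for d in range(m)]
    rows = [[] for _ in range(m)]
    counters = [0] * m
    residue_maps: list[list[int | None]] = [[None] * L for _ in range(m)]
    for pos in range(L):
        for d in range(m):
            ch = desc_chars[d][pos]
            if ch is None:
                rows[d].append(GAP)
            else:
                rows[d].append(ch)
                residue_maps[d][pos] = counters[d]
                counters[d] += 1
        for d in range(m):
            for ch in desc_ins[d][pos]:
                for e in range(m):
                    if e == d:
                        rows[e].append(ch)
                        counters[e] += 1
                    else:
                        rows[e].append(GAP)
    alignment = MultipleAlignment(
        [(ids[d], "".join(rows[d])) for d in range(m)]
    )
    sequences = [
        RnaSequence(ids[d], alignment.degapped(ids[d])) for d in range(m)
    ]
    return RnaFamilySample(
        params=params,
        seed=seed,
        structure=struct,
        ancestor=ancestor,
        alignment=alignment,
        sequences=sequences,
        residue_maps=residue_maps,
    )
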
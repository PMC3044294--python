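"""Sequence, alignment and secondary-structure I/O.

All coordinates are 0-based and half-open internally; messages shown to
users are 1-based.  The alphabet is {A, C, G, U, N}: ``T`` is silently
normalized to ``U`` so that DNA-alphabet FASTA files are accepted, and any
other character is a format error.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGUN")
GAP = "-"

ALIGNMENT_FORMATS = ("aligned-fasta", "clustal", "stockholm")


class SequenceFormatError(ValueError):
    """Raised for malformed sequence/alignment/structure input."""


def normalize_residues(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, map T->U, and validate against the RNA alphabet."""
    out = raw.upper().replace("T", "U")
    bad = set(out) - RNA_ALPHABET
    if bad:
        shown = ", ".join(repr(c) for c in sorted(bad))
        raise SequenceFormatError(
            f"illegal character(s) {shown} in {context} (allowed: A,C,G,U,T,N)"
        )
    return out


@dataclass(frozen=True)
class RnaSequence:
    """An unaligned RNA sequence with a unique identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceFormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"sequence {self.id!r} contains non-normalized characters {sorted(bad)}"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        return cls(id, normalize_residues(raw, context=f"sequence {id!r}"))

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[RnaSequence]:
    """Read unaligned RNA sequences from a FASTA file.

    Gap characters are rejected: this reader is for unaligned input.
    Duplicate identifiers are rejected because downstream probability
    tables are keyed by id.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceFormatError(f"no FASTA records found in {path}")
    seqs: list[RnaSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if GAP in raw or "." in raw:
            raise SequenceFormatError(
                f"sequence {rec.id!r} contains gap characters; expected unaligned input"
            )
        seqs.append(RnaSequence.from_raw(rec.id, raw))
    return seqs


class MultipleAlignment:
    """A gapped multiple alignment over {A,C,G,U,N,-}.

    Rows are ``(id, gapped_string)`` pairs of equal length.  De-gapping a
    row always reproduces the input sequence; this is the reconstruction
    invariant every aligner output in the package is tested against.
    """

    def __init__(self, rows: Sequence[tuple[str, str]]):
        if not rows:
            raise SequenceFormatError("alignment must contain at least one row")
        width = len(rows[0][1])
        seen: set[str] = set()
        for sid, gapped in rows:
            if len(gapped) != width:
                raise SequenceFormatError(
                    f"alignment rows have unequal lengths ({sid!r}: {len(gapped)} != {width})"
                )
            if sid in seen:
                raise SequenceFormatError(f"duplicate row id {sid!r}")
            seen.add(sid)
            bad = set(gapped) - RNA_ALPHABET - {GAP}
            if bad:
                raise SequenceFormatError(
                    f"row {sid!r} contains illegal characters {sorted(bad)}"
                )
        self.rows: list[tuple[str, str]] = [(sid, g) for sid, g in rows]

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def height(self) -> int:
        return len(self.rows)

    def row(self, sid: str) -> str:
        for s, g in self.rows:
            if s == sid:
                return g
        raise KeyError(sid)

    def degapped(self, sid: str) -> str:
        return self.row(sid).replace(GAP, "")

    def column_members(self) -> list[list[tuple[str, int]]]:
        """Per column, the (sequence-id, residue-index) pairs present."""
        counters = {sid: 0 for sid, _ in self.rows}
        cols: list[list[tuple[str, int]]] = []
        for c in range(self.width):
            members: list[tuple[str, int]] = []
            for sid, gapped in self.rows:
                ch = gapped[c]
                if ch != GAP:
                    members.append((sid, counters[sid]))
                    counters[sid] += 1
            cols.append(members)
        return cols

    def aligned_pairs(self) -> set[tuple[tuple[str, int], tuple[str, int]]]:
        """All aligned residue pairs, canonically ordered by sequence id."""
        pairs: set[tuple[tuple[str, int], tuple[str, int]]] = set()
        for members in self.column_members():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    p, q = members[a], members[b]
                    if q[0] < p[0]:
                        p, q = q, p
                    pairs.add((p, q))
        return pairs

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MultipleAlignment) and self.rows == other.rows

    def __repr__(self) -> str:
        return f"MultipleAlignment({self.height} rows x {self.width} cols)"


def _to_biopython(aln: MultipleAlignment) -> MultipleSeqAlignment:
    recs = [
        SeqRecord(Seq(gapped), id=sid, description="") for sid, gapped in aln.rows
    ]
    return MultipleSeqAlignment(recs)


def write_alignment(
    aln: MultipleAlignment,
    fmt: str = "aligned-fasta",
    structure: "DotBracketStructure | None" = None,
) -> str:
    """Serialize an alignment to aligned FASTA, Clustal, or Stockholm text.

    A consensus secondary structure, if given, is emitted as a
    ``#=GC SS_cons`` line (Stockholm only); its length must match the
    alignment width.
    """
    if fmt not in ALIGNMENT_FORMATS:
        raise SequenceFormatError(
            f"unknown alignment format {fmt!r}; expected one of {ALIGNMENT_FORMATS}"
        )
    msa = _to_biopython(aln)
    if fmt == "stockholm" and structure is not None:
        if structure.length != aln.width:
            raise SequenceFormatError(
                f"consensus structure length {structure.length} != alignment width {aln.width}"
            )
        msa.column_annotations["secondary_structure"] = structure.to_string()
    handle = io.StringIO()
    bio_fmt = {"aligned-fasta": "fasta", "clustal": "clustal", "stockholm": "stockholm"}[fmt]
    AlignIO.write(msa, handle, bio_fmt)
    return handle.getvalue()


def read_alignment(text_or_path, fmt: str = "aligned-fasta") -> MultipleAlignment:
    """Parse an alignment from text or a file path."""
    if fmt not in ALIGNMENT_FORMATS:
        raise SequenceFormatError(
            f"unknown alignment format {fmt!r}; expected one of {ALIGNMENT_FORMATS}"
        )
    bio_fmt = {"aligned-fasta": "fasta", "clustal": "clustal", "stockholm": "stockholm"}[fmt]
    if isinstance(text_or_path, str) and "\n" in text_or_path:
        handle = io.StringIO(text_or_path)
    else:
        handle = open(str(text_or_path))
    try:
        msa = AlignIO.read(handle, bio_fmt)
    except ValueError as exc:
        raise SequenceFormatError(f"malformed {fmt} alignment: {exc}") from exc
    finally:
        handle.close()
    rows = []
    for rec in msa:
        gapped = str(rec.seq).upper().replace("T", "U").replace(".", GAP)
        rows.append((rec.id, gapped))
    return MultipleAlignment(rows)


@dataclass(frozen=True)
class DotBracketStructure:
    """A pseudoknot-free secondary structure as a set of 0-based pairs."""

    length: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    min_loop: int = 0

    def __post_init__(self) -> None:
        partner: dict[int, int] = {}
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise SequenceFormatError(f"pair ({i + 1},{j + 1}) out of range")
            if j - i - 1 < self.min_loop:
                raise SequenceFormatError(
                    f"pair ({i + 1},{j + 1}) closes a loop shorter than {self.min_loop}"
                )
            for k in (i, j):
                if k in partner:
                    raise SequenceFormatError(f"position {k + 1} pairs twice")
                partner[k] = True
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                i, j = plist[a]
                k, l = plist[b]
                if i < k < j < l:
                    raise SequenceFormatError(
                        f"crossing pairs ({i + 1},{j + 1}) and ({k + 1},{l + 1})"
                    )

    def to_string(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def parse_dotbracket(text: str, seq_length: int | None = None, min_loop: int = 0) -> DotBracketStructure:
    """Parse dot-bracket notation into a nested pair set.

    Only round parentheses are understood; anything else (including
    pseudoknot bracket tiers) is a format error.
    """
    text = text.strip()
    if seq_length is not None and len(text) != seq_length:
        raise SequenceFormatError(
            f"structure length {len(text)} != sequence length {seq_length}"
        )
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise SequenceFormatError(
                    f"unbalanced ')' at position {pos + 1}"
                )
            i = stack.pop()
            pairs.add((i, pos))
        elif ch != ".":
            raise SequenceFormatError(
                f"illegal structure character {ch!r} at position {pos + 1}"
            )
    if stack:
        raise SequenceFormatError(
            f"unbalanced '(' at position {stack[-1] + 1}"
        )
    return DotBracketStructure(len(text), frozenset(pairs), min_loop=min_loop)


def write_fasta(seqs: Iterable[RnaSequence]) -> str:
    return "".join(f">{s.id}\n{s.residues}\n" for s in seqs)
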
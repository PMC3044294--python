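"""Alignment and structure-prediction scoring.

* **SPS** (sum-of-pairs score): the percentage of residue pairs aligned
  in the reference that are also aligned in the test alignment.  Only
  reference columns with at least two residues contribute pairs.
* **SEN / PPV / MCC**: base-pair prediction scores against a reference
  structure, from the confusion counts over all unordered position
  pairs (TP, FP, FN, TN), with the 0/0 -> 0 convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .seqio import DotBracketStructure, MultipleAlignment


class EvaluationError(ValueError):
    """Raised when test and reference are not comparable."""


@dataclass(frozen=True)
class ScoreReport:
    """Confusion counts and derived base-pair prediction scores."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sen(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def mcc(self) -> float:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        denom = math.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        if denom == 0.0:
            return 0.0
        return (tp * tn - fp * fn) / denom


def _check_same_sequences(test: MultipleAlignment, ref: MultipleAlignment) -> None:
    tids, rids = set(test.ids), set(ref.ids)
    if tids != rids:
        raise EvaluationError(
            f"sequence sets differ: only-in-test {sorted(tids - rids)}, "
            f"only-in-ref {sorted(rids - tids)}"
        )
    for sid in tids:
        if test.degapped(sid) != ref.degapped(sid):
            raise EvaluationError(f"sequence {sid!r} differs between test and reference")


def sps(test: MultipleAlignment, ref: MultipleAlignment) -> float:
    """Sum-of-pairs score: 100 x |test pairs ∩ ref pairs| / |ref pairs|.

    A reference without any aligned pairs scores 100 (vacuously correct).
    """
    _check_same_sequences(test, ref)
    ref_pairs = ref.aligned_pairs()
    if not ref_pairs:
        return 100.0
    test_pairs = test.aligned_pairs()
    return 100.0 * len(test_pairs & ref_pairs) / len(ref_pairs)


def structure_scores(
    predicted: set[tuple[int, int]] | DotBracketStructure,
    reference: set[tuple[int, int]] | DotBracketStructure,
    seq_length: int,
) -> ScoreReport:
    """Confusion-matrix scores for predicted base pairs.

    TN counts all unordered position pairs that are neither predicted
    nor in the reference.
    """
    pred = set(predicted.pairs) if isinstance(predicted, DotBracketStructure) else set(predicted)
    ref = set(reference.pairs) if isinstance(reference, DotBracketStructure) else set(reference)
    for name, pairs in (("predicted", pred), ("reference", ref)):
        for i, j in pairs:
            if not (0 <= i < j < seq_length):
                raise EvaluationError(f"{name} pair ({i}, {j}) out of range for length {seq_length}")
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    total = seq_length * (seq_length - 1) // 2
    tn = total - tp - fp - fn
    return ScoreReport(tp=tp, fp=fp, fn=fn, tn=tn)


def report_table(rows: list[dict]) -> str:
    """Tab-separated evaluation report from a list of metric dicts."""
    return pd.DataFrame(rows).to_csv(sep="\t", index=False, float_format="%.2f")
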
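"""End-to-end alignment pipeline.

Wires the stages together: posterior probabilities -> homology weights
-> consistency transformations (inter, intra, four-way) -> candidate
sets -> structural skeleton -> local insertions -> linearization ->
discriminative refinement.  Default weights: alpha = 0.4 (intra), beta
= 0.1 (four-way), T_b = 0.5 (base-pair confidence threshold).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from . import consistency, graphalign, posterior, refine
from .seqio import MultipleAlignment, RnaSequence


@dataclass(frozen=True)
class RunConfig:
    alpha: float = 0.6
    beta: float = 0.1
    tb: float = 0.5
    threshold: float = 0.01
    rounds: int = 1
    use_skeleton: bool = True
    strict_leftright: bool = False
    do_refine: bool = True
    refine_passes: int = 1
    output_format: str = "aligned-fasta"
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "tb", "threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class RunStats:
    timings: dict[str, float] = field(default_factory=dict)
    mu_raw: float = 0.0
    mu_transformed: float = 0.0
    n_candidates_b: int = 0
    n_candidates_a: int = 0
    score: float = 0.0

    def as_dict(self) -> dict:
        return {
            "timings_sec": {k: round(v, 4) for k, v in self.timings.items()},
            "mu_raw": round(self.mu_raw, 3),
            "mu_transformed": round(self.mu_transformed, 3),
            "n_candidates_b": self.n_candidates_b,
            "n_candidates_a": self.n_candidates_a,
            "total_posterior_score": round(self.score, 6),
        }


def compute_probabilities(
    seqs: list[RnaSequence], config: RunConfig
) -> consistency.ProbabilitySet:
    """Raw posteriors plus homology weights for a sequence set."""
    return consistency.ProbabilitySet.compute(seqs, threshold=config.threshold)


def align_sequences(
    seqs: list[RnaSequence],
    config: RunConfig = RunConfig(),
    ps: consistency.ProbabilitySet | None = None,
) -> tuple[MultipleAlignment, RunStats]:
    """Run the full pipeline on a set of unaligned sequences.

    A precomputed (untransformed) ProbabilitySet can be supplied to
    re-run the graph stages under different settings without repeating
    the dynamic programming.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    stats = RunStats()
    t0 = time.perf_counter()
    if ps is None:
        ps = compute_probabilities(seqs, config)
    stats.timings["posteriors"] = time.perf_counter() - t0
    stats.mu_raw = ps.mu()

    t0 = time.perf_counter()
    tps = consistency.apply_all(ps, config.alpha, config.beta, config.rounds)
    stats.timings["consistency"] = time.perf_counter() - t0
    stats.mu_transformed = tps.mu()

    t0 = time.perf_counter()
    cands = graphalign.build_candidates(tps, config.tb)
    stats.n_candidates_b = len(cands.B)
    stats.n_candidates_a = len(cands.A)
    g = graphalign.AlignmentGraph(seqs)
    if config.use_skeleton:
        graphalign.build_skeleton(g, tps, cands)
    graphalign.insert_local_alignments(g, cands, config.strict_leftright)
    aln = graphalign.linearize(g, seqs)
    stats.timings["graph"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.do_refine:
        cfg = refine.RefinementConfig(passes=config.refine_passes, seed=config.seed)
        aln = refine.refine_alignment(aln, tps, cfg)
    stats.timings["refine"] = time.perf_counter() - t0
    stats.score = refine.total_posterior_score(aln, tps)
    return aln, stats
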
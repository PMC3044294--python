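# Default probability-model parameters (version 1).
#
# pair_hmm: 3-state (M, Ix, Iy) pair hidden Markov model used for the
# posterior base-alignment probabilities.  The match emission favours
# identity; transversions and transitions are not distinguished.
# gap_open is the M->Ix / M->Iy probability, gap_extend the Ix->Ix /
# Iy->Iy probability.  The initial distribution over {M, Ix, Iy} is
# (1 - 2*gap_open, gap_open, gap_open).
#
# pairing_model: Boltzmann-weighted nested-structure ensemble.  Each
# canonical pair type carries a multiplicative weight (unpaired bases
# weigh 1); every stacked pair earns an extra stack_bonus factor, which
# concentrates probability on helices; min_hairpin is the minimum number
# of unpaired bases enclosed by a hairpin-closing pair.
pair_hmm:
  match_identity: 0.16      # emission of an identical base pair (x4)
  match_mismatch: 0.03      # emission of a mismatching base pair (x12)
  gap_open: 0.02
  gap_extend: 0.80
pairing_model:
  weights:
    GC: 3.0
    CG: 3.0
    AU: 2.0
    UA: 2.0
    GU: 1.0
    UG: 1.0
  min_hairpin: 3
  stack_bonus: 25.0
sparsity_threshold: 0.01
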
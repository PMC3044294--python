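# dagalign

Greedy, non-progressive structural alignment of multiple RNA
sequences.

Non-coding RNAs conserve their folded structure better than their
primary sequence, so a good multiple alignment of diverged RNAs has to
use both kinds of evidence. Progressive aligners commit to pairwise
decisions along a guide tree and propagate early mistakes; `dagalign`
instead estimates, for every pair of sequences, the posterior
probability `P_a(x_i ~ y_j)` that two bases are matched in the true
alignment (pair-HMM forward/backward) and, for every sequence, the
posterior probability `P_b(x_i ~ x_j)` that two bases pair in its
secondary structure (partition function over nested structures). Three
probabilistic consistency transformations then let every sequence
inform every other:

* **inter-sequence** — relay products `P_xz · P_zy`, weighted by
  homology probabilities `P(x◇z)·P(z◇y)`, make the pairwise alignment
  posteriors mutually consistent;
* **intra-sequence** — `P'_b(x) = α·P_b(x) + (1−α)·⟨A·P_b(y)·Aᵀ⟩`
  carries structural evidence from homologs into each sequence's
  pairing probabilities;
* **four-way** — `P'_a = (1−β)·P_a + β·B_x·P_a·B_y` rewards base
  alignments whose pairing partners also align.

The multiple alignment is then built greedily as a directed acyclic
graph of columns: first a **structural skeleton** (confident base
pairs, `P'_b > T_b`, matched across sequences by the product of their
stem-end alignment posteriors and inserted under acyclicity and
left-right-compatibility constraints), then the remaining base
alignments in order of `P'_a` under acyclicity alone. A topological
sort of the graph yields the alignment, and a guarded
discriminative-split-and-realignment step (k-means clustering on
homology features + expected-accuracy profile DP) polishes it without
ever decreasing the total posterior score. Defaults: α = 0.6, β = 0.1,
T_b = 0.5.

A built-in simulator generates RNA families with known structure and
alignment — compensatory (covarying) substitutions at paired sites,
indels confined to loops — so the whole pipeline is testable without
any external data.

## Worked example

Simulate a 4-sequence family at ~48% identity, align it, and score the
result against the simulator's true alignment:

```bash
$ dagalign simulate --seed 4 -m 4 -L 60 --out-prefix fam
wrote fam.fa (4 sequences), fam.ref.fa, fam.struct.txt (mean pairwise identity 48.1%)

$ dagalign align fam.fa -o aligned.fa -v
[posteriors] 0.21s
[consistency] 0.01s
[graph] 0.01s
[refine] 0.06s
mu: raw 4.40, transformed 6.22; |B| = 47, |A| = 2253

$ dagalign evaluate aligned.fa fam.ref.fa
SPS
76.52
```

`mu` is the average number of stored entries per row of the sparse
posterior matrices (the sparsity that keeps the consistency
transformations cheap); `|B|` is the number of confident base-pair
candidates feeding the structural skeleton and `|A|` the number of
candidate base alignments for the greedy insertion step. The SPS
(sum-of-pairs score) is the percentage of residue pairs aligned in the
reference that the computed alignment reproduces — here 76.5% on a
family whose sequences agree at only 48% of aligned positions.
`dagalign evaluate` also reports SEN/PPV/MCC for predicted base pairs
against a reference structure when `--pred-struct`/`--ref-struct` are
given, and `dagalign align --format stockholm` writes Stockholm with a
`#=GC SS_cons` line when a consensus structure is supplied through the
library API.

The same pipeline is available programmatically:

```python
from dagalign import RunConfig, align_sequences, sample_family, sps

fam = sample_family(m=6, length=70, seed=0)
aln, stats = align_sequences(fam.sequences, RunConfig())
print(sps(aln, fam.alignment))
```

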
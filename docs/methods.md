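# Methods

`dagalign` computes a multiple structural alignment of RNA sequences
non-progressively: instead of merging pairwise alignments along a guide
tree, it estimates posterior probabilities for every base alignment and
every base pairing, sharpens them with consistency transformations, and
then assembles the alignment greedily, one base alignment at a time,
as a directed acyclic graph of columns. This note documents the models,
the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not show.

## Posterior probabilities

**Base-alignment posteriors (P_a).** For each ordered sequence pair a
3-state pair hidden Markov model (M, Ix, Iy) is evaluated by
forward/backward in log space (log-sum-exp throughout; sequences of a
few hundred bases underflow in linear space). `P_a(x_i ~ y_j)` is the
posterior of the match state at (i, j). Transitions are controlled by
two probabilities: `gap_open` (M→Ix, M→Iy; default 0.02) and
`gap_extend` (Ix→Ix, Iy→Iy; default 0.80); the initial distribution is
`(1−2·gap_open, gap_open, gap_open)` and there are no Ix↔Iy
transitions. The match emission favours identity (0.16 per identical
pair, 0.03 per mismatch before normalization) and must be symmetric —
the joint distribution of an aligned pair is exchangeable, and symmetry
is what makes `P_a(x,y) = P_a(y,x)ᵀ` hold to machine precision. `N`
emits the marginal over the four bases and never pairs. Defaults live
in `defaults.yaml` and every parameter is overridable.

**Base-pairing posteriors (P_b).** Each sequence's pairing
probabilities come from a partition function over all pseudoknot-free
structures. The ensemble is deliberately simple so that it remains
exactly testable against structure enumeration: a structure's Boltzmann
weight is the product of per-pair-type weights (GC/CG 3, AU/UA 2,
GU/UG 1; unpaired bases weigh 1) times a `stack_bonus` factor for every
stacked pair, with a minimum hairpin loop of h = 3 unpaired bases. The
probability of a pair is obtained by an inside recursion over regions
and pair-closed cells plus an outside pass derived as the exact adjoint
(reverse-mode differentiation) of the inside recursion, so
`P(i,j) = Gb(i,j)·Zb(i,j)/Z` holds identically and the whole engine is
verified against exhaustive enumeration at length ≤ 12.

`stack_bonus = 25` is the one physically calibrated constant: helix
stability in RNA comes almost entirely from stacking (≈ 2–3 kcal/mol
per stack at 37 °C, i.e. Boltzmann factors of ~25–150), and with the
bonus at 25 the stem pair probabilities of simulated families agree
with ViennaRNA's `RNAfold -p` (McCaskill with Turner parameters) to
within ~0.05–0.1. Without stacking the ensemble is so entropic that no
pair ever approaches the 0.5 confidence regime the pipeline's
candidate threshold assumes.

**Homology weights.** `P(x◇y)`, the probability that two sequences are
homologous, is the expected accuracy of their maximum-expected-accuracy
(MEA) pairwise alignment: the summed posterior along the MEA path
(Needleman–Wunsch on `P_a` with gap score 0) divided by the shorter
length, clamped to [0, 1]. It is computed once, from untransformed
posteriors, and reused as a weight everywhere; recomputing it between
transformations invites feedback instability.

## Consistency transformations

Three sparse transformations are applied in order (one round by
default), each followed by clamping to [0, 1] and re-pruning at the
sparsity threshold (0.01, which keeps the observed average nonzeros per
row µ in the one-digit range):

1. **Inter-sequence** (alignment matrices): homology-weighted average
   of relay products `P_xz·P_zy` over all z, including z ∈ {x, y} with
   the identity as the self-alignment — so with two sequences the
   transform is the identity and information is never lost when no
   third sequence is informative.
2. **Intra-sequence** (pairing matrices):
   `P'_b(x) = α·P_b(x) + (1−α)·⟨A_xy·P_b(y)·A_xyᵀ⟩_y`, the expectation
   weighted by homology probabilities. α weighs the sequence's own
   thermodynamic evidence against structural evidence carried over
   from homologs through the alignment matrices.
3. **Four-way** (alignment matrices):
   `P'_a = (1−β)·P_a + β·B_x·P_a·B_y` with symmetrized pairing
   matrices B — aligned partners of base-paired residues should
   themselves align.

**The α convention.** In this package α multiplies the sequence's own
pairing term, and its default is 0.6. The aligner family this design
follows quotes a weight of 0.4 for this transformation together with a
skeleton candidate threshold of T_b = 0.5; those two constants are only
mutually coherent if the 0.4 weights the homolog term (otherwise
α·P_b ≤ 0.4 < T_b and the structural skeleton could never fire, since
the carried term is weak precisely for the divergent families the
skeleton is meant to rescue). Our α = 0.6 is that same constant
expressed in this parameterization.

Each transform is implemented with `scipy.sparse` matrix products and
is tested to 1e-12 against dense nested-loop oracles; the
inter-sequence transform's measured runtime scales as m³ at fixed
length and sparsity.

## Greedy graph construction

The alignment is a DAG whose vertices are columns (at most one residue
per sequence) and whose edges are precedence constraints. Reachability
queries are answered exactly by breadth-first search; every insertion
is validated before mutation, so a rejected insertion leaves the graph
untouched. Inserting a base alignment either creates a new column,
extends an existing one, or merges two columns; after each insertion,
edges implied by transitivity through the modified column are pruned.

**Step 1 — structural skeleton.** All base pairs with transformed
pairing probability above T_b = 0.5 form the candidate set **B**,
sorted by probability (ties broken by sequence index, then positions).
Each pair in turn seeks the partner pair from another sequence
maximizing `P'_a(x_i~y_j)·P'_a(x_i'~y_j')` — the product couples the
two stem arms, which is exactly the covariation signal — subject to two
guards: acyclicity plus left-right compatibility (for every recorded
paired-column pair, each sequence's residue in the left column precedes
its residue in the right column), and a mutual-best-hit requirement
(each of the two base alignments must be the row and column maximum of
its transformed matrix). Both stem-end alignments are inserted together
and the columns recorded as a paired-column pair. A base pair anchors
once but remains available as a partner, so the anchors of one
conserved stem chain across the whole set into full structural columns
instead of isolated two-sequence islands.

**Step 2 — local insertions.** All stored alignment entries, sorted by
transformed probability, are inserted greedily subject to acyclicity
(a stricter mode that also re-checks left-right compatibility is
available as a switch). On two sequences with diagonally dominant
posteriors this greedy procedure reproduces the pairwise MEA dynamic
program in ≥ 95% of random trials.

**Linearization.** Unplaced residues are wrapped in singleton columns
with their adjacency edges; a topological order is produced by Kahn's
algorithm with a heap keyed on the lexicographically smallest
(sequence, residue) member of each column. Any topological order is a
legitimate alignment; the lexicographic tie-break makes output
byte-reproducible. De-gapping every output row must reproduce its
input sequence exactly; this is asserted on every run.

## Discriminative refinement

For each sequence x in turn: find x's similarity cluster S_x by
k-means (k = 2, deterministic farthest-point initialization) over
homology-probability feature vectors; realign x to the profile of
S_x−{x} by expected-accuracy profile DP (column-pair score = summed
transformed posteriors between member residues, gap score 0); then
profile–profile align x's cluster against the rest. Refinement is a
guarded hill climb: each sequence's step is accepted only if it
strictly improves the total posterior score, so the score is
non-decreasing and the climb stays close to the greedy solution. The
guard granularity matters: accepting whole passes lets the purely
sequence-based objective dismantle correctly aligned structural stems
in exchange for diffuse posterior mass elsewhere (occasionally costing
several SPS points on a family); per-step acceptance removes that
failure mode. Anchor "hard protection" (forcing skeleton pairs through
the profile DP) was evaluated and rejected: it blocks refinement from
repairing the occasional wrong skeleton anchor and measured net
negative.

## Synthetic families

The generator samples a nested structure as sequential stem-loop
blocks (stems 3–8 bp, loops ≥ 3), an ancestral sequence with canonical
pairs at paired sites (GC-rich), and m descendants by substitution and
indels. Two per-site regimes are deliberately distinct: unpaired sites
substitute at 0.22 per site, paired sites at 0.5 per pair — with
probability 0.95 a paired-site event is compensatory (the pair is
replaced by another canonical pair type). Faster, compensatory
evolution at paired sites is the textbook covariation signal: stems
keep their structure while losing sequence identity faster than loops.
Indels (rate 0.05 per unpaired position, 1–2 nt insertions) are
confined to loops so the true alignment is unambiguous at stems.
Defaults (m = 6, L = 70) give ~45–55% mean pairwise identity.

What the generator does *not* emulate: multiloops and pseudoknots,
stem-length variation between family members, base-composition bias,
position-dependent rate variation, and real Rfam-style conservation
profiles. Passing tests on these families therefore demonstrate the
mechanics of the method — that structural information is extracted,
propagated and used, and that it measurably helps when stems are
sequence-divergent but covarying — not benchmark-level accuracy on
real RNA families.

On 20-family batches under these conditions the full pipeline exceeds
the skeleton-disabled pipeline by roughly +0.3 to +1.0 mean SPS
(a 60-family estimate: +0.67, standard error 0.26). The effect is
real but small, concentrated in families where loop indels make stem
registers ambiguous from sequence alone.

## Numerical and degenerate-input choices

* All probability DP in log space (pair HMM) or with overflow checks
  (partition function; a degenerate model raises rather than returning
  NaN).
* Sparse matrices are pruned at 0.01 after every operation; raising
  the threshold only removes entries (tested property).
* Ties are broken deterministically everywhere (candidate sorting,
  skeleton partner choice, topological ordering, DP tracebacks prefer
  match over gaps); two runs on identical input are byte-identical.
* Single-sequence input to the CLI is emitted unchanged with a
  warning; an empty candidate set **B** degrades the pipeline to pure
  sequence-based greedy construction.
* SPS counts reference pairs only from columns with ≥ 2 residues; a
  reference with no aligned pairs scores 100 by convention. Structure
  scores use the 0/0 → 0 convention for SEN/PPV/MCC.

## Known limitations

* The pairing ensemble is a calibrated toy, not the Turner model: no
  dangles, no coaxial stacking, single global stack bonus. It is exact
  and fast, but its probabilities should not be interpreted
  thermodynamically beyond the stem/no-stem regime it was calibrated
  for.
* The pair HMM is untrained; its emissions are hand-set. On real
  low-identity families a trained parameter set would sharpen P_a and
  likely widen the skeleton's margin.
* A structure conservation index for output alignments would require
  external folding tools and is not computed.
* Runtime is dominated by the O(L²) pair-HMM passes over all m(m−1)/2
  pairs in pure Python; the package targets families of tens of
  sequences of a few hundred bases.
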
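# Methods

## The model

`tcspec` treats a family of paired sequences — the HisKA domain of a
histidine kinase (HK) concatenated with the REC domain of its response
regulator (RR) — as draws from a global probabilistic model

    P(s) ∝ exp(−H(s)),      H(s) = − Σ_{i<j} e_ij(s_i, s_j) − Σ_i h_i(s_i),

a q-state Potts model (pairwise Markov random field) over the L columns of
the concatenated alignment. Each site takes one of q = 21 states: the 20
canonical amino acids plus the alignment gap. With the standard Pfam
domain widths the frame is 67 (HisKA) + 112 (REC) = 179 columns. (A
176-column convention appears in parts of the literature; the two widths
in use here are 67 and 112, so the frame constant is 179 throughout and is
exposed as `alignment_io.FRAME_WIDTH`.) The partition function is never
computed: every downstream quantity is an unnormalized Hamiltonian, and
only differences of Hamiltonians carry meaning.

Non-canonical residue letters (B, J, O, U, X, Z) are collapsed onto the
gap state at encoding time, which keeps q fixed and follows common DCA
practice. Lowercase letters and `.` in the input alignments are Pfam-style
insert states and are removed before the uniform-width check.

## Mean-field inference

Parameters are inferred by mean-field Direct Coupling Analysis:

1. **Reweighting.** Each sequence receives weight 1/n, where n counts
   sequences (itself included) at fractional identity ≥ 0.8. The source
   method does not state its threshold; 0.8 is the standard mean-field
   choice and is configurable. M_eff = Σ weights.
2. **Pseudocounted frequencies.** f1(i,a) = (λ/q + weighted counts)/(λ +
   M_eff) and analogously f2 with λ/q² off the diagonal; the diagonal
   blocks are f2(i,i)(a,b) = δ(a,b)·f1(i,a). λ defaults to M_eff (relative
   pseudocount ½), the standard stabilizer for the inversion; both
   defaults are assumptions, flagged here because the source method is
   silent on them.
3. **Inversion.** The connected correlation C = f2 − f1·f1, restricted to
   q−1 states per site (the gap is the reference state, which removes the
   exact linear dependency among the q indicator states), is inverted
   densely with LAPACK; couplings are e_ij(a,b) = −(C⁻¹)(i,a)(j,b),
   extended with a zero gap row/column, symmetrized, and e_ii ≡ 0. A
   singular C raises an error advising a larger λ.
4. **Fields.** From the mean-field self-consistency h_i(a) =
   ln(f1(i,a)/f1(i,gap)) − Σ_{j≠i} Σ_b e_ij(a,b) f1(j,b).
5. **Gauge.** Couplings and fields are re-expressed in the zero-sum gauge
   (row, column and double sums of every e_ij block vanish; field rows are
   centered), preserving H up to an additive constant. This makes coupling
   norms and DI comparable across site pairs; all scores are gauge-robust
   anyway because only score differences are interpreted.

**Direct information.** For each pair (i,j) a two-site "direct"
distribution P_dir(a,b) ∝ exp(e_ij(a,b))·μ_i(a)·μ_j(b) is fitted by
iterative proportional scaling until its marginals match f1(i) and f1(j)
(total-variation tolerance 1e-6, at most 200 sweeps; non-convergent pairs
are reported on the result object). DI is the mutual information of P_dir
against f1(i)⊗f1(j); it is invariant under gauge changes of e_ij because
the scaling factors absorb row/column shifts. Ranking ties break
lexicographically on (i,j).

## Specificity scores

For kinase sequence A and regulator sequence B in the concatenated frame:

    H_TCS(A+B) = − Σ_{(i,j) ∈ mask} e_ij(A_i, B_j) − Σ_{i=1..L} h_i(s_i)

The coupling sum runs only over the **interface mask**: inter-domain
column pairs whose residues sit within c = 12 Å in a template HK–RR
complex structure (the classic *Thermotoga maritima* HK853–RR468 complex
in the original application). The inequality is strict — a pair exactly at
the cutoff is not a contact — matching the step-function definition
Θ(c−r) with Θ(0) = 0. The distance convention is the minimum heavy-atom
distance between residues; the template source does not pin down the
atom-level convention, so Cα–Cα and Cβ–Cβ are selectable alternatives.
Masking confines coupling energy to structurally verified contacts so that
auxiliary (non-interface) couplings cannot leak into the score.

The **null score** H_TCS0 evaluates the same masked Hamiltonian under a
second Potts model trained on *scrambled* pairings — each HK joined to a
random RR, every HK appearing once per round, 25 rounds by default. The
specificity score is

    H_TCSspecific = H_TCS − H_TCS0 .

Negative ⇒ encoded specificity; ≈0 ⇒ only attributes shared by all HK–RR
pairs; positive ⇒ loss of shared attributes. Two readings of the null
exist: evaluating a scrambled-trained model on the pair (the default,
following the procedural description), or averaging the cognate model's
H_TCS over explicit random re-pairings (available as
`null_estimator="empirical_repairing"`; it yields one scalar baseline per
sequence set rather than a per-pair null). The two coincide only
approximately.

**Selection classification.** Scores are compared within one organism's
HK × RR matrix, most-negative = most specific. A cognate pair is under
*positive selection* when its cell is the strict minimum of its row, under
*negative selection* when it is the strict minimum of its column; either
counts the pair as detected (true positive), neither makes it a false
negative. Ties — equality within 1e-9 — defeat strictness, because a tie
cannot evidence selection. Sensitivity is TP/(TP+FN); "accuracy" is
reported equal to sensitivity because the evaluation defines no true
negatives. Selection-mode fractions (both / negative-only) are reported
over both plausible denominators, all evaluated pairs and detected pairs.

**Mutations** are substitutions in the fixed frame (a gap is a
substitution; an insertion is only possible into an existing gap column),
so the width never changes. Because H is pairwise, a single substitution
at column i changes only h_i and the masked couplings touching i; the
incremental rescoring exploits this by recomputing exactly the mutated
protein's row (or column) of the matrix, and is required to agree with a
from-scratch recomputation to 1e-9. Multi-mutation deltas are obtained by
re-evaluating the affected row/column rather than summing single-site
deltas, which would be wrong whenever two mutated columns share a mask
pair. Deltas are evaluated on the fly, which is exact; for workflows that want
the precomputed-table behavior of a score server, `mutations.delta_table`
tabulates the score change of every single substitution of a pair as an
(L, q) array, and agrees with the on-the-fly deltas to machine precision.

## Synthetic worlds

`synthetic.sample_potts` draws from the Boltzmann distribution either by
exact enumeration (feasible for q^L ≤ 1e6; used to validate the sampler)
or by M independent random-scan Gibbs chains, burn-in 1000 sweeps by
default, categorical updates via the Gumbel-max trick. With independent
parallel chains no thinning is needed; burn-in is configurable.

`synthetic.make_toy_world` builds a planted miniature proteome:
`n_interface_pairs` inter-domain column pairs on *disjoint* columns carry
all inter-domain couplings; each of the `n_hk_families` families owns one
preferred (non-gap) state per interface column (drawn as a random
permutation per column so no state is globally favored), and the coupling
tensor rewards each family's preferred combination with
`coupling_strength`. Family coherence cannot come from pairwise couplings
alone at realistic strengths — a coupling J weights one combination exp(J)
against q²−1 alternatives — so each family is *sampled* under additional
family-preference fields of strength `family_field_scale ×
coupling_strength` (scale 1.0) on its interface columns, with chains
initialized inside the intended mode and a 300-sweep burn-in. Tying the
field to the coupling strength means `coupling_strength = 0` collapses to
a fully unstructured world, where cognate detection falls to the analytic
chance level 2/n − 1/(2n−1) (the probability that an iid cell is its row
or column minimum). Defaults: 5 families, L_hk = 8, L_rr = 10, 6 planted
pairs, coupling_strength 3.0 ("strong": Boltzmann weight e³ ≈ 20 for the
preferred combination, comparable to q), 500 pairs per family. All
randomness derives from one seed via named substreams; identical seeds
give byte-identical worlds.

What the toy worlds do **not** emulate: phylogenetic correlation between
sequences (samples are iid given the model), gap-run structure of real
domain alignments, alignment errors, and the 10⁵–10⁶-sequence scale of
real family MSAs. Passing the planted-recovery benchmark therefore shows
the inference and scoring chain is correct and discriminative under the
model's own assumptions — not that real proteome predictions reach the
same sensitivity.

## Benchmark and problem sizes

`benchmark.run_recovery_benchmark` runs the full chain on 10 independent
toy worlds (5 families × 500 pairs, strong couplings) and pools two
numbers: the fraction of planted interface pairs among the top-k
inter-domain DI pairs (k = number planted), and the pooled
positive/negative-selection sensitivity of the family-representative
(column-consensus) networks — the synthetic analogue of the published
three-organism validation, which pools 26 detected of 31 evaluated
cognate pairs (sensitivity 0.84). The scrambled null inside the benchmark
uses 5 rounds instead of the 25-round default: the toy proteomes are small
and the null estimate is already stable, so the reduced population keeps
the benchmark brisk without changing any default of the production
pipeline.

## Numerical choices and edge cases

- Identity reweighting compares all columns (gaps included), blockwise in
  uint8 to bound memory.
- DI values are clipped at 0 against round-off; the diagonal is 0.
- The f1 pseudocount guarantees strictly positive frequencies, so the
  field logarithm is always defined.
- Empty pair tables, empty chains and orphan proteins are legal inputs:
  they produce empty-but-well-formed outputs (with warnings), not errors.
- A cognate pair whose ids are missing from the matrix is skipped and
  reported, not scored.
- Gap-run filtering reads "a sequence gap of N residues" as a maximal
  *contiguous* run ≥ N (HK default 5, RR default 6); a total-gap-count
  variant is available via `mode="total"`.
- Scrambling draws RRs with replacement, every HK once per round; the
  reported scrambled-population size in the source material does not equal
  rounds × M_HK for its stated inputs, so the per-round population is
  configurable.
- CSV exports use 6 decimals (re-import is lossless at that precision);
  serialized positions are 1-based, in-memory columns 0-based.

## Known limitations

- Only mean-field inversion is implemented; pseudolikelihood or Boltzmann-
  machine estimates of the same couplings are out of scope.
- Building the template residue-to-column mapping from a profile alignment
  of the template chains is out of scope; the mapping is supplied as TSV.
- The model assumes the interface geometry of the template complex for
  every scored pair and every mutant; structural rearrangement is not
  modeled.
- Scores are comparable within one organism's matrix, not across
  organisms.
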
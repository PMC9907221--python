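# Methods

## Problem setting

MHC class I proteins present short peptides (8–15 residues) on the cell
surface; which peptides an allele presents is summarized by its binding
motif, a position weight matrix (PWM) over the 20 canonical amino acids.
Experimental peptide repertoires exist for only a few hundred alleles.
`pepppo` treats motif characterization as a generation problem: learn a
mutation policy that turns uniformly random peptides into peptides a given
allele presents, generate a repertoire per allele, and read the motif off
the generated peptides.

## The mutation environment

A state is a pair (peptide, MHC pseudo sequence); the pseudo sequence is the
fixed 34-residue representation of the allele's peptide-contacting positions
and is consumed as input, never derived here.  An action substitutes one
residue: first a position, then a replacement type (never the residue already
present).  An episode starts from a uniformly random peptide and ends when
the presentation score of the current peptide exceeds sigma = 0.75 (strict
inequality) or after T = 8 mutations.  Only the terminal transition is
rewarded, with the terminal presentation score.  Presentation scoring is a
pluggable contract mapping (peptide, allele) to [0, 1]; production use wires
in an external predictor through a subprocess adapter, while all tests and
studies use the synthetic oracle described below.  sigma doubles as the
"qualified peptide" threshold used in every downstream filter, and T = 8 was
chosen as a small multiple of the typical Hamming distance between a random
peptide and a motif consensus (4 anchors); both are configurable.

## Policy and value networks

Residues are encoded as the concatenation of a scaled BLOSUM62 row
(scale 0.1, keeping entries O(1)), a one-hot vector, and a row of a learnable
16-wide embedding table, all in the fixed alphabet order
`ACDEFGHIKLMNPQRSTVWY`.  The peptide runs through a one-layer bidirectional
LSTM (hidden width 64 per direction); per-residue vectors concatenate the two
directions and the peptide embedding h_p concatenates the final forward and
first backward hidden states.  The boundary hidden/cell vectors are random
noise drawn once at initialization and frozen, so the policy is a
deterministic function of the state; a flag allows resampling them per call.
The MHC encoding matrix is flattened row-major and passed through a two-layer
ReLU perceptron to give h_m.

The position head scores each position from (h_i, h_m) and normalizes with a
softmax (scores are unbounded reals, so linear normalization is not
well-defined).  The residue head maps the chosen position's (h_i, h_m) to
20 logits; the current residue's logit receives a large negative additive
mask before the softmax, which implements "exclude the original type, then
renormalize" exactly and keeps self-substitution probability at 0 under any
parameters.  The joint action log-probability is the sum of the two head
log-probabilities.  A two-layer perceptron on h_m ++ h_p estimates the state
value.  All of this runs on a small tape-based reverse-mode autodiff engine
over numpy (`pepppo.autodiff`), whose gradients are finite-difference-checked
in the test suite.

## Learning

Training is proximal policy optimization.  Per iteration, at least N = 1024
transitions are collected from complete episodes run in vectorized waves;
returns use the terminal-only discounting R_t = gamma^(T-t) r_T and
advantages come from generalized advantage estimation (backward recursion
over TD errors, terminal bootstrap 0).  Advantages are mean/std normalized
per batch (switchable).  The update maximizes the ratio-clipped surrogate
and combines it with a value MSE, a diversity-buffer imitation term and an
entropy bonus:

    L = -L_CLIP + a1 L_V + a2 L_B - a3 H

Both the pretraining objective and the buffer term are implemented as
standard negative log-likelihoods (cross entropy); positive-sign readings of
those objectives would ascend rather than descend and contradict their
"cross entropy loss" designation.

Defaults: gamma 0.99, lambda 0.95, eps 0.2, a1 0.5, a2 0.1, a3 0.01, K 4
epochs, minibatch 256, Adam at 1e-3.  The reference study (below) overrides
minibatch to 512 and the learning rate to 5e-4, which halves the number of
updates per iteration at equal wall time and proved stabler on the oracle.

### Expert policy

For each allele with at least 50 qualifying binding records per length
(positive labels, or affinity below 500 nM when quantitative), per-position
residue distributions are tabulated with Laplace pseudocount 1.  The expert
mutates the position with the largest gap between the most popular and the
current residue's probability (ties to the lowest index) and samples the
replacement from the position's distribution with the current residue masked.
Alleles without data resolve to the most BLOSUM62-similar data-bearing
allele's distributions (similarities min-max normalized over candidates at
query time; ties break lexicographically).

The expert is used twice: behavior-cloning pretraining of the two action
heads (25 epochs over 512 sampled states by default), and expert-driven
episodes mixed into early rollouts — the mixing fraction starts at 0.5 and
decays linearly to 0 over the first 30% of iterations.  Expert actions enter
the PPO batch with log-probabilities evaluated under the current policy at
collection time, the minimal choice that keeps probability ratios
well-defined; a full off-policy correction is not attempted.

### Diversity buffer

State–action pairs from qualified trajectories (terminal score > sigma) are
stored with the replacement residue type as the action key (position keys are
length-confounded; a (position, residue) mode exists).  On overflow the most
frequent key loses its oldest entry, so flooding one action can never evict
the sole example of another.  Batches of 64 are drawn with weights inversely
proportional to key counts, and the imitation term is the mean negative
log-likelihood of those actions.  Stored states are pre-mutation (the state
in which the action was taken), consistent with imitation semantics.

## Motifs and screening

Generated repertoires are filtered at the qualification threshold (scores
below 0.75 removed; 0.75 itself retained), and PWMs are built per peptide
length from pure empirical frequencies (pseudocount 0; expert profiles use
pseudocount 1 because they must support masked sampling).  Motifs of equal
length are compared by the mean per-column Hellinger distance
H(p,q) = (1/sqrt 2)||sqrt p − sqrt q||, similarity = 1 − distance; motifs of
different lengths are never compared.

Neoantigen screening expands each protein-space point mutation into all
9-mer windows of the mutant sequence containing the mutated residue (windows
truncated by protein ends are omitted; only mutant windows are emitted).  The
motif matching score of a peptide is the sum of PWM probabilities of its
residues at their positions, min-max normalized by the PWM's analytic bounds
(sums of per-column minima and maxima) so that scores are comparable across
cohorts and stable under subsetting; per-cohort empirical normalization is
available by flag, and a degenerate uniform PWM normalizes to 1.0 with a
warning.  Discrimination of neoantigens (reference scorer above 0.75) from
non-neoantigens is reported as the rank-based AUC (ties averaged) and a
two-sided rank-sum test.  Coordinates are 1-based inclusive in all files and
0-based half-open internally.

## The synthetic oracle, and what it does not show

The test world's presentation scorer is a hidden PWM per (allele, length):
4 anchor columns put probability 0.9 on one residue, the rest are a mild
Dirichlet jitter around uniform.  A peptide's score is its normalized
matching score against the hidden PWM passed through a fixed rescaled
logistic (midpoint 0.85, steepness 14), frozen so that the consensus scores
exactly 1 and a peptide clears the 0.75 qualification threshold only when
every anchor is matched (all-but-one anchors score about 0.24; uniform-random
9-mers qualify with frequency around 20^-4).  The qualification boundary must
sit between "all but one" and "all" anchors: if a peptide missing one anchor
qualified, episodes would terminate the moment the remaining anchors were
fixed and the missing anchor column of every qualified repertoire would stay
uniform, making full-motif recovery impossible for any generator.  Because
the ground truth is itself a PWM, motif recovery is well-posed: the generated
repertoire's PWM can be compared to the hidden one at the anchor columns.

The oracle is deliberately simpler than a trained presentation predictor: it
is additive across positions, has no antigen-processing component, no
length competition, and no epistasis between anchors.  Passing the studies
here therefore demonstrates that the optimization and characterization
machinery works — not that the recovered motifs would match experimentally
derived human motifs; that claim requires an external predictor and real
repertoires, which are outside the test world.

Synthetic binding datasets rejection-sample peptides from the hidden PWM
until 200 qualify per allele (labels by oracle thresholding, an equal number
of uniform negatives added), emulating a confirmed-binder dataset.  Synthetic
cohorts plant a configurable fraction of mutations whose mutant window equals
an allele's consensus, each in its own protein so no record is invalidated by
a later rewrite.

## Reference study conditions

`pepppo.workflows.motif_discovery_study` freezes the package's reference
experiment: the 3-allele oracle above, 80 PPO iterations of N = 1024 steps
(after 25 pretraining epochs), 1000 generated peptides per allele.  One
training takes a few minutes on a single CPU at these sizes.  Typical
outcomes: 75–95% of generated peptides qualify (the uniform-random baseline
is essentially 0%, sPWM from the synthetic expert around 80%),
anchor-restricted motif similarity to the hidden PWM about 0.77, and
run-to-run motif similarity between independently trained policies around
0.85.  Anchor similarity sits near 0.77 rather than 1 because every
qualified peptide matches all four anchors exactly, so the recovered anchor
columns are point masses while the hidden columns hold probability 0.9; the
residual is the Hellinger distance between those two shapes.

## Numerical choices and edge cases

- PWM columns must sum to 1 within 1e-6 on input; probability-vector checks
  in the Hellinger distance use the same tolerance.
- Probability ratios in the surrogate are checked finite; the offending
  transition index is reported otherwise, and a non-finite combined loss
  aborts training with iteration diagnostics.
- The residue mask uses an additive -1e9 logit, which underflows to exact 0
  probability after the softmax; entropies then receive an exact 0
  contribution from the masked entry.
- Empirical-frequency assertions in tests use 4-sigma binomial bounds;
  chi-square checks use a 1e-4 p-value floor.
- Checkpoints are single .npz archives holding all parameters, the frozen
  LSTM boundary vectors, the alphabet order, and the environment config; a
  checkpoint plus a seed fully determines generation.

## Known limitations

- The LSTM is one layer by design; no attention or deeper stacks.
- Substitution-only action space: no insertions or deletions, so episode
  peptide length is fixed at reset.
- The expert's stopping behavior on a consensus peptide is undefined in
  principle (all gaps zero); the argmax then picks position 0, and the
  residue head still proposes a change.  In practice episodes terminate by
  score before this matters.
- Training on one CPU limits the reference study to 3 alleles and 9-mers;
  the machinery accepts 8–15-mers and arbitrary allele panels, at cost.
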
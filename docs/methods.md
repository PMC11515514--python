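# Methods

This note documents the models and procedures implemented in `molnp`,
the choices made where the design was genuinely open, and what the
synthetic studies do and do not demonstrate.

## Neural processes

A neural process (NP) models the predictive distribution of a task's
labels at target inputs `x_t` given a labelled context set `(x_c, y_c)`,
assuming conditional independence across targets:

    q(y_t | x_c, y_c; x_t) = prod_j N(y_tj | mu(x_tj, x_c, y_c),
                                       sigma^2(x_tj, x_c, y_c))

Computation is in three steps: an encoder `h` maps each context pair to
a local encoding `r_j`; the encodings are aggregated into a global
function encoding `r` by a commutative operation; a decoder `g` maps
`(r, x)` to the per-target mean and variance.

**Aggregation is the mean, not the sum.** Context sizes vary by an order
of magnitude during training (default sizes are drawn from [20, 150)),
and mean aggregation keeps the encoding scale size-independent. The
empty context set encodes to the zero vector, so prior predictions are
well defined.

**Conditional vs latent path.** The CNP decodes `r` directly and is
deterministic at test time. The LNP maps `r` through a latent network to
a diagonal Gaussian over a latent variable `z` (length 64 by default)
and decodes `z`. Training uses a single reparameterized sample of `z`
from the posterior given contexts-and-targets, plus a KL term pulling
that posterior toward the one given contexts only — the standard
variational NP objective. This KL regularizer is our decided form of the
latent-path regularization; alternatives exist, and the choice is
documented here rather than hidden. At test time the LNP decodes the
posterior mean of `z` (deterministic); S-sample mixture moment-matching
is available as an option.

**Architecture defaults.** Encoder: 3 fully connected layers, width 128,
ReLU, output `r` of length 128. Decoder: two width-128 hidden layers
followed by separate mean and raw-variance heads; the two heads together
are treated as the final decoder "layer" wherever layers are selected by
position. All widths are configurable; the sinusoid studies use width 64.

**Variance head.** `sigma^2 = softplus(raw) + 1e-4`. The floor prevents
likelihood spikes from collapsing variances during maximum-likelihood
training; it is far below every signal variance used in the studies
(labels are standardized to unit variance).

**Numerics.** The models are built on a small reverse-mode autodiff
engine over float64 numpy arrays (`molnp.autodiff`) with a dense-layer /
Adam layer on top (`molnp.nn`). Training uses Adam at 1e-3 with global
gradient-norm clipping at 10. Mini-batches of 16 tasks are padded to the
batch's largest context/target sizes and masked, so one tape evaluates
the whole batch (the 3-D task-batch layout). All randomness flows
through explicit `numpy.random.Generator` arguments; fixed seeds give
bit-identical runs.

## Molecular representations

Fingerprints are binary Morgan fingerprints (RDKit), length 1024 and
radius 3 by default. Tanimoto similarity of two all-zero fingerprints is
defined as 1.0 (identical empty sets), preserving "identical inputs have
similarity 1".

Molecular graphs cover heavy atoms only; hydrogens enter through the
n-H-neighbour count feature. Atom features: one-hot element
({C,N,O,S,F,Cl,Br,I,P,B,Si} + other), hydrogen and heavy-neighbour
counts (binned 0–6 with an overflow bin), formal charge (−2..+2 +
other), hybridisation (sp, sp2, sp3, sp3d, sp3d2 + other), ring /
aromatic / chirality flags, plus real-valued atomic mass (scaled by
1/100), Van der Waals radius and covalent radius. Bond features: one-hot
bond type (single/double/triple/aromatic), conjugation and ring flags,
and a stereo one-hot. The featurizer configuration (vocabularies and
dimensions) is serialized into checkpoints so a dimension mismatch
between a model and its inputs is detected, not silently broadcast.

## Graph attention encoder

The molecule-to-vector encoder works in three stages, producing a
length-50 representation that replaces the raw input in the NP's encoder
and decoder:

1. *Pre-embedding.* A 2-layer network (50 hidden units) maps atom
   features to length-25 vectors; another maps each incident bond's
   features to length 25 and sums them over the neighbour set (an empty
   sum for isolated atoms). Concatenation gives the length-50 atom
   state.
2. *Neighbour rounds.* 3 rounds of single-head scaled-dot-product
   attention restricted to each atom's neighbours. Queries and keys come
   from a single-layer network, values from a linear map. The update is
   residual: `s <- s + act(W m)` where `m` is the attended message;
   atoms without neighbours pass through unchanged. There are no gated
   recurrent units. Each round has its own weights.
3. *Superatom readout.* An auxiliary node connected to every atom is
   appended, initialized to the mean atom state (initialization is not
   otherwise constrained; the mean keeps permutation invariance exact),
   and 3 further attention rounds run on the augmented graph — real
   atoms keep their bonds and additionally exchange messages with the
   superatom. The superatom's state then passes through a small output
   network to give the final length-50 representation.

Attention operates on atom states only after pre-embedding; bond
features are not re-injected inside the attention rounds. Leaky-ReLU
activations are used throughout the graph encoder so that no parameter
group is gradient-dead at initialization. The whole map is exactly
invariant to atom relabelling, which the tests assert at 1e-6 across
alternative SMILES orderings.

## Meta-training

Each epoch visits every task once. Context and target sizes are drawn
uniformly from [20, 150) (independently per task per epoch) and the
index sets are disjoint, with `C + T <= O_i`. Tasks too small for the
requested ranges get proportionally shrunk ranges (each size at least
1). A fraction mode replaces the ranges with a fixed fraction of `O_i`
for both sets and can allow context/target overlap — this is the knob
used by the overfitting sweep, where fraction 1.0 with overlap means
every point is both context and target every epoch. The expectation in
the training objective is estimated with one split draw per task per
epoch (multi-draw averaging is exposed but defaults to 1).

*Effective epochs* `e_e = e * n_bar / O_i` measure how often an
individual observation is actually seen; `n_bar` counts views as either
context or target. The accounting is verified empirically (2,000 epochs,
`O = 200`, `C = T = 20`: mean views within 10% of 400).

`chunked_predict` processes targets in bounded chunks and is guaranteed
to agree with single-pass prediction because the decoder factorizes over
targets; it exists purely to bound memory.

## Fine-tuning adaptation

Fine-tuning treats a meta-test task's C labelled contexts as if they
were a meta-training task: each epoch they are re-split into fresh
disjoint new-contexts (C' = 20) and new-targets (T' = 20), and one Adam
step is taken on the NP objective. Only the last two decoder layers are
adapted (for LNPs, also the last two latent-path layers); all other
parameters are bitwise frozen. The epoch count is derived from a target
of 20 effective epochs as `e = ceil(e_e * C / T')` — the convention
counts views as a new target, following the dependence on C and T';
counting both views (`e = ceil(e_e * C / (C' + T'))`) is exposed as an
option. A 20-observation preset uses C' = T' = 5. The fine-tuning
learning rate defaults to 1e-4, ten times below meta-training, as a
conservative default against overfitting a single task.

## Synthetic task families

*Sinusoids* `y = A sin(rho (x - B))` with `A ~ U(0.1, 5)`,
`B ~ U(0, pi)`, `x ~ U(-5, 5)` — the standard meta-learning regression
benchmark ranges. Meta-training uses `rho = 1`; the divergent test
family uses `rho = 1.5`. Training tasks have 50 observations with
context/target sizes drawn from [5, 25); evaluation tasks provide 100
contexts and 100 targets (100 contexts is also the fine-tuning
regime).

*Synthetic molecular meta-datasets* emulate a complete docking-score
matrix: task i's labels are `(lambda w_shared + (1 - lambda) w_i) . fp`
over 1024-bit fingerprints, standardized per task, plus Gaussian noise
(sd 0.1 by default). The weights are sparse (32 active bits). The
shared-weight fraction `lambda` tunes inter-task correlation
continuously from unrelated (0) to identical (1); the calibration and
BO studies use `lambda = 0.7`, a high-but-imperfect correlation regime.
Molecules are generated by fragment assembly validated with RDKit, so
experiments at any size need no external data; a frozen list of 200
such molecules ships with the package for fixed fixtures.

These generators reproduce the *structure* of the real setting —
complete matrices, tunable task relatedness, fingerprint-linear signal
plus noise — but not its chemistry: real docking scores are not linear
in fingerprint bits, their noise is not Gaussian, and scaffold-split
generalization is harder than the random molecule splits used here.
Passing studies therefore demonstrate correctness and qualitative
behaviour of the algorithms, not real-data performance levels.

The DOCKSTRING-style reader consumes the published complete-matrix TSV
layout (SMILES column, optional train/test split column, numeric target
columns). Scaffold splitting itself is out of scope: the split column is
consumed, never computed, and the synthetic generator assigns splits
randomly under a seed.

## Study configurations

All studies run on one CPU core; sizes were chosen so the full suite
completes in minutes while leaving the qualitative effects
unambiguous.

- Sinusoid meta-generalization: width-64 CNP, 500 training tasks, 300
  epochs, 20 evaluation tasks per family, 5 seeds (median).
- Fine-tuning recovery: the models above, on the rho = 1.5 tasks, 100
  contexts, e_e = 20, C' = T' = 20.
- Calibration: lambda = 0.7, 50 tasks x 500 molecules, 45 tasks
  meta-trained for 60 epochs, 5 held-out tasks evaluated from 200
  contexts on 250 held-out molecules, 20 confidence percentiles, 5
  seeds.
- Overfitting sweep: 20 tasks x 200 molecules, fractions 0.05 vs 1.0
  (with overlap), 60 epochs, NLPD on 4 held-out tasks, 3 seeds.
- Bayesian optimization: 2,000 candidates, hidden objective drawn from
  the same lambda = 0.7 family as the 40 meta-training tasks, CNP
  meta-trained 60 epochs, batch 5, budget 200, n_init 20, kappa = 1,
  5 BO seeds per acquisition.

## Bayesian optimization details

Objectives are minimized throughout (docking-score convention);
maximization objectives should be negated at ingestion. LCB is
`mu - kappa * sigma` with `kappa = 1` by default; greedy is `mu`;
ties in batch selection break toward the lowest index. Initialization is
20 uniform-random molecules. By default the NP surrogate is conditioned
on the seen molecules as contexts without re-fitting; per-iteration
fine-tuning is available behind a flag. The Tanimoto-kernel GP baseline
is exact (Cholesky with observation noise on the diagonal, escalating
jitter retries on factorization failure, prior variance 1 since Tanimoto
self-similarity is 1, labels centred on the training mean). Where a GP
could also be viewed as a surrogate model of the same kind, the
brute-force matrix-inversion oracle in the tests is constructed
independently of the Cholesky path it checks.

Task augmentation from a complete score matrix draws uniformly over four
transform kinds — a scalar multiple of one column (weight U(0.1, 1)), a
two-column linear combination (weights U(0.1, 1)), and the elementwise
min or max of a column with its median — each combined additively with a
drug-likeness (QED) column weighted U(0.5, 2). Every transform records
its sources and weights; any transform touching an excluded target
(e.g. proteins appearing in the objective) is discarded rather than
resampled, so the returned count can fall below the requested one.

## Known limitations

- The latent-path regularizer is the standard variational KL; other
  regularizations of the LNP encoder would change the LNP loss surface.
- Graph-encoder training is exercised at unit scale (gradient flow,
  invariances); the large synthetic studies use fingerprint inputs,
  where the batched fast path applies. Batched (padded) training for
  graph inputs falls back to a per-task loop.
- Relative error is undefined at label 0; such molecules are excluded
  from applicability-domain buckets with a warning.
- The fraction mode with disjoint sets requires fraction <= 0.5;
  larger fractions require allowing overlap, which matches how the
  sweep is defined.
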
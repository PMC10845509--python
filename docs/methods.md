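# Methods

## The model

`dtiagg` regresses a real-valued binding affinity y for a compound–protein
pair (x, t).  Two encoders ("branches") map each side to an embedding:
g(x) ∈ R^D1 for the compound and h(t) ∈ R^D2 for the protein.  A head
combines them into the prediction f(x, t):

- **dot product** — f = Σ_d g_d(x) h_d(t); parameter-free, requires D1 = D2;
- **MLP** — f = MLP([g ; h]); a dense stack on the concatenation ending at a
  single output node (one hidden layer is the canonical form; more are
  allowed);
- **tensor product** — f = Σ_k Σ_l w_kl g_k(x) h_l(t) = gᵀ W h, a bilinear
  form with W ∈ R^{D1×D2}; evaluated as two matrix–vector products, never
  by materializing the outer product (the outer-product evaluation is kept
  only as a test oracle).  The bias is off by default.

Branches are chosen per feature type: an MLP on Morgan fingerprints
(compounds) or amino-acid composition (proteins); a 1-D CNN on label-encoded
SMILES / sequence tokens; an MPNN on the heavy-atom molecular graph
(compounds); or a single fully-connected layer on one-hot identity vectors —
the *implicit* branch, an embedding lookup.  With implicit branches and a dot
head the model is exactly learned matrix factorization of the interaction
matrix.  A *hybrid* branch concatenates an entity's explicit and implicit
intermediate embeddings and passes them through an internal MLP, so one
entity embedding carries both sources.

All forwards run on a small reverse-mode autodiff engine over NumPy
(`dtiagg.autograd`); everything is float64 CPU and deterministic given the
seeds threaded through every constructor.

## Prediction settings

Three splits with 70–10–20 % train/val/test ratios (floor rounding for train
and validation, remainder to test):

- **random** — the {compound, protein, affinity} triplets are shuffled and
  partitioned (matrix completion);
- **cold_drug** — the *drugs* are partitioned and triplets follow their
  drug, so test drugs never occur in training;
- **cold_target** — likewise over proteins.

The combined cold-drug-and-cold-target setting is deliberately not provided.
`audit_split` re-checks the disjointness contracts and reports any leaking
entity ids.

## Evaluation

MSE, R² = 1 − SS_res/SS_tot (may be negative; undefined for constant y), and
the concordance index: over ordered pairs with y_i > y_j, the fraction with
ŷ_i > ŷ_j.  Tied predictions score 0 under the default strict indicator;
`ties="half"` gives the 0.5-credit convention used in survival analysis.
`top_k_average` reports the mean metrics of the k configurations with the
lowest validation loss, the aggregation used when summarizing a random
search ("lowest overall loss" is read as the validation MSE at the
early-stopping checkpoint; it is configurable).

## Training and search

Training minimizes MSE with Adam (optionally decoupled weight decay), runs
up to `max_epochs` epochs (default 100) with early stopping on
the validation loss (patience 5 by default), and restores the
best-validation checkpoint.  Entities, not pairs, are encoded each step:
every unique compound and protein is embedded once and pair predictions
gather rows, which makes minibatching cheap even for graph branches.
Random search samples a fixed budget of configurations i.i.d. from a
declared space with one master seed; dot-head configurations always receive
a shared embedding dimension (the D1 = D2 restriction).  Hyperparameter
ranges are package defaults, declared rather than recovered from any
external source.

### Optimization recipe for the reference experiments

Unregularized full-batch factorization at the standard problem size showed
two failure modes: individual entity factors blowing up (excellent
validation loss by luck of coverage, terrible test loss) and rank-deficient
local minima that recover only part of the latent structure.  The reference
experiments therefore use minibatch Adam (batch 128) with decoupled weight
decay (1e-2 for implicit factorization, 1e-3 elsewhere) and select among
three random restarts by validation loss.  These are method settings of the
experiments, fixed once; the pass thresholds of the test suite are not
derived from them.

## Synthetic data

The generator emulates the structure the models exploit: a sparse
compound×protein matrix whose clean values are U Vᵀ with latent rank D*
(default 4), observed at a given density (default 0.5 over a 60×40 matrix)
with additive Gaussian noise (σ = 0.1).  Compounds are drawn from a small
C/N/O chain-and-ring SMILES grammar in which every string is valid by
construction (branch points restricted to carbon so no valence is
exceeded); proteins are uniform random sequences of length 50–120.

With `feature_link="none"`, U and V are i.i.d. standard normal: the signal
lives only in entity identity, so implicit models succeed under the random
split and nothing can generalize to cold entities.  With
`feature_link="linear"`, U = zscore(F A) and V = zscore(C B) for Morgan
fingerprints F, composition vectors C and normal link maps A, B — the
factors are functions of explicit descriptors, so explicit models can
generalize cold.  The link fingerprint is 32 bits wide: the width must stay
below the ~42 training drugs of a default cold split, otherwise the linear
map is unidentifiable from the training partition and cold generalization
is impossible *by construction* (we verified the identifiable setting with
an independent ridge-regression recovery of the true map before freezing
it).  Column z-scoring keeps the factors unit-scale, so affinity variance
decomposes as D* + σ² — checked by a Monte-Carlo test.

What the generator does **not** emulate: realistic affinity distributions
(Davis pKd, KIBA scores), correlated measurement error, chemically diverse
scaffolds, or sequence homology between proteins.  Passing tests show the
machinery is correct and the directional claims hold under controlled
low-rank conditions; they do not certify benchmark-level accuracy.

## The reference experiments

- **Expressivity** (`expressivity_check`): each head, with scalar-input
  2-unit MLP branches, is trained 2000 Adam steps on y = x·t over
  x, t ~ U(−1, 1); all three reach train MSE below 0.05.  A numeric
  counterpart to the universal-approximation property of the three
  strategies.
- **Recovery** (`recovery_experiment`): the implicit dot model with D = D*
  recovers the rank-4 matrix under the random split (test R² ≈ 0.99) but is
  indistinguishable from the mean predictor under cold-drug; the explicit
  MLP–MLP dot model on feature-linked data reaches R² ≈ 0.99 under
  cold-drug.  The contrast is the point: identity features support matrix
  completion only, explicit features support cold generalization.
- **Oversmoothing sweep** (`oversmoothing_experiment`): compound-branch
  variants trained identically on linked data with a dot head — a 2-round
  MPNN baseline, bare MPNNs of 8/10/12 rounds, and a 2-round MPNN followed
  by 64–32 fully-connected layers.  At this molecule scale (2–9 heavy
  atoms) moderate depth (4–6 rounds) still trains well; clear depth-driven
  degradation sets in once message-passing depth far exceeds the graph
  diameter, from about 8 rounds.  The sweep therefore probes that deep
  regime, where the FC-augmented shallow MPNN attains test MSE well below
  every bare variant of equal-or-larger parameter count.

## Numerical choices and edge cases

- Weight init: Glorot uniform from a seeded generator; every constructor
  takes a seed.
- Activation default ReLU; linear and tanh available.
- MPNN: messages are linear transforms of [neighbour state ; bond features]
  summed at the receiving atom; update adds a learned self-transform;
  readout sum (mean optional).  Default depth 3.
- CNN: token-embedding table (pad index 0), stacked valid-mode
  convolutions, global max pooling (sum optional), dense projection.
  A `max_len` shorter than the receptive field is a configuration error.
- Degenerate inputs: empty sequences, unparsable SMILES, out-of-range
  one-hot indices, constant y for R², and all-equal y for CI raise typed
  errors; NaN training loss aborts with a diagnostic.
- Ties in top-k selection break by trial order; partition rounding is
  floor/floor/remainder; an empty validation partition is an error.
- Davis affinities can be loaded raw (nM Kd) or as pKd = −log10(Kd/1e9)
  (the default, matching common practice; configurable because the
  upstream convention is not fixed).
- Nonstandard residues (B, J, O, U, X, Z) are rejected unless explicitly
  mapped to an unknown symbol.

## Known limitations

- Branch architectures are desk-scale; no GPU path exists and none is
  planned.
- The CNN/MPNN default hyperparameters are package choices, not recovered
  values; treat them as search starting points.
- The oversmoothing comparison is directional and scale-dependent (see
  above); it does not reproduce any printed benchmark number.
- Benchmark-scale random search (budget 100 × 100 epochs on Davis/KIBA)
  is supported by the API but not exercised by the test suite.
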
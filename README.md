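# dtiagg

Two-branch neural models for drug–target binding-affinity regression, built
to compare how the two entity embeddings are **aggregated** into a
prediction.  Given a compound x (SMILES) and a protein t (amino-acid
sequence), two encoders produce embeddings g(x) ∈ R^D1 and h(t) ∈ R^D2, and
one of three interchangeable heads scores the pair:

| head | f(x, t) | parameters |
|---|---|---|
| dot product | Σ_d g_d(x) h_d(t) | 0 (requires D1 = D2) |
| MLP | MLP([g(x) ; h(t)]) → 1 output | dense stack |
| tensor product | Σ_k Σ_l w_kl g_k(x) h_l(t) = gᵀWh | D1·D2 |

Branches cover the standard representations — MLP on Morgan fingerprints or
amino-acid composition, 1-D CNN on SMILES/sequence tokens, MPNN on the
heavy-atom molecular graph, and an embedding-lookup branch on one-hot
identity ("implicit") features; with implicit branches and the dot head the
model is exactly learned matrix factorization of the interaction matrix.  A
hybrid mode combines explicit and implicit features per entity.  The MPNN+FC
variant appends fully-connected layers after a shallow MPNN, growing capacity
without the oversmoothing that deep message passing suffers from.

Evaluation follows the three prediction settings — **random** (triplets
split 70–10–20), **cold drug** and **cold target** (entities split, so test
drugs/targets are unseen in training, with audited leakage guarantees) — and
three metrics: MSE, R², and the concordance index (the probability that two
comparable pairs are ranked correctly).  Random hyperparameter search with
early stopping and top-k-by-validation-loss reporting, a synthetic low-rank
data generator, and loaders for Davis/KIBA-style benchmark files round out
the toolkit.  Everything runs on CPU NumPy via a small built-in autodiff
engine; it is a desk-scale research tool, for method study rather than
leaderboard accuracy.

## Worked example

Matrix-factorization recovery: generate a rank-4 synthetic interaction
matrix (60 drugs × 40 targets, half the cells observed, noise σ = 0.1), fit
the implicit-feature dot-product model — i.e. rank-4 matrix factorization —
under a random split, and inspect the results object:

```python
from dtiagg import (DTIModel, SyntheticSpec, TrainConfig,
                    generate_dataset, random_split)

spec = SyntheticSpec(seed=1)                 # 60 x 40, rank 4, density 0.5
dataset, truth = generate_dataset(spec)
split = random_split(dataset, seed=1)        # 70-10-20 over triplets
model = DTIModel(dataset, split, features="implicit",
                 aggregation="dot", embedding_dim=4, seed=1)
res = model.fit(TrainConfig(max_epochs=400, lr=0.02, patience=60,
                            weight_decay=1e-2, batch_size=128))
print(res.summary())
```

```
Two-branch DTI regression results
================================================
dataset:          synthetic(rank=4,link=none): 60 drugs, 40 targets, 1200 interactions
setting:          random (seed 1)
compound branch:  embedding_lookup | protein branch: embedding_lookup
aggregation:      dot | features: implicit
trainable params: 408
epochs run:       336 (best epoch 276)
val MSE (best):   0.0197
------------------------------------------------
test MSE:         0.0196
test R2:          0.9932
test CI:          0.9674
test pairs:       240
```

Test MSE 0.0196 sits at the generator's noise floor (σ² = 0.01 plus
estimation error), and R² = 0.993 means the 408-parameter factorization has
recovered essentially all of the rank-4 signal from half-observed data.
Rerun the same model under `cold_drug_split` and R² collapses to ≈ 0:
identity features carry nothing transferable to unseen drugs — that
contrast, and the explicit-feature models that *do* generalize cold, are
what the package is for.

The same objects are scriptable from the shell:

```bash
dti simulate --out data/ --seed 1
dti search --dataset synthetic --setting cold_drug --aggregation tensor \
    --budget 10 --seed 1
dti sweep-capacity --seed 1
```

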
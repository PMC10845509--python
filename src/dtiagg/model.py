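"""Model/Results interface for two-branch affinity prediction.

:class:`DTIModel` is built from a dataset, a split and an architecture
description (branch kinds, feature mode, aggregation strategy);
:meth:`DTIModel.fit` minimizes the training MSE with Adam under
early stopping on the validation loss and returns a
:class:`DTIResults` carrying the trained weights, per-epoch history,
test-set metrics, a ``summary()`` table, prediction and
embedding-extraction methods.

Typical use::

    spec = SyntheticSpec(seed=1)
    dataset, truth = generate_dataset(spec)
    split = random_split(dataset, seed=1)
    model = DTIModel(dataset, split, compound_branch="embedding_lookup",
                     protein_branch="embedding_lookup", aggregation="dot",
                     embedding_dim=4)
    res = model.fit(TrainConfig(max_epochs=300))
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .aggregation import (ConfigurationError, HybridBranch, MLPHead,
                          TwoBranchModel, make_head)
from .branches import (CNNBranch, EmbeddingBranch, MLPBranch, MPNNBranch,
                       MPNNFCBranch, batch_graphs, count_parameters)
from .data import DTIDataset
from .featurization import (ATOM_FEATURE_DIM, BOND_FEATURE_DIM, build_vocab,
                            composition_descriptor, encode_protein,
                            encode_smiles, morgan_fingerprint, smiles_to_graph)
from .metrics import MetricsReport, evaluate, mse
from .splits import SplitAssignment


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are the desk-scale quickstart."""

    max_epochs: int = 100
    batch_size: int | None = None      # None = full-batch steps
    lr: float = 1e-3
    weight_decay: float = 0.0          # decoupled L2 shrinkage
    optimizer: str = "adam"
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is provided")


# ---------------------------------------------------------------------------
# feature preparation
# ---------------------------------------------------------------------------

_DEFAULT_COMPOUND_FEATURES = {"mlp": "fingerprint", "cnn": "tokens",
                              "mpnn": "graph", "mpnn_fc": "graph",
                              "embedding_lookup": "onehot"}
_DEFAULT_PROTEIN_FEATURES = {"mlp": "composition", "cnn": "tokens",
                             "embedding_lookup": "onehot"}


def prepare_compound_inputs(dataset: DTIDataset, representation: str,
                            fingerprint_radius: int = 2,
                            fingerprint_bits: int = 1024,
                            max_len: int = 100):
    """Entity-level compound inputs: one row/graph per compound, dataset order."""
    smiles = [c.smiles for c in dataset.compounds]
    if representation == "fingerprint":
        return np.stack([morgan_fingerprint(s, fingerprint_radius,
                                            fingerprint_bits).bits for s in smiles])
    if representation == "tokens":
        vocab = build_vocab(smiles)
        L = min(max_len, max(len(s) for s in smiles))
        return np.stack([encode_smiles(s, vocab, L).tokens for s in smiles])
    if representation == "graph":
        return batch_graphs([smiles_to_graph(s) for s in smiles])
    if representation == "onehot":
        return np.arange(dataset.n_compounds)
    raise ConfigurationError(f"unknown compound representation {representation!r}")


def prepare_protein_inputs(dataset: DTIDataset, representation: str,
                           composition_k: int = 1, max_len: int = 1000):
    seqs = [p.sequence for p in dataset.proteins]
    if representation == "composition":
        return np.stack([composition_descriptor(s, k=composition_k).freqs
                         for s in seqs])
    if representation == "tokens":
        vocab = build_vocab(seqs)
        L = min(max_len, max(len(s) for s in seqs))
        return np.stack([encode_protein(s, vocab, L).tokens for s in seqs])
    if representation == "onehot":
        return np.arange(dataset.n_proteins)
    raise ConfigurationError(f"unknown protein representation {representation!r}")


def binarize_affinity(y, threshold: float) -> np.ndarray:
    """Active/inactive labels: 1 where affinity >= threshold, else 0."""
    return (np.asarray(y, dtype=float) >= float(threshold)).astype(int)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DTIModel:
    """Two-branch affinity regression model bound to a dataset and split.

    Parameters
    ----------
    dataset, split
        The data and its train/val/test assignment.
    compound_branch, protein_branch
        Encoder kinds: ``mlp`` | ``cnn`` | ``mpnn`` | ``mpnn_fc`` |
        ``embedding_lookup`` (compound side only for the graph kinds).
    aggregation
        ``dot`` | ``mlp`` | ``tensor``.
    features
        ``explicit`` (descriptors only), ``implicit`` (identity one-hots
        only; forces embedding-lookup branches), or ``both`` (hybrid
        branches combining the two through an internal MLP).
    embedding_dim / compound_dim / protein_dim
        Branch output dimensionalities; the dot head requires them equal.
    """

    def __init__(self, dataset: DTIDataset, split: SplitAssignment, *,
                 compound_branch: str = "mlp", protein_branch: str = "mlp",
                 aggregation: str = "dot", features: str = "explicit",
                 embedding_dim: int = 16,
                 compound_dim: int | None = None, protein_dim: int | None = None,
                 compound_kwargs: dict | None = None,
                 protein_kwargs: dict | None = None,
                 head_kwargs: dict | None = None,
                 fingerprint_radius: int = 2, fingerprint_bits: int = 1024,
                 composition_k: int = 1,
                 smiles_max_len: int = 100, protein_max_len: int = 1000,
                 implicit_dim: int = 8, internal_hidden: tuple = (32,),
                 seed: int = 0):
        if features not in ("explicit", "implicit", "both"):
            raise ConfigurationError("features must be explicit, implicit or both")
        if features == "implicit":
            compound_branch = protein_branch = "embedding_lookup"
        self.dataset = dataset
        self.split = split
        self.features = features
        self.aggregation = aggregation
        self.compound_kind = compound_branch
        self.protein_kind = protein_branch
        self.seed = seed
        d1 = compound_dim or embedding_dim
        d2 = protein_dim or embedding_dim

        c_rep = _DEFAULT_COMPOUND_FEATURES[compound_branch]
        p_rep = _DEFAULT_PROTEIN_FEATURES[protein_branch]
        self._c_inputs = prepare_compound_inputs(
            dataset, c_rep, fingerprint_radius, fingerprint_bits, smiles_max_len)
        self._p_inputs = prepare_protein_inputs(
            dataset, p_rep, composition_k, protein_max_len)

        cb = self._build_branch(compound_branch, self._c_inputs, d1,
                                compound_kwargs or {}, seed)
        pb = self._build_branch(protein_branch, self._p_inputs, d2,
                                protein_kwargs or {}, seed + 1)
        if features == "both":
            cb = HybridBranch(cb, dataset.n_compounds, implicit_dim, d1,
                              internal_hidden=internal_hidden, seed=seed + 2)
            pb = HybridBranch(pb, dataset.n_proteins, implicit_dim, d2,
                              internal_hidden=internal_hidden, seed=seed + 3)
            self._c_inputs = (self._c_inputs, np.arange(dataset.n_compounds))
            self._p_inputs = (self._p_inputs, np.arange(dataset.n_proteins))

        head = make_head(aggregation, d1, d2,
                         **{"seed": seed + 4, **(head_kwargs or {})}
                         if aggregation != "dot" else {})
        self.network = TwoBranchModel(cb, pb, head)
        self._c_idx, self._p_idx, self._y = dataset.triplet_arrays()

    def _build_branch(self, kind, inputs, dim, kwargs, seed):
        if kind == "mlp":
            return MLPBranch(input_dim=inputs.shape[1], embedding_dim=dim,
                             seed=seed, **kwargs)
        if kind == "cnn":
            return CNNBranch(vocab_size=int(inputs.max()), max_len=inputs.shape[1],
                             embedding_dim=dim, seed=seed, **kwargs)
        if kind == "mpnn":
            return MPNNBranch(ATOM_FEATURE_DIM, BOND_FEATURE_DIM, embedding_dim=dim,
                              seed=seed, **kwargs)
        if kind == "mpnn_fc":
            return MPNNFCBranch(ATOM_FEATURE_DIM, BOND_FEATURE_DIM, embedding_dim=dim,
                                seed=seed, **kwargs)
        if kind == "embedding_lookup":
            n = len(inputs)
            return EmbeddingBranch(n, dim, seed=seed, **kwargs)
        raise ConfigurationError(f"unknown branch kind {kind!r}")

    # -- convenience ---------------------------------------------------------
    @property
    def param_count(self) -> int:
        return count_parameters(self.network)

    def _forward(self, idx: np.ndarray):
        return self.network.forward_pairs(self._c_inputs, self._p_inputs,
                                          self._c_idx[idx], self._p_idx[idx])

    def predict(self, idx: np.ndarray) -> np.ndarray:
        """Predicted affinities for the given triplet indices."""
        return self._forward(np.asarray(idx)).data.copy()

    # -- fitting -------------------------------------------------------------
    def fit(self, config: TrainConfig = TrainConfig()) -> "DTIResults":
        params = self.network.params()
        opt = ag.Adam(params, lr=config.lr, weight_decay=config.weight_decay)
        rng = np.random.default_rng(config.seed)
        train_idx, val_idx = self.split.train, self.split.val
        y_train, y_val = self._y[train_idx], self._y[val_idx]

        history = []
        best_val = np.inf
        best_weights = None
        best_epoch = 0
        since_best = 0
        for epoch in range(1, config.max_epochs + 1):
            if config.batch_size is None:
                batches = [train_idx]
            else:
                order = rng.permutation(len(train_idx))
                batches = [train_idx[order[i:i + config.batch_size]]
                           for i in range(0, len(order), config.batch_size)]
            epoch_losses = []
            for batch in batches:
                opt.zero_grad()
                pred = self._forward(batch)
                resid = pred - ag.constant(self._y[batch])
                loss = (resid * resid).mean()
                if not np.isfinite(loss.data):
                    raise TrainingError(
                        f"non-finite training loss at epoch {epoch}; "
                        f"lower the learning rate"
                    )
                loss.backward()
                opt.step()
                epoch_losses.append(loss.item())
            val_loss = mse(y_val, self.predict(val_idx))
            history.append({"epoch": epoch,
                            "train_loss": float(np.mean(epoch_losses)),
                            "val_loss": val_loss})
            if val_loss < best_val:
                best_val = val_loss
                best_epoch = epoch
                best_weights = [p.data.copy() for p in params]
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
        # restore the best-validation checkpoint
        for p, w in zip(params, best_weights):
            p.data = w
        return DTIResults(self, config, history, best_epoch, best_val)


class DTIResults:
    """Fit outcome: best-checkpoint weights, history, metrics, diagnostics."""

    def __init__(self, model: DTIModel, config: TrainConfig, history: list,
                 best_epoch: int, val_loss: float):
        self.model = model
        self.config = config
        self.history = history
        self.best_epoch = best_epoch
        self.stopped_epoch = history[-1]["epoch"]
        self.val_loss = val_loss
        self.param_count = model.param_count
        y_test = model._y[model.split.test]
        self.test_predictions = model.predict(model.split.test)
        self.metrics: MetricsReport = evaluate(y_test, self.test_predictions,
                                               param_count=self.param_count)

    def predict(self, idx) -> np.ndarray:
        return self.model.predict(idx)

    def history_frame(self):
        import pandas as pd
        return pd.DataFrame(self.history)

    # -- embedding extraction ------------------------------------------------
    def extract_embeddings(self, selector: str, triplet_idx=None) -> np.ndarray:
        """Activation rows for inspection (e.g. 2-D projection of embeddings).

        Selectors: ``compound_branch`` and ``protein_branch`` (the branch
        output embeddings), or ``head_hidden_k`` for the k-th hidden layer
        of an MLP head.  Rows follow ``triplet_idx`` order (default: the
        test partition).
        """
        m = self.model
        idx = np.asarray(triplet_idx if triplet_idx is not None else m.split.test)
        valid = ["compound_branch", "protein_branch"]
        if isinstance(m.network.head, MLPHead):
            valid += [f"head_hidden_{k}"
                      for k in range(len(m.network.head.layers) - 1)]
        if selector not in valid:
            raise ConfigurationError(
                f"unknown layer selector {selector!r}; valid selectors: {valid}"
            )
        G, H = m.network.embed(m._c_inputs, m._p_inputs)
        if selector == "compound_branch":
            return G.data[m._c_idx[idx]].copy()
        if selector == "protein_branch":
            return H.data[m._p_idx[idx]].copy()
        k = int(selector.rsplit("_", 1)[1])
        g = ag.constant(G.data[m._c_idx[idx]])
        h = ag.constant(H.data[m._p_idx[idx]])
        return m.network.head.hidden_activations(g, h)[k].data.copy()

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Two-branch DTI regression results",
            "=" * 48,
            f"dataset:          {m.dataset.summary()}",
            f"setting:          {m.split.setting} (seed {m.split.seed})",
            f"compound branch:  {m.compound_kind} | protein branch: {m.protein_kind}",
            f"aggregation:      {m.aggregation} | features: {m.features}",
            f"trainable params: {self.param_count}",
            f"epochs run:       {self.stopped_epoch} (best epoch {self.best_epoch})",
            f"val MSE (best):   {self.val_loss:.4f}",
            "-" * 48,
            f"test MSE:         {self.metrics.mse:.4f}",
            f"test R2:          {self.metrics.r2:.4f}",
            f"test CI:          {self.metrics.ci:.4f}",
            f"test pairs:       {self.metrics.n}",
        ]
        return "\n".join(lines)
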
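"""Random-search hyperparameter optimization and the capacity sweep.

``random_search`` samples a fixed budget of configurations i.i.d. from a
:class:`SearchSpace` with a master seed, trains each on the same split
with early stopping, and returns the trials sorted by validation loss;
``top_k_average`` from :mod:`dtiagg.metrics` then aggregates the best k.
``capacity_sweep`` trains a list of branch variants once each and
tabulates trainable-parameter count against test MSE — the comparison
that exposes the oversmoothing of deep message passing versus appending
fully-connected layers after a shallow MPNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DTIDataset
from .metrics import MetricsReport
from .model import DTIModel, TrainConfig
from .splits import SplitAssignment, make_split


class SearchSpaceError(ValueError):
    pass


@dataclass(frozen=True)
class SearchSpace:
    """Per-hyperparameter choices and ranges.

    ``embedding_dims`` are choices for the branch output dims; with the
    dot head a single shared D is sampled (the D1 == D2 restriction),
    otherwise D1 and D2 are sampled independently.  ``lr_range`` is
    sampled log-uniformly.
    """

    embedding_dims: tuple = (4, 8, 16, 32)
    compound_hidden: tuple = ((), (32,), (64, 32))
    protein_hidden: tuple = ((), (32,), (64, 32))
    head_hidden: tuple = ((16,), (64,), (64, 32))
    lr_range: tuple = (1e-4, 1e-2)
    batch_sizes: tuple = (None,)

    def __post_init__(self):
        for name in ("embedding_dims", "compound_hidden", "protein_hidden",
                     "head_hidden", "batch_sizes"):
            if len(getattr(self, name)) == 0:
                raise SearchSpaceError(f"search space field {name} is empty")
        lo, hi = self.lr_range
        if not (0 < lo <= hi):
            raise SearchSpaceError(f"bad learning-rate range {self.lr_range}")

    def sample(self, rng: np.random.Generator, aggregation: str) -> dict:
        def choice(seq):
            return seq[int(rng.integers(len(seq)))]

        if aggregation == "dot":
            d1 = d2 = choice(self.embedding_dims)
        else:
            d1 = choice(self.embedding_dims)
            d2 = choice(self.embedding_dims)
        lo, hi = self.lr_range
        config = {
            "compound_dim": d1,
            "protein_dim": d2,
            "compound_hidden": choice(self.compound_hidden),
            "protein_hidden": choice(self.protein_hidden),
            "lr": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "batch_size": choice(self.batch_sizes),
        }
        if aggregation == "mlp":
            config["head_hidden"] = choice(self.head_hidden)
        return config


@dataclass(frozen=True)
class TrialResult:
    config: dict
    val_loss: float
    epoch_stopped: int
    report: MetricsReport
    param_count: int
    seed: int


def random_search(space: SearchSpace, dataset: DTIDataset, setting: str,
                  budget: int = 10, seed: int = 0, *,
                  compound_branch: str = "mlp", protein_branch: str = "mlp",
                  aggregation: str = "dot", features: str = "explicit",
                  max_epochs: int = 30, patience: int = 5,
                  split: SplitAssignment | None = None,
                  model_kwargs: dict | None = None) -> list[TrialResult]:
    """Train ``budget`` sampled configurations; return trials sorted by val loss."""
    if budget < 1:
        raise SearchSpaceError("budget must be >= 1")
    if not isinstance(space, SearchSpace):
        raise SearchSpaceError("space must be a SearchSpace")
    if split is None:
        split = make_split(dataset, setting, seed=seed)
    master = np.random.default_rng(seed)
    # sample all configs up front so the draw depends only on the master seed
    configs = [space.sample(master, aggregation) for _ in range(budget)]

    trials = []
    for trial_no, cfg in enumerate(configs):
        head_kwargs = {}
        if aggregation == "mlp":
            head_kwargs["hidden"] = list(cfg["head_hidden"])
        model = DTIModel(
            dataset, split,
            compound_branch=compound_branch, protein_branch=protein_branch,
            aggregation=aggregation, features=features,
            compound_dim=cfg["compound_dim"], protein_dim=cfg["protein_dim"],
            compound_kwargs=_hidden_kwargs(compound_branch, cfg["compound_hidden"]),
            protein_kwargs=_hidden_kwargs(protein_branch, cfg["protein_hidden"]),
            head_kwargs=head_kwargs,
            seed=seed + 1000 + trial_no,
            **(model_kwargs or {}),
        )
        res = model.fit(TrainConfig(max_epochs=max_epochs, patience=patience,
                                    lr=cfg["lr"], batch_size=cfg["batch_size"],
                                    seed=seed + 2000 + trial_no))
        trials.append(TrialResult(config=cfg, val_loss=res.val_loss,
                                  epoch_stopped=res.stopped_epoch,
                                  report=res.metrics,
                                  param_count=res.param_count,
                                  seed=seed + 1000 + trial_no))
    return sorted(trials, key=lambda t: t.val_loss)


def _hidden_kwargs(branch_kind: str, hidden) -> dict:
    """Map a sampled hidden-layer tuple onto the branch's constructor."""
    if branch_kind == "mlp":
        return {"hidden": list(hidden)}
    if branch_kind == "mpnn_fc":
        return {"fc_hidden": list(hidden)} if hidden else {}
    return {}  # cnn / mpnn / embedding_lookup take their own capacity knobs


def trials_frame(trials: list[TrialResult]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({"val_loss": t.val_loss, "epoch_stopped": t.epoch_stopped,
                     "param_count": t.param_count, **t.report.as_dict(),
                     **{f"cfg_{k}": v for k, v in t.config.items()}})
    return pd.DataFrame(rows)


def capacity_sweep(branch_configs: list[dict], head_kinds: list[str],
                   dataset: DTIDataset, setting: str,
                   train_config: TrainConfig = TrainConfig(), *,
                   protein_branch: str = "mlp", embedding_dim: int = 8,
                   split: SplitAssignment | None = None, seed: int = 0,
                   n_restarts: int = 1,
                   model_kwargs: dict | None = None) -> pd.DataFrame:
    """Train each (compound-branch variant, head) pair and tabulate capacity.

    ``branch_configs`` entries: ``{"name": str, "kind": "mpnn"|"mpnn_fc"|...,
    "kwargs": {...}}``.  Each pair is fitted from ``n_restarts`` random
    initializations and the restart with the lowest validation loss is
    kept.  Returns a table of variant, head, param_count and test
    metrics — the capacity-versus-error comparison.
    """
    if split is None:
        split = make_split(dataset, setting, seed=seed)
    rows = []
    for bc in branch_configs:
        for head in head_kinds:
            res = None
            for restart in range(n_restarts):
                model = DTIModel(
                    dataset, split,
                    compound_branch=bc["kind"], protein_branch=protein_branch,
                    aggregation=head, embedding_dim=embedding_dim,
                    compound_kwargs=bc.get("kwargs", {}),
                    seed=seed * 100 + restart, **(model_kwargs or {}),
                )
                candidate = model.fit(train_config)
                if res is None or candidate.val_loss < res.val_loss:
                    res = candidate
            rows.append({"variant": bc["name"], "kind": bc["kind"], "head": head,
                         "param_count": res.param_count,
                         "test_mse": res.metrics.mse, "test_r2": res.metrics.r2,
                         "test_ci": res.metrics.ci})
    return pd.DataFrame(rows)
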
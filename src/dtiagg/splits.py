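"""Train/validation/test split construction for the three prediction settings.

- ``random``: the {compound, protein, affinity} triplets themselves are
  shuffled and partitioned by the ratios (matrix-completion setting);
- ``cold_drug``: the *drugs* are partitioned, every triplet follows its
  drug, so test drugs are never seen in training;
- ``cold_target``: the mirror image over proteins.

Default ratios are (0.70, 0.10, 0.20).  Partition sizes use
floor(ratio * n) for train and validation with the remainder going to
test, and every split is a pure function of (dataset, ratios, seed).
The fourth setting (cold drug AND cold target simultaneously) is
deliberately not provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import DTIDataset

SETTINGS = ("random", "cold_drug", "cold_target")
DEFAULT_RATIOS = (0.7, 0.1, 0.2)


class SplitError(ValueError):
    pass


@dataclass
class SplitAssignment:
    """Disjoint, covering partition of triplet indices with its provenance."""

    setting: str
    ratios: tuple[float, float, float]
    seed: int
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def partitions(self) -> dict[str, np.ndarray]:
        return {"train": self.train, "val": self.val, "test": self.test}

    def to_manifest(self, dataset: DTIDataset) -> dict:
        """JSON-serializable manifest (triplet keys per partition) for exact re-use."""
        out = {"setting": self.setting, "ratios": list(self.ratios), "seed": self.seed}
        for name, idx in self.partitions().items():
            out[name] = [[dataset.triplets[i].compound_id,
                          dataset.triplets[i].protein_id] for i in idx]
        return out

    def save(self, path, dataset: DTIDataset):
        Path(path).write_text(json.dumps(self.to_manifest(dataset), indent=1))


def _check_ratios(ratios):
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise SplitError(f"ratios must be 3 positive fractions, got {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise SplitError(f"ratios must sum to 1, got {ratios}")
    return ratios


def _partition_sizes(n: int, ratios) -> tuple[int, int, int]:
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    return n_train, n_val, n - n_train - n_val


def _finalize(setting, ratios, seed, train, val, test) -> SplitAssignment:
    if len(val) == 0:
        raise SplitError("validation partition received no triplets")
    if len(train) == 0 or len(test) == 0:
        raise SplitError("train and test partitions must be nonempty")
    return SplitAssignment(setting=setting, ratios=ratios, seed=seed,
                           train=np.sort(train), val=np.sort(val), test=np.sort(test))


def random_split(dataset: DTIDataset, ratios=DEFAULT_RATIOS, seed: int = 0) -> SplitAssignment:
    """Shuffle the triplets with ``seed`` and partition them by the ratios."""
    ratios = _check_ratios(ratios)
    n = dataset.n_triplets
    if n < 3:
        raise SplitError(f"need at least 3 triplets to split, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train, n_val, _ = _partition_sizes(n, ratios)
    return _finalize("random", ratios, seed,
                     perm[:n_train], perm[n_train:n_train + n_val],
                     perm[n_train + n_val:])


def _cold_split(dataset: DTIDataset, ratios, seed: int, over: str) -> SplitAssignment:
    ratios = _check_ratios(ratios)
    c_idx, p_idx, _ = dataset.triplet_arrays()
    entity_of_triplet = c_idx if over == "drug" else p_idx
    n_entities = dataset.n_compounds if over == "drug" else dataset.n_proteins
    if n_entities < 3:
        raise SplitError(
            f"cold_{over if over == 'drug' else 'target'} split needs >= 3 distinct "
            f"{over}s, got {n_entities}"
        )
    perm = np.random.default_rng(seed).permutation(n_entities)
    n_train, n_val, _ = _partition_sizes(n_entities, ratios)
    membership = np.empty(n_entities, dtype=np.intp)  # 0=train 1=val 2=test
    membership[perm[:n_train]] = 0
    membership[perm[n_train:n_train + n_val]] = 1
    membership[perm[n_train + n_val:]] = 2
    triplet_part = membership[entity_of_triplet]
    all_idx = np.arange(dataset.n_triplets)
    setting = "cold_drug" if over == "drug" else "cold_target"
    return _finalize(setting, ratios, seed,
                     all_idx[triplet_part == 0], all_idx[triplet_part == 1],
                     all_idx[triplet_part == 2])


def cold_drug_split(dataset: DTIDataset, ratios=DEFAULT_RATIOS, seed: int = 0) -> SplitAssignment:
    """Partition the drugs by the ratios; triplets follow their drug."""
    return _cold_split(dataset, ratios, seed, over="drug")


def cold_target_split(dataset: DTIDataset, ratios=DEFAULT_RATIOS, seed: int = 0) -> SplitAssignment:
    """Partition the proteins by the ratios; triplets follow their protein."""
    return _cold_split(dataset, ratios, seed, over="target")


def make_split(dataset: DTIDataset, setting: str, ratios=DEFAULT_RATIOS,
               seed: int = 0) -> SplitAssignment:
    if setting == "random":
        return random_split(dataset, ratios, seed)
    if setting == "cold_drug":
        return cold_drug_split(dataset, ratios, seed)
    if setting == "cold_target":
        return cold_target_split(dataset, ratios, seed)
    raise SplitError(f"unknown prediction setting {setting!r}; choose from {SETTINGS}")


def audit_split(dataset: DTIDataset, assignment: SplitAssignment) -> dict:
    """Leakage report: partition sizes, entity overlaps, contract pass/fail."""
    c_idx, p_idx, _ = dataset.triplet_arrays()
    parts = assignment.partitions()
    report: dict = {
        "setting": assignment.setting,
        "sizes": {k: int(len(v)) for k, v in parts.items()},
        "passed": True,
        "violations": [],
    }
    # triplet partition: disjoint and covering
    concat = np.concatenate([parts["train"], parts["val"], parts["test"]])
    covers = (len(concat) == dataset.n_triplets
              and len(np.unique(concat)) == dataset.n_triplets)
    report["covers_all_triplets"] = bool(covers)
    if not covers:
        report["passed"] = False
        report["violations"].append("triplet partition is not a disjoint cover")
    # entity overlap accounting
    for entity, idx_arr in (("drug", c_idx), ("target", p_idx)):
        sets = {k: set(idx_arr[v].tolist()) for k, v in parts.items()}
        overlaps = {}
        for a, b in (("train", "val"), ("train", "test"), ("val", "test")):
            shared = sets[a] & sets[b]
            overlaps[f"{a}/{b}"] = len(shared)
            must_be_cold = (assignment.setting == "cold_drug" and entity == "drug") or \
                           (assignment.setting == "cold_target" and entity == "target")
            if must_be_cold and shared:
                report["passed"] = False
                ids = sorted(shared)[:5]
                names = [dataset.compounds[i].compound_id if entity == "drug"
                         else dataset.proteins[i].protein_id for i in ids]
                report["violations"].append(
                    f"{entity} leakage between {a} and {b}: {names}"
                )
        report[f"{entity}_overlap"] = overlaps
    return report
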
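"""Synthetic drug-target affinity datasets with known low-rank ground truth.

The generator emulates the structure the two-branch models exploit: a
sparse compound x protein interaction matrix whose clean values are
U V' for latent factor matrices U (n_compounds x D*) and V
(n_proteins x D*), observed at a controllable density with additive
Gaussian noise.  With ``feature_link="none"`` the factors are i.i.d.
standard normal — pure matrix structure, learnable only by implicit
(identity) features under a random split.  With ``feature_link="linear"``
the factors are linear maps of explicit descriptors (Morgan fingerprints
for compounds, amino-acid composition for proteins), so explicit-feature
models can generalize to cold drugs/targets while implicit models cannot.

Compounds are drawn from a small combinatorial SMILES grammar (C/N/O
acyclic chains, optional branches, 5-6 membered rings) chosen so every
generated string is valid without a chemistry engine in the loop;
proteins are uniform random sequences over the 20-letter alphabet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import DTIDataset, InteractionTriplet
from .featurization import (AMINO_ACIDS, CompoundRecord, ProteinRecord,
                            composition_descriptor, morgan_fingerprint)

#: fingerprint size used for the linear feature link; must stay below the
#: training-drug count of a 70-10-20 cold split at default sizes so the
#: latent map is identifiable from the training partition alone
LINK_FP_BITS = 32
LINK_FP_RADIUS = 2


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_compounds: int = 60
    n_proteins: int = 40
    rank: int = 4                      # latent dimensionality D*
    noise_sd: float = 0.1              # sigma of additive Gaussian noise
    density: float = 0.5               # fraction of matrix cells observed
    feature_link: str = "none"         # "none" | "linear"
    seq_length_range: tuple[int, int] = (50, 120)
    seed: int = 0

    def __post_init__(self):
        if self.rank < 1:
            raise GenerationError("rank must be >= 1")
        if not 0.0 < self.density <= 1.0:
            raise GenerationError("density must be in (0, 1]")
        if self.density * self.n_compounds * self.n_proteins < 3:
            raise GenerationError("spec yields fewer than 3 observed triplets")
        if self.feature_link not in ("none", "linear"):
            raise GenerationError("feature_link must be 'none' or 'linear'")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Latent factors (and link maps, when the factors are feature-driven)."""

    U: np.ndarray                       # n_compounds x D*
    V: np.ndarray                       # n_proteins x D*
    A: np.ndarray | None = None         # fingerprint -> U link map
    B: np.ndarray | None = None         # composition -> V link map

    def clean_affinity(self, i: int, j: int) -> float:
        return float(self.U[i] @ self.V[j])

    def clean_matrix(self) -> np.ndarray:
        return self.U @ self.V.T


# ---------------------------------------------------------------------------
# entity generators
# ---------------------------------------------------------------------------

_CHAIN_ATOMS = ["C", "N", "O"]
_RING_TEMPLATES = ["C1CCCC1", "C1CCCCC1", "C1CCOC1", "C1CCNC1",
                   "C1CCOCC1", "C1CCNCC1", "C1CCCCC1O", "C1CCCC1N"]


def generate_smiles(n: int, seed: int = 0) -> list[str]:
    """n distinct valid SMILES from a C/N/O chain-and-ring grammar.

    Chains are single-bonded runs of C/N/O (any such run is valid);
    branch points are restricted to carbon so no valence is exceeded.
    """
    if n < 1:
        raise GenerationError("n must be >= 1")
    # loose upper bound on distinct strings the grammar can emit
    capacity = len(_RING_TEMPLATES) * 3 ** 3 + sum(3 ** L * (1 + (L - 2) * 3)
                                                   for L in range(2, 9))
    if n > capacity:
        raise GenerationError(
            f"n={n} exceeds the grammar's capacity of ~{capacity} distinct strings"
        )
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    stagnant = 0
    while len(out) < n:
        if stagnant > 5000:
            raise GenerationError(
                f"grammar capacity exhausted after {len(out)} of {n} strings"
            )
        if rng.random() < 0.25:
            smi = str(rng.choice(_RING_TEMPLATES))
            tail_len = int(rng.integers(0, 4))
            smi += "".join(rng.choice(_CHAIN_ATOMS, size=tail_len))
        else:
            length = int(rng.integers(2, 9))
            atoms = [str(a) for a in rng.choice(_CHAIN_ATOMS, size=length)]
            if length >= 4 and rng.random() < 0.5:
                pos = int(rng.integers(1, length - 1))
                atoms[pos] = "C(" + str(rng.choice(_CHAIN_ATOMS)) + ")"
            smi = "".join(atoms)
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
            stagnant = 0
        else:
            stagnant += 1
    return out


def generate_sequences(n: int, length_range: tuple[int, int] = (50, 120),
                       seed: int = 0) -> list[str]:
    """n i.i.d. uniform amino-acid sequences with lengths in the range."""
    if n < 1:
        raise GenerationError("n must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise GenerationError(f"bad length range {length_range}")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    seqs = []
    for _ in range(n):
        L = int(rng.integers(lo, hi + 1))
        seqs.append("".join(rng.choice(letters, size=L)))
    return seqs


# ---------------------------------------------------------------------------
# dataset generator
# ---------------------------------------------------------------------------

def _standardize_columns(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0, keepdims=True)
    sd = M.std(axis=0, keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (M - mu) / sd


def generate_dataset(spec: SyntheticSpec) -> tuple[DTIDataset, GroundTruth]:
    """Materialize a dataset and its ground truth from a spec.

    Observed cells are a seeded uniform sample (without replacement) of
    the matrix at the requested density; observed affinity is the clean
    low-rank value plus N(0, noise_sd^2) noise.
    """
    rng = np.random.default_rng(spec.seed)
    smiles = generate_smiles(spec.n_compounds, seed=spec.seed)
    seqs = generate_sequences(spec.n_proteins, spec.seq_length_range,
                              seed=spec.seed + 1)
    compounds = [CompoundRecord(f"cmpd_{i:04d}", s) for i, s in enumerate(smiles)]
    proteins = [ProteinRecord(f"prot_{j:04d}", s) for j, s in enumerate(seqs)]

    if spec.feature_link == "none":
        U = rng.standard_normal((spec.n_compounds, spec.rank))
        V = rng.standard_normal((spec.n_proteins, spec.rank))
        truth = GroundTruth(U=U, V=V)
    else:
        F = np.stack([morgan_fingerprint(s, LINK_FP_RADIUS, LINK_FP_BITS).bits
                      for s in smiles])
        C = np.stack([composition_descriptor(s).freqs for s in seqs])
        A = rng.standard_normal((LINK_FP_BITS, spec.rank))
        B = rng.standard_normal((C.shape[1], spec.rank))
        # column z-scoring keeps unit-scale factors (still affine in features)
        U = _standardize_columns(F @ A)
        V = _standardize_columns(C @ B)
        truth = GroundTruth(U=U, V=V, A=A, B=B)

    n_cells = spec.n_compounds * spec.n_proteins
    n_obs = max(3, int(round(spec.density * n_cells)))
    cells = rng.choice(n_cells, size=n_obs, replace=False)
    clean = truth.clean_matrix()
    noise = rng.normal(0.0, spec.noise_sd, size=n_obs)
    triplets = []
    for cell, eps in zip(cells, noise):
        i, j = divmod(int(cell), spec.n_proteins)
        triplets.append(InteractionTriplet(
            compounds[i].compound_id, proteins[j].protein_id,
            float(clean[i, j] + eps)))
    dataset = DTIDataset(compounds, proteins, triplets,
                         name=f"synthetic(rank={spec.rank},link={spec.feature_link})")
    return dataset, truth


def mf_equivalence_fixture(spec: SyntheticSpec):
    """Dataset + random split + the model config whose fit is matrix factorization.

    The implicit-feature (embedding-lookup) branches aggregated by the
    dot product, with embedding dimension equal to the spec's latent
    rank, are exactly a learned rank-D* factorization of the observed
    interaction matrix.
    """
    if spec.feature_link != "none":
        raise GenerationError("mf_equivalence_fixture requires feature_link='none'")
    from .splits import random_split
    dataset, truth = generate_dataset(spec)
    assignment = random_split(dataset, seed=spec.seed)
    config = {
        "compound_branch": "embedding_lookup",
        "protein_branch": "embedding_lookup",
        "aggregation": "dot",
        "embedding_dim": spec.rank,
    }
    return dataset, assignment, config, truth


# ---------------------------------------------------------------------------
# writers (the `dti simulate` output)
# ---------------------------------------------------------------------------

def write_dataset(dataset: DTIDataset, truth: GroundTruth, outdir) -> dict:
    """Write triplet TSV + compound TSV + protein FASTA + ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "triplets": outdir / "triplets.tsv",
        "compounds": outdir / "compounds.tsv",
        "proteins": outdir / "proteins.fasta",
        "ground_truth": outdir / "ground_truth.json",
    }
    with open(paths["triplets"], "w") as fh:
        for t in dataset.triplets:
            fh.write(f"{t.compound_id}\t{t.protein_id}\t{t.affinity:.10g}\n")
    with open(paths["compounds"], "w") as fh:
        for c in dataset.compounds:
            fh.write(f"{c.compound_id}\t{c.smiles}\n")
    with open(paths["proteins"], "w") as fh:
        for p in dataset.proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")
    gt = {"U": truth.U.tolist(), "V": truth.V.tolist()}
    if truth.A is not None:
        gt["A"] = truth.A.tolist()
        gt["B"] = truth.B.tolist()
    paths["ground_truth"].write_text(json.dumps(gt))
    return {k: str(v) for k, v in paths.items()}
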
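"""Dataset container and loaders for drug-target affinity benchmarks.

A dataset is a sparse compound x protein interaction matrix stored as
{compound, protein, affinity} triplets with referential integrity.
Two on-disk layouts are read:

- the DeepPurpose-style benchmark layout (Davis / KIBA): an affinity
  matrix file with NaN for unmeasured pairs plus compound SMILES and
  protein sequence files (JSON id->string dicts or plain line lists);
- a generic layout: triplet TSV (compound_id, protein_id, affinity),
  compound TSV (id, smiles), and protein FASTA or TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .featurization import CompoundRecord, ProteinRecord


class LoadingError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionTriplet:
    compound_id: str
    protein_id: str
    affinity: float


@dataclass
class DTIDataset:
    """Compounds, proteins and affinity triplets (the sparse interaction matrix)."""

    compounds: list[CompoundRecord]
    proteins: list[ProteinRecord]
    triplets: list[InteractionTriplet]
    name: str = "dataset"
    compound_index: dict = field(init=False, repr=False)
    protein_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.compound_index = {c.compound_id: i for i, c in enumerate(self.compounds)}
        self.protein_index = {p.protein_id: i for i, p in enumerate(self.proteins)}
        if len(self.compound_index) != len(self.compounds):
            raise LoadingError("duplicate compound ids")
        if len(self.protein_index) != len(self.proteins):
            raise LoadingError("duplicate protein ids")
        if not self.triplets:
            raise LoadingError("dataset must contain at least one triplet")
        seen = set()
        for t in self.triplets:
            if t.compound_id not in self.compound_index:
                raise LoadingError(f"triplet references unknown compound {t.compound_id!r}")
            if t.protein_id not in self.protein_index:
                raise LoadingError(f"triplet references unknown protein {t.protein_id!r}")
            key = (t.compound_id, t.protein_id)
            if key in seen:
                raise LoadingError(f"duplicate (compound, protein) pair {key}")
            seen.add(key)

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_triplets(self) -> int:
        return len(self.triplets)

    def triplet_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(compound_idx, protein_idx, affinity) arrays over all triplets."""
        c = np.array([self.compound_index[t.compound_id] for t in self.triplets])
        p = np.array([self.protein_index[t.protein_id] for t in self.triplets])
        y = np.array([t.affinity for t in self.triplets], dtype=float)
        return c, p, y

    def summary(self) -> str:
        return (f"{self.name}: {self.n_compounds} drugs, {self.n_proteins} targets, "
                f"{self.n_triplets} interactions")


# ---------------------------------------------------------------------------
# affinity transforms
# ---------------------------------------------------------------------------

def davis_log_transform(kd_nm: np.ndarray) -> np.ndarray:
    """pKd = -log10(Kd / 1e9) for Kd in nanomolar (common Davis practice)."""
    return -np.log10(np.asarray(kd_nm, dtype=float) / 1e9)


_TRANSFORMS = {None: None, "none": None, "davis_log": davis_log_transform}


def _resolve_transform(affinity_transform):
    if callable(affinity_transform):
        return affinity_transform
    try:
        return _TRANSFORMS[affinity_transform]
    except KeyError:
        raise LoadingError(f"unknown affinity transform {affinity_transform!r}") from None


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def _read_named_strings(path: Path, prefix: str) -> list[tuple[str, str]]:
    """Read a JSON id->string dict or a plain one-string-per-line file."""
    text = path.read_text().strip()
    if not text:
        raise LoadingError(f"{path}: empty file")
    if text[0] == "{":
        try:
            mapping = json.loads(text)
        except json.JSONDecodeError as exc:
            raise LoadingError(f"{path}: invalid JSON ({exc})") from exc
        return [(str(k), str(v)) for k, v in mapping.items()]
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    return [(f"{prefix}{i}", ln) for i, ln in enumerate(lines)]


def load_benchmark(path, affinity_transform=None, name: str | None = None,
                   allow_unknown_residues: bool = True) -> DTIDataset:
    """Load a DeepPurpose-layout benchmark directory.

    Expects ``affinity.txt`` (whitespace-separated drugs x targets matrix,
    ``NaN`` marking unmeasured pairs), ``SMILES.txt`` and
    ``target_seq.txt``.  Unmeasured entries are excluded from the triplet
    list.  ``affinity_transform`` is None, "davis_log", or a callable
    applied to the affinity values.
    """
    path = Path(path)
    matrix_file = path / "affinity.txt"
    smiles_file = path / "SMILES.txt"
    target_file = path / "target_seq.txt"
    for f in (matrix_file, smiles_file, target_file):
        if not f.exists():
            raise LoadingError(f"benchmark file missing: {f}")
    compounds = [CompoundRecord(cid, smi)
                 for cid, smi in _read_named_strings(smiles_file, "drug")]
    proteins = [ProteinRecord(pid, seq, allow_unknown=allow_unknown_residues)
                for pid, seq in _read_named_strings(target_file, "target")]
    rows = []
    for lineno, line in enumerate(matrix_file.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rows.append([float(v) for v in line.replace(",", " ").split()])
        except ValueError as exc:
            raise LoadingError(f"{matrix_file}:{lineno}: {exc}") from exc
    matrix = np.array(rows, dtype=float)
    if matrix.shape != (len(compounds), len(proteins)):
        raise LoadingError(
            f"{matrix_file}: matrix shape {matrix.shape} does not match "
            f"{len(compounds)} compounds x {len(proteins)} proteins"
        )
    transform = _resolve_transform(affinity_transform)
    triplets = []
    for i, c in enumerate(compounds):
        for j, p in enumerate(proteins):
            y = matrix[i, j]
            if np.isnan(y):
                continue
            if transform is not None:
                y = float(transform(y))
            triplets.append(InteractionTriplet(c.compound_id, p.protein_id, float(y)))
    return DTIDataset(compounds, proteins, triplets, name=name or path.name)


def load_davis(path, log_transform: bool = True) -> DTIDataset:
    """Davis kinase benchmark; raw Kd (nM) log-transformed to pKd by default."""
    return load_benchmark(path, affinity_transform="davis_log" if log_transform else None,
                          name="DAVIS")


def load_kiba(path) -> DTIDataset:
    """KIBA benchmark; KIBA scores are used as distributed."""
    return load_benchmark(path, affinity_transform=None, name="KIBA")


def read_compounds_tsv(path) -> list[CompoundRecord]:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise LoadingError(f"{path}:{lineno}: expected 2 tab-separated columns")
        records.append(CompoundRecord(parts[0], parts[1]))
    return records


def read_proteins_tsv(path, allow_unknown: bool = False) -> list[ProteinRecord]:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise LoadingError(f"{path}:{lineno}: expected 2 tab-separated columns")
        records.append(ProteinRecord(parts[0], parts[1], allow_unknown=allow_unknown))
    return records


def read_proteins_fasta(path, allow_unknown: bool = False) -> list[ProteinRecord]:
    records = [ProteinRecord(rec.id, str(rec.seq).upper(), allow_unknown=allow_unknown)
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise LoadingError(f"{path}: no FASTA records found")
    return records


def read_triplets_tsv(path) -> list[InteractionTriplet]:
    triplets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise LoadingError(f"{path}:{lineno}: expected 3 tab-separated columns")
        try:
            affinity = float(parts[2])
        except ValueError as exc:
            raise LoadingError(f"{path}:{lineno}: bad affinity {parts[2]!r}") from exc
        triplets.append(InteractionTriplet(parts[0], parts[1], affinity))
    return triplets


def load_triplet_dataset(triplets_tsv, compounds_tsv, proteins_path,
                         name: str = "dataset",
                         allow_unknown_residues: bool = False) -> DTIDataset:
    """Assemble a dataset from the generic triplet/compound/protein files."""
    proteins_path = Path(proteins_path)
    if proteins_path.suffix.lower() in (".fa", ".fasta", ".faa"):
        proteins = read_proteins_fasta(proteins_path, allow_unknown=allow_unknown_residues)
    else:
        proteins = read_proteins_tsv(proteins_path, allow_unknown=allow_unknown_residues)
    return DTIDataset(read_compounds_tsv(compounds_tsv), proteins,
                      read_triplets_tsv(triplets_tsv), name=name)
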
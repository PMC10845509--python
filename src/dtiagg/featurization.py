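"""Explicit and implicit feature representations for compounds and proteins.

Compounds arrive as SMILES strings and proteins as amino-acid sequences.
Four explicit representations are produced here — Morgan (circular)
fingerprints, amino-acid composition descriptors, label-encoded token
sequences for 1-D CNN branches, and heavy-atom molecular graphs for MPNN
branches — plus the one-hot *implicit* representation that encodes only
an entity's identity.  All featurizers are pure functions: the same
input always yields a bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

#: canonical 20-letter amino-acid alphabet, alphabetical order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: symbol nonstandard residues are mapped to when allow_unknown=True
UNKNOWN_RESIDUE = "X"

_ORGANIC_ELEMENTS = ["C", "N", "O", "S", "F", "P", "Cl", "Br", "I"]
_MAX_DEGREE = 5
ATOM_FEATURE_DIM = len(_ORGANIC_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1 + 1
BOND_FEATURE_DIM = 5  # single / double / triple / aromatic + in-ring


class FeaturizationError(ValueError):
    """Raised when a raw record cannot be converted to features."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str

    def __post_init__(self):
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise FeaturizationError(
                f"compound {self.compound_id!r}: invalid SMILES {self.smiles!r}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    allow_unknown: bool = False

    def __post_init__(self):
        validate_sequence(self.sequence, allow_unknown=self.allow_unknown,
                          context=f"protein {self.protein_id!r}")


def validate_sequence(sequence: str, allow_unknown: bool = False,
                      context: str = "sequence") -> str:
    """Check a protein sequence against the canonical alphabet.

    Returns the sequence with nonstandard residues replaced by
    :data:`UNKNOWN_RESIDUE` when ``allow_unknown`` is set; otherwise any
    letter outside the 20-letter alphabet raises a featurization error.
    """
    if not sequence:
        raise FeaturizationError(f"{context}: empty sequence")
    allowed = set(AMINO_ACIDS)
    cleaned = []
    for ch in sequence:
        if ch in allowed:
            cleaned.append(ch)
        elif allow_unknown:
            cleaned.append(UNKNOWN_RESIDUE)
        else:
            raise FeaturizationError(
                f"{context}: nonstandard residue {ch!r} "
                f"(pass allow_unknown=True to map it to {UNKNOWN_RESIDUE!r})"
            )
    return "".join(cleaned)


# ---------------------------------------------------------------------------
# feature containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintVector:
    bits: np.ndarray
    radius: int
    n_bits: int

    def __post_init__(self):
        assert self.bits.shape == (self.n_bits,)
        assert set(np.unique(self.bits)).issubset({0, 1})


@dataclass(frozen=True)
class CompositionDescriptor:
    freqs: np.ndarray
    k: int = 1

    def __post_init__(self):
        assert np.all(self.freqs >= 0)
        assert abs(self.freqs.sum() - 1.0) < 1e-9


@dataclass(frozen=True)
class TokenSequence:
    tokens: np.ndarray
    vocab: dict
    pad_index: int = 0

    def __post_init__(self):
        assert self.tokens.max(initial=0) < len(self.vocab) + 1


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom skeleton with per-atom and per-bond feature rows."""
    atom_features: np.ndarray   # (n_atoms, ATOM_FEATURE_DIM)
    bonds: np.ndarray           # (n_bonds, 2) undirected atom-index pairs
    bond_features: np.ndarray   # (n_bonds, BOND_FEATURE_DIM)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]


@dataclass(frozen=True)
class ImplicitVector:
    """One-hot dummy vector identifying one entity among ``length``."""
    index: int
    length: int

    def __post_init__(self):
        if not 0 <= self.index < self.length:
            raise FeaturizationError(
                f"one-hot index {self.index} out of range [0, {self.length})"
            )

    def materialize(self) -> np.ndarray:
        vec = np.zeros(self.length)
        vec[self.index] = 1.0
        return vec


# ---------------------------------------------------------------------------
# featurizers
# ---------------------------------------------------------------------------

def _parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    return mol


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024) -> FingerprintVector:
    """Circular (Morgan/ECFP-style) fingerprint of a molecule.

    ``radius=2`` corresponds to the ECFP4 neighbourhood size.
    """
    if radius < 0 or n_bits < 1:
        raise ValueError("radius must be >= 0 and n_bits >= 1")
    mol = _parse_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.array(gen.GetFingerprintAsNumPy(mol), dtype=np.float64)
    return FingerprintVector(bits=arr, radius=radius, n_bits=n_bits)


def composition_descriptor(sequence: str, k: int = 1,
                           allow_unknown: bool = False) -> CompositionDescriptor:
    """k-mer composition of a protein sequence (default: monomer frequencies).

    For ``k=1`` this is the 20-dimensional amino-acid composition vector
    freqs[a] = count(a) / len(sequence); ``k=2`` gives the 400 dipeptide
    frequencies.  With ``allow_unknown`` the alphabet gains a 21st symbol.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    seq = validate_sequence(sequence, allow_unknown=allow_unknown)
    alphabet = AMINO_ACIDS + (UNKNOWN_RESIDUE if allow_unknown else "")
    index = {a: i for i, a in enumerate(alphabet)}
    A = len(alphabet)
    if k == 1:
        freqs = np.zeros(A)
        for ch in seq:
            freqs[index[ch]] += 1
        freqs /= len(seq)
    else:
        if len(seq) < 2:
            raise FeaturizationError("k=2 composition requires length >= 2")
        freqs = np.zeros(A * A)
        for a, b in zip(seq[:-1], seq[1:]):
            freqs[index[a] * A + index[b]] += 1
        freqs /= len(seq) - 1
    return CompositionDescriptor(freqs=freqs, k=k)


def build_vocab(corpus: list[str]) -> dict:
    """Character vocabulary from a training corpus; index 0 is reserved for pad."""
    chars = sorted({ch for s in corpus for ch in s})
    return {ch: i + 1 for i, ch in enumerate(chars)}


def _encode(string: str, vocab: dict, max_len: int, what: str) -> TokenSequence:
    if not string:
        raise FeaturizationError(f"empty {what} cannot be encoded")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tokens = np.zeros(max_len, dtype=np.intp)
    for i, ch in enumerate(string[:max_len]):
        if ch not in vocab:
            raise FeaturizationError(f"{what} character {ch!r} absent from vocabulary")
        tokens[i] = vocab[ch]
    return TokenSequence(tokens=tokens, vocab=vocab)


def encode_smiles(smiles: str, vocab: dict, max_len: int = 100) -> TokenSequence:
    """Label-encode a SMILES string to a fixed-length padded index sequence."""
    return _encode(smiles, vocab, max_len, "SMILES")


def encode_protein(sequence: str, vocab: dict, max_len: int = 1000) -> TokenSequence:
    """Label-encode a protein sequence to a fixed-length padded index sequence."""
    return _encode(sequence, vocab, max_len, "protein")


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    f = np.zeros(ATOM_FEATURE_DIM)
    sym = atom.GetSymbol()
    try:
        f[_ORGANIC_ELEMENTS.index(sym)] = 1.0
    except ValueError:
        f[len(_ORGANIC_ELEMENTS)] = 1.0  # "other" element slot
    off = len(_ORGANIC_ELEMENTS) + 1
    f[off + min(atom.GetDegree(), _MAX_DEGREE)] = 1.0
    off += _MAX_DEGREE + 1
    f[off] = atom.GetFormalCharge()
    f[off + 1] = 1.0 if atom.GetIsAromatic() else 0.0
    return f


_BOND_ORDER_SLOT = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    f = np.zeros(BOND_FEATURE_DIM)
    f[_BOND_ORDER_SLOT.get(bond.GetBondType(), 0)] = 1.0
    f[4] = 1.0 if bond.IsInRing() else 0.0
    return f


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Heavy-atom molecular graph: one node per heavy atom, one edge per bond.

    Hydrogens stay implicit.  Atom rows carry element one-hot (organic
    subset + other), degree one-hot, formal charge and an aromatic flag;
    bond rows carry bond-order one-hot and a ring flag.
    """
    mol = _parse_smiles(smiles)
    n = mol.GetNumAtoms()
    atoms = np.stack([_atom_features(mol.GetAtomWithIdx(i)) for i in range(n)]) \
        if n else np.zeros((0, ATOM_FEATURE_DIM))
    bonds, bf = [], []
    for bond in mol.GetBonds():
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bf.append(_bond_features(bond))
    bonds_arr = np.array(bonds, dtype=np.intp).reshape(-1, 2)
    bf_arr = np.stack(bf) if bf else np.zeros((0, BOND_FEATURE_DIM))
    return MolecularGraph(atom_features=atoms, bonds=bonds_arr, bond_features=bf_arr)


def one_hot(index: int, length: int) -> ImplicitVector:
    """Implicit (identity-only) feature: a one-hot vector of ``length``."""
    return ImplicitVector(index=index, length=length)
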
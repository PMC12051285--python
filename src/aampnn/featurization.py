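"""SMILES → directed molecular graph and fingerprint featurization.

Molecules are encoded as directed graphs: every chemical bond
contributes two directed edges (v→w and w→v), each carrying the same
bond feature vector, so that messages can flow along bonds while
excluding the reverse direction.  Atom and bond descriptors are
concatenated one-hot blocks; the full category lists — the single
authoritative definition of the encoding — are the module-level
``ATOM_FEATURE_BLOCKS`` / ``BOND_FEATURE_BLOCKS`` below.

Atom feature rows carry one extra trailing column, the *mask slot*: it
is 0 for every real atom and 1 only in the mask token used by the
contrastive-pretraining augmentation, which guarantees the token is
distinct from every valid atom encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class ValidationError(ValueError):
    """Raised when a parsed input violates a structural precondition."""


# ----------------------------------------------------------------------
# feature schemas
# ----------------------------------------------------------------------

#: (name, categories, has_unknown_bucket) per one-hot block.
ATOM_FEATURE_BLOCKS: tuple[tuple[str, list, bool], ...] = (
    ("atomic_number", list(range(1, 101)), True),
    ("degree", [0, 1, 2, 3, 4, 5], True),
    ("formal_charge", [-2, -1, 0, 1, 2], True),
    ("chirality", ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW",
                   "CHI_TETRAHEDRAL_CCW", "CHI_OTHER"], False),
    ("num_hs", [0, 1, 2, 3, 4], True),
    ("hybridization", ["SP", "SP2", "SP3", "SP3D", "SP3D2"], True),
)

BOND_FEATURE_BLOCKS: tuple[tuple[str, list, bool], ...] = (
    ("bond_type", ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"], False),
    ("in_ring", [False, True], False),
    ("stereo", ["STEREONONE", "STEREOANY", "STEREOZ", "STEREOE",
                "STEREOCIS", "STEREOTRANS"], False),
)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered one-hot blocks; ``total_width`` is the sum of block widths."""

    blocks: tuple[tuple[str, list, bool], ...]

    @property
    def total_width(self) -> int:
        return sum(len(cats) + int(unk) for _, cats, unk in self.blocks)

    def encode(self, values: dict) -> np.ndarray:
        """One-hot encode ``{block name: value}``; unlisted values fall in
        the unknown bucket (an error if the block has none)."""
        out = np.zeros(self.total_width)
        offset = 0
        for name, cats, unk in self.blocks:
            width = len(cats) + int(unk)
            v = values[name]
            if v in cats:
                out[offset + cats.index(v)] = 1.0
            elif unk:
                out[offset + width - 1] = 1.0
            else:
                raise ValidationError(
                    f"value {v!r} not a category of block {name!r}")
            offset += width
        return out


ATOM_SCHEMA = FeatureSchema(ATOM_FEATURE_BLOCKS)
BOND_SCHEMA = FeatureSchema(BOND_FEATURE_BLOCKS)

#: index of the mask-slot column appended to every atom feature row
MASK_SLOT = ATOM_SCHEMA.total_width


def mask_token(atom_schema: FeatureSchema = ATOM_SCHEMA) -> np.ndarray:
    """The mask-token feature row: all-zeros with the mask slot set."""
    token = np.zeros(atom_schema.total_width + 1)
    token[-1] = 1.0
    return token


# ----------------------------------------------------------------------
# molecular graph
# ----------------------------------------------------------------------

@dataclass
class MolGraph:
    """Directed molecular graph consumed by the encoder.

    ``atom_features`` has shape (n_atoms, atom_schema.total_width + 1);
    the trailing column is the mask slot (0 for real atoms).  Directed
    bonds come in reverse pairs: ``reverse_index[b]`` is the index of
    the opposite-direction edge of bond ``b``.
    """

    n_atoms: int
    atom_features: np.ndarray
    directed_bonds: list[tuple[int, int]]
    bond_features: np.ndarray
    reverse_index: np.ndarray
    smiles_canonical: str
    incoming_bonds: list[list[int]] = field(default_factory=list)

    @property
    def n_directed_bonds(self) -> int:
        return len(self.directed_bonds)

    @property
    def bond_sources(self) -> np.ndarray:
        return np.array([v for v, _ in self.directed_bonds], dtype=np.intp)

    @property
    def bond_targets(self) -> np.ndarray:
        return np.array([w for _, w in self.directed_bonds], dtype=np.intp)


def _atom_values(atom: Chem.Atom) -> dict:
    return {
        "atomic_number": atom.GetAtomicNum(),
        "degree": atom.GetDegree(),
        "formal_charge": atom.GetFormalCharge(),
        "chirality": str(atom.GetChiralTag()),
        "num_hs": atom.GetTotalNumHs(),
        "hybridization": str(atom.GetHybridization()),
    }


def _bond_values(bond: Chem.Bond) -> dict:
    return {
        "bond_type": str(bond.GetBondType()),
        "in_ring": bond.IsInRing(),
        "stereo": str(bond.GetStereo()),
    }


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def featurize_molecule(smiles: str,
                       atom_schema: FeatureSchema = ATOM_SCHEMA,
                       bond_schema: FeatureSchema = BOND_SCHEMA) -> MolGraph:
    """Convert a SMILES string into a :class:`MolGraph`.

    Hydrogens stay implicit (they enter only through the H-count
    feature); chirality falls back to the "unspecified" category and
    bond stereo to "none" when the SMILES carries no annotation.
    """
    mol = _parse(smiles)
    n_atoms = mol.GetNumAtoms()
    if n_atoms == 0:
        raise ValidationError(f"no heavy atoms in input: {smiles!r}")

    x = np.zeros((n_atoms, atom_schema.total_width + 1))
    for atom in mol.GetAtoms():
        x[atom.GetIdx(), :-1] = atom_schema.encode(_atom_values(atom))

    directed: list[tuple[int, int]] = []
    bond_rows: list[np.ndarray] = []
    for bond in mol.GetBonds():
        v, w = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        e = bond_schema.encode(_bond_values(bond))
        directed.append((v, w))
        bond_rows.append(e)
        directed.append((w, v))
        bond_rows.append(e)

    n_bonds = len(directed)
    reverse = np.arange(n_bonds, dtype=np.intp)
    reverse[0::2] += 1
    reverse[1::2] -= 1

    incoming: list[list[int]] = [[] for _ in range(n_atoms)]
    for b, (_, w) in enumerate(directed):
        incoming[w].append(b)

    return MolGraph(
        n_atoms=n_atoms,
        atom_features=x,
        directed_bonds=directed,
        bond_features=(np.array(bond_rows)
                       if bond_rows else np.zeros((0, bond_schema.total_width))),
        reverse_index=reverse,
        smiles_canonical=Chem.MolToSmiles(mol),
        incoming_bonds=incoming,
    )


# ----------------------------------------------------------------------
# fingerprints
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Fingerprint:
    """Extended-connectivity (Morgan) fingerprint as a 0/1 bit vector."""

    bits: np.ndarray
    radius: int
    n_bits: int

    def tanimoto(self, other: "Fingerprint") -> float:
        a, b = self.bits.astype(bool), other.bits.astype(bool)
        union = np.logical_or(a, b).sum()
        if union == 0:
            return 0.0
        return float(np.logical_and(a, b).sum() / union)


def compute_ecfp(smiles: str, radius: int = 2,
                 n_bits: int = 2048) -> Fingerprint:
    """Morgan/ECFP bit vector of a molecule; ECFP diameter = 2 × radius."""
    mol = _parse(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.float64)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1.0
    return Fingerprint(bits=arr, radius=radius, n_bits=n_bits)


def canonical_ranks(smiles: str) -> list[int]:
    """Canonical atom ranks; maps between atom orderings of one molecule."""
    mol = _parse(smiles)
    return list(Chem.CanonicalRankAtoms(mol, breakTies=True))
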
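"""Peptide chemistry: amino-acid sequences to explicit-hydrogen molecules.

A peptide chain is assembled by amide condensation of free amino acids: each
junction eliminates one water, so an n-mer's molecular formula is the sum of
the free-residue formulas minus (n-1) x H2O.  Residue chemistry (atoms, bonds,
aromaticity, stereocentres) is delegated to RDKit via curated per-residue
SMILES fragments; the extracted :class:`Molecule` is a plain-Python container
so downstream featurization does not depend on the toolkit's object model.

An MHC pseudo-sequence and a candidate peptide are presented to the classifier
as a single *disconnected* molecule (SMILES ``.`` notation): two covalently
independent components in one graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from rdkit import Chem

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "InvalidSequenceError",
    "CANONICAL_AMINO_ACIDS",
    "RESIDUE_FORMULAS",
    "build_peptide",
    "combine",
    "to_smiles",
    "molecular_formula",
    "peptide_smiles",
]

CANONICAL_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Backbone fragment is N[C@@H](<side chain>)C(=O); glycine has no stereocentre
# and proline's backbone nitrogen sits in the pyrrolidine ring.  Chaining the
# fragments and appending a terminal "O" yields the neutral peptide with free
# -NH2 and -COOH termini (no zwitterion).
_RESIDUE_FRAGMENTS: dict[str, str] = {
    "A": "N[C@@H](C)C(=O)",
    "R": "N[C@@H](CCCNC(=N)N)C(=O)",
    "N": "N[C@@H](CC(N)=O)C(=O)",
    "D": "N[C@@H](CC(O)=O)C(=O)",
    "C": "N[C@@H](CS)C(=O)",
    "E": "N[C@@H](CCC(O)=O)C(=O)",
    "Q": "N[C@@H](CCC(N)=O)C(=O)",
    "G": "NCC(=O)",
    "H": "N[C@@H](Cc1c[nH]cn1)C(=O)",
    "I": "N[C@@H]([C@@H](C)CC)C(=O)",
    "L": "N[C@@H](CC(C)C)C(=O)",
    "K": "N[C@@H](CCCCN)C(=O)",
    "M": "N[C@@H](CCSC)C(=O)",
    "F": "N[C@@H](Cc1ccccc1)C(=O)",
    "P": "N1CCC[C@H]1C(=O)",
    "S": "N[C@@H](CO)C(=O)",
    "T": "N[C@@H]([C@@H](O)C)C(=O)",
    "W": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)",
    "Y": "N[C@@H](Cc1ccc(O)cc1)C(=O)",
    "V": "N[C@@H](C(C)C)C(=O)",
}

#: Molecular formulas of the free (unbound) canonical amino acids.  These are
#: textbook constants and serve as the independent oracle for the condensation
#: arithmetic: formula(n-mer) = sum(residues) - (n-1) * {H: 2, O: 1}.
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 5, "N": 1, "O": 2},
    "A": {"C": 3, "H": 7, "N": 1, "O": 2},
    "S": {"C": 3, "H": 7, "N": 1, "O": 3},
    "P": {"C": 5, "H": 9, "N": 1, "O": 2},
    "V": {"C": 5, "H": 11, "N": 1, "O": 2},
    "T": {"C": 4, "H": 9, "N": 1, "O": 3},
    "C": {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1},
    "L": {"C": 6, "H": 13, "N": 1, "O": 2},
    "I": {"C": 6, "H": 13, "N": 1, "O": 2},
    "N": {"C": 4, "H": 8, "N": 2, "O": 3},
    "D": {"C": 4, "H": 7, "N": 1, "O": 4},
    "Q": {"C": 5, "H": 10, "N": 2, "O": 3},
    "K": {"C": 6, "H": 14, "N": 2, "O": 2},
    "E": {"C": 5, "H": 9, "N": 1, "O": 4},
    "M": {"C": 5, "H": 11, "N": 1, "O": 2, "S": 1},
    "H": {"C": 6, "H": 9, "N": 3, "O": 2},
    "F": {"C": 9, "H": 11, "N": 1, "O": 2},
    "R": {"C": 6, "H": 14, "N": 4, "O": 2},
    "Y": {"C": 9, "H": 11, "N": 1, "O": 3},
    "W": {"C": 11, "H": 12, "N": 2, "O": 2},
}

_HYBRIDIZATIONS = ("SP3", "SP2", "SP", "S", "SP3D", "SP3D2")
_BOND_TYPES = ("single", "aromatic", "double", "triple")
_STEREO_TYPES = ("any", "cis", "E", "none", "trans", "Z")

_CHIRALITY_MAP = {
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "CCW",
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "CW",
}
_BOND_TYPE_MAP = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.AROMATIC: "aromatic",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
}
_STEREO_MAP = {
    Chem.BondStereo.STEREOANY: "any",
    Chem.BondStereo.STEREOCIS: "cis",
    Chem.BondStereo.STEREOE: "E",
    Chem.BondStereo.STEREONONE: "none",
    Chem.BondStereo.STEREOTRANS: "trans",
    Chem.BondStereo.STEREOZ: "Z",
}


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or non-canonical amino-acid letters."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int = 0
    chirality: str = "other"  # CCW | CW | other
    aromatic: bool = False
    hybridization: str = "SP3"  # SP3 | SP2 | SP | S | SP3D | SP3D2
    radical_electrons: int = 0

    def __post_init__(self):
        if self.hybridization not in _HYBRIDIZATIONS:
            raise ValueError(f"unknown hybridization {self.hybridization!r}")
        if self.chirality not in ("CCW", "CW", "other"):
            raise ValueError(f"unknown chirality {self.chirality!r}")


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    bond_type: str = "single"  # single | aromatic | double | triple
    stereo: str = "none"  # any | cis | E | none | trans | Z
    in_ring: bool = False
    conjugated: bool = False

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("bond endpoints must be distinct")
        if self.bond_type not in _BOND_TYPES:
            raise ValueError(f"unknown bond type {self.bond_type!r}")
        if self.stereo not in _STEREO_TYPES:
            raise ValueError(f"unknown bond stereo {self.stereo!r}")


@dataclass
class Molecule:
    """Explicit-hydrogen molecular graph with chemistry annotations.

    ``component_id[k]`` labels the connected component of atom ``k``; a
    combined MHC+peptide structure has two components.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    component_id: list[int] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) indexes outside {n} atoms")
        if not self.component_id:
            self.component_id = _connected_components(n, self.bonds)

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_components(self) -> int:
        return 0 if not self.component_id else max(self.component_id) + 1

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out


def _connected_components(n: int, bonds: list[Bond]) -> list[int]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for b in bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    comp = [-1] * n
    cid = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = cid
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp[v] < 0:
                    comp[v] = cid
                    stack.append(v)
        cid += 1
    return comp


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InvalidSequenceError("empty amino-acid sequence")
    for pos, letter in enumerate(sequence, start=1):
        if letter not in _RESIDUE_FRAGMENTS:
            raise InvalidSequenceError(
                f"non-canonical amino acid {letter!r} at position {pos}",
                position=pos,
            )


def peptide_smiles(sequence: str) -> str:
    """SMILES of the neutral linear peptide for ``sequence``."""
    _validate_sequence(sequence)
    return "".join(_RESIDUE_FRAGMENTS[c] for c in sequence) + "O"


def _extract(mol: Chem.Mol) -> Molecule:
    atoms = []
    for a in mol.GetAtoms():
        hyb = str(a.GetHybridization())
        if hyb not in _HYBRIDIZATIONS:
            # RDKit leaves hydrogens UNSPECIFIED; they occupy the S slot.
            hyb = "S"
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                chirality=_CHIRALITY_MAP.get(a.GetChiralTag(), "other"),
                aromatic=a.GetIsAromatic(),
                hybridization=hyb,
                radical_electrons=a.GetNumRadicalElectrons(),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        bonds.append(
            Bond(
                i=b.GetBeginAtomIdx(),
                j=b.GetEndAtomIdx(),
                bond_type=_BOND_TYPE_MAP[b.GetBondType()],
                stereo=_STEREO_MAP[b.GetStereo()],
                in_ring=b.IsInRing(),
                conjugated=b.GetIsConjugated(),
            )
        )
    return Molecule(atoms=atoms, bonds=bonds)


@lru_cache(maxsize=4096)
def _build_peptide_cached(sequence: str) -> Molecule:
    smiles = peptide_smiles(sequence)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - fragments are pre-validated
        raise RuntimeError(f"internal SMILES assembly failed for {sequence!r}")
    mol = Chem.AddHs(mol)
    return _extract(mol)


def build_peptide(sequence: str) -> Molecule:
    """Build the explicit-hydrogen molecule of a linear peptide.

    Residues are joined by amide bonds with one water eliminated per
    junction; the termini are the free amine and carboxylic acid.

    Raises
    ------
    InvalidSequenceError
        If the sequence is empty or contains a letter outside the 20
        canonical amino acids (including B, J, O, U, X, Z).
    """
    return _build_peptide_cached(sequence)


def combine(a: Molecule, b: Molecule) -> Molecule:
    """Disjoint union of two molecules (SMILES ``.`` semantics).

    No bond is created between the inputs; ``a``'s atoms come first, and the
    component count is additive.
    """
    if not isinstance(a, Molecule) or not isinstance(b, Molecule):
        raise TypeError("combine expects two Molecule instances")
    if a.num_atoms == 0 or b.num_atoms == 0:
        raise ValueError("combine requires two non-empty molecules")
    off = a.num_atoms
    ncomp = a.num_components
    bonds = list(a.bonds) + [
        Bond(b_.i + off, b_.j + off, b_.bond_type, b_.stereo, b_.in_ring, b_.conjugated)
        for b_ in b.bonds
    ]
    comp = list(a.component_id) + [c + ncomp for c in b.component_id]
    return Molecule(atoms=list(a.atoms) + list(b.atoms), bonds=bonds, component_id=comp)


_RD_BOND_TYPE = {v: k for k, v in _BOND_TYPE_MAP.items()}
_RD_CHIRALITY = {v: k for k, v in _CHIRALITY_MAP.items()}


def _to_rdkit(m: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for atom in m.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetIsAromatic(atom.aromatic)
        a.SetNumRadicalElectrons(atom.radical_electrons)
        a.SetNoImplicit(True)
        if atom.chirality in _RD_CHIRALITY:
            a.SetChiralTag(_RD_CHIRALITY[atom.chirality])
        rw.AddAtom(a)
    for b in m.bonds:
        rw.AddBond(b.i, b.j, _RD_BOND_TYPE[b.bond_type])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def to_smiles(m: Molecule) -> str:
    """Emit SMILES; disconnected components are separated by ``.``."""
    return Chem.MolToSmiles(_to_rdkit(m))


def molecular_formula(m: Molecule) -> dict[str, int]:
    """Exact per-element atom counts of a molecule."""
    counts: dict[str, int] = {}
    for atom in m.atoms:
        counts[atom.element] = counts.get(atom.element, 0) + 1
    return counts


def sequence_formula(sequence: str) -> dict[str, int]:
    """Condensation-arithmetic formula: sum of residues minus (n-1) waters.

    Independent of the structure builder; used as a conservation oracle.
    """
    _validate_sequence(sequence)
    total: dict[str, int] = {}
    for letter in sequence:
        for el, k in RESIDUE_FORMULAS[letter].items():
            total[el] = total.get(el, 0) + k
    n_waters = len(sequence) - 1
    total["H"] -= 2 * n_waters
    total["O"] -= n_waters
    return {el: k for el, k in total.items() if k}
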
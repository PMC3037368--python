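"""Reduced-atom 3D protein structures and PDB I/O.

The package works on a reduced representation of alpha-helical proteins:
per residue the four backbone atoms (N, CA, C, O), a CB placed radially
off the helix axis, and a single side-chain "tip" pseudo-atom placed
along the CA->CB direction at a residue-type-dependent distance.  The
tip stands in for the charged / polar terminal group of the side chain
(the ammonium of Lys, the carboxylate of Glu, ...), which is all the
interface analysis and the energetics need.

All coordinates are in Angstrom, charges in elementary charges.
Full-atom structures read from PDB files are carried in the same
containers; their atoms get element-based radii and formal charges on
the charged-group atoms of Asp/Glu/Lys/Arg.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

# one-letter <-> three-letter codes for the 20 standard residues
AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}

# CA->tip pseudo-atom distances (Angstrom).  These approximate the
# distance from CA to the functional end group of each side chain in an
# extended rotamer; ALA's tip coincides with CB.
TIP_LENGTH = {
    "ASP": 3.7, "GLU": 5.0, "LYS": 6.4, "ARG": 7.3, "HIS": 4.6,
    "LEU": 3.9, "ALA": 1.5,
}
TIP_LENGTH_DEFAULT = 2.4

# element assigned to the tip pseudo-atom: the heteroatom of the
# side-chain end group, used for donor/acceptor typing
TIP_ELEMENT = {
    "ASP": "O", "GLU": "O", "SER": "O", "THR": "O", "TYR": "O",
    "LYS": "N", "ARG": "N", "HIS": "N", "ASN": "N", "GLN": "N",
    "TRP": "N", "CYS": "S",
}

# formal charge carried by the tip pseudo-atom (His neutral by default;
# the energetics config can switch it on)
FORMAL_TIP_CHARGE = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}

# steric / SASA radii by element; the tip pseudo-atom gets a larger
# radius because it represents a whole end group
VDW_RADIUS = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
TIP_RADIUS = 2.0

# formal charges for full-atom structures, keyed (res_name, atom_name);
# carboxylates and the Arg guanidinium split the unit charge
FULLATOM_CHARGE = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

CHARGED_RESIDUES = {"ASP", "GLU", "LYS", "ARG", "HIS"}


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    charge: float = 0.0
    radius: float = 1.70

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be a finite 3-vector")


@dataclass
class Residue:
    index: int
    name: str
    atoms: list = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return AA_3TO1.get(self.name, "X")


@dataclass
class Chain:
    id: str
    residues: list = field(default_factory=list)

    def residue(self, index: int) -> Residue | None:
        for r in self.residues:
            if r.index == index:
                return r
        return None


@dataclass
class Structure3D:
    chains: list = field(default_factory=list)

    def __post_init__(self):
        for ch in self.chains:
            idx = [r.index for r in ch.residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(
                    f"residue indices not strictly increasing in chain {ch.id}"
                )
            for res in ch.residues:
                for atom in res.atoms:
                    if atom.charge != 0.0 and res.name not in CHARGED_RESIDUES:
                        raise ValueError(
                            f"charged atom on non-ionizable residue {res.name}"
                        )

    # -- accessors -----------------------------------------------------
    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise KeyError(chain_id)

    def iter_atoms(self):
        for ch in self.chains:
            for res in ch.residues:
                for atom in res.atoms:
                    yield ch, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self, atom_names=None) -> np.ndarray:
        pts = [a.xyz for _, _, a in self.iter_atoms()
               if atom_names is None or a.name in atom_names]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def copy(self) -> "Structure3D":
        return _copy.deepcopy(self)

    # -- geometry ------------------------------------------------------
    def transform(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)):
        """Apply x -> R x + t to every atom in place."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        for _, _, atom in self.iter_atoms():
            atom.xyz = rotation @ atom.xyz + translation
        return self

    def translate(self, shift):
        return self.transform(np.eye(3), shift)

    # -- interop -------------------------------------------------------
    def to_atom_array(self) -> bst.AtomArray:
        n = self.n_atoms
        arr = bst.AtomArray(n)
        coord = np.empty((n, 3))
        i = 0
        for ch, res, atom in self.iter_atoms():
            coord[i] = atom.xyz
            arr.chain_id[i] = ch.id
            arr.res_id[i] = res.index
            arr.res_name[i] = res.name
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element
            arr.hetero[i] = False
            i += 1
        arr.coord = coord
        arr.set_annotation("occupancy", np.ones(n))
        arr.set_annotation("b_factor", np.zeros(n))
        return arr

    def radii(self) -> np.ndarray:
        return np.array([a.radius for _, _, a in self.iter_atoms()])


# -- atom parameter assignment ----------------------------------------

def tip_length(res_name: str) -> float:
    return TIP_LENGTH.get(res_name, TIP_LENGTH_DEFAULT)


def make_tip_atom(res_name: str, xyz, his_charged: bool = False) -> Atom:
    charge = FORMAL_TIP_CHARGE.get(res_name, 0.0)
    if res_name == "HIS" and his_charged:
        charge = 1.0
    return Atom(name="TIP", element=TIP_ELEMENT.get(res_name, "C"),
                xyz=np.asarray(xyz, dtype=float), charge=charge,
                radius=TIP_RADIUS)


def assign_full_atom_params(atom: Atom, res_name: str) -> None:
    """Radii by element and formal charges for full-atom PDB input."""
    if atom.name == "TIP":
        atom.radius = TIP_RADIUS
        atom.charge = FORMAL_TIP_CHARGE.get(res_name, 0.0)
    else:
        atom.radius = VDW_RADIUS.get(atom.element, 1.70)
        atom.charge = FULLATOM_CHARGE.get((res_name, atom.name), 0.0)


# -- PDB I/O -----------------------------------------------------------

def write_pdb(structure: Structure3D, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(structure.to_atom_array())
    pdb.write(str(path))


def read_pdb(path) -> Structure3D:
    """Read a PDB file; charges and radii are (re)assigned from the
    package's parameter tables, they do not round-trip through PDB."""
    arr = PDBFile.read(str(path)).get_structure(model=1)
    chains = []
    for cid in np.unique(arr.chain_id):
        mask = arr.chain_id == cid
        sub = arr[mask]
        residues = []
        for rid in np.unique(sub.res_id):
            rmask = sub.res_id == rid
            rsub = sub[rmask]
            res_name = str(rsub.res_name[0])
            atoms = []
            for j in range(rsub.array_length()):
                element = str(rsub.element[j]).upper() or "C"
                atom = Atom(name=str(rsub.atom_name[j]), element=element,
                            xyz=rsub.coord[j])
                assign_full_atom_params(atom, res_name)
                atoms.append(atom)
            residues.append(Residue(index=int(rid), name=res_name, atoms=atoms))
        residues.sort(key=lambda r: r.index)
        chains.append(Chain(id=str(cid), residues=residues))
    chains.sort(key=lambda c: c.id)
    return Structure3D(chains=chains)
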
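"""Intermolecular salt-bridge and hydrogen-bond inventory.

Contacts are detected between the two chains of a dimer only; a residue
pair is reported once per interaction type, at its minimum atom-atom
distance, and typed by its strongest interaction (salt bridge first).

Criteria
--------
salt bridge
    Minimum distance between charged-group atoms of opposite sign on
    different chains <= 4.0 A (the common literature convention; the
    source data state no criterion).  In the reduced representation the
    charged group is the side-chain tip pseudo-atom of Asp/Glu/Lys/Arg;
    in full-atom structures it is the carboxylate O / ammonium N /
    guanidinium N atoms.
hydrogen bond
    Donor and acceptor heavy atoms on different chains within 3.5 A.
    Backbone N donates, backbone O accepts; side-chain heteroatoms are
    typed by residue.  An explicit-H angle criterion (D-H...A >= 120
    degrees) is applied only when hydrogens exist in the input; reduced
    models carry none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import Structure3D

SALT_BRIDGE_CUTOFF = 4.0
HBOND_CUTOFF = 3.5
HBOND_ANGLE_MIN = 120.0

# donor/acceptor roles of side-chain end groups, by residue
_TIP_ROLES = {
    "ASP": {"acceptor"}, "GLU": {"acceptor"},
    "LYS": {"donor"}, "ARG": {"donor"},
    "SER": {"donor", "acceptor"}, "THR": {"donor", "acceptor"},
    "TYR": {"donor", "acceptor"}, "ASN": {"donor", "acceptor"},
    "GLN": {"donor", "acceptor"}, "HIS": {"donor", "acceptor"},
    "TRP": {"donor"}, "CYS": {"donor"},
}
_HYDROXYL_RESIDUES = {"SER", "THR", "TYR"}


@dataclass(frozen=True)
class Contact:
    chain_a: str
    res_a_index: int
    res_a_name: str
    chain_b: str
    res_b_index: int
    res_b_name: str
    type: str  # "salt_bridge" | "hydrogen_bond"
    distance: float


@dataclass
class ContactInventory:
    contacts: list = field(default_factory=list)

    @property
    def n_salt_bridges(self) -> int:
        return sum(1 for c in self.contacts if c.type == "salt_bridge")

    @property
    def n_hbonds(self) -> int:
        return sum(1 for c in self.contacts if c.type == "hydrogen_bond")

    def residue_pairs(self, contact_type=None) -> set:
        return {(c.res_a_index, c.res_b_index) for c in self.contacts
                if contact_type is None or c.type == contact_type}

    def to_tsv(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("#chainA_res\tchainA_index\tchainB_res\tchainB_index"
                     "\ttype\tdistance_A\n")
            for c in self.contacts:
                fh.write(f"{c.res_a_name}\t{c.res_a_index}\t{c.res_b_name}"
                         f"\t{c.res_b_index}\t{c.type}\t{c.distance:.3f}\n")


def _atom_table(structure: Structure3D):
    """Flat per-atom arrays: coordinates plus (chain pos, residue) keys."""
    rows = []
    for ci, ch in enumerate(structure.chains):
        for res in ch.residues:
            for atom in res.atoms:
                rows.append((ci, ch.id, res, atom))
    return rows


def _roles(res_name: str, atom) -> set:
    """Donor/acceptor roles of a heavy atom."""
    if atom.name == "N":
        return {"donor"}
    if atom.name == "O":
        return {"acceptor"}
    if atom.name == "TIP":
        return _TIP_ROLES.get(res_name, set())
    # full-atom side chains: N donates, O accepts, hydroxyl O does both
    if atom.element == "N":
        return {"donor"}
    if atom.element == "O":
        if res_name in _HYDROXYL_RESIDUES:
            return {"donor", "acceptor"}
        return {"acceptor"}
    return set()


def _require_dimer(structure: Structure3D) -> bool:
    if len(structure.chains) < 2:
        warnings.warn("contact detection needs >= 2 chains; returning "
                      "empty inventory", stacklevel=3)
        return False
    return True


def _min_distance_pairs(rows_a, rows_b, cutoff):
    """Minimum atom-atom distance per residue pair within cutoff."""
    best = {}
    if not rows_a or not rows_b:
        return best
    xa = np.array([a.xyz for _, _, _, a in rows_a])
    xb = np.array([a.xyz for _, _, _, a in rows_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    ii, jj = np.nonzero(d <= cutoff)
    for i, j in zip(ii, jj):
        _, cid_a, res_a, atom_a = rows_a[i]
        _, cid_b, res_b, atom_b = rows_b[j]
        key = (cid_a, res_a.index, cid_b, res_b.index)
        dist = float(d[i, j])
        if key not in best or dist < best[key][0]:
            best[key] = (dist, res_a, res_b, atom_a, atom_b)
    return best


def detect_salt_bridges(structure: Structure3D,
                        cutoff: float = SALT_BRIDGE_CUTOFF) -> list:
    """Intermolecular acidic-basic contacts within ``cutoff``."""
    if not _require_dimer(structure):
        return []
    rows = _atom_table(structure)
    contacts = []
    n_chains = len(structure.chains)
    for ca in range(n_chains):
        for cb in range(ca + 1, n_chains):
            neg_a = [r for r in rows if r[0] == ca and r[3].charge < 0]
            pos_a = [r for r in rows if r[0] == ca and r[3].charge > 0]
            neg_b = [r for r in rows if r[0] == cb and r[3].charge < 0]
            pos_b = [r for r in rows if r[0] == cb and r[3].charge > 0]
            best = _min_distance_pairs(neg_a, pos_b, cutoff)
            for key, (dist, res_a, res_b, _, _) in _min_distance_pairs(
                    pos_a, neg_b, cutoff).items():
                if key not in best or dist < best[key][0]:
                    best[key] = (dist, res_a, res_b, None, None)
            for (cid_a, ria, cid_b, rib), (dist, res_a, res_b, _, _) in \
                    best.items():
                contacts.append(Contact(
                    chain_a=cid_a, res_a_index=ria, res_a_name=res_a.name,
                    chain_b=cid_b, res_b_index=rib, res_b_name=res_b.name,
                    type="salt_bridge", distance=dist))
    contacts.sort(key=lambda c: (c.chain_a, c.res_a_index, c.chain_b,
                                 c.res_b_index))
    return contacts


def _explicit_hydrogens(structure: Structure3D) -> bool:
    return any(a.element == "H" for _, _, a in structure.iter_atoms())


def _donor_hydrogens(res, donor):
    """Hydrogens bonded to the donor heavy atom (within 1.3 A)."""
    return [a for a in res.atoms if a.element == "H"
            and np.linalg.norm(a.xyz - donor.xyz) <= 1.3]


def _angle_ok(res_donor, donor, acceptor, angle_min: float) -> bool:
    hs = _donor_hydrogens(res_donor, donor)
    if not hs:
        return True
    for h in hs:
        v1 = donor.xyz - h.xyz
        v2 = acceptor.xyz - h.xyz
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if ang >= angle_min:
            return True
    return False


def detect_hbonds(structure: Structure3D, heavy_cutoff: float = HBOND_CUTOFF,
                  angle_min: float = HBOND_ANGLE_MIN) -> list:
    """Intermolecular donor-acceptor heavy-atom contacts.

    The angle criterion activates only when explicit hydrogens are
    present in the input (full-atom mode).
    """
    if not _require_dimer(structure):
        return []
    rows = [r for r in _atom_table(structure) if r[3].element != "H"]
    use_angle = _explicit_hydrogens(structure)
    contacts = []
    n_chains = len(structure.chains)
    for ca in range(n_chains):
        for cb in range(ca + 1, n_chains):
            rows_a = [r for r in rows if r[0] == ca]
            rows_b = [r for r in rows if r[0] == cb]
            don_a = [r for r in rows_a if "donor" in _roles(r[2].name, r[3])]
            acc_a = [r for r in rows_a if "acceptor" in _roles(r[2].name, r[3])]
            don_b = [r for r in rows_b if "donor" in _roles(r[2].name, r[3])]
            acc_b = [r for r in rows_b if "acceptor" in _roles(r[2].name, r[3])]
            best = {}
            for pairs, donor_on_a in ((_min_distance_pairs(don_a, acc_b,
                                                           heavy_cutoff), True),
                                      (_min_distance_pairs(acc_a, don_b,
                                                           heavy_cutoff), False)):
                for key, (dist, res_a, res_b, atom_a, atom_b) in pairs.items():
                    if use_angle:
                        if donor_on_a:
                            ok = _angle_ok(res_a, atom_a, atom_b, angle_min)
                        else:
                            ok = _angle_ok(res_b, atom_b, atom_a, angle_min)
                        if not ok:
                            continue
                    if key not in best or dist < best[key][0]:
                        best[key] = (dist, res_a, res_b)
            for (cid_a, ria, cid_b, rib), (dist, res_a, res_b) in best.items():
                contacts.append(Contact(
                    chain_a=cid_a, res_a_index=ria, res_a_name=res_a.name,
                    chain_b=cid_b, res_b_index=rib, res_b_name=res_b.name,
                    type="hydrogen_bond", distance=dist))
    contacts.sort(key=lambda c: (c.chain_a, c.res_a_index, c.chain_b,
                                 c.res_b_index))
    return contacts


def interface_inventory(structure: Structure3D,
                        salt_cutoff: float = SALT_BRIDGE_CUTOFF,
                        hbond_cutoff: float = HBOND_CUTOFF) -> ContactInventory:
    """Merged, deduplicated contact table (Table-of-residue-pairs
    semantics): a residue pair is typed by its strongest interaction,
    salt bridge first; hydrogen bonds for pairs already listed as salt
    bridges are dropped."""
    bridges = detect_salt_bridges(structure, cutoff=salt_cutoff)
    hbonds = detect_hbonds(structure, heavy_cutoff=hbond_cutoff)
    bridged = {(c.chain_a, c.res_a_index, c.chain_b, c.res_b_index)
               for c in bridges}
    merged = bridges + [
        c for c in hbonds
        if (c.chain_a, c.res_a_index, c.chain_b, c.res_b_index) not in bridged
    ]
    merged.sort(key=lambda c: (c.chain_a, c.res_a_index, c.chain_b,
                               c.res_b_index, c.type))
    return ContactInventory(contacts=merged)


def inventory_ratio(inv_a: ContactInventory,
                    inv_b: ContactInventory) -> tuple:
    """Count ratios (hbond_ratio, salt_ratio) of inventory A over B.

    A zero denominator with a nonzero numerator is reported as ``inf``;
    0/0 is reported as 1.0 (identical emptiness).
    """
    def ratio(a, b):
        if b == 0:
            return 1.0 if a == 0 else float("inf")
        return a / b

    return (ratio(inv_a.n_hbonds, inv_b.n_hbonds),
            ratio(inv_a.n_salt_bridges, inv_b.n_salt_bridges))
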
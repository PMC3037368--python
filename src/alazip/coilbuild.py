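"""Parametric helix / coiled-coil dimer construction and superposition.

The builder places idealized alpha-helices on a straight axis: CA atoms
on a cylinder (default radius 2.3 A, rise 1.5 A per residue), the other
backbone atoms at fixed cylindrical offsets, CB radially outward and a
side-chain tip pseudo-atom along CA->CB (see :mod:`alazip.structure`).
Bonded backbone geometry is approximate by design; only CA geometry and
side-chain directions matter for the downstream interface analysis.

Dimer construction is a rigid-body placement: for parallel orientation
chain B is chain A rotated 180 degrees about the midline between the two
helix axes (a C2 operation), which makes the two interface faces meet;
for antiparallel orientation chain B is flipped end-over-end (a proper
180-degree rotation about an axis perpendicular to the helix axes).

For dimer models the helix twist should be *heptad-commensurate*
(720/7 = 102.857 degrees per residue, exactly 3.5 residues per turn):
this is the straightened representation of a coiled-coil helix, in which
the heptad face orientation is invariant along the axis, so every heptad
presents the same geometry to the partner chain.  The canonical 100
degrees per residue of an isolated alpha-helix is the default of
:class:`HelixParams`; use :meth:`HelixParams.heptad_locked` for dimers.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, replace

import numpy as np

from .records import ProteinRecord
from .structure import (
    AA_1TO3, BACKBONE_ATOMS, Atom, Chain, Residue, Structure3D,
    VDW_RADIUS, make_tip_atom, tip_length,
)

HEPTAD_TWIST = 720.0 / 7.0  # degrees per residue, exactly 3.5 res/turn

# interface face convention: the 'a' position CB direction sits at
# +180/7 degrees from the face center, 'd' at -180/7 (a and d straddle
# the direction toward the partner chain)
_A_FACE_ANGLE = 180.0 / 7.0

# cylindrical placement of backbone atoms relative to CA:
# (radius, delta_angle_deg, delta_z)
_BACKBONE_CYL = {
    "N": (1.86, -26.0, -0.95),
    "C": (2.00, 21.0, 0.63),
    "O": (2.00, 23.0, 1.85),
}
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass(frozen=True)
class HelixParams:
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    helix_radius: float = 2.3
    superhelix_radius: float = 4.9
    superhelix_pitch: float = 148.0
    orientation: str = "parallel"
    interhelical_offset: float = 9.8

    def __post_init__(self):
        if min(self.rise_per_residue, self.helix_radius,
               self.superhelix_radius, self.superhelix_pitch,
               self.interhelical_offset) <= 0:
            raise ValueError("all lengths must be positive")
        if not 0.0 < self.twist_per_residue < 180.0:
            raise ValueError("twist must be in (0, 180) degrees")
        if self.orientation not in ("parallel", "antiparallel"):
            raise ValueError("orientation must be parallel or antiparallel")

    @classmethod
    def heptad_locked(cls, **kwargs) -> "HelixParams":
        """Parameters with the heptad-commensurate twist used for dimer
        models (the face of each heptad is invariant along the axis)."""
        kwargs.setdefault("twist_per_residue", HEPTAD_TWIST)
        return cls(**kwargs)

    def with_(self, **kwargs) -> "HelixParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ThreadingMap:
    """One-to-one residue correspondence between a query sequence span
    and a template structure span, with a register shift annotation."""

    query_span: tuple
    template_span: tuple
    offset: int = 0

    def __post_init__(self):
        qlen = self.query_span[1] - self.query_span[0] + 1
        tlen = self.template_span[1] - self.template_span[0] + 1
        if qlen != tlen:
            raise ValueError(
                f"query span length {qlen} != template span length {tlen}")
        if qlen < 1:
            raise ValueError("spans must be non-degenerate")

    @property
    def n_pairs(self) -> int:
        return self.query_span[1] - self.query_span[0] + 1


def interface_phase(first_residue_heptad_index: int,
                    twist: float = HEPTAD_TWIST) -> float:
    """Phase (degrees) for :func:`build_ideal_helix` that points the
    a/d core face of the helix toward +x, given the heptad letter index
    (a=0 ... g=6) of the first residue.  Exact for the
    heptad-commensurate twist."""
    return _A_FACE_ANGLE + twist * (first_residue_heptad_index % 7)


def build_ideal_helix(sequence, params: HelixParams | None = None,
                      phase_deg: float = 0.0, start_index: int = 1,
                      chain_id: str = "A") -> Structure3D:
    """Build a single-chain idealized helix along +z through the origin.

    ``sequence`` is a 1-letter string or :class:`ProteinRecord`.  The CB
    direction of residue i points at angle ``phase_deg + twist * i``
    from +x (radially outward); the tip pseudo-atom continues along
    CA->CB at the residue-type length.
    """
    if isinstance(sequence, ProteinRecord):
        sequence = sequence.sequence
    if not sequence:
        raise ValueError("sequence must be nonempty")
    params = params or HelixParams()
    residues = []
    for i, aa in enumerate(sequence):
        if aa not in AA_1TO3:
            raise ValueError(f"unknown residue code {aa!r}")
        res_name = AA_1TO3[aa]
        theta = math.radians(phase_deg + params.twist_per_residue * i)
        z = params.rise_per_residue * i
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        ca_xyz = params.helix_radius * u + np.array([0.0, 0.0, z])
        atoms = [Atom("CA", "C", ca_xyz, radius=VDW_RADIUS["C"])]
        for name, (r, dth, dz) in _BACKBONE_CYL.items():
            ang = theta + math.radians(dth)
            xyz = np.array([r * math.cos(ang), r * math.sin(ang), z + dz])
            atoms.insert(0 if name == "N" else len(atoms),
                         Atom(name, _ELEMENT[name], xyz,
                              radius=VDW_RADIUS[_ELEMENT[name]]))
        cb_xyz = ca_xyz + 1.53 * u
        if res_name != "GLY":
            atoms.append(Atom("CB", "C", cb_xyz, radius=VDW_RADIUS["C"]))
        atoms.append(make_tip_atom(res_name, ca_xyz + tip_length(res_name) * u))
        residues.append(Residue(index=start_index + i, name=res_name,
                                atoms=atoms))
    return Structure3D(chains=[Chain(id=chain_id, residues=residues)])


def _tip_direction(res: Residue) -> np.ndarray:
    """Unit CA->CB direction; for CB-less residues fall back to the
    direction away from the local backbone."""
    ca = res.atom("CA")
    if ca is None:
        raise ValueError(f"residue {res.index} has no CA atom")
    cb = res.atom("CB")
    if cb is not None:
        d = cb.xyz - ca.xyz
    else:
        n, c = res.atom("N"), res.atom("C")
        if n is None or c is None:
            raise ValueError(f"residue {res.index}: cannot place side chain")
        d = 2 * ca.xyz - n.xyz - c.xyz
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError(f"degenerate side-chain direction at {res.index}")
    return d / norm


def _rebuild_side_chain(res: Residue, new_name: str) -> Residue:
    """Return a residue with ``new_name``, identical backbone/CB
    coordinates and a tip pseudo-atom rebuilt for the new residue type."""
    direction = _tip_direction(res)
    ca = res.atom("CA")
    atoms = [Atom(a.name, a.element, a.xyz.copy(), charge=0.0,
                  radius=a.radius)
             for a in res.atoms if a.name in BACKBONE_ATOMS + ("CB",)]
    atoms.append(make_tip_atom(new_name,
                               ca.xyz + tip_length(new_name) * direction))
    return Residue(index=res.index, name=new_name, atoms=atoms)


def thread_sequence(query: ProteinRecord, template: Structure3D,
                    tmap: ThreadingMap) -> Structure3D:
    """Thread a query span onto a template backbone.

    The output keeps the template backbone coordinates bit-for-bit,
    renames residues to the query residues (renumbered to the query
    span) and rebuilds the side-chain tip pseudo-atoms for the new
    residue types along the template's CA->CB directions.
    """
    qstart, qend = tmap.query_span
    if not (1 <= qstart <= qend <= len(query)):
        raise IndexError("query span out of bounds")
    if len(template.chains) != 1:
        raise ValueError("template must be single-chain")
    tstart, tend = tmap.template_span
    tres = [r for r in template.chains[0].residues if tstart <= r.index <= tend]
    if len(tres) != tmap.n_pairs:
        raise ValueError(
            f"template span provides {len(tres)} residues, "
            f"expected {tmap.n_pairs}")
    out = []
    for k, res in enumerate(tres):
        aa = query.residue(qstart + k)
        new = _rebuild_side_chain(res, AA_1TO3[aa])
        new.index = qstart + k
        out.append(new)
    return Structure3D(chains=[Chain(id=template.chains[0].id, residues=out)])


def mutate_core(structure: Structure3D, from_res: str, to_res: str,
                positions) -> Structure3D:
    """Swap the residue type at ``positions`` (applied in every chain),
    rebuilding tips; backbone untouched.  1-letter or 3-letter codes."""
    from_res = AA_1TO3.get(from_res.upper(), from_res.upper())
    to_res = AA_1TO3.get(to_res.upper(), to_res.upper())
    positions = list(positions)
    result = []
    for ch in structure.chains:
        residues = []
        for res in ch.residues:
            if res.index in positions:
                if res.name != from_res:
                    raise ValueError(
                        f"position {res.index} carries {res.name}, "
                        f"not {from_res}")
                residues.append(_rebuild_side_chain(res, to_res))
            else:
                residues.append(_copy.deepcopy(res))
        result.append(Chain(id=ch.id, residues=residues))
    return Structure3D(chains=result)


def build_dimer(monomer_a: Structure3D, monomer_b: Structure3D,
                params: HelixParams | None = None) -> Structure3D:
    """Place two single-chain helices (built in the builder frame: axis
    +z through the origin) as a dimer.

    Parallel: chain B is chain A's partner under a C2 rotation about the
    midline, so the +x interface face of A meets the -x face of B.
    Antiparallel: chain B is flipped end-over-end (180 degrees about y)
    and z-aligned so its first residue meets A's last residue.
    """
    params = params or HelixParams.heptad_locked()
    if len(monomer_a.chains) != 1 or len(monomer_b.chains) != 1:
        raise ValueError("monomers must be single-chain")
    a = monomer_a.copy()
    b = monomer_b.copy()
    a.chains[0].id = "A"
    b.chains[0].id = "B"
    off = params.interhelical_offset
    if params.orientation == "parallel":
        # (x, y, z) -> (off - x, -y, z): C2 about the vertical midline
        b.transform(np.diag([-1.0, -1.0, 1.0]), (off, 0.0, 0.0))
    else:
        # (x, y, z) -> (off - x, y, zmax - z): 180 degrees about y
        ca_z = [r.atom("CA").xyz[2] for r in b.chains[0].residues]
        zmax = max(ca_z)
        b.transform(np.diag([-1.0, 1.0, -1.0]), (off, 0.0, zmax))
    return Structure3D(chains=[a.chains[0], b.chains[0]])


# -- superposition ------------------------------------------------------

_SELECTIONS = {
    "backbone": set(BACKBONE_ATOMS),
    "CA": {"CA"},
    "all": None,
}


def _selected_coords(structure: Structure3D, atom_selection) -> np.ndarray:
    names = _SELECTIONS.get(atom_selection, atom_selection)
    if names is not None:
        names = set(names)
    return structure.coords(atom_names=names)


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple:
    """Least-squares rigid superposition (proper rotations only).

    Returns ``(R, t)`` with ``R @ x + t`` mapping ``moving`` onto
    ``fixed``.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cf - rot @ cm


def superpose_and_rmsd(struct_a: Structure3D, struct_b: Structure3D,
                       atom_selection: str = "backbone") -> tuple:
    """Optimally superpose B onto A and return ``(rmsd, (R, t))``.

    Reflections are excluded; RMSD is over the selected atoms after the
    superposition.
    """
    xa = _selected_coords(struct_a, atom_selection)
    xb = _selected_coords(struct_b, atom_selection)
    if xa.shape != xb.shape:
        raise ValueError(
            f"atom count mismatch after selection: {xa.shape[0]} vs "
            f"{xb.shape[0]}")
    if xa.shape[0] == 0:
        raise ValueError("empty atom selection")
    rot, t = kabsch(xb, xa)
    moved = xb @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - xa) ** 2, axis=1))))
    return rmsd, (rot, t)


# -- side-chain relaxation ----------------------------------------------

def _overlap_energy(tips: np.ndarray, tip_radii: np.ndarray,
                    obstacles: np.ndarray, obs_radii: np.ndarray,
                    pair_mask: np.ndarray) -> float:
    """Soft-sphere overlap energy sum of max(0, ri+rj-d)^2 over allowed
    tip/obstacle pairs (``pair_mask`` excludes same-residue pairs)."""
    d = np.linalg.norm(tips[:, None, :] - obstacles[None, :, :], axis=2)
    overlap = np.maximum(0.0, tip_radii[:, None] + obs_radii[None, :] - d)
    overlap = np.where(pair_mask, overlap, 0.0)
    return float(np.sum(overlap ** 2))


def relax_sidechains(structure: Structure3D, n_steps: int = 200,
                     step_size: float = 0.1,
                     return_trace: bool = False):
    """Greedy reduction of tip-atom steric overlap.

    Tips move on spheres of fixed radius around their CA (bond lengths
    preserved); all other atoms are frozen.  A step is accepted only if
    the soft-sphere overlap energy does not increase, so the energy
    trace is monotone non-increasing.  Deterministic.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    result = structure.copy()
    tip_entries = []  # (atom, ca_xyz, bond_length, residue_key, obs_index)
    obstacles = []
    for ci, ch in enumerate(result.chains):
        for res in ch.residues:
            key = (ci, res.index)
            ca = res.atom("CA")
            for atom in res.atoms:
                if atom.name == "TIP" and ca is not None:
                    bond = float(np.linalg.norm(atom.xyz - ca.xyz))
                    tip_entries.append((atom, ca.xyz.copy(), bond, key,
                                        len(obstacles)))
                obstacles.append((atom, key))

    if not tip_entries or n_steps == 0:
        return (result, []) if return_trace else result

    obs_xyz = np.array([a.xyz for a, _ in obstacles])
    obs_r = np.array([a.radius for a, _ in obstacles])
    obs_keys = [k for _, k in obstacles]
    tip_r = np.array([e[0].radius for e in tip_entries])
    tip_keys = [e[3] for e in tip_entries]
    tip_obs_index = [e[4] for e in tip_entries]
    # mask: exclude same-residue pairs and the tip's own obstacle entry
    mask = np.array([[tk != ok for ok in obs_keys] for tk in tip_keys])

    def positions():
        return np.array([e[0].xyz for e in tip_entries])

    def set_positions(pts):
        for entry, p in zip(tip_entries, pts):
            entry[0].xyz = p.copy()
        for idx, entry in zip(tip_obs_index, tip_entries):
            obs_xyz[idx] = entry[0].xyz

    def energy(pts):
        tmp = obs_xyz.copy()
        for idx, p in zip(tip_obs_index, pts):
            tmp[idx] = p
        return _overlap_energy(pts, tip_r, tmp, obs_r, mask)

    ca_xyz = np.array([e[1] for e in tip_entries])
    bonds = np.array([e[2] for e in tip_entries])
    pts = positions()
    e = energy(pts)
    trace = [e]
    step = float(step_size)
    for _ in range(int(n_steps)):
        if e == 0.0 or step < 1e-9:
            trace.append(e)
            continue
        # gradient of the overlap energy wrt tip positions
        tmp = obs_xyz.copy()
        for idx, p in zip(tip_obs_index, pts):
            tmp[idx] = p
        diff = pts[:, None, :] - tmp[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        overlap = np.maximum(0.0, tip_r[:, None] + obs_r[None, :] - d)
        overlap = np.where(mask, overlap, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            coef = np.where(d > 0, -2.0 * overlap / d, 0.0)
        grad = np.sum(coef[:, :, None] * diff, axis=1)
        # tip atoms also appear as obstacles for other tips; the mirrored
        # contribution doubles the inter-tip gradient, which only changes
        # the effective step, not the descent direction guarantee
        proposal = pts - step * grad
        rel = proposal - ca_xyz
        norm = np.linalg.norm(rel, axis=1, keepdims=True)
        proposal = ca_xyz + bonds[:, None] * rel / np.where(norm == 0, 1, norm)
        e_new = energy(proposal)
        if e_new <= e:
            pts, e = proposal, e_new
        else:
            step *= 0.5
        trace.append(e)
    set_positions(pts)
    return (result, trace) if return_trace else result
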
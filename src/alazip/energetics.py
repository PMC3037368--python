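"""Binding free-energy decomposition (single-structure MM-GBSA style).

The binding free energy of a dimer is decomposed end-state style:

    dG_bind = G(complex) - G(monomer A) - G(monomer B)
    G       = E_gas + G_polar + G_sa

* ``E_gas`` is the molecular-mechanics gas-phase energy: Coulomb
  electrostatics (k q_i q_j / (eps_in r_ij)) plus an optional 12-6
  Lennard-Jones term.  Internal bonded terms (bond/angle/torsion) are
  omitted: under the single-structure convention the monomers keep the
  complex coordinates, so bonded terms cancel identically in dG.
* ``G_polar`` is the polar solvation energy from the generalized-Born
  model with the Still interpolation
  f_GB = sqrt(r^2 + Ri Rj exp(-r^2 / (4 Ri Rj))), self-terms included,
  with solute/solvent dielectrics 1/80.
* ``G_sa`` is the nonpolar solvation energy, exactly
  gamma * SASA + beta with gamma = 0.0072 kcal/(mol A^2) and beta = 0.
* The conformational entropy term (-T dS) is not computed; reports
  carry an explicit "not computed" marker.

Instead of molecular-dynamics snapshot averaging, an optional seeded
conformer ensemble perturbs the complex coordinates with Gaussian
jitter and averages the per-conformer binding energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bst

from .structure import Structure3D

COULOMB_CONSTANT = 332.0636  # kcal A / (mol e^2)

DEFAULT_BORN_RADII = {"TIP": 2.0, "N": 1.55, "O": 1.50, "C": 1.70,
                      "S": 1.80, "H": 1.20}

# minimal 12-6 parameters by element, used only in full-atom mode
DEFAULT_LJ = {"C": (0.086, 3.40), "N": (0.170, 3.25), "O": (0.210, 2.96),
              "S": (0.250, 3.56), "H": (0.016, 2.47)}


@dataclass(frozen=True)
class EnergeticsConfig:
    coulomb_constant: float = COULOMB_CONSTANT
    eps_in: float = 1.0
    eps_out: float = 80.0
    gamma: float = 0.0072  # kcal / (mol A^2)
    beta: float = 0.0      # kcal / mol
    probe_radius: float = 1.4
    sasa_points: int = 960
    use_lj: bool = False
    lj_table: dict | None = None
    born_radius_table: dict = field(
        default_factory=lambda: dict(DEFAULT_BORN_RADII))
    his_charged: bool = False
    ensemble_n: int = 1
    ensemble_sigma: float = 0.3  # A
    seed: int = 0

    def __post_init__(self):
        if not self.eps_out > self.eps_in >= 1.0:
            raise ValueError("need eps_out > eps_in >= 1")
        if self.gamma <= 0 or self.probe_radius <= 0:
            raise ValueError("gamma and probe_radius must be positive")
        if self.ensemble_n < 1:
            raise ValueError("ensemble_n must be >= 1")

    def with_(self, **kwargs) -> "EnergeticsConfig":
        return replace(self, **kwargs)


@dataclass
class EnergyTerms:
    e_gas: float
    g_polar: float
    g_sa: float
    sasa: float

    @property
    def total(self) -> float:
        return self.e_gas + self.g_polar + self.g_sa

    def to_dict(self) -> dict:
        return {"e_gas": self.e_gas, "g_polar": self.g_polar,
                "g_sa": self.g_sa, "sasa": self.sasa, "g_total": self.total}


@dataclass
class EnergyReport:
    complex: EnergyTerms
    monomer_a: EnergyTerms
    monomer_b: EnergyTerms
    delta_g_binding: float
    entropy_term: str = "not computed"
    ensemble_n: int = 1
    ensemble_mean: float | None = None
    ensemble_sd: float | None = None

    def to_dict(self) -> dict:
        out = {
            "complex": self.complex.to_dict(),
            "monomerA": self.monomer_a.to_dict(),
            "monomerB": self.monomer_b.to_dict(),
            "delta_g_binding": self.delta_g_binding,
            "entropy": "omitted",
            "ensemble": {"n": self.ensemble_n, "mean": self.ensemble_mean,
                         "sd": self.ensemble_sd},
        }
        return out


# -- SASA ---------------------------------------------------------------

def sasa(structure: Structure3D, config: EnergeticsConfig | None = None):
    """Per-atom and total solvent-accessible surface area (A^2),
    computed by probe-sphere sampling (Shrake-Rupley with Fibonacci
    points; deterministic for a fixed point count)."""
    config = config or EnergeticsConfig()
    radii = structure.radii()
    if radii.size == 0:
        raise ValueError("structure has no atoms")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("every atom needs a positive radius for SASA")
    arr = structure.to_atom_array()
    per_atom = bst.sasa(arr, probe_radius=config.probe_radius,
                        point_number=config.sasa_points,
                        vdw_radii=radii)
    per_atom = np.nan_to_num(per_atom, nan=0.0)
    return per_atom, float(per_atom.sum())


# -- gas-phase term -----------------------------------------------------

def _charge_table(structure: Structure3D, config: EnergeticsConfig):
    """Coordinates / charges / residue keys of all charged atoms."""
    xyz, q, keys, names = [], [], [], []
    for ci, ch in enumerate(structure.chains):
        for res in ch.residues:
            for atom in res.atoms:
                charge = atom.charge
                if (atom.name == "TIP" and res.name == "HIS"
                        and config.his_charged):
                    charge = 1.0
                if charge != 0.0:
                    xyz.append(atom.xyz)
                    q.append(charge)
                    keys.append((ci, res.index))
                    names.append((atom.name, atom.element))
    return (np.array(xyz).reshape(-1, 3), np.array(q), keys, names)


def _pair_matrix(keys):
    """Upper-triangle mask excluding same-residue pairs."""
    n = len(keys)
    mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    for i in range(n):
        for j in range(i + 1, n):
            if keys[i] == keys[j]:
                mask[i, j] = False
    return mask


def e_gas(structure: Structure3D, config: EnergeticsConfig | None = None) -> float:
    """Gas-phase molecular-mechanics energy (kcal/mol): Coulomb sum over
    nonbonded (different-residue) pairs, plus 12-6 LJ when enabled."""
    config = config or EnergeticsConfig()
    xyz, q, keys, _ = _charge_table(structure, config)
    energy = 0.0
    if len(q) > 1:
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
        mask = _pair_matrix(keys)
        if np.any(d[mask] == 0.0):
            raise ValueError("zero-distance charged pair")
        qq = np.outer(q, q)
        energy += config.coulomb_constant / config.eps_in * float(
            np.sum(qq[mask] / d[mask]))
    if config.use_lj:
        energy += _lj_energy(structure, config)
    return energy


def _lj_energy(structure: Structure3D, config: EnergeticsConfig) -> float:
    table = config.lj_table or DEFAULT_LJ
    rows = [(ci, res.index, atom)
            for ci, ch in enumerate(structure.chains)
            for res in ch.residues for atom in res.atoms]
    xyz = np.array([a.xyz for _, _, a in rows])
    eps = np.array([table.get(a.element, (0.1, 3.4))[0] for _, _, a in rows])
    sig = np.array([table.get(a.element, (0.1, 3.4))[1] for _, _, a in rows])
    keys = [(ci, ri) for ci, ri, _ in rows]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    mask = _pair_matrix(keys)
    if np.any(d[mask] == 0.0):
        raise ValueError("zero-distance atom pair")
    eps_ij = np.sqrt(np.outer(eps, eps))
    sig_ij = 0.5 * (sig[:, None] + sig[None, :])
    with np.errstate(divide="ignore"):
        sr6 = np.where(mask, (sig_ij / np.where(d == 0, np.inf, d)) ** 6, 0.0)
    return float(np.sum(4.0 * eps_ij * (sr6 ** 2 - sr6), where=mask))


# -- polar solvation (generalized Born) ----------------------------------

def _born_radii(structure: Structure3D, config: EnergeticsConfig,
                names) -> np.ndarray:
    table = config.born_radius_table
    radii = []
    for name, element in names:
        r = table.get(name, table.get(element))
        if r is None:
            raise ValueError(f"no Born radius for atom {name!r} ({element})")
        if r <= 0:
            raise ValueError("Born radii must be positive")
        radii.append(r)
    return np.array(radii)


def g_polar(structure: Structure3D,
            config: EnergeticsConfig | None = None) -> float:
    """Generalized-Born polar solvation energy (kcal/mol).

    dG_pol = -1/2 (1/eps_in - 1/eps_out) k sum_ij q_i q_j / f_GB with
    the Still interpolation; self-terms (i = j, f_GB = R_i) included.
    """
    config = config or EnergeticsConfig()
    xyz, q, _, names = _charge_table(structure, config)
    if len(q) == 0:
        return 0.0
    born = _born_radii(structure, config, names)
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=2)
    rr = np.outer(born, born)
    f_gb = np.sqrt(d2 + rr * np.exp(-d2 / (4.0 * rr)))
    prefactor = -0.5 * (1.0 / config.eps_in - 1.0 / config.eps_out) \
        * config.coulomb_constant
    return prefactor * float(np.sum(np.outer(q, q) / f_gb))


# -- nonpolar solvation ---------------------------------------------------

def g_sa(sasa_total: float, config: EnergeticsConfig | None = None) -> float:
    """Nonpolar solvation term: exactly gamma * SASA + beta."""
    config = config or EnergeticsConfig()
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    return config.gamma * sasa_total + config.beta


# -- binding free energy ---------------------------------------------------

def entity_energy(structure: Structure3D,
                  config: EnergeticsConfig | None = None) -> EnergyTerms:
    config = config or EnergeticsConfig()
    _, total_sasa = sasa(structure, config)
    return EnergyTerms(e_gas=e_gas(structure, config),
                       g_polar=g_polar(structure, config),
                       g_sa=g_sa(total_sasa, config),
                       sasa=total_sasa)


def _split_dimer(complex_structure: Structure3D):
    if len(complex_structure.chains) != 2:
        raise ValueError("binding energy needs a complex of exactly 2 chains")
    mono_a = Structure3D(chains=[complex_structure.chains[0]])
    mono_b = Structure3D(chains=[complex_structure.chains[1]])
    return mono_a, mono_b


def _single_point(complex_structure: Structure3D,
                  config: EnergeticsConfig):
    mono_a, mono_b = _split_dimer(complex_structure)
    terms_c = entity_energy(complex_structure, config)
    terms_a = entity_energy(mono_a, config)
    terms_b = entity_energy(mono_b, config)
    dg = terms_c.total - terms_a.total - terms_b.total
    return terms_c, terms_a, terms_b, dg


def delta_g_binding(complex_structure: Structure3D,
                    config: EnergeticsConfig | None = None) -> EnergyReport:
    """End-state binding free energy of a two-chain complex.

    Monomers are extracted from the complex with identical coordinates
    and no re-relaxation (single-structure convention).  When
    ``config.ensemble_n > 1``, seeded Gaussian coordinate jitter
    (sigma = ``ensemble_sigma``) generates conformers whose terms are
    averaged; ``ensemble_n = 1`` is bit-for-bit the deterministic
    single-structure result.
    """
    config = config or EnergeticsConfig()
    terms_c, terms_a, terms_b, dg = _single_point(complex_structure, config)
    report = EnergyReport(complex=terms_c, monomer_a=terms_a,
                          monomer_b=terms_b, delta_g_binding=dg,
                          ensemble_n=config.ensemble_n)
    if config.ensemble_n > 1:
        rng = np.random.default_rng(config.seed)
        dgs = []
        for _ in range(config.ensemble_n):
            conformer = complex_structure.copy()
            for _, _, atom in conformer.iter_atoms():
                atom.xyz = atom.xyz + rng.normal(
                    0.0, config.ensemble_sigma, size=3)
            dgs.append(_single_point(conformer, config)[3])
        dgs = np.array(dgs)
        report.ensemble_mean = float(dgs.mean())
        report.ensemble_sd = float(dgs.std(ddof=1))
        report.delta_g_binding = report.ensemble_mean
    return report
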
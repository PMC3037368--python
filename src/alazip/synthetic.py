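"""Seeded generators of group-II BBR/BPC-like synthetic data.

The generators emit sequences and reduced-atom dimer structures that
carry the signatures the analysis modules look for, together with the
ground truth of what was planted, so every pipeline stage runs and can
be validated without any external download:

* a zipper segment with a small-residue core (Ala by default) at the
  'd' register every 7 residues, flanked in a configurable fraction of
  heptads by an acidic residue at 'g' and a basic residue at 'a';
* a full protein with the zipper at the N-terminus, the three NLS-like
  motifs (KPKRxKR, KRxxK, KxKK) planted at their canonical offsets
  (165, 184, 192) and a C-terminal basic domain carrying five invariant
  cysteines;
* parallel or antiparallel reduced-atom dimer models of the zipper at
  native or shifted register.

Random filler is drawn uniformly from residues that can create neither
a core (no A/G/L) nor a charge pair nor a basic motif (no D/E/K/R/H),
so planted features are exactly the detectable ones; ``hard_mode``
switches the filler to natural amino-acid frequencies instead.
Identical spec + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ProteinRecord
from .structure import Structure3D, FORMAL_TIP_CHARGE
from .coilbuild import (HelixParams, HEPTAD_TWIST, build_dimer,
                        build_ideal_helix, interface_phase)

# filler residues: helix-compatible, uncharged, never core-like
FILLER = "SNQTVIMFYW"

# approximate natural amino-acid frequencies (vertebrate+plant average),
# used only in hard mode
NATURAL_FREQS = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.069,
}

ACIDIC = "DE"
BASIC = "KR"


@dataclass(frozen=True)
class ZipperSpec:
    n_heptads: int = 6
    core_residue: str = "A"
    core_register: str = "d"
    complementarity_fraction: float = 1.0
    hard_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_heptads < 2:
            raise ValueError("need at least 2 heptads")
        if self.core_residue not in "ALG":
            raise ValueError("core residue must be A, L or G")
        if self.core_register not in "da":
            raise ValueError("core register must be 'd' or 'a'")
        if not 0.0 <= self.complementarity_fraction <= 1.0:
            raise ValueError("complementarity fraction must be in [0, 1]")
        if self.core_register == "a" and self.complementarity_fraction > 0:
            raise ValueError(
                "core at 'a' occupies the basic charge position; "
                "complementarity_fraction must be 0 for register 'a'")


@dataclass
class ZipperTruth:
    """Ground truth of a planted zipper (1-based positions)."""

    span: tuple
    core_positions: list
    phase: int  # (core_position - 1) % 7
    register: str
    complementary_heptads: list  # 0-based heptad indices
    charge_positions: list = field(default_factory=list)  # (g_pos, a_pos)


@dataclass(frozen=True)
class BPCSpec:
    zipper: ZipperSpec = field(default_factory=ZipperSpec)
    zipper_start: int = 38
    nls_offsets: tuple = (165, 184, 192)
    basic_domain_length: int = 90
    cys_offsets: tuple = (8, 25, 45, 65, 82)  # within the basic domain
    total_length: int = 300
    hard_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        spans = sorted([(self.nls_offsets[0], self.nls_offsets[0] + 6),
                        (self.nls_offsets[1], self.nls_offsets[1] + 4),
                        (self.nls_offsets[2], self.nls_offsets[2] + 3)])
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("NLS motif offsets overlap")
        zipper_end = self.zipper_start + 7 * self.zipper.n_heptads - 1
        if zipper_end >= spans[0][0]:
            raise ValueError("zipper overlaps the NLS region")
        if len(self.cys_offsets) != 5:
            raise ValueError("exactly 5 cysteines are planted")
        if max(self.cys_offsets) > self.basic_domain_length:
            raise ValueError("cysteine offsets exceed the basic domain")
        if spans[-1][1] > self.total_length - self.basic_domain_length:
            raise ValueError("NLS region overlaps the basic domain")


@dataclass
class BPCTruth:
    zipper: ZipperTruth
    nls_spans: dict  # pattern_id -> (start, end)
    cys_positions: list
    basic_domain_span: tuple


def _filler(rng: np.random.Generator, n: int, hard_mode: bool) -> list:
    if hard_mode:
        aas = list(NATURAL_FREQS)
        p = np.array(list(NATURAL_FREQS.values()))
        p = p / p.sum()
        return list(rng.choice(aas, size=n, p=p))
    return list(rng.choice(list(FILLER), size=n))


def _zipper_from_rng(spec: ZipperSpec, rng: np.random.Generator,
                     offset: int = 0):
    """Zipper sequence as a char list plus ground truth; positions in
    the truth are shifted by ``offset`` (0 for a standalone zipper)."""
    n = spec.n_heptads
    chars = _filler(rng, 7 * n, spec.hard_mode)
    core_rel = 3 if spec.core_register == "d" else 0
    n_comp = int(round(spec.complementarity_fraction * n))
    comp = sorted(rng.choice(n, size=n_comp, replace=False).tolist())
    core_positions, charge_positions = [], []
    for h in range(n):
        base = 7 * h
        chars[base + core_rel] = spec.core_residue
        core_positions.append(offset + base + core_rel + 1)
        if h in comp:
            chars[base + 6] = str(rng.choice(list(ACIDIC)))
            chars[base + 0] = str(rng.choice(list(BASIC)))
            charge_positions.append((offset + base + 7, offset + base + 1))
    truth = ZipperTruth(
        span=(offset + 1, offset + 7 * n),
        core_positions=core_positions,
        phase=(core_positions[0] - 1) % 7,
        register=spec.core_register,
        complementary_heptads=comp,
        charge_positions=charge_positions,
    )
    return chars, truth


def generate_zipper(spec: ZipperSpec) -> tuple:
    """A standalone zipper segment and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    chars, truth = _zipper_from_rng(spec, rng)
    record = ProteinRecord(
        id=f"synthetic-zipper-seed{spec.seed}",
        sequence="".join(chars),
        annotations={"generator": "alazip.synthetic.generate_zipper",
                     "seed": str(spec.seed)},
    )
    return record, truth


# residues for the basic DNA-binding domain filler: polar/basic-leaning
# but without K/R (which would create spurious NLS matches) and without
# the planted C
BASIC_DOMAIN_FILLER = "HSGNQTY"


def generate_bpc_protein(spec: BPCSpec) -> tuple:
    """A full synthetic group-II-like protein and its ground truth:
    N-terminal zipper, the three NLS-like motifs at the configured
    offsets, and a C-terminal basic domain with five cysteines."""
    rng = np.random.default_rng(spec.seed)
    chars = _filler(rng, spec.total_length, spec.hard_mode)

    zip_chars, zip_truth = _zipper_from_rng(spec.zipper, rng,
                                            offset=spec.zipper_start - 1)
    chars[spec.zipper_start - 1:
          spec.zipper_start - 1 + len(zip_chars)] = zip_chars

    def put(pos0, text):
        for k, ch in enumerate(text):
            chars[pos0 + k] = ch

    def x(n=1):
        return "".join(rng.choice(list(FILLER), size=n))

    o1, o2, o3 = spec.nls_offsets
    put(o1 - 1, "KPKR" + x() + "KR")
    put(o2 - 1, "KR" + x(2) + "K")
    put(o3 - 1, "K" + x() + "KK")
    nls_spans = {"KPKRxKR": (o1, o1 + 6), "KRxxK": (o2, o2 + 4),
                 "KxKK": (o3, o3 + 3)}

    basic_start = spec.total_length - spec.basic_domain_length + 1
    basic = list(rng.choice(list(BASIC_DOMAIN_FILLER),
                            size=spec.basic_domain_length))
    cys_positions = []
    for off in spec.cys_offsets:
        basic[off - 1] = "C"
        cys_positions.append(basic_start + off - 1)
    chars[basic_start - 1:] = basic

    record = ProteinRecord(
        id=f"synthetic-bpc-seed{spec.seed}",
        sequence="".join(chars),
        annotations={"generator": "alazip.synthetic.generate_bpc_protein",
                     "seed": str(spec.seed)},
    )
    truth = BPCTruth(zipper=zip_truth, nls_spans=nls_spans,
                     cys_positions=cys_positions,
                     basic_domain_span=(basic_start, spec.total_length))
    return record, truth


# -- structural fixtures --------------------------------------------------

def zipper_monomer(record: ProteinRecord, params: HelixParams | None = None,
                   register_offset: int = 0,
                   first_residue_heptad_index: int = 0,
                   chain_id: str = "A") -> Structure3D:
    """Build a zipper monomer with its interface face oriented for dimer
    placement; ``register_offset`` slides the sequence along the backbone
    register (rotating the side-chain pattern by offset * 102.857 deg)."""
    params = params or HelixParams.heptad_locked()
    phase = interface_phase(first_residue_heptad_index,
                            params.twist_per_residue) \
        + register_offset * HEPTAD_TWIST
    return build_ideal_helix(record, params=params, phase_deg=phase,
                             chain_id=chain_id)


def expected_salt_bridge_pairs(truth: ZipperTruth) -> list:
    """Residue pairs (chain A index, chain B index) guaranteed by
    construction in a parallel complementary dimer at native register:
    the 'g' of each complementary heptad pairs with the 'a' of the next
    complementary heptad on the partner chain, and mirrored."""
    offset = truth.span[0] - 1
    comp = set(truth.complementary_heptads)
    pairs = []
    for h in sorted(comp):
        if h + 1 in comp:
            g_pos = offset + 7 * h + 7
            a_pos = offset + 7 * (h + 1) + 1
            pairs.append((g_pos, a_pos))
            pairs.append((a_pos, g_pos))
    return sorted(pairs)


def generate_dimer_fixture(spec: ZipperSpec, orientation: str = "parallel",
                           register_offset: int = 0,
                           separation: float | None = None) -> tuple:
    """A reduced-atom zipper dimer plus ground truth contact list.

    The ground truth enumerates the geometrically guaranteed
    complementary residue pairs (nonempty only for the parallel,
    native-register construction).
    """
    record, truth = generate_zipper(spec)
    params = HelixParams.heptad_locked(orientation=orientation)
    if separation is not None:
        params = params.with_(interhelical_offset=separation)
    mono = zipper_monomer(record, params=params,
                          register_offset=register_offset)
    dimer = build_dimer(mono, mono, params)
    if orientation == "parallel" and register_offset == 0 \
            and (separation is None or separation <= 10.5):
        expected = expected_salt_bridge_pairs(truth)
    else:
        expected = []
    return dimer, {"record": record, "zipper": truth,
                   "expected_salt_bridges": expected}


def scramble_charges(structure: Structure3D, seed: int = 0) -> Structure3D:
    """Charge-scrambled control at matched geometry: within each chain,
    the residue identities are randomly permuted across positions (tips
    rebuilt), so composition and backbone stay identical but the planted
    charge complementarity is destroyed."""
    from .coilbuild import _rebuild_side_chain  # shared tip rebuild logic

    rng = np.random.default_rng(seed)
    out = structure.copy()
    for ch in out.chains:
        names = [r.name for r in ch.residues]
        perm = rng.permutation(len(names))
        ch.residues = [
            _rebuild_side_chain(res, names[perm[i]])
            for i, res in enumerate(ch.residues)
        ]
    return out


def is_charged_residue(name: str) -> bool:
    return name in FORMAL_TIP_CHARGE
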
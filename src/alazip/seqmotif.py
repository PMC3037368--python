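"""Sequence-level coiled-coil and NLS motif analysis.

Implements heptad register assignment (a-g labels with period 7),
detection of Alanine-zipper motifs (small residues at the core register
with exact 7-residue spacing, flanked by complementary charge pairs:
acidic at 'g', basic at 'a'), scanning for the three NLS-like motifs of
group-II BBR/BPC proteins (KxKK, KRxxK, KPKRxKR), and helical-wheel
projection (100 degrees per residue, clockwise viewed from the
N-terminus).

Conventions
-----------
* Positions are 1-based inclusive.
* ``HeptadAssignment.phase`` is the letter index (a=0 ... g=6) of the
  first residue of the span.
* ``AlaZipperHit.phase`` is the 0-based residue class of the core
  positions, i.e. ``(core_position - 1) % 7``; two hits have the same
  phase iff their cores lie on the same mod-7 lattice.
* The conserved core is assigned to register 'd' by default.  Because
  the underlying data permit no definite register decision, ``register``
  may be set to 'a' instead; span and charge-pair positions shift
  accordingly.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .records import ProteinRecord, STANDARD_AA

HEPTAD_LETTERS = "abcdefg"
ACIDIC = frozenset("DE")
BASIC = frozenset("KR")
DEFAULT_CORE = frozenset("AG")

# offset of the core register within a heptad that starts at 'a'
REGISTER_OFFSET = {"d": 3, "a": 0}

# the three NLS-like motifs; x = any standard residue (never a gap)
_X = "".join(sorted(STANDARD_AA))
NLS_PATTERNS = {
    "KxKK": f"K[{_X}]KK",
    "KRxxK": f"KR[{_X}][{_X}]K",
    "KPKRxKR": f"KPKR[{_X}]KR",
}


@dataclass
class HeptadAssignment:
    """Per-residue heptad letters over a span; labels cycle with period 7."""

    start: int
    end: int
    phase: int
    labels: str

    def label(self, position: int) -> str:
        if not self.start <= position <= self.end:
            raise IndexError(f"position {position} outside span")
        return self.labels[position - self.start]

    def positions_with_label(self, letter: str) -> list[int]:
        return [self.start + i for i, l in enumerate(self.labels) if l == letter]


@dataclass
class AlaZipperHit:
    span: tuple
    core_positions: list
    core_residue_counts: dict
    spacings: list
    register: str
    phase: int
    n_complementary_pairs: int
    score: float
    n_core_matches: int = 0

    def __post_init__(self):
        if sorted(self.core_positions) != list(self.core_positions):
            raise ValueError("core positions must be sorted ascending")
        if any(s <= 0 for s in self.spacings):
            raise ValueError("spacings must be positive")


@dataclass
class NLSHit:
    pattern_id: str
    span: tuple
    matched_text: str

    def __post_init__(self):
        length = {"KxKK": 4, "KRxxK": 5, "KPKRxKR": 7}[self.pattern_id]
        if self.span[1] - self.span[0] + 1 != length:
            raise ValueError("span length does not match pattern length")


@dataclass
class WheelProjection:
    entries: list = field(default_factory=list)
    direction: str = "clockwise"


def _check_span(record: ProteinRecord, span) -> tuple:
    start, end = int(span[0]), int(span[1])
    if not (1 <= start <= end <= len(record)):
        raise IndexError(f"span ({start}, {end}) out of bounds for "
                         f"sequence of length {len(record)}")
    return start, end


def assign_heptads(record: ProteinRecord, span, phase: int) -> HeptadAssignment:
    """Label every residue in ``span`` with its heptad letter.

    ``phase`` (0-6) is the letter index of the first residue of the
    span; labels then cycle a-g with exact period 7.
    """
    start, end = _check_span(record, span)
    if not 0 <= int(phase) <= 6:
        raise ValueError("phase must be an integer 0-6")
    labels = "".join(HEPTAD_LETTERS[(i + phase) % 7] for i in range(end - start + 1))
    return HeptadAssignment(start=start, end=end, phase=int(phase), labels=labels)


def helical_wheel(record: ProteinRecord, span, phase: int = 0) -> WheelProjection:
    """Project a span onto the classical 100-degrees-per-residue wheel.

    angle(i) = ((i - start) * 100) mod 360, measured clockwise viewed
    from the N-terminus; ring_index increments each full turn.
    """
    start, end = _check_span(record, span)
    entries = []
    for pos in range(start, end + 1):
        total = (pos - start) * 100
        entries.append((pos, record.residue(pos), float(total % 360), total // 360))
    return WheelProjection(entries=entries)


def scan_nls(record: ProteinRecord) -> list[NLSHit]:
    """Report every (possibly overlapping) match of the three NLS-like
    motifs, with 1-based spans."""
    hits = []
    for pattern_id, pattern in NLS_PATTERNS.items():
        # lookahead makes overlapping matches visible
        for m in re.finditer(f"(?=({pattern}))", record.sequence):
            text = m.group(1)
            start = m.start() + 1
            hits.append(NLSHit(pattern_id=pattern_id,
                               span=(start, start + len(text) - 1),
                               matched_text=text))
    hits.sort(key=lambda h: (h.span[0], -(h.span[1] - h.span[0])))
    return hits


def charge_complementarity(assignment: HeptadAssignment,
                           record: ProteinRecord) -> tuple:
    """Per-heptad complementarity flags over the complete heptads of a
    span: a heptad is complementary iff its 'g' residue is acidic (D/E)
    and its 'a' residue is basic (K/R).

    Returns ``(flags, n_complementary_pairs)`` where ``flags`` is one
    boolean per complete heptad (a through g inside the span).
    """
    flags = []
    for pos in assignment.positions_with_label("a"):
        if pos + 6 > assignment.end:
            continue
        a_res = record.residue(pos)
        g_res = record.residue(pos + 6)
        flags.append(a_res in BASIC and g_res in ACIDIC)
    return flags, sum(flags)


def _complementary_pairs(sequence: str, core_positions, register: str) -> int:
    """Count heptads (one per core position) whose 'g' residue is acidic
    and whose 'a' residue is basic, with a/g located relative to the
    core register."""
    n = len(sequence)
    if register == "d":
        rel_a, rel_g = -3, 3
    else:  # register 'a': the core *is* 'a'; 'g' closes the heptad
        rel_a, rel_g = 0, 6
    count = 0
    for core in core_positions:
        a_pos, g_pos = core + rel_a, core + rel_g
        if 1 <= a_pos <= n and 1 <= g_pos <= n:
            if sequence[a_pos - 1] in BASIC and sequence[g_pos - 1] in ACIDIC:
                count += 1
    return count


def _hit_from_core(record: ProteinRecord, core_positions, n_matches: int,
                   register: str, weight: float) -> AlaZipperHit:
    seq = record.sequence
    n = len(seq)
    rel = REGISTER_OFFSET[register]
    first, last = core_positions[0], core_positions[-1]
    span = (max(1, first - rel), min(n, last + (6 - rel)))
    n_comp = _complementary_pairs(seq, core_positions, register)
    counts = dict(Counter(seq[p - 1] for p in core_positions))
    return AlaZipperHit(
        span=span,
        core_positions=list(core_positions),
        core_residue_counts=counts,
        spacings=[7] * (len(core_positions) - 1),
        register=register,
        phase=(first - 1) % 7,
        n_complementary_pairs=n_comp,
        score=n_matches + weight * n_comp,
        n_core_matches=n_matches,
    )


def detect_ala_zipper(record: ProteinRecord, min_core: int = 4,
                      max_core_mismatch: int = 1,
                      permissive_core=DEFAULT_CORE,
                      register: str = "d",
                      complementarity_weight: float = 2.0) -> list[AlaZipperHit]:
    """Detect Alanine-zipper motifs.

    A hit is a maximal arithmetic progression of positions with step 7
    (>= ``min_core`` positions) whose first and last residues are in
    ``permissive_core`` and with at most ``max_core_mismatch`` interior
    positions outside it.  Hits are scored by the number of core matches
    plus ``complementarity_weight`` per charge-complementary heptad and
    sorted by descending score (ties: leftmost start, lowest phase).
    """
    if register not in REGISTER_OFFSET:
        raise ValueError("register must be 'd' or 'a'")
    permissive_core = frozenset(permissive_core)
    seq = record.sequence
    n = len(seq)

    # candidate runs per mod-7 residue class
    candidates = []
    for cls in range(7):
        positions = list(range(cls + 1, n + 1, 7))  # 1-based
        m = len(positions)
        for i in range(m):
            if seq[positions[i] - 1] not in permissive_core:
                continue
            mismatches = 0
            for j in range(i, m):
                if seq[positions[j] - 1] not in permissive_core:
                    mismatches += 1
                    if mismatches > max_core_mismatch:
                        break
                    continue
                if j - i + 1 >= min_core:
                    candidates.append((cls, i, j))

    # keep only maximal runs (not contained in another valid run of the
    # same class)
    by_class = {}
    for cls, i, j in candidates:
        by_class.setdefault(cls, []).append((i, j))
    hits = []
    for cls, runs in by_class.items():
        positions = list(range(cls + 1, n + 1, 7))
        maximal = [
            (i, j) for (i, j) in runs
            if not any(i2 <= i and j <= j2 and (i2, j2) != (i, j)
                       for (i2, j2) in runs)
        ]
        for i, j in sorted(set(maximal)):
            core = positions[i:j + 1]
            n_matches = sum(1 for p in core if seq[p - 1] in permissive_core)
            hits.append(_hit_from_core(record, core, n_matches, register,
                                       complementarity_weight))

    hits.sort(key=lambda h: (-h.score, h.span[0], h.phase))
    return hits
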
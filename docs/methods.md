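# Methods

This note documents the models behind `alazip`: what is computed, under
which assumptions, with which defaults, and where the desk-scale
simplifications end.

## The motif

An Alanine zipper (Alacoil) is a coiled-coil segment whose heptad core
carries small residues — alanine, sometimes glycine — instead of the
leucines/isoleucines of a canonical Leucine zipper. In the group-II
BBR/BPC arrangement the core alanines sit at register **d** with an
exact 7-residue spacing, and the interface is stabilized
electrostatically: acidic residues (D/E) at position **g** of one helix
face basic residues (K/R) at position **a** of the partner helix.
Because Alacoils are also known with the core at register **a**, and the
sequence alone does not force a choice, the detector's register
convention is a parameter (`register="d"` by default, `"a"`
available); span boundaries and the a/g charge positions shift
accordingly.

## Sequence analysis

**Heptad assignment.** Labels a–g cycle with exact period 7;
`phase` is the letter index of the first residue of the span.

**Zipper detection.** A hit is a *maximal* arithmetic progression of
positions with step 7 (≥ `min_core` positions, default 4) whose first
and last residues belong to the permissive core set (default `{A, G}`,
motivated by naturally occurring glycine-core variants) with at most
`max_core_mismatch` interior exceptions (default 1). Hits are scored
`n_core_matches + w · n_complementary_pairs` with `w = 2.0`. The data
provide no canonical score; the weight is chosen so that a fully
complementary 4-heptad hit outranks a bare 6-heptad hit, making charge
complementarity the dominant evidence. Ties break deterministically:
leftmost start, then lowest phase. The production detector is kept
equivalent to an exhaustive window × phase enumeration (asserted against
an independently written brute-force oracle in the tests).

**NLS motifs.** The three basic motifs `KxKK`, `KRxxK`, `KPKRxKR` are
matched with `x` = any of the 20 standard residues (never a gap, never
`X`); overlapping matches are all reported with 1-based inclusive
spans. The scanner reports every occurrence and takes no position on
which of two near-identical published coordinate sets for the second
motif is correct — both are found if present. The canonical group-II
arrangement places the motifs at offsets 165, 184 and 192, spanning
positions 165–195: a 31-residue region (note that the flanking region
often quoted as "164–195" would be 32 residues; the package treats the
motif-to-motif span of 31 as the authoritative arithmetic).

**Helical wheel.** The classical projection at 100°/residue, clockwise
viewed from the N-terminus; residues 7 apart land 340° clockwise
(equivalently 20° counter-clockwise), the drift that supercoiling
absorbs in a real coiled coil.

## Reduced-atom structural model

Residues are represented by the four backbone atoms, a CB placed
radially off the helix axis, and a single side-chain **tip**
pseudo-atom along the CA→CB direction representing the side chain's
functional end group. CA→tip distances (Å): ASP 3.7, GLU 5.0, LYS 6.4,
ARG 7.3, HIS 4.6, LEU 3.9, ALA 1.5 (= CB), others 2.4 — approximate
extended-rotamer reaches. Tips of D/E/K/R carry formal charges ±1 e
(His neutral by default, switchable). Full-atom PDB input bypasses the
tip table: element-based radii and split formal charges on
carboxylate/ammonium/guanidinium atoms are assigned instead, and both
representations flow through identical downstream code.

**Helix builder.** CA atoms on a cylinder (radius 2.3 Å, rise
1.5 Å/residue); N, C, O at fixed cylindrical offsets. Bonded backbone
geometry is deliberately approximate — only CA geometry and side-chain
directions matter for interface analysis and energetics. The default
twist is the 100°/residue of an isolated α-helix. For dimer models the
builder uses the **heptad-commensurate twist** 720/7 ≈ 102.857°/residue
(exactly 3.5 residues/turn): this is the straightened representation of
a supercoiled coiled-coil helix, in which every heptad presents an
identical face to the partner, so a rigid straight-axis placement
reproduces the periodic interface without modelling the supercoil
itself (superhelix radius 4.9 Å and pitch 148 Å are carried as
parameters for reference; the axis separation 9.8 Å = 2 × 4.9 Å).

**Dimer placement.** Parallel: chain B is chain A rotated 180° about
the vertical midline (a C2 operation), so the a/d core faces meet, with
the a/d positions straddling the interface direction at ±180/7° and the
charged g/e positions at ±77°. This construction guarantees that in a
fully complementary n-heptad zipper, the Glu tip at *g* of heptad *i*
lies within the 4 Å salt-bridge cutoff of the Lys tip at *a* of heptad
*i+1* on the partner chain (and mirrored): ≥ n−1 bridges per direction
by construction, verified by the contact detector. Antiparallel: chain
B is flipped end-over-end by a proper 180° rotation about the
perpendicular axis and re-aligned axially, which breaks the planted g–a
pairing.

**Register-shifted variants.** Threading the same sequence one register
position along the backbone moves the core from d to c (the "1"
variant); three positions give d→c→b→a (the "3" variant, core at a).
In the reduced model a register slide rotates the whole side-chain
pattern rigidly by (slide × 102.857°) about each helix axis while the
placement stays fixed, so *both* shifted variants lose their planted
salt bridges — the one-position slide maximally (−102.9°), the
three-position slide partially (+51.4°). Limitation: real side chains
repack; all-atom work finds the a-register dimer of comparable
stability to the native d-register, which rigid radial tips cannot
reproduce. The pipeline therefore only relies on the robust ordering:
the one-position slide is the least stable model variant.

**Superposition.** Kabsch least-squares with proper rotations only
(reflections excluded via the SVD determinant correction); RMSD over a
named atom selection (backbone by default).

**Side-chain relaxation.** Greedy projected gradient descent on a
soft-sphere overlap energy Σ max(0, rᵢ+rⱼ−d)², moving tips only, each
tip constrained to its CA sphere (bond length preserved). A step is
accepted only if the energy does not increase (the step halves
otherwise), so the trace is monotone non-increasing and the procedure
is deterministic. Degenerate input: a perfectly collinear CA–tip–tip
overlap has a purely radial gradient that the sphere projection
annihilates; such saddle configurations do not relax (they do not occur
in built models). Defaults echo common minimization practice: 200 steps
for monomer tips, 2000 for dimers.

## Interface contacts

Salt bridge: minimum distance between opposite-sign charged-group atoms
on different chains ≤ 4.0 Å — the common literature convention; the
criterion is a config key because the underlying studies rarely state
one. Hydrogen bond: donor/acceptor heavy atoms on different chains ≤
3.5 Å (backbone N donates, backbone O accepts; side-chain heteroatoms
typed by residue); a D–H···A ≥ 120° angle test activates only when
explicit hydrogens exist in the input, since reduced models carry none.
A residue pair is counted once per type at its minimum distance and
typed by its strongest interaction (salt bridge first) — residue-pair,
not atom-pair, semantics. Because geometric contact definitions vary
between analysis tools, absolute counts are comparable only within this
package; ratios across variants are the robust quantity.

## Binding energetics

End-state decomposition with single-structure monomer extraction: the
monomers keep the complex coordinates, so internal bonded terms cancel
identically in ΔG and are not computed at all (the cancellation is
asserted in the tests by differencing).

* **E_gas**: Coulomb k·qᵢqⱼ/(εᵢₙ·rᵢⱼ) over different-residue pairs,
  k = 332.0636 kcal Å mol⁻¹ e⁻², εᵢₙ = 1. A 12-6 Lennard-Jones term is
  available for full-atom input and off by default in reduced mode,
  where steric validity is the builder's job.
* **G_polar**: generalized Born with the Still interpolation
  f_GB = sqrt(r² + RᵢRⱼ·exp(−r²/4RᵢRⱼ)), self-terms included,
  ΔG = −½(1/εᵢₙ − 1/εₒᵤₜ)·k·Σᵢⱼ qᵢqⱼ/f_GB, εₒᵤₜ = 80. GB is the
  standard analytic surrogate for a finite-difference Poisson–Boltzmann
  solver, which is out of desk scope. Born radii are a fixed per-type
  table (tips 2.0 Å; backbone N 1.55, O 1.50, C 1.70 Å): radii do not
  respond to burial, so GB screening is position-independent — adequate
  for sign/ordering comparisons between variants at matched geometry,
  not for absolute solvation energies.
* **G_sa**: exactly γ·SASA + β, γ = 0.0072 kcal mol⁻¹ Å⁻², β = 0. SASA
  by probe-sphere sampling (Shrake–Rupley, probe 1.4 Å, 960 Fibonacci
  points per atom, deterministic; an isolated sphere is reproduced to
  well under 1 %). The point grid is fixed in the lab frame, so SASA —
  and hence ΔG — is rotation invariant only to sampling tolerance
  (≲ 0.1 kcal/mol on the fixtures); the analytic terms are exactly
  invariant.
* **Entropy**: not computed. Normal-mode analysis on a reduced
  pseudo-atom model would be meaningless; every report carries an
  explicit "not computed"/"omitted" marker rather than a silent zero.

**Ensembles.** Instead of extracting snapshots from a molecular-dynamics
trajectory, `ensemble_n > 1` applies seeded Gaussian coordinate jitter
(σ = 0.3 Å default) to the complex and averages the per-conformer ΔG
(mean ± sd reported). The default is `ensemble_n = 1`: the
deterministic single-structure result, which `ensemble_n = 1` matches
bit-for-bit by construction. A 500-conformer ensemble — the size
matching common snapshot-averaging practice — is a config switch away
but is not the default, because the package's comparisons are
construction-based orderings for which jitter adds cost, not
information.

**What ΔG means here.** Absolute values from the reduced model are not
comparable to all-atom explicit-solvent MM-PBSA ensemble averages and
the package makes no such claim. The meaningful outputs are signs and
orderings on matched-geometry fixtures: parallel complementary <
antiparallel; complementary < charge-scrambled; shrinking the core
(Ala→Gly) does not flip the sign, because the charges, not the core,
drive binding in this model.

## Synthetic data: what it does and does not emulate

The generators plant exactly the signatures the detectors look for:
heptad-aligned zipper (core at d, charges at g/a in a configurable
fraction of heptads), the three NLS motifs at offsets 165/184/192, five
cysteines in a C-terminal basic domain, total length 300. Random filler
is uniform over `SNQTVIMFYW` — no A/G/L (core-like), no D/E/K/R/H
(charge/basic motifs), no C, no P — so the planted features are the
only detectable ones and ground truth is exact; `hard_mode` switches to
natural amino-acid frequencies, where spurious partial motifs can and
do occur. The filler has no positional correlations, no phylogenetic
structure and no real compositional bias: passing the round-trip suite
shows the detectors recover what the model says is there, not that they
would rank hits correctly on proteomes. The basic domain is "basic"
only architecturally (position + cysteines); its filler avoids K/R to
keep the NLS census exact. Structural fixtures use the commensurate-
twist builder, so their contact geometry is idealized rather than
crystallographic.

## Pipeline and reproducibility

One seeded run produces, per input: a motif TSV, a PDB + contact TSV +
energy JSON per variant (native / slide-1 / slide-3 / core-swap /
charge-scrambled / antiparallel), and a summary JSON with the variant
comparison (ratios vs. native, ordering booleans, the least-stable
*model* variant flagged — the scrambled/antiparallel controls are
tabulated but never flagged). Config files are flat `key = value` text
with one dotted nesting level (`energetics.gamma = 0.0072`); unknown
keys are hard errors, because silently ignored typos are the main
reproducibility hazard. The output directory is not part of the config
hash. No timestamps are written anywhere; identical config + seed gives
byte-identical output trees, which the test suite asserts by byte
comparison of two complete runs.

## Problem sizes

Defaults used throughout tests and the acceptance script: 6-heptad
zippers (42 residues, ~500 atoms per dimer), 300-residue synthetic
proteins, 200-seed recovery and ordering suites, 960 SASA points. A
full acceptance run is under a minute on one CPU; the complete test
suite under two minutes.

## Known limitations

* Rigid radial side chains: no rotamers, no induced fit; register-slide
  variants are penalized more harshly than all-atom modelling suggests.
* Straight-axis dimers: supercoiling is absorbed into the commensurate
  twist, not modelled; backbone bonded geometry is approximate.
* Fixed Born radii: no burial dependence in the polar term.
* No entropy term; ΔG values are enthalpy-like scores.
* Contact definitions are tool-specific; only within-package
  comparisons are meaningful.
* The synthetic filler is deliberately unrealistic (see above); use
  `hard_mode` for harder negatives.
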
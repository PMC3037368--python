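"""End-to-end analysis pipeline: scan -> build -> interface -> energy
-> report, as one seeded, reproducible run.

For each input protein the pipeline detects the zipper and NLS motifs,
builds a set of reduced-atom dimer model variants of the top zipper hit
(native register, register shifted by -1 and +3, core swapped to
leucine, a charge-scrambled control at matched geometry and an
antiparallel placement), inventories the interface contacts and computes
the binding free-energy decomposition of every variant, and writes a
summary that compares the variants and flags the least stable one.

All outputs are plain text (TSV with a single '#'-header line, JSON,
PDB); identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .records import ProteinRecord, read_fasta, write_motif_tsv
from .seqmotif import detect_ala_zipper, scan_nls
from .structure import Structure3D, write_pdb
from .coilbuild import HelixParams, build_dimer, mutate_core
from .interactions import interface_inventory
from .energetics import EnergeticsConfig, delta_g_binding
from .synthetic import BPCSpec, generate_bpc_protein, scramble_charges, \
    zipper_monomer

VARIANTS = ("native", "minus1", "plus3", "core_swap", "scrambled",
            "antiparallel")

# register slides in residues: the "1" variant moves the core from 'd'
# to 'c', the "3" variant three positions further to 'a' (d->c->b->a)
_REGISTER_OFFSET = {"native": 0, "minus1": -1, "plus3": -3,
                    "core_swap": 0, "scrambled": 0, "antiparallel": 0}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "alazip-run"
    fasta: str | None = None  # None -> synthetic group-II fixture
    register: str = "d"
    min_core: int = 4
    salt_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    variants: tuple = VARIANTS
    energetics: EnergeticsConfig = field(default_factory=EnergeticsConfig)

    # -- flat key-value (one nesting level) form -----------------------
    # ``outdir`` is accepted on read but never emitted: the run location
    # is not part of the analysis configuration (and must not perturb
    # the config hash of otherwise identical runs)
    _SCALARS = ("seed", "fasta", "register", "min_core",
                "salt_cutoff", "hbond_cutoff")
    _READ_ONLY_KEYS = ("outdir",)
    _ENERGY_KEYS = ("coulomb_constant", "eps_in", "eps_out", "gamma",
                    "beta", "probe_radius", "sasa_points", "ensemble_n",
                    "ensemble_sigma", "seed", "his_charged", "use_lj")

    def to_text(self) -> str:
        lines = []
        for key in self._SCALARS:
            value = getattr(self, key)
            if value is not None:
                lines.append(f"{key} = {value}")
        lines.append("variants = " + ",".join(self.variants))
        for key in self._ENERGY_KEYS:
            lines.append(f"energetics.{key} = {getattr(self.energetics, key)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        plain, energy = {}, {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key.startswith("energetics."):
                subkey = key[len("energetics."):]
                if subkey not in cls._ENERGY_KEYS:
                    raise ValueError(f"unknown config key {key!r}")
                energy[subkey] = value
            elif key == "variants":
                plain["variants"] = tuple(
                    v.strip() for v in value.split(",") if v.strip())
            elif key in cls._SCALARS or key in cls._READ_ONLY_KEYS:
                plain[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")

        def convert(value, target_type):
            if target_type is bool:
                return value in ("True", "true", "1", "yes")
            if value == "None":
                return None
            return target_type(value)

        kwargs = {}
        casts = {"seed": int, "min_core": int, "salt_cutoff": float,
                 "hbond_cutoff": float, "outdir": str, "fasta": str,
                 "register": str}
        for key, value in plain.items():
            if key == "variants":
                kwargs[key] = value
            else:
                kwargs[key] = convert(value, casts[key])
        ecasts = {"coulomb_constant": float, "eps_in": float,
                  "eps_out": float, "gamma": float, "beta": float,
                  "probe_radius": float, "sasa_points": int,
                  "ensemble_n": int, "ensemble_sigma": float, "seed": int,
                  "his_charged": bool, "use_lj": bool}
        ekwargs = {k: convert(v, ecasts[k]) for k, v in energy.items()}
        kwargs["energetics"] = EnergeticsConfig(**ekwargs)
        cfg = cls(**kwargs)
        for variant in cfg.variants:
            if variant not in VARIANTS:
                raise ValueError(f"unknown variant {variant!r}")
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def build_variant(record: ProteinRecord, hit, variant: str,
                  seed: int = 0) -> Structure3D:
    """Build one dimer model variant of a detected zipper hit."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    start, end = hit.span
    segment = ProteinRecord(id=f"{record.id}|zipper",
                            sequence=record.subsequence(start, end))
    # heptad letter index of the segment's first residue, in the hit's
    # register frame (core at 'd' -> core class maps to letter index 3)
    core_rel = 3 if hit.register == "d" else 0
    first_idx = (core_rel - (hit.core_positions[0] - start)) % 7
    orientation = "antiparallel" if variant == "antiparallel" else "parallel"
    params = HelixParams.heptad_locked(orientation=orientation)
    mono = zipper_monomer(segment, params=params,
                          register_offset=_REGISTER_OFFSET[variant],
                          first_residue_heptad_index=first_idx)
    if variant == "core_swap":
        core_local = [p - start + 1 for p in hit.core_positions]
        swap_to = "LEU" if segment.sequence[core_local[0] - 1] != "L" else "ALA"
        from_res = segment.sequence[core_local[0] - 1]
        mono = mutate_core(mono, from_res, swap_to, core_local)
    dimer = build_dimer(mono, mono, params)
    if variant == "scrambled":
        dimer = scramble_charges(dimer, seed=seed)
    return dimer


def variant_report(reports: dict,
                   flag_among=("native", "minus1", "plus3",
                               "core_swap")) -> dict:
    """Comparison table across variant energy/contact reports.

    ``reports`` maps variant name -> dict with keys ``delta_g``,
    ``n_salt_bridges``, ``n_hbonds`` (missing variants allowed: they are
    reported as absent).  Flags the least stable model variant (highest
    binding energy among ``flag_among``; controls such as the scrambled
    or antiparallel placements are tabulated but never flagged); ratios
    are relative to ``native``.
    """
    table = {}
    present = {k: v for k, v in reports.items() if v is not None}
    native = present.get("native")
    for name in reports:
        rep = reports[name]
        if rep is None:
            table[name] = {"status": "absent"}
            continue
        row = {"status": "ok", "delta_g": rep["delta_g"],
               "n_salt_bridges": rep["n_salt_bridges"],
               "n_hbonds": rep["n_hbonds"]}
        if native is not None:
            def rel(a, b):
                return 1.0 if a == b else (
                    float("inf") if b == 0 else a / b)
            row["salt_ratio_vs_native"] = rel(rep["n_salt_bridges"],
                                              native["n_salt_bridges"])
            row["hbond_ratio_vs_native"] = rel(rep["n_hbonds"],
                                               native["n_hbonds"])
        table[name] = row
    least_stable = None
    dgs = {k: v["delta_g"] for k, v in present.items()
           if not flag_among or k in flag_among}
    if dgs and len(set(dgs.values())) > 1:
        least_stable = max(sorted(dgs), key=lambda k: dgs[k])
    return {"variants": table, "least_stable": least_stable}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"alazip {__version__}", f"seed {config.seed}",
                 f"config_hash {config.config_hash()}"]
    (outdir / "config.txt").write_text(config.to_text())

    # ---- inputs -------------------------------------------------------
    stage = "input"
    try:
        if config.fasta:
            records = read_fasta(config.fasta)
            if not records:
                raise PipelineError(stage, f"no records in {config.fasta}")
        else:
            record, _ = generate_bpc_protein(BPCSpec(seed=config.seed))
            records = [record]
            log_lines.append("input synthetic group-II fixture")
    except PipelineError:
        _write_log(outdir, log_lines)
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        _write_log(outdir, log_lines)
        raise PipelineError(stage, str(exc)) from exc

    summary = {"alazip_version": __version__, "seed": config.seed,
               "config_hash": config.config_hash(), "records": {}}
    for record in records:
        summary["records"][record.id] = _run_one(record, config, outdir,
                                                 log_lines)
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True)
                            + "\n")
    _write_log(outdir, log_lines)
    return outdir


def _write_log(outdir: Path, lines) -> None:
    (Path(outdir) / "run.log").write_text("\n".join(lines) + "\n")


def _safe(name: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-_." else "_" for ch in name)


def _run_one(record: ProteinRecord, config: RunConfig, outdir: Path,
             log_lines: list) -> dict:
    rid = _safe(record.id)

    # ---- scan ---------------------------------------------------------
    stage = "scan"
    try:
        zipper_hits = detect_ala_zipper(record, min_core=config.min_core,
                                        register=config.register)
        nls_hits = scan_nls(record)
        rows = []
        for hit in zipper_hits:
            rows.append({
                "record_id": record.id, "motif_type": "ala_zipper",
                "start": hit.span[0], "end": hit.span[1],
                "phase": hit.phase, "score": hit.score,
                "details": {"core_positions": hit.core_positions,
                            "register": hit.register,
                            "n_complementary_pairs":
                                hit.n_complementary_pairs},
            })
        for hit in nls_hits:
            rows.append({
                "record_id": record.id, "motif_type": f"nls:{hit.pattern_id}",
                "start": hit.span[0], "end": hit.span[1], "phase": "",
                "score": "", "details": {"matched": hit.matched_text},
            })
        write_motif_tsv(rows, outdir / f"{rid}.motifs.tsv")
        log_lines.append(f"scan {record.id}: {len(zipper_hits)} zipper, "
                         f"{len(nls_hits)} NLS hits")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    if not zipper_hits:
        log_lines.append(f"{record.id}: no zipper hit; structural stages "
                         "skipped")
        return {"zipper": None, "n_nls": len(nls_hits)}
    top = zipper_hits[0]

    # ---- build / interface / energy per variant -----------------------
    reports = {}
    for variant in config.variants:
        stage = f"build:{variant}"
        try:
            dimer = build_variant(record, top, variant, seed=config.seed)
            write_pdb(dimer, outdir / f"{rid}.{variant}.pdb")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"interface:{variant}"
        try:
            inventory = interface_inventory(dimer,
                                            salt_cutoff=config.salt_cutoff,
                                            hbond_cutoff=config.hbond_cutoff)
            inventory.to_tsv(outdir / f"{rid}.{variant}.contacts.tsv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        stage = f"energy:{variant}"
        try:
            energy_cfg = config.energetics.with_(seed=config.seed)
            report = delta_g_binding(dimer, energy_cfg)
            (outdir / f"{rid}.{variant}.energy.json").write_text(
                json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

        reports[variant] = {"delta_g": report.delta_g_binding,
                            "n_salt_bridges": inventory.n_salt_bridges,
                            "n_hbonds": inventory.n_hbonds}
        log_lines.append(
            f"{record.id} {variant}: dG={report.delta_g_binding:.3f} "
            f"salt={inventory.n_salt_bridges} hbond={inventory.n_hbonds}")

    comparison = variant_report(reports)
    if "native" in reports and "scrambled" in reports:
        comparison["native_below_scrambled"] = (
            reports["native"]["delta_g"] < reports["scrambled"]["delta_g"])
    if "native" in reports and "antiparallel" in reports:
        comparison["parallel_below_antiparallel"] = (
            reports["native"]["delta_g"] < reports["antiparallel"]["delta_g"])
    return {
        "zipper": {"span": list(top.span), "phase": top.phase,
                   "core_positions": top.core_positions,
                   "score": top.score},
        "n_nls": len(nls_hits),
        "comparison": comparison,
    }
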
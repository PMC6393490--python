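"""End-to-end report generation.

One YAML config drives a run: structures with labels and chain pairs, a
register file, comparison regions, SASA settings and detection cutoffs.
Reports are plain TSV with fixed headers; given the same config and seed a
rerun is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import flexibility, geometry, packing
from .errors import ConfigError
from .register import HeptadAssignment, enumerate_heptads, read_register
from .structure import StructureModel, read_ensemble, read_structure, selection

log = logging.getLogger(__name__)


@dataclass
class StructureSpec:
    path: str
    label: str
    chains: tuple[str, str] | None = None  # None -> auto-detect two longest
    exclude_chains: tuple[str, ...] = ()   # e.g. bound-ligand chains for SASA


@dataclass
class RegionSpec:
    label: str
    ranges: list[tuple[int, int]]
    atom_class: str = "backbone"


@dataclass
class AnalysisConfig:
    structures: list[StructureSpec] = field(default_factory=list)
    register_path: str | None = None
    regions: list[RegionSpec] = field(default_factory=list)
    ensemble_path: str | None = None
    sasa_probe: float = 1.4
    sasa_points: int = 960
    salt_bridge_cutoff: float = 4.0
    knob_cutoff: float = 7.0
    underwound_threshold: float = 0.5
    symmetrize_spacing: bool = True
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        cfg = cls()
        for s in raw.get("structures", []):
            cfg.structures.append(StructureSpec(
                path=s["path"], label=s["label"],
                chains=tuple(s["chains"]) if s.get("chains") else None,
                exclude_chains=tuple(s.get("exclude_chains", ()))))
        for r in raw.get("regions", []):
            cfg.regions.append(RegionSpec(
                label=r["label"],
                ranges=[tuple(x) for x in r["ranges"]],
                atom_class=r.get("atom_class", "backbone")))
        for key in ("register_path", "ensemble_path", "sasa_probe", "sasa_points",
                    "salt_bridge_cutoff", "knob_cutoff", "underwound_threshold",
                    "symmetrize_spacing", "out_dir", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        for spec in cfg.structures:
            if not Path(spec.path).exists():
                raise ConfigError(f"structure file not found: {spec.path}")
        if cfg.register_path and not Path(cfg.register_path).exists():
            raise ConfigError(f"register file not found: {cfg.register_path}")
        return cfg

    def to_yaml(self) -> str:
        raw = {
            "structures": [
                {"path": s.path, "label": s.label,
                 **({"chains": list(s.chains)} if s.chains else {}),
                 **({"exclude_chains": list(s.exclude_chains)} if s.exclude_chains else {})}
                for s in self.structures],
            "regions": [
                {"label": r.label, "ranges": [list(x) for x in r.ranges],
                 "atom_class": r.atom_class} for r in self.regions],
            "register_path": self.register_path,
            "ensemble_path": self.ensemble_path,
            "sasa_probe": self.sasa_probe,
            "sasa_points": self.sasa_points,
            "salt_bridge_cutoff": self.salt_bridge_cutoff,
            "knob_cutoff": self.knob_cutoff,
            "underwound_threshold": self.underwound_threshold,
            "symmetrize_spacing": self.symmetrize_spacing,
            "out_dir": self.out_dir,
            "seed": self.seed,
        }
        return yaml.safe_dump(raw, sort_keys=False)


def _load(spec: StructureSpec) -> tuple[StructureModel, tuple[str, str]]:
    s = read_structure(spec.path)
    chains = spec.chains or s.auto_dimer_chains()
    return s, chains


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.2f}"


def run_geometry_report(cfg: AnalysisConfig) -> dict[str, Path]:
    """Per-structure spacing-profile TSVs plus a combined table with one
    mean column per structure label, aligned on heptad a-position."""
    if not cfg.register_path:
        raise ConfigError("geometry report needs register_path")
    assign = read_register(cfg.register_path)
    heptads = enumerate_heptads(assign)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    profiles = {}
    for spec in cfg.structures:
        s, chains = _load(spec)
        profile = geometry.spacing_profile(
            s, chains, heptads, symmetrize=cfg.symmetrize_spacing,
            structure_label=spec.label)
        path = out_dir / f"spacing_{spec.label}.tsv"
        path.write_text(profile.to_tsv())
        written[spec.label] = path
        profiles[spec.label] = profile
    combined = out_dir / "spacing_combined.tsv"
    labels = [s.label for s in cfg.structures]
    lines = ["\t".join(["a", "a_prime", "d"] + [f"mean_{l}" for l in labels])]
    for i, h in enumerate(heptads):
        row = [str(h.a), str(h.a_prime), str(h.d)]
        row += [_fmt(profiles[l].records[i].mean) for l in labels]
        lines.append("\t".join(row))
    combined.write_text("\n".join(lines) + "\n")
    written["combined"] = combined
    return written


def run_comparison_report(cfg: AnalysisConfig) -> Path:
    """Per-region RMSD rows between the first two structures plus a/d-region
    SASA rows per structure (excluded chains stripped first)."""
    if len(cfg.structures) < 2:
        raise ConfigError("comparison report needs two structures")
    spec1, spec2 = cfg.structures[0], cfg.structures[1]
    s1, chains1 = _load(spec1)
    s2, _ = _load(spec2)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["kind\tlabel\tatom_class\tvalue\tdetail"]
    for region in cfg.regions:
        sel = selection(chains=chains1, ranges=region.ranges,
                        atom_class=region.atom_class)
        try:
            rmsd, cmap = geometry.region_rmsd(s1, s2, sel, chain_map="auto")
            lines.append(f"rmsd\t{region.label}\t{region.atom_class}\t{rmsd:.3f}\t"
                         f"chain_map={cmap}")
        except Exception as exc:  # per-row marker, run continues
            log.error("region %s failed: %s", region.label, exc)
            lines.append(f"rmsd\t{region.label}\t{region.atom_class}\tERROR\t{exc}")
    if cfg.register_path:
        assign = read_register(cfg.register_path)
        core = [n for n in assign.letters
                if assign.letters[n] in ("a", "d") and 65 <= n <= 97]
        for spec in (spec1, spec2):
            s, chains = _load(spec)
            keep = [c for c in s.chain_ids() if c not in spec.exclude_chains]
            areas = geometry.sasa(s, probe=cfg.sasa_probe,
                                  n_points=cfg.sasa_points, chains=keep)
            total = geometry.sasa_sum(
                areas, [(c, n) for c in chains for n in core])
            lines.append(f"sasa_ad_65_97\t{spec.label}\tall-heavy\t{total:.1f}\t"
                         f"chains={chains}")
    path = out_dir / "comparison.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_flexibility_report(cfg: AnalysisConfig) -> dict[str, Path]:
    """Windowed normalized B-factors per chain; RMSF and per-heptad spacing
    SD when an ensemble is configured."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if cfg.structures:
        spec = cfg.structures[0]
        s, chains = _load(spec)
        lines = ["chain\tresidue\tB\tBN\twindowed"]
        for chain in chains:
            prof = flexibility.normalize_bfactors(s, chain)
            for i, num in enumerate(prof.residues):
                lines.append(f"{chain}\t{num}\t{prof.B[i]:.2f}\t"
                             f"{prof.BN[i]:.3f}\t{prof.windowed[i]:.3f}")
        path = out_dir / f"bfactors_{spec.label}.tsv"
        path.write_text("\n".join(lines) + "\n")
        written["bfactors"] = path
    if cfg.ensemble_path:
        ens = read_ensemble(cfg.ensemble_path)
        chains = (cfg.structures[0].chains if cfg.structures and cfg.structures[0].chains
                  else ens.frames[0].auto_dimer_chains())
        sel = selection(chains=chains, atom_class="calpha")
        prof = flexibility.ensemble_rmsf(ens, sel)
        lines = ["chain\tresidue\tatom\trmsf"]
        for (cid, num, name), val in zip(prof.keys, prof.rmsf):
            lines.append(f"{cid}\t{num}\t{name}\t{val:.3f}")
        path = out_dir / "rmsf.tsv"
        path.write_text("\n".join(lines) + "\n")
        written["rmsf"] = path
        if cfg.register_path:
            assign = read_register(cfg.register_path)
            heptads = enumerate_heptads(assign)
            rows = flexibility.ensemble_spacing_sd(
                ens, chains, heptads, symmetrize=cfg.symmetrize_spacing)
            lines = ["d_residue\tspacing_mean\tspacing_sd"]
            for d, mean, sd in rows:
                lines.append(f"{d}\t{_fmt(mean)}\t{_fmt(sd)}")
            path = out_dir / "spacing_sd.tsv"
            path.write_text("\n".join(lines) + "\n")
            written["spacing_sd"] = path
    return written
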
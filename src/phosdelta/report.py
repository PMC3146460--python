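"""Pipeline orchestration, configuration, and table/report emission.

The run configuration is a flat keyword-value text file (``key = value``
per line, ``#`` comments, ``include other.cfg`` supported). `run_pipeline`
drives the full toy analysis — global and local interaction-energy
difference tables, the entropy table, dihedral distribution exports, and
a machine-readable JSON bundle validated against a shipped pydantic
schema. All defaults are echoed into the outputs so results are
self-describing; nothing time-stamped goes into the JSON, so reruns with
the same seeds are bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel

from . import __version__
from .binding_analysis import (
    delta_delta, ensemble_average, local_interaction_energy, shell_select,
)
from .dihedral_entropy import (
    EntropyRecord, dihedral_series, entropy_decomposition, extract_dihedrals,
    histogram_probabilities,
)
from .synthetic_data import ToySpec, methyl_deletion_benchmark

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def read_config(path) -> dict[str, str]:
    """Flat keyword-value configuration with include support."""
    out: dict[str, str] = {}
    path = Path(path)
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("include "):
            out.update(read_config(path.parent / line.split(None, 1)[1]))
            continue
        if "=" not in line:
            raise ConfigError(f"malformed config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        out[key] = value
    return out


PIPELINE_DEFAULTS = {
    "mode": "toy",
    "seed": "0",
    "n_seeds": "5",
    "n_frames": "200",
    "stride": "10",
    "pocket_geometry": "enclosed-cavity",
    "polar_model": "GB",
    "cutoff_angstrom": "40",
    "shell_cutoff": "6",
    "bins": "36",
    "temperature": "300",
    "np_preset": "pb",
    "label": "toy-pocket",
}

REQUIRED_KEYS = ("phosphoresidue",)


def resolve_config(config: dict[str, str]) -> dict[str, str]:
    for key in REQUIRED_KEYS:
        if key not in config:
            raise ConfigError(f"config missing required key {key!r}")
    merged = dict(PIPELINE_DEFAULTS)
    merged.update(config)
    return merged


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------

DELTA_COLUMNS = ["domain", "mutated_site", "mutation", "ddU_VDW", "ddU_Coul",
                 "ddW_polar", "ddE_ele", "ddE_tot-np", "ddW_np", "ddE_tot"]
ENTROPY_COLUMNS = ["domain", "mutated_site", "mutation", "TdS_phi", "TdS_psi",
                   "TdS_omega", "TdS_sidechain", "TdS_total"]


def _delta_row(rec) -> list[str]:
    return [rec.label, str(rec.mutated_site), rec.mutation] + [
        f"{v:.2f}" for v in (rec.dd_U_vdw, rec.dd_U_coul, rec.dd_W_polar,
                             rec.dd_E_ele, rec.dd_E_tot_np, rec.dd_W_np,
                             rec.dd_E_tot)]


def _entropy_row(label, site, mutation, rec: EntropyRecord) -> list[str]:
    return [label, str(site), mutation] + [
        f"{v:.2f}" for v in (rec.tds_phi, rec.tds_psi, rec.tds_omega,
                             rec.tds_sidechain, rec.tds_total)]


def render_tables(delta_records, entropy_records, out_dir,
                  metadata: dict | None = None) -> dict[str, Path]:
    """Write the global/local difference tables and the entropy table.

    `delta_records` maps table name ("global"/"local") to a record list;
    `entropy_records` is a list of (label, site, mutation, EntropyRecord).
    Configuration metadata is embedded as `#`-prefixed header comments.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = [f"# {k} = {v}" for k, v in (metadata or {}).items()]
    paths = {}
    for name, records in delta_records.items():
        lines = header + ["\t".join(DELTA_COLUMNS)]
        lines += ["\t".join(_delta_row(r)) for r in records]
        p = out_dir / f"{name}_energy.tsv"
        p.write_text("\n".join(lines) + "\n")
        paths[name] = p
    lines = header + ["\t".join(ENTROPY_COLUMNS)]
    lines += ["\t".join(_entropy_row(*e)) for e in entropy_records]
    p = out_dir / "entropy.tsv"
    p.write_text("\n".join(lines) + "\n")
    paths["entropy"] = p
    return paths


def export_distributions(series_map, out_dir, bins: int = 36) -> dict[str, str]:
    """Two-column (bin center, probability) TSV per dihedral."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    centers = np.linspace(-180.0, 180.0, bins, endpoint=False) + 180.0 / bins
    paths = {}
    for key, series in series_map.items():
        resi, label = key if isinstance(key, tuple) else (0, str(key))
        p = histogram_probabilities(series.angles, bins=bins)
        fname = f"dist_res{resi}_{label}.tsv"
        lines = ["bin_center_deg\tprobability"]
        lines += [f"{c:.1f}\t{v:.6f}" for c, v in zip(centers, p)]
        (out_dir / fname).write_text("\n".join(lines) + "\n")
        paths[f"res{resi}_{label}"] = fname
    return paths


# ---------------------------------------------------------------------------
# JSON bundle schema
# ---------------------------------------------------------------------------

class DeltaRowModel(BaseModel):
    domain: str
    mutated_site: int
    mutation: str
    dd_U_vdw: float
    dd_U_coul: float
    dd_W_polar: float
    dd_E_ele: float
    dd_E_tot_np: float
    dd_W_np: float
    dd_E_tot: float
    polar_model: str


class EntropyRowModel(BaseModel):
    domain: str
    mutated_site: int
    mutation: str
    tds_phi: float
    tds_psi: float
    tds_omega: float
    tds_sidechain: float
    tds_total: float
    temperature: float
    bin_count: int


class BundleModel(BaseModel):
    version: str
    config: dict[str, str]
    global_table: list[DeltaRowModel]
    local_table: list[DeltaRowModel]
    entropy_table: list[EntropyRowModel]
    distributions: dict[str, str]


def validate_bundle(data: dict) -> BundleModel:
    return BundleModel.model_validate(data)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _delta_to_model(rec) -> dict:
    return {"domain": rec.label, "mutated_site": rec.mutated_site,
            "mutation": rec.mutation, "dd_U_vdw": rec.dd_U_vdw,
            "dd_U_coul": rec.dd_U_coul, "dd_W_polar": rec.dd_W_polar,
            "dd_E_ele": rec.dd_E_ele, "dd_E_tot_np": rec.dd_E_tot_np,
            "dd_W_np": rec.dd_W_np, "dd_E_tot": rec.dd_E_tot,
            "polar_model": rec.polar_model}


def run_pipeline(config: dict[str, str], out_dir) -> dict:
    """Full toy analysis: energies, entropy, distributions, JSON bundle.

    Returns the bundle dict (also written to ``bundle.json``); any stage
    failure is re-raised as PipelineError naming the stage.
    """
    cfg = resolve_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg["mode"] != "toy":
        raise ConfigError("only mode=toy is orchestrated end to end; use the "
                          "library functions for file-based systems")

    seed = int(cfg["seed"])
    stride = int(cfg["stride"])
    bins = int(cfg["bins"])
    temperature = float(cfg["temperature"])

    def stage(name, fn, *args, **kw):
        logger.info("stage %s ...", name)
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    bench = stage("simulate", methyl_deletion_benchmark,
                  ToySpec(pocket_geometry=cfg["pocket_geometry"], seed=seed),
                  seed=seed, n_seeds=int(cfg["n_seeds"]),
                  n_frames=int(cfg["n_frames"]))
    top = bench.topology_wild
    rec_idx = sorted(top.groups["receptor"])
    lig_idx = sorted(top.groups["ligand"])
    mut_top = bench.topology_mutant
    mrec = sorted(mut_top.groups["receptor"])
    mlig = sorted(mut_top.groups["ligand"])

    kw = dict(cutoff=float(cfg["cutoff_angstrom"]))
    wild_glob = stage("global-energy(wild)", ensemble_average,
                      top, bench.wild, rec_idx, lig_idx, stride=stride, **kw)
    mut_glob = stage("global-energy(mutant)", ensemble_average,
                     mut_top, bench.mutant_static, mrec, mlig,
                     stride=stride, **kw)
    g_rec = delta_delta(wild_glob, mut_glob, cfg["label"], 1, "pT->pS")

    shell = stage("shell-select", shell_select, top,
                  bench.frame_wild, bench.phospho_residue,
                  cutoff=float(cfg["shell_cutoff"]))
    wild_loc = stage("local-energy(wild)", local_interaction_energy,
                     top, bench.wild, shell, bench.phospho_residue,
                     stride=stride)
    mut_shell = shell_select(mut_top, bench.mutant_static.trajectories[0].frame(0),
                             bench.phospho_residue,
                             cutoff=float(cfg["shell_cutoff"]))
    mut_loc = stage("local-energy(mutant)", local_interaction_energy,
                    mut_top, bench.mutant_static, mut_shell,
                    bench.phospho_residue, stride=stride)
    l_rec = delta_delta(wild_loc, mut_loc, cfg["label"], 1, "pT->pS")

    wild_defs = extract_dihedrals(top, [bench.phospho_residue])
    mut_defs = extract_dihedrals(mut_top, [bench.phospho_residue])
    wild_series = stage("dihedrals(wild)", dihedral_series,
                        top, bench.wild, wild_defs)
    mut_series = stage("dihedrals(mutant)", dihedral_series,
                       mut_top, bench.mutant_relaxed, mut_defs)
    ent = stage("entropy", entropy_decomposition,
                wild_series.values(), mut_series.values(),
                temperature=temperature, bins=bins)

    dist_map = {(d.residue_index, d.dihedral_class): s
                for d, s in wild_series.items()}
    dist_map.update({(d.residue_index, d.dihedral_class + "_mut"): s
                     for d, s in mut_series.items()})
    dist_paths = stage("distributions", export_distributions,
                       dist_map, out_dir / "distributions", bins=bins)

    render_tables({"global": [g_rec], "local": [l_rec]},
                  [(cfg["label"], 1, "pT->pS", ent)], out_dir, metadata=cfg)

    bundle = {
        "version": __version__,
        "config": cfg,
        "global_table": [_delta_to_model(g_rec)],
        "local_table": [_delta_to_model(l_rec)],
        "entropy_table": [{
            "domain": cfg["label"], "mutated_site": 1, "mutation": "pT->pS",
            "tds_phi": ent.tds_phi, "tds_psi": ent.tds_psi,
            "tds_omega": ent.tds_omega, "tds_sidechain": ent.tds_sidechain,
            "tds_total": ent.tds_total, "temperature": ent.temperature,
            "bin_count": ent.bin_count}],
        "distributions": dist_paths,
    }
    validate_bundle(bundle)
    (out_dir / "bundle.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    return bundle
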
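"""Condition-comparison pipeline: control vs hydrostatic pressure vs gas.

Runs the full analysis sequence per condition — PBC cleanup when a bond
map is available, RMSD from the first frame, greedy clustering over the
last half of the trajectory with centroid extraction, Z density, RDF
layouts with control normalisation, acyl-chain order parameters, volumes
with percent change against the control, and pore/site/gate geometry on
the centroid frame — and writes a comparative report (TSV tables, a JSON
metrics bundle, centroid PDBs, a structured JSON-line log).

Conditions are only compared on matched analysis parameters: the same
bins, windows and cutoffs are applied to every condition by construction.
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import pore as pore_mod
from . import spatial, structure, synth, volume
from .order import order_parameter
from .trajio import IndexGroup, Trajectory, read_gro, select, write_pdb

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "leaflet_bounds_from_density"]


class ConfigError(Exception):
    pass


@dataclass
class AnalysisParams:
    cluster_cutoff: float = 0.5          # nm
    cluster_window: str = "last-half"
    density_bins: int = 120
    rdf_bin_width: float = 0.02
    rdf_r_range: tuple[float, float] = (0.0, 3.4)
    layout_chains: tuple[str, ...] = ("A", "B", "C", "D")
    molecule_probe: float = 0.14         # nm, water-sized probe
    molecule_grid: float = 0.06          # nm
    bubble_probe: float = 0.6            # nm
    bubble_grid: float = 0.1             # nm
    gate_residue: int = 299
    gate_threshold_A: float = 28.0
    slice_thickness: float = 0.1         # nm, pore profile
    tmd_z: tuple[float, float] = (10.5, 13.5)


@dataclass
class RunConfig:
    conditions: dict[str, dict]
    output_dir: Path = Path("results/pipeline")
    seed: int = 0
    normalize_to_control: bool = True
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        if self.normalize_to_control and "control" not in self.conditions:
            raise ConfigError(
                "normalization requested but no condition named 'control'"
            )
        for name, cond in self.conditions.items():
            if "spec" not in cond and "trajectory" not in cond:
                raise ConfigError(
                    f"condition {name!r} needs either a 'spec' or a 'trajectory'"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = AnalysisParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("analysis", {}).items()
        })
        return cls(
            conditions=raw["conditions"],
            output_dir=Path(raw.get("output_dir", "results/pipeline")),
            seed=int(raw.get("seed", 0)),
            normalize_to_control=bool(raw.get("normalize_to_control", True)),
            params=params,
        )


def leaflet_bounds_from_density(
    trajectory: Trajectory, phosphate_group: IndexGroup, n_bins: int = 120
) -> tuple[float, float]:
    """Inter-leaflet z bounds from the two phosphate density peaks."""
    prof = spatial.density_profile(trajectory, phosphate_group, n_bins=n_bins)
    k1 = int(np.argmax(prof.density))
    z1 = prof.bin_centers[k1]
    far = np.abs(prof.bin_centers - z1) > 1.0
    k2 = int(np.argmax(np.where(far, prof.density, -np.inf)))
    z2 = prof.bin_centers[k2]
    return (min(z1, z2), max(z1, z2))


class _Logger:
    def __init__(self, path: Path):
        self.path = path
        self.records: list[dict] = []

    def stage(self, condition: str, name: str, status: str, dt: float, **extra):
        rec = {"condition": condition, "stage": name, "status": status,
               "wall_s": round(dt, 3), **extra}
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def _load_condition(name: str, cond: dict, seed: int, index: int):
    if "trajectory" in cond:
        traj = read_gro(cond["trajectory"])
        return traj.topology, traj, None
    overrides = dict(cond.get("spec") or {})
    overrides.setdefault("seed", seed + 1000 * index)
    for key in ("box", "tmd_z", "site_half_diagonals", "reservoir_z"):
        if key in overrides and isinstance(overrides[key], list):
            overrides[key] = tuple(overrides[key])
    spec = synth.SynthSpec(**overrides)
    top, traj = synth.build_system(spec)
    return top, traj, spec


def _run_condition(name, top, traj, spec, p: AnalysisParams, outdir: Path,
                   log: _Logger) -> dict:
    res: dict = {"name": name}
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(label, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
            log.stage(name, label, "ok", time.perf_counter() - t0)
            return value
        except Exception as exc:  # independent stages keep running
            log.stage(name, label, "failed", time.perf_counter() - t0,
                      error=f"{type(exc).__name__}: {exc}")
            res.setdefault("failed_stages", []).append(
                {"stage": label, "error": str(exc),
                 "trace": traceback.format_exc(limit=3)}
            )
            return None

    protein = select(top, name="CA", group_name="protein_ca")

    def do_rmsd():
        series = structure.rmsd_series(traj, protein)
        series.to_frame().to_csv(outdir / "rmsd.tsv", sep="\t", index=False)
        return {"final_nm": float(series.values[-1]),
                "max_nm": float(series.values.max())}

    res["rmsd"] = stage("rmsd", do_rmsd)

    def do_cluster():
        half = np.arange(traj.n_frames // 2, traj.n_frames)
        mat = structure.pairwise_rmsd_matrix(traj, protein, half)
        cres = structure.gromos_cluster(mat, p.cluster_cutoff)
        summary = structure.summarize_clusters(cres, traj.times[half])
        centroid_frame = int(half[cres.centroids[0]])
        write_pdb(traj.frames[centroid_frame], top, outdir / "centroid.pdb")
        summary["centroid_frame"] = centroid_frame
        return summary

    res["clusters"] = stage("cluster", do_cluster)
    centroid_idx = (res["clusters"] or {}).get("centroid_frame", traj.n_frames - 1)
    centroid = traj.frames[centroid_idx]

    def do_density():
        out = {}
        for label, kwargs in (
            ("gas", {"residue_name": "HE"}),
            ("lipid", {"residue_name": "DOPC"}),
            ("protein", {"name": "CA"}),
        ):
            try:
                grp = select(top, group_name=label, **kwargs)
            except Exception:
                continue
            prof = spatial.density_profile(traj, grp, n_bins=p.density_bins)
            prof.to_frame().to_csv(outdir / f"density_{label}.tsv", sep="\t",
                                   index=False)
            out[label] = {"peak_z_nm": float(prof.bin_centers[np.argmax(prof.density)]),
                          "peak_kg_m3": float(prof.density.max())}
        return out

    res["density"] = stage("density", do_density)

    def make_windows():
        t = traj.times
        t0, t1 = t[len(t) // 2], t[-1]
        span = t1 - t0
        return spatial.sampling_windows(t0, t1, width=0.4 * span, gap=0.1 * span)

    def do_layouts():
        out = {}
        windows = make_windows()
        for species, kwargs in (("water", {"name": "OW"}),
                                ("gas", {"residue_name": "HE"})):
            try:
                grp = select(top, group_name=species, **kwargs)
            except Exception:
                continue
            per_chain = {}
            for ch in p.layout_chains:
                lay = spatial.rdf_layout(
                    traj, ch, grp, windows, r_range=p.rdf_r_range,
                    bin_width=p.rdf_bin_width,
                )
                lay.to_frame().to_csv(
                    outdir / f"layout_{species}_{ch}.tsv", sep="\t", index=False
                )
                per_chain[ch] = lay
            out[species] = per_chain
        return out

    res["_layouts"] = stage("rdf_layouts", do_layouts)

    def do_order():
        if spec is None:
            raise ValueError("order parameters require lipid chain definitions")
        out = {}
        for tail, cdef in synth.chain_definitions(spec).items():
            prof = order_parameter(traj, cdef)
            prof.to_frame().to_csv(outdir / f"order_{tail}.tsv", sep="\t",
                                   index=False)
            out[tail] = {"mean_proR": float(prof.proR_mean.mean()),
                         "mean_proS": float(prof.proS_mean.mean())}
        return out

    res["order"] = stage("order", do_order)

    def do_volumes():
        out = {}
        lipid = select(top, residue_name="DOPC", group_name="DOPC")
        out["DOPC_nm3"] = volume.excluded_volume(
            centroid, top, lipid, p.molecule_probe, p.molecule_grid
        ).volume
        out["protein_nm3"] = volume.excluded_volume(
            centroid, top, protein, p.molecule_probe, p.molecule_grid
        ).volume
        try:
            gas = select(top, residue_name="HE", group_name="gas")
            phos = select(top, name="P8", group_name="phosphates")
            bounds = leaflet_bounds_from_density(traj, phos)
            out["bubble_nm3"] = volume.gas_phase_volume(
                centroid, top, gas, bounds, p.bubble_probe, p.bubble_grid
            ).volume
            out["leaflet_bounds_nm"] = [float(b) for b in bounds]
        except Exception:
            out["bubble_nm3"] = 0.0
        return out

    res["volumes"] = stage("volumes", do_volumes)

    def do_pore():
        chains = np.isin(top.chain_ids, ("A", "B", "C", "D"))
        wall = IndexGroup("protein_all",
                          tuple(int(i) + 1 for i in np.nonzero(chains)[0]))
        prof = pore_mod.pore_profile(
            centroid, top, wall, p.tmd_z, p.slice_thickness
        )
        prof.to_frame().to_csv(outdir / "pore.tsv", sep="\t", index=False)
        return {"min_radius_nm": prof.min_radius,
                "min_radius_z_nm": prof.min_radius_z,
                "extent_z_nm": prof.extent_z, "extent_x_nm": prof.extent_x}

    res["pore"] = stage("pore", do_pore)

    def do_site():
        od1 = select(top, name="OD1", group_name="site_od1")
        geom = pore_mod.site_geometry(centroid, top, od1)
        (outdir / "site.json").write_text(json.dumps(geom.to_dict(), indent=1))
        return geom.to_dict()

    res["site"] = stage("site", do_site)

    def do_gate():
        d, state = pore_mod.gate_distance(
            centroid, top, residue_number=p.gate_residue,
            threshold_A=p.gate_threshold_A,
        )
        return {"distance_A": d, "state": state}

    res["gate"] = stage("gate", do_gate)
    return res


def run_pipeline(config: RunConfig) -> dict:
    """Execute every condition and write the comparative report bundle."""
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    logpath = outdir / "pipeline.log.jsonl"
    logpath.write_text("")
    log = _Logger(logpath)
    order = sorted(config.conditions, key=lambda n: (n != "control", n))
    results: dict[str, dict] = {}
    layouts: dict[str, dict] = {}
    for i, name in enumerate(order):
        top, traj, spec = _load_condition(name, config.conditions[name],
                                          config.seed, i)
        res = _run_condition(name, top, traj, spec, config.params,
                             outdir / name, log)
        layouts[name] = res.pop("_layouts", None) or {}
        results[name] = res

    # control-normalised water layouts
    if config.normalize_to_control and "control" in layouts:
        ctrl = layouts["control"].get("water", {})
        for name in order:
            if name == "control":
                continue
            norm_summary = {}
            for ch, lay in layouts[name].get("water", {}).items():
                if ch not in ctrl:
                    continue
                ratio = spatial.normalize_layout(lay, ctrl[ch])
                ratio.to_frame().to_csv(
                    outdir / name / f"layout_water_norm_{ch}.tsv",
                    sep="\t", index=False,
                )
                norm_summary[ch] = {
                    "min_ratio": float(np.nanmin(ratio.mean)),
                    "mean_ratio": float(np.nanmean(ratio.mean)),
                }
            results[name]["normalized_water"] = norm_summary

    # percent change of volumes vs control
    ctrl_vol = (results.get("control") or {}).get("volumes") or {}
    for name in order:
        vols = results[name].get("volumes") or {}
        pc = {}
        for key in ("DOPC_nm3", "protein_nm3"):
            if key in vols and ctrl_vol.get(key):
                pc[key.replace("_nm3", "_pct")] = volume.percent_change(
                    vols[key], ctrl_vol[key]
                )
        results[name]["volume_pct_change"] = pc

    _write_report(results, order, outdir)
    (outdir / "metrics.json").write_text(
        json.dumps(results, indent=1, default=_json_default)
    )
    return {"results": results, "log": log.records, "output_dir": str(outdir)}


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)


def _write_report(results: dict, order: list[str], outdir: Path) -> None:
    lines = ["# Condition comparison report", ""]
    lines += ["## Cluster summary", "",
              "condition\ttotal_frames\tn_clusters\tp_biggest\tfirst_ps\tmiddle_ps\tlast_ps"]
    for name in order:
        c = results[name].get("clusters") or {}
        if c:
            lines.append(
                f"{name}\t{c['total_frames']}\t{c['n_clusters']}\t"
                f"{c['biggest_probability']:.2f}\t{c['biggest_first_ps']:g}\t"
                f"{c['biggest_middle_ps']:g}\t{c['biggest_last_ps']:g}"
            )
    lines += ["", "## Volumes", "",
              "condition\tDOPC_nm3\tDOPC_pct\tprotein_nm3\tprotein_pct\tbubble_nm3"]
    for name in order:
        v = results[name].get("volumes") or {}
        pc = results[name].get("volume_pct_change") or {}
        if v:
            lines.append(
                f"{name}\t{v.get('DOPC_nm3', float('nan')):.1f}\t"
                f"{pc.get('DOPC_pct', 0.0):.2f}\t"
                f"{v.get('protein_nm3', float('nan')):.1f}\t"
                f"{pc.get('protein_pct', 0.0):.2f}\t"
                f"{v.get('bubble_nm3', float('nan')):.1f}"
            )
    lines += ["", "## Gate and pore", "",
              "condition\tgate_A\tstate\tpore_min_radius_nm"]
    for name in order:
        g = results[name].get("gate") or {}
        p = results[name].get("pore") or {}
        if g:
            lines.append(
                f"{name}\t{g['distance_A']:.2f}\t{g['state']}\t"
                f"{p.get('min_radius_nm', float('nan')):.3f}"
            )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
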
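"""Per-model analysis orchestration.

A :class:`RunConfig` names a model, its replicate trajectories and the
analysis thresholds; :func:`run_model` executes the enabled analyses per
replicate, averages across replicates (replicates are the statistical
unit), and writes a machine-readable JSON report plus TSV tables.
:func:`compare` runs replicate-level Welch tests between two reports and
attaches significance stars.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import clustering, conformation, crosslink, dynamics, hydration
from .trajectory_io import Trajectory, concatenate, equilibrium_window, load

logger = logging.getLogger("hypelast")

__all__ = ["RunConfig", "run_model", "compare", "load_config", "write_config"]


@dataclass
class RunConfig:
    model_name: str
    replicates: list = field(default_factory=list)  # paths (coords, traj) or Trajectory
    equilibrium_fraction: float = 0.5
    hbond_selection: str = "protein"
    hydration_selection: str | None = None  # None -> global scope
    ring_residues: list = field(default_factory=list)
    lysine_positions: list = field(default_factory=list)
    analyses: list = field(
        default_factory=lambda: ["hbonds", "hydration", "energy", "pucker", "rmsf"]
    )
    hbond_d_cut: float = 3.5
    hbond_angle_cut: float = 150.0
    layer_bounds: tuple = (2.0, 3.2, 4.0)
    energy_cutoff: float = 12.0
    sweep_cutoffs: list = field(default_factory=lambda: list(crosslink.DEFAULT_CUTOFFS))
    cluster_k: int = 10
    cluster_min_shared: int = 3
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.equilibrium_fraction <= 0 or self.equilibrium_fraction > 1:
            raise ValueError("equilibrium_fraction must be in (0, 1]")
        for name, value in (
            ("hbond_d_cut", self.hbond_d_cut),
            ("energy_cutoff", self.energy_cutoff),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    data["sweep_cutoffs"] = [float(c) for c in data.get("sweep_cutoffs", crosslink.DEFAULT_CUTOFFS)]
    data["layer_bounds"] = tuple(data.get("layer_bounds", (2.0, 3.2, 4.0)))
    return RunConfig(**data)


def write_config(config: RunConfig, path) -> None:
    data = asdict(config)
    data["layer_bounds"] = list(data["layer_bounds"])
    data["replicates"] = [list(r) if isinstance(r, (tuple, list)) else r for r in data["replicates"]]
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def _resolve_replicates(config: RunConfig) -> list[Trajectory]:
    out = []
    for i, rep in enumerate(config.replicates):
        if isinstance(rep, Trajectory):
            t = rep
        elif isinstance(rep, (tuple, list)):
            t = load(*rep, replicate_id=i)
        else:
            t = load(rep, replicate_id=i)
        t.replicate_id = i
        out.append(t)
    return out


def _summarize(values) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "replicate_values": arr.tolist(),
        "mean": float(np.mean(arr)),
        "sd": float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0,
    }


def run_model(config: RunConfig) -> dict:
    """Execute the enabled analyses on each equilibrium-windowed replicate
    and pool the results; returns (and optionally writes) the report."""
    replicates = [
        equilibrium_window(t, config.equilibrium_fraction)
        for t in _resolve_replicates(config)
    ]
    if not replicates:
        raise ValueError("no replicate trajectories configured")
    l1, l2, l3 = config.layer_bounds
    report: dict = {
        "model": config.model_name,
        "n_replicates": len(replicates),
        "equilibrium_frames": [t.n_frames for t in replicates],
        "metrics": {},
    }
    metrics = report["metrics"]

    if "hbonds" in config.analyses:
        logger.info("counting protein-water hydrogen bonds")
        per_rep = [
            hydration.count_hbonds(
                t, config.hbond_selection, config.hbond_d_cut, config.hbond_angle_cut
            )[1]
            for t in replicates
        ]
        metrics["hbonds_with_water"] = _summarize(per_rep)

    if "hydration" in config.analyses:
        logger.info("classifying hydration waters")
        scope = "global" if config.hydration_selection is None else "local"
        sums = [
            hydration.hydration_counts(
                t, scope=scope, selection=config.hydration_selection, l1=l1, l2=l2, l3=l3
            )
            for t in replicates
        ]
        metrics["hydration_total"] = _summarize([s.total for s in sums])
        metrics["hydration_hydrophilic"] = _summarize([s.hydrophilic for s in sums])
        metrics["hydration_hydrophobic"] = _summarize([s.hydrophobic for s in sums])

    if "energy" in config.analyses:
        logger.info("computing protein-solvent interaction energy")
        per_rep = [
            float(
                np.mean(
                    [
                        hydration.interaction_energy(f, t.atoms, config.energy_cutoff)
                        for f in t.frames
                    ]
                )
            )
            for t in replicates
        ]
        metrics["interaction_energy"] = _summarize(per_rep)

    if "pucker" in config.analyses and config.ring_residues:
        logger.info("classifying ring pucker states")
        per_rep_exo = []
        for t in replicates:
            recs = conformation.pucker_timeseries(t, config.ring_residues)
            occ = conformation.occupancy(recs)
            per_rep_exo.append(
                float(np.mean([occ[r].get("exo", 0.0) for r in config.ring_residues]))
            )
        metrics["exo_occupancy_percent"] = _summarize(per_rep_exo)

    if "rmsf" in config.analyses:
        logger.info("computing per-residue RMSF")
        per_rep = [float(np.mean(dynamics.rmsf(t).values)) for t in replicates]
        metrics["mean_rmsf"] = _summarize(per_rep)

    if "crosslink" in config.analyses and len(config.lysine_positions) >= 2:
        logger.info("running lysine contact sweep")
        sweeps = [
            crosslink.contact_sweep(t, config.lysine_positions, config.sweep_cutoffs)
            for t in replicates
        ]
        for ci, cutoff in enumerate(config.sweep_cutoffs):
            metrics[f"lysine_contacts_{cutoff:g}A"] = _summarize(
                [s.mean_counts[ci] for s in sweeps]
            )

    if "cluster" in config.analyses:
        logger.info("clustering the concatenated ensemble")
        ens = concatenate(replicates) if len(replicates) > 1 else replicates[0]
        d = clustering.pairwise_rmsd(ens)
        result = clustering.jarvis_patrick(d, config.cluster_k, config.cluster_min_shared)
        metrics["n_clusters"] = {"replicate_values": [], "mean": float(result.n_clusters), "sd": 0.0}
        report["most_populated_cluster_size"] = int(result.sizes[result.most_populated])

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def compare(report_a: dict, report_b: dict) -> dict:
    """Replicate-level Welch comparison of every shared metric between two
    model reports, with direction and significance stars."""
    out = {"model_a": report_a["model"], "model_b": report_b["model"], "metrics": {}}
    shared = set(report_a["metrics"]) & set(report_b["metrics"])
    if not shared:
        raise ValueError("reports share no metrics")
    for name in sorted(shared):
        a = np.asarray(report_a["metrics"][name]["replicate_values"], dtype=float)
        b = np.asarray(report_b["metrics"][name]["replicate_values"], dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        diff = float(b.mean() - a.mean())
        out["metrics"][name] = {
            "p_value": p,
            "stars": crosslink.significance_stars(p),
            "direction": "none" if diff == 0 else ("increase" if diff > 0 else "decrease"),
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
        }
    return out
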
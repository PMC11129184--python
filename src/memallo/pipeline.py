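"""End-to-end synthetic pipeline: simulate → occupancy → sites → PRS.

Runs every analysis stage on generator output with planted ground truth and
emits a machine-readable report comparing each estimate against the planted
value, plus the CSV/DX artifacts of the individual stages. Used by the
``memallo run`` command and as the package's integration check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from memallo import __version__, constants, density, prs, sites, synthetic
from memallo.errors import MemalloError
from memallo.trajectory import Selection, write_trajectory


@dataclass
class RunConfig:
    """Resolved parameters for a full synthetic pipeline run.

    Every stochastic stage derives its own stream from ``seed``; the
    resolved config is serialized verbatim into the output directory.
    """

    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "occupancy", "sites", "prs")
    # lipid walk
    box: tuple[float, float, float] = (60.0, 60.0, 60.0)
    n_lipids: int = 40
    diffusion_step: float = 2.0
    site_center: tuple[float, float, float] = (30.0, 30.0, 30.0)
    r_bind: float = 4.0
    mean_dwell: float = 50.0
    frame_dt: float = 1.0
    n_frames: int = 4000
    # occupancy
    grid_spacing: float = constants.GRID_SPACING
    min_occupancy: float = constants.MIN_OCCUPANCY
    # contact detection
    r_on: float = constants.R_ON
    r_off: float = constants.R_OFF
    co_occurrence_min: float = constants.CO_OCCURRENCE_MIN
    # PRS ensemble
    prs_n_residues: int = 20
    prs_sigma2: float = 0.01
    prs_lambda: float = 1.0
    prs_planted_node: int = 7
    prs_n_frames: int = 5000
    prs_n_directions: int = constants.N_DIRECTIONS
    prs_n_repeats: int = constants.N_REPEATS
    overlap_threshold: float = constants.OVERLAP_THRESHOLD

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the requested stages and write report.json + MANIFEST.

    Returns the report dict. Raises MemalloError subclasses on stage
    failures; partial outputs stay on disk with the MANIFEST marking which
    stages completed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    report: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    manifest: list[str] = ["config.json"]
    walk = None

    try:
        if "simulate" in config.stages:
            walk = _stage_simulate(config, out, report, manifest)
        if "occupancy" in config.stages:
            if walk is None:
                walk = _make_walk(config)
            _stage_occupancy(config, walk, out, report, manifest)
        if "sites" in config.stages:
            if walk is None:
                walk = _make_walk(config)
            _stage_sites(config, walk, out, report, manifest)
        if "prs" in config.stages:
            _stage_prs(config, out, report, manifest)
    finally:
        (out / "report.json").write_text(json.dumps(report, indent=2))
        manifest.append("report.json")
        done = set(report["stages"])
        lines = [f"{name}\tcomplete" for name in done] + [
            f"{name}\tINCOMPLETE" for name in config.stages if name not in done
        ]
        (out / "MANIFEST").write_text(
            "\n".join(sorted(lines) + sorted(set(manifest))) + "\n"
        )
    return report


def _make_walk(config: RunConfig) -> synthetic.LipidWalkResult:
    protein = synthetic.toy_protein(np.asarray(config.site_center))
    spec = synthetic.LipidKineticsSpec(
        box=np.asarray(config.box),
        n_lipids=config.n_lipids,
        diffusion_step=config.diffusion_step,
        site_centers=np.asarray([config.site_center]),
        r_bind=config.r_bind,
        mean_dwell=config.mean_dwell,
        frame_dt=config.frame_dt,
        n_frames=config.n_frames,
        seed=config.seed,
    )
    return synthetic.generate_lipid_walk(spec, protein)


def _stage_simulate(config, out, report, manifest) -> synthetic.LipidWalkResult:
    walk = _make_walk(config)
    write_trajectory(walk.trajectory, out / "walk.pdb", out / "walk.xtc")
    truth = {
        "mean_dwell_ns": config.mean_dwell,
        "site_center": list(config.site_center),
        "n_bound_segments": len(walk.bound_segments),
        "segments": [asdict(s) for s in walk.bound_segments[:200]],
    }
    (out / "walk_truth.json").write_text(json.dumps(truth, indent=2))
    manifest += ["walk.pdb", "walk.xtc", "walk_truth.json"]
    report["stages"]["simulate"] = {
        "n_frames": config.n_frames,
        "n_lipids": config.n_lipids,
        "n_bound_segments": len(walk.bound_segments),
    }
    return walk


def _stage_occupancy(config, walk, out, report, manifest) -> None:
    grid = density.compute_occupancy(
        walk.trajectory, "resname CHOL", config.grid_spacing, lipid_type="CHOL"
    )
    mask = density.protein_proximity_mask(
        grid, walk.trajectory.topology.coordinates[
            walk.trajectory.topology.chains == "P"
        ],
    )
    filtered = density.threshold_grid(grid, config.min_occupancy, mask)
    density.write_dx(filtered, out / "occupancy_CHOL.dx")
    manifest.append("occupancy_CHOL.dx")
    center_vox = tuple(
        int(v) for v in np.floor(np.asarray(config.site_center) / config.grid_spacing)
    )
    report["stages"]["occupancy"] = {
        "n_voxels_above_threshold": int((filtered.values > 0).sum()),
        "site_center_occupancy": float(grid.values[center_vox]),
        "max_occupancy": float(grid.values.max()),
    }


def _stage_sites(config, walk, out, report, manifest) -> None:
    traj = walk.trajectory
    events = sites.detect_contacts(
        traj, "chain P", "resname CHOL", config.r_on, config.r_off
    )
    total_time = float(traj.times[-1] - traj.times[0] + config.frame_dt)
    stats = sites.residue_residence_times(events, total_time)
    rows = [
        {"chain": rk[0], "resid": rk[1], "residence_time_ns": st.residence_time,
         "mean_duration_ns": st.mean_duration, "max_duration_ns": st.max_duration,
         "occupancy": st.occupancy_fraction, "n_events": st.n_events}
        for rk, st in sorted(stats.items())
    ]
    pd.DataFrame(rows).to_csv(out / "residues.csv", index=False)
    found = sites.cluster_sites(
        events, traj.n_frames, traj.times, config.co_occurrence_min
    )
    sites.flag_long_lived(found)
    site_rows = [
        {"residues": ";".join(f"{c}:{r}" for c, r in sorted(s.residues)),
         "residence_time_ns": s.residence_time, "max_duration_ns": s.max_duration,
         "occupancy": s.occupancy_fraction,
         "pose_frame": None if s.representative_pose is None else s.representative_pose[0],
         "pose_lipid": None if s.representative_pose is None else s.representative_pose[1],
         "long_lived": s.long_lived}
        for s in found
    ]
    pd.DataFrame(site_rows).to_csv(out / "sites.csv", index=False)
    manifest += ["residues.csv", "sites.csv"]

    planted = {("P", r) for r in (1, 2, 3, 4)}
    top = found[0] if found else None
    durs = walk.segment_durations_ns()
    report["stages"]["sites"] = {
        "n_events": len(events),
        "n_sites": len(found),
        "top_site_residues": sorted(r for _, r in top.residues) if top else [],
        "planted_site_recovered": bool(top and top.residues == planted),
        "top_site_residence_time_ns": top.residence_time if top else 0.0,
        "planted_mean_dwell_ns": config.mean_dwell,
        "planted_segment_mean_ns": float(durs.mean()) if len(durs) else 0.0,
    }


def _stage_prs(config, out, report, manifest) -> None:
    n = config.prs_n_residues
    mean_coords = np.column_stack(
        [np.arange(n) * 3.8, np.zeros(n), np.zeros(n)]
    )
    u = np.zeros(3 * n)
    u[3 * config.prs_planted_node: 3 * config.prs_planted_node + 3] = [1.0, 1.0, 1.0]
    spec = synthetic.GaussianEnsembleSpec(
        n_residues=n,
        mean_coords=mean_coords,
        covariance_builder=synthetic.Spiked(config.prs_sigma2, config.prs_lambda, u),
        n_frames=config.prs_n_frames,
        seed=config.seed + 1,
    )
    traj, true_cov = synthetic.generate_gaussian_ensemble(spec)
    cov = prs.compute_covariance(traj, "name CA", align=False)
    target = prs.DisplacementField(
        true_cov[:, 3 * config.prs_planted_node], cov.node_resids
    )
    profile = prs.scan(
        cov, target, config.prs_n_directions, config.prs_n_repeats,
        seed=config.seed + 2,
    )
    hotspots = prs.rank_hotspots(profile, config.overlap_threshold)
    pd.DataFrame(
        {"chain": [c for c, _ in profile.node_resids],
         "resid": [r for _, r in profile.node_resids],
         "best_overlap": profile.best_overlap,
         "fx": profile.best_direction[:, 0],
         "fy": profile.best_direction[:, 1],
         "fz": profile.best_direction[:, 2]}
    ).to_csv(out / "prs_profile.csv", index=False)
    manifest.append("prs_profile.csv")
    top_node = int(np.argmax(profile.best_overlap))
    report["stages"]["prs"] = {
        "planted_node_resid": config.prs_planted_node + 1,
        "top_node_resid": profile.node_resids[top_node][1],
        "planted_recovered": top_node == config.prs_planted_node,
        "top_overlap": float(profile.best_overlap[top_node]),
        "n_hotspots": len(hotspots),
    }
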
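"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes the requested stages on a synthetic system (or a
trajectory read from disk), writes every product under the configured output
directory, and records a manifest (config hash, seeds, package version, the
defaulted design decisions in effect, per-stage status).  Outputs are
byte-reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .binding import (BindingSite, aggregate_events, com_distance_series,
                      contact_probability, detect_binding_events, occupancy_map)
from .core import Selection
from .ephys import (decay_ratio, estimate_leak, fit_activation_tau,
                    fit_boltzmann, gv_curve, leak_subtract_and_density)
from .ephys_synth import (GatingModelParams, VoltageProtocol,
                          generate_activation_sweeps, generate_vsp_sweeps)
from .errors import ConfigurationError
from .helix import orientation_series
from .io import (read_sites, read_trajectory, write_dx, write_ground_truth,
                 write_matrix_csv, write_network_graphml, write_sites,
                 write_trajectory)
from .network import build_network, community_report, covering_count, detect_communities
from .synth_traj import (PlantedBinding, PlantedCommunities, PlantedTilt,
                         ToySystemConfig, build_toy_system, partition_by_tags,
                         simulate_binding_trajectory,
                         simulate_correlated_trajectory)

log = logging.getLogger("kv7pip2")

ALL_STAGES = ("synth-traj", "occupancy", "events", "contacts",
              "network", "helix-angle", "synth-ephys", "gv-fit", "vsp-decay")


@dataclass
class PipelineConfig:
    outdir: str = "kv7pip2_out"
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    # synthetic trajectory scale
    n_frames: int = 200
    dt_ns: float = 1.0
    lipids_per_leaflet: int = 60
    pip2_fraction: float = 0.022
    # binding criterion
    d_bind: float = 6.0
    min_dwell_ns: float = 50.0
    rejoin_gap_ns: float = 5.0
    # contact cutoffs (A) and network parameters
    phosphate_cutoff: float = 4.0
    hydroxyl_cutoff: float = 3.5
    network_cutoff: float = 4.5
    persistence_fraction: float = 0.75
    community_cutoff: float = 13.0   # bead-scale cutoff for the toy observable
    # paths (optional external inputs)
    trajectory_pdb: Optional[str] = None
    sites_json: Optional[str] = None
    # ephys generating parameters
    v_half: float = -30.5
    k_slope: float = 5.9
    tau_act_ms: float = 100.0
    noise_sd_pA: float = 2.0
    tau_dep_s: float = 14.4

    def validate(self) -> None:
        for name in ("d_bind", "phosphate_cutoff", "hydroxyl_cutoff",
                     "network_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 < self.persistence_fraction <= 1.0:
            raise ConfigurationError("persistence_fraction must be in (0, 1]")
        for key in ("trajectory_pdb", "sites_json"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"config key {key!r}: no such file {path}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]

# defaulted conventions recorded with every run so results are auditable
DECISIONS_IN_EFFECT = {
    "units": "A / ns / Da; membrane normal +z",
    "heavy_atom": "element != H, inferred from atom-name lead when absent",
    "binding_criterion": "headgroup-site COM distance <= d_bind, "
                         "merge gaps <= rejoin_gap, discard runs < min_dwell",
    "analysis_window": "trailing 40% of the trajectory unless overridden",
    "contact_cutoffs": "phosphate 4.0 A, hydroxyl 3.5 A, any heavy atom",
    "network": "Calpha nodes, 4.5 A / 75% persistence edges, w = -log|C|, "
               "Girvan-Newman + strength-weighted modularity",
    "gv": "steady-state current (final 10% of step) / (V - E_K), E_K -84 mV",
    "boltzmann": "G/Gmax = 1/(1+exp((V1/2-V)/k)), k > 0",
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(cfg), "config_hash": _config_hash(cfg),
                "seed": cfg.seed, "version": __version__,
                "decisions": DECISIONS_IN_EFFECT, "stages": {}}
    t_begin = time.time()

    state: dict = {}
    for stage in cfg.stages:
        try:
            _STAGE_FUNCS[stage](cfg, outdir, state)
            manifest["stages"][stage] = "ok"
            log.info("stage %s: ok", stage)
        except Exception as exc:
            manifest["stages"][stage] = f"failed: {exc}"
            manifest["elapsed_s"] = round(time.time() - t_begin, 3)
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest["elapsed_s"] = round(time.time() - t_begin, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# --- trajectory stages ------------------------------------------------------


def _ensure_traj(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    if "traj" in state:
        return
    if cfg.trajectory_pdb is not None:
        state["traj"] = read_trajectory(cfg.trajectory_pdb)
        state["sites"] = read_sites(cfg.sites_json) if cfg.sites_json else []
        state["system"] = None
        return
    _stage_synth_traj(cfg, outdir, state)


def _stage_synth_traj(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    system = build_toy_system(ToySystemConfig(
        lipids_per_leaflet=cfg.lipids_per_leaflet,
        pip2_fraction=cfg.pip2_fraction, seed=cfg.seed,
        box=(110.0, 110.0, 80.0)))
    lipid = next(lp for lp in system.pip2_lipids if lp[0] == "L")
    site = system.site("Site-O4-A")
    span = cfg.n_frames * cfg.dt_ns
    plan = [PlantedBinding(
        lipid=lipid, site_label=site.label, t_start=0.2 * span,
        dwell=(0.4 * span, (cfg.n_frames - 1) * cfg.dt_ns),
        contact_plan={(site.residues[0], "P5"): 0.6})]
    traj = simulate_binding_trajectory(system, plan, cfg.n_frames,
                                       dt=cfg.dt_ns, seed=cfg.seed)
    state.update(system=system, traj=traj, plan=plan, lipid=lipid, site=site,
                 sites=(read_sites(cfg.sites_json) if cfg.sites_json
                        else system.sites))
    write_trajectory(traj, outdir / "trajectory.pdb")
    write_sites(system.sites, outdir / "sites.json")
    write_ground_truth({"planted": [{"lipid": list(lipid),
                                     "site": site.label,
                                     "dwell_ns": list(plan[0].dwell),
                                     "bound_distance_A": plan[0].bound_distance}]},
                       outdir / "ground_truth.json")


def _headgroup_sel(state: dict) -> Selection:
    system, lipid = state["system"], state["lipid"]
    return system.pip2_headgroup_selection(lipid)


def _stage_occupancy(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    _ensure_traj(cfg, outdir, state)
    traj = state["traj"]
    sel = (_headgroup_sel(state) if state.get("system")
           else Selection.make(tags=["LIPID_PIP2"]))
    w0 = int(0.6 * traj.n_frames)
    grid = occupancy_map(traj, sel, spacing=1.0,
                         frames=np.arange(w0, traj.n_frames))
    write_dx(grid, outdir / "occupancy.dx")


def _stage_events(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    _ensure_traj(cfg, outdir, state)
    traj, site = state["traj"], state["site"]
    times, dist = com_distance_series(traj, _headgroup_sel(state), site)
    pd.DataFrame({"time_ns": times, "distance_A": dist}).to_csv(
        outdir / "com_distance.csv", index=False)
    events = detect_binding_events(times, dist, d_bind=cfg.d_bind,
                                   min_dwell=cfg.min_dwell_ns,
                                   rejoin_gap=cfg.rejoin_gap_ns,
                                   lipid=state["lipid"], site_label=site.label)
    pd.DataFrame([asdict(e) for e in events]).to_csv(
        outdir / "binding_events.csv", index=False)
    state["events"] = events


def _stage_contacts(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    _ensure_traj(cfg, outdir, state)
    traj, site, system = state["traj"], state["site"], state["system"]
    table = contact_probability(
        traj, list(site.residues), state["lipid"], system.schema,
        cutoffs={"phosphate": cfg.phosphate_cutoff,
                 "hydroxyl": cfg.hydroxyl_cutoff})
    agg = aggregate_events([table])
    agg.data.to_csv(outdir / "contact_probabilities.csv", index=False)
    state["contacts"] = agg


COUPLING_TAGS = ("S4", "S4S5_LINKER", "S6", "PRE_HELIX_A")


def _stage_network(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    """Community analysis of a coupled synthetic trajectory restricted to
    the VSD-pore tag set of one monomer (the coupled/decoupled observable)."""
    system = state.get("system") or build_toy_system(ToySystemConfig(
        lipids_per_leaflet=cfg.lipids_per_leaflet, seed=cfg.seed,
        box=(110.0, 110.0, 80.0)))
    part = partition_by_tags(system, {"vsd_pore": COUPLING_TAGS})
    comm = PlantedCommunities(part, {"vsd_pore": 1.0, "rest": 1.0},
                              noise_amplitude=0.1, coupling=0.0)
    traj = simulate_correlated_trajectory(system, comm, None, 300,
                                          dt=cfg.dt_ns, seed=cfg.seed)
    # interface-residue nodes with a bead-scale neighbour cutoff; the
    # generator adds no rigid-body motion, so no pre-alignment
    net = build_network(traj, system.vsd_pore_selection("A"),
                        cutoff=cfg.community_cutoff,
                        fraction=cfg.persistence_fraction, align=False)
    detect_communities(net)
    write_network_graphml(net, outdir / "network.graphml")
    write_matrix_csv(net.C, outdir / "correlation_matrix.csv")
    write_matrix_csv(net.persistence, outdir / "persistence_matrix.csv")
    community_report(net, traj.topology).to_csv(
        outdir / "community_report.csv", index=False)
    state["network"] = net
    state["covering_count"] = covering_count(net, COUPLING_TAGS)


def _stage_helix(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    system = state.get("system") or build_toy_system(ToySystemConfig(
        lipids_per_leaflet=cfg.lipids_per_leaflet, seed=cfg.seed,
        box=(110.0, 110.0, 80.0)))
    part = partition_by_tags(system, {})
    comm = PlantedCommunities(part, {}, noise_amplitude=0.05)
    tilt = PlantedTilt(95.5, 3.7)
    traj = simulate_correlated_trajectory(system, comm, tilt, 150,
                                          dt=cfg.dt_ns, seed=cfg.seed)
    series = orientation_series(
        traj, Selection.make(chains=["A"], tags=["HELIX_A"]),
        Selection.make(chains=["A"], tags=["HELIX_B"]))
    pd.DataFrame({"time_ns": series.times, "theta_deg": series.theta}).to_csv(
        outdir / "helix_orientation.csv", index=False)
    (outdir / "helix_orientation.json").write_text(json.dumps(
        {"window_ns": series.window, "mean_deg": series.mean,
         "sd_deg": series.sd}))
    state["orientation"] = series


# --- ephys stages -----------------------------------------------------------


def _ephys_params(cfg: PipelineConfig, depletion: bool) -> GatingModelParams:
    levels = np.arange(-20.0, 100.0 + 10, 20.0)
    return GatingModelParams(
        v_half=cfg.v_half, k=cfg.k_slope, tau_act=cfg.tau_act_ms,
        noise_sd=cfg.noise_sd_pA, seed=cfg.seed,
        tau_dep={float(v): cfg.tau_dep_s for v in levels} if depletion else None)


def _stage_synth_ephys(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    sweeps = generate_activation_sweeps(_ephys_params(cfg, False),
                                        VoltageProtocol.activation())
    sweeps.to_frame().to_csv(outdir / "activation_sweeps.csv", index=False)
    (outdir / "activation_sweeps_header.json").write_text(json.dumps(
        {"capacitance_pF": sweeps.capacitance, **sweeps.metadata}))
    state["act_sweeps"] = sweeps


def _stage_gv_fit(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    if "act_sweeps" not in state:
        _stage_synth_ephys(cfg, outdir, state)
    sweeps = state["act_sweeps"]
    leak_ref = generate_activation_sweeps(
        GatingModelParams(v_half=cfg.v_half, k=cfg.k_slope, g_max=1e-9,
                          g_leak=0.5, noise_sd=cfg.noise_sd_pA,
                          seed=cfg.seed + 1),
        sweeps.protocol)
    leak = estimate_leak(sweeps, method="reference_cellline",
                         reference=leak_ref)
    subtracted, density = leak_subtract_and_density(sweeps, leak)
    gv = gv_curve(subtracted)
    fit = fit_boltzmann(gv)
    sw20 = sweeps.sweeps[-1]
    sl = sw20.segment_slice(sw20.main_segment())
    tau = fit_activation_tau(sw20.times[sl], subtracted.sweeps[-1].current[sl])
    density.to_csv(outdir / "current_density.csv", index=False)
    pd.DataFrame({"voltage_mV": gv.voltages, "g_norm": gv.g_norm}).to_csv(
        outdir / "gv_curve.csv", index=False)
    (outdir / "boltzmann_fit.json").write_text(json.dumps(
        {"v_half_mV": fit.v_half, "k_mV": fit.k, "converged": fit.converged,
         "tau_act_ms": tau.tau, "g_leak_nS": leak.g_leak,
         "e_leak_mV": leak.e_leak}))
    state.update(gv=gv, boltzmann=fit, tau=tau, leak=leak)


def _stage_vsp(cfg: PipelineConfig, outdir: Path, state: dict) -> None:
    from .ephys import leak_subtract
    sweeps = generate_vsp_sweeps(_ephys_params(cfg, True),
                                 VoltageProtocol.vsp())
    leak = estimate_leak(sweeps, method="reference_step")
    result = decay_ratio(leak_subtract(sweeps, leak))
    result.table.to_csv(outdir / "vsp_decay.csv", index=False)
    state["decay"] = result


_STAGE_FUNCS = {
    "synth-traj": _stage_synth_traj,
    "occupancy": _stage_occupancy,
    "events": _stage_events,
    "contacts": _stage_contacts,
    "network": _stage_network,
    "helix-angle": _stage_helix,
    "synth-ephys": _stage_synth_ephys,
    "gv-fit": _stage_gv_fit,
    "vsp-decay": _stage_vsp,
}
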
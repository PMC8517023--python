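"""Synthetic channel/bilayer trajectory generator with planted ground truth.

The generator builds a coarse, tetrameric pseudo-channel whose residues carry
the full domain-tag vocabulary (S1..S6, linkers, intracellular helices), one
bead per residue, embedded between two leaflets of bead lipids.  A small
fraction of the lipids are PIP2-like, carrying the six headgroup moieties
(P1/P4/P5 phosphate beads, 2-/3-/6-hydroxyl beads) as distinct atoms so that
moiety-resolved contact analysis has real structure to act on.

Three kinds of ground truth can be planted:

* binding events — a chosen PIP2 lipid approaches a declared binding site and
  holds a prescribed centre-of-mass distance for a prescribed dwell, while
  individual moiety beads realise prescribed contact fractions against
  individual site residues;
* correlated-motion communities — groups of residues share a latent
  displacement mode, with independent noise and a tunable inter-group
  coupling;
* helix-pair tilt — the helices A+B rod is re-oriented each frame so its
  principal axis makes a Gaussian-distributed angle with the membrane normal.

None of this is physically realistic (no force field, no solvent); the point
is that every analysis stage downstream has an exact, recoverable truth.
All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .binding import BindingSite
from .core import (ATOMIC_MASSES, Atom, MoietySchema, Selection, Topology,
                   Trajectory)
from .errors import ConfigurationError, PlanError

# residues per domain of one monomer, in chain order
DEFAULT_RESIDUES_PER_DOMAIN: dict[str, int] = {
    "NT_TAIL": 6, "S1": 10, "S2": 10, "S2S3_LINKER": 4, "S3": 10,
    "S4": 10, "S4S5_LINKER": 4, "S5": 10, "PORE_LOOP": 6, "S6": 10,
    "PRE_HELIX_A": 4, "HELIX_A": 8, "AB_LINKER": 6, "HELIX_B": 8,
    "BC_LINKER": 4,
}

PROTEIN_CHAINS = ("A", "B", "C", "D")
UPPER_CHAIN, LOWER_CHAIN = "U", "L"

# class-specific contact cutoffs (A) used when planting contacts
CONTACT_CUTOFFS = {"phosphate": 4.0, "hydroxyl": 3.5}
_D_ON = {"phosphate": 3.2, "hydroxyl": 2.7}    # planted "in contact" distance
_D_OFF_PAD = 2.0                                # planted "no contact" margin

LEAFLET_Z = 17.0        # head-bead plane of each leaflet (+/- z)
CHANNEL_EXCLUSION = 18.0  # lipids start outside this xy radius


@dataclass(frozen=True)
class ToySystemConfig:
    monomers: int = 4
    residues_per_domain: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUES_PER_DOMAIN))
    lipids_per_leaflet: int = 364
    pip2_fraction: float = 0.022
    min_initial_site_distance: float = 15.0
    box: tuple[float, float, float] = (160.0, 160.0, 80.0)
    seed: int = 0


@dataclass(frozen=True)
class PlantedBinding:
    """One planned binding event for a PIP2 lipid.

    ``contact_plan`` maps ((chain, residue_index), moiety_label) to the
    contact fraction to realise over the analysis window of the dwell.
    """

    lipid: tuple[str, int]                 # (chain_id, residue_index) of the PIP2
    site_label: str
    t_start: float                         # approach begins (ns)
    dwell: tuple[float, float]             # bound interval (ns)
    bound_distance: float = 4.0            # headgroup-COM to site-COM (A)
    contact_plan: Mapping[tuple[tuple[str, int], str], float] = field(
        default_factory=dict)

    def __post_init__(self):
        if not (self.t_start <= self.dwell[0] < self.dwell[1]):
            raise PlanError("need t_start <= dwell start < dwell end")
        for key, frac in self.contact_plan.items():
            if not 0.0 <= frac <= 1.0:
                raise PlanError(f"contact fraction {frac} for {key} not in [0,1]")


@dataclass(frozen=True)
class PlantedCommunities:
    """Planted partition of protein residues into correlated groups."""

    partition: Mapping[str, frozenset[tuple[str, int]]]
    amplitudes: Mapping[str, float]        # shared-mode amplitude per group (A)
    noise_amplitude: float = 0.1           # independent per-residue noise (A)
    coupling: float = 0.0                  # inter-group latent mixing in [0,1]

    def __post_init__(self):
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigurationError("coupling must be in [0,1]")
        if self.noise_amplitude < 0:
            raise ConfigurationError("noise amplitude must be >= 0")
        seen: set[tuple[str, int]] = set()
        for label, members in self.partition.items():
            if self.amplitudes.get(label, 0.0) < 0:
                raise ConfigurationError("amplitudes must be >= 0")
            overlap = seen & set(members)
            if overlap:
                raise ConfigurationError(f"groups overlap at {sorted(overlap)[:3]}")
            seen |= set(members)


@dataclass(frozen=True)
class PlantedTilt:
    """Gaussian orientation of the helices A+B principal axis vs +z."""

    theta_mean: float                      # degrees, in (0, 180)
    theta_sd: float                        # degrees

    def __post_init__(self):
        if not 0.0 < self.theta_mean < 180.0:
            raise ConfigurationError("theta_mean must be in (0, 180) degrees")
        if self.theta_sd < 0:
            raise ConfigurationError("theta_sd must be >= 0")


class ToySystem:
    """Topology + initial frame + declared binding sites of a toy channel."""

    def __init__(self, topology: Topology, coords: np.ndarray,
                 box: tuple[float, float, float], sites: Sequence[BindingSite],
                 pip2_lipids: Sequence[tuple[str, int]],
                 config: ToySystemConfig):
        self.topology = topology
        self.coords = coords
        self.box = box
        self.sites = list(sites)
        self.pip2_lipids = list(pip2_lipids)
        self.config = config
        self.schema = MoietySchema.default()

    def site(self, label: str) -> BindingSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(f"no site labelled {label!r}")

    def pip2_headgroup_selection(self, lipid: tuple[str, int]) -> Selection:
        chain, resid = lipid
        return Selection.make(chains=[chain], residues=[resid],
                              names=["C1", "P1", "P4", "P5", "O2", "O3", "O6"])

    def calpha_selection(self) -> Selection:
        return Selection.make(chains=PROTEIN_CHAINS[:self.config.monomers],
                              names=["CA"])

    def vsd_pore_selection(self, chain: str = "A") -> Selection:
        """Calpha nodes of one monomer's VSD-pore coupling interface: the
        cytoplasmic ends of S4 and S6, the S4-S5 linker and pre-Helix-A
        (the residues of that monomer's Site-O4)."""
        site = self.site(f"Site-O4-{chain}")
        return Selection.make(chains=[chain],
                              residues=[r for _, r in site.residues])


def _rotz(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _monomer_template(rpd: Mapping[str, int]) -> tuple[list[tuple[str, np.ndarray]], int]:
    """Bead positions of one monomer built at azimuth 0.

    Transmembrane helices are vertical rods around the pore axis; the
    intracellular domains (N-tail, pre-Helix-A, helices A/B and their
    linkers) sit below the lower leaflet, with helices A and B laid out as a
    single collinear in-plane rod so their principal axis starts near 90 deg
    from the membrane normal.
    """
    out: list[tuple[str, np.ndarray]] = []

    def rod(tag: str, start: np.ndarray, step: np.ndarray):
        for k in range(rpd[tag]):
            out.append((tag, start + k * step))

    r_tm = 11.0
    tm_angles = {"S1": -40.0, "S2": -24.0, "S3": -8.0, "S4": 8.0,
                 "S5": 24.0, "S6": 40.0}
    for tag, ang in tm_angles.items():
        a = math.radians(ang)
        base = np.array([r_tm * math.cos(a), r_tm * math.sin(a), -14.0])
        rod(tag, base, np.array([0.0, 0.0, 28.0 / max(rpd[tag] - 1, 1)]))

    def arc(tag: str, ang0: float, ang1: float, radius: float, z: float):
        n = rpd[tag]
        for k in range(n):
            a = math.radians(ang0 + (ang1 - ang0) * k / max(n - 1, 1))
            out.append((tag, np.array([radius * math.cos(a),
                                       radius * math.sin(a), z])))

    arc("NT_TAIL", -55.0, -45.0, 15.0, -24.0)
    arc("S2S3_LINKER", -24.0, -8.0, 12.0, -17.0)
    arc("S4S5_LINKER", 8.0, 24.0, 12.0, -16.0)
    arc("PORE_LOOP", 24.0, 40.0, 12.0, 16.0)
    # kept within Calpha contact range of the S6 cytoplasmic end
    arc("PRE_HELIX_A", 41.0, 47.0, 11.5, -16.5)

    # helices A and B: one collinear rod at z = -23, pointing radially outward
    ab_dir = np.array([math.cos(math.radians(20.0)),
                       math.sin(math.radians(20.0)), 0.0])
    start = 14.0
    spacing = 1.5
    posA = [start + k * spacing for k in range(rpd["HELIX_A"])]
    gap = 3.0
    posB0 = posA[-1] + gap
    for k, s in enumerate(posA):
        out.append(("HELIX_A", s * ab_dir + np.array([0.0, 0.0, -23.0])))
    arc("AB_LINKER", 30.0, 42.0, 20.0, -24.0)
    for k in range(rpd["HELIX_B"]):
        s = posB0 + k * spacing
        out.append(("HELIX_B", s * ab_dir + np.array([0.0, 0.0, -23.0])))
    arc("BC_LINKER", 46.0, 54.0, 22.0, -24.0)

    return out, len(out)


def _declare_sites(rpd: Mapping[str, int], chains: Sequence[str],
                   residue_tags: dict[tuple[str, int], str]) -> list[BindingSite]:
    """Per-monomer binding sites mirroring the open-state site anatomy:

    ``Site-O4-<chain>``: cytoplasmic ends of S4 and S6, the S4-S5 linker and
    pre-Helix-A; ``Site-O2-<chain>``: distal Helix-B.
    """
    sites = []
    for chain in chains:
        by_tag: dict[str, list[int]] = {}
        for (c, r), tag in residue_tags.items():
            if c == chain:
                by_tag.setdefault(tag, []).append(r)
        for v in by_tag.values():
            v.sort()
        o4 = (by_tag["S4"][:3] + by_tag["S4S5_LINKER"]
              + by_tag["S6"][:3] + by_tag["PRE_HELIX_A"])
        sites.append(BindingSite(f"Site-O4-{chain}",
                                 tuple((chain, r) for r in sorted(o4))))
        o2 = by_tag["HELIX_B"][-3:]
        sites.append(BindingSite(f"Site-O2-{chain}",
                                 tuple((chain, r) for r in o2)))
    return sites


# hexagon of moiety beads around the PIP2 head-centre bead (xy plane)
_MOIETY_RING: dict[str, np.ndarray] = {}
for _i, _name in enumerate(["P1", "O2", "P4", "O3", "P5", "O6"]):
    _a = math.radians(60.0 * _i)
    _MOIETY_RING[_name] = 1.2 * np.array([math.cos(_a), math.sin(_a), 0.0])


def _lipid_atoms(resname: str, head: np.ndarray, leaflet_sign: float
                 ) -> list[tuple[str, str, np.ndarray]]:
    """(atom_name, element, position) triples for one lipid."""
    tail_dz = -leaflet_sign  # tails point toward the membrane centre
    if resname == "POP":
        return [("N", "N", head),
                ("C2", "C", head + np.array([0.0, 0.0, 4.0 * tail_dz])),
                ("C3", "C", head + np.array([0.0, 0.0, 8.0 * tail_dz]))]
    atoms = [("C1", "C", head)]
    for name, off in _MOIETY_RING.items():
        atoms.append((name, name[0], head + off))
    atoms.append(("C2", "C", head + np.array([0.0, 0.0, 4.0 * tail_dz])))
    atoms.append(("C3", "C", head + np.array([0.0, 0.0, 8.0 * tail_dz])))
    return atoms


def build_toy_system(cfg: ToySystemConfig) -> ToySystem:
    """Construct the tetrameric pseudo-channel in its bilayer.

    The PIP2 count per leaflet is round(pip2_fraction * lipids_per_leaflet)
    and must be >= 1; every PIP2 headgroup starts at least
    ``min_initial_site_distance`` from every declared binding-site COM.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pip2 = int(round(cfg.pip2_fraction * cfg.lipids_per_leaflet))
    if n_pip2 < 1:
        raise ConfigurationError(
            f"pip2_fraction {cfg.pip2_fraction} with {cfg.lipids_per_leaflet} "
            "lipids per leaflet yields zero PIP2 lipids")

    chains = PROTEIN_CHAINS[:cfg.monomers]
    template, n_res = _monomer_template(cfg.residues_per_domain)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    residue_tags: dict[tuple[str, int], str] = {}
    aid = 1
    for m, chain in enumerate(chains):
        R = _rotz(2.0 * math.pi * m / cfg.monomers)
        for resid, (tag, pos) in enumerate(template, start=1):
            atoms.append(Atom(aid, "CA", "C", ATOMIC_MASSES["C"], resid,
                              "GLY", chain, tag))
            coords.append(R @ pos)
            residue_tags[(chain, resid)] = tag
            aid += 1

    sites = _declare_sites(cfg.residues_per_domain, chains, residue_tags)
    # site COMs from the just-built protein frame (all beads equal mass)
    pos_by_key = {(a.chain_id, a.residue_index): c
                  for a, c in zip(atoms, coords)}
    site_coms = {s.label: np.mean([pos_by_key[k] for k in s.residues], axis=0)
                 for s in sites}

    bx, by, bz = cfg.box
    pip2_lipids: list[tuple[str, int]] = []
    for leaflet_sign, chain in ((1.0, UPPER_CHAIN), (-1.0, LOWER_CHAIN)):
        z = leaflet_sign * LEAFLET_Z
        n_side = math.ceil(math.sqrt(cfg.lipids_per_leaflet * 1.4))
        xs = np.linspace(-bx / 2 + 4, bx / 2 - 4, n_side)
        ys = np.linspace(-by / 2 + 4, by / 2 - 4, n_side)
        grid = [np.array([x, y, z]) for x in xs for y in ys
                if math.hypot(x, y) >= CHANNEL_EXCLUSION]
        if len(grid) < cfg.lipids_per_leaflet:
            raise ConfigurationError(
                f"box {cfg.box} too small for {cfg.lipids_per_leaflet} lipids "
                "per leaflet outside the channel footprint")
        order = rng.permutation(len(grid))[:cfg.lipids_per_leaflet]
        heads = [grid[i] for i in order]
        far = [i for i, h in enumerate(heads)
               if all(np.linalg.norm(h - com) >= cfg.min_initial_site_distance
                      for com in site_coms.values())]
        if len(far) < n_pip2:
            raise ConfigurationError(
                "box too small to place PIP2 lipids at least "
                f"{cfg.min_initial_site_distance} A from every binding site")
        pip2_slots = set(rng.choice(far, size=n_pip2, replace=False).tolist())
        for resid, head in enumerate(heads, start=1):
            is_pip2 = (resid - 1) in pip2_slots
            resname = "PIP" if is_pip2 else "POP"
            tag = "LIPID_PIP2" if is_pip2 else "LIPID_POPC"
            if is_pip2:
                pip2_lipids.append((chain, resid))
            for name, elem, pos in _lipid_atoms(resname, head, leaflet_sign):
                atoms.append(Atom(aid, name, elem, ATOMIC_MASSES[elem],
                                  resid, resname, chain, tag))
                coords.append(pos)
                aid += 1

    top = Topology(atoms)
    return ToySystem(top, np.array(coords), cfg.box, sites, pip2_lipids, cfg)


# ---------------------------------------------------------------------------
# binding-event trajectories


def _validate_plan(system: ToySystem, plan: Sequence[PlantedBinding]) -> None:
    pip2_set = set(system.pip2_lipids)
    by_site: dict[str, list[PlantedBinding]] = {}
    by_lipid: dict[tuple[str, int], list[PlantedBinding]] = {}
    for pb in plan:
        if pb.lipid not in pip2_set:
            raise PlanError(f"{pb.lipid} is not a PIP2 lipid of this system")
        try:
            system.site(pb.site_label)
        except KeyError as exc:
            raise PlanError(str(exc)) from None
        by_site.setdefault(pb.site_label, []).append(pb)
        by_lipid.setdefault(pb.lipid, []).append(pb)
        moieties = [k[1] for k in pb.contact_plan]
        if len(moieties) != len(set(moieties)):
            raise PlanError("a moiety can target at most one residue per event")
    for label, events in by_site.items():
        events.sort(key=lambda e: e.dwell[0])
        for a, b in zip(events, events[1:]):
            if b.dwell[0] < a.dwell[1]:
                raise PlanError(
                    f"overlapping dwells at site {label}: {a.dwell} / {b.dwell}")
    for lipid, events in by_lipid.items():
        events.sort(key=lambda e: e.dwell[0])
        for a, b in zip(events, events[1:]):
            if b.t_start < a.dwell[1]:
                raise PlanError(f"overlapping plans for lipid {lipid}")


def simulate_binding_trajectory(system: ToySystem,
                                plan: Sequence[PlantedBinding],
                                n_frames: int, dt: float = 1.0,
                                seed: int = 0,
                                walk_sigma: float = 0.5,
                                bound_jitter: float = 0.3,
                                analysis_window_frac: float = 0.4,
                                ) -> Trajectory:
    """Diffuse the lipids and execute the planted binding events.

    Unplanted lipids random-walk in their leaflet plane (step sigma
    ``walk_sigma`` A/frame) and are reflected out of a 9-A exclusion shell
    around every site COM so they can never register as bound.  A planted
    lipid walks until ``t_start``, moves linearly to its bound pose until the
    dwell begins, then holds its headgroup COM at ``bound_distance`` from the
    site COM with Gaussian jitter (sigma ``bound_jitter`` A).  Per-moiety
    contact fractions are realised exactly (to frame rounding) over the
    trailing ``analysis_window_frac`` of the trajectory intersected with the
    dwell: on "contact" frames the moiety bead sits inside its class cutoff
    of the planned residue, on the remaining dwell frames it is held outside.
    """
    _validate_plan(system, plan)
    rng = np.random.default_rng(seed)
    top = system.topology
    times = np.arange(n_frames, dtype=float) * dt

    coords = np.tile(system.coords[None, :, :], (n_frames, 1, 1))

    pos_by_key = {(c, int(r)): i for i, (c, r) in
                  enumerate(zip(top.chain_id, top.residue_index))}
    # per-lipid atom index blocks
    lipid_atoms: dict[tuple[str, int], np.ndarray] = {}
    for chain in (UPPER_CHAIN, LOWER_CHAIN):
        mask = top.chain_id == chain
        for resid in np.unique(top.residue_index[mask]):
            lipid_atoms[(chain, int(resid))] = np.nonzero(
                mask & (top.residue_index == resid))[0]

    site_coms = {}
    prot_mask = np.isin(top.chain_id, PROTEIN_CHAINS[:system.config.monomers])
    for s in system.sites:
        idx = [np.nonzero((top.chain_id == c) & (top.residue_index == r)
                          & prot_mask)[0] for c, r in s.residues]
        idx = np.concatenate(idx)
        w = top.mass[idx]
        site_coms[s.label] = (w[:, None] * system.coords[idx]).sum(0) / w.sum()
    site_com_arr = np.array(list(site_coms.values()))

    planned_lipids = {pb.lipid: pb for pb in plan}
    all_lipids = sorted(lipid_atoms)
    free = [lp for lp in all_lipids if lp not in planned_lipids]

    # --- free lipids: vectorised 2D walks with site-shell exclusion
    heads0 = np.array([system.coords[lipid_atoms[lp][0]] for lp in free])
    steps = rng.normal(0.0, walk_sigma, size=(n_frames, len(free), 2))
    steps[0] = 0.0
    pos = heads0.copy()
    for f in range(n_frames):
        pos[:, :2] += steps[f]
        # push any lipid that wandered inside a site exclusion shell back out
        d = np.linalg.norm(pos[:, None, :] - site_com_arr[None, :, :], axis=2)
        j, k = np.nonzero(d < 9.0)
        for ji, ki in zip(j, k):
            v = pos[ji, :2] - site_com_arr[ki, :2]
            norm = np.linalg.norm(v)
            v = v / norm if norm > 1e-9 else np.array([1.0, 0.0])
            pos[ji, :2] = site_com_arr[ki, :2] + v * 9.0
        for li, lp in enumerate(free):
            idx = lipid_atoms[lp]
            shift = pos[li] - system.coords[idx[0]]
            coords[f, idx] = system.coords[idx] + shift

    # --- planted lipids: walk -> approach -> dwell -> walk
    w0 = int(math.floor(n_frames * (1.0 - analysis_window_frac)))
    analysis_frames = np.arange(w0, n_frames)
    for lp, pb in planned_lipids.items():
        idx = lipid_atoms[lp]
        site_com = site_coms[pb.site_label]
        radial = np.array([site_com[0], site_com[1], 0.0])
        radial /= np.linalg.norm(radial)
        bound_center = site_com + radial * pb.bound_distance

        # dwell is an inclusive [t0, t1] time interval
        dwell_f = (int(round(pb.dwell[0] / dt)),
                   int(round(pb.dwell[1] / dt)) + 1)
        start_f = int(round(pb.t_start / dt))
        if dwell_f[1] > n_frames:
            raise PlanError("dwell extends beyond the trajectory span")

        head = system.coords[idx[0]].copy()
        approach_from = None
        centers = np.empty((n_frames, 3))
        for f in range(n_frames):
            if f < start_f:
                head[:2] += rng.normal(0.0, walk_sigma, size=2)
                centers[f] = head
            elif f < dwell_f[0]:
                if approach_from is None:
                    approach_from = head.copy()
                frac = (f - start_f + 1) / max(dwell_f[0] - start_f, 1)
                centers[f] = approach_from + frac * (bound_center - approach_from)
            elif f < dwell_f[1]:
                centers[f] = bound_center + rng.normal(0.0, bound_jitter, size=3)
            else:
                if f == dwell_f[1]:
                    head = centers[f - 1].copy()
                head[:2] += rng.normal(0.0, walk_sigma, size=2)
                head += radial * walk_sigma  # drift away after release
                centers[f] = head
        for f in range(n_frames):
            shift = centers[f] - system.coords[idx[0]]
            coords[f, idx] = system.coords[idx] + shift

        # realise the per-moiety contact plan inside the dwell
        dwell_frames = np.arange(dwell_f[0], dwell_f[1])
        window = np.intersect1d(dwell_frames, analysis_frames)
        name_to_idx = {str(top.atom_name[i]): i for i in idx}
        for ((chain, resid), moiety), frac in pb.contact_plan.items():
            bead_names = system.schema.moieties[moiety]
            cls = system.schema.classes[moiety]
            cutoff = CONTACT_CUTOFFS[cls]
            res_i = pos_by_key[(chain, resid)]
            res_pos = system.coords[res_i]
            n_on = int(round(frac * len(window)))
            on = set(rng.choice(window, size=n_on, replace=False).tolist()) \
                if n_on else set()
            for bead in bead_names:
                bi = name_to_idx[bead]
                for f in dwell_frames:
                    u = centers[f] - res_pos
                    u /= np.linalg.norm(u)
                    d = _D_ON[cls] if f in on else cutoff + _D_OFF_PAD
                    coords[f, bi] = res_pos + u * d

    return Trajectory(top, coords, times, box=np.array(system.box))


# ---------------------------------------------------------------------------
# correlated-motion / tilt trajectories


def partition_by_tags(system: ToySystem,
                      groups: Mapping[str, Sequence[str]],
                      rest_label: str = "rest") -> dict[str, frozenset[tuple[str, int]]]:
    """Partition protein residues into groups by domain tag (all chains);
    residues not named by any group fall into ``rest_label``."""
    top = system.topology
    chains = PROTEIN_CHAINS[:system.config.monomers]
    out: dict[str, set[tuple[str, int]]] = {g: set() for g in groups}
    rest: set[tuple[str, int]] = set()
    assigned: dict[str, str] = {}
    for g, tags in groups.items():
        for t in tags:
            if t in assigned:
                raise ConfigurationError(f"tag {t} assigned to two groups")
            assigned[t] = g
    for c, r, tag in zip(top.chain_id, top.residue_index, top.tag):
        if c not in chains:
            continue
        key = (str(c), int(r))
        if tag in assigned:
            out[assigned[tag]].add(key)
        else:
            rest.add(key)
    result = {g: frozenset(v) for g, v in out.items() if v}
    if rest:
        result[rest_label] = frozenset(rest)
    return result


def simulate_correlated_trajectory(system: ToySystem,
                                   comm: PlantedCommunities,
                                   tilt: Optional[PlantedTilt],
                                   n_frames: int, dt: float = 1.0,
                                   seed: int = 0) -> Trajectory:
    """Overlay shared latent modes (and optionally a helix-pair tilt) on the
    rest structure.

    Each residue bead moves as rest + amplitude * m_g(t) + noise, where
    m_g(t) is the group's 3-vector latent mode; with coupling c the group
    modes share a common component, m_g = sqrt(1-c)*independent + sqrt(c)*
    common.  When ``tilt`` is given, each monomer's helices A+B rod is
    rebuilt every frame along a direction whose angle to +z is drawn from
    N(theta_mean, theta_sd), keeping the A-to-B bead order (sign convention).
    Lipids stay at their initial positions.
    """
    top = system.topology
    rng = np.random.default_rng(seed)
    chains = PROTEIN_CHAINS[:system.config.monomers]

    prot_keys = [(str(c), int(r)) for c, r in zip(top.chain_id, top.residue_index)
                 if c in chains]
    covered = set().union(*comm.partition.values()) if comm.partition else set()
    missing = set(prot_keys) - covered
    if missing:
        raise ConfigurationError(
            f"partition must cover all protein residues; missing {len(missing)}")

    atom_of = {}
    for i, (c, r) in enumerate(zip(top.chain_id, top.residue_index)):
        if c in chains:
            atom_of[(str(c), int(r))] = i

    times = np.arange(n_frames, dtype=float) * dt
    coords = np.tile(system.coords[None, :, :], (n_frames, 1, 1))

    rest = system.coords.copy()
    if tilt is not None:
        helix_keys = {ch: [] for ch in chains}
        for (c, r), i in atom_of.items():
            if top.tag[i] in ("HELIX_A", "HELIX_B"):
                helix_keys[c].append((r, i, str(top.tag[i])))
        thetas = np.clip(rng.normal(tilt.theta_mean, tilt.theta_sd,
                                    size=(n_frames, len(chains))), 1e-3, 180 - 1e-3)
        zhat = np.array([0.0, 0.0, 1.0])
        for ci, chain in enumerate(chains):
            entries = sorted(helix_keys[chain])
            ids = np.array([i for _, i, _ in entries])
            pts = rest[ids]
            centroid = pts.mean(axis=0)
            centered = pts - centroid
            # rest principal axis, signed from Helix-A COM to Helix-B COM
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            a0 = vt[0]
            com_a = pts[[k for k, (_, _, t) in enumerate(entries)
                         if t == "HELIX_A"]].mean(axis=0)
            com_b = pts[[k for k, (_, _, t) in enumerate(entries)
                         if t == "HELIX_B"]].mean(axis=0)
            if np.dot(a0, com_b - com_a) < 0:
                a0 = -a0
            s = centered @ a0                      # bead abscissae on the rod
            e = a0 - np.dot(a0, zhat) * zhat       # in-plane direction of tilt
            e /= np.linalg.norm(e)
            for f in range(n_frames):
                th = math.radians(thetas[f, ci])
                d = math.sin(th) * e + math.cos(th) * zhat
                coords[f, ids] = centroid + s[:, None] * d[None, :]

    group_labels = sorted(comm.partition)
    common = rng.normal(size=(n_frames, 3))
    for g in group_labels:
        amp = comm.amplitudes.get(g, 0.0)
        ind = rng.normal(size=(n_frames, 3))
        c = comm.coupling
        mode = math.sqrt(1.0 - c) * ind + math.sqrt(c) * common
        ids = np.array(sorted(atom_of[k] for k in comm.partition[g]))
        coords[:, ids, :] += amp * mode[:, None, :]
    if comm.noise_amplitude > 0:
        ids = np.array(sorted(atom_of.values()))
        coords[:, ids, :] += rng.normal(
            0.0, comm.noise_amplitude, size=(n_frames, len(ids), 3))

    return Trajectory(top, coords, times, box=np.array(system.box))
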
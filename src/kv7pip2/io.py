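"""Readers and writers for the standard formats the pipeline touches.

Trajectories travel as multi-model PDB (via biotite) plus a JSON sidecar
carrying frame times, box dimensions and per-residue domain tags — PDB has
no slot for any of those.  Occupancy grids are OpenDX scalar grids (via
GridDataFormats), networks are GraphML, tables are CSV, and binding-site
definitions are JSON of the form {label: [[chain, resid], ...]}.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from gridData import Grid

from .binding import BindingSite, OccupancyGrid
from .core import ATOMIC_MASSES, Atom, Topology, Trajectory, infer_element
from .errors import FormatError


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(traj: Trajectory, pdb_path: str | Path,
                     sidecar_path: Optional[str | Path] = None) -> None:
    """Write a multi-model PDB plus a JSON sidecar (times, box, tags)."""
    pdb_path = Path(pdb_path)
    top = traj.topology
    n_frames, n_atoms = traj.n_frames, top.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = traj.coords.astype(np.float32)
    stack.chain_id = top.chain_id.astype("U4")
    stack.res_id = top.residue_index
    stack.res_name = np.asarray(top.residue_name, dtype="U5")
    stack.atom_name = np.asarray(top.atom_name, dtype="U6")
    stack.element = np.asarray(top.element, dtype="U2")
    stack.hetero = np.asarray([t.startswith("LIPID") or t == "SOLVENT"
                               for t in top.tag])
    if traj.box is not None:
        box = np.zeros((n_frames, 3, 3))
        for f in range(n_frames):
            box[f] = np.diag(traj.box[f])
        stack.box = box
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(pdb_path))

    sidecar_path = Path(sidecar_path) if sidecar_path is not None \
        else pdb_path.with_suffix(".json")
    tags = {f"{c}:{int(r)}": str(t) for c, r, t in
            zip(top.chain_id, top.residue_index, top.tag)}
    payload = {
        "times_ns": traj.times.tolist(),
        "box_A": traj.box.tolist() if traj.box is not None else None,
        "tags": tags,
    }
    sidecar_path.write_text(json.dumps(payload))


def _scan_model_counts(pdb_path: Path) -> list[int]:
    counts: list[int] = []
    current = 0
    in_model = False
    for line in pdb_path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not counts:            # single-model file without MODEL records
        counts = [current] if current else []
    elif not in_model and current:
        counts.append(current)
    return counts


def read_trajectory(pdb_path: str | Path,
                    sidecar_path: Optional[str | Path] = None,
                    tag_map: Optional[dict] = None) -> Trajectory:
    """Read a multi-model PDB into a Trajectory.

    Tags come from the sidecar's per-residue table (``{"A:12": "S4"}``) or a
    tag map of ranges (``[{"chain": "A", "start": 1, "end": 10, "tag":
    "S4"}]``); untagged protein residues become OTHER, and POPC/PIP2
    residue names map to their lipid tags automatically.  A model whose atom
    count differs from the first model raises FormatError naming the model.
    """
    pdb_path = Path(pdb_path)
    counts = _scan_model_counts(pdb_path)
    if not counts:
        raise FormatError(f"{pdb_path}: no coordinates found")
    for i, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise FormatError(
                f"{pdb_path}: model {i} has {c} atoms, expected {counts[0]}")

    pdbf = PDBFile.read(str(pdb_path))
    stack = pdbf.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    n_frames, n_atoms = stack.stack_depth(), stack.array_length()

    sidecar = None
    if sidecar_path is None:
        candidate = pdb_path.with_suffix(".json")
        if candidate.exists():
            sidecar = json.loads(candidate.read_text())
    else:
        sidecar = json.loads(Path(sidecar_path).read_text())

    sidecar_tags = (sidecar or {}).get("tags", {})
    range_tags = []
    if tag_map:
        range_tags = tag_map if isinstance(tag_map, list) else tag_map.get("ranges", [])

    def tag_for(chain: str, resid: int, resname: str) -> str:
        key = f"{chain}:{resid}"
        if key in sidecar_tags:
            return sidecar_tags[key]
        for entry in range_tags:
            if entry["chain"] == chain and entry["start"] <= resid <= entry["end"]:
                return entry["tag"]
        if resname in ("POP", "POPC"):
            return "LIPID_POPC"
        if resname in ("PIP", "PIP2"):
            return "LIPID_PIP2"
        if resname in ("HOH", "TIP3", "WAT"):
            return "SOLVENT"
        return "OTHER"

    atoms = []
    for i in range(n_atoms):
        elem = str(stack.element[i]).strip() or infer_element(str(stack.atom_name[i]))
        elem = elem[0].upper() + elem[1:].lower() if len(elem) > 1 else elem.upper()
        mass = ATOMIC_MASSES.get(elem, ATOMIC_MASSES.get(elem.upper(), 12.011))
        atoms.append(Atom(i + 1, str(stack.atom_name[i]), elem, mass,
                          int(stack.res_id[i]), str(stack.res_name[i]),
                          str(stack.chain_id[i]),
                          tag_for(str(stack.chain_id[i]), int(stack.res_id[i]),
                                  str(stack.res_name[i]))))
    top = Topology(atoms)

    if sidecar and sidecar.get("times_ns") is not None:
        times = np.asarray(sidecar["times_ns"], dtype=float)
    else:
        times = np.arange(n_frames, dtype=float)
    box = None
    if sidecar and sidecar.get("box_A") is not None:
        box = np.asarray(sidecar["box_A"], dtype=float)
    elif stack.box is not None:
        box = np.array([np.diag(stack.box[f]) for f in range(n_frames)])
    return Trajectory(top, np.asarray(stack.coord, dtype=float), times, box=box)


# ---------------------------------------------------------------------------
# grids, sites, networks


def write_dx(grid: OccupancyGrid, path: str | Path) -> None:
    """Write an occupancy grid as an OpenDX regular scalar grid."""
    g = Grid(grid.values, origin=np.asarray(grid.origin, dtype=float),
             delta=float(grid.spacing))
    g.export(str(path), file_format="dx")


def read_dx(path: str | Path) -> OccupancyGrid:
    g = Grid(str(path))
    delta = np.atleast_1d(np.asarray(g.delta))
    spacing = float(delta.flat[0])
    return OccupancyGrid(origin=np.asarray(g.origin, dtype=float),
                         spacing=spacing, values=np.asarray(g.grid))


def read_sites(path: str | Path) -> list[BindingSite]:
    """Binding-site JSON: {label: [[chain, resid], ...], ...}."""
    raw = json.loads(Path(path).read_text())
    return [BindingSite(label, tuple((str(c), int(r)) for c, r in members))
            for label, members in raw.items()]


def write_sites(sites: list[BindingSite], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {s.label: [[c, r] for c, r in s.residues] for s in sites}, indent=1))


def write_network_graphml(net, path: str | Path) -> None:
    """GraphML export with chain/resid/tag (and community, if computed)."""
    import networkx as nx
    G = net.graph.copy()
    for i, (chain, resid, tag) in enumerate(net.nodes):
        G.nodes[i]["chain"] = chain
        G.nodes[i]["resid"] = resid
        G.nodes[i]["tag"] = tag
        if net.partition is not None:
            G.nodes[i]["community"] = int(net.partition[i])
    nx.write_graphml(G, str(path))


def write_matrix_csv(matrix: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(matrix).to_csv(path, index=False, header=False)


def write_ground_truth(payload: dict, path: str | Path) -> None:
    """JSON sidecar of planted events/partition/tilt for test harnesses."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset, tuple)):
            return list(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(payload, default=default, indent=1))
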
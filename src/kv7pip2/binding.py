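"""Lipid-binding analysis: occupancy grids, COM-distance series, binding
events and moiety-resolved contact probabilities.

A contact between a protein residue and a headgroup moiety is a heavy-atom
distance within a class-specific cutoff: 4.0 A for phosphate moieties and
3.5 A for hydroxyls.  Contact probabilities are fractions of frames within
an analysis window (default: the trailing 40% of the trajectory, mirroring
the last 200 ns of a 500-ns run).  A binding event is a maximal run of
frames with headgroup-COM to site-COM distance <= d_bind, after merging
short unbinding gaps and discarding short-lived runs; event-level tables are
aggregated as mean +/- SEM with SEM = sample SD / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import MoietySchema, Selection, Trajectory
from .errors import SchemaError, SelectionError

DEFAULT_CUTOFFS = {"phosphate": 4.0, "hydroxyl": 3.5}


@dataclass(frozen=True)
class BindingSite:
    """A labelled set of (chain, residue_index) pairs forming one site."""

    label: str
    residues: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"site {self.label!r} has no residues")

    def selection(self) -> Selection:
        chains = frozenset(c for c, _ in self.residues)
        resids = frozenset(r for _, r in self.residues)
        return Selection.make(chains=chains, residues=resids)


@dataclass
class OccupancyGrid:
    """Regular voxel grid of occupied-frame fractions in [0, 1]."""

    origin: np.ndarray          # (3,) A
    spacing: float              # A
    values: np.ndarray          # (nx, ny, nz) fractions

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BindingEvent:
    lipid: tuple[str, int]
    site_label: str
    t_start: float              # ns
    t_end: float                # ns
    mean_distance: float        # A over the bound run


class ContactProbabilityTable:
    """Per-(residue, moiety) contact statistics.

    ``data`` has columns chain, residue_index, moiety, mean, sem, n_events;
    per-event probabilities are retained in ``event_tables``.
    """

    def __init__(self, data: pd.DataFrame, window: tuple[float, float],
                 event_tables: Optional[list[pd.DataFrame]] = None):
        if len(data) and not ((data["mean"] >= 0) & (data["mean"] <= 1)).all():
            raise ValueError("contact probabilities must lie in [0, 1]")
        self.data = data.reset_index(drop=True)
        self.window = window
        self.event_tables = event_tables or []

    def probability(self, chain: str, resid: int, moiety: str) -> float:
        row = self.data[(self.data["chain"] == chain)
                        & (self.data["residue_index"] == resid)
                        & (self.data["moiety"] == moiety)]
        if row.empty:
            raise KeyError((chain, resid, moiety))
        return float(row["mean"].iloc[0])


def occupancy_map(traj: Trajectory, sel: Selection, spacing: float = 1.0,
                  frames: Optional[Sequence[int]] = None) -> OccupancyGrid:
    """Fraction of frames in which each voxel holds >= 1 selected atom.

    The grid spans the selection's bounding box over the window, padded by
    one voxel; voxel membership is half-open [lower, upper) per axis.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    frames = np.arange(traj.n_frames) if frames is None else np.asarray(frames)
    if frames.size == 0:
        raise ValueError("empty frame window")
    idx = sel.resolve(traj.topology)
    pts = traj.coords[np.ix_(frames, idx)]
    lo = pts.reshape(-1, 3).min(axis=0)
    hi = pts.reshape(-1, 3).max(axis=0)
    origin = lo - spacing
    dims = np.floor((hi - origin) / spacing).astype(int) + 2
    values = np.zeros(tuple(dims))
    for f in range(frames.size):
        vox = np.floor((pts[f] - origin) / spacing).astype(int)
        vox = np.unique(vox, axis=0)
        values[vox[:, 0], vox[:, 1], vox[:, 2]] += 1.0
    values /= frames.size
    return OccupancyGrid(origin=origin, spacing=spacing, values=values)


def com_distance_series(traj: Trajectory, lipid_headgroup: Selection,
                        site: BindingSite) -> tuple[np.ndarray, np.ndarray]:
    """Distance between the headgroup COM and the site COM, per frame.

    The site COM uses the heavy atoms of its member residues.  Returns
    (times, distances).
    """
    top = traj.topology
    hg = lipid_headgroup.resolve(top)
    site_idx = site.selection().resolve(top)
    heavy = top.heavy_mask()
    site_idx = site_idx[heavy[site_idx]]
    if site_idx.size == 0:
        raise SelectionError(f"site {site.label} has no heavy atoms")
    m_hg = top.mass[hg]
    m_site = top.mass[site_idx]
    com_hg = np.einsum("tij,i->tj", traj.coords[:, hg], m_hg) / m_hg.sum()
    com_site = np.einsum("tij,i->tj", traj.coords[:, site_idx], m_site) / m_site.sum()
    return traj.times.copy(), np.linalg.norm(com_hg - com_site, axis=1)


def detect_binding_events(times: np.ndarray, distances: np.ndarray,
                          d_bind: float = 6.0, min_dwell: float = 50.0,
                          rejoin_gap: float = 5.0,
                          lipid: tuple[str, int] = ("", 0),
                          site_label: str = "") -> list[BindingEvent]:
    """Maximal bound runs (distance <= d_bind), merging unbound gaps whose
    duration is <= rejoin_gap and discarding runs shorter than min_dwell."""
    if d_bind <= 0:
        raise ValueError("d_bind must be positive")
    if min_dwell < 0:
        raise ValueError("min_dwell must be >= 0")
    times = np.asarray(times, dtype=float)
    bound = np.asarray(distances, dtype=float) <= d_bind
    if not bound.any():
        return []
    # maximal runs of bound frames
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bound.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2] - 1))   # inclusive frame spans
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        if times[a] - times[pb] <= rejoin_gap:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    events = []
    for a, b in merged:
        if times[b] - times[a] >= min_dwell:
            sel = slice(a, b + 1)
            events.append(BindingEvent(
                lipid=lipid, site_label=site_label,
                t_start=float(times[a]), t_end=float(times[b]),
                mean_distance=float(np.asarray(distances)[sel].mean())))
    events.sort(key=lambda e: e.t_start)
    return events


def contact_probability(traj: Trajectory,
                        residues: Sequence[tuple[str, int]],
                        pip2_residue: tuple[str, int],
                        schema: MoietySchema,
                        window: Optional[tuple[float, float]] = None,
                        cutoffs: Mapping[str, float] = DEFAULT_CUTOFFS,
                        side_chain_only: bool = False,
                        ) -> ContactProbabilityTable:
    """Single-event contact probabilities for every (residue, moiety) pair.

    A residue is "in contact" with a moiety in a frame when any residue
    heavy atom lies within the moiety-class cutoff of any moiety atom.  With
    ``side_chain_only`` backbone atoms (N, CA, C, O) are excluded from the
    residue side.  ``window`` is a (t0, t1) time interval; the default is the
    trailing 40% of the trajectory.
    """
    for cls in set(schema.classes.values()):
        if cls not in cutoffs:
            raise SchemaError(f"no cutoff for moiety class {cls!r}")
    top = traj.topology
    if window is None:
        t0 = traj.times[0] + 0.6 * (traj.times[-1] - traj.times[0])
        window = (t0, traj.times[-1])
    frames = traj.window_frames(window)

    lip_chain, lip_resid = pip2_residue
    lip_mask = (top.chain_id == lip_chain) & (top.residue_index == lip_resid)
    heavy = top.heavy_mask()
    backbone = np.isin(top.atom_name, ["N", "CA", "C", "O"])

    rows = []
    for chain, resid in residues:
        res_mask = (top.chain_id == chain) & (top.residue_index == resid) & heavy
        if side_chain_only and (res_mask & ~backbone).any():
            res_mask &= ~backbone
        res_idx = np.nonzero(res_mask)[0]
        if res_idx.size == 0:
            raise SelectionError(f"residue ({chain}, {resid}) has no heavy atoms")
        for moiety in MoietySchema.MOIETY_LABELS:
            names = schema.moieties[moiety]
            m_idx = np.nonzero(lip_mask & np.isin(top.atom_name, list(names))
                               & heavy)[0]
            if m_idx.size == 0:
                raise SelectionError(
                    f"moiety {moiety} atoms missing on lipid {pip2_residue}")
            cutoff = cutoffs[schema.classes[moiety]]
            hits = 0
            for f in frames:
                if cdist(traj.coords[f, res_idx], traj.coords[f, m_idx]).min() <= cutoff:
                    hits += 1
            rows.append({"chain": chain, "residue_index": resid,
                         "moiety": moiety, "mean": hits / frames.size,
                         "sem": 0.0, "n_events": 1})
    df = pd.DataFrame(rows)
    return ContactProbabilityTable(df, window, event_tables=[df.copy()])


def aggregate_events(tables: Sequence[ContactProbabilityTable]
                     ) -> ContactProbabilityTable:
    """Mean +/- SEM over events; SEM = sample SD / sqrt(n), 0 when n = 1.

    Tables must share the same (chain, residue, moiety) keys.
    """
    if not tables:
        raise ValueError("need at least one event table")
    key = ["chain", "residue_index", "moiety"]
    ref = tables[0].data[key]
    stacks = []
    for t in tables:
        d = t.data.sort_values(key).reset_index(drop=True)
        if not d[key].equals(ref.sort_values(key).reset_index(drop=True)):
            raise ValueError("event tables have incongruent keys")
        stacks.append(d["mean"].to_numpy())
    probs = np.column_stack(stacks)     # (n_keys, n_events)
    n = probs.shape[1]
    mean = probs.mean(axis=1)
    sem = (probs.std(axis=1, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros(len(mean))
    out = ref.sort_values(key).reset_index(drop=True).copy()
    out["mean"] = mean
    out["sem"] = sem
    out["n_events"] = n
    window = tables[0].window
    return ContactProbabilityTable(out, window,
                                   event_tables=[t.data for t in tables])
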
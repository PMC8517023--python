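"""Orientation of the helices A+B pair relative to the membrane normal.

The pair axis is the dominant principal axis of the combined Calpha cloud,
sign-fixed to point from the Helix-A centre of mass toward the Helix-B
centre of mass.  The orientation angle theta(t) = arccos(axis . n) is
reported unfolded on [0, 180] degrees (not reflected at 90), so that
solvent-exposed (< 90) and bilayer-interacting (> 90) poses of the helical
pair are distinguishable.  The membrane normal defaults to +z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Selection, Trajectory
from .errors import GeometryError


def helix_pair_axis(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Unit principal axis of the combined helix A+B Calpha coordinates.

    Requires >= 3 Calpha per helix and a non-spherical cloud; the sign is
    chosen so the axis points from the A centroid toward the B centroid.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 3 or b.shape[1] != 3:
        raise GeometryError("helix coordinates must be (n, 3) arrays")
    if len(a) < 3 or len(b) < 3:
        raise GeometryError("need at least 3 Calpha per helix")
    pts = np.vstack([a, b])
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9 or (s[1] / s[0]) > 1.0 - 1e-9:
        raise GeometryError("degenerate (spherical) coordinate cloud")
    axis = vt[0]
    direction = b.mean(axis=0) - a.mean(axis=0)
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


@dataclass
class OrientationSeries:
    times: np.ndarray           # ns
    theta: np.ndarray           # degrees in [0, 180]
    window: tuple[float, float]
    mean: float                 # over the window
    sd: float                   # frame-level SD over the window

    def window_values(self) -> np.ndarray:
        m = (self.times >= self.window[0]) & (self.times <= self.window[1])
        return self.theta[m]


def orientation_series(traj: Trajectory, helix_a_sel: Selection,
                       helix_b_sel: Selection,
                       window: Optional[tuple[float, float]] = None,
                       normal: np.ndarray = np.array([0.0, 0.0, 1.0]),
                       ) -> OrientationSeries:
    """Per-frame pair-axis angle to the membrane normal, with window stats.

    The default window is the trailing 40% of the trajectory.
    """
    ia = helix_a_sel.resolve(traj.topology)
    ib = helix_b_sel.resolve(traj.topology)
    n = np.asarray(normal, dtype=float)
    n /= np.linalg.norm(n)
    theta = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        axis = helix_pair_axis(traj.coords[f, ia], traj.coords[f, ib])
        theta[f] = np.degrees(np.arccos(np.clip(np.dot(axis, n), -1.0, 1.0)))
    if window is None:
        t0 = traj.times[0] + 0.6 * (traj.times[-1] - traj.times[0])
        window = (float(t0), float(traj.times[-1]))
    m = (traj.times >= window[0]) & (traj.times <= window[1])
    if not m.any():
        raise ValueError(f"window {window} contains no frames")
    vals = theta[m]
    return OrientationSeries(times=traj.times.copy(), theta=theta,
                             window=window, mean=float(vals.mean()),
                             sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0)


def pooled_orientation_stats(series: list[OrientationSeries]) -> tuple[float, float]:
    """Frame-level mean and SD pooled across monomers/replicates."""
    vals = np.concatenate([s.window_values() for s in series])
    return float(vals.mean()), float(vals.std(ddof=1))
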
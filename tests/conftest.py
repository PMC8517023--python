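"""Shared fixtures and tiny-topology builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from kv7pip2.core import Atom, Topology, Trajectory
from kv7pip2.synth_traj import ToySystemConfig, build_toy_system

# toy-scale study conditions used across trajectory tests: a small bilayer
# patch (46 lipids/leaflet -> 2 PIP2 at 4.4%) in a box that satisfies the
# 15-A placement constraint
TOY_CFG = dict(lipids_per_leaflet=60, pip2_fraction=0.033,
               box=(110.0, 110.0, 80.0), seed=1)


def make_atoms(spec):
    """Build Atom records from (name, element, mass, resid, chain, tag)."""
    return [Atom(i + 1, name, elem, mass, resid, "RES", chain, tag)
            for i, (name, elem, mass, resid, chain, tag) in enumerate(spec)]


def point_traj(coords, masses=None, times=None, tags=None, names=None,
               elements=None, resids=None, chains=None, box=None):
    """Trajectory of bare point atoms; coords is (T, N, 3) or (N, 3)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    masses = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    tags = ["OTHER"] * n if tags is None else tags
    names = [f"X{i}" for i in range(n)] if names is None else names
    elements = ["C"] * n if elements is None else elements
    resids = list(range(1, n + 1)) if resids is None else resids
    chains = ["A"] * n if chains is None else chains
    atoms = [Atom(i + 1, names[i], elements[i], float(masses[i]),
                  int(resids[i]), "RES", chains[i], tags[i])
             for i in range(n)]
    times = np.arange(coords.shape[0], dtype=float) if times is None else times
    return Trajectory(Topology(atoms), coords, np.asarray(times, float), box=box)


@pytest.fixture(scope="session")
def toy_system():
    return build_toy_system(ToySystemConfig(**TOY_CFG))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
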
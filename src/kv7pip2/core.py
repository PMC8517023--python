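"""Core in-memory model: topologies, trajectories, selections and geometric
primitives.

Conventions used throughout the package:

* coordinates in Angstrom, times in nanoseconds, masses in Dalton;
* the membrane normal is +z and leaflets sit at +/-z;
* "heavy atom" means element != "H"; the element is taken from the topology,
  and when absent it is inferred from the leading alphabetic character of the
  atom name (with an override table for two-letter elements);
* selections always resolve in ascending atom_id order so that every
  downstream reduction is deterministic.

Analyses operate on unwrapped/whole-molecule coordinates.  Distances can
optionally apply the minimum-image convention for an orthorhombic box; the
default is no wrapping because the synthetic systems are built whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import GeometryError, SchemaError, SelectionError

# Domain-label vocabulary for channel residues and membrane components.
DOMAIN_TAGS = (
    "NT_TAIL", "S1", "S2", "S2S3_LINKER", "S3", "S4", "S4S5_LINKER",
    "S5", "PORE_LOOP", "S6", "PRE_HELIX_A", "HELIX_A", "AB_LINKER",
    "HELIX_B", "BC_LINKER", "LIPID_POPC", "LIPID_PIP2", "SOLVENT", "OTHER",
)

# Standard atomic masses (Da) for the elements the toy systems use.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "K": 39.098,
}

# Atom names whose leading character would mis-identify the element.
ELEMENT_OVERRIDES: dict[str, str] = {
    "CL": "Cl", "NA": "Na", "MG": "Mg", "CA2": "Ca", "ZN": "Zn", "FE": "Fe",
}


def infer_element(atom_name: str) -> str:
    """Guess the element from an atom name (PDB-style heuristics)."""
    name = atom_name.strip().upper()
    if name in ELEMENT_OVERRIDES:
        return ELEMENT_OVERRIDES[name]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True)
class Atom:
    atom_id: int
    atom_name: str
    element: str
    mass: float
    residue_index: int
    residue_name: str
    chain_id: str
    tag: str


class Topology:
    """Immutable atom table with per-atom domain/lipid tags.

    Atoms are stored column-wise in numpy arrays for vectorised analysis;
    :meth:`atom` reconstructs a record view on demand.
    """

    def __init__(self, atoms: Sequence[Atom]):
        if len(atoms) == 0:
            raise ValueError("topology must contain at least one atom")
        self.atom_id = np.array([a.atom_id for a in atoms], dtype=np.int64)
        if len(np.unique(self.atom_id)) != len(atoms):
            raise ValueError("atom_ids must be unique")
        self.atom_name = np.array([a.atom_name for a in atoms], dtype=object)
        self.element = np.array([a.element for a in atoms], dtype=object)
        self.mass = np.array([a.mass for a in atoms], dtype=float)
        if np.any(self.mass <= 0):
            raise ValueError("all masses must be positive")
        self.residue_index = np.array([a.residue_index for a in atoms], dtype=np.int64)
        self.residue_name = np.array([a.residue_name for a in atoms], dtype=object)
        self.chain_id = np.array([a.chain_id for a in atoms], dtype=object)
        self.tag = np.array([a.tag for a in atoms], dtype=object)
        for t in self.tag:
            if t not in DOMAIN_TAGS:
                raise ValueError(f"unknown domain tag {t!r}")
        # deterministic storage order: ascending atom_id
        order = np.argsort(self.atom_id, kind="stable")
        for name in ("atom_id", "atom_name", "element", "mass",
                     "residue_index", "residue_name", "chain_id", "tag"):
            setattr(self, name, getattr(self, name)[order])

    def __len__(self) -> int:
        return len(self.atom_id)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    def atom(self, i: int) -> Atom:
        return Atom(
            int(self.atom_id[i]), str(self.atom_name[i]), str(self.element[i]),
            float(self.mass[i]), int(self.residue_index[i]),
            str(self.residue_name[i]), str(self.chain_id[i]), str(self.tag[i]),
        )

    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_index) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_id, self.residue_index):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)


@dataclass(frozen=True)
class Selection:
    """Declarative atom predicate: any combination of chain ids, residue
    indices, atom names and domain tags; unspecified components match all."""

    chains: Optional[frozenset[str]] = None
    residues: Optional[frozenset[int]] = None
    names: Optional[frozenset[str]] = None
    tags: Optional[frozenset[str]] = None

    @classmethod
    def make(cls, chains: Iterable[str] | None = None,
             residues: Iterable[int] | None = None,
             names: Iterable[str] | None = None,
             tags: Iterable[str] | None = None) -> "Selection":
        f = lambda x: None if x is None else frozenset(x)
        return cls(f(chains), f(residues), f(names), f(tags))

    def mask(self, top: Topology) -> np.ndarray:
        m = np.ones(top.n_atoms, dtype=bool)
        if self.chains is not None:
            m &= np.isin(top.chain_id, list(self.chains))
        if self.residues is not None:
            m &= np.isin(top.residue_index, list(self.residues))
        if self.names is not None:
            m &= np.isin(top.atom_name, list(self.names))
        if self.tags is not None:
            m &= np.isin(top.tag, list(self.tags))
        return m

    def resolve(self, top: Topology) -> np.ndarray:
        """Indices of matching atoms in ascending atom_id order.

        Raises :class:`SelectionError` when nothing matches.
        """
        idx = np.nonzero(self.mask(top))[0]
        if idx.size == 0:
            raise SelectionError(f"selection matched no atoms: {self}")
        return idx


class Trajectory:
    """Topology plus a (T, N, 3) coordinate block with frame times.

    ``box`` holds per-frame orthorhombic dimensions (T, 3) or None.
    """

    def __init__(self, topology: Topology, coords: np.ndarray,
                 times: np.ndarray, box: Optional[np.ndarray] = None):
        coords = np.asarray(coords, dtype=float)
        times = np.asarray(times, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (T, N, 3)")
        if coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {coords.shape[1]} != topology "
                f"atom count {topology.n_atoms}")
        if times.shape != (coords.shape[0],):
            raise ValueError("times must be length T")
        if coords.shape[0] > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if box is not None:
            box = np.asarray(box, dtype=float)
            if box.shape == (3,):
                box = np.tile(box, (coords.shape[0], 1))
            if box.shape != (coords.shape[0], 3):
                raise ValueError("box must have shape (T, 3)")
        self.topology = topology
        self.coords = coords
        self.times = times
        self.box = box

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        if not (-self.n_frames <= i < self.n_frames):
            raise IndexError(f"frame {i} out of range (T={self.n_frames})")
        return self.coords[i]

    def window_frames(self, window: tuple[float, float] | None) -> np.ndarray:
        """Frame indices whose times fall in [t0, t1]; None selects all."""
        if window is None:
            return np.arange(self.n_frames)
        t0, t1 = window
        idx = np.nonzero((self.times >= t0) & (self.times <= t1))[0]
        if idx.size == 0:
            raise ValueError(f"window {window} contains no frames")
        return idx


@dataclass(frozen=True)
class MoietySchema:
    """Names of the atoms forming each headgroup moiety of one PIP2 residue.

    The six moieties of the inositol headgroup are the P1/P4/P5 phosphates
    and the 2-/3-/6-hydroxyls; the membership class decides which distance
    cutoff applies (phosphates 4.0 A, hydroxyls 3.5 A by default).
    """

    moieties: Mapping[str, frozenset[str]]
    classes: Mapping[str, str]

    MOIETY_LABELS = ("P1", "P4", "P5", "OH2", "OH3", "OH6")

    def __post_init__(self):
        labels = set(self.moieties)
        if labels != set(self.MOIETY_LABELS):
            raise SchemaError(f"schema must define exactly {self.MOIETY_LABELS}")
        if set(self.classes) != labels:
            raise SchemaError("classes must cover all six moieties")
        for label, cls in self.classes.items():
            if cls not in ("phosphate", "hydroxyl"):
                raise SchemaError(f"unknown moiety class {cls!r} for {label}")
        all_names: list[str] = []
        for label, names in self.moieties.items():
            if not names:
                raise SchemaError(f"moiety {label} is empty")
            all_names.extend(names)
        if len(all_names) != len(set(all_names)):
            raise SchemaError("moiety atom-name sets must be pairwise disjoint")

    @classmethod
    def default(cls) -> "MoietySchema":
        """Schema matching the single-bead moieties of the toy PIP2 residue."""
        return cls(
            moieties={
                "P1": frozenset({"P1"}), "P4": frozenset({"P4"}),
                "P5": frozenset({"P5"}), "OH2": frozenset({"O2"}),
                "OH3": frozenset({"O3"}), "OH6": frozenset({"O6"}),
            },
            classes={"P1": "phosphate", "P4": "phosphate", "P5": "phosphate",
                     "OH2": "hydroxyl", "OH3": "hydroxyl", "OH6": "hydroxyl"},
        )


# ---------------------------------------------------------------------------
# geometric primitives


def center_of_mass(traj: Trajectory, sel: Selection, frame: int) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms in one frame."""
    idx = sel.resolve(traj.topology)
    xyz = traj.frame(frame)[idx]
    m = traj.topology.mass[idx]
    return (m[:, None] * xyz).sum(axis=0) / m.sum()


def com_from_coords(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    m = np.asarray(masses, dtype=float)
    return (m[:, None] * coords).sum(axis=0) / m.sum()


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with R a proper rotation (det = +1) and t a
    translation such that ``R @ x + t`` best fits the reference; rmsd is
    evaluated after the transform.  Kabsch via quaternion alignment.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # collinear (rank < 2) clouds leave the rotation under-determined
    if np.linalg.matrix_rank(mob_c, tol=1e-9 * max(1.0, np.abs(mob_c).max())) < 2:
        raise GeometryError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = reference.mean(axis=0) - R @ mobile.mean(axis=0)
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def pair_min_distance(traj: Trajectory, sel_a: Selection, sel_b: Selection,
                      frame: int, use_box: bool = False) -> float:
    """Minimum heavy-atom distance between two disjoint selections.

    Hydrogens are excluded.  With ``use_box`` the per-frame orthorhombic box
    applies the minimum-image convention.
    """
    top = traj.topology
    ia = sel_a.resolve(top)
    ib = sel_b.resolve(top)
    if np.intersect1d(ia, ib).size:
        raise SelectionError("selections overlap")
    heavy = top.heavy_mask()
    ia = ia[heavy[ia]]
    ib = ib[heavy[ib]]
    if ia.size == 0 or ib.size == 0:
        raise SelectionError("no heavy atoms in one of the selections")
    xyz = traj.frame(frame)
    return min_distance_between(xyz[ia], xyz[ib],
                                traj.box[frame] if (use_box and traj.box is not None) else None)


def min_distance_between(a: np.ndarray, b: np.ndarray,
                         box: Optional[np.ndarray] = None) -> float:
    """Minimum pairwise distance between two coordinate sets (optionally
    minimum-image for an orthorhombic box)."""
    if box is None:
        return float(cdist(a, b).min())
    d = np.abs(a[:, None, :] - b[None, :, :])
    d -= box[None, None, :] * np.round(d / box[None, None, :])
    return float(np.sqrt((d ** 2).sum(axis=2)).min())
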
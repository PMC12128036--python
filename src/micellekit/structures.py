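"""Data model for coarse-grained frames and topologies, GRO I/O, and periodic geometry.

Internal length unit is the angstrom throughout; GRO files (nm) are converted
at the boundary.  Boxes are orthorhombic: the systems analysed here are cubic
or rectangular simulation cells, and triclinic input is rejected explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    GroParseError,
    MappingError,
    UnsupportedFormatError,
)

NM_TO_ANGSTROM = 10.0

#: Default (mass / amu, sigma_LJ / angstrom) per Martini 3 bead size class:
#: regular (R, 4 heavy atoms), small (S, 3) and tiny (T, 2).  Editable via
#: explicit BeadSpec fields; the table only supplies defaults.
BEAD_SIZE_TABLE: dict[str, tuple[float, float]] = {
    "R": (72.0, 4.70),
    "S": (54.0, 4.10),
    "T": (36.0, 3.40),
}

BEAD_ROLES = ("head", "tail", "other")


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic cell with edge lengths in angstrom."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(f"box lengths must be positive, got {self.lengths}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def volume(self) -> float:
        return float(self.lx * self.ly * self.lz)


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead: a name, a Martini size class and a role.

    ``mass`` (amu) and ``sigma`` (angstrom, the LJ zero-crossing distance)
    default to the size-class table when not given explicitly.
    """

    name: str
    size_class: str
    role: str = "other"
    mass: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.size_class not in BEAD_SIZE_TABLE:
            raise ValueError(
                f"unknown size class {self.size_class!r}; expected one of "
                f"{sorted(BEAD_SIZE_TABLE)}"
            )
        if self.role not in BEAD_ROLES:
            raise ValueError(f"unknown bead role {self.role!r}")
        default_mass, default_sigma = BEAD_SIZE_TABLE[self.size_class]
        if self.mass is None:
            object.__setattr__(self, "mass", default_mass)
        if self.sigma is None:
            object.__setattr__(self, "sigma", default_sigma)
        if not self.mass > 0:
            raise ValueError("bead mass must be positive")
        if not self.sigma > 0:
            raise ValueError("bead sigma must be positive")


@dataclass(frozen=True)
class MoleculeTopology:
    """Ordered bead list for one molecular species."""

    name: str
    beads: tuple[BeadSpec, ...]
    is_surfactant: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "beads", tuple(self.beads))
        if len(self.beads) == 0:
            raise ValueError("topology must contain at least one bead")
        if self.is_surfactant:
            roles = {b.role for b in self.beads}
            if "head" not in roles or "tail" not in roles:
                raise ConfigurationError(
                    f"surfactant species {self.name!r} needs at least one head "
                    "and one tail bead"
                )

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads], dtype=float)

    @property
    def head_indices(self) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.beads) if b.role == "head"], dtype=int)

    @property
    def tail_indices(self) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.beads) if b.role == "tail"], dtype=int)

    def smallest_tail_sigma(self) -> float:
        """sigma_LJ of the smallest tail bead — the length entering r_cut."""
        tails = [b.sigma for b in self.beads if b.role == "tail"]
        if not tails:
            raise ConfigurationError(f"species {self.name!r} has no tail beads")
        return float(min(tails))


@dataclass
class Frame:
    """Bead coordinates for one time point plus the molecule bookkeeping.

    ``mol_index`` assigns every bead to a molecule (contiguous, ascending ids
    starting at 0); ``species`` labels each molecule; ``topologies`` maps
    species labels to their bead topologies (may be empty for raw GRO input).
    """

    time: float
    box: Box
    coordinates: np.ndarray
    mol_index: np.ndarray
    species: np.ndarray
    topologies: dict[str, MoleculeTopology] = field(default_factory=dict)
    bead_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.mol_index = np.asarray(self.mol_index, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        if self.coordinates.shape[0] != self.mol_index.shape[0]:
            raise ValueError("one molecule index required per bead")
        if self.mol_index.size:
            d = np.diff(self.mol_index)
            if self.mol_index[0] != 0 or np.any(d < 0) or np.any(d > 1):
                raise ValueError("mol_index must be contiguous ascending from 0")
            if self.mol_index[-1] + 1 != self.species.shape[0]:
                raise ValueError("species must label every molecule exactly once")

    @property
    def n_beads(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def n_molecules(self) -> int:
        return int(self.species.shape[0])

    def molecule_slices(self) -> list[slice]:
        starts = np.searchsorted(self.mol_index, np.arange(self.n_molecules))
        ends = np.append(starts[1:], self.n_beads)
        return [slice(int(s), int(e)) for s, e in zip(starts, ends)]

    def topology_of(self, mol: int) -> MoleculeTopology:
        label = str(self.species[mol])
        try:
            return self.topologies[label]
        except KeyError:
            raise ConfigurationError(f"no topology declared for species {label!r}")

    def validate_against_topologies(self) -> None:
        for mol, sl in enumerate(self.molecule_slices()):
            topo = self.topology_of(mol)
            got = sl.stop - sl.start
            if got != topo.n_beads:
                raise ConfigurationError(
                    f"molecule {mol} ({self.species[mol]}) has {got} beads, "
                    f"topology declares {topo.n_beads}"
                )

    def surfactant_molecules(self) -> np.ndarray:
        """Indices of molecules whose species is a declared surfactant."""
        flags = np.array(
            [self.topologies.get(str(s)) is not None and self.topologies[str(s)].is_surfactant
             for s in self.species],
            dtype=bool,
        )
        return np.flatnonzero(flags)

    def tail_beads(self) -> tuple[np.ndarray, np.ndarray]:
        """(global bead indices, owning molecule index) of all surfactant tail beads."""
        idx: list[int] = []
        owner: list[int] = []
        for mol, sl in zip(range(self.n_molecules), self.molecule_slices()):
            topo = self.topologies.get(str(self.species[mol]))
            if topo is None or not topo.is_surfactant:
                continue
            tails = topo.tail_indices
            if tails.size == 0:
                raise ConfigurationError(
                    f"surfactant species {self.species[mol]!r} has no tail beads"
                )
            idx.extend(range(sl.start, sl.stop)[t] for t in tails)
            owner.extend([mol] * tails.size)
        return np.array(idx, dtype=int), np.array(owner, dtype=int)


@dataclass
class Trajectory:
    """Ordered frames sharing one set of topologies; times strictly increasing (ns)."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(p, q, box: Box) -> np.ndarray:
    """Minimum-image displacement q - p; each component in [-L/2, L/2)."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    L = box.lengths
    return d - L * np.floor(d / L + 0.5)


def wrap_into_box(coords, box: Box) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    c = np.asarray(coords, dtype=float)
    L = box.lengths
    wrapped = np.mod(c, L)
    # np.mod can return exactly L for tiny negative inputs; fold those back
    return np.where(wrapped >= L, wrapped - L, wrapped)


def map_atomistic_to_cg(atom_coords, mapping: Sequence[Iterable[int]] | Mapping[str, Iterable[int]]) -> np.ndarray:
    """Center-of-geometry mapping of atomistic coordinates onto CG beads.

    Each bead's coordinate is the unweighted mean of its constituent atoms'
    coordinates.  ``mapping`` is an ordered collection of atom-index sets
    (dict values are used in insertion order).
    """
    coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
    if isinstance(mapping, Mapping):
        groups = list(mapping.values())
    else:
        groups = list(mapping)
    out = np.empty((len(groups), 3), dtype=float)
    for b, grp in enumerate(groups):
        idx = np.asarray(list(grp), dtype=int)
        if idx.size == 0:
            raise MappingError(f"bead {b} maps to an empty atom set")
        if idx.min() < 0 or idx.max() >= coords.shape[0]:
            raise IndexError(
                f"bead {b} references atom index outside [0, {coords.shape[0]})"
            )
        out[b] = coords[idx].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# GRO reading / writing
# ---------------------------------------------------------------------------

def read_gro(path, topologies: dict[str, MoleculeTopology] | None = None,
             time: float = 0.0) -> Frame:
    """Read a GROMACS GRO coordinate file into a Frame (nm converted to angstrom).

    Molecule grouping is inferred from residue numbers; residue names become
    species labels.  Only orthorhombic boxes are supported.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GroParseError(f"{path}: file too short to be a GRO file")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise GroParseError(f"{path}, line 2: expected the atom count, got {lines[1]!r}")
    if len(lines) < n_atoms + 3:
        raise GroParseError(
            f"{path}: truncated atom block — header declares {n_atoms} atoms but "
            f"only {max(0, len(lines) - 3)} atom lines precede the box line"
        )

    coords = np.empty((n_atoms, 3), dtype=float)
    resids = np.empty(n_atoms, dtype=int)
    resnames: list[str] = []
    names: list[str] = []
    for i in range(n_atoms):
        ln = lines[2 + i]
        lineno = 3 + i
        if len(ln) < 44:
            raise GroParseError(
                f"{path}, line {lineno}: atom line shorter than the fixed-column "
                f"minimum of 44 characters"
            )
        try:
            resids[i] = int(ln[0:5])
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            coords[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except ValueError as exc:
            raise GroParseError(f"{path}, line {lineno}: malformed fixed-width field ({exc})")

    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise GroParseError(f"{path}, line {3 + n_atoms}: missing or malformed box line")
    try:
        box_vals = [float(x) for x in box_fields]
    except ValueError:
        raise GroParseError(f"{path}, line {3 + n_atoms}: non-numeric box entry")
    if len(box_vals) > 3 and any(abs(v) > 0 for v in box_vals[3:]):
        raise UnsupportedFormatError(
            f"{path}: triclinic box detected; only orthorhombic cells are supported"
        )
    box = Box(*(v * NM_TO_ANGSTROM for v in box_vals[:3]))

    # residue number changes delimit molecules (GRO resids wrap at 100000)
    mol_index = np.zeros(n_atoms, dtype=int)
    species: list[str] = []
    current = -1
    prev = None
    for i in range(n_atoms):
        if prev is None or resids[i] != prev:
            current += 1
            species.append(resnames[i])
            prev = resids[i]
        mol_index[i] = current

    return Frame(
        time=time,
        box=box,
        coordinates=coords * NM_TO_ANGSTROM,
        mol_index=mol_index,
        species=np.array(species, dtype=object),
        topologies=topologies or {},
        bead_names=np.array(names, dtype=object),
    )


def write_gro(frame: Frame, path, title: str = "micellekit frame") -> None:
    """Write a Frame to GRO (angstrom converted to nm, fixed columns)."""
    path = Path(path)
    lines = [title, f"{frame.n_beads:5d}"]
    names = frame.bead_names
    coords_nm = frame.coordinates / NM_TO_ANGSTROM
    for i in range(frame.n_beads):
        mol = int(frame.mol_index[i])
        resname = str(frame.species[mol])[:5]
        name = str(names[i]) if names is not None else "BEAD"
        if len(name) > 5:
            warnings.warn(f"bead name {name!r} truncated to 5 characters in GRO output")
            name = name[:5]
        resid = (mol + 1) % 100000
        atomid = (i + 1) % 100000
        x, y, z = coords_nm[i]
        lines.append(f"{resid:5d}{resname:<5s}{name:>5s}{atomid:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    bx, by, bz = frame.box.lengths / NM_TO_ANGSTROM
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# columnar trajectory fixture format (self-describing JSON)
# ---------------------------------------------------------------------------

def _topology_to_dict(t: MoleculeTopology) -> dict:
    return {
        "name": t.name,
        "is_surfactant": t.is_surfactant,
        "beads": [
            {"name": b.name, "size_class": b.size_class, "role": b.role,
             "mass": b.mass, "sigma": b.sigma}
            for b in t.beads
        ],
    }


def _topology_from_dict(d: dict) -> MoleculeTopology:
    return MoleculeTopology(
        name=d["name"],
        beads=tuple(BeadSpec(**b) for b in d["beads"]),
        is_surfactant=bool(d.get("is_surfactant", True)),
    )


def write_trajectory_json(traj: Trajectory, path) -> None:
    """Serialize a trajectory (times in ns, coordinates in angstrom) to JSON."""
    topos: dict[str, MoleculeTopology] = {}
    for f in traj.frames:
        topos.update(f.topologies)
    doc = {
        "format": "micellekit-trajectory",
        "version": 1,
        "units": {"length": "angstrom", "time": "ns"},
        "topologies": {k: _topology_to_dict(v) for k, v in topos.items()},
        "frames": [
            {
                "time": f.time,
                "box": list(f.box.lengths),
                "coordinates": f.coordinates.tolist(),
                "mol_index": f.mol_index.tolist(),
                "species": [str(s) for s in f.species],
            }
            for f in traj.frames
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_trajectory_json(path) -> Trajectory:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "micellekit-trajectory":
        raise UnsupportedFormatError(f"{path}: not a micellekit trajectory container")
    topos = {k: _topology_from_dict(v) for k, v in doc.get("topologies", {}).items()}
    frames = [
        Frame(
            time=float(fd["time"]),
            box=Box(*fd["box"]),
            coordinates=np.asarray(fd["coordinates"], dtype=float),
            mol_index=np.asarray(fd["mol_index"], dtype=int),
            species=np.asarray(fd["species"], dtype=object),
            topologies=topos,
        )
        for fd in doc["frames"]
    ]
    return Trajectory(frames=frames)
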
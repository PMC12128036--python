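"""Aggregate detection by single-linkage clustering of tail beads under PBC.

Two surfactants belong to the same aggregate when any pair of their tail-group
beads lies within ``r_cut`` (minimum-image distance); aggregates are the
connected components of this contact relation.  The cutoff is 5/4 of the
Lennard-Jones sigma of the *smallest* tail bead, which respects the different
equilibrium tail spacings of models at different coarse-graining resolutions.

The partition always covers every surfactant (monomers are singleton
clusters); the minimum aggregation number only filters *reporting*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .structures import Box, Frame, wrap_into_box

RCUT_PREFACTOR = 5.0 / 4.0


def compute_rcut(sigma: float) -> float:
    """Clustering cutoff (5/4)·sigma_LJ in angstrom.

    With the Martini 3 size-class sigmas this gives 5.875 A for a regular
    (R) tail bead and 4.250 A for a tiny (T) tail bead.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return RCUT_PREFACTOR * float(sigma)


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of the tail-bead contact clustering."""

    r_cut: float
    min_aggregation_number: int = 5

    def __post_init__(self) -> None:
        if not self.r_cut > 0:
            raise ValueError("r_cut must be positive")
        if self.min_aggregation_number < 1:
            raise ValueError("min_aggregation_number must be >= 1")

    @classmethod
    def for_frame(cls, frame: Frame, min_aggregation_number: int = 5) -> "ClusterParams":
        """Derive r_cut from the smallest tail-bead sigma present in the frame."""
        sigmas = [
            t.smallest_tail_sigma()
            for t in frame.topologies.values()
            if t.is_surfactant
        ]
        if not sigmas:
            raise ConfigurationError("frame declares no surfactant topologies")
        return cls(r_cut=compute_rcut(min(sigmas)),
                   min_aggregation_number=min_aggregation_number)


@dataclass
class Aggregate:
    """One detected cluster of whole surfactant molecules.

    ``coordinates`` are the unwrapped bead coordinates of all member
    molecules (angstrom), in the order given by ``bead_indices`` into the
    parent frame.  ``percolating`` is set when the cluster connects to its
    own periodic image so no consistent unwrapping exists.
    """

    molecule_ids: np.ndarray
    time: float
    coordinates: np.ndarray
    bead_indices: np.ndarray
    percolating: bool
    aggregate_id: int = -1
    species: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    @property
    def n(self) -> int:
        """Aggregation number: the number of member surfactant molecules."""
        return int(self.molecule_ids.size)


def _whole_molecules(frame: Frame) -> np.ndarray:
    """Coordinates with each molecule made whole around its first bead."""
    coords = frame.coordinates.copy()
    L = frame.box.lengths
    for sl in frame.molecule_slices():
        ref = coords[sl.start]
        d = coords[sl] - ref
        coords[sl] = ref + (d - L * np.floor(d / L + 0.5))
    return coords


def _tail_contact_edges(frame: Frame, params: ClusterParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(tail bead indices, owning molecules, contact pairs into the tail list)."""
    tails, owners = frame.tail_beads()
    if tails.size == 0:
        raise ConfigurationError("no surfactant tail beads in frame")
    pts = wrap_into_box(frame.coordinates[tails], frame.box)
    if 2.0 * params.r_cut >= frame.box.lengths.min():
        raise ConfigurationError(
            "r_cut too large relative to the box for minimum-image clustering"
        )
    tree = cKDTree(pts, boxsize=frame.box.lengths)
    pairs = tree.query_pairs(params.r_cut, output_type="ndarray")
    return tails, owners, pairs


def find_aggregates(frame: Frame, params: ClusterParams | None = None) -> list[Aggregate]:
    """Partition all surfactant molecules of a frame into aggregates.

    Returns one Aggregate per connected component (including singleton
    monomers), sorted by descending aggregation number, with unwrapped
    coordinates and percolation flags.
    """
    if params is None:
        params = ClusterParams.for_frame(frame)
    surf = frame.surfactant_molecules()
    if surf.size == 0:
        raise ConfigurationError("frame contains no surfactant molecules")

    tails, owners, pairs = _tail_contact_edges(frame, params)

    # connected components on the molecule graph
    mol_pos = {m: i for i, m in enumerate(surf)}
    n = surf.size
    if pairs.size:
        i = np.array([mol_pos[owners[a]] for a in pairs[:, 0]], dtype=int)
        j = np.array([mol_pos[owners[b]] for b in pairs[:, 1]], dtype=int)
        keep = i != j
        g = sparse.coo_matrix(
            (np.ones(keep.sum()), (i[keep], j[keep])), shape=(n, n)
        )
    else:
        g = sparse.coo_matrix((n, n))
    n_comp, labels = connected_components(g, directed=False)

    whole = _whole_molecules(frame)
    slices = frame.molecule_slices()
    out: list[Aggregate] = []
    order = sorted(range(n_comp), key=lambda c: (-(labels == c).sum(), int(np.min(surf[labels == c]))))
    for new_id, comp in enumerate(order):
        members = surf[labels == comp]
        coords, beads, percolating = _unwrap_members(
            frame, whole, slices, members, owners, tails, pairs
        )
        out.append(
            Aggregate(
                molecule_ids=members,
                time=frame.time,
                coordinates=coords,
                bead_indices=beads,
                percolating=percolating,
                aggregate_id=new_id,
                species=frame.species[members],
            )
        )
    return out


def _unwrap_members(frame, whole, slices, members, owners, tails,
                    pairs) -> tuple[np.ndarray, np.ndarray, bool]:
    """BFS over contact edges assigning one lattice offset per molecule."""
    L = frame.box.lengths
    member_set = {int(m): k for k, m in enumerate(members)}
    # adjacency among member molecules with the raw edge displacement
    adj: dict[int, list[tuple[int, np.ndarray]]] = {int(m): [] for m in members}
    for a, b in pairs:
        ma, mb = int(owners[a]), int(owners[b])
        if ma == mb or ma not in member_set or mb not in member_set:
            continue
        d = whole[tails[b]] - whole[tails[a]]
        shift = -L * np.floor(d / L + 0.5)  # image shift applied to mb
        adj[ma].append((mb, shift))
        adj[mb].append((ma, -shift))

    offsets: dict[int, np.ndarray] = {}
    percolating = False
    root = int(members[0])
    offsets[root] = np.zeros(3)
    queue = [root]
    while queue:
        cur = queue.pop()
        for nb, shift in adj[cur]:
            prop = offsets[cur] + shift
            if nb in offsets:
                if not np.allclose(offsets[nb], prop, atol=1e-6):
                    percolating = True
            else:
                offsets[nb] = prop
                queue.append(nb)

    beads = np.concatenate([np.arange(slices[m].start, slices[m].stop) for m in members])
    coords = np.concatenate(
        [whole[slices[m]] + offsets.get(int(m), np.zeros(3)) for m in members]
    )
    return coords, beads, percolating


def unwrap_aggregate(aggregate: Aggregate, frame: Frame,
                     params: ClusterParams | None = None) -> tuple[np.ndarray, bool]:
    """Recompute unwrapped coordinates and the percolation flag for one aggregate.

    Provided for use on aggregates constructed externally; `find_aggregates`
    already returns unwrapped members.
    """
    if params is None:
        params = ClusterParams.for_frame(frame)
    tails, owners, pairs = _tail_contact_edges(frame, params)
    whole = _whole_molecules(frame)
    slices = frame.molecule_slices()
    coords, _, percolating = _unwrap_members(
        frame, whole, slices, aggregate.molecule_ids, owners, tails, pairs
    )
    return coords, percolating


def normalized_aggregation_number(aggregate: Aggregate, frame: Frame) -> float:
    """Fraction of all surfactants in the frame belonging to this aggregate."""
    total = frame.surfactant_molecules().size
    if total == 0:
        raise ConfigurationError("frame contains no surfactant molecules")
    return aggregate.n / total


def aggregates_table(aggregates: list[Aggregate], frame: Frame) -> pd.DataFrame:
    """Per-frame aggregate table: time, id, N, normalized N, percolation flag."""
    total = max(1, frame.surfactant_molecules().size)
    return pd.DataFrame(
        {
            "time": [a.time for a in aggregates],
            "aggregate_id": [a.aggregate_id for a in aggregates],
            "N": [a.n for a in aggregates],
            "normalized_N": [a.n / total for a in aggregates],
            "percolating": [a.percolating for a in aggregates],
        }
    )
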
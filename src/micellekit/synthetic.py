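"""Synthetic self-assembled structures with known ground truth.

Generates frames emulating the aggregate morphologies of dilute surfactant
systems — ellipsoidal micelles, bilayer vesicles, disc-like bicelles,
box-percolating lamellae and dispersed monomers — so that every analysis
stage (clustering, shape, surface, convergence) can be validated without MD
trajectories.  All generators are deterministic given their seed.

Surfactants are placed head-first on the structure's outer surface with the
tail chain running inward along the local normal.  Head anchor points come
from a Fibonacci lattice (thinned by seeded rejection where area-uniformity
on a non-spherical surface requires it): a low-discrepancy layout is needed
because the eccentricity of a finite random sample of a sphere is O(n^-1/4)
and would swamp the spherical/ellipsoidal distinction at realistic
aggregation numbers.

Opposing leaflets of bilayer structures interdigitate: chains span 3/4 of
the bilayer thickness, the strongly interdigitated regime characteristic of
double-tailed surfactants like AOT.  This doubles the bead density in the
bilayer core relative to a single leaflet, which places the rho_max/3
Willard-Chandler isosurface at the head planes — i.e. the generator's
declared thickness is the head-to-head distance the surface method measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import PlacementError
from .structures import BeadSpec, Box, Frame, MoleculeTopology, wrap_into_box

#: AOT-like 7-bead surfactant at mixed resolution: a sulfonate head bead,
#: two ester linker beads, and two 2-bead ethylhexyl tails.
DEFAULT_TOPOLOGY = MoleculeTopology(
    name="AOT",
    beads=(
        BeadSpec("SO3", "R", "head"),
        BeadSpec("GLA", "S", "head"),
        BeadSpec("GLB", "S", "head"),
        BeadSpec("C1A", "S", "tail"),
        BeadSpec("C2A", "T", "tail"),
        BeadSpec("C1B", "S", "tail"),
        BeadSpec("C2B", "T", "tail"),
    ),
)

#: Default area per headgroup used to pick surfactant counts (A^2).
DEFAULT_AREA_PER_HEAD = 55.0

#: Fraction of a bilayer thickness spanned by one leaflet's chain (see module
#: docstring).
INTERDIGITATION = 0.75


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of one synthetic structure (CLI surface)."""

    kind: str
    seed: int = 0
    noise: float = 0.0
    params: dict = dc_field(default_factory=dict)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci / golden-spiral lattice)."""
    if n < 1:
        raise ValueError("need at least one direction")
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Thomsen's approximation to the ellipsoid surface area (<1.1% error)."""
    p = 1.6075
    s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return float(4.0 * np.pi * s ** (1.0 / p))


#: Lateral offset (angstrom) of each tail branch at the chain tip.  AOT's two
#: ethylhexyl tails splay into a wedge; the splay also provides the lateral
#: tail-tail contacts that make neighbouring molecules cluster.
TAIL_SPLAY = 5.0


def _chains(anchors: np.ndarray, inward: np.ndarray, depth,
            topology: MoleculeTopology, noise: float,
            rng: np.random.Generator, splay: float = TAIL_SPLAY,
            lateral: np.ndarray | None = None) -> np.ndarray:
    """Bead coordinates for surfactants anchored head-out along inward normals.

    Beads are laid out along the inward direction at evenly spaced depths up
    to ``depth`` (scalar or per-molecule array).  Tail beads additionally
    splay into two branches with opposite offsets along a lateral direction
    growing linearly with depth.  ``lateral`` may be given per molecule
    (planar structures use a fixed direction so the bead layers stay
    void-free lattices); by default an equidistributed azimuth sequence is
    used — independent random azimuths would add n^{-1/2} anisotropy noise
    that dominates the eccentricity of near-spherical shells.
    """
    n_mol = anchors.shape[0]
    nb = topology.n_beads
    depth = np.broadcast_to(np.asarray(depth, dtype=float), (n_mol,))
    frac = np.linspace(0.0, 1.0, nb)
    coords = (anchors[:, None, :]
              + inward[:, None, :] * (depth[:, None] * frac)[:, :, None])

    tails = topology.tail_indices
    if tails.size and splay > 0:
        if lateral is None:
            ref = np.where(np.abs(inward[:, [2]]) < 0.9,
                           np.tile([0.0, 0.0, 1.0], (n_mol, 1)),
                           np.tile([1.0, 0.0, 0.0], (n_mol, 1)))
            u = np.cross(inward, ref)
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            v = np.cross(inward, u)
            az = 2.0 * np.pi * ((np.sqrt(2.0) * np.arange(n_mol)
                                 + rng.uniform()) % 1.0)
            lateral = u * np.cos(az)[:, None] + v * np.sin(az)[:, None]
        half = tails.size // 2 if tails.size > 1 else 1
        for rank, t in enumerate(tails):
            sign = 1.0 if rank < half else -1.0
            coords[:, t, :] += sign * splay * frac[t] * lateral
    if noise > 0:
        coords = coords + rng.normal(0.0, noise, size=coords.shape)
    return coords.reshape(-1, 3)


def _frame_from_chains(coords: np.ndarray, n_mol: int, box: Box,
                       topology: MoleculeTopology, time: float = 0.0) -> Frame:
    nb = topology.n_beads
    return Frame(
        time=time,
        box=box,
        coordinates=wrap_into_box(coords, box),
        mol_index=np.repeat(np.arange(n_mol), nb),
        species=np.full(n_mol, topology.name, dtype=object),
        topologies={topology.name: topology},
    )


def _ellipsoid_anchors(a: float, b: float, c: float, n: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """n area-quasi-uniform points on an ellipsoid surface + inward normals.

    Fibonacci directions are mapped onto the surface and thinned by rejection
    with the area-element weight sqrt((bc u_x)^2 + (ac u_y)^2 + (ab u_z)^2);
    for a sphere the weight is constant and the exact lattice is kept.
    """
    # Low-discrepancy area-quasi-uniform layout: latitudes follow the inverse
    # CDF of the area-element marginal (azimuth-averaged), azimuths advance by
    # the golden angle with a seeded random phase.  Independent rejection
    # sampling would blur the near-degenerate axis pairs of spheres and
    # oblates (eigenvalue noise ~n^{-1/2} maps to eccentricities ~n^{-1/4}),
    # so the stratified construction is essential for ground-truth recovery.
    zg = np.linspace(-1.0, 1.0, 2049)
    phig = np.linspace(0.0, 2.0 * np.pi, 257)[:-1]
    rg = np.sqrt(np.maximum(0.0, 1.0 - zg ** 2))
    ux = rg[:, None] * np.cos(phig)
    uy = rg[:, None] * np.sin(phig)
    w = np.sqrt((b * c * ux) ** 2 + (a * c * uy) ** 2
                + (a * b * zg[:, None]) ** 2).mean(axis=1)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(zg))])
    cdf /= cdf[-1]
    t = (np.arange(n) + 0.5) / n
    z = np.interp(t, cdf, zg)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n) + 2.0 * np.pi * rng.uniform()
    r = np.sqrt(np.maximum(0.0, 1.0 - z ** 2))
    u = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts = u * np.array([a, b, c])
    normals = u / np.array([a, b, c])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return pts, -normals


def make_ellipsoid_micelle(a: float, b: float, c: float, n: int | None = None,
                           box: Box | None = None, noise: float = 0.0,
                           seed: int = 0,
                           topology: MoleculeTopology = DEFAULT_TOPOLOGY,
                           area_per_head: float = DEFAULT_AREA_PER_HEAD,
                           chain_depth: float | None = None
                           ) -> tuple[Frame, dict]:
    """Ellipsoidal micelle with semiaxes a >= b >= c (angstrom).

    Heads sit quasi-uniformly on the ellipsoid surface; tails run inward
    along the surface normal.  Ground truth records the semiaxes, analytic
    CPE, Thomsen surface area and ellipsoid volume.
    """
    if not (a >= b >= c > 0):
        raise ValueError("semiaxes must satisfy a >= b >= c > 0")
    rng = np.random.default_rng(seed)
    area = ellipsoid_area(a, b, c)
    if n is None:
        n = max(5, int(round(area / area_per_head)))
    if n * area_per_head < 0.5 * area:
        import warnings
        warnings.warn(
            f"{n} surfactants cannot cover a {area:.0f} A^2 surface at "
            f"{area_per_head} A^2 each; the shell will be sparse"
        )
    if box is None:
        side = 2.0 * a + 80.0
        box = Box(side, side, side)
    anchors, _ = _ellipsoid_anchors(a, b, c, n, rng)
    # tails run toward the aggregate center (a micelle's core is tail-filled),
    # reaching a fixed fraction of the way in
    dist = np.linalg.norm(anchors, axis=1)
    inward = -anchors / dist[:, None]
    if chain_depth is not None:
        depth = np.full(n, float(chain_depth))
    else:
        depth = INTERDIGITATION * dist
    center = 0.5 * box.lengths
    coords = _chains(anchors + center, inward, depth, topology, noise, rng)
    frame = _frame_from_chains(coords, n, box, topology)
    e_ab = float(np.sqrt(1.0 - (b / a) ** 2))
    e_ac = float(np.sqrt(1.0 - (c / a) ** 2))
    truth = {
        "kind": "ellipsoid_micelle", "a": a, "b": b, "c": c, "n": n,
        "e_ab": e_ab, "e_ac": e_ac, "area": area,
        "volume": 4.0 / 3.0 * np.pi * a * b * c,
        "center": center.tolist(),
    }
    return frame, truth


def make_vesicle(r_outer: float = 80.0, shell_thickness: float = 20.0,
                 n: int | None = None, box: Box | None = None,
                 noise: float = 0.0, seed: int = 0,
                 topology: MoleculeTopology = DEFAULT_TOPOLOGY,
                 area_per_head: float = DEFAULT_AREA_PER_HEAD
                 ) -> tuple[Frame, dict]:
    """Closed bilayer vesicle: outer leaflet heads out, inner leaflet heads in.

    Ground truth: outer/inner radii, shell (material) volume
    4/3 pi (R_out^3 - R_in^3) and outer area 4 pi R_out^2.
    """
    if not r_outer > shell_thickness:
        raise ValueError("outer radius must exceed the shell thickness")
    rng = np.random.default_rng(seed)
    r_inner = r_outer - shell_thickness
    area_out = 4.0 * np.pi * r_outer ** 2
    area_in = 4.0 * np.pi * r_inner ** 2
    if n is None:
        n = int(round((area_out + area_in) / area_per_head))
    n_out = max(5, int(round(n * area_out / (area_out + area_in))))
    n_in = max(5, n - n_out)
    if box is None:
        side = 2.0 * r_outer + 80.0
        box = Box(side, side, side)
    center = 0.5 * box.lengths
    depth = INTERDIGITATION * shell_thickness

    u_out = fibonacci_sphere(n_out)
    u_in = fibonacci_sphere(n_in)
    coords_out = _chains(center + r_outer * u_out, -u_out, depth, topology, noise, rng)
    coords_in = _chains(center + r_inner * u_in, u_in, depth, topology, noise, rng)
    coords = np.concatenate([coords_out, coords_in])
    frame = _frame_from_chains(coords, n_out + n_in, box, topology)
    truth = {
        "kind": "vesicle", "r_outer": r_outer, "r_inner": r_inner,
        "n": n_out + n_in, "n_outer": n_out, "n_inner": n_in,
        "shell_volume": 4.0 / 3.0 * np.pi * (r_outer ** 3 - r_inner ** 3),
        "outer_area": area_out, "inner_area": area_in,
        "center": center.tolist(),
    }
    return frame, truth


def make_bicelle(disc_radius: float = 60.0, thickness: float = 20.0,
                 n: int | None = None, box: Box | None = None,
                 noise: float = 0.0, seed: int = 0,
                 topology: MoleculeTopology = DEFAULT_TOPOLOGY,
                 area_per_head: float = DEFAULT_AREA_PER_HEAD
                 ) -> tuple[Frame, dict]:
    """Disc-like bicelle: a flat circular bilayer patch with a rounded rim."""
    rng = np.random.default_rng(seed)
    r = disc_radius
    t = thickness
    area_faces = 2.0 * np.pi * r ** 2
    area_rim = np.pi * t * np.pi * r  # half-torus outer surface, roughly
    if n is None:
        n = int(round((area_faces + area_rim) / area_per_head))
    n_face = max(5, int(round(0.5 * n * area_faces / (area_faces + area_rim))))
    n_rim = max(5, n - 2 * n_face)
    if box is None:
        side = 2.0 * (r + t) + 80.0
        box = Box(side, side, side)
    center = 0.5 * box.lengths
    depth = INTERDIGITATION * t

    # sunflower layout on each face
    k = np.arange(n_face, dtype=float) + 0.5
    rad = r * np.sqrt(k / n_face)
    ang = np.pi * (3.0 - np.sqrt(5.0)) * k
    face_xy = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    top = np.column_stack([face_xy, np.full(n_face, 0.5 * t)])
    bottom = np.column_stack([face_xy, np.full(n_face, -0.5 * t)])
    down = np.tile([0.0, 0.0, -1.0], (n_face, 1))
    up = -down

    # rim: golden-angle winding of the half-torus
    j = np.arange(n_rim, dtype=float)
    psi = 2.0 * np.pi * j / n_rim
    phi = np.pi * (j * (3.0 - np.sqrt(5.0)) % 2.0) - 0.5 * np.pi
    phi = np.clip(phi, -0.45 * np.pi, 0.45 * np.pi)
    rim_normal = np.column_stack([
        np.cos(phi) * np.cos(psi), np.cos(phi) * np.sin(psi), np.sin(phi)
    ])
    rim_anchor = np.column_stack([
        (r + 0.5 * t * np.cos(phi) - 0.5 * t) * np.cos(psi),
        (r + 0.5 * t * np.cos(phi) - 0.5 * t) * np.sin(psi),
        0.5 * t * np.sin(phi),
    ])

    anchors = np.concatenate([top, bottom, rim_anchor]) + center
    inward = np.concatenate([down, up, -rim_normal])
    coords = _chains(anchors, inward, depth, topology, noise, rng)
    n_total = 2 * n_face + n_rim
    frame = _frame_from_chains(coords, n_total, box, topology)
    truth = {
        "kind": "bicelle", "disc_radius": r, "thickness": t, "n": n_total,
        "face_area": np.pi * r ** 2, "center": center.tolist(),
    }
    return frame, truth


def make_lamella(lx: float = 100.0, ly: float = 100.0, lz: float = 60.0,
                 thickness: float = 20.0, n: int | None = None,
                 corrugation_amplitude: float = 0.0,
                 corrugation_periods: int = 1,
                 noise: float = 0.0, seed: int = 0,
                 topology: MoleculeTopology = DEFAULT_TOPOLOGY,
                 area_per_head: float = 50.0) -> tuple[Frame, dict]:
    """Box-percolating flat (optionally corrugated) bilayer in the xy-plane.

    Head planes sit at z0 +/- thickness/2 (plus a matched-phase sinusoidal
    corrugation along x); ground-truth area per headgroup is 2*Lx*Ly/N for
    the flat case.
    """
    if not thickness < lz:
        raise ValueError("bilayer thickness must be smaller than the box height")
    rng = np.random.default_rng(seed)
    box = Box(lx, ly, lz)
    if n is None:
        n = 2 * int(round(lx * ly / area_per_head))
    n_leaf = n // 2
    z0 = 0.5 * lz
    depth = INTERDIGITATION * thickness

    # near-square in-plane lattice per leaflet
    nx = max(1, int(round(np.sqrt(n_leaf * lx / ly))))
    ny = int(np.ceil(n_leaf / nx))
    gx, gy = np.meshgrid(
        (np.arange(nx) + 0.5) * lx / nx, (np.arange(ny) + 0.5) * ly / ny,
        indexing="ij",
    )
    xy = np.column_stack([gx.ravel(), gy.ravel()])[:n_leaf]
    # stagger the lower leaflet by half a cell along y: the interdigitated
    # tails of each leaflet fill the other's inter-row channels (the slab
    # core stays above the isovalue everywhere) and the two leaflets' mid-
    # plane beads come within tail-contact range, so the cluster percolates
    xy_lo = np.mod(xy + [0.0, 0.5 * ly / ny], [lx, ly])
    dz = corrugation_amplitude * np.sin(
        2.0 * np.pi * corrugation_periods * xy[:, 0] / lx
    )
    dz_lo = corrugation_amplitude * np.sin(
        2.0 * np.pi * corrugation_periods * xy_lo[:, 0] / lx
    )
    upper = np.column_stack([xy, z0 + 0.5 * thickness + dz])
    lower = np.column_stack([xy_lo, z0 - 0.5 * thickness + dz_lo])
    anchors = np.concatenate([upper, lower])
    inward = np.concatenate([
        np.tile([0.0, 0.0, -1.0], (n_leaf, 1)),
        np.tile([0.0, 0.0, 1.0], (n_leaf, 1)),
    ])
    # deterministic splay along +/-x: each bead depth layer remains a perfect
    # lattice (no density voids) and x-neighbour tail tips stay in contact
    lateral = np.tile([1.0, 0.0, 0.0], (2 * n_leaf, 1))
    coords = _chains(anchors, inward, depth, topology, noise, rng, lateral=lateral)
    frame = _frame_from_chains(coords, 2 * n_leaf, box, topology)
    truth = {
        "kind": "lamella", "thickness": thickness, "n": 2 * n_leaf,
        "area_per_headgroup": 2.0 * lx * ly / (2 * n_leaf),
        "z0": z0, "percolating": True,
        "corrugation_amplitude": corrugation_amplitude,
    }
    return frame, truth


def make_monomers(n: int, box: Box, seed: int = 0, noise: float = 0.0,
                  topology: MoleculeTopology = DEFAULT_TOPOLOGY,
                  min_separation: float = 30.0,
                  max_tries: int = 20000) -> tuple[Frame, dict]:
    """n dispersed monomeric surfactants with pairwise clearance."""
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} monomers with {min_separation} A "
                "clearance; box too small"
            )
        tries += 1
        cand = rng.random(3) * box.lengths
        ok = all(
            np.linalg.norm(_mi(cand - c, box)) > min_separation for c in centers
        )
        if ok:
            centers.append(cand)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    chain_len = 3.0 * (topology.n_beads - 1)
    coords = _chains(np.array(centers), dirs, chain_len, topology, noise, rng)
    frame = _frame_from_chains(coords, n, box, topology)
    return frame, {"kind": "monomers", "n": n}


def _mi(d: np.ndarray, box: Box) -> np.ndarray:
    L = box.lengths
    return d - L * np.floor(d / L + 0.5)


def make_dispersed_system(components: list[tuple[Frame, dict]], box: Box,
                          seed: int = 0, clearance: float = 15.0,
                          max_tries: int = 5000) -> tuple[Frame, dict]:
    """Union frame of several pre-built structures at non-overlapping centers.

    Each component is translated from the center of its own box to a random
    center such that center separations exceed the sum of component extents
    plus ``clearance``; the ground truth records the molecule-id partition.
    """
    if not components:
        raise ValueError("at least one component is required")
    rng = np.random.default_rng(seed)

    extents = []
    for frame, _ in components:
        rel = frame.coordinates - 0.5 * frame.box.lengths
        rel = _mi(rel, frame.box)
        extents.append(float(np.linalg.norm(rel, axis=1).max()))

    centers: list[np.ndarray] = []
    for i, ext in enumerate(extents):
        placed = False
        for _ in range(max_tries):
            cand = rng.random(3) * box.lengths
            if all(
                np.linalg.norm(_mi(cand - c, box)) > ext + extents[j] + clearance
                for j, c in enumerate(centers)
            ):
                centers.append(cand)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place component {i} (extent {ext:.1f} A) in the box"
            )

    all_coords = []
    all_mol = []
    all_species = []
    labels = []
    topologies: dict[str, MoleculeTopology] = {}
    mol_offset = 0
    for comp_id, ((frame, _), center) in enumerate(zip(components, centers)):
        rel = _mi(frame.coordinates - 0.5 * frame.box.lengths, frame.box)
        all_coords.append(rel + center)
        all_mol.append(frame.mol_index + mol_offset)
        all_species.extend(str(s) for s in frame.species)
        labels.extend([comp_id] * frame.n_molecules)
        topologies.update(frame.topologies)
        mol_offset += frame.n_molecules

    union = Frame(
        time=0.0,
        box=box,
        coordinates=wrap_into_box(np.concatenate(all_coords), box),
        mol_index=np.concatenate(all_mol),
        species=np.array(all_species, dtype=object),
        topologies=topologies,
    )
    truth = {
        "kind": "mixture",
        "labels": np.array(labels, dtype=int),
        "components": [gt for _, gt in components],
        "centers": [c.tolist() for c in centers],
    }
    return union, truth


def make_frame(spec: SyntheticSpec) -> tuple[Frame, dict]:
    """Dispatch a SyntheticSpec to the matching generator (CLI entry point)."""
    kinds = {
        "ellipsoid_micelle": make_ellipsoid_micelle,
        "vesicle": make_vesicle,
        "bicelle": make_bicelle,
        "lamella": make_lamella,
        "monomers": make_monomers,
    }
    if spec.kind not in kinds:
        raise ValueError(f"unknown structure kind {spec.kind!r}; "
                         f"expected one of {sorted(kinds)}")
    kwargs = dict(spec.params)
    if "box" in kwargs and not isinstance(kwargs["box"], Box):
        kwargs["box"] = Box(*kwargs["box"])
    return kinds[spec.kind](seed=spec.seed, noise=spec.noise, **kwargs)
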
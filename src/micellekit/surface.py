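"""Willard-Chandler instantaneous interfaces and derived surface metrics.

The interface of an aggregate is the level set rho = rho_max/3 of an
unnormalized Gaussian kernel density built from all of the aggregate's
surfactant beads (bandwidth h = 4 A, grid spacing 2 A).  Periodicity is
handled either by replicating the beads into a 3x3x3 supercell or by the
minimum-image convention; the level set is triangulated by marching cubes on
the periodically padded grid, stitched across the box seam, and split into
connected components.  Areas are triangle sums; enclosed volumes are signed
tetrahedron sums (divergence theorem) with face orientation following the
density gradient, so nested inner surfaces subtract the cavity they enclose
and the total is the *material* volume of the dense phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .errors import (
    DegenerateSurfaceError,
    GridResourceError,
    NoSurfaceError,
    NotABilayerError,
    OpenMeshError,
    PercolationError,
)
from .structures import Box, wrap_into_box


@dataclass(frozen=True)
class WCParams:
    """Parameters of the Willard-Chandler construction.

    bandwidth      Gaussian kernel standard deviation h (angstrom).
    spacing        target grid spacing (angstrom); the actual spacing divides
                   each box edge exactly.
    iso_fraction   isovalue as a fraction of the field maximum rho_max.
    truncation     kernel truncation radius in multiples of h.
    max_grid_cells guard against accidentally huge grids.
    """

    bandwidth: float = 4.0
    spacing: float = 2.0
    iso_fraction: float = 1.0 / 3.0
    truncation: float = 4.0
    max_grid_cells: int = 20_000_000

    def __post_init__(self) -> None:
        if not self.bandwidth > 0:
            raise ValueError("bandwidth must be positive")
        if not self.spacing > 0:
            raise ValueError("grid spacing must be positive")
        if not 0 < self.iso_fraction < 1:
            raise ValueError("iso_fraction must be in (0, 1)")
        if not self.truncation > 0:
            raise ValueError("truncation must be positive")


@dataclass
class DensityField:
    """Scalar density on a regular grid over the central box.

    ``values[i, j, k]`` is the density at node (i*sx, j*sy, k*sz); node
    counts are chosen so the grid tiles the box periodically.
    """

    values: np.ndarray
    box: Box
    spacings: np.ndarray
    mode: str

    @property
    def rho_max(self) -> float:
        return float(self.values.max())


@dataclass
class SurfaceMesh:
    """Stitched triangulated isosurface with per-component bookkeeping.

    Faces are oriented with outward normals (away from the dense phase).
    ``component_closed`` marks components in which every edge is shared by
    exactly two faces after periodic stitching; ``component_percolating``
    marks components that wind around the box, for which no embedded
    enclosed volume exists (their ``component_volume`` is NaN).
    """

    vertices: np.ndarray
    faces: np.ndarray
    box: Box
    vertex_component: np.ndarray
    face_component: np.ndarray
    component_area: np.ndarray
    component_volume: np.ndarray
    component_closed: np.ndarray
    component_percolating: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return int(self.component_area.size)

    @property
    def total_area(self) -> float:
        return float(self.component_area.sum())


# ---------------------------------------------------------------------------
# density field
# ---------------------------------------------------------------------------

def _grid_shape(box: Box, params: WCParams) -> tuple[np.ndarray, np.ndarray]:
    ns = np.maximum(2, np.rint(box.lengths / params.spacing).astype(int))
    if int(np.prod(ns)) > params.max_grid_cells:
        raise GridResourceError(
            f"grid of {np.prod(ns)} cells exceeds the cap of "
            f"{params.max_grid_cells}; use a coarser spacing"
        )
    return ns, box.lengths / ns


def _scatter_kernel(values: np.ndarray, pts: np.ndarray, ns: np.ndarray,
                    ss: np.ndarray, h: float, rc: float, periodic: bool) -> None:
    """Add a truncated Gaussian for each point onto the grid in place."""
    inv2h2 = 1.0 / (2.0 * h * h)
    rc2 = rc * rc
    for p in pts:
        lo = np.ceil((p - rc) / ss).astype(int)
        hi = np.floor((p + rc) / ss).astype(int)
        if not periodic:
            lo = np.maximum(lo, 0)
            hi = np.minimum(hi, ns - 1)
            if np.any(hi < lo):
                continue
        axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        deltas = [axes[d] * ss[d] - p[d] for d in range(3)]
        r2 = (deltas[0][:, None, None] ** 2
              + deltas[1][None, :, None] ** 2
              + deltas[2][None, None, :] ** 2)
        contrib = np.where(r2 <= rc2, np.exp(-r2 * inv2h2), 0.0)
        if periodic:
            ii = np.mod(axes[0], ns[0])
            jj = np.mod(axes[1], ns[1])
            kk = np.mod(axes[2], ns[2])
            np.add.at(
                values,
                (ii[:, None, None], jj[None, :, None], kk[None, None, :]),
                contrib,
            )
        else:
            values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += contrib


def gaussian_density_grid(points, box: Box, params: WCParams | None = None,
                          mode: str = "supercell") -> DensityField:
    """Unnormalized Gaussian KDE of bead positions on a periodic grid.

    ``mode="supercell"`` evaluates every bead through its 27 replicas in a
    3x3x3 supercell (replicas beyond the truncation radius of the box are
    skipped); ``mode="minimum_image"`` uses each bead's nearest periodic
    image.  The two agree for compact aggregates away from the boundary.
    """
    if params is None:
        params = WCParams()
    pts = wrap_into_box(np.asarray(points, dtype=float).reshape(-1, 3), box)
    if pts.shape[0] == 0:
        raise ValueError("at least one point is required")
    if mode not in ("supercell", "minimum_image"):
        raise ValueError(f"unknown density mode {mode!r}")

    ns, ss = _grid_shape(box, params)
    values = np.zeros(tuple(ns))
    h = params.bandwidth
    rc = params.truncation * h
    L = box.lengths

    if mode == "supercell":
        for shift in product((-1.0, 0.0, 1.0), repeat=3):
            sp = pts + np.array(shift) * L
            inside = np.all((sp > -rc) & (sp < L + rc), axis=1)
            if np.any(inside):
                _scatter_kernel(values, sp[inside], ns, ss, h, rc, periodic=False)
    else:
        if 2.0 * rc >= L.min():
            warnings.warn(
                "kernel truncation radius exceeds half the box; minimum-image "
                "density is ill-defined at this scale"
            )
        _scatter_kernel(values, pts, ns, ss, h, rc, periodic=True)

    return DensityField(values=values, box=box, spacings=ss, mode=mode)


# ---------------------------------------------------------------------------
# marching cubes + periodic stitching
# ---------------------------------------------------------------------------

def _merge_seam_vertices(verts: np.ndarray, faces: np.ndarray,
                         box: Box) -> tuple[np.ndarray, np.ndarray]:
    """Identify vertices across the periodic seam (coordinate 0 vs L)."""
    L = box.lengths
    tol = 1e-6 * float(L.min())
    keys = np.round(np.mod(verts, L) / tol).astype(np.int64)
    nmax = np.round(L / tol).astype(np.int64)
    keys = np.mod(keys, nmax)  # wrap key exactly at the seam
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    new_verts = verts[first]
    new_faces = inverse[faces]
    # drop faces collapsed by the merge and duplicated faces
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    new_faces = new_faces[ok]
    sorted_faces = np.sort(new_faces, axis=1)
    _, keep = np.unique(sorted_faces, axis=0, return_index=True)
    return new_verts, new_faces[np.sort(keep)]


def _face_components(n_vertices: int, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    edges_i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    edges_j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    g = sparse.coo_matrix(
        (np.ones_like(edges_i), (edges_i, edges_j)), shape=(n_vertices, n_vertices)
    )
    n_comp, vlabels = connected_components(g, directed=False)
    flabels = vlabels[faces[:, 0]]
    return vlabels, flabels, n_comp


def _component_closed(faces: np.ndarray) -> tuple[bool, int]:
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = int(np.sum(counts != 2))
    return boundary == 0, boundary


def _unwrap_component(verts: np.ndarray, faces: np.ndarray, vidx: np.ndarray,
                      box: Box) -> tuple[np.ndarray, bool]:
    """Unwrap a component's vertices across the seam; detect winding."""
    L = box.lengths
    pos = {int(v): None for v in vidx}
    edges: dict[int, list[tuple[int, np.ndarray]]] = {int(v): [] for v in vidx}
    for f in faces:
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            d = verts[v] - verts[u]
            d_mi = d - L * np.floor(d / L + 0.5)
            edges[int(u)].append((int(v), d_mi))
    root = int(vidx[0])
    pos[root] = verts[root].copy()
    stack = [root]
    percolating = False
    while stack:
        u = stack.pop()
        for v, d in edges[u]:
            cand = pos[u] + d
            if pos[v] is None:
                pos[v] = cand
                stack.append(v)
            elif not np.allclose(pos[v], cand, atol=1e-4 * L.min()):
                percolating = True
    out = verts.copy()
    for v in vidx:
        if pos[int(v)] is not None:
            out[int(v)] = pos[int(v)]
    return out, percolating


def _triangle_areas(verts: np.ndarray, faces: np.ndarray,
                    box: Box | None = None) -> np.ndarray:
    """Triangle areas; with a box, edges are taken minimum-image so faces of
    a seam-stitched mesh (whose merged vertices wrap) are measured correctly."""
    a = verts[faces[:, 1]] - verts[faces[:, 0]]
    b = verts[faces[:, 2]] - verts[faces[:, 0]]
    if box is not None:
        L = box.lengths
        a = a - L * np.floor(a / L + 0.5)
        b = b - L * np.floor(b / L + 0.5)
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def _signed_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)


def willard_chandler_surface(field: DensityField,
                             params: WCParams | None = None) -> SurfaceMesh:
    """Triangulate the iso-density level set at iso_fraction * rho_max.

    The field is padded by one periodically wrapped layer so the grid covers
    the full box [0, L]; seam vertices are merged afterwards so components
    that touch or cross the boundary stitch up correctly.
    """
    if params is None:
        params = WCParams()
    vals = field.values
    if not np.isfinite(vals).all():
        raise ValueError("density field contains non-finite values")
    if vals.max() <= 0 or np.allclose(vals, vals.flat[0]):
        raise NoSurfaceError("density field is constant; the level set is empty")
    level = params.iso_fraction * field.rho_max
    if level <= vals.min():
        raise NoSurfaceError("isovalue below the field minimum; no surface crossing")

    padded = np.pad(vals, ((0, 1), (0, 1), (0, 1)), mode="wrap")
    verts, faces, _normals, _v = marching_cubes(
        padded, level=level, spacing=tuple(field.spacings),
        allow_degenerate=False,
    )
    # skimage orients faces so normals follow decreasing density (outward);
    # its vertex winding yields negative signed volume for a blob, so flip.
    faces = faces[:, ::-1]

    verts, faces = _merge_seam_vertices(verts, faces, field.box)
    return mesh_from_arrays(verts, faces, field.box,
                            seam_margin=float(field.spacings.max()))


def mesh_from_arrays(verts: np.ndarray, faces: np.ndarray, box: Box,
                     seam_margin: float = 0.0) -> SurfaceMesh:
    """Build a SurfaceMesh (components, areas, volumes, flags) from raw
    triangle arrays with outward-oriented faces.

    Components entirely farther than ``seam_margin`` from the box boundary
    skip the periodic unwrapping pass.
    """
    verts = np.asarray(verts, dtype=float)
    faces = np.asarray(faces, dtype=int)
    vlabels, flabels, n_comp = _face_components(verts.shape[0], faces)

    areas = np.zeros(n_comp)
    volumes = np.full(n_comp, np.nan)
    closed = np.zeros(n_comp, dtype=bool)
    percolating = np.zeros(n_comp, dtype=bool)
    tri_areas = _triangle_areas(verts, faces, box)
    notes: list[str] = []
    for c in range(n_comp):
        fmask = flabels == c
        comp_faces = faces[fmask]
        areas[c] = float(tri_areas[fmask].sum())
        is_closed, n_open = _component_closed(comp_faces)
        closed[c] = is_closed
        vidx = np.flatnonzero(vlabels == c)
        cverts = verts[vidx]
        if ((cverts > seam_margin).all()
                and (cverts < box.lengths - seam_margin).all()):
            # interior component: nothing to unwrap, cannot wind
            unwrapped, winds = verts, False
        else:
            unwrapped, winds = _unwrap_component(verts, comp_faces, vidx, box)
        percolating[c] = winds
        if is_closed and not winds:
            volumes[c] = _signed_volume(unwrapped, comp_faces)
        elif not is_closed:
            notes.append(f"component {c}: {n_open} boundary edges (open)")
        else:
            notes.append(f"component {c}: percolates the box; no enclosed volume")

    return SurfaceMesh(
        vertices=verts, faces=faces, box=box,
        vertex_component=vlabels, face_component=flabels,
        component_area=areas, component_volume=volumes,
        component_closed=closed, component_percolating=percolating,
        warnings=notes,
    )


def aggregate_surface(points, box: Box, params: WCParams | None = None,
                      mode: str = "supercell", tight: bool = True) -> SurfaceMesh:
    """Willard-Chandler surface of one (compact, unwrapped) aggregate.

    The point cloud is recentered (circular mean) before the density is
    evaluated, which makes area and volume exactly invariant under periodic
    translation of the input; the returned mesh is shifted back to the
    original location.  With ``tight=True`` the field is evaluated on a snug
    grid around the aggregate (padded by the kernel truncation radius) rather
    than over the whole box — a large speedup for small aggregates in big
    dilute boxes, with no effect beyond grid-alignment discretization.  Use
    ``gaussian_density_grid`` directly for whole-box fields, e.g. when
    contrasting supercell against minimum-image periodicity handling.
    """
    if params is None:
        params = WCParams()
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    L = box.lengths
    theta = 2.0 * np.pi * pts / L
    center = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    center = np.mod(center / (2.0 * np.pi), 1.0) * L
    shift = 0.5 * L - center

    work_box = box
    if tight:
        centered = pts + shift - 0.5 * L
        centered -= L * np.floor(centered / L + 0.5)
        half_extent = np.abs(centered).max(axis=0)
        margin = params.truncation * params.bandwidth + 2.0 * params.spacing
        side = 2.0 * (half_extent + margin)
        side = np.ceil(side / params.spacing) * params.spacing
        if np.all(side < L):
            work_box = Box(*side)
            shift = shift + 0.5 * work_box.lengths - 0.5 * L

    field = gaussian_density_grid(pts + shift, work_box, params, mode=mode)
    mesh = willard_chandler_surface(field, params)
    mesh.vertices = mesh.vertices - shift
    mesh.box = box
    return mesh


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def mesh_area_volume(mesh: SurfaceMesh) -> tuple[float, float]:
    """(total area, material volume) of a closed mesh.

    Material volume is |sum of per-component signed volumes|: outward-oriented
    outer surfaces count positive and nested inner surfaces (normals toward
    the cavity) negative, so a vesicle shell reports the shell volume.
    """
    if not mesh.component_closed.all():
        n_open = sum(
            _component_closed(mesh.faces[mesh.face_component == c])[1]
            for c in range(mesh.n_components)
            if not mesh.component_closed[c]
        )
        raise OpenMeshError(
            f"mesh has open components ({n_open} boundary edges)", n_open
        )
    if mesh.component_percolating.any():
        raise PercolationError("mesh percolates the box; enclosed volume undefined")
    return mesh.total_area, float(abs(np.nansum(mesh.component_volume)))


def per_surfactant_metrics(area: float, volume: float, n: int) -> tuple[float, float, float]:
    """(area/N, volume/N, area/volume) for an aggregate of N surfactants."""
    if n < 1:
        raise ValueError("aggregation number must be >= 1")
    if not volume > 0:
        raise DegenerateSurfaceError("surface encloses no volume")
    return area / n, volume / n, area / volume


def component_submesh(mesh: SurfaceMesh, component: int) -> "SurfaceMesh":
    """Extract one connected component as a standalone mesh."""
    vmask = mesh.vertex_component == component
    remap = -np.ones(mesh.vertices.shape[0], dtype=int)
    remap[vmask] = np.arange(vmask.sum())
    fmask = mesh.face_component == component
    return SurfaceMesh(
        vertices=mesh.vertices[vmask],
        faces=remap[mesh.faces[fmask]],
        box=mesh.box,
        vertex_component=np.zeros(vmask.sum(), dtype=int),
        face_component=np.zeros(fmask.sum(), dtype=int),
        component_area=mesh.component_area[[component]],
        component_volume=mesh.component_volume[[component]],
        component_closed=mesh.component_closed[[component]],
        component_percolating=mesh.component_percolating[[component]],
    )


# ---------------------------------------------------------------------------
# bilayers
# ---------------------------------------------------------------------------

def split_bilayer_leaflets(mesh: SurfaceMesh) -> tuple[SurfaceMesh, SurfaceMesh]:
    """The two leaflet surfaces of a lamellar mesh, (upper, lower) by mean z.

    The two largest components by area are taken; extra components (e.g. a
    coexisting micelle) trigger a warning and are ignored.
    """
    if mesh.n_components < 2:
        raise NotABilayerError(
            f"expected two leaflet surfaces, found {mesh.n_components} component(s)"
        )
    order = np.argsort(mesh.component_area)[::-1]
    if mesh.n_components > 2:
        warnings.warn(
            f"bilayer mesh has {mesh.n_components} components; using the two "
            "largest by area"
        )
        mesh.warnings.append(f"{mesh.n_components - 2} extra component(s) ignored")
    first, second = component_submesh(mesh, int(order[0])), component_submesh(mesh, int(order[1]))
    if first.vertices[:, 2].mean() >= second.vertices[:, 2].mean():
        return first, second
    return second, first


def bilayer_thickness(upper: SurfaceMesh, lower: SurfaceMesh) -> np.ndarray:
    """Pooled nearest-neighbor vertex distances between the two leaflets.

    For every vertex of each surface, the minimum-image distance to the
    nearest vertex of the other surface; the pooled array's mean is the
    bilayer thickness.
    """
    if upper.vertices.size == 0 or lower.vertices.size == 0:
        raise ValueError("both leaflet surfaces must be non-empty")
    box = upper.box
    up = wrap_into_box(upper.vertices, box)
    lo = wrap_into_box(lower.vertices, box)
    d_up, _ = cKDTree(lo, boxsize=box.lengths).query(up)
    d_lo, _ = cKDTree(up, boxsize=box.lengths).query(lo)
    return np.concatenate([d_up, d_lo])


def area_per_headgroup(upper: SurfaceMesh, lower: SurfaceMesh, n: int) -> float:
    """Combined leaflet area divided by the number of surfactants (A^2)."""
    if n < 1:
        raise ValueError("surfactant count must be >= 1")
    return (upper.total_area + lower.total_area) / n


# ---------------------------------------------------------------------------
# mesh export
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> None:
    """Export a mesh as ASCII PLY or OBJ (inferred from the suffix)."""
    from pathlib import Path

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        lines = [f"v {x:.6f} {y:.6f} {z:.6f}" for x, y, z in mesh.vertices]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "ply":
        header = [
            "ply", "format ascii 1.0",
            f"element vertex {mesh.vertices.shape[0]}",
            "property float x", "property float y", "property float z",
            f"element face {mesh.faces.shape[0]}",
            "property list uchar int vertex_indices", "end_header",
        ]
        body = [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in mesh.vertices]
        body += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
        path.write_text("\n".join(header + body) + "\n")
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")
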
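"""Per-aggregate size and shape: radius of gyration, principal semiaxes and
coordinate-pair eccentricities (CPE).

Each aggregate is reduced to one point per surfactant (the mass-weighted mean
of its beads, carrying the summed bead mass).  The inertia tensor about the
center of mass is diagonalised, its principal moments are inverted through
the solid-ellipsoid relations

    A = M/5 (b^2 + c^2),   B = M/5 (a^2 + c^2),   C = M/5 (a^2 + b^2)

to ordered semiaxes a >= b >= c, and the two eccentricities

    e_ab = sqrt(1 - b^2/a^2),   e_ac = sqrt(1 - c^2/a^2)

classify the aggregate as spherical, prolate, oblate or triaxial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NonEllipsoidalMomentsError, PercolationError

#: CPE below which both axes are considered equal (spherical side).
DEFAULT_SPHERE_TOL = 0.15
#: Max e_ac - e_ab separation still considered prolate.
DEFAULT_SPLIT_TOL = 0.10

ELLIPSOID_CLASSES = ("spherical", "prolate", "oblate", "triaxial")


@dataclass(frozen=True)
class ShapeDescriptors:
    """Size/shape summary of one aggregate."""

    r_g: float
    a: float
    b: float
    c: float
    e_ab: float
    e_ac: float
    ellipsoid_class: str
    n: int


def radius_of_gyration(positions, masses) -> float:
    """Mass-weighted radius of gyration sqrt(sum m_i |r_i|^2 / sum m_i).

    ``r_i`` is the displacement of point i from the mass-weighted center.
    Coordinates must be unwrapped (no periodic jumps).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    m = np.asarray(masses, dtype=float).ravel()
    if pos.shape[0] != m.size:
        raise ValueError("one mass per position required")
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    com = np.average(pos, axis=0, weights=m)
    d2 = np.sum((pos - com) ** 2, axis=1)
    return float(np.sqrt(np.sum(m * d2) / np.sum(m)))


def inertia_principal_moments(positions, masses) -> tuple[np.ndarray, float]:
    """Principal moments of inertia about the center of mass, ascending, and M.

    A rank-deficient point configuration (collinear/coplanar degeneracy of the
    second-moment tensor) triggers a warning; moments are still returned.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    m = np.asarray(masses, dtype=float).ravel()
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    total = float(np.sum(m))
    com = np.average(pos, axis=0, weights=m)
    r = pos - com
    # I = sum m (|r|^2 delta - r r^T)
    r2 = np.sum(r * r, axis=1)
    tensor = np.eye(3) * np.sum(m * r2) - (r.T * m) @ r
    moments = np.linalg.eigvalsh(tensor)
    scale = max(np.max(np.abs(moments)), 1e-300)
    if moments[0] / scale < 1e-9:
        warnings.warn("degenerate (rank-deficient) mass distribution; "
                      "principal moments are near-singular")
    return moments, total


def principal_semiaxes(A: float, B: float, C: float, M: float) -> tuple[float, float, float]:
    """Invert the solid-ellipsoid inertia relations to ordered semiaxes.

    a^2 = 5(B+C-A)/(2M) and cyclic permutations; requires the moments to
    satisfy the ellipsoid triangle conditions (every radicand positive).
    """
    if not M > 0:
        raise ValueError("total mass must be positive")
    if not (A <= B <= C):
        raise ValueError("moments must be supplied in ascending order A <= B <= C")
    a2 = 5.0 * (B + C - A) / (2.0 * M)
    b2 = 5.0 * (A + C - B) / (2.0 * M)
    c2 = 5.0 * (A + B - C) / (2.0 * M)
    if min(a2, b2, c2) <= 0:
        raise NonEllipsoidalMomentsError(
            f"moments (A={A}, B={B}, C={C}) are not consistent with a solid "
            "ellipsoid (non-positive squared semiaxis)"
        )
    axes = sorted((np.sqrt(a2), np.sqrt(b2), np.sqrt(c2)), reverse=True)
    return float(axes[0]), float(axes[1]), float(axes[2])


def coordinate_pair_eccentricities(a: float, b: float, c: float) -> tuple[float, float]:
    """CPE (e_ab, e_ac) of an ellipsoid with ordered semiaxes a >= b >= c > 0."""
    if not (a >= b >= c > 0):
        raise ValueError(f"semiaxes must satisfy a >= b >= c > 0, got ({a}, {b}, {c})")
    e_ab = np.sqrt(max(0.0, 1.0 - (b / a) ** 2))
    e_ac = np.sqrt(max(0.0, 1.0 - (c / a) ** 2))
    return float(e_ab), float(e_ac)


def classify_ellipsoid(e_ab: float, e_ac: float,
                       sphere_tol: float = DEFAULT_SPHERE_TOL,
                       split_tol: float = DEFAULT_SPLIT_TOL) -> str:
    """Map a CPE pair onto {spherical, prolate, oblate, triaxial}.

    Spherical: both eccentricities near zero.  Prolate: e_ab ~ e_ac well above
    zero.  Oblate: e_ab near zero with large e_ac.  Everything else: triaxial.
    """
    if not (0 <= e_ab <= e_ac):
        raise ValueError("require 0 <= e_ab <= e_ac")
    if e_ac < sphere_tol:
        return "spherical"
    if e_ac - e_ab < split_tol:
        return "prolate"
    if e_ab < sphere_tol <= e_ac:
        return "oblate"
    return "triaxial"


def experimental_rg(c: float, epsilon: float) -> float:
    """Radius of gyration of an oblate ellipsoid with minor semiaxis c and
    major/minor axis ratio epsilon: R_g = (c/sqrt(5)) sqrt(1 + 2 eps^2).

    Used to convert scattering-derived micelle dimensions (c = extended tail
    length, eps from fits) into an R_g comparable with simulation.
    """
    if not c > 0:
        raise ValueError("c must be positive")
    if epsilon < 1:
        raise ValueError("epsilon is the major/minor ratio and must be >= 1")
    return float(c / np.sqrt(5.0) * np.sqrt(1.0 + 2.0 * epsilon ** 2))


# ---------------------------------------------------------------------------
# aggregate-level driver
# ---------------------------------------------------------------------------

def surfactant_points(aggregate, frame) -> tuple[np.ndarray, np.ndarray]:
    """One (position, mass) per member surfactant.

    Position is the mass-weighted mean of the molecule's unwrapped beads and
    the mass the sum of its bead masses.
    """
    pos = np.empty((aggregate.n, 3))
    mass = np.empty(aggregate.n)
    offset = 0
    for k, mol in enumerate(aggregate.molecule_ids):
        topo = frame.topology_of(int(mol))
        nb = topo.n_beads
        beads = aggregate.coordinates[offset:offset + nb]
        m = topo.masses
        pos[k] = np.average(beads, axis=0, weights=m)
        mass[k] = m.sum()
        offset += nb
    return pos, mass


def describe_aggregate(aggregate, frame, bead_resolved: bool = False,
                       sphere_tol: float = DEFAULT_SPHERE_TOL,
                       split_tol: float = DEFAULT_SPLIT_TOL) -> ShapeDescriptors:
    """Full shape pipeline for one aggregate: R_g, semiaxes, CPE, class.

    ``bead_resolved=True`` uses every bead as a mass point instead of one
    point per surfactant.  Percolating aggregates have no defined shape and
    are refused.
    """
    if aggregate.percolating:
        raise PercolationError(
            f"aggregate {aggregate.aggregate_id} percolates the box; "
            "shape descriptors are undefined"
        )
    if bead_resolved:
        masses = np.concatenate(
            [frame.topology_of(int(m)).masses for m in aggregate.molecule_ids]
        )
        pos = aggregate.coordinates
    else:
        pos, masses = surfactant_points(aggregate, frame)

    r_g = radius_of_gyration(pos, masses)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        moments, total = inertia_principal_moments(pos, masses)
    try:
        a, b, c = principal_semiaxes(*moments, total)
        e_ab, e_ac = coordinate_pair_eccentricities(a, b, c)
        cls = classify_ellipsoid(e_ab, e_ac, sphere_tol, split_tol)
    except NonEllipsoidalMomentsError:
        a = b = c = float("nan")
        e_ab = e_ac = float("nan")
        cls = "degenerate"
    return ShapeDescriptors(r_g=r_g, a=a, b=b, c=c, e_ab=e_ab, e_ac=e_ac,
                            ellipsoid_class=cls, n=aggregate.n)
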
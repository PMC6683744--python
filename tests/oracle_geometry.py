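"""Independent continuum-geometry oracle for angularity.

Deliberately avoids the package's code paths: second moments come from an
exact degree-2 triangle quadrature (edge-midpoint rule) over a fan
triangulation, and the ellipse perimeter from direct numerical quadrature
of the arc-length integrand, instead of the Green's-theorem vertex sums
and the closed-form elliptic integral the implementation uses.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


def regular_polygon_vertices(n: int, circumradius: float,
                             phase_deg: float = 0.0) -> np.ndarray:
    ang = np.deg2rad(phase_deg) + 2 * np.pi * np.arange(n) / n
    return np.column_stack([circumradius * np.cos(ang),
                            circumradius * np.sin(ang)])


def polygon_covariance(verts: np.ndarray) -> tuple[float, np.ndarray]:
    """Area and per-area central second moments via triangle quadrature.

    Fan-triangulate about the vertex mean; on each triangle the 3-point
    edge-midpoint rule integrates quadratics exactly.
    """
    verts = np.asarray(verts, dtype=float)
    c = verts.mean(axis=0)
    area = 0.0
    m = np.zeros(3)  # xx, yy, xy raw moments about the origin
    first = np.zeros(2)
    for i in range(len(verts)):
        p1, p2 = verts[i], verts[(i + 1) % len(verts)]
        a_t = 0.5 * ((p1[0] - c[0]) * (p2[1] - c[1]) - (p2[0] - c[0]) * (p1[1] - c[1]))
        mids = [(c + p1) / 2, (p1 + p2) / 2, (p2 + c) / 2]
        area += a_t
        first += a_t / 3.0 * np.sum(mids, axis=0)
        for mx, my in mids:
            m += a_t / 3.0 * np.array([mx * mx, my * my, mx * my])
    cx, cy = first / area
    cov = np.array([[m[0] / area - cx * cx, m[2] / area - cx * cy],
                    [m[2] / area - cx * cy, m[1] / area - cy * cy]])
    return abs(area), cov


def ellipse_perimeter_quadrature(a: float, b: float) -> float:
    """Arc length of an ellipse by adaptive quadrature (rel tol ~1e-10)."""
    val, _ = quad(lambda th: np.hypot(a * np.sin(th), b * np.cos(th)),
                  0.0, 2.0 * np.pi, epsabs=1e-12, epsrel=1e-10, limit=200)
    return val


def polygon_angularity_oracle(verts: np.ndarray) -> float:
    """Continuum angularity of a convex polygon."""
    verts = np.asarray(verts, dtype=float)
    d = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    hull_perimeter = np.linalg.norm(d, axis=1).sum()
    _, cov = polygon_covariance(verts)
    lam = np.linalg.eigvalsh(cov)
    b, a = 2.0 * np.sqrt(lam)
    return (hull_perimeter / ellipse_perimeter_quadrature(a, b)) ** 2


def regular_polygon_angularity_oracle(n: int, circumradius: float = 1.0) -> float:
    return polygon_angularity_oracle(regular_polygon_vertices(n, circumradius))
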
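"""Vectorized ray-triangle intersection (Moller-Trumbore) for closed surfaces."""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def ray_hits(
    origin: np.ndarray, direction: np.ndarray, vertices: np.ndarray, triangles: np.ndarray
) -> np.ndarray:
    """Parameters t > 0 of intersections of one ray with all triangles."""
    v0 = vertices[triangles[:, 0]]
    e1 = vertices[triangles[:, 1]] - v0
    e2 = vertices[triangles[:, 2]] - v0
    d = np.asarray(direction, dtype=float)
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > _EPS
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origin - v0
    u = np.einsum("ij,ij->i", s, p) * inv
    q = np.cross(s, e1)
    v = np.einsum("j,ij->i", d, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= -1e-10) & (v >= -1e-10) & (u + v <= 1 + 1e-10) & (t > _EPS)
    return t[hit]


def points_inside(
    points: np.ndarray, vertices: np.ndarray, triangles: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Ray-parity containment of each point in a closed triangle surface."""
    rng = np.random.default_rng(seed)
    inside = np.zeros(len(points), dtype=bool)
    for i, pt in enumerate(np.asarray(points, dtype=float)):
        # retry with a fresh direction if the ray grazes an edge (duplicate t)
        for _ in range(8):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            t = np.sort(ray_hits(pt, d, vertices, triangles))
            grazing = len(t) > 1 and np.min(np.diff(t)) < 1e-9
            if not grazing:
                break
        inside[i] = len(t) % 2 == 1
    return inside
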
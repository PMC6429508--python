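"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the algorithms they check: alignment scores come
from explicit enumeration of all monotone alignment paths, clustering from
step-by-step agglomeration over explicit cluster sets, and superposition
from a dense grid search over Euler angles.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_align_score(a: str, b: str, score, gap_open: float,
                            gap_extend: float) -> float:
    """Best global alignment score by enumerating every monotone path.

    A gap run of length L costs gap_open + gap_extend*(L-1); runs are
    tracked by the type of the previous move so adjacent opposite-type gaps
    each pay the opening penalty.
    """
    best = float("-inf")

    def walk(i: int, j: int, prev: str, total: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, total)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, "D", total + score(a[i], b[j]))
        if i < len(a):
            cost = gap_extend if prev == "U" else gap_open
            walk(i + 1, j, "U", total - cost)
        if j < len(b):
            cost = gap_extend if prev == "L" else gap_open
            walk(i, j + 1, "L", total - cost)

    walk(0, 0, "", 0.0)
    return best


def brute_force_single_linkage(d: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Step-by-step nearest-point agglomeration over explicit member sets.

    Returns the merge list as (cluster A members, cluster B members,
    height) triples in merge order.
    """
    n = d.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            dist = min(d[i, j] for i in clusters[x] for j in clusters[y])
            if best is None or dist < best[0]:
                best = (dist, x, y)
        dist, x, y = best
        merges.append((clusters[x], clusters[y], dist))
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return merges


def grid_search_rmsd(P: np.ndarray, Q: np.ndarray, n_steps: int = 60,
                     refine: int = 3) -> float:
    """Minimum RMSD over rigid motions by iteratively refined Euler-angle
    grid search (translation handled by centering)."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_for(angles: tuple[float, float, float]) -> float:
        ax, ay, az = angles
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        R = Rz @ Ry @ Rx
        diff = Qc @ R.T - Pc
        return float(np.sqrt((diff ** 2).sum(axis=1).mean()))

    lo = np.array([0.0, -np.pi / 2, 0.0])
    span = np.array([2 * np.pi, np.pi, 2 * np.pi])
    best_angles, best = None, float("inf")
    for _ in range(refine):
        axes = [np.linspace(lo[k], lo[k] + span[k], n_steps) for k in range(3)]
        for angles in itertools.product(*axes):
            r = rmsd_for(angles)
            if r < best:
                best, best_angles = r, np.array(angles)
        step = span / (n_steps - 1)
        lo = best_angles - 2 * step
        span = 4 * step
    return best


def two_sphere_ses_interior(point: np.ndarray, centers: np.ndarray,
                            radius: float, probe: float,
                            n_dirs: int = 20000, seed: int = 0) -> bool:
    """Direct sphere-rolling test: is ``point`` inside the solvent-excluded
    region of two equal spheres?

    The point is solvent iff some probe sphere of the given radius contains
    it while overlapping neither atom: equivalently there is a probe centre
    c with |c - point| <= probe and |c - center_i| >= radius + probe for
    both atoms. We certify by sampling candidate probe centres densely.
    """
    rng = np.random.default_rng(seed)
    inflated = radius + probe
    d = np.linalg.norm(centers - point, axis=1)
    if (d <= radius).any():
        return True          # inside an atom: protein
    if (d > inflated).all():
        return False         # outside the inflated union: solvent
    # candidate probe centres around the point
    dirs = rng.normal(size=(n_dirs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = probe * rng.uniform(0, 1, size=(n_dirs, 1)) ** (1 / 3)
    candidates = point + dirs * radii
    candidates = np.vstack([candidates, point])
    for c in candidates:
        dc = np.linalg.norm(centers - c, axis=1)
        if (dc >= inflated - 1e-9).all() and np.linalg.norm(c - point) <= probe + 1e-9:
            return False     # a probe position reaches the point: solvent
    return True              # probe-inaccessible: protein interior
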
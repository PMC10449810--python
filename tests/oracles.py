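"""Independent brute-force oracles used to validate the lattice and MLE code.

Everything here is deliberately written in the most literal way possible
(pure-Python loops, union-find, exhaustive grid search) and shares no code
with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import special


def _neighbor_offsets(ndim: int, max_order: int):
    offs = []
    for off in itertools.product((-1, 0, 1), repeat=ndim):
        order = sum(abs(o) for o in off)
        if 0 < order <= max_order:
            offs.append(off)
    return offs


def union_find_components(grid: np.ndarray, max_order: int = 1) -> list[int]:
    """Cluster sizes of the True voxels by union-find over neighbor pairs."""
    coords = [tuple(c) for c in np.argwhere(grid)]
    index = {c: i for i, c in enumerate(coords)}
    parent = list(range(len(coords)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    offsets = _neighbor_offsets(grid.ndim, max_order)
    for c in coords:
        for off in offsets:
            nb = tuple(a + b for a, b in zip(c, off))
            if nb in index:
                ri, rj = find(index[c]), find(index[nb])
                if ri != rj:
                    parent[ri] = rj
    sizes: dict[int, int] = {}
    for i in range(len(coords)):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return sorted(sizes.values())


def enumerate_join_counts(laa: np.ndarray, lung: np.ndarray) -> tuple[int, int, int]:
    """(LL, NL, NN) face-join counts by looping over every voxel pair."""
    j_ll = j_nl = j_nn = 0
    shape = lung.shape
    axes = len(shape)
    for c in np.ndindex(*shape):
        if not lung[c]:
            continue
        for ax in range(axes):
            nb = list(c)
            nb[ax] += 1
            nb = tuple(nb)
            if nb[ax] >= shape[ax] or not lung[nb]:
                continue
            a, b = bool(laa[c]), bool(laa[nb])
            if a and b:
                j_ll += 1
            elif a or b:
                j_nl += 1
            else:
                j_nn += 1
    return j_ll, j_nl, j_nn


def grid_search_discrete_alpha(sizes: np.ndarray, x_min: int = 1) -> float:
    """Discrete power-law MLE by exhaustive two-stage grid search."""
    sizes = np.asarray(sizes, dtype=float)
    tail = sizes[sizes >= x_min]
    log_sum = np.log(tail).sum()
    n = len(tail)

    def loglik(alpha):
        return -n * np.log(special.zeta(alpha, x_min)) - alpha * log_sum

    coarse = np.arange(1.01, 8.0, 0.01)
    best = coarse[np.argmax([loglik(a) for a in coarse])]
    fine = np.arange(best - 0.02, best + 0.02, 1e-6)
    vals = [loglik(a) for a in fine]
    return float(fine[int(np.argmax(vals))])


def riemann_log_likelihood(points: np.ndarray, window_grid: np.ndarray,
                           spacing: tuple[float, float], state,
                           step: float = 0.1) -> float:
    """Poisson log-likelihood with the intensity integral computed by a fine
    Riemann sum (midpoint, ``step`` mm) over the same window region."""
    dx, dy = spacing
    rx = int(round(dx / step))
    ry = int(round(dy / step))
    fine = np.repeat(np.repeat(window_grid, rx, axis=0), ry, axis=1)
    ij = np.argwhere(fine)
    centers = (ij + 0.5) * np.array([dx / rx, dy / ry])
    cell_area = (dx / rx) * (dy / ry)

    def dens(pts, c, cov):
        inv = np.linalg.inv(cov)
        det = np.linalg.det(cov)
        d = pts - c
        q = np.einsum("ni,ij,nj->n", d, inv, d)
        return np.exp(-0.5 * q) / (2 * np.pi * np.sqrt(det))

    lam_cells = np.full(len(centers), state.epsilon)
    lam_pts = np.full(len(points), state.epsilon)
    for j in range(state.K):
        lam_cells = lam_cells + state.weights[j] * dens(centers, state.centers[j],
                                                        state.kernels[j])
        if len(points):
            lam_pts = lam_pts + state.weights[j] * dens(points, state.centers[j],
                                                        state.kernels[j])
    integral = lam_cells.sum() * cell_area
    if len(points) and lam_pts.min() <= 0:
        return -np.inf
    point_term = np.log(lam_pts).sum() if len(points) else 0.0
    return float(point_term - integral)
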
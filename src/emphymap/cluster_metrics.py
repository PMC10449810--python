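"""Cluster-size distributions with power-law exponent D, and join-count statistics.

Two of the three spatial heterogeneity measures live here:

* **D** — contiguous low-attenuation clusters (LACs) are found by connected
  components on the voxel lattice; their sizes follow an approximate power law
  ``P(S = s) ∝ s^(−α)`` and the exponent is fit by maximum likelihood.  The
  reported D can follow either the density convention (α) or the CCDF-slope
  convention (α − 1); both are carried in the fit result.  Smaller D means the
  size distribution is shifted toward larger clusters.

* **NJC** — the normalized join count: the fraction (as a percent) of
  within-lung adjacent voxel pairs ("joins", shared faces in 3D / shared edges
  in 2D) that are LAA-to-LAA.  A compact disease pattern produces a much higher
  NJC than scattered disease at the same burden.

Adjacency is defined on the index lattice irrespective of anisotropic spacing:
a shared face is a join whether it is an in-plane or through-plane face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, special

from .imaging_io import BinaryMask

CONNECTIVITY_RANKS = {"faces": 1, "faces+edges": 2, "faces+edges+corners": 3}

# Unit offsets for face adjacency, one per axis (positive direction only so
# each unordered pair is visited exactly once).
_FACE_OFFSETS_3D = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


@dataclass(frozen=True)
class LabeledClusters:
    """Connected-component labeling of an LAA mask."""

    labels: np.ndarray      # integer grid, 0 = background
    n_clusters: int
    connectivity: str

    def __post_init__(self):
        if self.connectivity not in CONNECTIVITY_RANKS:
            raise ValueError(f"unknown connectivity {self.connectivity!r}")


@dataclass(frozen=True)
class ClusterSizeDistribution:
    """Multiset of cluster sizes (voxels per cluster), including singletons."""

    sizes: np.ndarray

    def __post_init__(self):
        sizes = np.asarray(self.sizes, dtype=int)
        if len(sizes) and sizes.min() < 1:
            raise ValueError("cluster sizes must be positive")
        object.__setattr__(self, "sizes", sizes)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def total_voxels(self) -> int:
        return int(self.sizes.sum())


@dataclass(frozen=True)
class PowerLawFit:
    """Maximum-likelihood power-law fit to a cluster-size distribution.

    ``alpha`` is the density exponent (P(s) ∝ s^−α); ``D`` is the reported
    exponent under ``d_convention`` ("alpha" or "alpha-1", the latter being the
    slope of the log cumulative distribution).
    """

    alpha: float
    D: float
    x_min: int
    log_likelihood: float
    n_tail: int
    method: str
    d_convention: str
    degenerate: bool = False


@dataclass(frozen=True)
class JoinCountResult:
    """Counts of LAA-LAA (ll), normal-LAA (nl) and normal-normal (nn) joins."""

    j_ll: int
    j_nl: int
    j_nn: int

    @property
    def total(self) -> int:
        return self.j_ll + self.j_nl + self.j_nn

    @property
    def njc(self) -> float:
        """Normalized join count, percent: 100 * LL / (LL + NL + NN)."""
        return 100.0 * self.j_ll / self.total


def _as_bool_grid(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.indicator
    arr = np.asarray(mask)
    return arr.astype(bool)


def label_connected_components(laa, connectivity: str = "faces") -> LabeledClusters:
    """Label contiguous LAA clusters on the (2D or 3D) voxel lattice.

    Labeling order is deterministic (raster scan), so identical inputs give
    bit-identical label grids.
    """
    if connectivity not in CONNECTIVITY_RANKS:
        raise ValueError(f"unknown connectivity {connectivity!r}; "
                         f"choose from {sorted(CONNECTIVITY_RANKS)}")
    grid = _as_bool_grid(laa)
    rank = min(CONNECTIVITY_RANKS[connectivity], grid.ndim)
    structure = ndimage.generate_binary_structure(grid.ndim, rank)
    labels, n = ndimage.label(grid, structure=structure)
    return LabeledClusters(labels=labels, n_clusters=int(n), connectivity=connectivity)


def cluster_size_distribution(labels: LabeledClusters) -> ClusterSizeDistribution:
    """Sizes (in voxels) of each labeled cluster, including singletons."""
    if labels.n_clusters == 0:
        return ClusterSizeDistribution(sizes=np.array([], dtype=int))
    counts = np.bincount(labels.labels.ravel(), minlength=labels.n_clusters + 1)[1:]
    return ClusterSizeDistribution(sizes=counts)


# ---------------------------------------------------------------------------
# Power-law MLE


def _discrete_loglik(alpha: float, log_sum: float, n: int, x_min: int) -> float:
    # log L = -n log ζ(α, x_min) - α Σ log s_i
    return -n * np.log(special.zeta(alpha, x_min)) - alpha * log_sum


def fit_power_law(
    sizes,
    x_min_policy: str | int = "fixed",
    method: str = "discrete",
    x_min: int = 1,
    d_convention: str = "alpha-1",
    min_tail: int = 5,
) -> PowerLawFit:
    """Fit a power law to cluster sizes by maximum likelihood.

    Parameters
    ----------
    sizes
        A :class:`ClusterSizeDistribution` or array of positive integers.
    x_min_policy
        ``"fixed"`` uses ``x_min`` as given (default 1: every cluster, even a
        single voxel, enters the fit); ``"ks"`` scans candidate x_min values
        and picks the one minimizing the Kolmogorov–Smirnov distance between
        the empirical and fitted tail distributions.
    method
        ``"discrete"`` (zeta-function MLE on integer sizes, the default) or
        ``"continuous"`` (closed form ``α̂ = 1 + n / Σ ln(s_i / x_min)``).
    d_convention
        ``"alpha-1"`` reports D as the CCDF slope α − 1 (default);
        ``"alpha"`` reports the density exponent itself.
    min_tail
        Minimum number of tail observations for a non-degenerate fit.

    A degenerate input (all sizes equal, or fewer than ``min_tail`` tail
    points) yields a flagged result with ``D = nan``.
    """
    if isinstance(sizes, ClusterSizeDistribution):
        sizes = sizes.sizes
    sizes = np.asarray(sizes, dtype=float)
    if method not in ("discrete", "continuous"):
        raise ValueError(f"unknown method {method!r}")
    if d_convention not in ("alpha", "alpha-1"):
        raise ValueError(f"unknown d_convention {d_convention!r}")

    if x_min_policy == "ks":
        return _fit_power_law_ks(sizes, method, d_convention, min_tail)
    if x_min_policy != "fixed":
        raise ValueError(f"unknown x_min_policy {x_min_policy!r}")

    x_min = int(x_min)
    tail = sizes[sizes >= x_min]
    n = len(tail)
    degenerate = n < min_tail or len(np.unique(tail)) < 2
    if degenerate:
        return PowerLawFit(alpha=np.nan, D=np.nan, x_min=x_min, log_likelihood=np.nan,
                           n_tail=n, method=method, d_convention=d_convention,
                           degenerate=True)

    if method == "continuous":
        log_ratio_sum = float(np.log(tail / x_min).sum())
        alpha = 1.0 + n / log_ratio_sum
        loglik = n * np.log((alpha - 1) / x_min) - alpha * log_ratio_sum
    else:
        log_sum = float(np.log(tail).sum())
        res = optimize.minimize_scalar(
            lambda a: -_discrete_loglik(a, log_sum, n, x_min),
            bounds=(1.0 + 1e-8, 30.0), method="bounded",
            options={"xatol": 1e-10},
        )
        alpha = float(res.x)
        loglik = float(-res.fun)

    d_value = alpha - 1.0 if d_convention == "alpha-1" else alpha
    return PowerLawFit(alpha=alpha, D=d_value, x_min=x_min, log_likelihood=loglik,
                       n_tail=n, method=method, d_convention=d_convention)


def _fit_power_law_ks(sizes, method, d_convention, min_tail) -> PowerLawFit:
    candidates = np.unique(sizes.astype(int))
    candidates = candidates[candidates >= 1][:50]
    best: PowerLawFit | None = None
    best_ks = np.inf
    for xm in candidates:
        fit = fit_power_law(sizes, "fixed", method, x_min=int(xm),
                            d_convention=d_convention, min_tail=min_tail)
        if fit.degenerate:
            continue
        tail = np.sort(sizes[sizes >= xm])
        # empirical vs fitted discrete CDF on the observed support
        support = np.unique(tail)
        emp_cdf = np.searchsorted(tail, support, side="right") / len(tail)
        if method == "discrete":
            z0 = special.zeta(fit.alpha, xm)
            fit_cdf = 1.0 - special.zeta(fit.alpha, support + 1) / z0
        else:
            fit_cdf = 1.0 - (support / xm) ** (1.0 - fit.alpha)
        ks = float(np.abs(emp_cdf - fit_cdf).max())
        if ks < best_ks:
            best, best_ks = fit, ks
    if best is None:
        return fit_power_law(sizes, "fixed", method, x_min=1,
                             d_convention=d_convention, min_tail=min_tail)
    return best


# ---------------------------------------------------------------------------
# Join counts


def compute_join_counts(laa, lung, connectivity: str = "faces") -> JoinCountResult:
    """Classify within-lung adjacent voxel pairs as LL / NL / NN joins.

    Only pairs with *both* voxels inside the lung are counted (out-of-lung air
    would otherwise inflate the normal-normal count).  Works for 2D slices
    (shared edges) and 3D volumes (shared faces).
    """
    laa_grid = _as_bool_grid(laa)
    lung_grid = _as_bool_grid(lung)
    if laa_grid.shape != lung_grid.shape:
        raise ValueError("LAA and lung grids must share shape")
    if (laa_grid & ~lung_grid).any():
        raise ValueError("LAA mask must be a subset of the lung mask")
    offsets = _join_offsets(lung_grid.ndim, connectivity)

    j_ll = j_nl = j_nn = 0
    for off in offsets:
        a = _shift_view(lung_grid, off, head=True)
        b = _shift_view(lung_grid, off, head=False)
        both_lung = a & b
        la = _shift_view(laa_grid, off, head=True)
        lb = _shift_view(laa_grid, off, head=False)
        j_ll += int((both_lung & la & lb).sum())
        j_nn += int((both_lung & ~la & ~lb).sum())
        j_nl += int((both_lung & (la ^ lb)).sum())
    if j_ll + j_nl + j_nn == 0:
        raise ValueError("no within-lung joins: lung region too small")
    return JoinCountResult(j_ll=j_ll, j_nl=j_nl, j_nn=j_nn)


def _join_offsets(ndim: int, connectivity: str) -> list[tuple[int, ...]]:
    if connectivity not in CONNECTIVITY_RANKS:
        raise ValueError(f"unknown connectivity {connectivity!r}")
    rank = CONNECTIVITY_RANKS[connectivity]
    offsets = []
    for off in np.ndindex(*(3,) * ndim):
        delta = tuple(o - 1 for o in off)
        order = sum(abs(d) for d in delta)
        if order == 0 or order > rank:
            continue
        # keep one representative of each {+δ, −δ} pair: first nonzero positive
        first = next(d for d in delta if d != 0)
        if first > 0:
            offsets.append(delta)
    return offsets


def _shift_view(arr: np.ndarray, offset: tuple[int, ...], head: bool) -> np.ndarray:
    """Paired slices so arr[head-slice][i] and arr[tail-slice][i] are neighbors at +offset."""
    slices = []
    for d in offset:
        if d == 0:
            slices.append(slice(None))
        elif d > 0:
            slices.append(slice(None, -d) if head else slice(d, None))
        else:
            slices.append(slice(-d, None) if head else slice(None, d))
    return arr[tuple(slices)]
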
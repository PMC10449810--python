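"""Ground-truth-known synthetic data: slice patterns, CT stacks, and cohorts.

Real emphysema cohorts with linked CT imaging, clinical outcomes and plasma
proteomics are access-restricted, so method behaviour is established on
simulated data whose generative structure matches what the analysis assumes:

* **Slice patterns** are drawn from the shot-noise Cox model itself — Poisson
  noise points uniform on the lung window plus per-cluster Poisson counts with
  Gaussian-kernel locations (truncated to the window by rejection).
* **CT stacks** rasterize those patterns into HU volumes with elliptical lung
  windows, so the full imaging pipeline (threshold → metrics → fit) can be
  exercised end to end; thresholding a rasterized volume reproduces its mask
  exactly.
* **Cohorts** couple per-subject heterogeneity metrics to clinical outcomes
  through linear models on standardized log-metrics, to a 6-level visual
  assessment via a noisy monotone function of the true average cluster size,
  and to biomarker panels with configurable LLOQ censoring and effect routes.

The cohort metric generator uses three independent latent factors per subject:
overall burden ``s`` (drives every metric), a shared clustering factor ``g``
(drives NJC, D, %-Diffuse, ACA and partly ACS/NC), and a point-process-specific
factor ``h`` that only ACS and NC carry.  ``h`` encodes the claim under test:
the point-process summaries contain information about spatial aggregation that
%LAA, NJC and D do not.  Scales are calibrated so metric means/SDs sit in
realistic COPD-cohort ranges (%LAA ≈ 10%, D ≈ 1.7, ACS ≈ 20 mm², NC ≈ 17 per
100 cm², %-Diffuse ≈ 30%, ACA ≈ 60 mm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging_io import BinaryMask, CTVolume, SlicePattern, Window2D
from .point_process import SNCPState, _WindowQuadrature, gaussian_density_2d

OUTCOME_NAMES = ("fev1", "fvc", "fev1_fvc", "frc", "frc_tlc", "six_mwd", "sgrq", "pct_gt")
METRIC_NAMES = ("pct_laa", "D", "njc", "acs", "nc", "pct_diffuse", "aca")
CLE_LEVELS = ("absent", "trace", "mild", "moderate", "confluent", "advanced_destructive")
PARASEPTAL_LEVELS = ("absent", "mild", "substantial")


@dataclass(frozen=True)
class SliceTruth:
    """Generative ground truth for one simulated slice pattern."""

    state: SNCPState
    window: Window2D
    n_cluster_points: int
    n_noise_points: int

    @property
    def n_points(self) -> int:
        return self.n_cluster_points + self.n_noise_points


def elliptical_window(semi_axes_mm: tuple[float, float],
                      spacing: tuple[float, float] = (1.0, 1.0),
                      margin_mm: float = 2.0) -> Window2D:
    """A lung-like elliptical observation window on a voxel grid."""
    a, b = semi_axes_mm
    dx, dy = spacing
    nx = int(np.ceil(2 * (a + margin_mm) / dx))
    ny = int(np.ceil(2 * (b + margin_mm) / dy))
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(x, y, indexing="ij")
    grid = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
    return Window2D(grid=grid, spacing=spacing)


def simulate_slice_pattern(
    truth: SNCPState,
    window: Window2D,
    rng: np.random.Generator,
) -> tuple[SlicePattern, SliceTruth]:
    """Draw one pattern from the shot-noise Cox model restricted to ``window``.

    Noise points: Poisson(ε·|W|), uniform over the window.  Cluster j: count
    Poisson(w_j · m_j) with m_j the kernel's window mass, locations from the
    window-truncated Gaussian (rejection sampling).
    """
    quad = _WindowQuadrature(window)
    cells = window.cell_centers()
    spacing = np.asarray(window.spacing)
    pieces = []

    n_cluster = 0
    for j in range(truth.K):
        mass = quad.mass(truth.centers[j], truth.kernels[j])
        count = rng.poisson(truth.weights[j] * mass)
        if count == 0:
            continue
        accepted = []
        L = np.linalg.cholesky(truth.kernels[j])
        remaining, guard = count, 0
        while remaining > 0 and guard < 200:
            prop = truth.centers[j] + rng.standard_normal((max(remaining * 2, 8), 2)) @ L.T
            keep = prop[window.contains(prop)][:remaining]
            accepted.append(keep)
            remaining -= len(keep)
            guard += 1
        pts = np.vstack(accepted) if accepted else np.empty((0, 2))
        n_cluster += len(pts)
        pieces.append(pts)

    n_noise = rng.poisson(truth.epsilon * window.area)
    if n_noise:
        which = rng.integers(len(cells), size=n_noise)
        noise = cells[which] + (rng.random((n_noise, 2)) - 0.5) * spacing
        pieces.append(noise)

    points = np.vstack(pieces) if pieces else np.empty((0, 2))
    pattern = SlicePattern(points=points, window=window)
    return pattern, SliceTruth(state=truth, window=window,
                               n_cluster_points=n_cluster, n_noise_points=int(n_noise))


def rasterize_pattern(
    pattern: SlicePattern,
    rng: np.random.Generator,
    dz: float = 1.0,
) -> tuple[BinaryMask, CTVolume]:
    """Rasterize a slice pattern into a one-slice LAA mask and HU volume.

    Voxels holding at least one point get HU drawn below −950; remaining lung
    voxels get HU in (−950, −600]; non-lung voxels get HU ≥ 0 — so applying
    the −950 threshold to the emitted volume reproduces the emitted mask.
    """
    window = pattern.window
    if dz <= 0:
        raise ValueError("dz must be positive")
    dx, dy = window.spacing
    grid = window.grid
    laa2d = np.zeros(grid.shape, dtype=bool)
    if pattern.n_points:
        idx = np.floor(pattern.points / np.array([dx, dy])).astype(int)
        laa2d[idx[:, 0], idx[:, 1]] = True
    laa2d &= grid

    hu2d = np.full(grid.shape, 50.0)
    n_lung = int(grid.sum())
    hu2d[grid] = rng.uniform(-949.5, -600.0, size=n_lung)
    n_laa = int(laa2d.sum())
    hu2d[laa2d] = rng.uniform(-1000.0, -951.0, size=n_laa)

    spacing3 = (dx, dy, dz)
    mask = BinaryMask(indicator=laa2d[:, :, None], spacing=spacing3, role="LAA")
    volume = CTVolume(hu=hu2d[:, :, None], spacing=spacing3)
    return mask, volume


@dataclass(frozen=True)
class SubjectImagingSpec:
    """Generative settings for one subject's simulated CT stack."""

    n_slices: int = 10
    max_semi_axes_mm: tuple[float, float] = (28.0, 28.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    clusters_per_100cm2: float = 15.0
    w: float = 80.0              # expected points per cluster
    sigma_mm: float = 3.0        # isotropic kernel SD
    noise_share: float = 0.2     # fraction of expected points from the noise term
    min_lung_voxels: int = 100


def simulate_subject(
    spec: SubjectImagingSpec,
    seed=None,
) -> tuple[CTVolume, BinaryMask, BinaryMask, list[SliceTruth]]:
    """Simulate a full CT stack: (volume, lung mask, LAA mask, per-slice truths).

    Slice windows are ellipses whose axes shrink smoothly toward the apical and
    basal slices; each slice gets an independent draw from the subject's truth
    state with K ~ Poisson(rate × area).
    """
    rng = np.random.default_rng(seed)
    dx, dy, dz = spec.spacing
    amax, bmax = spec.max_semi_axes_mm

    # fixed global grid large enough for the largest window
    proto = elliptical_window((amax, bmax), (dx, dy))
    nx, ny = proto.grid.shape
    nz = spec.n_slices

    hu = np.full((nx, ny, nz), 50.0)
    lung = np.zeros((nx, ny, nz), dtype=bool)
    laa = np.zeros((nx, ny, nz), dtype=bool)
    truths: list[SliceTruth] = []

    for z in range(nz):
        # lung cross-section shrinks toward the ends of the stack
        frac = np.sqrt(max(1.0 - (2.0 * (z + 0.5) / nz - 1.0) ** 2, 0.05))
        window = _ellipse_on_grid((nx, ny), (dx, dy), (amax * frac, bmax * frac))
        area = window.area
        k = rng.poisson(spec.clusters_per_100cm2 * area / 100.0 / 100.0)  # area mm²→cm²
        cells = window.cell_centers()
        centers = cells[rng.integers(len(cells), size=k)] if k else np.empty((0, 2))
        kernels = np.repeat(spec.sigma_mm**2 * np.eye(2)[None], k, axis=0)
        weights = np.full(k, spec.w)
        expected_cluster = spec.w * k
        eps = (spec.noise_share / max(1.0 - spec.noise_share, 1e-6)) * \
            max(expected_cluster, spec.w) / area
        state = SNCPState(centers=centers, weights=weights, kernels=kernels, epsilon=eps)
        pattern, truth = simulate_slice_pattern(state, window, rng)
        mask_s, vol_s = rasterize_pattern(pattern, rng, dz=dz)
        lung[:, :, z] = window.grid
        laa[:, :, z] = mask_s.indicator[:, :, 0]
        hu[:, :, z] = vol_s.hu[:, :, 0]
        truths.append(truth)

    spacing3 = (dx, dy, dz)
    return (
        CTVolume(hu=hu, spacing=spacing3),
        BinaryMask(indicator=lung, spacing=spacing3, role="lung"),
        BinaryMask(indicator=laa, spacing=spacing3, role="LAA"),
        truths,
    )


def _ellipse_on_grid(shape, spacing, semi_axes) -> Window2D:
    nx, ny = shape
    dx, dy = spacing
    a, b = semi_axes
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(x, y, indexing="ij")
    grid = ((X - cx) / max(a, dx)) ** 2 + ((Y - cy) / max(b, dy)) ** 2 <= 1.0
    if not grid.any():
        grid[nx // 2, ny // 2] = True
    return Window2D(grid=grid, spacing=(dx, dy))


# ---------------------------------------------------------------------------
# Cohort simulation


def _default_outcome_model() -> dict:
    """Per-outcome (intercept, metric betas on z-scaled log metrics, noise SD).

    Effects are routed dominantly through ACS — the structure whose detection
    the association pipeline is meant to demonstrate — with a secondary D
    contribution; signs follow the physiology (larger clusters ⇒ worse
    function, lower D ⇒ worse).  Magnitudes give R² broadly in 0.2–0.8.
    """
    return {
        "fev1":     {"intercept": 2.6, "betas": {"acs": -0.62, "D": 0.12}, "sd": 0.45},
        "fvc":      {"intercept": 3.6, "betas": {"acs": -0.45, "D": 0.10}, "sd": 0.55},
        "fev1_fvc": {"intercept": 0.65, "betas": {"acs": -0.13, "D": 0.03}, "sd": 0.07},
        "frc":      {"intercept": 3.4, "betas": {"acs": 0.70, "D": -0.10}, "sd": 0.60},
        "frc_tlc":  {"intercept": 0.55, "betas": {"acs": 0.07, "D": -0.015}, "sd": 0.055},
        "six_mwd":  {"intercept": 1500.0, "betas": {"acs": -210.0, "D": 60.0}, "sd": 250.0},
        "sgrq":     {"intercept": 28.0, "betas": {"acs": 14.0, "D": -4.0}, "sd": 16.0},
        "pct_gt":   {"intercept": 22.0, "betas": {"acs": 10.0, "D": -2.0}, "sd": 7.0},
    }


def _default_biomarker_routes(n_null=10, n_burden=8, n_shared=8, n_pp=10) -> list[str]:
    """Effect route per marker: null, burden (%LAA), shared clustering factor
    (reachable by NJC/D, hence EHP2), or point-process-specific factor
    (reachable only through ACS/NC, hence EHP4)."""
    return (["null"] * n_null + ["burden"] * n_burden
            + ["shared"] * n_shared + ["pp"] * n_pp)


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of the synthetic cohort generator.

    Demographic marginals follow a typical heavy-smoker COPD study population
    (ages ~63±9, half male, quarter current smokers).  ``outcome_model`` maps
    outcome name → dict(intercept, betas on z-scaled log metrics, noise sd);
    ``biomarker_routes`` assigns each marker an effect route;
    ``censor_fractions`` gives per-marker target below-LLOQ fractions.
    """

    n_subjects: int = 300
    outcome_model: dict = field(default_factory=_default_outcome_model)
    biomarker_routes: list = field(default_factory=_default_biomarker_routes)
    biomarker_effect: float = 0.45
    censor_fractions: tuple | None = None   # default derived per route
    metric_noise: float = 0.22              # log-scale idiosyncratic SD on metrics

    def resolved_censoring(self) -> np.ndarray:
        if self.censor_fractions is not None:
            arr = np.asarray(self.censor_fractions, dtype=float)
            if len(arr) != len(self.biomarker_routes):
                raise ValueError("censor_fractions length must match biomarker_routes")
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("censoring fractions must be in [0, 1]")
            return arr
        # defaults: a few excluded-class markers, some binary, rest continuous
        n = len(self.biomarker_routes)
        fractions = np.zeros(n)
        for i in range(n):
            if i % 10 == 9:
                fractions[i] = 0.97          # excluded class (> 0.95)
            elif i % 10 in (7, 8):
                fractions[i] = 0.40          # binary class
            else:
                fractions[i] = 0.02          # continuous class
        return fractions


@dataclass(frozen=True)
class SimulatedCohort:
    cohort: pd.DataFrame         # demographics + metrics + outcomes + VA labels
    biomarkers: pd.DataFrame     # raw abundances, one column per marker
    lloq: pd.Series              # per-marker LLOQ
    truth: dict                  # latent factors and generative settings


def simulate_cohort(spec: CohortSpec, seed=None) -> SimulatedCohort:
    """Generate a cohort table with metrics, outcomes, VA labels and biomarkers."""
    rng = np.random.default_rng(seed)
    n = spec.n_subjects

    # demographics
    age = rng.normal(63.5, 8.6, n)
    sex_male = rng.random(n) < 0.51
    height = np.where(sex_male, rng.normal(176, 7, n), rng.normal(163, 7, n))
    bmi = rng.normal(28.3, 5.6, n).clip(15, 55)
    smoker = rng.random(n) < 0.25

    # latent factors: burden s, shared clustering g, point-process-specific h
    s = rng.beta(1.2, 2.5, n)
    g = rng.standard_normal(n)
    h = rng.standard_normal(n)
    e = lambda scale=1.0: rng.normal(0.0, spec.metric_noise * scale, n)

    pct_laa = np.exp(0.9 + 3.3 * s + e(0.7)).clip(0.05, 60.0)
    acs = np.exp(2.25 + 1.6 * s + 0.35 * g + 0.50 * h + e())
    nc = np.exp(2.25 + 1.2 * s + 0.25 * g - 0.40 * h + e())
    njc = pct_laa * (0.30 + 0.60 / (1.0 + np.exp(-(g + 1.5 * s)))) * np.exp(e(0.5))
    D = (1.82 - 0.38 * s - 0.07 * g + rng.normal(0, 0.07, n)).clip(1.05, None)
    pct_diffuse = 100.0 / (1.0 + np.exp(-(-0.3 - 2.0 * s - 0.7 * g + rng.normal(0, 0.4, n))))
    aca = np.exp(3.75 + 0.8 * s + 0.3 * g + e())

    metrics = pd.DataFrame({
        "pct_laa": pct_laa, "D": D, "njc": njc, "acs": acs,
        "nc": nc, "pct_diffuse": pct_diffuse, "aca": aca,
    })
    zlog = {m: _zscore(np.log(metrics[m].to_numpy())) for m in METRIC_NAMES}

    # outcomes: covariate effects + metric betas on z-scaled log metrics + noise
    cov_effect = (-0.01 * (age - 63.5) + 0.1 * sex_male.astype(float)
                  + 0.005 * (height - 170.0) - 0.005 * (bmi - 28.3)
                  - 0.05 * smoker.astype(float))
    outcomes = {}
    for name, model in spec.outcome_model.items():
        y = model["intercept"] + _outcome_scale(model) * cov_effect
        for metric, beta in model["betas"].items():
            y = y + beta * zlog[metric]
        outcomes[name] = y + rng.normal(0.0, model["sd"], n)

    # visual assessment: noisy monotone functions of true ACS / %LAA
    cle_latent = _zscore(np.log(acs)) + rng.normal(0, 0.6, n)
    cle = pd.Categorical.from_codes(
        np.digitize(cle_latent, [-1.2, -0.4, 0.3, 1.0, 1.7]), categories=CLE_LEVELS)
    para_latent = 0.5 * _zscore(np.log(pct_laa)) + rng.normal(0, 1.0, n)
    paraseptal = pd.Categorical.from_codes(
        np.digitize(para_latent, [0.8, 1.8]), categories=PARASEPTAL_LEVELS)

    cohort = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age": age, "sex_male": sex_male.astype(int), "bmi": bmi,
        "height": height, "smoker": smoker.astype(int),
        **{m: metrics[m] for m in METRIC_NAMES},
        **outcomes,
        "cle_va": cle, "paraseptal_va": paraseptal,
    })

    # biomarkers with LLOQ censoring
    routes = list(spec.biomarker_routes)
    censor = spec.resolved_censoring()
    route_signal = {"null": np.zeros(n), "burden": zlog["pct_laa"], "shared": g, "pp": h}
    marker_cols, lloqs = {}, {}
    for i, route in enumerate(routes):
        name = f"bm_{i:03d}_{route}"
        latent = spec.biomarker_effect * route_signal[route] + rng.standard_normal(n)
        abundance = np.exp(latent)
        lloq = float(np.quantile(abundance, censor[i])) if censor[i] > 0 else 0.0
        marker_cols[name] = abundance
        lloqs[name] = lloq
    biomarkers = pd.DataFrame(marker_cols, index=cohort.index)
    lloq_series = pd.Series(lloqs, name="lloq")

    truth = {"s": s, "g": g, "h": h, "routes": routes,
             "censor_fractions": censor, "spec": spec}
    return SimulatedCohort(cohort=cohort, biomarkers=biomarkers,
                           lloq=lloq_series, truth=truth)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _outcome_scale(model: dict) -> float:
    betas = np.array(list(model["betas"].values()))
    return float(np.abs(betas).max())
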
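"""Synthetic cohort and session generator with known ground truth.

The study data this package is designed for (longitudinal MRI/PET in
clinically normal older adults) are not publicly deposited, so everything the
analysis chain consumes is emulated here:

* spatial network template maps (smooth non-negative blobs standing in for
  rotated group-PCA component maps),
* 4D resting-state BOLD sessions (120 volumes at TR 3 s) built as
  template-shaped sources carrying band-limited time courses, plus
  motion-correlated and tissue-localized nuisance and Gaussian noise,
* 6-parameter motion tables and tissue probability maps,
* a longitudinal cortical-thickness cohort following a random-intercept /
  random-slope growth model in which baseline connectivity and amyloid burden
  interact on the thinning rate,
* a two-component amyloid (PiB DVR) mixture and PET ROI-mean uptake tables.

Each generator returns the planted ground truth alongside the data so that
recovery can be asserted in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionConfig",
    "CohortConfig",
    "FixedEffects",
    "TemplateSet",
    "BoldSeries",
    "MotionParams",
    "TissueMaps",
    "SessionTruth",
    "CohortTruth",
    "generate_templates",
    "generate_session",
    "generate_cohort",
    "generate_roi_uptake_table",
]

# Desikan-Killiany regions entering the frontal/lateral/retrosplenial (FLR)
# amyloid composite, both hemispheres.
FLR_REGIONS = (
    "precuneus",
    "rostralanteriorcingulate",
    "medialorbitofrontal",
    "superiorfrontal",
    "rostralmiddlefrontal",
    "inferiorparietal",
    "inferiortemporal",
    "middletemporal",
)
REFERENCE_REGION = "cerebellum_cortex"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TemplateSet:
    """Spatial network maps on a voxel grid (the template matrix IC).

    ``maps`` has shape ``(nx, ny, nz, k)``; ``names`` labels the k components.
    """

    maps: np.ndarray
    names: list[str]
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("template maps must be a 4D (x, y, z, component) array")
        if self.maps.shape[3] != len(self.names):
            raise ValueError("number of names must match number of maps")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("template maps must be finite")
        flat = self.flat()
        if np.any(np.all(flat == 0.0, axis=0)):
            raise ValueError("template set contains an all-zero map")

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.maps.shape[:3]

    @property
    def n_components(self) -> int:
        return self.maps.shape[3]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def flat(self) -> np.ndarray:
        """Maps as a (voxels, components) matrix, x-fastest linearization."""
        return self.maps.reshape(-1, self.maps.shape[3], order="F")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown template component {name!r}") from None


@dataclass
class BoldSeries:
    """One (preprocessed or raw) 4D BOLD session: grid x time, plus timing."""

    data: np.ndarray
    tr: float
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 volumes")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def flat(self) -> np.ndarray:
        """(voxels, volumes) view with x-fastest linearization."""
        return self.data.reshape(-1, self.data.shape[3], order="F")


@dataclass
class MotionParams:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("motion table must have 6 columns")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass
class TissueMaps:
    """Per-voxel tissue probabilities (each in [0, 1], sum <= 1 per voxel)."""

    wm: np.ndarray
    csf: np.ndarray
    bone: np.ndarray
    gm: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.wm, self.csf, self.bone, self.gm)}
        if len(shapes) != 1:
            raise ValueError("tissue maps must share a grid")
        for name in ("wm", "csf", "bone", "gm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            setattr(self, name, arr)

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.wm.shape

    def stacked(self) -> np.ndarray:
        """Classes stacked (4, nx, ny, nz) in fixed priority order WM, CSF, bone, GM."""
        return np.stack([self.wm, self.csf, self.bone, self.gm])


@dataclass
class SessionTruth:
    """Planted quantities for one session: source time courses and couplings."""

    timecourses: np.ndarray  # (n_volumes, n_sources), unit variance
    amplitudes: np.ndarray  # (n_sources,) planted coupling amplitudes
    nuisance_timecourses: np.ndarray | None = None


# ---------------------------------------------------------------------------
# session-level configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionConfig:
    """Generative parameters of a synthetic resting-state session.

    Defaults follow the emulated acquisition: 120 retained volumes at
    TR 3 s (a six-minute run after dummy-volume removal), with the planted
    sources band-limited inside the analysis passband so temporal filtering
    does not destroy them.
    """

    grid: tuple[int, int, int] = (12, 12, 12)
    n_volumes: int = 120
    tr: float = 3.0
    n_sources: int = 3
    source_amplitude: float = 1.0
    nuisance_amplitude: float = 0.5
    noise_sd: float = 0.5
    voxel_size_mm: float = 3.0
    band: tuple[float, float] = (0.08, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_sources < 1:
            raise ValueError("need at least one source")
        if int(np.prod(self.grid)) < self.n_sources:
            raise ValueError("grid volume must be at least n_sources")
        if not (0 < self.band[0] < self.band[1] < 0.5 / self.tr):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")


def _default_names(k: int) -> list[str]:
    base = ["DMN", "FPCN_L", "FPCN_R"]
    if k <= 3:
        return base[:k]
    return base + [f"NET{i:02d}" for i in range(4, k + 1)]


def generate_templates(config: SessionConfig) -> TemplateSet:
    """Build ``n_sources`` smooth non-negative spatial maps on the session grid.

    Each map is a Gaussian blob with a unique maximum voxel.  The first two
    components (a DMN analog and an FPCN analog) are placed close enough to
    overlap, mirroring spatially interdigitated cortical networks; remaining
    centers are drawn with a minimum-separation constraint.  Raises a sizing
    error when the grid cannot host the requested number of distinct maps.
    """
    if config.n_sources < 2:
        raise ValueError("generate_templates needs n_sources >= 2")
    grid = np.asarray(config.grid)
    if np.any(grid < 6):
        raise ValueError("grid too small to place distinct maps (min dim 6)")
    rng = np.random.default_rng(config.seed)
    sigma = max(1.2, float(grid.min()) / 8.0)
    center = (grid - 1) / 2.0

    centers = [center.copy()]
    # DMN / FPCN_L analog overlap: second blob offset by ~1 sigma along x
    offset = np.array([sigma, 0.0, 0.0])
    centers.append(np.clip(center + offset, 1, grid - 2))
    if config.n_sources >= 3:
        centers.append(np.clip(center - offset, 1, grid - 2))

    min_sep = max(2.0, sigma)
    attempts = 0
    while len(centers) < config.n_sources:
        cand = rng.uniform(1, grid - 2)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 2000:
            raise ValueError(
                "grid too small to place distinct maps for "
                f"{config.n_sources} sources"
            )

    ii, jj, kk = np.meshgrid(
        np.arange(grid[0]), np.arange(grid[1]), np.arange(grid[2]), indexing="ij"
    )
    # compactly supported blobs (clipped Gaussians, peak renormalized to 1):
    # the exact-zero skirt keeps the sources out of the nuisance tissue
    # classes so tissue PCs cannot soak up planted signal
    cut = 0.1
    maps = np.empty((*config.grid, config.n_sources))
    for m, c in enumerate(centers):
        d2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        maps[..., m] = np.clip(np.exp(-d2 / (2.0 * sigma**2)) - cut, 0.0, None) / (1.0 - cut)
    return TemplateSet(maps, _default_names(config.n_sources), config.voxel_size_mm)


def _bandlimited_timecourses(
    rng: np.random.Generator, n_volumes: int, tr: float, band: tuple[float, float], k: int
) -> np.ndarray:
    """Unit-variance time courses supported strictly inside the passband."""
    t = np.arange(n_volumes) * tr
    low, high = band
    margin = 0.1 * (high - low)
    out = np.empty((n_volumes, k))
    for m in range(k):
        freqs = rng.uniform(low + margin, high - margin, size=8)
        phases = rng.uniform(0, 2 * np.pi, size=8)
        s = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
        s -= s.mean()
        sd = s.std()
        if sd < 1e-12:  # pathological phase cancellation; retry deterministic-ish
            s = np.sin(2 * np.pi * 0.5 * (low + high) * t)
            s -= s.mean()
            sd = s.std()
        out[:, m] = s / sd
    return out


def _tissue_maps(grid: tuple[int, int, int], templates: TemplateSet) -> TissueMaps:
    g = np.asarray(grid)
    center = (g - 1) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(g[0]), np.arange(g[1]), np.arange(g[2]), indexing="ij"
    )
    d = np.sqrt((ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2)
    r = d / np.linalg.norm((g - 1) / 2.0)

    gm_support = templates.maps.sum(axis=3)
    gm_support = gm_support / max(gm_support.max(), 1e-12)

    # partition: gray matter wherever the network blobs have support; white
    # matter fills the interior strictly off-support; CSF and bone form outer
    # shells.  Keeping the nuisance classes clear of template support
    # prevents the tissue PCs from soaking up the planted sources.
    interior = (r <= 0.70) & (gm_support <= 0.0)
    wm = np.where(interior, 0.95, 0.02)
    csf = np.where((r > 0.70) & (r <= 0.88), 0.90, 0.02)
    bone = np.where(r > 0.88, 0.95, 0.01)
    gm = np.where(gm_support > 0, 0.85 * np.clip(gm_support + 0.15, None, 1.0), 0.0)

    total = wm + csf + bone + gm
    scale = np.where(total > 1.0, total, 1.0)
    return TissueMaps(wm / scale, csf / scale, bone / scale, gm / scale)


def generate_session(
    templates: TemplateSet,
    config: SessionConfig,
    coupling: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BoldSeries, MotionParams, TissueMaps, SessionTruth]:
    """Simulate one BOLD session from a template set.

    BOLD = sum_k a_k * map_k(v) * s_k(t) + tissue-localized, motion-correlated
    nuisance + white Gaussian noise.  ``coupling`` scales each source's
    amplitude (the controllable connectivity knob, default 1); with
    ``noise_sd = 0`` and ``nuisance_amplitude = 0`` the series equals the
    template-weighted time courses exactly.
    """
    if templates.grid != tuple(config.grid):
        raise ValueError("templates are not defined on the session grid")
    k = templates.n_components
    if coupling is None:
        coupling = np.ones(k)
    coupling = np.asarray(coupling, dtype=float)
    if coupling.shape != (k,):
        raise ValueError(f"coupling must have length {k}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    s = _bandlimited_timecourses(rng, config.n_volumes, config.tr, config.band, k)
    amps = config.source_amplitude * coupling
    bold = np.einsum("xyzk,tk->xyzt", templates.maps, s * amps)

    # motion: slow random walk plus jitter; rotations ~mrad scale
    steps = rng.normal(0.0, 1.0, size=(config.n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    jitter = rng.normal(0.0, 1.0, size=(config.n_volumes, 6))
    motion = 0.02 * walk + 0.05 * jitter
    motion[:, 3:] *= 0.02  # radians
    motion_tab = MotionParams(motion)

    tissues = _tissue_maps(config.grid, templates)

    nuis_tc = None
    if config.nuisance_amplitude > 0:
        t = np.arange(config.n_volumes) * config.tr
        fd_like = np.abs(np.diff(motion, axis=0, prepend=motion[:1])).sum(axis=1)
        fd_like = (fd_like - fd_like.mean()) / (fd_like.std() + 1e-12)
        nuis_tc = np.empty((config.n_volumes, 3))
        for c in range(3):
            drift = np.sin(2 * np.pi * rng.uniform(0.003, 0.02) * t + rng.uniform(0, 2 * np.pi))
            u = drift + 0.7 * fd_like + 0.3 * rng.normal(size=config.n_volumes)
            u = (u - u.mean()) / u.std()
            nuis_tc[:, c] = u
        for c, pmap in enumerate((tissues.wm, tissues.csf, tissues.bone)):
            bold += config.nuisance_amplitude * pmap[..., None] * nuis_tc[:, c]

    if config.noise_sd > 0:
        bold = bold + rng.normal(0.0, config.noise_sd, size=bold.shape)

    series = BoldSeries(bold, config.tr, config.voxel_size_mm)
    truth = SessionTruth(timecourses=s, amplitudes=amps, nuisance_timecourses=nuis_tc)
    return series, motion_tab, tissues, truth


# ---------------------------------------------------------------------------
# cohort-level configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedEffects:
    """Fixed-effect coefficients of the generative growth model.

    Thickness units are mm; time is years from first visit.  Coefficients
    apply to *centered* predictors: connectivity is zero-mean by construction,
    amyloid (PiB DVR) and the covariates are centered at their population
    means inside the generator.  Defaults are calibrated to study-like effect
    magnitudes: a mean thinning of ~0.01 mm/yr modulated by connectivity,
    amyloid, and their interaction.
    """

    intercept: float = 2.55
    time: float = -0.010
    fc: float = 0.0
    pib: float = 0.0
    fc_pib: float = 0.0
    fc_time: float = 0.030
    pib_time: float = -0.018
    fc_pib_time: float = 0.20
    age: float = -0.010
    sex: float = 0.05
    education: float = 0.0
    age_time: float = -0.0005
    sex_time: float = 0.0
    education_time: float = 0.0


# Visit-count distribution over 2..8 visits, matched to the reported cohort
# (4 subjects with 2 scans, 56 with 3, 60 with 4+; mean 3.6).
VISIT_COUNT_PROBS = np.array([4, 56, 47, 9, 2, 1, 1], dtype=float) / 120.0


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of the synthetic longitudinal cohort.

    Defaults reproduce the emulated study's structure: 120 subjects with 2-8
    MRI visits (mean 3.6) roughly every two years, baseline age 73.35 (SD 6),
    58% female, 16 years of education, and a two-component amyloid mixture
    with low/high means 1.08/1.46 (SD 0.1 each) weighted 87:33.
    """

    n_subjects: int = 120
    visit_range: tuple[int, int] = (2, 8)
    visit_interval: float = 1.94
    visit_jitter: float = 0.30
    baseline_age: tuple[float, float] = (73.35, 6.0)
    education: tuple[float, float] = (16.02, 2.9)
    p_female: float = 70.0 / 120.0
    fc_sd: float = 0.10
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    random_intercept_sd: float = 0.12
    random_slope_sd: float = 0.010
    random_corr: float = 0.0
    residual_sd: float = 0.05
    pib_means: tuple[float, float] = (1.08, 1.46)
    pib_sds: tuple[float, float] = (0.10, 0.10)
    pib_weights: tuple[float, float] = (87.0 / 120.0, 33.0 / 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.visit_range[0] < 2:
            raise ValueError("every subject needs at least two visits")
        for sd in (
            self.random_intercept_sd,
            self.random_slope_sd,
            self.residual_sd,
            self.fc_sd,
            *self.pib_sds,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if abs(sum(self.pib_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not -1.0 <= self.random_corr <= 1.0:
            raise ValueError("random_corr must lie in [-1, 1]")

    @property
    def pib_population_mean(self) -> float:
        w = self.pib_weights
        return w[0] * self.pib_means[0] + w[1] * self.pib_means[1]


@dataclass
class CohortTruth:
    """Planted subject-level quantities of a generated cohort."""

    fc: np.ndarray
    pib: np.ndarray
    pib_component: np.ndarray  # 0 = low, 1 = high mixture component
    random_intercepts: np.ndarray
    random_slopes: np.ndarray
    config: CohortConfig


def draw_pib_mixture(config: CohortConfig, n: int, rng: np.random.Generator):
    """Draw n amyloid DVR values from the two-component Gaussian mixture."""
    comp = (rng.random(n) < config.pib_weights[1]).astype(int)
    mu = np.asarray(config.pib_means)[comp]
    sd = np.asarray(config.pib_sds)[comp]
    return rng.normal(mu, sd), comp


def _visit_counts(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.visit_range
    support = np.arange(2, 9)
    probs = VISIT_COUNT_PROBS.copy()
    keep = (support >= lo) & (support <= hi)
    support, probs = support[keep], probs[keep]
    probs = probs / probs.sum()
    return rng.choice(support, size=config.n_subjects, p=probs)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate the longitudinal thickness table and its ground truth.

    Thickness follows
    ``y_it = b_0 + u_i + (b_t + b_fc FC_i + b_pib PiB_i + b_int FC_i PiB_i
    + covariate terms + v_i) t_it + level terms + e_it``
    with correlated per-subject random intercept ``u_i`` and slope ``v_i``.
    Predictors enter the formula centered (see :class:`FixedEffects`).

    Returns a long table with one row per visit (columns: subject, visit,
    time, thickness, fc_true, pib_dvr, age, sex, education) and the
    :class:`CohortTruth` sidecar.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    fe = config.fixed_effects

    fc = rng.normal(0.0, config.fc_sd, size=n)
    pib, comp = draw_pib_mixture(config, n, rng)
    age = rng.normal(*config.baseline_age, size=n)
    sex = (rng.random(n) < config.p_female).astype(float)  # 1 = female
    edu = rng.normal(*config.education, size=n)

    # correlated random intercept/slope via explicit Cholesky factors so that
    # zero SDs (degenerate noiseless cohorts) are handled exactly
    z = rng.standard_normal((n, 2))
    rho = config.random_corr
    b0 = config.random_intercept_sd * z[:, 0]
    b1 = config.random_slope_sd * (rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1])

    counts = _visit_counts(config, rng)

    pib_c = pib - config.pib_population_mean
    age_c = age - config.baseline_age[0]
    edu_c = edu - config.education[0]

    rows: list[tuple] = []
    for i in range(n):
        gaps = config.visit_interval + rng.uniform(
            -config.visit_jitter, config.visit_jitter, size=counts[i] - 1
        )
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        slope = (
            fe.time
            + fe.fc_time * fc[i]
            + fe.pib_time * pib_c[i]
            + fe.fc_pib_time * fc[i] * pib_c[i]
            + fe.age_time * age_c[i]
            + fe.sex_time * sex[i]
            + fe.education_time * edu_c[i]
            + b1[i]
        )
        level = (
            fe.intercept
            + b0[i]
            + fe.fc * fc[i]
            + fe.pib * pib_c[i]
            + fe.fc_pib * fc[i] * pib_c[i]
            + fe.age * age_c[i]
            + fe.sex * sex[i]
            + fe.education * edu_c[i]
        )
        eps = (
            rng.normal(0.0, config.residual_sd, size=counts[i])
            if config.residual_sd > 0
            else np.zeros(counts[i])
        )
        for j, t in enumerate(times):
            rows.append(
                (f"S{i:03d}", j, t, level + slope * t + eps[j],
                 fc[i], pib[i], age[i], sex[i], edu[i])
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "subject", "visit", "time", "thickness",
            "fc_true", "pib_dvr", "age", "sex", "education",
        ],
    )
    truth = CohortTruth(fc, pib, comp, b0, b1, config)
    return table, truth


def generate_roi_uptake_table(
    truth: CohortTruth,
    rng: np.random.Generator | None = None,
    roi_noise_sd: float = 0.01,
    reference_uptake: float = 1.0,
) -> pd.DataFrame:
    """PET ROI-mean uptake table consistent with the cohort's planted DVRs.

    Emits a long table (subject, region, uptake) with the 16 FLR target ROIs,
    bilateral inferior-temporal tau proxies, and the cerebellar-gray reference
    row, such that the FLR DVR recomputed downstream equals the planted DVR up
    to ROI-level noise.
    """
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 1)
    rows = []
    n = len(truth.pib)
    for i in range(n):
        sid = f"S{i:03d}"
        base = truth.pib[i] * reference_uptake
        uptakes = base + rng.normal(0.0, roi_noise_sd, size=16)
        # zero-sum perturbation keeps the 16-ROI mean exactly at the planted DVR
        uptakes -= uptakes.mean() - base
        j = 0
        for region in FLR_REGIONS:
            for hemi in ("lh", "rh"):
                rows.append((sid, f"{hemi}_{region}", max(uptakes[j], 0.0)))
                j += 1
        rows.append((sid, REFERENCE_REGION, reference_uptake))
    return pd.DataFrame(rows, columns=["subject", "region", "uptake"])


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Convenience: a copy of the cohort config with a different seed."""
    return replace(config, seed=seed)
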
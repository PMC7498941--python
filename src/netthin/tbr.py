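"""Template Based Rotation (TBR) connectivity.

Given fixed spatial template maps IC (voxels x components) and a session's
data matrix X (voxels x volumes), the network time courses are the
least-squares solution M = pinv(X) . IC — the per-volume weights whose
template-weighted volume sum best recapitulates each spatial pattern.  A
network's whole-network connectivity is the average Pearson correlation
between its TBR time course and the series of every voxel inside the
network mask (voxels above 40% of the template's maximum by default).
Between-subject variance tied to head motion (mean framewise displacement)
and data dimensionality (retained nuisance-PC count) is regressed out across
subjects before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from netthin.synth import BoldSeries, TemplateSet

__all__ = [
    "NetworkMask",
    "tbr_timecourses",
    "network_mask",
    "network_connectivity",
    "bilateral_average",
    "cross_network_connectivity",
    "residualize_between_subject",
]

logger = logging.getLogger(__name__)


@dataclass
class NetworkMask:
    """Boolean voxel mask derived from one template component."""

    mask: np.ndarray  # boolean, template grid shape
    component: str
    fraction: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"empty network mask for component {self.component!r}")

    def flat(self) -> np.ndarray:
        return self.mask.reshape(-1, order="F")


def tbr_timecourses(
    series: BoldSeries, templates: TemplateSet, rcond: float | None = None
) -> np.ndarray:
    """Network time courses M = pinv(X) . IC (volumes x components).

    The pseudo-inverse is computed by SVD, equivalent to the minimum-norm
    least-squares solution of X . M ~ IC.  ``rcond`` truncates singular
    values below ``rcond * sigma_1`` (None uses numpy's machine-precision
    cutoff).  For temporally filtered sessions a substantial cutoff (the
    pipeline uses 0.1) is advisable: the filter's transition band leaves a
    tail of tiny singular values whose noise-only directions are amplified
    by 1/sigma and would otherwise dominate the solution.
    """
    if series.grid != templates.grid:
        raise ValueError("BOLD series and templates must share the voxel grid")
    x = series.flat()  # voxels x volumes
    if not np.any(x):
        raise ValueError("degenerate input: all-zero BOLD series")
    if rcond is None:
        return np.linalg.pinv(x) @ templates.flat()
    return np.linalg.pinv(x, rcond=rcond) @ templates.flat()


def network_mask(
    templates: TemplateSet, component: str, fraction: float = 0.4
) -> NetworkMask:
    """Voxels strictly above ``fraction`` x the component map's maximum."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    idx = templates.index(component)
    m = templates.maps[..., idx]
    mask = m > fraction * m.max()
    return NetworkMask(mask, component, fraction)


def _masked_mean_correlation(
    series: BoldSeries, tc: np.ndarray, flat_mask: np.ndarray, fisher: bool
) -> float:
    vox = series.flat()[flat_mask]
    t = tc - tc.mean()
    t_norm = np.linalg.norm(t)
    if t_norm < 1e-12:
        raise ValueError("network time course has zero variance")
    v = vox - vox.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(v, axis=1)
    ok = norms > 1e-12
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluded %d zero-variance voxel series", n_excluded)
    if not ok.any():
        raise ValueError("all in-mask voxels have zero variance")
    r = (v[ok] @ t) / (norms[ok] * t_norm)
    r = np.clip(r, -1.0, 1.0)
    if fisher:
        return float(np.tanh(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)).mean()))
    return float(r.mean())


def network_connectivity(
    series: BoldSeries,
    timecourses: np.ndarray,
    templates: TemplateSet,
    mask: NetworkMask,
    fisher: bool = False,
) -> float:
    """Whole-network connectivity of one component.

    Mean Pearson correlation, over in-mask voxels of the cleaned series,
    between each voxel's time series and the component's TBR time course.
    Zero-variance voxels are excluded (logged); ``fisher=True`` averages on
    the Fisher-z scale instead of the plain mean of r.
    """
    if series.grid != mask.mask.shape:
        raise ValueError("series and mask must share the voxel grid")
    tc = timecourses[:, templates.index(mask.component)]
    if tc.shape[0] != series.n_volumes:
        raise ValueError("time course length must equal the number of volumes")
    return _masked_mean_correlation(series, tc, mask.flat(), fisher)


def bilateral_average(left: float, right: float) -> float:
    """Arithmetic mean of left/right hemisphere network measures."""
    return 0.5 * (left + right)


def cross_network_connectivity(
    series: BoldSeries,
    timecourses: np.ndarray,
    templates: TemplateSet,
    inner: NetworkMask,
    outer: NetworkMask,
    fisher: bool = False,
) -> float:
    """Inter-network measure: inner-mask voxels against the outer network's time course.

    E.g. with ``inner`` = FPCN and ``outer`` = DMN this is the
    FPCN-within-DMN measure: the mean correlation, over voxels in the mask
    intersection, between the voxel series and the DMN TBR time course.  The
    symmetric variant swaps the roles.  Raises on an empty intersection.
    """
    both = inner.mask & outer.mask
    if not both.any():
        raise ValueError(
            f"masks {inner.component!r} and {outer.component!r} do not overlap"
        )
    tc = timecourses[:, templates.index(outer.component)]
    return _masked_mean_correlation(series, tc, both.reshape(-1, order="F"), fisher)


def residualize_between_subject(
    values: np.ndarray, mean_fd: np.ndarray, n_retained_pcs: np.ndarray
) -> np.ndarray:
    """Remove between-subject variance tied to motion and dimensionality.

    Across subjects, the raw connectivity values are regressed on
    [intercept, mean framewise displacement, retained-PC count]; the OLS
    residuals are the adjusted values, exactly uncorrelated with both
    covariates in-sample.
    """
    values = np.asarray(values, dtype=float)
    fd = np.asarray(mean_fd, dtype=float)
    pcs = np.asarray(n_retained_pcs, dtype=float)
    n = values.shape[0]
    if fd.shape[0] != n or pcs.shape[0] != n:
        raise ValueError("values and covariates must have one row per subject")
    if n < 4:
        raise ValueError("need at least 4 subjects to residualize")
    design = np.column_stack([np.ones(n), fd, pcs])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("collinear covariates in between-subject residualization")
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta
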
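"""Amyloid and tau PET quantification from ROI-mean uptake tables.

The continuous amyloid measure is the FLR DVR: the mean tracer uptake over
16 frontal/lateral/retrosplenial Desikan-Killiany ROIs (8 regions, both
hemispheres) divided by cerebellar-gray uptake.  Neocortical tau is proxied
by the inferior-temporal SUVR (bilateral mean over cerebellar gray).
Subjects are dichotomised into low/high amyloid groups at a fixed DVR
cutoff (default 1.186, the published threshold of the emulated protocol);
alternatively a cutoff can be re-derived from the sample as the
equal-posterior crossing point of a two-component Gaussian mixture fitted
by EM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from netthin.synth import FLR_REGIONS, REFERENCE_REGION

__all__ = [
    "FLR_ROIS",
    "DEFAULT_CUTOFF",
    "flr_dvr",
    "it_suvr",
    "gmm_cutoff",
    "classify_amyloid",
]

FLR_ROIS = tuple(f"{h}_{r}" for r in FLR_REGIONS for h in ("lh", "rh"))
IT_ROIS = ("lh_inferiortemporal", "rh_inferiortemporal")
DEFAULT_CUTOFF = 1.186


def _uptake_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (subject, region, uptake) table to subjects x regions."""
    required = {"subject", "region", "uptake"}
    if not required.issubset(table.columns):
        raise ValueError(f"ROI table needs columns {sorted(required)}")
    if (table["uptake"] < 0).any():
        raise ValueError("uptake values must be non-negative")
    return table.pivot_table(index="subject", columns="region", values="uptake")


def _reference(wide: pd.DataFrame) -> pd.Series:
    if REFERENCE_REGION not in wide.columns:
        raise ValueError(f"missing reference region {REFERENCE_REGION!r}")
    ref = wide[REFERENCE_REGION]
    if (ref <= 0).any() or ref.isna().any():
        raise ValueError("reference uptake must be positive for every subject")
    return ref


def flr_dvr(table: pd.DataFrame) -> pd.Series:
    """FLR DVR per subject: mean of 16 target-ROI uptakes over cerebellar gray."""
    wide = _uptake_wide(table)
    missing = [r for r in FLR_ROIS if r not in wide.columns or wide[r].isna().any()]
    if missing:
        raise ValueError(f"missing FLR ROI(s): {missing}")
    ref = _reference(wide)
    return (wide[list(FLR_ROIS)].mean(axis=1) / ref).rename("flr_dvr")


def it_suvr(table: pd.DataFrame) -> pd.Series:
    """Inferior-temporal SUVR per subject: bilateral IT mean over cerebellar gray."""
    wide = _uptake_wide(table)
    missing = [r for r in IT_ROIS if r not in wide.columns or wide[r].isna().any()]
    if missing:
        raise ValueError(f"missing inferior-temporal ROI(s): {missing}")
    ref = _reference(wide)
    return (wide[list(IT_ROIS)].mean(axis=1) / ref).rename("it_suvr")


def gmm_cutoff(
    dvr_values: np.ndarray,
    n_components: int = 2,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> float:
    """Amyloid positivity cutoff from a two-component Gaussian mixture.

    Fits a univariate GMM by EM (k-means init, ``n_init`` restarts) and
    returns the equal-posterior crossing point of the two components between
    their means.  Errors on non-convergence or a degenerate (near-zero
    variance) component.
    """
    x = np.asarray(dvr_values, dtype=float).ravel()
    if n_components != 2:
        raise ValueError("cutoff derivation expects exactly 2 components")
    if x.size < 20:
        raise ValueError("need at least 20 values to fit the mixture")
    if np.ptp(x) < 1e-10:
        raise ValueError("degenerate input: all DVR values identical")
    gm = GaussianMixture(
        n_components=2,
        n_init=n_init,
        tol=tol,
        max_iter=max_iter,
        init_params="kmeans",
        random_state=seed,
    )
    gm.fit(x[:, None])
    if not gm.converged_:
        raise RuntimeError(f"EM did not converge within {max_iter} iterations")
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    if np.any(sd < 1e-6 * max(np.std(x), 1e-12)) or mu[1] - mu[0] < 1e-9:
        raise RuntimeError("degenerate mixture component (collapsed variance or means)")

    def diff(t: float) -> float:
        return w[0] * norm.pdf(t, mu[0], sd[0]) - w[1] * norm.pdf(t, mu[1], sd[1])

    lo, hi = float(mu[0]), float(mu[1])
    if diff(lo) <= 0 or diff(hi) >= 0:
        raise RuntimeError("no posterior crossing point between the component means")
    return float(brentq(diff, lo, hi))


def classify_amyloid(dvr, cutoff: float = DEFAULT_CUTOFF):
    """Dichotomise DVR at the cutoff: strictly above -> 'high', else 'low'.

    The boundary value itself classifies as 'low'.  Accepts a scalar or an
    array/Series and returns the matching type.
    """
    arr = np.asarray(dvr, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("DVR values must be positive")
    out = np.where(arr > cutoff, "high", "low")
    if np.isscalar(dvr) or arr.ndim == 0:
        return str(out)
    if isinstance(dvr, pd.Series):
        return pd.Series(out, index=dvr.index, name="amyloid_group")
    return out
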
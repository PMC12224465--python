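"""Global signal extraction and per-subject GS-coupling topography maps.

The global signal (GS) is the unweighted mean time series over gray-matter
voxels (probability mask, strict > threshold).  Each voxel's series is then
regressed on [1, GS] over retained frames; the slope is the voxel's GS
coupling (beta) and its t statistic is mapped through the t CDF to a standard
normal quantile (z).  Infinite z values are capped at a documented ceiling.
The alternative Fisher-z-of-correlation dialect is available via config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import BoldRun, Phenotype
from .exceptions import DegenerateError, InsufficientDataError, ShapeError
from .preprocess import CensorMask

__all__ = [
    "GsSeries",
    "TopographyMap",
    "gray_mask",
    "compute_gs",
    "topography_map",
    "decade_average_maps",
    "GsTopographyRegressor",
    "t_to_z",
]

Z_CAP = 8.2


@dataclass
class GsSeries:
    """The global signal of one run."""

    values: np.ndarray
    mask_voxel_count: int
    source_pipeline: str = ""


@dataclass
class TopographyMap:
    """Per-voxel GS-coupling statistic volume (beta and z forms)."""

    beta: np.ndarray
    z: np.ndarray
    retained_frames: int
    subject_id: str


def gray_mask(gm_probability: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Boolean gray-matter mask: probability strictly greater than ``threshold``."""
    mask = np.asarray(gm_probability) > threshold
    if not mask.any():
        raise DegenerateError("gray-matter mask is empty")
    return mask


def compute_gs(run: BoldRun, mask: np.ndarray, source_pipeline: str = "") -> GsSeries:
    """Unweighted mean time series over mask voxels."""
    if mask.shape != run.data.shape[:3]:
        raise ShapeError(f"mask shape {mask.shape} != volume shape {run.data.shape[:3]}")
    if not mask.any():
        raise DegenerateError("mask selects no voxels")
    return GsSeries(values=run.data[mask].mean(axis=0).astype(float),
                    mask_voxel_count=int(mask.sum()),
                    source_pipeline=source_pipeline)


def t_to_z(tvals: np.ndarray, df: int, cap: float = Z_CAP) -> np.ndarray:
    """Map t statistics to standard normal quantiles through the t CDF.

    Uses survival functions on each sign for numerical stability; infinities
    and overflow are capped at ±``cap``.
    """
    tvals = np.asarray(tvals, dtype=float)
    z = np.empty_like(tvals)
    pos = tvals >= 0
    with np.errstate(divide="ignore"):
        z[pos] = stats.norm.isf(stats.t.sf(tvals[pos], df))
        z[~pos] = -stats.norm.isf(stats.t.sf(-tvals[~pos], df))
    return np.clip(np.nan_to_num(z, nan=0.0, posinf=cap, neginf=-cap), -cap, cap)


class GsTopographyRegressor(BaseEstimator):
    """Per-voxel OLS of voxel series on [1, GS] over retained frames.

    Fitted attributes: ``beta_`` (slopes), ``tstat_``, ``z_``, ``df_``.
    ``z_dialect='fisher'`` instead reports the Fisher z of the voxel-GS
    correlation (config dialect; the t-CDF route is the default).
    """

    def __init__(self, z_dialect="tcdf", z_cap=Z_CAP):
        self.z_dialect = z_dialect
        self.z_cap = z_cap

    def fit(self, X, gs, keep=None):
        """X: T x V voxel matrix; gs: length-T global signal."""
        X = np.asarray(X, dtype=float)
        gs = np.asarray(gs, dtype=float)
        if X.shape[0] != gs.shape[0]:
            raise ShapeError("voxel matrix and GS disagree on frame count")
        if keep is not None and not np.all(keep):
            X, gs = X[keep], gs[keep]
        n = X.shape[0]
        if n < 20:
            raise InsufficientDataError(f"only {n} retained frames (< 20)")
        gc = gs - gs.mean()
        ss_g = float(gc @ gc)
        if ss_g <= 0:
            raise DegenerateError("GS has zero variance over retained frames")
        xc = X - X.mean(axis=0)
        beta = (gc @ xc) / ss_g
        resid = xc - np.outer(gc, beta)
        df = n - 2
        sigma2 = (resid**2).sum(axis=0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / np.sqrt(sigma2 / ss_g)
        tstat = np.nan_to_num(tstat, nan=0.0, posinf=np.inf, neginf=-np.inf)
        self.beta_ = beta
        self.tstat_ = tstat
        self.df_ = df
        self.n_retained_ = n
        if self.z_dialect == "fisher":
            r = np.clip(beta * np.sqrt(ss_g) / np.sqrt((xc**2).sum(axis=0)), -1, 1)
            with np.errstate(divide="ignore"):
                self.z_ = np.clip(np.arctanh(r), -self.z_cap, self.z_cap)
        else:
            self.z_ = t_to_z(tstat, df, cap=self.z_cap)
        return self


def topography_map(run: BoldRun, gs: GsSeries, censor: CensorMask | None = None,
                   mask: np.ndarray | None = None,
                   z_dialect: str = "tcdf") -> TopographyMap:
    """Whole-brain voxel-wise GS-coupling map for one run.

    ``mask`` limits the map support (non-mask voxels are NaN); default is the
    full grid.  With a censor mask, only retained frames enter the regression.
    """
    shape = run.data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if mask.shape != shape:
        raise ShapeError("mask shape mismatch")
    if len(gs.values) != run.t_frames:
        raise ShapeError("GS length does not match run")
    X = run.data[mask].T.astype(float)       # T x V_mask
    keep = None if censor is None else censor.keep
    reg = GsTopographyRegressor(z_dialect=z_dialect).fit(X, gs.values, keep=keep)
    beta = np.full(shape, np.nan)
    z = np.full(shape, np.nan)
    beta[mask] = reg.beta_
    z[mask] = reg.z_
    return TopographyMap(beta=beta, z=z, retained_frames=reg.n_retained_,
                         subject_id=run.phenotype_ref)


def decade_average_maps(maps: list[TopographyMap], phenotypes: list[Phenotype],
                        min_bin_size: int = 3) -> dict[int, dict]:
    """Voxel-wise mean z maps per 10-year age bin.

    Returns {decade: {"mean_z": volume, "n": count, "flagged": bool}} where
    decade = floor(age / 10) and bins with fewer than ``min_bin_size``
    subjects are flagged.
    """
    if len(maps) != len(phenotypes):
        raise ShapeError("one map per phenotype required")
    bins: dict[int, list[np.ndarray]] = {}
    for m, ph in zip(maps, phenotypes):
        bins.setdefault(int(ph.age // 10), []).append(m.z)
    out = {}
    for dec in sorted(bins):
        stack = np.stack(bins[dec])
        out[dec] = {"mean_z": stack.mean(axis=0), "n": stack.shape[0],
                    "flagged": stack.shape[0] < min_bin_size}
    return out
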
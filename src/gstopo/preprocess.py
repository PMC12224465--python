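"""Nuisance regression and filtering stages shared by all pipelines.

Stage orders are fixed and named:

* ``mp``   — smooth -> bandpass (minimal preprocessing);
* ``cr``   — smooth -> nuisance regression (Friston-24 + WM/CSF + detrend)
  -> bandpass (covariate regression);
* ``tica`` — smooth -> ICA cascade cleanup (see :mod:`gstopo.ica`).

The bandpass is a frequency-domain ideal filter (bit-reproducible and exactly
idempotent), a documented dialect difference from IIR implementations.
Scrubbing censors frames with FD > 0.5 mm from *regression estimation* only;
censored frames are never interpolated and residuals are evaluated at all
frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import BoldRun, replace_data
from .exceptions import InsufficientDataError, ParameterError, ShapeError

__all__ = [
    "NuisanceSet",
    "CensorMask",
    "friston24",
    "regress_nuisance",
    "bandpass",
    "gaussian_smooth",
    "make_censor_mask",
    "tissue_mean_series",
    "NuisanceRegressor",
    "BandpassFilter",
    "GaussianSmoother",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceSet:
    """A T x Q nuisance regressor matrix with column labels."""

    regressors: np.ndarray
    names: list[str]
    detrend_flag: bool = False

    def __post_init__(self):
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] != len(self.names):
            raise ShapeError("names must match regressor columns")

    def stacked_with(self, other: "NuisanceSet") -> "NuisanceSet":
        if other.regressors.shape[0] != self.regressors.shape[0]:
            raise ShapeError("regressor row counts differ")
        return NuisanceSet(
            np.hstack([self.regressors, other.regressors]),
            self.names + other.names,
            self.detrend_flag or other.detrend_flag,
        )


@dataclass
class CensorMask:
    """Frame retention mask from the FD scrubbing rule (strict > threshold)."""

    keep: np.ndarray
    threshold: float

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())

    def censored_seconds(self, tr: float) -> float:
        """Duration of censored data in seconds at repetition time ``tr``."""
        return self.n_censored * float(tr)


def make_censor_mask(fd_trace: np.ndarray, threshold: float = 0.5,
                     min_retained: int = 20) -> CensorMask:
    """Scrubbing mask: a frame is censored iff its FD strictly exceeds ``threshold``."""
    fd = np.asarray(fd_trace, dtype=float)
    keep = ~(fd > threshold)
    if keep.sum() < min_retained:
        raise InsufficientDataError(
            f"only {int(keep.sum())} frames retained (< {min_retained})")
    return CensorMask(keep=keep, threshold=float(threshold))


def friston24(motion_params: np.ndarray) -> NuisanceSet:
    """Friston-24 expansion of 6 rigid-body motion parameters.

    For each parameter m: [m(t), m(t-1), m(t)^2, m(t-1)^2], 24 columns total.
    The lagged term at t=0 is zero-padded.
    """
    m = np.asarray(motion_params, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ShapeError(f"motion parameters must be (T, 6), got {m.shape}")
    if m.shape[0] < 2:
        raise ShapeError("need at least 2 frames for the lagged expansion")
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    cols, names = [], []
    for j in range(6):
        cols += [m[:, j], lag[:, j], m[:, j] ** 2, lag[:, j] ** 2]
        names += [f"m{j}", f"m{j}_lag", f"m{j}_sq", f"m{j}_lag_sq"]
    return NuisanceSet(np.column_stack(cols), names)


def tissue_mean_series(run: BoldRun, labels: np.ndarray, label_values) -> np.ndarray:
    """Mean time series over the voxels whose label is in ``label_values``."""
    mask = np.isin(labels, np.atleast_1d(label_values))
    if not mask.any():
        raise ShapeError("tissue mask is empty")
    return run.data[mask].mean(axis=0)


class NuisanceRegressor(BaseEstimator, TransformerMixin):
    """OLS nuisance removal over a T x V data matrix.

    The design is [intercept | regressors | linear trend (if detrend)].
    Coefficients are estimated on retained frames only (``keep``); residuals
    are evaluated at every frame, so censored-frame values never influence the
    fit.  Rank-deficient designs fall back to the pseudoinverse with a warning.
    """

    def __init__(self, regressors=None, detrend=False, keep=None):
        self.regressors = regressors
        self.detrend = detrend
        self.keep = keep

    def _design(self, t_frames: int) -> np.ndarray:
        cols = [np.ones(t_frames)]
        if self.regressors is not None:
            reg = np.atleast_2d(np.asarray(self.regressors, dtype=float))
            if reg.shape[0] != t_frames:
                raise ShapeError("regressor rows must equal the frame count")
            cols.append(reg)
        if self.detrend:
            cols.append(np.linspace(-1.0, 1.0, t_frames)[:, None])
        return np.column_stack(cols)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        t = X.shape[0]
        design = self._design(t)
        keep = np.ones(t, dtype=bool) if self.keep is None else np.asarray(self.keep, bool)
        if keep.shape != (t,):
            raise ShapeError("keep mask length must equal the frame count")
        dk = design[keep]
        rank = np.linalg.matrix_rank(dk)
        if rank < dk.shape[1]:
            warnings.warn("rank-deficient nuisance design; using pseudoinverse",
                          stacklevel=2)
            self.coef_ = np.linalg.pinv(dk) @ X[keep]
        else:
            self.coef_, *_ = np.linalg.lstsq(dk, X[keep], rcond=None)
        self.design_ = design
        self.keep_ = keep
        self.rank_ = int(rank)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X - self.design_ @ self.coef_


def regress_nuisance(run: BoldRun, nuisance: NuisanceSet | None,
                     censor: CensorMask | None = None) -> BoldRun:
    """Replace every voxel's series by its OLS residual (intercept always included)."""
    t = run.t_frames
    flat = run.data.reshape(-1, t).T.astype(float)        # T x V
    reg = None if nuisance is None else nuisance.regressors
    detrend = False if nuisance is None else nuisance.detrend_flag
    keep = None if censor is None else censor.keep
    nr = NuisanceRegressor(regressors=reg, detrend=detrend, keep=keep).fit(flat)
    resid = nr.transform(flat)
    return replace_data(run, resid.T.reshape(run.data.shape).astype(np.float32))


class BandpassFilter(BaseEstimator, TransformerMixin):
    """Ideal frequency-domain bandpass over a T x V matrix (axis 0 = time).

    Fourier components with f < low or f > high are zeroed; the temporal mean
    is removed first and restored afterwards.  Exactly idempotent.
    """

    def __init__(self, tr=1.4, low=0.01, high=0.1):
        self.tr = tr
        self.low = low
        self.high = high

    def fit(self, X=None, y=None):
        nyquist = 1.0 / (2.0 * self.tr)
        if self.high <= self.low:
            raise ParameterError("high cutoff must exceed low cutoff")
        if self.high > nyquist + 1e-12:
            raise ParameterError(f"high cutoff {self.high} Hz exceeds Nyquist {nyquist:.4f} Hz")
        return self

    def transform(self, X):
        self.fit()
        X = np.asarray(X, dtype=float)
        t = X.shape[0]
        mean = X.mean(axis=0, keepdims=True)
        spec = np.fft.rfft(X - mean, axis=0)
        freqs = np.fft.rfftfreq(t, d=self.tr)
        spec[(freqs < self.low) | (freqs > self.high)] = 0.0
        return np.fft.irfft(spec, n=t, axis=0) + mean


def bandpass(run: BoldRun, low: float = 0.01, high: float = 0.1) -> BoldRun:
    """Per-voxel ideal bandpass of a BOLD run."""
    flat = run.data.reshape(-1, run.t_frames).T
    out = BandpassFilter(tr=run.tr, low=low, high=high).fit().transform(flat)
    return replace_data(run, out.T.reshape(run.data.shape).astype(np.float32))


class GaussianSmoother(BaseEstimator, TransformerMixin):
    """Separable spatial Gaussian smoothing of 4D volumes (reflective boundary)."""

    def __init__(self, fwhm=6.0, voxel_size=3.0):
        self.fwhm = fwhm
        self.voxel_size = voxel_size

    def fit(self, X=None, y=None):
        if self.fwhm < 0:
            raise ParameterError("fwhm must be nonnegative")
        return self

    def transform(self, X):
        self.fit()
        if self.fwhm == 0:
            return np.asarray(X, dtype=float).copy()
        sigma = self.fwhm * _FWHM_TO_SIGMA / self.voxel_size
        sigmas = (sigma, sigma, sigma, 0) if X.ndim == 4 else (sigma,) * X.ndim
        return ndimage.gaussian_filter(np.asarray(X, dtype=float), sigma=sigmas,
                                       mode="reflect")


def gaussian_smooth(run: BoldRun, fwhm: float) -> BoldRun:
    """Spatial Gaussian smoothing with kernel FWHM in mm."""
    sm = GaussianSmoother(fwhm=fwhm, voxel_size=run.voxel_size)
    return replace_data(run, sm.fit().transform(run.data).astype(np.float32))
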
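"""Group-level voxel-wise GLMs for age effects with cluster-level inference.

Two models are used: linear (intercept, z-age, centered mean FD, centered sex)
and quadratic (adds centered z-age^2).  Age is standardized before squaring and
the quadratic column is centered, which makes the linear and quadratic columns
near-orthogonal for age distributions symmetric about their mean.

Cluster correction follows standard Gaussian-random-field practice: residual
smoothness (per-axis FWHM) is estimated from the variance of spatial first
differences of standardized residuals, resels are mask volume over the product
of FWHMs, the expected number of clusters above the threshold comes from the
EC densities of a 3D stationary Gaussian field, and the cluster-size tail is
the classic exp(-beta * k^(2/3)) form.  A Freedman-Lane permutation engine
provides the assumption-free check of the GRF p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .cohort import Phenotype
from .exceptions import DegenerateError, ParameterError, ShapeError
from .topography import TopographyMap, t_to_z

__all__ = [
    "DesignMatrix",
    "GroupGlmResult",
    "build_design",
    "voxelwise_glm",
    "estimate_smoothness",
    "grf_cluster_correct",
    "permutation_cluster_null",
    "cluster_scatter",
    "MassUnivariateGLM",
    "stack_maps",
]


@dataclass
class DesignMatrix:
    """N x P design with named columns and named contrast vectors."""

    matrix: np.ndarray
    column_names: list[str]
    contrast_vectors: dict[str, np.ndarray]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def drop_column(self, name: str) -> "DesignMatrix":
        j = self.column_names.index(name)
        keep = [i for i in range(self.p) if i != j]
        contrasts = {k: v[keep] for k, v in self.contrast_vectors.items()
                     if v[j] == 0}
        return DesignMatrix(self.matrix[:, keep],
                            [self.column_names[i] for i in keep], contrasts)


@dataclass
class GroupGlmResult:
    """Voxel-wise effect/t/z volumes for one contrast plus smoothness info."""

    effect: np.ndarray
    tstat: np.ndarray
    zstat: np.ndarray
    residual_fwhm: np.ndarray      # per-axis, mm
    resel_count: float
    df: int
    mask: np.ndarray
    voxel_size: float
    contrast: str
    residuals: np.ndarray | None = field(default=None, repr=False)  # N x Vmask


def build_design(phenotypes: list[Phenotype], quadratic: bool = False,
                 extra: dict[str, np.ndarray] | None = None) -> DesignMatrix:
    """Design matrix [intercept, z(age), (z(age)^2 centered), FD, sex, extras].

    All covariates except the intercept are centered; contrasts "age_linear"
    and (if quadratic) "age_quadratic" are unit vectors on their columns.
    """
    age = np.array([p.age for p in phenotypes], dtype=float)
    if age.std() == 0:
        raise DegenerateError("ages are constant; design is rank deficient")
    z = (age - age.mean()) / age.std()
    fd = np.array([p.mean_fd for p in phenotypes], dtype=float)
    sex = np.array([p.sex for p in phenotypes], dtype=float)

    cols = [np.ones(len(phenotypes)), z]
    names = ["intercept", "age_linear"]
    if quadratic:
        q = z**2
        cols.append(q - q.mean())
        names.append("age_quadratic")
    cols.append(fd - fd.mean())
    names.append("mean_fd")
    cols.append(sex - sex.mean())
    names.append("sex")
    for key, val in (extra or {}).items():
        val = np.asarray(val, dtype=float)
        cols.append(val - val.mean())
        names.append(key)

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns by checking rank with each one removed
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise DegenerateError(f"design is rank deficient; collinear columns: {bad}")

    contrasts = {}
    for cname in ("age_linear", "age_quadratic"):
        if cname in names:
            v = np.zeros(X.shape[1])
            v[names.index(cname)] = 1.0
            contrasts[cname] = v
    return DesignMatrix(X, names, contrasts)


class MassUnivariateGLM(BaseEstimator):
    """OLS fitted independently at every voxel (shared design).

    Fitted attributes: ``coef_`` (P x V), ``sigma2_``, ``df_``, ``residuals_``.
    ``contrast_stats(c)`` returns (effect, t, z) arrays for a P-vector c.
    """

    def __init__(self, z_cap=8.2):
        self.z_cap = z_cap

    def fit(self, X, Y):
        """X: N x P design; Y: N x V responses."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ShapeError("design and response row counts differ")
        n, p = X.shape
        self.xtx_inv_ = np.linalg.inv(X.T @ X)
        self.coef_ = self.xtx_inv_ @ (X.T @ Y)
        self.residuals_ = Y - X @ self.coef_
        self.df_ = n - p
        if self.df_ <= 0:
            raise DegenerateError("no residual degrees of freedom")
        self.sigma2_ = (self.residuals_**2).sum(axis=0) / self.df_
        return self

    def contrast_stats(self, c):
        c = np.asarray(c, dtype=float)
        effect = c @ self.coef_
        var_c = float(c @ self.xtx_inv_ @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / np.sqrt(self.sigma2_ * var_c)
        t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
        return effect, t, t_to_z(t, self.df_, cap=self.z_cap)


def stack_maps(maps: list[TopographyMap], use: str = "z") -> tuple[np.ndarray, np.ndarray]:
    """Stack subject maps into (N x Vmask, mask); mask = voxels finite in all."""
    vols = [getattr(m, use) for m in maps]
    shape = vols[0].shape
    if any(v.shape != shape for v in vols):
        raise ShapeError("subject maps have inconsistent shapes")
    stack = np.stack(vols)
    mask = np.isfinite(stack).all(axis=0)
    return stack[:, mask], mask


def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray,
                        voxel_size: float = 1.0) -> tuple[np.ndarray, float]:
    """Residual smoothness (per-axis FWHM, mm) and resel count.

    Residuals are standardized per voxel across maps; for each axis the
    variance of spatial first differences lambda estimates the derivative
    variance of the unit-variance field, giving FWHM = sqrt(4 ln2 / lambda)
    voxels.  Resels = mask voxel count / prod(FWHM in voxels).
    """
    if residuals.ndim != 2 or residuals.shape[0] < 2:
        raise ShapeError("need at least 2 residual maps (N x Vmask)")
    shape = mask.shape
    sd = residuals.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    std = residuals / sd

    vols = np.full((residuals.shape[0],) + shape, np.nan)
    vols[:, mask] = std

    fwhm_vox = np.empty(3)
    for ax in range(3):
        d = np.diff(vols, axis=ax + 1)
        valid = np.isfinite(d)
        if valid.sum() == 0:
            fwhm_vox[ax] = 1.0
            continue
        lam = float(np.nanvar(d))
        lam = min(max(lam, 1e-3), 4.0 - 1e-3)
        fwhm_vox[ax] = np.sqrt(4.0 * np.log(2.0) / lam)
    resels = float(mask.sum() / np.prod(fwhm_vox))
    return fwhm_vox * voxel_size, resels


def voxelwise_glm(maps: list[TopographyMap], design: DesignMatrix,
                  contrast: str, voxel_size: float = 3.0,
                  use: str = "z", keep_residuals: bool = True) -> GroupGlmResult:
    """Group GLM over stacked subject maps for one named contrast."""
    if contrast not in design.contrast_vectors:
        raise ParameterError(f"unknown contrast {contrast!r}")
    Y, mask = stack_maps(maps, use=use)
    if Y.shape[0] != design.n:
        raise ShapeError("number of maps does not match design rows")
    model = MassUnivariateGLM().fit(design.matrix, Y)
    effect, t, z = model.contrast_stats(design.contrast_vectors[contrast])
    fwhm, resels = estimate_smoothness(model.residuals_, mask, voxel_size)

    def unflatten(v):
        out = np.full(mask.shape, np.nan)
        out[mask] = v
        return out

    return GroupGlmResult(effect=unflatten(effect), tstat=unflatten(t),
                          zstat=unflatten(z), residual_fwhm=fwhm,
                          resel_count=resels, df=model.df_, mask=mask,
                          voxel_size=voxel_size, contrast=contrast,
                          residuals=model.residuals_ if keep_residuals else None)


# ---------------------------------------------------------------------------
# GRF cluster correction
# ---------------------------------------------------------------------------

def _ec_densities(z: float) -> tuple[float, float, float]:
    """EC densities rho_1..rho_3 of a unit Gaussian field (FWHM resel units)."""
    f = np.exp(-z**2 / 2.0)
    four_ln2 = 4.0 * np.log(2.0)
    rho1 = np.sqrt(four_ln2) / (2.0 * np.pi) * f
    rho2 = four_ln2 / (2.0 * np.pi) ** 1.5 * z * f
    rho3 = four_ln2**1.5 / (2.0 * np.pi) ** 2 * (z**2 - 1.0) * f
    return rho1, rho2, rho3


def _expected_clusters(z_thresh: float, mask: np.ndarray,
                       fwhm_vox: np.ndarray) -> float:
    """Expected suprathreshold clusters via EC densities on an equivalent box."""
    extents = []
    idx = np.where(mask)
    for ax in range(3):
        extents.append((idx[ax].max() - idx[ax].min() + 1) / fwhm_vox[ax])
    a, b, c = extents
    # scale the box volume term to the true mask volume in resels
    r3 = mask.sum() / float(np.prod(fwhm_vox))
    r2 = a * b + a * c + b * c
    r1 = a + b + c
    rho1, rho2, rho3 = _ec_densities(z_thresh)
    em = r1 * rho1 + r2 * rho2 + r3 * rho3
    return max(float(em), 1e-12)


def _label_clusters(binary: np.ndarray, connectivity: int = 26):
    structure = (np.ones((3, 3, 3)) if connectivity == 26
                 else ndimage.generate_binary_structure(3, 1))
    return ndimage.label(binary, structure=structure)


def grf_cluster_p(size_vox: int, z_thresh: float, mask: np.ndarray,
                  fwhm_vox: np.ndarray) -> float:
    """Corrected p for one cluster of ``size_vox`` voxels (GRF theory)."""
    em = _expected_clusters(z_thresh, mask, fwhm_vox)
    en = mask.sum() * stats.norm.sf(z_thresh) / em   # expected cluster size, voxels
    if en <= 0:
        return 1.0
    beta = (math.gamma(2.5) / en) ** (2.0 / 3.0)
    p_ge = np.exp(-beta * size_vox ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_ge))


def grf_cluster_correct(result: GroupGlmResult, voxel_p: float = 0.001,
                        cluster_p: float = 0.05, sign: str = "pos",
                        connectivity: int = 26,
                        z_thresh: float | None = None) -> pd.DataFrame:
    """Cluster table (size, peak z, peak index, corrected p) at one sign.

    Thresholds the signed z map at Phi^{-1}(1 - voxel_p) (one-sided), labels
    clusters at the requested connectivity, and retains those whose GRF
    corrected p is below ``cluster_p``.  Call once per sign.
    """
    if result.resel_count <= 0:
        raise ParameterError("resel count must be positive")
    if sign not in ("pos", "neg"):
        raise ParameterError("sign must be 'pos' or 'neg'")
    zt = float(stats.norm.isf(voxel_p)) if z_thresh is None else float(z_thresh)
    zmap = np.where(result.mask, result.zstat, -np.inf)
    if sign == "neg":
        zmap = -zmap
    binary = zmap > zt
    labeled, n_lab = _label_clusters(binary, connectivity)
    fwhm_vox = result.residual_fwhm / result.voxel_size
    rows = []
    for lab in range(1, n_lab + 1):
        idx = np.where(labeled == lab)
        size = len(idx[0])
        peak_pos = int(np.argmax(zmap[idx]))
        peak_index = tuple(int(idx[ax][peak_pos]) for ax in range(3))
        pcorr = grf_cluster_p(size, zt, result.mask, fwhm_vox)
        rows.append(dict(cluster_id=lab, size_voxels=size,
                         peak_z=float(zmap[idx].max()), peak_index=peak_index,
                         corrected_p=pcorr))
    table = pd.DataFrame(rows, columns=["cluster_id", "size_voxels", "peak_z",
                                        "peak_index", "corrected_p"])
    table = table[table.corrected_p < cluster_p]
    return table.sort_values("size_voxels", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# permutation oracle
# ---------------------------------------------------------------------------

def permutation_cluster_null(maps: list[TopographyMap], design: DesignMatrix,
                             contrast: str, n_perm: int = 500, seed: int = 0,
                             voxel_p: float = 0.001, sign: str = "pos",
                             connectivity: int = 26) -> dict:
    """Freedman-Lane permutation null of the maximum suprathreshold cluster size.

    Residuals of the reduced model (contrast column removed) are row-permuted,
    the reduced fit is added back, and the full GLM is re-run; the maximum
    cluster size above the voxel threshold is recorded per permutation.
    Returns the observed cluster table with permutation-corrected p-values and
    the null distribution itself.
    """
    if n_perm == 0:
        raise ParameterError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    Y, mask = stack_maps(maps)
    zt = float(stats.norm.isf(voxel_p))

    reduced = design.drop_column(contrast)
    red_model = MassUnivariateGLM().fit(reduced.matrix, Y)
    fitted_red = reduced.matrix @ red_model.coef_
    resid_red = red_model.residuals_

    cvec = design.contrast_vectors[contrast]

    def max_cluster(Yp):
        model = MassUnivariateGLM().fit(design.matrix, Yp)
        _, _, z = model.contrast_stats(cvec)
        vol = np.zeros(mask.shape)
        vol[mask] = z if sign == "pos" else -z
        labeled, n_lab = _label_clusters(vol > zt, connectivity)
        if n_lab == 0:
            return 0, labeled, vol
        sizes = np.bincount(labeled.ravel())[1:]
        return int(sizes.max()), labeled, vol

    obs_max, obs_labeled, obs_vol = max_cluster(Y)
    obs_sizes = np.bincount(obs_labeled.ravel())[1:] if obs_max else np.array([], int)

    null = np.empty(n_perm, dtype=int)
    n = Y.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b], _, _ = max_cluster(fitted_red + resid_red[perm])

    rows = []
    for lab, size in enumerate(obs_sizes, start=1):
        p = (1.0 + np.sum(null >= size)) / (n_perm + 1.0)
        idx = np.where(obs_labeled == lab)
        rows.append(dict(cluster_id=lab, size_voxels=int(size),
                         peak_z=float(obs_vol[idx].max()), corrected_p=float(p)))
    table = pd.DataFrame(rows, columns=["cluster_id", "size_voxels", "peak_z",
                                        "corrected_p"])
    return {"null_max_sizes": null,
            "clusters": table.sort_values("size_voxels", ascending=False)
                              .reset_index(drop=True)}


def cluster_scatter(maps: list[TopographyMap], phenotypes: list[Phenotype],
                    region_mask: np.ndarray, quadratic: bool = True) -> dict:
    """Per-subject mean z inside a region plus fitted age-curve coefficients.

    Fits mean-z on [1, z(age)] (and centered z(age)^2 if ``quadratic``);
    returns the subject values and coefficient estimates.
    """
    vals = np.array([np.nanmean(m.z[region_mask]) for m in maps])
    age = np.array([p.age for p in phenotypes], dtype=float)
    z = (age - age.mean()) / age.std()
    cols = [np.ones_like(z), z]
    names = ["intercept", "linear"]
    if quadratic:
        q = z**2
        cols.append(q - q.mean())
        names.append("quadratic")
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, vals, rcond=None)
    return {"subject_mean_z": vals, "age": age,
            "coefficients": dict(zip(names, coef.tolist()))}
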
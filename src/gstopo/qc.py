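"""Motion/confound QC and cross-pipeline robustness audits.

Contents: parcel-level functional connectivity and its distance-dependence
against head motion; behavioral partial least squares (PLS) relating the
voxel-wise topography maps to mean FD with permutation significance and
bootstrap stability; GLM re-runs with the PLS brain score as an extra
nuisance; cross-pipeline correlation matrices (GS time series, subject maps,
group maps); and phenotype-versus-age sanity checks.

Within-subject correlations are averaged on the Fisher-z scale and
back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import BoldRun, Phenotype
from .exceptions import DegenerateError, ParameterError, ShapeError
from .glm import DesignMatrix, GroupGlmResult, build_design, voxelwise_glm
from .topography import TopographyMap

__all__ = [
    "EdgeDistanceProfile",
    "PlsResult",
    "PipelineCorrMatrix",
    "block_parcellation",
    "parcel_fc",
    "distance_dependence",
    "pls_fd",
    "glm_with_brainscore",
    "pipeline_correlations",
    "phenotype_age_checks",
    "BehavioralPLS",
]


@dataclass
class EdgeDistanceProfile:
    """Across-subject FD-FC correlation per edge vs. inter-parcel distance."""

    distances: np.ndarray
    fd_fc_correlation: np.ndarray
    slope: float
    intercept: float
    degenerate: bool = False


@dataclass
class PlsResult:
    saliences: np.ndarray
    singular_value: float
    perm_p: float
    bootstrap_ratios: np.ndarray
    brain_scores: np.ndarray
    n_perm: int
    n_boot: int


@dataclass
class PipelineCorrMatrix:
    labels: list[str]
    matrix: np.ndarray
    level: str


def _fisher_mean(rs: np.ndarray) -> float:
    rs = np.clip(np.asarray(rs, dtype=float), -1.0 + 1e-15, 1.0 - 1e-15)
    return float(np.tanh(np.arctanh(rs).mean()))


def block_parcellation(mask: np.ndarray, block: int = 6) -> np.ndarray:
    """Grid the mask into contiguous cubic blocks; returns a label volume.

    Blocks with no mask voxels get no label; labels are 1..P in raster order.
    """
    labels = np.zeros(mask.shape, dtype=np.int32)
    nxt = 1
    sx, sy, sz = mask.shape
    for i0 in range(0, sx, block):
        for j0 in range(0, sy, block):
            for k0 in range(0, sz, block):
                sl = (slice(i0, i0 + block), slice(j0, j0 + block),
                      slice(k0, k0 + block))
                sub = mask[sl]
                if sub.any():
                    blk = np.zeros(sub.shape, dtype=np.int32)
                    blk[sub] = nxt
                    labels[sl] = blk
                    nxt += 1
    return labels


def parcel_fc(run: BoldRun, parcel_atlas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parcel-mean time series correlations and parcel centroids (mm)."""
    if parcel_atlas.shape != run.data.shape[:3]:
        raise ShapeError("parcel atlas shape mismatch")
    parcels = np.unique(parcel_atlas)
    parcels = parcels[parcels > 0]
    if parcels.size < 2:
        raise DegenerateError("need at least 2 parcels")
    series, centroids = [], []
    for p in parcels:
        m = parcel_atlas == p
        series.append(run.data[m].mean(axis=0))
        centroids.append(np.array(np.nonzero(m)).mean(axis=1) * run.voxel_size)
    fc = np.corrcoef(np.stack(series))
    return fc, np.stack(centroids)


def distance_dependence(fc_matrices: np.ndarray, fd: np.ndarray,
                        centroids: np.ndarray) -> EdgeDistanceProfile:
    """Across-subject correlation of each FC edge with FD, against distance.

    ``fc_matrices``: N x P x P; ``fd``: length N; ``centroids``: P x 3 (mm).
    Fits r(FC, FD) = intercept + slope * distance by OLS over edges.
    """
    fc_matrices = np.asarray(fc_matrices, dtype=float)
    fd = np.asarray(fd, dtype=float)
    n, p, _ = fc_matrices.shape
    iu = np.triu_indices(p, k=1)
    edges = fc_matrices[:, iu[0], iu[1]]                     # N x E
    dists = np.linalg.norm(centroids[iu[0]] - centroids[iu[1]], axis=1)
    if np.ptp(fd) == 0 or fd.std() < 1e-12 * (np.abs(fd).mean() + 1.0):
        return EdgeDistanceProfile(distances=dists,
                                   fd_fc_correlation=np.full(len(dists), np.nan),
                                   slope=np.nan, intercept=np.nan, degenerate=True)
    fd_c = (fd - fd.mean()) / fd.std()
    ec = edges - edges.mean(axis=0)
    sd = ec.std(axis=0)
    sd[sd == 0] = np.inf
    rs = (fd_c @ ec) / (n * sd)
    slope, intercept = np.polyfit(dists, rs, 1)
    return EdgeDistanceProfile(distances=dists, fd_fc_correlation=rs,
                               slope=float(slope), intercept=float(intercept))


class BehavioralPLS(BaseEstimator):
    """Behavioral PLS of voxel maps against one behavioral variable.

    With one behavior the latent variable is the leading (only) singular
    triple of the cross-covariance between the centered behavior and the
    centered voxel data: the salience map is the unit-norm covariance
    pattern, the singular value its norm.  Significance comes from behavior
    permutation; voxel stability from bootstrap ratios (salience / bootstrap
    SE over subject resamples); the per-subject brain score is the projection
    of the subject's map on the saliences, sign-aligned so that
    corr(brain score, behavior) >= 0.
    """

    def __init__(self, n_perm=500, n_boot=500, random_state=0):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _salience(maps_c, y_c):
        cov = y_c @ maps_c
        sv = float(np.linalg.norm(cov))
        if sv == 0:
            raise DegenerateError("zero cross-covariance; PLS undefined")
        return cov / sv, sv

    def fit(self, X, y):
        if self.n_perm < 100 or self.n_boot < 100:
            warnings.warn("fewer than 100 permutations/bootstraps gives coarse "
                          "p-values", stacklevel=2)
        rng = np.random.default_rng(self.random_state)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()

        sal, sv = self._salience(Xc, yc)
        scores = Xc @ sal
        if np.corrcoef(scores, y)[0, 1] < 0:
            sal, scores = -sal, -scores

        null = np.empty(self.n_perm)
        for b in range(self.n_perm):
            yp = yc[rng.permutation(n)]
            null[b] = np.linalg.norm(yp @ Xc)
        perm_p = float((1.0 + np.sum(null >= sv)) / (self.n_perm + 1.0))

        boots = np.empty((self.n_boot, X.shape[1]))
        for b in range(self.n_boot):
            idx = rng.integers(0, n, size=n)
            Xb = X[idx] - X[idx].mean(axis=0)
            yb = y[idx] - y[idx].mean()
            if yb.std() == 0 or not np.any(yb @ Xb):
                boots[b] = sal
                continue
            sb, _ = self._salience(Xb, yb)
            if sb @ sal < 0:
                sb = -sb
            boots[b] = sb
        se = boots.std(axis=0, ddof=1)
        se[se == 0] = np.inf
        self.saliences_ = sal
        self.singular_value_ = sv
        self.perm_p_ = perm_p
        self.bootstrap_ratios_ = sal / se
        self.brain_scores_ = scores
        self.null_singular_values_ = null
        return self


def pls_fd(maps: np.ndarray, fd: np.ndarray, n_perm: int = 500,
           n_boot: int = 500, seed: int = 0) -> PlsResult:
    """Behavioral PLS of subject x voxel maps against mean FD."""
    est = BehavioralPLS(n_perm=n_perm, n_boot=n_boot, random_state=seed).fit(maps, fd)
    return PlsResult(saliences=est.saliences_, singular_value=est.singular_value_,
                     perm_p=est.perm_p_, bootstrap_ratios=est.bootstrap_ratios_,
                     brain_scores=est.brain_scores_, n_perm=n_perm, n_boot=n_boot)


def glm_with_brainscore(maps: list[TopographyMap], phenotypes: list[Phenotype],
                        brain_scores: np.ndarray, contrast: str = "age_linear",
                        quadratic: bool = False,
                        voxel_size: float = 3.0) -> GroupGlmResult:
    """Group GLM with the PLS brain score as an extra centered nuisance column.

    A constant (zero-variance) brain-score vector carries no information and
    is dropped, which reduces exactly to the base GLM.
    """
    scores = np.asarray(brain_scores, float)
    extra = {} if scores.std() == 0 else {"brain_score": scores}
    design = build_design(phenotypes, quadratic=quadratic, extra=extra)
    return voxelwise_glm(maps, design, contrast, voxel_size=voxel_size)


def pipeline_correlations(per_pipeline: dict[str, list[np.ndarray]],
                          level: str) -> PipelineCorrMatrix:
    """Correlation matrix between pipelines at one comparison level.

    ``per_pipeline`` maps pipeline name -> list of per-subject 1D arrays
    (GS series or flattened maps); for group-level maps pass one array per
    pipeline.  Per-subject correlations are Fisher-averaged.
    """
    names = list(per_pipeline)
    k = len(names)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a_list, b_list = per_pipeline[names[i]], per_pipeline[names[j]]
            if len(a_list) != len(b_list):
                raise ShapeError("pipelines disagree on subject count")
            rs = []
            for a, b in zip(a_list, b_list):
                a, b = np.ravel(a), np.ravel(b)
                ok = np.isfinite(a) & np.isfinite(b)
                rs.append(np.corrcoef(a[ok], b[ok])[0, 1])
            mat[i, j] = mat[j, i] = _fisher_mean(np.array(rs))
    return PipelineCorrMatrix(labels=names, matrix=mat, level=level)


def phenotype_age_checks(phenotypes: list[Phenotype],
                         fd_threshold: float = 0.5) -> pd.DataFrame:
    """Pearson tests of confounds against age plus FD-age model fits.

    Rows: scan_start vs age, sleep_score vs age (r, p); FD-age standardized
    linear slope and quadratic term with p-values; scrub-count vs age slope.
    """
    age = np.array([p.age for p in phenotypes], dtype=float)
    z = (age - age.mean()) / age.std()
    rows = []
    for name, vals in (("scan_start", [p.scan_start for p in phenotypes]),
                       ("sleep_score", [p.sleep_score for p in phenotypes])):
        r, pval = stats.pearsonr(np.asarray(vals, float), age)
        rows.append(dict(variable=f"{name}_vs_age", estimate=float(r), p=float(pval)))

    def _standardized_fit(y):
        ys = (y - y.mean()) / y.std()
        X = np.column_stack([np.ones_like(z), z, z**2 - (z**2).mean()])
        coef, *_ = np.linalg.lstsq(X, ys, rcond=None)
        resid = ys - X @ coef
        df = len(ys) - X.shape[1]
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        tvals = coef / np.sqrt(np.diag(cov))
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        return coef, pvals

    fd = np.array([p.mean_fd for p in phenotypes], dtype=float)
    coef, pvals = _standardized_fit(fd)
    rows.append(dict(variable="fd_age_linear", estimate=float(coef[1]), p=float(pvals[1])))
    rows.append(dict(variable="fd_age_quadratic", estimate=float(coef[2]), p=float(pvals[2])))

    scrub = np.array([(p.fd_trace > fd_threshold).sum() for p in phenotypes], float)
    if scrub.std() > 0:
        coef_s, pvals_s = _standardized_fit(scrub)
        rows.append(dict(variable="scrub_count_age_linear",
                         estimate=float(coef_s[1]), p=float(pvals_s[1])))
    return pd.DataFrame(rows)
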
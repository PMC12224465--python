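"""Synthetic cohort generator for lifespan global-signal topography studies.

The generator produces phenotype tables and 4D BOLD runs with the statistical
structure the downstream analysis assumes:

* ages uniform over 6-85 years, sex ~ Bernoulli(0.4 male);
* mean framewise displacement (FD) built so its standardized regression on
  z-scored age has a chosen expected slope (default 0.35) and no quadratic term;
* spiky, heavy-tailed per-frame FD traces whose exceedances of the 0.5 mm
  scrub threshold grow with the subject's mean FD (and hence with age);
* a shared band-limited (0.01-0.1 Hz) unit-variance global latent g(t);
* region-specific GS coupling w(a) = w0 + w1*z(a) + w2*z(a)^2 with the signs
  observed across the lifespan (thalamus +linear, putamen/sensorimotor -linear,
  nucleus basalis / frontoparietal / dorsal-attention u-shaped, medial
  prefrontal-caudate-visual inverted-u);
* three structured noise processes with deterministic spatial loadings — a
  respiratory-like high-frequency global series, a brain-stem-localized series
  with mild anti-correlation elsewhere, and a striped motion series whose
  amplitude tracks the FD trace — plus white voxel noise and frame-wise spike
  offsets wherever FD exceeds 0.5 mm.

White and CSF voxels carry no global latent, which is what lets tissue masks
and edge features separate signal from structured noise downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import CohortConfig, BoldConfig, GridConfig, coupling_table, stage_rng
from .exceptions import CohortError, LayoutError, ParameterError

__all__ = [
    "Phenotype",
    "CouplingAtlas",
    "BoldRun",
    "LatentSignals",
    "simulate_phenotypes",
    "build_coupling_atlas",
    "simulate_bold",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "band_limited_series",
]


@dataclass
class Phenotype:
    """Per-subject phenotype record.

    ``age_z`` is the subject's age standardized over the simulated cohort
    (the same centering the group GLM uses).
    """

    subject_id: str
    age: float
    sex: int
    mean_fd: float
    fd_trace: np.ndarray
    scan_start: float
    sleep_score: int
    age_z: float = 0.0

    def __post_init__(self):
        self.fd_trace = np.asarray(self.fd_trace, dtype=float)
        if not (0.0 < self.mean_fd < 0.5):
            raise ParameterError(f"mean_fd must lie in (0, 0.5) mm, got {self.mean_fd}")
        if abs(float(self.fd_trace.mean()) - self.mean_fd) > 1e-9:
            raise ParameterError("fd_trace must average to mean_fd within 1e-9")


@dataclass
class CouplingAtlas:
    """Labeled region grid with per-region age-coupling coefficients.

    ``region_table`` columns: label, name, tissue (gray/white/csf), w0, w1, w2,
    where the coupling at age a is w(a) = w0 + w1*z(a) + w2*z(a)^2.
    """

    labels: np.ndarray
    region_table: pd.DataFrame
    gm_probability: np.ndarray
    voxel_size: float

    def region_mask(self, name: str) -> np.ndarray:
        row = self.region_table[self.region_table["name"] == name]
        if row.empty:
            raise KeyError(f"no region named {name!r}")
        return self.labels == int(row["label"].iloc[0])

    def coupling(self, name: str, age_z: float) -> float:
        row = self.region_table[self.region_table["name"] == name].iloc[0]
        return float(row.w0 + row.w1 * age_z + row.w2 * age_z**2)


@dataclass
class BoldRun:
    """One subject's 4D BOLD time series with aligned motion traces."""

    data: np.ndarray          # (X, Y, Z, T)
    tr: float
    voxel_size: float
    motion_params: np.ndarray  # (T, 6): 3 translations mm, 3 rotations rad
    phenotype_ref: str

    @property
    def t_frames(self) -> int:
        return self.data.shape[-1]

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ParameterError("BOLD data must be 4D (X, Y, Z, T)")
        if self.data.shape[-1] < 50:
            raise ParameterError("runs shorter than 50 frames are not supported")
        if self.motion_params.shape != (self.data.shape[-1], 6):
            raise ParameterError("motion_params must be (T, 6) aligned to the run")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("BOLD data contains NaN/Inf")


@dataclass
class LatentSignals:
    """Generator ground truth for one run (for oracles and label injection)."""

    global_latent: np.ndarray                 # (T,), unit variance
    structured_noise: np.ndarray              # (K, T)
    noise_loadings: np.ndarray                # (K, X, Y, Z)
    noise_names: tuple[str, ...]
    local_network_signals: dict[str, np.ndarray] = field(default_factory=dict)


def band_limited_series(t_frames: int, tr: float, low: float, high: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian series with power confined to [low, high] Hz."""
    white = rng.standard_normal(t_frames)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(t_frames, d=tr)
    spec[(freqs < low) | (freqs > high)] = 0.0
    series = np.fft.irfft(spec, n=t_frames)
    sd = series.std()
    if sd == 0:
        raise ParameterError("requested band contains no frequency bins")
    return series / sd


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _fd_trace(mean_fd: float, t_frames: int, cfg: CohortConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Positive, spiky FD trace averaging exactly ``mean_fd``.

    Frame values are a two-part mixture (mostly small magnitudes, occasional
    spikes above the 0.5 mm scrub threshold); the spike probability scales
    with the subject's mean FD so scrub counts inherit the FD-age gradient.
    The whole trace is rescaled so its mean matches ``mean_fd`` exactly.
    """
    p_spike = float(np.clip(cfg.fd_spike_prob * mean_fd / cfg.fd_mean, 0.002, 0.12))
    base = np.abs(rng.normal(cfg.fd_frame_loc, cfg.fd_frame_sd, size=t_frames))
    spikes = rng.random(t_frames) < p_spike
    base[spikes] = cfg.fd_spike_floor + np.abs(rng.normal(0.0, cfg.fd_spike_sd,
                                                          size=int(spikes.sum())))
    base = np.maximum(base, 1e-4)
    return base * (mean_fd / base.mean())


def simulate_phenotypes(n: int, seed: int, fd_age_slope: float | None = None,
                        t_frames: int | None = None,
                        config: CohortConfig | None = None) -> list[Phenotype]:
    """Simulate ``n`` subject phenotypes.

    Parameters
    ----------
    n : cohort size (>= 10).
    seed : master seed; all phenotype randomness derives from it.
    fd_age_slope : expected standardized regression coefficient of mean FD on
        z-scored age (default from config, 0.35); must lie in (-1, 1).
    t_frames : FD trace length (defaults to the BOLD frame count).
    """
    cfg = config or CohortConfig()
    if n < 10:
        raise CohortError(f"cohort must have at least 10 subjects, got {n}")
    slope = cfg.fd_age_slope if fd_age_slope is None else float(fd_age_slope)
    if not (-1.0 < slope < 1.0):
        raise ParameterError(f"fd_age_slope must lie in (-1, 1), got {slope}")
    t_frames = t_frames if t_frames is not None else BoldConfig().t_frames

    rng = stage_rng(seed, "phenotypes")
    ages = rng.uniform(cfg.age_min, cfg.age_max, size=n)
    age_z = (ages - ages.mean()) / ages.std()
    sex = (rng.random(n) < cfg.male_fraction).astype(int)

    # noise orthogonalized against z(age) in-sample, so each simulated cohort
    # realizes the requested standardized slope exactly (up to FD clipping)
    noise = rng.standard_normal(n)
    noise = noise - age_z * (age_z @ noise) / (age_z @ age_z)
    noise = noise / noise.std()
    fd_std = slope * age_z + np.sqrt(1.0 - slope**2) * noise
    fd_std = fd_std / fd_std.std()
    mean_fd = np.clip(cfg.fd_mean + cfg.fd_sd * fd_std, cfg.fd_min, cfg.fd_max)

    scan_start = rng.uniform(cfg.scan_start_min, cfg.scan_start_max, size=n)
    sleep = rng.poisson(cfg.sleep_score_mean, size=n)

    phenos = []
    for i in range(n):
        trace = _fd_trace(float(mean_fd[i]), t_frames, cfg, stage_rng(seed, "fd_trace", i))
        phenos.append(Phenotype(
            subject_id=f"sub-{i:04d}",
            age=float(ages[i]),
            sex=int(sex[i]),
            mean_fd=float(trace.mean()),
            fd_trace=trace,
            scan_start=float(scan_start[i]),
            sleep_score=int(sleep[i]),
            age_z=float(age_z[i]),
        ))
    return phenos


# ---------------------------------------------------------------------------
# coupling atlas
# ---------------------------------------------------------------------------

# Region layout in normalized [-1, 1] coordinates: (center, radius).  These are
# invented geometric blobs, not anatomy; only the coupling signs carry meaning.
_SPHERES = {
    "white": ((0.0, 0.0, 0.0), 0.24),
    "csf": ((0.0, 0.45, 0.0), 0.13),
    "thalamus": ((0.45, 0.0, 0.0), 0.18),
    "putamen": ((-0.45, 0.0, 0.0), 0.18),
    "nucleus_basalis": ((0.0, -0.45, -0.2), 0.14),
    "fpn": ((0.0, 0.45, 0.45), 0.17),
    "dan": ((0.45, 0.45, 0.35), 0.15),
    "mpfc_caudate_visual": ((0.0, -0.45, 0.35), 0.16),
}
_BRAIN_RADIUS = 0.92
_SENSORIMOTOR_Z = 0.60   # dorsal cap above this normalized height

_TISSUE = {"white": "white", "csf": "csf"}


def _norm_coords(shape: tuple[int, int, int]) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def build_coupling_atlas(grid_shape: tuple[int, int, int] = (24, 24, 24),
                         seed: int = 0,
                         coupling: dict[str, tuple[float, float, float]] | None = None,
                         voxel_size: float = 3.0) -> CouplingAtlas:
    """Build the synthetic region atlas with age-coupling coefficients.

    Regions are connected geometric blobs inside a spherical "brain": a white
    core, a CSF blob, subcortical spheres (thalamus, putamen, nucleus basalis),
    cortical spheres (fpn, dan, mpfc_caudate_visual), a dorsal sensorimotor
    cap, and a generic gray background filling the rest.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 16:
        raise LayoutError(f"grid extents must all be >= 16, got {grid_shape}")
    coupling = coupling or coupling_table()

    coords = _norm_coords(grid_shape)
    r2 = (coords**2).sum(axis=0)
    brain = r2 <= _BRAIN_RADIUS**2

    labels = np.zeros(grid_shape, dtype=np.int32)
    names = ["gray_background", "sensorimotor", "fpn", "dan", "mpfc_caudate_visual",
             "thalamus", "putamen", "nucleus_basalis", "white", "csf"]
    label_of = {name: i + 1 for i, name in enumerate(names)}

    labels[brain] = label_of["gray_background"]
    labels[brain & (coords[2] > _SENSORIMOTOR_Z)] = label_of["sensorimotor"]
    # later paints win, so subcortical and tissue blobs override cortex
    for name in ["fpn", "dan", "mpfc_caudate_visual", "thalamus", "putamen",
                 "nucleus_basalis", "white", "csf"]:
        (cx, cy, cz), rad = _SPHERES[name]
        d2 = (coords[0] - cx)**2 + (coords[1] - cy)**2 + (coords[2] - cz)**2
        labels[brain & (d2 <= rad**2)] = label_of[name]

    rows = []
    for name, lab in label_of.items():
        mask = labels == lab
        if not mask.any():
            raise LayoutError(f"region {name!r} is empty on grid {grid_shape}")
        n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))[1]
        if n_comp != 1:
            raise LayoutError(f"region {name!r} is not a single connected blob")
        tissue = _TISSUE.get(name, "gray")
        w0, w1, w2 = coupling.get(name, (0.0, 0.0, 0.0)) if tissue == "gray" \
            else (0.0, 0.0, 0.0)
        rows.append(dict(label=lab, name=name, tissue=tissue, w0=w0, w1=w1, w2=w2))
    table = pd.DataFrame(rows)

    rng = stage_rng(seed, "atlas_gm")
    gm = np.zeros(grid_shape)
    gray = np.isin(labels, table.loc[table.tissue == "gray", "label"].to_numpy())
    nongray = np.isin(labels, table.loc[table.tissue != "gray", "label"].to_numpy())
    gm[gray] = 0.85 + 0.1 * rng.random(int(gray.sum()))
    gm[nongray] = 0.05
    return CouplingAtlas(labels=labels, region_table=table,
                         gm_probability=gm, voxel_size=float(voxel_size))


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def _noise_loadings(atlas: CouplingAtlas) -> tuple[np.ndarray, tuple[str, ...]]:
    """Deterministic spatial loadings for the three structured noise processes."""
    shape = atlas.labels.shape
    coords = _norm_coords(shape)
    brain = atlas.labels > 0

    # respiratory-like: global but spatially graded (stronger inferior-anterior,
    # as vascular/edge effects are), nonzero over the whole brain incl. white/CSF
    resp = np.where(brain, 1.0 + 0.6 * coords[0] - 0.5 * coords[2], 0.0)

    # brain-stem-like blob at the inferior pole, mildly anti-correlated elsewhere
    d2 = coords[0]**2 + coords[1]**2 + (coords[2] + 0.8)**2
    stem = np.exp(-d2 / (2 * 0.22**2))
    stem = np.where(stem > 0.05, stem, 0.0)
    stem[brain & (stem == 0.0)] = -0.05

    # striped banding in 2-slice bands (coarse enough to survive 6 mm smoothing),
    # everywhere in the FOV including outside the brain
    band = np.where((np.arange(shape[2]) // 2) % 2 == 0, 1.0, -1.0)
    stripes = np.ones(shape) * band[None, None, :]

    return np.stack([resp, stem, stripes]), ("respiratory", "brainstem", "motion_stripes")


def simulate_bold(phenotype: Phenotype, atlas: CouplingAtlas,
                  t_frames: int | None = None, seed: int = 0,
                  config: BoldConfig | None = None) -> tuple[BoldRun, LatentSignals]:
    """Simulate one subject's 4D BOLD run on the atlas grid.

    A voxel in region r follows
    ``y_v(t) = w_r(a) g(t) + u_r(t) + sum_k b_kv n_k(t) + eps_v(t)``
    with g band-limited to the neural band and unit variance; white/CSF voxels
    carry no g.  Frames with FD > 0.5 mm receive additional spike offsets.
    """
    cfg = config or BoldConfig()
    t_frames = int(t_frames if t_frames is not None else cfg.t_frames)
    if t_frames < 50:
        raise ParameterError(f"t_frames must be >= 50, got {t_frames}")
    fd = phenotype.fd_trace
    if len(fd) != t_frames:
        raise ParameterError("phenotype fd_trace length must equal t_frames")

    rng = stage_rng(seed, "bold")
    shape = atlas.labels.shape

    g = band_limited_series(t_frames, cfg.tr, cfg.band_low, cfg.band_high, rng)
    resp = band_limited_series(t_frames, cfg.tr, *cfg.respiratory_band, rng)
    stem = band_limited_series(t_frames, cfg.tr, *cfg.brainstem_band, rng)
    # amplitude tracks absolute FD (mm), so high-motion subjects carry
    # proportionally stronger striped artifact across the cohort
    motion = fd * rng.standard_normal(t_frames)
    noise_tc = np.stack([cfg.respiratory_amplitude * resp,
                         cfg.brainstem_amplitude * stem,
                         cfg.motion_amplitude * motion])
    loadings, noise_names = _noise_loadings(atlas)

    data = np.zeros(shape + (t_frames,), dtype=np.float64)
    locals_: dict[str, np.ndarray] = {}
    z = phenotype.age_z
    for row in atlas.region_table.itertuples():
        mask = atlas.labels == row.label
        u = cfg.local_amplitude * band_limited_series(
            t_frames, cfg.tr, cfg.band_low, cfg.band_high, rng)
        if row.tissue != "gray":
            u = 0.6 * u  # physiological-ish local fluctuation, weaker than gray
        locals_[row.name] = u
        w = row.w0 + row.w1 * z + row.w2 * z**2 if row.tissue == "gray" else 0.0
        data[mask] += w * g + u

    for k in range(noise_tc.shape[0]):
        data += loadings[k][..., None] * noise_tc[k]

    # spontaneous background fluctuations: spatially smooth, neural-band voxel
    # noise (keeps single-subject GS-coupling statistics off the z ceiling the
    # way idiosyncratic neural activity does in real data), plus iid thermal noise
    if cfg.background_noise_sd > 0:
        bg = rng.standard_normal(data.shape)
        spec = np.fft.rfft(bg, axis=-1)
        freqs = np.fft.rfftfreq(t_frames, d=cfg.tr)
        spec[..., (freqs < cfg.band_low) | (freqs > cfg.band_high)] = 0.0
        bg = np.fft.irfft(spec, n=t_frames, axis=-1)
        if cfg.noise_smooth_fwhm > 0:
            sigma_vox = cfg.noise_smooth_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) \
                / atlas.voxel_size
            bg = ndimage.gaussian_filter(bg, sigma=(sigma_vox,) * 3 + (0,))
        data += cfg.background_noise_sd * (bg / bg.std())
    data += rng.normal(0.0, cfg.white_noise_sd, size=data.shape)

    spike_frames = np.flatnonzero(fd > 0.5)
    if spike_frames.size:
        pattern = rng.standard_normal(shape)
        data[..., spike_frames] += cfg.spike_amplitude * pattern[..., None]

    # motion parameters whose Power-style FD reproduces the trace exactly:
    # FD(t) = sum |d trans| + 50 * sum |d rot|, split across axes by random weights
    weights = rng.dirichlet(np.ones(6), size=t_frames)
    signs = rng.choice([-1.0, 1.0], size=(t_frames, 6))
    deltas = weights * signs * fd[:, None]
    deltas[0] = 0.0
    deltas[:, 3:] /= 50.0
    motion_params = np.cumsum(deltas, axis=0)

    run = BoldRun(data=data.astype(np.float32), tr=cfg.tr,
                  voxel_size=atlas.voxel_size, motion_params=motion_params,
                  phenotype_ref=phenotype.subject_id)
    latents = LatentSignals(global_latent=g, structured_noise=noise_tc,
                            noise_loadings=loadings, noise_names=noise_names,
                            local_network_signals=locals_)
    return run, latents


def simulate_cohort(n: int, seed: int, atlas: CouplingAtlas | None = None,
                    t_frames: int | None = None,
                    grid_shape: tuple[int, int, int] = (24, 24, 24),
                    cohort_config: CohortConfig | None = None,
                    bold_config: BoldConfig | None = None,
                    ) -> tuple[list[Phenotype], CouplingAtlas,
                               list[BoldRun], list[LatentSignals]]:
    """Convenience wrapper: phenotypes + atlas + one BOLD run per subject.

    Per-subject BOLD seeds derive from ``(seed, "bold", subject_index)``.
    """
    bcfg = bold_config or BoldConfig()
    t_frames = int(t_frames if t_frames is not None else bcfg.t_frames)
    phenos = simulate_phenotypes(n, seed, t_frames=t_frames, config=cohort_config)
    if atlas is None:
        atlas = build_coupling_atlas(grid_shape, seed=seed)
    runs, latents = [], []
    for i, ph in enumerate(phenos):
        run, lat = simulate_bold(ph, atlas, t_frames=t_frames,
                                 seed=(seed * 100003 + i) % (2**31), config=bcfg)
        runs.append(run)
        latents.append(lat)
    return phenos, atlas, runs, latents


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(runs: list[BoldRun], phenotypes: list[Phenotype], out_dir,
                 atlas: CouplingAtlas | None = None,
                 params: dict | None = None) -> dict:
    """Write a cohort to disk (NIfTI + motion text + TSV + JSON manifest).

    Round-trips bit-exactly through :func:`read_cohort`.
    """
    from . import io as gio
    return gio.write_cohort(runs, phenotypes, out_dir, atlas=atlas, params=params)


def read_cohort(out_dir) -> tuple[list[BoldRun], list[Phenotype],
                                  CouplingAtlas | None, dict]:
    from . import io as gio
    return gio.read_cohort(out_dir)


def replace_data(run: BoldRun, data: np.ndarray) -> BoldRun:
    """New BoldRun sharing metadata with ``run`` but holding ``data``."""
    return dataclasses.replace(run, data=data)
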
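"""Configuration: validated run parameters and seed derivation.

All tunables live in ``defaults.yaml`` shipped with the package; a
:class:`RunConfig` validates them (pydantic) and is serialized next to every
output tree so a run can be replayed bit-for-bit.

Randomness contract: every stage derives its generator from
``stage_rng(seed, stage_name, index)``, which feeds ``numpy.random.SeedSequence``
with ``[seed, crc32(stage_name), index]``.  Identical ``(seed, stage, index)``
triples therefore yield identical streams regardless of execution order.
"""

from __future__ import annotations

import zlib
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator


def _load_defaults() -> dict:
    with resources.files("gstopo").joinpath("defaults.yaml").open("r") as fh:
        return yaml.safe_load(fh)


class CohortConfig(BaseModel):
    n_subjects: int = 60
    age_min: float = 6.0
    age_max: float = 85.0
    male_fraction: float = 0.4
    fd_age_slope: float = 0.35
    fd_mean: float = 0.20
    fd_sd: float = 0.07
    fd_min: float = 0.03
    fd_max: float = 0.49
    fd_frame_loc: float = 0.18
    fd_frame_sd: float = 0.08
    fd_spike_prob: float = 0.015
    fd_spike_floor: float = 0.55
    fd_spike_sd: float = 0.25
    scan_start_min: float = 480.0
    scan_start_max: float = 1080.0
    sleep_score_mean: float = 5.0


class GridConfig(BaseModel):
    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 3.0


class BoldConfig(BaseModel):
    tr: float = 1.4
    t_frames: int = 200
    band_low: float = 0.01
    band_high: float = 0.1
    local_amplitude: float = 0.5
    white_noise_sd: float = 0.5
    background_noise_sd: float = 2.5
    noise_smooth_fwhm: float = 6.0
    respiratory_amplitude: float = 0.8
    respiratory_band: tuple[float, float] = (0.15, 0.3)
    brainstem_amplitude: float = 1.3
    brainstem_band: tuple[float, float] = (0.03, 0.15)
    motion_amplitude: float = 5.0
    spike_amplitude: float = 3.0


class PreprocessConfig(BaseModel):
    fd_threshold: float = 0.5
    min_retained: int = 20
    gm_threshold: float = 0.2
    smooth_fwhm: float = 6.0


class IcaConfig(BaseModel):
    k_sica: int = 125
    k_tica: int = 75
    desk_k_sica: int = 12
    desk_k_tica: int = 8
    tau_edge: float = 0.35
    tau_hf: float = 0.5
    tau_spike: float = 5.0
    tau_stripe: float = 0.5
    match_threshold: float = 0.4
    treat_global_negative_as_noise: bool = True


class GlmConfig(BaseModel):
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    connectivity: int = 26
    z_cap: float = 8.2
    z_dialect: str = "tcdf"

    @field_validator("connectivity")
    @classmethod
    def _conn(cls, v: int) -> int:
        if v not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        return v

    @field_validator("z_dialect")
    @classmethod
    def _dialect(cls, v: str) -> str:
        if v not in ("tcdf", "fisher"):
            raise ValueError("z_dialect must be 'tcdf' or 'fisher'")
        return v


class QcConfig(BaseModel):
    n_perm: int = 500
    n_boot: int = 500
    parcel_block: int = 6


class RunConfig(BaseModel):
    """Validated configuration for an end-to-end run."""

    seed: int = 0
    pipelines: tuple[str, ...] = ("mp", "cr", "tica")
    scrub: bool = True
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    bold: BoldConfig = Field(default_factory=BoldConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    ica: IcaConfig = Field(default_factory=IcaConfig)
    glm: GlmConfig = Field(default_factory=GlmConfig)
    qc: QcConfig = Field(default_factory=QcConfig)

    @field_validator("pipelines")
    @classmethod
    def _pipes(cls, v: Sequence[str]) -> tuple[str, ...]:
        allowed = {"mp", "cr", "tica"}
        bad = set(v) - allowed
        if bad:
            raise ValueError(f"unknown pipelines: {sorted(bad)}; allowed {sorted(allowed)}")
        return tuple(v)


def default_config(**overrides) -> RunConfig:
    """RunConfig built from the packaged defaults, with keyword overrides.

    Overrides may be nested dicts, e.g. ``default_config(cohort={"n_subjects": 30})``.
    """
    data = _load_defaults()
    # flatten yaml groups into the model layout
    merged = {
        "cohort": data["cohort"],
        "grid": data["grid"],
        "bold": data["bold"],
        "preprocess": data["preprocess"],
        "ica": data["ica"],
        "glm": data["glm"],
        "qc": data["qc"],
    }
    for key, val in overrides.items():
        if isinstance(val, dict) and key in merged:
            merged[key] = {**merged[key], **val}
        else:
            merged[key] = val
    return RunConfig(**merged)


def load_config(path) -> RunConfig:
    """Load a YAML config file, layered over the packaged defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return default_config(**user)


def coupling_table() -> dict[str, tuple[float, float, float]]:
    """Default per-region coupling coefficients (w0, w1, w2) from defaults.yaml."""
    data = _load_defaults()
    return {k: tuple(v) for k, v in data["coupling"].items()}


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-stage generator; see module docstring."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode()), int(index)])
    return np.random.Generator(np.random.PCG64(ss))


def stage_int_seed(seed: int, stage: str, index: int = 0) -> int:
    """A 31-bit integer seed (for scikit-learn) derived like :func:`stage_rng`."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode()), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))
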
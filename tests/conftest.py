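import numpy as np
import pytest
from hypothesis import settings

import gstopo
import gstopo.topography as tp
from gstopo.config import default_config
from gstopo.preprocess import gaussian_smooth

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

GRID = (16, 16, 16)
T_FRAMES = 120


@pytest.fixture(scope="session")
def atlas():
    return gstopo.build_coupling_atlas(GRID, seed=0)


@pytest.fixture(scope="session")
def gm(atlas):
    return tp.gray_mask(atlas.gm_probability)


@pytest.fixture(scope="session")
def brain(atlas):
    return atlas.labels > 0


@pytest.fixture(scope="session")
def small_cohort(atlas):
    """20 subjects on the 16^3 grid: phenotypes, raw runs, latents."""
    cfg = default_config()
    phenos = gstopo.simulate_phenotypes(20, seed=0, t_frames=T_FRAMES,
                                        config=cfg.cohort)
    runs, latents = [], []
    for i, p in enumerate(phenos):
        run, lat = gstopo.simulate_bold(p, atlas, t_frames=T_FRAMES, seed=900 + i,
                                        config=cfg.bold)
        runs.append(run)
        latents.append(lat)
    return phenos, runs, latents


@pytest.fixture(scope="session")
def smoothed_runs(small_cohort):
    _, runs, _ = small_cohort
    return [gaussian_smooth(r, 6.0) for r in runs]


@pytest.fixture(scope="session")
def cascade(small_cohort, smoothed_runs, atlas, gm, brain):
    """Ground-truth-labeled sICA -> tICA cascade over the small cohort."""
    from gstopo.ica import run_cascade
    _, _, latents = small_cohort
    model, cleaned = run_cascade(smoothed_runs, brain, gm, k_sica=12, k_tica=8,
                                 seed=7, labels="manifest", latents=latents)
    return model, cleaned


@pytest.fixture(scope="session")
def medium_cohort_maps():
    """120 subjects on an 18^3 grid: phenotypes, atlas, per-subject z maps."""
    atlas = gstopo.build_coupling_atlas((18, 18, 18), seed=0)
    gmask = tp.gray_mask(atlas.gm_probability)
    phenos = gstopo.simulate_phenotypes(120, seed=3, t_frames=T_FRAMES)
    maps = []
    for i, p in enumerate(phenos):
        run, _ = gstopo.simulate_bold(p, atlas, t_frames=T_FRAMES, seed=5000 + i)
        maps.append(tp.topography_map(run, tp.compute_gs(run, gmask),
                                      mask=atlas.labels > 0))
    return phenos, atlas, maps
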
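"""Group GLM, smoothness estimation, GRF cluster inference, permutation oracle."""

import numpy as np
import pytest
from scipy import ndimage, stats

import gstopo
import gstopo.glm as gg
import gstopo.topography as tp
from gstopo.exceptions import DegenerateError, ParameterError


def _maps_from_stack(stack):
    return [tp.TopographyMap(beta=v, z=v, retained_frames=100,
                             subject_id=f"sub-{i:04d}")
            for i, v in enumerate(stack)]


class TestBuildDesign:
    def test_quadratic_design_shape(self):
        phenos = gstopo.simulate_phenotypes(30, seed=0, t_frames=60)
        d = gg.build_design(phenos, quadratic=True)
        assert d.p == 5
        assert d.n - d.p == 25
        assert set(d.contrast_vectors) == {"age_linear", "age_quadratic"}
        # all non-intercept columns centered
        assert np.abs(d.matrix[:, 1:].mean(axis=0)).max() < 1e-10

    def test_symmetric_ages_orthogonal_columns(self):
        phenos = gstopo.simulate_phenotypes(30, seed=1, t_frames=60)
        ages = np.linspace(20, 70, 30)          # symmetric about the mean
        for p, a in zip(phenos, ages):
            p.age = float(a)
        d = gg.build_design(phenos, quadratic=True)
        lin = d.matrix[:, d.column_names.index("age_linear")]
        quad = d.matrix[:, d.column_names.index("age_quadratic")]
        assert abs(np.corrcoef(lin, quad)[0, 1]) < 1e-10

    def test_constant_sex_rank_error(self):
        phenos = gstopo.simulate_phenotypes(20, seed=2, t_frames=60)
        for p in phenos:
            p.sex = 1
        with pytest.raises(DegenerateError, match="sex"):
            gg.build_design(phenos)

    def test_quadratic_does_not_move_linear_effect_when_orthogonal(self):
        # mirrored age pairs sharing FD/sex: every covariate is an even
        # function of centered age, so the linear column stays orthogonal
        phenos = gstopo.simulate_phenotypes(40, seed=3, t_frames=60)
        ages = np.linspace(10, 80, 40)
        for p, a in zip(phenos, ages):
            p.age = float(a)
        for i in range(20):
            j = 39 - i
            phenos[j].fd_trace = phenos[i].fd_trace.copy()
            phenos[j].mean_fd = phenos[i].mean_fd
            phenos[j].sex = phenos[i].sex
        rng = np.random.default_rng(0)
        stack = rng.standard_normal((40, 3, 3, 3))
        maps = _maps_from_stack(stack)
        r_lin = gg.voxelwise_glm(maps, gg.build_design(phenos), "age_linear")
        r_both = gg.voxelwise_glm(maps, gg.build_design(phenos, quadratic=True),
                                  "age_linear")
        assert np.allclose(r_lin.effect, r_both.effect, atol=1e-10)


class TestVoxelwiseGlm:
    def test_exact_linear_response(self):
        phenos = gstopo.simulate_phenotypes(30, seed=4, t_frames=60)
        z = np.array([p.age_z for p in phenos])
        stack = np.tile(2.0 * z[:, None, None, None], (1, 3, 3, 3))
        res = gg.voxelwise_glm(_maps_from_stack(stack),
                               gg.build_design(phenos), "age_linear")
        assert np.allclose(res.effect, 2.0, atol=1e-10)
        assert np.allclose(np.abs(res.zstat), 8.2)     # capped

    def test_matches_bruteforce_normal_equations(self):
        phenos = gstopo.simulate_phenotypes(25, seed=5, t_frames=60)
        rng = np.random.default_rng(1)
        stack = rng.standard_normal((25, 5, 5, 5))
        design = gg.build_design(phenos, quadratic=True)
        res = gg.voxelwise_glm(_maps_from_stack(stack), design, "age_quadratic")
        X = design.matrix
        c = design.contrast_vectors["age_quadratic"]
        for idx in ((0, 0, 0), (2, 3, 4), (4, 4, 4)):
            y = stack[(slice(None),) + idx]
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            sigma2 = resid @ resid / (25 - 5)
            t_exp = (c @ beta) / np.sqrt(sigma2 * c @ np.linalg.inv(X.T @ X) @ c)
            assert abs(res.tstat[idx] - t_exp) < 1e-8

    def test_injected_sign_pattern(self, medium_cohort_maps):
        phenos, atlas, maps = medium_cohort_maps
        res = gg.voxelwise_glm(maps, gg.build_design(phenos, quadratic=True),
                               "age_quadratic", voxel_size=3.0)
        pos = np.concatenate([res.zstat[atlas.region_mask(n)]
                              for n in ("fpn", "dan", "nucleus_basalis")])
        neg = res.zstat[atlas.region_mask("mpfc_caudate_visual")]
        assert np.nanmean(pos) > 1.0
        assert np.nanmean(neg) < -1.0


class TestSmoothness:
    def test_white_noise_fwhm_near_voxel(self):
        rng = np.random.default_rng(2)
        mask = np.ones((16, 16, 16), bool)
        fwhms = []
        for _ in range(20):
            R = rng.standard_normal((15, mask.sum()))
            f, _ = gg.estimate_smoothness(R, mask, voxel_size=3.0)
            fwhms.append(f / 3.0)
        assert np.abs(np.mean(fwhms, axis=0) - 1.0).max() < 0.2

    def test_smoothed_noise_fwhm_recovered(self):
        rng = np.random.default_rng(3)
        mask = np.ones((20, 20, 20), bool)
        sigma = 2.0 / (2 * np.sqrt(2 * np.log(2)))     # 6 mm at 3 mm voxels
        fwhms = []
        for _ in range(20):
            R = ndimage.gaussian_filter(
                rng.standard_normal((15, 20, 20, 20)),
                sigma=(0,) + (sigma,) * 3, mode="wrap")
            f, _ = gg.estimate_smoothness(R.reshape(15, -1), mask, voxel_size=3.0)
            fwhms.append(f)
        assert np.abs(np.mean(fwhms, axis=0) - 6.0).max() < 1.2

    def test_resels_proportional_to_mask(self):
        rng = np.random.default_rng(4)
        full = np.ones((16, 16, 16), bool)
        R = rng.standard_normal((12,) + full.shape)
        _, resels_full = gg.estimate_smoothness(R.reshape(12, -1), full, 3.0)
        half = full.copy()
        half[8:] = False
        _, resels_half = gg.estimate_smoothness(R[:, half].reshape(12, -1),
                                                half, 3.0)
        assert resels_full / resels_half == pytest.approx(2.0, rel=0.15)


class TestGrfClusters:
    def _null_result(self, seed=0, n=30, shape=(16, 16, 16)):
        rng = np.random.default_rng(seed)
        mask = np.ones(shape, bool)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        maps = ndimage.gaussian_filter(rng.standard_normal((n,) + shape),
                                       sigma=(0, 1.1, 1.1, 1.1), mode="wrap")
        model = gg.MassUnivariateGLM().fit(X, maps.reshape(n, -1))
        eff, t, z = model.contrast_stats([0, 1])
        fwhm, resels = gg.estimate_smoothness(model.residuals_, mask, 3.0)
        return gg.GroupGlmResult(effect=eff.reshape(shape),
                                 tstat=t.reshape(shape), zstat=z.reshape(shape),
                                 residual_fwhm=fwhm, resel_count=resels,
                                 df=model.df_, mask=mask, voxel_size=3.0,
                                 contrast="x")

    def test_zero_map_empty_table(self):
        res = self._null_result()
        res.zstat[:] = 0.0
        assert len(gg.grf_cluster_correct(res)) == 0

    def test_planted_blob_retained(self):
        res = self._null_result(seed=1)
        res.zstat[4:10, 4:10, 4:10] = 6.0      # ~200-voxel blob
        tab = gg.grf_cluster_correct(res, sign="pos")
        assert len(tab) >= 1
        assert tab.corrected_p.iloc[0] < 0.001
        assert tab.size_voxels.iloc[0] >= 200

    def test_sign_separation(self):
        res = self._null_result(seed=2)
        res.zstat[2:6, 2:6, 2:6] = -6.0
        assert len(gg.grf_cluster_correct(res, sign="pos")) == 0
        assert len(gg.grf_cluster_correct(res, sign="neg")) >= 1

    def test_invalid_resels(self):
        res = self._null_result(seed=3)
        res.resel_count = 0.0
        with pytest.raises(ParameterError):
            gg.grf_cluster_correct(res)


class TestPermutationOracle:
    def _planted_dataset(self, seed, effect=0.0, n=28, shape=(14, 14, 14)):
        rng = np.random.default_rng(seed)
        phenos = gstopo.simulate_phenotypes(n, seed=seed, t_frames=60)
        z = np.array([p.age_z for p in phenos])
        stack = ndimage.gaussian_filter(rng.standard_normal((n,) + shape),
                                        sigma=(0, 1.1, 1.1, 1.1), mode="wrap")
        stack[:, 4:9, 4:9, 4:9] += effect * z[:, None, None, None]
        return phenos, _maps_from_stack(stack)

    def test_zero_perm_rejected(self):
        phenos, maps = self._planted_dataset(0)
        design = gg.build_design(phenos)
        with pytest.raises(ParameterError):
            gg.permutation_cluster_null(maps, design, "age_linear", n_perm=0)

    def test_planted_cluster_significant_both_methods(self):
        phenos, maps = self._planted_dataset(1, effect=1.5)
        design = gg.build_design(phenos)
        perm = gg.permutation_cluster_null(maps, design, "age_linear",
                                           n_perm=200, seed=0)
        assert (perm["clusters"].corrected_p < 0.05).any()
        res = gg.voxelwise_glm(maps, design, "age_linear", voxel_size=3.0)
        tab = gg.grf_cluster_correct(res, sign="pos")
        assert len(tab) >= 1

    def test_grf_permutation_corrected_p_rank_agreement(self):
        """Graded planted clusters: GRF and permutation corrected p agree in
        rank (the permutation engine is the assumption-free reference)."""
        grf_ps, perm_ps = [], []
        widths = [2, 2, 3, 3, 4, 4, 5, 5]
        amps = [0.25, 0.45] * 4
        for i, (wd, amp) in enumerate(zip(widths, amps)):
            rng = np.random.default_rng(700 + i)
            n, shape = 28, (14, 14, 14)
            phenos = gstopo.simulate_phenotypes(n, seed=700 + i, t_frames=60)
            z = np.array([p.age_z for p in phenos])
            stack = ndimage.gaussian_filter(
                rng.standard_normal((n,) + shape), sigma=(0, 1.1, 1.1, 1.1),
                mode="wrap")
            stack /= stack.std()
            stack[:, 4:4 + wd, 4:4 + wd, 4:4 + wd] += \
                amp * z[:, None, None, None]
            maps = _maps_from_stack(stack)
            design = gg.build_design(phenos)
            res = gg.voxelwise_glm(maps, design, "age_linear", voxel_size=3.0)
            perm = gg.permutation_cluster_null(maps, design, "age_linear",
                                               n_perm=200, seed=i)
            if len(perm["clusters"]):
                top = perm["clusters"].iloc[0]
                grf_ps.append(gg.grf_cluster_p(
                    int(top.size_voxels), stats.norm.isf(0.001), res.mask,
                    res.residual_fwhm / res.voxel_size))
                perm_ps.append(float(top.corrected_p))
        assert len(grf_ps) >= 5
        assert stats.spearmanr(grf_ps, perm_ps).statistic > 0.9


class TestClusterScatter:
    def test_region_curve_signs(self, medium_cohort_maps):
        phenos, atlas, maps = medium_cohort_maps
        thal = gg.cluster_scatter(maps, phenos, atlas.region_mask("thalamus"))
        put = gg.cluster_scatter(maps, phenos, atlas.region_mask("putamen"))
        nb = gg.cluster_scatter(maps, phenos,
                                atlas.region_mask("nucleus_basalis"))
        assert thal["coefficients"]["linear"] > 0
        assert put["coefficients"]["linear"] < 0
        assert nb["coefficients"]["quadratic"] > 0
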
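"""ICA denoising cascade: planted-source recovery, classification, cleanup."""

import numpy as np
import pytest
from scipy import stats

from gstopo.cohort import BoldRun
from gstopo.exceptions import (DegenerateError, ParameterError, ProvenanceError,
                               ShapeError)
from gstopo.ica import (IcaCascadeModel, classify_noise, clean_sica_timecourses,
                        component_features, concat_frames, group_sica,
                        subject_cleanup, temporal_ica, ComponentFeatures)
from gstopo.preprocess import BandpassFilter, NuisanceRegressor, friston24


def _best_assignment_corr(recovered, truth):
    """Max |corr| match of each true pattern to some recovered one (greedy)."""
    k = truth.shape[0]
    c = np.abs(np.corrcoef(np.vstack([truth, recovered]))[:k, k:])
    out = []
    taken = set()
    for i in range(k):
        j = int(np.argmax([c[i, j] if j not in taken else -1
                           for j in range(c.shape[1])]))
        taken.add(j)
        out.append(c[i, j])
    return np.array(out)


def _blob_runs(seed=0, n_sub=3, t=80):
    """Three disjoint spatial blobs driven by independent heavy-tailed TCs."""
    rng = np.random.default_rng(seed)
    shape = (12, 12, 12)
    blobs = np.zeros((3,) + shape)
    blobs[0, 1:5, 1:5, 1:5] = 1.0
    blobs[1, 7:11, 7:11, 1:5] = 1.0
    blobs[2, 1:5, 7:11, 7:11] = 1.0
    runs, tcs = [], []
    for s in range(n_sub):
        tc = rng.standard_t(df=3, size=(3, t))
        data = np.einsum("kxyz,kt->xyzt", blobs, tc)
        data += 0.01 * rng.standard_normal(data.shape)
        runs.append(BoldRun(data=data.astype(np.float32), tr=1.4, voxel_size=3.0,
                            motion_params=np.zeros((t, 6)),
                            phenotype_ref=f"sub-{s:04d}"))
        tcs.append(tc)
    return runs, blobs, tcs, shape


class TestGroupSpatialICA:
    def test_planted_blob_recovery(self):
        runs, blobs, _, shape = _blob_runs()
        mask = np.ones(shape, bool)
        model = group_sica(runs, mask, k=3, seed=0)
        rec = _best_assignment_corr(model.sica_maps, blobs.reshape(3, -1))
        assert (rec > 0.95).all()

    def test_component_count_contract(self, smoothed_runs, brain):
        model = group_sica(smoothed_runs[:6], brain, k=5, seed=1)
        assert model.sica_maps.shape[0] == 5
        assert model.sica_timecourses.shape == (6, smoothed_runs[0].t_frames, 5)

    def test_duplicate_subjects_identical_maps(self):
        runs, _, _, shape = _blob_runs(seed=3)
        mask = np.ones(shape, bool)
        m1 = group_sica(runs, mask, k=3, seed=2)
        m2 = group_sica(runs + runs, mask, k=3, seed=2)
        match = _best_assignment_corr(m2.sica_maps, m1.sica_maps)
        assert (match > 0.999).all()

    def test_concat_row_invariant(self, smoothed_runs, brain):
        model = group_sica(smoothed_runs[:4], brain, k=4, seed=0)
        n, t, k = model.sica_timecourses.shape
        assert n * t == concat_frames(4, smoothed_runs[0].t_frames)

    def test_determinism(self):
        runs, _, _, shape = _blob_runs(seed=5)
        mask = np.ones(shape, bool)
        m1 = group_sica(runs, mask, k=3, seed=9)
        m2 = group_sica(runs, mask, k=3, seed=9)
        assert np.array_equal(m1.sica_maps, m2.sica_maps)
        assert np.array_equal(m1.sica_timecourses, m2.sica_timecourses)


class TestClassifyNoise:
    def _features(self, vol, tc, mask, gray, tr=1.4):
        return component_features(vol[mask][None, :], tc[None, :, None],
                                  mask, gray, tr)[0]

    def test_striped_component_flagged(self, atlas, gm, brain):
        rng = np.random.default_rng(0)
        shape = atlas.labels.shape
        stripes = np.where((np.arange(shape[2]) // 2) % 2 == 0, 1.0, -1.0)
        vol = np.ones(shape) * stripes[None, None, :]
        tc = rng.standard_normal(120)
        f = self._features(vol, tc, brain, gm)
        assert f.stripe_score > 0.5
        assert classify_noise([f])[0]

    def test_brainstem_edge_component_flagged(self, atlas, gm, brain):
        rng = np.random.default_rng(1)
        vol = np.zeros(atlas.labels.shape)
        vol[~gm & brain] = 1.0           # energy concentrated outside gray
        f = self._features(vol, rng.standard_normal(120), brain, gm)
        assert f.edge_fraction > 0.35
        assert classify_noise([f])[0]

    def test_inband_gray_component_clean(self, atlas, gm, brain):
        from gstopo.cohort import band_limited_series
        rng = np.random.default_rng(2)
        vol = np.zeros(atlas.labels.shape)
        vol[atlas.region_mask("fpn")] = 1.0
        tc = band_limited_series(120, 1.4, 0.01, 0.1, rng)
        f = self._features(vol, tc, brain, gm)
        assert not classify_noise([f])[0]

    def test_high_frequency_component_flagged(self, atlas, gm, brain):
        from gstopo.cohort import band_limited_series
        rng = np.random.default_rng(3)
        vol = np.zeros(atlas.labels.shape)
        vol[atlas.region_mask("gray_background")] = 1.0
        tc = band_limited_series(120, 1.4, 0.15, 0.3, rng)
        f = self._features(vol, tc, brain, gm)
        assert f.hf_power_fraction > 0.5
        assert classify_noise([f])[0]

    def test_global_negative_component_toggle(self, atlas, gm, brain):
        from gstopo.ica import global_negativity
        from gstopo.cohort import band_limited_series
        rng = np.random.default_rng(9)
        vol = np.zeros(atlas.labels.shape)
        vol[gm] = -1.0                 # uniform cortical negativity
        tc = band_limited_series(120, 1.4, 0.01, 0.1, rng)
        f = self._features(vol, tc, brain, gm)
        neg = global_negativity(vol[brain][None, :], brain, gm)
        assert classify_noise([f], global_negativity=neg,
                              treat_global_negative_as_noise=True)[0]
        assert not classify_noise([f], global_negativity=neg,
                                  treat_global_negative_as_noise=False)[0]

    def test_overrides_win(self):
        f = ComponentFeatures(edge_fraction=0.9, hf_power_fraction=0.9,
                              spike_score=99.0, stripe_score=1.0)
        assert not classify_noise([f], overrides=np.array([False]))[0]


class TestCleanTimecourses:
    def _model(self, k=6, noise_idx=(0, 1), n=2, t=60, seed=0):
        rng = np.random.default_rng(seed)
        tcs = rng.standard_normal((n, t, k))
        model = IcaCascadeModel(mask=np.ones((4, 4, 4), bool),
                                subject_ids=[f"sub-{i:04d}" for i in range(n)],
                                t_frames=t, sica_maps=rng.standard_normal((k, 64)),
                                sica_timecourses=tcs)
        labels = np.zeros(k, bool)
        labels[list(noise_idx)] = True
        model.set_labels("sica", labels)
        return model

    def test_zero_noise_identity(self):
        model = self._model(noise_idx=())
        cleaned = clean_sica_timecourses(model)
        expected = model.sica_timecourses.reshape(-1, 6)
        assert np.array_equal(cleaned, expected)

    def test_residual_orthogonal_to_noise(self):
        model = self._model(seed=4)
        # plant contamination: non-noise TC = 0.5*noise + independent part
        model.sica_timecourses[:, :, 2] = (
            0.5 * model.sica_timecourses[:, :, 0]
            + np.random.default_rng(5).standard_normal((2, 60)))
        cleaned = clean_sica_timecourses(model)
        for s in range(2):
            block = cleaned[s * 60:(s + 1) * 60]
            r = np.corrcoef(block[:, 0], model.sica_timecourses[s, :, 0])[0, 1]
            assert abs(r) < 0.05

    def test_study_scale_bookkeeping(self):
        model = self._model(k=125, noise_idx=range(39), n=2, t=50)
        cleaned = clean_sica_timecourses(model)
        assert cleaned.shape == (2 * 50, 86)

    def test_all_noise_rejected(self):
        model = self._model(noise_idx=range(6))
        with pytest.raises(DegenerateError):
            clean_sica_timecourses(model)


class TestTemporalICA:
    def test_planted_source_recovery(self):
        rng = np.random.default_rng(0)
        nt, k = 2000, 3
        sources = rng.standard_t(df=3, size=(nt, k))
        mixing = rng.standard_normal((6, k))
        X = sources @ mixing.T
        model = IcaCascadeModel(mask=np.ones((4, 4, 4), bool),
                                subject_ids=["sub-0000"], t_frames=nt,
                                sica_maps=rng.standard_normal((6, 64)),
                                sica_timecourses=X[None, ...])
        model.set_labels("sica", np.zeros(6, bool))
        clean_sica_timecourses(model)
        temporal_ica(model, k_t=3, seed=0)
        rec = _best_assignment_corr(model.tica_timecourses.T, sources.T)
        assert (rec > 0.95).all()
        assert model.tica_mixing.shape == (6, 3)

    def test_k_exceeds_channels(self):
        rng = np.random.default_rng(1)
        model = IcaCascadeModel(mask=np.ones((4, 4, 4), bool),
                                subject_ids=["sub-0000"], t_frames=100,
                                sica_maps=rng.standard_normal((4, 64)),
                                sica_timecourses=rng.standard_normal((1, 100, 4)))
        model.set_labels("sica", np.zeros(4, bool))
        clean_sica_timecourses(model)
        with pytest.raises(ParameterError):
            temporal_ica(model, k_t=10, seed=0)

    def test_group_maps_are_mixing_weighted_sums(self, cascade):
        model, _ = cascade
        nonnoise = model.sica_maps[~model.sica_noise_labels]
        expected = (nonnoise.T @ model.tica_mixing).T
        assert np.allclose(model.tica_maps, expected)


class TestSubjectCleanup:
    def test_all_nonnoise_equals_motion_detrend_bandpass(self, small_cohort,
                                                         smoothed_runs, brain, gm):
        _, _, latents = small_cohort
        from gstopo.ica import group_sica
        runs = smoothed_runs[:3]
        model = group_sica(runs, brain, k=4, seed=0)
        model.set_labels("sica", np.zeros(4, bool))
        clean_sica_timecourses(model)
        temporal_ica(model, k_t=3, seed=1)
        model.set_labels("tica", np.zeros(3, bool))
        run = runs[0]
        out = subject_cleanup(run, model)
        flat = run.data.reshape(-1, run.t_frames).T.astype(float)
        nr = NuisanceRegressor(regressors=friston24(run.motion_params).regressors,
                               detrend=True).fit(flat)
        ref = BandpassFilter(tr=run.tr).fit().transform(nr.transform(flat))
        assert np.abs(out.data.reshape(-1, run.t_frames).T - ref).max() < 1e-4

    def test_unknown_subject_rejected(self, cascade, smoothed_runs):
        model, _ = cascade
        import dataclasses
        alien = dataclasses.replace(smoothed_runs[0], phenotype_ref="sub-9999")
        with pytest.raises(ProvenanceError):
            subject_cleanup(alien, model)

    def test_labels_frozen_after_cleanup(self, cascade):
        model, _ = cascade
        with pytest.raises(ProvenanceError):
            model.set_labels("sica", np.zeros(model.k_sica, bool))

    def test_respiratory_noise_attenuated(self, small_cohort, cascade):
        _, _, latents = small_cohort
        _, cleaned = cascade
        frac_low = []
        for run, lat in zip(cleaned, latents):
            resp = lat.structured_noise[0]
            resp_c = (resp - resp.mean()) / resp.std()
            flat = run.data.reshape(-1, run.t_frames).astype(float)
            sd = flat.std(axis=1)
            ok = sd > 0
            r = (flat[ok] - flat[ok].mean(axis=1, keepdims=True)) @ resp_c \
                / (run.t_frames * sd[ok])
            frac_low.append(np.mean(np.abs(r) < 0.1))
        assert np.mean(frac_low) > 0.95

    def test_cascade_rerun_bit_identical(self, small_cohort, smoothed_runs,
                                         brain, gm):
        from gstopo.ica import run_cascade
        _, _, latents = small_cohort
        runs = smoothed_runs[:5]
        m1, c1 = run_cascade(runs, brain, gm, 6, 4, seed=3, labels="manifest",
                             latents=latents[:5])
        m2, c2 = run_cascade(runs, brain, gm, 6, 4, seed=3, labels="manifest",
                             latents=latents[:5])
        assert np.array_equal(m1.sica_noise_labels, m2.sica_noise_labels)
        assert np.array_equal(m1.tica_timecourses, m2.tica_timecourses)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.data, b.data)


def test_conservative_vs_liberal_labels_same_sign_pattern(small_cohort,
                                                          smoothed_runs, brain,
                                                          gm, atlas):
    """Toggling one borderline noise component leaves group age-effect signs."""
    from gstopo.ica import run_cascade, labels_from_latents, group_sica
    import gstopo.topography as tp
    import gstopo.glm as gg
    phenos, _, latents = small_cohort

    def group_sign(cleaned):
        maps = [tp.topography_map(r, tp.compute_gs(r, gm), mask=brain)
                for r in cleaned]
        design = gg.build_design(phenos, quadratic=False)
        res = gg.voxelwise_glm(maps, design, "age_linear", voxel_size=3.0)
        thal = np.nanmean(res.zstat[atlas.region_mask("thalamus")])
        put = np.nanmean(res.zstat[atlas.region_mask("putamen")])
        return np.sign(thal), np.sign(put)

    base = group_sica(smoothed_runs, brain, k=12, seed=7)
    labels = labels_from_latents(base.sica_timecourses, latents)
    liberal = labels.copy()
    liberal[int(np.flatnonzero(~labels)[-1])] = True    # one extra "noise" comp
    signs = []
    for lab in (labels, liberal):
        model = group_sica(smoothed_runs, brain, k=12, seed=7)
        model.set_labels("sica", classify_noise([], overrides=lab))
        clean_sica_timecourses(model)
        temporal_ica(model, 8, seed=8)
        model.set_labels("tica", labels_from_latents(model.tica_timecourses,
                                                     latents))
        cleaned = [subject_cleanup(r, model) for r in smoothed_runs]
        signs.append(group_sign(cleaned))
    assert signs[0] == signs[1] == (1.0, -1.0)
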
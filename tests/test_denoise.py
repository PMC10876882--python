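"""Nuisance-regressor construction and removal for the five methods."""

import numpy as np
import pytest

import fastbold as fb
from fastbold.containers import CSF, GM, WM
from fastbold.denoise import (
    acompcor_regressors,
    aroma_like_components,
    erode_mask,
    gsr_regressor,
    high_frequency_content,
    no_correction,
    regress_nuisance,
    tcompcor_regressors,
    wmcsf_regressors,
)

from conftest import toy_series


def _grid_series(values, shape, tissue=None, tr=0.38):
    """Series whose rows enumerate a full 3-D grid in C order."""
    idx = np.argwhere(np.ones(shape, dtype=bool))
    return fb.VoxelTimeSeries(
        values=values, tr=tr, voxel_index=idx, tissue=tissue, grid_shape=shape
    )


class TestGSR:
    def test_recovers_shared_global_course(self, rng):
        T, V = 500, 1000
        g = rng.normal(size=T)
        vals = g[None, :] + rng.normal(size=(V, T))
        nuis = gsr_regressor(toy_series(vals))
        r = np.corrcoef(nuis.regressors[:, 0], g)[0, 1]
        assert r > 0.99
        assert nuis.regressors[:, 0].mean() == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_data_warns(self):
        # zero voxels are not representable (constant rows are fine)
        vals = np.zeros((5, 50))
        with pytest.warns(UserWarning, match="zero"):
            nuis = gsr_regressor(toy_series(vals))
        np.testing.assert_array_equal(nuis.regressors, 0.0)

    def test_csf_only_mask_rejected(self, rng):
        vals = rng.normal(size=(4, 50))
        tissue = np.full(4, CSF)
        series = toy_series(vals, tissue=tissue)
        with pytest.raises(ValueError, match="empty"):
            gsr_regressor(series)


class TestWMCSF:
    def test_recovers_tissue_courses(self, rng, subject):
        # plant known courses into the subject's WM and CSF voxels
        series = subject.bold.with_values(subject.bold.values.copy())
        T = series.n_timepoints
        w, c = rng.normal(size=(2, T))
        series.values[series.tissue == WM] = w + 0.1 * rng.normal(
            size=((series.tissue == WM).sum(), T)
        )
        series.values[series.tissue == CSF] = c + 0.1 * rng.normal(
            size=((series.tissue == CSF).sum(), T)
        )
        nuis = wmcsf_regressors(series, erosion_voxels=1)
        assert nuis.k == 2
        assert abs(np.corrcoef(nuis.regressors[:, 0], w)[0, 1]) > 0.99
        assert abs(np.corrcoef(nuis.regressors[:, 1], c)[0, 1]) > 0.99

    def test_zero_erosion_is_plain_mask_mean(self, subject):
        series = subject.bold
        nuis = wmcsf_regressors(series, erosion_voxels=0)
        wm_mean = series.values[series.tissue == WM].mean(axis=0)
        np.testing.assert_allclose(
            nuis.regressors[:, 0], wm_mean - wm_mean.mean(), atol=1e-10
        )

    def test_overerosion_names_the_emptied_mask(self, subject):
        with pytest.raises(ValueError, match="white_matter|csf"):
            wmcsf_regressors(subject.bold, erosion_voxels=4)


class TestACompCor:
    def test_recovers_two_planted_orthogonal_sources(self, rng, subject):
        series = subject.bold.with_values(subject.bold.values.copy())
        T = series.n_timepoints
        s1 = np.sin(2 * np.pi * 0.2 * np.arange(T) * series.tr)
        s2 = np.cos(2 * np.pi * 0.45 * np.arange(T) * series.tr)
        wm, csf = series.tissue == WM, series.tissue == CSF
        series.values[wm] = 5 * s1 + 0.2 * rng.normal(size=(wm.sum(), T))
        series.values[csf] = 5 * s2 + 0.2 * rng.normal(size=(csf.sum(), T))
        nuis = acompcor_regressors(series, n_components=2)
        got = nuis.regressors
        cors = np.abs(np.corrcoef(np.column_stack([s1, s2, got]).T)[:2, 2:])
        # each source matched by one of the two components
        assert cors.max(axis=1).min() > 0.95

    def test_components_orthogonal(self, pre_series):
        nuis = acompcor_regressors(pre_series, n_components=5)
        assert nuis.k == 5
        gram = nuis.regressors.T @ nuis.regressors
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()
        ev = nuis.metadata["explained_variance"]
        assert all(a >= b for a, b in zip(ev, ev[1:]))

    def test_constant_rows_dropped(self, rng):
        shape = (8, 8, 6)
        n = np.prod(shape)
        vals = rng.normal(size=(n, 60))
        tissue = np.full(n, WM)
        vals[:10] = 3.0  # constant voxels inside the mask
        series = _grid_series(vals, shape, tissue=tissue)
        nuis = acompcor_regressors(series, n_components=3, erosion_voxels=0)
        assert np.isfinite(nuis.regressors).all()

    def test_insufficient_voxels_rejected(self, rng):
        shape = (4, 4, 2)
        vals = rng.normal(size=(32, 30))
        tissue = np.full(32, GM)
        tissue[:3] = WM  # 3 WM voxels < 5 components
        series = _grid_series(vals, shape, tissue=tissue)
        with pytest.raises(ValueError, match="voxels"):
            acompcor_regressors(series, n_components=5, erosion_voxels=0)


class TestTCompCor:
    def test_high_variance_cluster_found_as_first_component(self, rng):
        shape = (8, 8, 4)
        n = np.prod(shape)
        T = 400
        vals = rng.normal(size=(n, T))
        source = 10 * np.sin(2 * np.pi * 1.0 * np.arange(T) * 0.38)
        vals[:6] += source  # small high-amplitude cluster
        series = _grid_series(vals, shape, tr=0.38)
        nuis = tcompcor_regressors(series, std_percentile=90)
        r = abs(np.corrcoef(nuis.regressors[:, 0], source)[0, 1])
        assert r > 0.95

    def test_variance_target_one_returns_full_rank(self, rng):
        shape = (6, 6, 2)
        vals = rng.normal(size=(72, 40))
        series = _grid_series(vals, shape)
        nuis = tcompcor_regressors(series, std_percentile=90, variance_target=1.0)
        n_sel = nuis.metadata["n_voxels"]
        assert nuis.k == min(n_sel, series.n_timepoints - 1)

    def test_uniform_noise_flat_spectrum_of_variance(self, rng):
        shape = (8, 8, 4)
        vals = rng.normal(size=(np.prod(shape), 200))
        series = _grid_series(vals, shape)
        nuis = tcompcor_regressors(series)
        assert nuis.k >= 1
        ev = np.asarray(nuis.metadata["explained_variance"])
        assert ev.max() / ev.min() < 5  # no dominant direction


class TestAromaClassifier:
    def test_hfc_of_pure_tone(self):
        # 1 Hz tone at TR 0.38 s: half the power sits at 1.0/1.316 of Nyquist
        t = np.arange(1950) * 0.38
        hfc = high_frequency_content(np.sin(2 * np.pi * 1.0 * t), tr=0.38)
        assert hfc == pytest.approx(1.0 / (1.0 / (2 * 0.38)), rel=0.02)
        assert hfc > 0.35  # lands on the noise side of the HFC threshold

    def _planted_subject(self, rng, T=700):
        """Background noise + four spatially disjoint planted components."""
        shape = (12, 12, 8)
        idx = np.argwhere(np.ones(shape, dtype=bool))
        center = np.array(shape) / 2.0
        r = np.sqrt((((idx - center + 0.5) / (np.array(shape) / 2.0)) ** 2).sum(axis=1))
        brain = r <= 0.95
        idx = idx[brain]
        n = idx.shape[0]
        tissue = np.full(n, GM)
        rr = r[brain]
        tissue[rr > 0.85] = CSF
        tr = 0.38
        t = np.arange(T) * tr
        vals = rng.normal(size=(n, T))
        motion = np.cumsum(rng.normal(size=(T, 6)) * 0.01, axis=0)

        def bandpass(lo, hi):
            spec = np.fft.rfft(rng.standard_normal(T))
            f = np.fft.rfftfreq(T, tr)
            spec[(f < lo) | (f > hi)] = 0
            x = np.fft.irfft(spec, T)
            return (x - x.mean()) / x.std()

        interior = np.flatnonzero((tissue == GM) & (rr < 0.7))
        quarters = np.array_split(interior, 4)
        courses = {
            "tone": np.sin(2 * np.pi * 1.0 * t),
            "motion": (motion[:, 0] - motion[:, 0].mean()) / motion[:, 0].std(),
            "network": bandpass(0.02, 0.04),
        }
        vals[quarters[0]] += 6 * courses["tone"]
        vals[quarters[1]] += 6 * courses["motion"]
        vals[quarters[2]] += 6 * courses["network"]
        edge = np.flatnonzero(tissue == CSF)[: max(8, n // 10)]
        courses["edge"] = bandpass(0.05, 0.2)
        vals[edge] += 6 * courses["edge"]
        series = fb.VoxelTimeSeries(
            values=vals, tr=tr, voxel_index=idx, tissue=tissue, grid_shape=shape
        )
        return series, motion, courses

    def _match(self, report, course):
        cors = [
            abs(np.corrcoef(report.time_courses[:, k], course)[0, 1])
            for k in range(report.time_courses.shape[1])
        ]
        return int(np.argmax(cors)), max(cors)

    def test_planted_components_classified(self, rng):
        series, motion, courses = self._planted_subject(rng)
        report = aroma_like_components(series, motion, n_components=8, seed=1)
        labels = report.features["classification"]
        k, r = self._match(report, courses["tone"])
        assert r > 0.9 and labels[k] == "noise"
        assert report.features.loc[k, "hfc"] > 0.35
        k, r = self._match(report, courses["motion"])
        assert r > 0.9 and labels[k] == "noise"
        assert report.features.loc[k, "max_rp_corr"] > 0.95
        k, r = self._match(report, courses["edge"])
        assert r > 0.9 and labels[k] == "noise"
        k, r = self._match(report, courses["network"])
        assert r > 0.9 and labels[k] == "signal"

    def test_feature_ranges(self, rng):
        series, motion, _ = self._planted_subject(rng, T=400)
        report = aroma_like_components(series, motion, n_components=6, seed=0)
        f = report.features
        for col in ("hfc", "edge_fract", "csf_fract"):
            assert ((f[col] >= 0) & (f[col] <= 1)).all()
        assert f["classification"].isin(["noise", "signal"]).all()

    def test_too_few_timepoints_rejected(self, rng):
        series, motion, _ = self._planted_subject(rng, T=400)
        with pytest.raises(ValueError, match="timepoints"):
            aroma_like_components(series, motion, n_components=500)


class TestRegressNuisance:
    def test_voxel_equal_to_regressor_zeroed(self, rng):
        g = rng.normal(size=200)
        vals = np.vstack([g, rng.normal(size=200)])
        series = toy_series(vals)
        nuis = fb.NuisanceSet(method="GSR", regressors=(g - g.mean())[:, None],
                              names=["global_signal"])
        out = regress_nuisance(series, nuis)
        assert np.linalg.norm(out.values[0]) < 1e-8 * np.linalg.norm(vals[0])

    def test_orthogonal_voxel_unchanged(self):
        T = 400
        t = np.arange(T)
        reg = np.sin(2 * np.pi * 5 * t / T)
        voxel = np.sin(2 * np.pi * 11 * t / T)  # orthogonal harmonic, zero mean
        series = toy_series(voxel)
        nuis = fb.NuisanceSet(method="GSR", regressors=reg[:, None], names=["g"])
        out = regress_nuisance(series, nuis)
        np.testing.assert_allclose(out.values[0], voxel, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        vals = rng.normal(size=(20, 300))
        series = toy_series(vals)
        regs = rng.normal(size=(300, 4))
        regs -= regs.mean(axis=0)
        nuis = fb.NuisanceSet(method="aCompCor", regressors=regs,
                              names=[f"a_comp_cor_{i:02d}" for i in range(4)])
        out = regress_nuisance(series, nuis)
        ip = out.values @ regs
        norms = np.linalg.norm(out.values, axis=1)[:, None] * np.linalg.norm(regs, axis=0)
        assert np.abs(ip / norms).max() < 1e-8

    def test_variance_never_increases(self, rng):
        vals = rng.normal(size=(30, 250))
        series = toy_series(vals)
        regs = rng.normal(size=(250, 3))
        regs -= regs.mean(axis=0)
        nuis = fb.NuisanceSet(method="aCompCor", regressors=regs,
                              names=["a", "b", "c"])
        out = regress_nuisance(series, nuis)
        assert (out.values.var(axis=1) <= series.values.var(axis=1) + 1e-12).all()

    def test_column_order_invariance(self, rng):
        vals = rng.normal(size=(10, 150))
        series = toy_series(vals)
        regs = rng.normal(size=(150, 3))
        regs -= regs.mean(axis=0)
        a = regress_nuisance(series, fb.NuisanceSet(
            method="aCompCor", regressors=regs, names=["a", "b", "c"]))
        b = regress_nuisance(series, fb.NuisanceSet(
            method="aCompCor", regressors=regs[:, ::-1], names=["c", "b", "a"]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_nonaggressive_equals_aggressive_under_orthogonality(self, rng):
        """With noise components orthogonal to signal components, removing the
        noise set non-aggressively equals aggressive removal of that set."""
        T = 300
        M = rng.normal(size=(T, 6))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)  # zero-mean *and* orthonormal columns
        noise_flags = np.array([True, True, False, False, False, False])
        vals = rng.normal(size=(15, T))
        series = toy_series(vals)
        nonagg = regress_nuisance(series, fb.NuisanceSet(
            method="AROMA", regressors=Q, names=list("abcdef"),
            mode="nonaggressive", noise_flags=noise_flags))
        agg = regress_nuisance(series, fb.NuisanceSet(
            method="AROMA", regressors=Q[:, :2], names=list("ab"),
            mode="aggressive"))
        scale = np.abs(vals).max()
        np.testing.assert_allclose(nonagg.values, agg.values, atol=1e-8 * scale)

    def test_collinear_columns_dropped_with_warning(self, rng):
        vals = rng.normal(size=(5, 100))
        series = toy_series(vals)
        base = rng.normal(size=(100, 2))
        base -= base.mean(axis=0)
        regs = np.column_stack([base, base[:, 0] + base[:, 1]])
        nuis = fb.NuisanceSet(method="aCompCor", regressors=regs,
                              names=["a", "b", "a+b"])
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_nuisance(series, nuis)
        ip = out.values @ base
        assert np.abs(ip).max() < 1e-6

    def test_none_method_only_demeans(self, rng):
        vals = 7.0 + rng.normal(size=(4, 80))
        series = toy_series(vals)
        out = regress_nuisance(series, no_correction(series))
        np.testing.assert_allclose(
            out.values, vals - vals.mean(axis=1, keepdims=True), atol=1e-12
        )

    def test_gsr_residuals_uncorrelated_with_global(self, pre_series):
        nuis = gsr_regressor(pre_series)
        out = regress_nuisance(pre_series, nuis)
        g = nuis.regressors[:, 0]
        cors = (out.values @ g) / (
            np.linalg.norm(out.values, axis=1) * np.linalg.norm(g)
        )
        assert np.abs(cors).max() < 1e-8


class TestOracleCardiacRemoval:
    def test_true_cardiac_regression_removes_injected_fraction(self, small_cohort):
        """Regressing the generator's own cardiac course removes cardiac-band
        power equal to the injected cardiac variance fraction (15% rel tol)."""
        from scipy.signal import periodogram

        for sub in small_cohort[:2]:
            series = fb.highpass(sub.bold, 0.01)
            truth = sub.ground_truth
            card = truth.course("cardiac")
            nuis = fb.NuisanceSet(
                method="GSR", regressors=(card - card.mean())[:, None],
                names=["true_cardiac"],
            )
            out = regress_nuisance(series, nuis)
            band = fb.cardiac_band(truth.cardiac_freq)
            gm = series.tissue == GM
            f, p0 = periodogram(series.values[gm], fs=1 / series.tr, detrend="constant")
            _, p1 = periodogram(out.values[gm], fs=1 / series.tr, detrend="constant")
            sel = (f >= band.lo) & (f <= band.hi)
            df = f[1] - f[0]
            removed = (p0[:, sel].sum(axis=1) - p1[:, sel].sum(axis=1)) * df
            frac = removed.mean() / series.values[gm].var(axis=1).mean()
            injected = truth.fractions.loc[np.asarray(gm), "cardiac"].mean()
            assert frac == pytest.approx(injected, rel=0.15)


class TestErosion:
    def test_erosion_shrinks_and_zero_iterations_identity(self, subject):
        series = subject.bold
        wm = series.tissue == WM
        assert erode_mask(wm, series, 0).sum() == wm.sum()
        eroded = erode_mask(wm, series, 1)
        assert 0 < eroded.sum() < wm.sum()
        assert (wm[eroded]).all()
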
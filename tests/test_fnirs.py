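"""fNIRS preprocessing: OD conversion, channel QC, motion correction, the
modified Beer-Lambert inversion, filtering, downsampling and aggregation."""

import numpy as np
import pandas as pd
import pytest

from dyadsync import fnirs, optics
from dyadsync.simulate import SimulationConfig, generate_dyad_hemo, inject_motion_artifacts

RATE = fnirs.SAMPLING_RATE


def make_recording(rng, n_t=600, signal_uM=0.3, noise=0.0):
    """Forward-model recording with known concentrations."""
    t = np.arange(n_t) / RATE
    hbo = signal_uM * np.sin(2 * np.pi * 0.05 * t)[None, :] * np.ones((8, 1))
    hbr = -0.3 * hbo
    od = optics.mbll_forward(hbo, hbr, 3.0, 30.0)       # (wl, ch, t)
    od = np.moveaxis(od, 0, 1)
    if noise:
        od = od + rng.normal(0, noise, od.shape)
    intensity = 1.2 * np.exp(-od)
    rec = fnirs.IntensityRecording(samples=intensity, age_years=30.0)
    return rec, hbo, hbr


class TestOd:
    def test_constant_intensity_zero_od(self):
        rec = fnirs.IntensityRecording(samples=np.full((8, 2, 300), 2.0))
        od = fnirs.intensity_to_od(rec)
        np.testing.assert_allclose(od.od, 0.0, atol=1e-15)

    def test_unit_od_closed_form(self):
        x = np.full((8, 2, 300), np.e)
        # one sample at mean/e: od = 1 + ln(mean ratio correction)
        samples = np.ones((8, 2, 300))
        samples[0, 0, 10] = 1 / np.e
        rec = fnirs.IntensityRecording(samples=samples)
        od = fnirs.intensity_to_od(rec)
        ref = samples[0, 0].mean()
        assert od.od[0, 0, 10] == pytest.approx(-np.log((1 / np.e) / ref), abs=1e-12)

    def test_matches_bruteforce(self, rng):
        samples = rng.uniform(0.5, 2.0, (8, 2, 128))
        od = fnirs.intensity_to_od(fnirs.IntensityRecording(samples=samples))
        expect = -np.log(samples / samples.mean(axis=2, keepdims=True))
        np.testing.assert_allclose(od.od, expect, atol=1e-12)

    def test_nonpositive_intensity_names_channel(self):
        samples = np.ones((8, 2, 300))
        samples[3, 1, 5] = 0.0
        with pytest.raises(ValueError, match="channel 3"):
            fnirs.intensity_to_od(fnirs.IntensityRecording(samples=samples))


class TestPruning:
    def test_clean_channels_usable(self, rng):
        rec, *_ = make_recording(rng)
        q = fnirs.prune_channels(fnirs.intensity_to_od(rec))
        assert q["usable"].all()

    def test_flatline_channel_pruned(self, rng):
        rec, *_ = make_recording(rng)
        rec.samples[2, :, :] = 1.0
        q = fnirs.prune_channels(fnirs.intensity_to_od(rec))
        assert not q.loc[q.channel == 2, "usable"].item()
        assert "flatline" in q.loc[q.channel == 2, "reason"].item()

    def test_high_cv_channel_pruned(self, rng):
        rec, *_ = make_recording(rng)
        rec.samples[5, 0, :] *= rng.uniform(0.2, 3.0, rec.samples.shape[-1])
        q = fnirs.prune_channels(fnirs.intensity_to_od(rec))
        assert not q.loc[q.channel == 5, "usable"].item()

    def test_region_validity_rule(self):
        q = pd.DataFrame(dict(channel=range(8),
                              region=["left_dlPFC"] * 4 + ["right_dlPFC"] * 4,
                              usable=[True, True, False, False] + [True] * 4))
        valid = fnirs.region_validity(q)
        assert valid == {"left_dlPFC": True, "right_dlPFC": True}
        q.loc[1, "usable"] = False
        assert fnirs.region_validity(q)["left_dlPFC"] is False


class TestChannelAccounting:
    def test_study_numbers(self):
        acc = fnirs.channel_accounting(usable_dyads=65, enrolled_dyads=80)
        assert acc["analyzed_channels"] == 1040
        assert acc["total_channels"] == 1280
        assert acc["pct_usable"] == pytest.approx(81.25)
        assert acc["pct_excluded"] == pytest.approx(18.75)

    def test_degenerate_zero(self):
        acc = fnirs.channel_accounting(0, 80)
        assert acc["analyzed_channels"] == 0 and acc["pct_usable"] == 0.0


class TestMotionCorrection:
    def _od(self, rng, noise=0.002):
        rec, *_ = make_recording(rng, noise=noise)
        od = fnirs.intensity_to_od(rec)
        fnirs.prune_channels(od)
        return od

    def test_artifact_free_nearly_unchanged(self, rng):
        od = self._od(rng, noise=0.0)
        out = fnirs.spline_motion_correct(od)
        np.testing.assert_allclose(out.od, od.od, atol=1e-6)

    def test_step_shift_removed(self, rng):
        od = self._od(rng)
        clean = od.od[0, 0].copy()
        step_at = 300
        od.od[0, 0, step_at:] += 0.15
        out = fnirs.spline_motion_correct(od)
        def level_diff(x):
            return abs(x[step_at + 20: step_at + 80].mean()
                       - x[step_at - 80: step_at - 20].mean())
        assert level_diff(out.od[0, 0]) < 0.1 * level_diff(od.od[0, 0])

    def test_spike_rmse_reduced(self, rng):
        od = self._od(rng)
        clean = od.od.copy()
        corrupt, mask = inject_motion_artifacts(od.od[1, 0], RATE, 6.0, rng)
        od.od[1, 0] = corrupt
        out = fnirs.spline_motion_correct(od)
        out = fnirs.wavelet_motion_correct(out)
        def rmse(x):
            return np.sqrt(np.mean((x - clean[1, 0]) ** 2))
        assert rmse(out.od[1, 0]) < rmse(corrupt)

    def test_wavelet_spike_attenuated(self, rng):
        od = self._od(rng)
        od.history.append("spline")
        base = od.od[0, 1].copy()
        od.od[0, 1, 250] += 0.5
        out = fnirs.wavelet_motion_correct(od)
        residual = abs(out.od[0, 1, 250] - base[250])
        assert residual < 0.2 * 0.5

    def test_wavelet_no_outliers_near_identity(self, rng):
        od = self._od(rng, noise=0.002)
        od.history.append("spline")
        out = fnirs.wavelet_motion_correct(od, iqr_k=1e9)
        np.testing.assert_allclose(out.od, od.od, atol=1e-9)


class TestBeerLambert:
    def test_zero_od_zero_concentration(self):
        hbo, hbr = optics.mbll_inverse(np.zeros((2, 8, 100)), 3.0, 30.0)
        assert np.all(hbo == 0) and np.all(hbr == 0)

    def test_roundtrip_recovers_concentrations(self, rng):
        hbo = rng.normal(0, 0.5, (8, 200))
        hbr = rng.normal(0, 0.2, (8, 200))
        od = optics.mbll_forward(hbo, hbr, 3.0, 6.0)
        hbo2, hbr2 = optics.mbll_inverse(od, 3.0, 6.0)
        np.testing.assert_allclose(hbo2, hbo, atol=1e-9)
        np.testing.assert_allclose(hbr2, hbr, atol=1e-9)

    def test_hbt_identity(self, rng):
        rec, *_ = make_recording(rng, noise=0.001)
        od = fnirs.intensity_to_od(rec)
        hemo = fnirs.od_to_hemoglobin(od)
        np.testing.assert_array_equal(hemo.hbt, hemo.hbo + hemo.hbr)

    def test_dpf_age_dependence(self):
        # the general-age DPF fit increases with age and stays in 4-8
        assert optics.dpf(760.0, 36.0) > optics.dpf(760.0, 6.0)
        for lam in (760.0, 850.0):
            for age in (6.0, 36.0):
                assert 4.0 < optics.dpf(lam, age) < 8.0

    def test_full_optical_roundtrip_noiseless(self, rng):
        rec, hbo, hbr = make_recording(rng, noise=0.0)
        od = fnirs.intensity_to_od(rec)
        hemo = fnirs.od_to_hemoglobin(od)
        # mean-referenced OD recovers concentrations up to a per-channel offset
        got = hemo.hbo - hemo.hbo.mean(axis=1, keepdims=True)
        want = hbo - hbo.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(got, want, atol=1e-6)


class TestFilterDownsampleAggregate:
    def _hemo(self, rng, n_t=2400):
        rec, *_ = make_recording(rng, n_t=n_t, noise=0.001)
        od = fnirs.intensity_to_od(rec)
        fnirs.prune_channels(od)
        return fnirs.od_to_hemoglobin(od)

    def test_bandpass_kills_dc_keeps_band(self, rng):
        hemo = self._hemo(rng)
        t = np.arange(hemo.hbo.shape[1]) / RATE
        hemo.hbo[0] = 5.0
        hemo.hbo[1] = np.sin(2 * np.pi * 0.05 * t)
        hemo.hbo[2] = np.sin(2 * np.pi * 2.0 * t)
        out = fnirs.bandpass_hemo(hemo)
        assert np.abs(out.hbo[0][200:-200]).max() < 1e-3
        mid = slice(400, -400)
        gain = out.hbo[1][mid].std() / hemo.hbo[1][mid].std()
        assert abs(gain - 1) < 0.05
        att = out.hbo[2][mid].std() / hemo.hbo[2][mid].std()
        assert 20 * np.log10(att) < -20

    def test_downsample_preserves_slow_band(self, rng):
        hemo = self._hemo(rng)
        t = np.arange(hemo.hbo.shape[1]) / RATE
        hemo.hbo[0] = np.sin(2 * np.pi * 0.05 * t)
        hemo.history.append("bandpass")
        out = fnirs.downsample_hemo(hemo, 1.0)
        assert out.rate == 1.0
        mid = slice(30, -30)
        assert out.hbo[0][mid].std() == pytest.approx(np.sqrt(0.5), rel=0.02)

    def test_downsample_constant_is_constant(self, rng):
        hemo = self._hemo(rng)
        hemo.hbo[:] = 1.5
        hemo.hbr[:] = -0.5
        hemo.history.append("bandpass")
        out = fnirs.downsample_hemo(hemo, 1.0)
        np.testing.assert_allclose(out.hbo, 1.5, atol=1e-9)

    def test_aggregate_region_mean_and_masking(self, rng):
        hemo = self._hemo(rng)
        hemo.history += ["bandpass", "downsample"]
        hemo.quality_mask[3] = False   # left region loses one channel
        out = fnirs.aggregate_region(hemo)
        left_hbo = out[(out.region == "left_dlPFC") & (out.chromophore == "HbO")]
        expect = hemo.hbo[[0, 1, 2]].mean(axis=0)
        np.testing.assert_allclose(left_hbo["value_uM"].to_numpy(), expect, atol=1e-12)

    def test_aggregate_drops_invalid_region(self, rng):
        hemo = self._hemo(rng)
        hemo.history += ["bandpass", "downsample"]
        hemo.quality_mask[:3] = False
        out = fnirs.aggregate_region(hemo)
        assert "left_dlPFC" not in set(out.region)


class TestPipelineOrder:
    def test_rerunning_stage_raises(self, rng):
        rec, *_ = make_recording(rng, noise=0.001)
        od = fnirs.intensity_to_od(rec)
        fnirs.prune_channels(od)
        od = fnirs.spline_motion_correct(od)
        with pytest.raises(fnirs.PipelineOrderError):
            fnirs.spline_motion_correct(od)

    def test_spline_requires_prune(self, rng):
        rec, *_ = make_recording(rng, noise=0.001)
        od = fnirs.intensity_to_od(rec)
        with pytest.raises(fnirs.PipelineOrderError):
            fnirs.spline_motion_correct(od)


def test_generated_recording_preprocesses_cleanly(rng):
    cfg = SimulationConfig(n_dyads=4, seed=0)
    mother, child, masks = generate_dyad_hemo(cfg, 0.5, rng)
    hemo = fnirs.preprocess_person(mother)
    assert set(hemo.region_series["region"]) == {"left_dlPFC", "right_dlPFC"}
    assert hemo.rate == 1.0
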
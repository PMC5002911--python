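"""VOI extraction, percent-change normalization, and rolling averages."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import muscleox as mx
from tests.conftest import make_ntc


def _labeled_series(rng, shape=(6, 6, 2), nt=20, labels_spec=None):
    data = rng.random(shape + (nt,)) * 100 + 10
    labels = np.zeros(shape, dtype=np.int16)
    for lbl, coords in (labels_spec or {}).items():
        for c in coords:
            labels[c] = lbl
    series = mx.BoldSeries(voxels=data, voxel_size=(1, 1, 1), tr=3.0)
    return series, labels


class TestExtraction:
    def test_constant_voi_yields_constant_course(self, rng):
        series, labels = _labeled_series(rng, labels_spec={1: [(0, 0, 0), (1, 1, 1)]})
        series.voxels[labels == 1] = 5.0
        vmap = mx.VoiLabelMap(labels=labels, legend={1: "soleus"}, voxel_size=(1, 1, 1))
        raw = mx.extract_voi_timecourse(series, vmap, "soleus")
        np.testing.assert_allclose(raw.si, 5.0)
        assert raw.n_voxels == 2

    def test_two_voxel_mean(self, rng):
        series, labels = _labeled_series(rng, labels_spec={1: [(0, 0, 0), (1, 0, 0)]})
        series.voxels[0, 0, 0, :] = 2.0
        series.voxels[1, 0, 0, :] = 4.0
        vmap = mx.VoiLabelMap(labels=labels, legend={1: "soleus"}, voxel_size=(1, 1, 1))
        np.testing.assert_allclose(mx.extract_voi_timecourse(series, vmap, "soleus").si, 3.0)

    def test_matches_explicit_per_frame_loop(self, rng):
        coords = [(0, 0, 0), (1, 2, 1), (3, 3, 0), (5, 5, 1), (2, 4, 0), (4, 1, 1), (0, 5, 0)]
        series, labels = _labeled_series(rng, labels_spec={2: coords})
        vmap = mx.VoiLabelMap(labels=labels, legend={2: "gastrocnemius"}, voxel_size=(1, 1, 1))
        raw = mx.extract_voi_timecourse(series, vmap, "gastrocnemius")
        # independent oracle: accumulate voxel by voxel, frame by frame
        expected = []
        for t in range(series.n_frames):
            acc = 0.0
            for c in coords:
                acc += float(series.voxels[c + (t,)])
            expected.append(acc / len(coords))
        np.testing.assert_allclose(raw.si, expected, rtol=1e-12)
        assert raw.n_voxels == 7

    def test_union_of_disjoint_vois_is_count_weighted_mean(self, rng):
        a = [(0, 0, 0), (1, 1, 0), (2, 2, 0)]
        b = [(3, 3, 1), (4, 4, 1)]
        series, labels = _labeled_series(rng, labels_spec={1: a, 2: b})
        vmap = mx.VoiLabelMap(
            labels=labels, legend={1: "soleus", 2: "gastrocnemius"}, voxel_size=(1, 1, 1)
        )
        union_labels = np.where(labels > 0, 3, 0).astype(np.int16)
        union = mx.VoiLabelMap(labels=union_labels, legend={3: "other"}, voxel_size=(1, 1, 1))
        si_a = mx.extract_voi_timecourse(series, vmap, "soleus").si
        si_b = mx.extract_voi_timecourse(series, vmap, "gastrocnemius").si
        si_u = mx.extract_voi_timecourse(series, union, "other").si
        np.testing.assert_allclose(si_u, (3 * si_a + 2 * si_b) / 5, rtol=1e-12)

    def test_empty_voi_and_unknown_muscle(self, rng):
        series, labels = _labeled_series(rng, labels_spec={1: [(0, 0, 0)]})
        vmap = mx.VoiLabelMap(labels=labels, legend={1: "soleus"}, voxel_size=(1, 1, 1))
        with pytest.raises(mx.MaskError, match="not in legend"):
            mx.extract_voi_timecourse(series, vmap, "peroneus_longus")


class TestNormalization:
    def test_percent_change_formula(self):
        timing = mx.ProtocolTiming(0, 3, 3.4, 4, tr=1.0, baseline_discard=0)
        raw = mx.RawTimeCourse(
            muscle="soleus", times=np.array([0.5, 1.5, 2.5, 3.5]),
            si=np.array([10.0, 10.0, 10.0, 12.0]), n_voxels=4,
        )
        ntc = mx.percent_change_normalize(raw, timing)
        np.testing.assert_allclose(ntc.pct, [0.0, 0.0, 0.0, 20.0])
        assert ntc.baseline_si == pytest.approx(10.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    def test_scale_invariance(self, scale):
        timing = mx.ProtocolTiming(0, 3, 3.4, 4, tr=1.0, baseline_discard=0)
        si = np.array([10.0, 11.0, 9.5, 14.0])
        times = np.array([0.5, 1.5, 2.5, 3.5])
        base = mx.percent_change_normalize(
            mx.RawTimeCourse("m", times, si, 1), timing
        )
        scaled = mx.percent_change_normalize(
            mx.RawTimeCourse("m", times, si * scale, 1), timing
        )
        np.testing.assert_allclose(scaled.pct, base.pct, rtol=1e-9, atol=1e-9)

    def test_baseline_mean_of_pct_is_zero(self, timing, rng):
        si = rng.random(timing.n_frames) * 50 + 100
        raw = mx.RawTimeCourse("m", timing.frame_centers(), si, 5)
        ntc = mx.percent_change_normalize(raw, timing)
        used = np.flatnonzero(timing.baseline_mask(ntc.times))[timing.baseline_discard:]
        assert abs(ntc.pct[used].mean()) < 1e-9

    def test_discard_skips_saturation_transient(self, timing):
        si = np.full(timing.n_frames, 100.0)
        si[:5] = 150.0  # T1 saturation transient
        raw = mx.RawTimeCourse("m", timing.frame_centers(), si, 5)
        ntc = mx.percent_change_normalize(raw, timing)
        assert ntc.baseline_si == pytest.approx(100.0)
        np.testing.assert_allclose(ntc.pct[5:], 0.0)

    def test_nonpositive_baseline_rejected(self, timing):
        si = np.full(timing.n_frames, -1.0)
        raw = mx.RawTimeCourse("m", timing.frame_centers(), si, 5)
        with pytest.raises(mx.DataError, match="baseline"):
            mx.percent_change_normalize(raw, timing)

    def test_too_few_baseline_frames_rejected(self):
        timing = mx.ProtocolTiming(0, 12, 18, 30, tr=3.0, baseline_discard=1)
        raw = mx.RawTimeCourse("m", timing.frame_centers()[2:], np.ones(8), 1)
        with pytest.raises(mx.ProtocolError, match="baseline"):
            mx.percent_change_normalize(raw, timing)

    def test_detrend_option_removes_linear_drift(self, timing):
        t = timing.frame_centers()
        si = 100.0 + 0.01 * t  # 0.6 %/min drift, no physiology
        raw = mx.RawTimeCourse("m", t, si, 5)
        drifting = mx.percent_change_normalize(raw, timing)
        flat = mx.percent_change_normalize(raw, timing, detrend_baseline=True)
        assert abs(drifting.pct[-1]) > 5.0
        np.testing.assert_allclose(flat.pct, 0.0, atol=1e-9)


class TestProtocolTiming:
    def test_unordered_phases_rejected(self):
        with pytest.raises(mx.ProtocolError, match="ordered"):
            mx.ProtocolTiming(0, 600, 300, 900)

    def test_discard_must_leave_three_baseline_frames(self):
        with pytest.raises(mx.ProtocolError, match="fewer than 3"):
            mx.ProtocolTiming(0, 30, 60, 90, tr=3.0, baseline_discard=8)

    def test_default_paradigm_has_300_frames(self, timing):
        assert timing.n_frames == 300
        assert timing.frame_centers()[0] == pytest.approx(1.5)
        assert timing.frame_centers()[-1] == pytest.approx(898.5)


class TestRollingAverage:
    def test_single_frame_window_is_identity(self):
        ntc = make_ntc([0.0, 5.0, 12.0, 8.0])
        out = mx.rolling_average(ntc, 3.0)
        np.testing.assert_allclose(out.pct, ntc.pct)
        np.testing.assert_allclose(out.times, ntc.times)

    def test_two_frame_window_pairwise_means(self):
        ntc = make_ntc([0.0, 5.0, 12.0, 8.0])
        out = mx.rolling_average(ntc, 6.0)
        np.testing.assert_allclose(out.pct, [2.5, 8.5, 10.0])
        # center-timestamped: first window covers frames at 1.5 and 4.5 s
        np.testing.assert_allclose(out.times, [3.0, 6.0, 9.0])

    @pytest.mark.parametrize("w_frames", [1, 2, 3, 7])
    def test_matches_nested_loop_oracle(self, rng, w_frames):
        pct = rng.normal(size=200)
        ntc = make_ntc(pct)
        out = mx.rolling_average(ntc, w_frames * 3.0)
        expected = []
        for i in range(200 - w_frames + 1):
            acc = 0.0
            for j in range(w_frames):
                acc += pct[i + j]
            expected.append(acc / w_frames)
        np.testing.assert_allclose(out.pct, expected, atol=1e-12)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(mx.DataError, match="longer than series"):
            mx.rolling_average(make_ntc([1.0, 2.0]), 30.0)

    @given(
        data=st.lists(st.floats(-50, 50), min_size=4, max_size=40),
        w=st.integers(min_value=1, max_value=4),
    )
    def test_stays_within_window_extrema(self, data, w):
        pct = np.asarray(data)
        if w > pct.size:
            return
        out = mx.rolling_average(make_ntc(pct), w * 3.0)
        for i, v in enumerate(out.pct):
            window = pct[i : i + w]
            assert window.min() - 1e-9 <= v <= window.max() + 1e-9
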
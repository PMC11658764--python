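import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanocal.core_io import BinaryMask, ClusterRecord, ClusterSet, IntensityTrace
from nanocal.quantify import (
    cluster_count_by_window,
    compartment_intensity_pair,
    kinetics_metrics,
    mfi_in_mask,
    ratio_trace,
    shape_metrics,
)

PX = 0.284


def _cluster_set(frame_index, n, px=PX):
    recs = tuple(
        ClusterRecord(i + 1, (0.0, 0.0), 2 * px**2, 2) for i in range(n)
    )
    return ClusterSet(frame_index, recs, px)


class TestMfiInMask:
    def test_uniform_frame_returns_value(self, disk_mask):
        assert mfi_in_mask(np.full(disk_mask.pixels.shape, 7.5), disk_mask) == 7.5

    def test_linearity(self, rng, disk_mask):
        frame = rng.random(disk_mask.pixels.shape)
        assert mfi_in_mask(2 * frame, disk_mask) == pytest.approx(
            2 * mfi_in_mask(frame, disk_mask)
        )

    def test_empty_mask_is_missing_not_zero(self):
        empty = BinaryMask(np.zeros((8, 8), dtype=bool), PX)
        assert np.isnan(mfi_in_mask(np.ones((8, 8)), empty))

    def test_conservation_over_compartments(self, rng, disk_mask):
        """Area-weighted compartment MFIs recombine to the whole-cell MFI."""
        frame = rng.random(disk_mask.pixels.shape) * 100
        sub = np.zeros_like(disk_mask.pixels)
        sub[40:55, 40:55] = True
        cluster = BinaryMask(sub & disk_mask.pixels, PX)
        negative = BinaryMask(disk_mask.pixels & ~cluster.pixels, PX)
        whole = mfi_in_mask(frame, disk_mask)
        combined = (
            mfi_in_mask(frame, cluster) * cluster.n_pixels
            + mfi_in_mask(frame, negative) * negative.n_pixels
        ) / disk_mask.n_pixels
        assert combined == pytest.approx(whole, rel=1e-12)


class TestClusterCountByWindow:
    WINDOWS = ((0.0, 60.0), (300.0, 360.0), (540.0, 600.0))

    def test_constant_counts(self):
        sets = [_cluster_set(f, 7) for f in range(300)]
        means = cluster_count_by_window(sets, 2.0, self.WINDOWS)
        assert all(v == 7.0 for v in means.values())

    def test_constructed_contrast(self):
        sets = [
            _cluster_set(f, 0 if f * 2.0 < 60 else 10) for f in range(300)
        ]
        means = cluster_count_by_window(sets, 2.0, self.WINDOWS)
        assert means[(0.0, 60.0)] == 0.0
        assert means[(540.0, 600.0)] == 10.0

    def test_matches_brute_force_on_random_schedule(self, rng):
        counts = rng.poisson(5, size=300)
        sets = [_cluster_set(f, int(c)) for f, c in enumerate(counts)]
        means = cluster_count_by_window(sets, 2.0, self.WINDOWS)
        for (a, b), got in means.items():
            expected = np.mean(
                [c for f, c in enumerate(counts) if a <= f * 2.0 < b]
            )
            assert got == pytest.approx(expected)

    def test_empty_window_is_missing(self):
        sets = [_cluster_set(f, 1) for f in range(10)]  # 20 s movie
        means = cluster_count_by_window(sets, 2.0, self.WINDOWS)
        assert np.isnan(means[(300.0, 360.0)])


class TestCompartmentIntensityPair:
    def test_uniform_frame_equal_compartments(self, disk_mask):
        sub = np.zeros_like(disk_mask.pixels)
        sub[45:50, 45:50] = True
        cluster = BinaryMask(sub & disk_mask.pixels, PX)
        negative = BinaryMask(disk_mask.pixels & ~sub, PX)
        inside, outside = compartment_intensity_pair(
            np.full(disk_mask.pixels.shape, 4.0), cluster, negative
        )
        assert inside == outside == 4.0

    def test_constructed_values(self, disk_mask):
        sub = np.zeros_like(disk_mask.pixels)
        sub[45:50, 45:50] = True
        cluster = BinaryMask(sub & disk_mask.pixels, PX)
        negative = BinaryMask(disk_mask.pixels & ~sub, PX)
        frame = np.where(sub, 3.0, 1.0)
        assert compartment_intensity_pair(frame, cluster, negative) == (3.0, 1.0)

    def test_overlap_rejected(self, disk_mask):
        with pytest.raises(ValueError, match="overlap"):
            compartment_intensity_pair(
                np.ones(disk_mask.pixels.shape), disk_mask, disk_mask
            )

    def test_programmed_enrichment_recovered(self, disk_mask):
        from nanocal.synth import (
            ClusterProcessParams,
            render_calcium_channel,
            sample_point_pattern,
            spot_footprint,
        )

        pattern = sample_point_pattern(
            disk_mask, ClusterProcessParams(expected_total_points=15, rng_seed=8)
        )
        frames, _ = render_calcium_channel(
            disk_mask, pattern, enrichment=1.5, noise_sd=0.0, baseline=40.0
        )
        foot = spot_footprint(disk_mask, pattern, 0.5)
        cluster = BinaryMask(foot, PX)
        negative = BinaryMask(disk_mask.pixels & ~foot, PX)
        inside, outside = compartment_intensity_pair(frames[0], cluster, negative)
        assert inside / outside == pytest.approx(1.5, rel=0.01)


class TestShapeMetrics:
    def test_square_closed_form(self):
        n = 20
        pixels = np.zeros((n + 10, n + 10), dtype=bool)
        pixels[5 : 5 + n, 5 : 5 + n] = True
        m = shape_metrics(BinaryMask(pixels, PX))
        assert m.area_um2 == pytest.approx((n * PX) ** 2)
        assert m.perimeter_um == pytest.approx(4 * n * PX)
        assert m.circularity == pytest.approx(np.pi / 4)
        assert m.solidity == pytest.approx(1.0)

    def test_large_disk_circularity_near_one(self):
        from skimage import draw

        pixels = np.zeros((101, 101), dtype=bool)
        rr, cc = draw.disk((50, 50), 25.5)
        pixels[rr, cc] = True
        m = shape_metrics(BinaryMask(pixels, PX))
        assert 0.95 <= m.circularity <= 1.05

    def test_convex_mask_solidity_near_one(self, disk_mask):
        m = shape_metrics(disk_mask)
        assert m.solidity == pytest.approx(1.0, abs=0.02)

    def test_disk_beats_square_and_bar_in_circularity(self):
        from skimage import draw

        disk = np.zeros((101, 101), dtype=bool)
        rr, cc = draw.disk((50, 50), 25.5)
        disk[rr, cc] = True
        square = np.zeros((101, 101), dtype=bool)
        square[30:75, 30:75] = True
        bar = np.zeros((101, 101), dtype=bool)
        bar[45:55, 5:95] = True
        c = {k: shape_metrics(BinaryMask(v, PX)).circularity
             for k, v in [("disk", disk), ("square", square), ("bar", bar)]}
        assert c["disk"] > c["square"] > c["bar"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape_metrics(BinaryMask(np.zeros((8, 8), dtype=bool), PX))

    def test_disconnected_mask_uses_largest_component(self):
        pixels = np.zeros((40, 40), dtype=bool)
        pixels[5:25, 5:25] = True
        pixels[30:32, 30:32] = True
        with pytest.warns(UserWarning, match="components"):
            m = shape_metrics(BinaryMask(pixels, PX))
        assert m.area_um2 == pytest.approx((20 * PX) ** 2)


class TestRatioTrace:
    def test_equal_traces_constant_one(self):
        t = np.arange(10.0)
        a = IntensityTrace(t, np.linspace(1, 5, 10))
        assert np.all(ratio_trace(a, a).values == 1.0)

    def test_double_numerator(self):
        t = np.arange(10.0)
        b = IntensityTrace(t, np.linspace(1, 5, 10))
        a = IntensityTrace(t, 2 * b.values)
        assert np.allclose(ratio_trace(a, b).values, 2.0)

    def test_programmed_step_reproduced(self):
        t = np.arange(0, 100, 1.0)
        bound = np.where(t < 50, 1.0, 3.0)
        unbound = np.full_like(t, 2.0)
        r = ratio_trace(IntensityTrace(t, bound), IntensityTrace(t, unbound))
        assert r.values[10] == pytest.approx(0.5)
        assert r.values[80] == pytest.approx(1.5)

    def test_zero_denominator_names_index(self):
        t = np.arange(5.0)
        a = IntensityTrace(t, np.ones(5))
        b = IntensityTrace(t, np.array([1.0, 1.0, 0.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="index 2"):
            ratio_trace(a, b)


class TestKineticsMetrics:
    @staticmethod
    def triangular_trace():
        # baseline 1 on [0,30); rise to 3 at t=60; linear decay to 1 at t=120
        t = np.arange(0, 151.0)
        v = np.piecewise(
            t,
            [t < 30, (t >= 30) & (t < 60), (t >= 60) & (t < 120), t >= 120],
            [1.0, lambda x: 1 + 2 * (x - 30) / 30, lambda x: 3 - 2 * (x - 60) / 60,
             1.0],
        )
        return IntensityTrace(t, v)

    def test_constant_trace(self):
        t = np.arange(0, 100.0)
        m = kinetics_metrics(IntensityTrace(t, np.full(100, 2.0)))
        assert m.peak_ratio == 1.0
        assert m.auc_peak_to_half == 0.0

    def test_triangular_pulse_closed_form(self):
        m = kinetics_metrics(self.triangular_trace())
        assert m.baseline == pytest.approx(1.0)
        assert m.peak_ratio == pytest.approx(3.0)
        assert m.peak_time_s == pytest.approx(60.0)
        assert m.half_life_time_s == pytest.approx(90.0)
        # trapezoid of (trace - baseline) from 60 to 90: (2+1)/2 * 30
        assert m.auc_peak_to_half == pytest.approx(45.0)
        assert m.decayed_to_half

    def test_auc_invariant_under_constant_shift(self):
        tr = self.triangular_trace()
        shifted = IntensityTrace(tr.times_s, tr.values + 5.0)
        m0 = kinetics_metrics(tr)
        m1 = kinetics_metrics(shifted)
        assert m1.auc_peak_to_half == pytest.approx(m0.auc_peak_to_half)
        assert m1.peak_ratio != pytest.approx(m0.peak_ratio)

    def test_steeper_decay_smaller_auc_equal_ratio(self):
        t = np.arange(0, 301.0)

        def trace(tau):
            v = np.where(
                t < 60, 1.0, 1.0 + 2 * np.exp(-np.clip(t - 60, 0, None) / tau)
            )
            v[(t >= 30) & (t < 60)] = 1 + 2 * (t[(t >= 30) & (t < 60)] - 30) / 30
            return IntensityTrace(t, v)

        fast = kinetics_metrics(trace(20.0))
        slow = kinetics_metrics(trace(80.0))
        assert fast.peak_ratio == pytest.approx(slow.peak_ratio, rel=0.01)
        assert fast.auc_peak_to_half < slow.auc_peak_to_half

    def test_never_decaying_trace_flagged(self):
        t = np.arange(0, 100.0)
        v = np.where(t < 40, 1.0, 5.0)
        with pytest.warns(UserWarning, match="never decays"):
            m = kinetics_metrics(IntensityTrace(t, v))
        assert not m.decayed_to_half
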
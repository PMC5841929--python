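import numpy as np
import pytest

from ca1ephys import behavior, spatial
from ca1ephys.core import DataError, PositionTrace, SpikeTrain, VelocityTrace
from conftest import uniform_trajectory


def constant_velocity(pos, speed=15.0):
    return VelocityTrace(pos.t, np.full(len(pos), speed))


def make_map(p, lam, occ_total=100.0):
    """RateMap directly from occupancy probabilities and rates."""
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    visited = p > 0
    return spatial.RateMap(rate=lam, occ_time_s=p * occ_total, p=p,
                           visited=visited, smoothing_sd_bins=0.0)


class TestComputeRateMap:
    def setup_method(self):
        self.pos = uniform_trajectory(duration_s=120.0)
        self.lin = behavior.project_to_track(self.pos)
        self.vel = behavior.compute_velocity(self.pos)

    def test_spikes_in_one_bin_peak_there(self):
        # spikes whenever the animal crosses bin 85
        mask = np.abs(self.lin - 85.0) < 0.5
        spikes = SpikeTrain("u", self.pos.t[mask])
        m = spatial.compute_rate_map(spikes, self.lin, self.pos, self.vel,
                                     170.0)
        assert abs(int(np.nanargmax(np.where(m.visited, m.rate, np.nan)))
                   - 85) <= 1

    def test_no_spikes_all_zero(self):
        spikes = SpikeTrain("u", np.array([]))
        m = spatial.compute_rate_map(spikes, self.lin, self.pos, self.vel,
                                     170.0)
        assert m.mean_rate == 0.0
        assert np.nanmax(m.rate) == 0.0

    def test_spike_mass_conserved(self):
        rng = np.random.default_rng(0)
        spikes = SpikeTrain("u", np.sort(rng.uniform(0, 119, 400)))
        m = spatial.compute_rate_map(spikes, self.lin, self.pos, self.vel,
                                     170.0)
        mass = np.nansum(np.where(m.visited, m.rate * m.occ_time_s, 0.0))
        assert mass == pytest.approx(400, rel=0.01)

    def test_speed_gate_excludes_slow_samples(self):
        vel = VelocityTrace(self.pos.t, np.ones(len(self.pos)))  # all slow
        spikes = SpikeTrain("u", self.pos.t[::50])
        with pytest.raises(DataError):
            spatial.compute_rate_map(spikes, self.lin, self.pos, vel, 170.0)

    def test_smooth_modes_agree_on_uniform_occupancy(self):
        rng = np.random.default_rng(1)
        spikes = SpikeTrain("u", np.sort(rng.uniform(0, 119, 500)))
        a = spatial.compute_rate_map(spikes, self.lin, self.pos, self.vel,
                                     170.0, smooth_mode="divide_then_smooth")
        b = spatial.compute_rate_map(spikes, self.lin, self.pos, self.vel,
                                     170.0, smooth_mode="smooth_then_divide")
        v = a.visited & b.visited
        assert np.nanmax(np.abs(a.rate[v] - b.rate[v])) < 0.5


class TestDetectPlaceFields:
    def gaussian_map(self, peak=10.0, sd_bins=5.0, center=85, n=170):
        bins = np.arange(n)
        lam = peak * np.exp(-0.5 * ((bins - center) / sd_bins) ** 2)
        return make_map(np.full(n, 1.0 / n), lam)

    def test_analytic_20pct_width(self):
        # width at 20% of peak for a Gaussian: 2*sd*sqrt(2 ln 5)
        m = self.gaussian_map(peak=10.0, sd_bins=5.0)
        fields, main = spatial.detect_place_fields(m)
        expected = 2 * 5.0 * np.sqrt(2 * np.log(5))
        assert main is not None
        assert abs(main.size_bins - expected) <= 2

    def test_peak_bin_inside_main_field(self):
        m = self.gaussian_map()
        _, main = spatial.detect_place_fields(m)
        assert main.peak_bin in main.bin_set
        assert main.peak_rate == pytest.approx(10.0)

    def test_silent_map_no_fields(self):
        m = make_map(np.full(10, 0.1), np.zeros(10))
        fields, main = spatial.detect_place_fields(m)
        assert fields == [] and main is None


class TestSpatialInformation:
    def test_two_bin_hand_computation(self):
        # p=(.5,.5), lam=(2,0): mean 1 Hz, SI = .5*2*log2(2) = 1 bit/s
        m = make_map([0.5, 0.5], [2.0, 0.0])
        assert spatial.spatial_information(m) == pytest.approx(1.0)

    def test_uniform_map_zero(self):
        m = make_map(np.full(20, 0.05), np.full(20, 3.0))
        assert spatial.spatial_information(m) == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(30))
        lam = rng.uniform(0, 5, 30)
        m1 = make_map(p, lam)
        perm = rng.permutation(30)
        m2 = make_map(p[perm], lam[perm])
        assert spatial.spatial_information(m1) == pytest.approx(
            spatial.spatial_information(m2))

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.dirichlet(np.ones(15))
            m = make_map(p, rng.uniform(0, 10, 15))
            assert spatial.spatial_information(m) >= -1e-12


class TestSparsity:
    def test_uniform_is_zero(self):
        m = make_map(np.full(20, 0.05), np.full(20, 3.0))
        assert spatial.sparsity(m) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_of_n(self):
        n = 25
        lam = np.zeros(n)
        lam[7] = 5.0
        m = make_map(np.full(n, 1 / n), lam)
        assert spatial.sparsity(m) == pytest.approx(1 - 1 / n)

    def test_plug_in_example(self):
        m = make_map([0.5, 0.5], [2.0, 0.0])
        assert spatial.sparsity(m) == pytest.approx(0.5)

    def test_sharpening_fields_raise_si_and_sparsity_together(self):
        # fields sharpen at fixed mean rate: both metrics must increase
        n = 170
        bins = np.arange(n)
        prev_si, prev_sp = -1.0, -1.0
        for sd in [40.0, 20.0, 10.0, 5.0, 2.5]:
            lam = np.exp(-0.5 * ((bins - 85) / sd) ** 2)
            lam *= 2.0 / lam.mean()
            m = make_map(np.full(n, 1 / n), lam)
            si = spatial.spatial_information(m)
            sp = spatial.sparsity(m)
            assert si > prev_si and sp > prev_sp
            prev_si, prev_sp = si, sp


class TestDirectionalityIndex:
    @pytest.mark.parametrize("lm,rm,expected",
                             [(2.0, 0.0, 1.0), (3.0, 3.0, 0.0),
                              (3.0, 1.0, 0.5)])
    def test_values(self, lm, rm, expected):
        assert spatial.directionality_index(lm, rm) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(DataError):
            spatial.directionality_index(0.0, 0.0)


class TestRateSummaries:
    def test_poisson_unit_mean_rate(self):
        pos = uniform_trajectory(duration_s=200.0)
        vel = constant_velocity(pos)
        rng = np.random.default_rng(4)
        rate = 3.0
        n = rng.poisson(rate * 200.0)
        spikes = SpikeTrain("u", np.sort(rng.uniform(0, 200.0, n)))
        est = spatial.mean_run_rate(spikes, vel)
        se = np.sqrt(rate / 200.0)
        assert abs(est - rate) < 3 * se

    def test_peak_at_least_mean(self, analyzed):
        df = analyzed["units"].dropna(subset=["peak_rate_hz"])
        assert (df.peak_rate_hz >= df.mean_rate_hz - 1e-9).all()

    def test_all_spikes_infield_zero_outfield(self):
        pos = uniform_trajectory(duration_s=120.0)
        lin = behavior.project_to_track(pos)
        vel = constant_velocity(pos)
        mask = np.abs(lin - 85.0) < 5.0
        spikes = SpikeTrain("u", pos.t[mask])
        m = spatial.compute_rate_map(spikes, lin, pos, vel, 170.0)
        _, main = spatial.detect_place_fields(m)
        r_in, r_out = spatial.in_out_field_rates(spikes, lin, pos, vel, m,
                                                 main)
        assert r_out == pytest.approx(0.0, abs=1e-9)
        assert r_in > 0
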
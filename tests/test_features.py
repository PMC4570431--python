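"""The 36-variable spectral characterisation: moment, percentile and band
oracles, invariances, and median smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emgcycle.features import (
    FEATURE_NAMES,
    MPF_INDEX,
    PowerDistribution,
    assemble_features,
    band_plan,
    band_powers,
    distribution_moments,
    distribution_percentiles,
    median_smooth,
    power_distribution,
    segment_features,
    time_domain_features,
)

FS = 1000.0
N = 256
DF = FS / N  # 3.90625 Hz


def _make_distribution(mass_per_bin):
    """PowerDistribution from per-bin probability mass on the 129-bin grid."""
    mass = np.zeros(N // 2 + 1)
    for k, m in mass_per_bin.items():
        mass[k] = m
    mass = mass / mass.sum()
    freqs = np.arange(N // 2 + 1) * DF
    return PowerDistribution(freqs, mass / DF)


class TestPowerDistribution:
    def test_unit_area(self):
        rng = np.random.default_rng(0)
        d, _ = power_distribution(rng.normal(size=N), fs=FS)
        assert np.sum(d.mass) == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_mass_concentrated(self):
        t = np.arange(N) / FS
        d, _ = power_distribution(np.sin(2 * np.pi * 125.0 * t + 0.2), fs=FS)
        bin_125 = int(round(125.0 / DF))
        near = d.mass[bin_125 - 2 : bin_125 + 3].sum()
        assert near >= 0.95

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=N)
        d1, _ = power_distribution(s, fs=FS)
        d2, _ = power_distribution(10.0 * s, fs=FS)
        np.testing.assert_allclose(d1.density, d2.density, atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            power_distribution(np.zeros(N))


class TestTimeDomain:
    def test_rms_arithmetic(self):
        rms, _, _ = time_domain_features(np.array([3.0, -4.0]))
        assert rms == pytest.approx(np.sqrt(12.5))

    def test_constant_segment(self):
        _, drms, inst_f = time_domain_features(np.full(N, 2.0))
        assert drms == 0.0 and inst_f == 0.0

    def test_if_counts_sign_changes_halved(self):
        t = np.arange(N) / FS
        s = np.sin(2 * np.pi * 125.0 * t + 0.3)
        _, _, inst_f = time_domain_features(s)
        nz = s[s != 0]
        oracle = np.count_nonzero(np.diff(np.sign(nz))) / 2.0
        assert inst_f == oracle
        assert abs(inst_f - 32.0) <= 1.0  # 125 Hz over 256 ms: ~64 crossings


class TestMoments:
    def test_symmetric_two_bin(self):
        k100, k200 = int(round(100 / DF)), int(round(200 / DF))
        d = _make_distribution({k100: 0.5, k200: 0.5})
        _, mean, _, skew, _ = distribution_moments(d)
        assert mean == pytest.approx((k100 + k200) / 2 * DF)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_point_mass(self):
        k = int(round(100 / DF))
        d = _make_distribution({k: 1.0})
        mode, mean, sd, skew, kurt = distribution_moments(d)
        assert mode == pytest.approx(k * DF)
        assert sd == 0.0 and skew == 0.0 and kurt == 0.0

    def test_four_bin_brute_force_oracle(self):
        bins = {10: 0.1, 20: 0.4, 40: 0.3, 60: 0.2}
        d = _make_distribution(bins)
        mode, mean, sd, skew, kurt = distribution_moments(d)
        f = np.array([k * DF for k in bins])
        m = np.array(list(bins.values()))
        mu = np.sum(f * m)
        var = np.sum((f - mu) ** 2 * m)
        z = (f - mu) / np.sqrt(var)
        assert mode == pytest.approx(20 * DF)
        assert mean == pytest.approx(mu, abs=1e-12)
        assert sd == pytest.approx(np.sqrt(var), abs=1e-12)
        assert skew == pytest.approx(np.sum(z**3 * m), abs=1e-12)
        assert kurt == pytest.approx(np.sum(z**4 * m) - 3, abs=1e-12)

    def test_dc_excluded_from_mode(self):
        d = _make_distribution({0: 0.6, 30: 0.4})
        mode, *_ = distribution_moments(d)
        assert mode == pytest.approx(30 * DF)


class TestPercentiles:
    def test_uniform_density(self):
        d = _make_distribution({k: 1.0 for k in range(N // 2 + 1)})
        q = distribution_percentiles(d)
        for p, qp in zip(np.arange(1, 10) / 10, q):
            assert abs(qp - 500.0 * p) <= DF / 2 + 1e-9

    def test_point_mass_all_percentiles_at_that_bin(self):
        k = int(round(100 / DF))
        q = distribution_percentiles(_make_distribution({k: 1.0}))
        assert np.all(np.abs(q - k * DF) <= DF / 2 + 1e-9)

    def test_eight_bin_cumulative_oracle(self):
        bins = dict(zip([5, 9, 14, 22, 30, 41, 55, 70], [3, 1, 4, 1, 5, 9, 2, 6]))
        d = _make_distribution(bins)
        q = distribution_percentiles(d)
        # independent cumulative-crossing oracle with the same bin convention
        mass = d.mass
        c = np.cumsum(mass)
        for p, qp in zip(np.arange(1, 10) / 10, q):
            k = int(np.searchsorted(c, p))
            prev = c[k - 1] if k else 0.0
            expected = k * DF - DF / 2 + DF * (p - prev) / mass[k]
            assert qp == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_for_random_densities(self, seed):
        rng = np.random.default_rng(seed)
        mass = rng.dirichlet(np.ones(N // 2 + 1))
        d = PowerDistribution(np.arange(N // 2 + 1) * DF, mass / DF)
        q = distribution_percentiles(d)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all((q >= 0) & (q <= 500.0))


class TestBandPowers:
    def test_band_plan_matches_printed_edges(self):
        plan = band_plan(N, FS)
        lo0, hi0 = plan[0]
        assert lo0 == pytest.approx(23.44, abs=0.00501)
        assert hi0 == pytest.approx(46.88, abs=0.00501)
        widths = [hi - lo for lo, hi in plan]
        assert all(w == pytest.approx(23.44, abs=0.00501) for w in widths)
        steps = [plan[k + 1][0] - plan[k][0] for k in range(len(plan) - 1)]
        assert all(s == pytest.approx(11.72, abs=0.00501) for s in steps)
        assert plan[-1][0] == pytest.approx(234.4, abs=0.03)
        assert plan[-1][1] == pytest.approx(257.8, abs=0.02)

    def test_flat_spectrum_uniform_bands(self):
        p = np.ones(N // 2 + 1)
        out = band_powers(p, N, FS)
        np.testing.assert_allclose(out, 6.0 / 128.0, atol=1e-12)

    def test_30hz_sinusoid_dominates_first_band(self):
        t = np.arange(N) / FS
        _, p = power_distribution(np.sin(2 * np.pi * 30.0 * t + 0.1), fs=FS)
        out = band_powers(p, N, FS)
        assert np.argmax(out) == 0  # p23_47 contains 30 Hz

    def test_each_band_in_unit_interval(self):
        rng = np.random.default_rng(3)
        _, p = power_distribution(rng.normal(size=N), fs=FS)
        out = band_powers(p, N, FS)
        assert np.all((out >= 0) & (out <= 1))

    def test_incompatible_length_rejected(self):
        with pytest.raises(ValueError):
            band_powers(np.ones(64), n=256)
        with pytest.raises(ValueError):
            band_plan(n=128, fs=1000.0)  # plan does not fit in 65 bins


class TestAssembly:
    def test_matrix_shape_and_order(self, thirty_cycle_segments):
        segset, _ = thirty_cycle_segments
        fm = assemble_features(segset)
        assert fm.shape == (len(segset), 36)
        assert list(fm.columns) == FEATURE_NAMES
        assert FEATURE_NAMES[3] == "ModF" and FEATURE_NAMES[MPF_INDEX] == "q50"

    def test_mpf_column_is_median_percentile(self, thirty_cycle_segments):
        segset, _ = thirty_cycle_segments
        fm = assemble_features(segset)
        for i in (0, len(segset) // 2):
            d, _ = power_distribution(segset.segments[i], fs=FS)
            q50 = distribution_percentiles(d, probs=np.array([0.5]))[0]
            assert fm.iloc[i, MPF_INDEX] == pytest.approx(q50)

    def test_spectral_features_amplitude_invariant(self, thirty_cycle_segments):
        segset, _ = thirty_cycle_segments
        seg = segset.segments[5]
        a = segment_features(seg, fs=FS)
        b = segment_features(4.0 * seg, fs=FS)
        np.testing.assert_allclose(b[:2], 4.0 * a[:2], rtol=1e-9)   # RMS, dRMS linear
        np.testing.assert_allclose(b[3:], a[3:], rtol=1e-7, atol=1e-9)  # rest invariant

    def test_percentile_monotonicity_every_segment(self, thirty_cycle_segments):
        segset, _ = thirty_cycle_segments
        fm = assemble_features(segset)
        q_cols = fm[[f"q{10 * i}" for i in range(1, 10)]].to_numpy()
        assert np.all(np.diff(q_cols, axis=1) >= -1e-9)

    def test_tail_mass_shift_raises_q90(self):
        """More high-band burst power must move the 90th percentile up."""
        from emgcycle.experiments import simulated_feature_matrix
        from emgcycle.synthetic import SpectralParams

        means = []
        for tail in (0.05, 0.25, 0.5):
            sp = SpectralParams(tail_mass=tail, tail_jitter_sd=0.0)
            fm = simulated_feature_matrix(n_cycles=20, seed=6, spectral=sp)
            means.append(fm["q90"].mean())
        assert means[0] < means[1] < means[2]

    def test_all_zero_segment_reported_as_zeros(self):
        assert np.all(segment_features(np.zeros(N)) == 0.0)


class TestMedianSmooth:
    def test_constant_column_unchanged(self):
        df = pd.DataFrame({"a": np.full(40, 3.0)})
        np.testing.assert_array_equal(median_smooth(df)["a"], df["a"])

    def test_single_spike_removed(self):
        col = np.full(41, 1.0)
        col[20] = 99.0
        out = median_smooth(pd.DataFrame({"a": col}))
        np.testing.assert_array_equal(out["a"], 1.0)

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=60)
        out = median_smooth(pd.DataFrame({"a": col}), window=11)["a"].to_numpy()
        half = 5
        for i in range(60):
            window = col[max(0, i - half) : min(60, i + half + 1)]
            assert out[i] == pytest.approx(np.median(window))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_smooth(pd.DataFrame({"a": [1.0, 2.0]}), window=4)

    def test_output_shape_preserved(self, thirty_cycle_segments):
        segset, _ = thirty_cycle_segments
        fm = assemble_features(segset)
        assert median_smooth(fm).shape == fm.shape
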
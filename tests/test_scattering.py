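"""Morlet scattering filter bank and three-layer transform."""

import numpy as np
import pytest

import ecgsqa as e
from ecgsqa.scattering import ScatteringConfig, build_filter_bank, scattering_transform


def _oracle_transform(x, bank, config):
    """Direct per-path cascade: FFT products written out independently.

    Mirrors the definition — convolve, modulus, convolve, modulus,
    low-pass — path by path, with no batching or intermediate reuse
    beyond the formula itself.
    """
    n = config.signal_length
    stride = n // config.frames_per_segment

    def conv(sig, filt_freq):
        return np.fft.ifft(np.fft.fft(sig) * filt_freq)

    rows = [np.maximum(conv(x, bank.phi).real[::stride], 0.0)]
    for i in range(bank.n_first_order):
        u1 = np.abs(conv(x, bank.psi1[i]))
        rows.append(np.maximum(conv(u1, bank.phi).real[::stride], 0.0))
    for p in bank.paths:
        if p.order != 2:
            continue
        u1 = np.abs(conv(x, bank.psi1[p.i]))
        u2 = np.abs(conv(u1, bank.psi2[p.j]))
        rows.append(np.maximum(conv(u2, bank.phi).real[::stride], 0.0))
    return np.asarray(rows)


class TestFilterBank:
    def test_default_counts(self, default_bank):
        assert default_bank.n_first_order == 41
        assert default_bank.n_second_order == 7
        assert default_bank.n_paths_order2 == 39
        assert default_bank.n_paths == 81

    @pytest.mark.parametrize("order", [1, 2])
    def test_centers_strictly_decreasing_geometric(self, default_bank, order):
        centers = default_bank.centers1 if order == 1 else default_bank.centers2
        q = default_bank.config.quality_factors[order - 1]
        assert (np.diff(centers) < 0).all()
        ratios = centers[1:] / centers[:-1]
        np.testing.assert_allclose(ratios, 2 ** (-1.0 / q), rtol=1e-12)

    def test_littlewood_paley_bounded_by_one(self, default_bank):
        _, lp = default_bank.littlewood_paley(n_grid=4096)
        assert lp.max() <= 1 + 1e-6
        assert lp.min() > 0

    def test_deterministic_construction(self, default_config, default_bank):
        again = e.build_filter_bank(default_config)
        np.testing.assert_array_equal(again.psi1, default_bank.psi1)
        np.testing.assert_array_equal(again.phi, default_bank.phi)
        assert again.paths == default_bank.paths

    def test_admissibility_is_frequency_decreasing(self, default_bank):
        for p in default_bank.paths:
            if p.order == 2:
                assert default_bank.centers2[p.j] < default_bank.centers1[p.i]

    def test_overlong_invariance_scale_rejected(self):
        with pytest.raises(ValueError):
            ScatteringConfig(invariance_scale_s=11.0)  # > 10-s segment

    def test_invariance_scale_sweep(self):
        """I = 1..10 s all build and transform; path count varies with I."""
        x = e.synth_ecg(seed=3).samples
        x = (x - x.min()) / (x.max() - x.min())
        counts = []
        for i_s in range(1, 11):
            cfg = ScatteringConfig(invariance_scale_s=float(i_s))
            bank = build_filter_bank(cfg)
            fm = scattering_transform(x, bank, cfg)
            assert fm.shape[1] == cfg.frames_per_segment
            counts.append(fm.shape[0])
        assert len(set(counts)) > 1


class TestTransform:
    def test_default_output_shape(self, default_bank, clean_segment):
        fm = e.scattering_transform(clean_segment, default_bank)
        assert fm.shape == (81, 20)
        assert (fm.values >= 0).all()

    def test_zero_input_gives_zero_matrix(self, default_bank):
        fm = e.scattering_transform(np.zeros(2500), default_bank)
        assert np.all(fm.values == 0)

    def test_length_mismatch_rejected(self, default_bank):
        with pytest.raises(ValueError):
            e.scattering_transform(np.zeros(1000), default_bank)

    def test_sine_energy_peaks_at_matching_filter(self, default_bank, default_config):
        """A 10 Hz tone excites the first-order filter tuned nearest 10 Hz."""
        t = np.arange(2500) / 250.0
        fm = e.scattering_transform(np.sin(2 * np.pi * 10 * t), default_bank)
        order1 = fm.values[1:42]
        best = np.argmax(order1.sum(axis=1))
        centers_hz = default_bank.centers1 * 250.0
        assert best == np.argmin(np.abs(centers_hz - 10.0))

    def test_matches_direct_oracle_at_default_size(self, default_bank, default_config,
                                                   clean_segment):
        fm = e.scattering_transform(clean_segment, default_bank)
        want = _oracle_transform(clean_segment.samples, default_bank, default_config)
        np.testing.assert_allclose(fm.values, want, rtol=1e-6, atol=1e-12)

    def test_matches_direct_oracle_on_short_inputs(self):
        cfg = ScatteringConfig(fs=256.0, signal_length=256, invariance_scale_s=0.5,
                               frames_per_segment=16)
        bank = build_filter_bank(cfg)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.standard_normal(256)
            got = scattering_transform(x, bank, cfg).values
            want = _oracle_transform(x, bank, cfg)
            err = np.linalg.norm(got - want) / np.linalg.norm(want)
            assert err < 1e-6

    def test_non_expansive_on_random_pairs(self, default_bank):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.standard_normal(2500)
            y = rng.standard_normal(2500)
            d_feat = e.scattering_distance(
                e.scattering_transform(x, default_bank),
                e.scattering_transform(y, default_bank),
            )
            assert d_feat <= np.linalg.norm(x - y) * (1 + 1e-9)

    def test_shift_stability_monotone(self, default_bank, clean_segment):
        """Features drift slowly and monotonically under small circular shifts."""
        base = e.scattering_transform(clean_segment, default_bank)
        norm = np.linalg.norm(base.values)
        rel = []
        for tau in (4, 16, 64):
            shifted = np.roll(clean_segment.samples, tau)
            d = e.scattering_distance(
                base, e.scattering_transform(shifted, default_bank)
            )
            rel.append(d / norm)
        assert rel[0] < 0.1
        assert rel[0] <= rel[1] <= rel[2]

    def test_order_energy_decreases_for_broadband_input(self, default_bank):
        x = np.random.default_rng(5).standard_normal(2500)
        fm = e.scattering_transform(x, default_bank)
        e1 = np.sum(fm.values[1:42] ** 2)
        e2 = np.sum(fm.values[42:] ** 2)
        assert e2 < e1


class TestDistance:
    def test_identical_matrices_distance_zero(self, default_bank, clean_segment):
        fm = e.scattering_transform(clean_segment, default_bank)
        assert e.scattering_distance(fm, fm) == 0.0

    def test_symmetry_and_triangle_inequality(self, default_bank):
        rng = np.random.default_rng(8)
        fms = [
            e.scattering_transform(rng.standard_normal(2500), default_bank)
            for _ in range(3)
        ]
        a, b, c = fms
        assert e.scattering_distance(a, b) == pytest.approx(e.scattering_distance(b, a))
        assert e.scattering_distance(a, c) <= (
            e.scattering_distance(a, b) + e.scattering_distance(b, c) + 1e-12
        )

    def test_shape_mismatch_rejected(self, default_bank, clean_segment):
        cfg = ScatteringConfig(invariance_scale_s=1.0)
        other_bank = build_filter_bank(cfg)
        fm_a = e.scattering_transform(clean_segment, default_bank)
        fm_b = e.scattering_transform(clean_segment, other_bank, cfg)
        with pytest.raises(ValueError):
            e.scattering_distance(fm_a, fm_b)
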
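"""Filtering, envelopes, symmetric orthogonalization and AEC."""

import numpy as np
import pytest

from eegaec.connectivity import (
    aec,
    amplitude_envelope,
    bandpass,
    matrices_to_pairs,
    symmetric_orthogonalize,
)
from eegaec.core import DEFAULT_BANDS, BandDefinition
from eegaec.simulate import envelope_correlation_oracle, simulate_coupled_sources

BETA1 = DEFAULT_BANDS[2]
FS = 512.0


def _tone(freq, fs=FS, dur=10.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


class TestBandpass:
    def test_passband_tone_preserved(self):
        x, _ = _tone(15.0)
        y = bandpass(x, BETA1, FS)
        sl = slice(int(FS), -int(FS))  # stay clear of 1-s edges
        gain = np.sqrt(np.mean(y[sl] ** 2) / np.mean(x[sl] ** 2))
        assert 0.95 <= gain <= 1.0

    def test_stopband_tone_suppressed(self):
        x, _ = _tone(2.0)
        y = bandpass(x, BETA1, FS)
        sl = slice(int(FS), -int(FS))
        gain = np.sqrt(np.mean(y[sl] ** 2) / np.mean(x[sl] ** 2))
        assert gain < 0.05

    def test_near_idempotent_on_noise(self, rng):
        x = rng.standard_normal(int(30 * FS))
        once = bandpass(x, BETA1, FS)
        twice = bandpass(once, BETA1, FS)
        first_change = np.sqrt(np.mean((once - x) ** 2))
        second_change = np.sqrt(np.mean((twice - once) ** 2))
        assert second_change < 0.05 * first_change

    def test_band_and_length_validation(self, rng):
        with pytest.raises(ValueError):
            bandpass(rng.standard_normal(1000), BandDefinition("hi", 200, 300), FS)
        with pytest.raises(ValueError):
            bandpass(rng.standard_normal(10), BETA1, FS)


class TestEnvelope:
    def test_constant_amplitude_tone(self):
        x, _ = _tone(15.0, amp=2.5)
        env = amplitude_envelope(x)
        sl = slice(int(0.5 * FS), -int(0.5 * FS))
        assert abs(env[sl].mean() - 2.5) < 0.05

    def test_am_modulated_tone_matches_analytic_envelope(self):
        _, t = _tone(15.0)
        x = (1 + 0.5 * np.cos(2 * np.pi * 1.0 * t)) * np.sin(2 * np.pi * 15.0 * t)
        expected = 1 + 0.5 * np.cos(2 * np.pi * 1.0 * t)
        env = amplitude_envelope(x)
        sl = slice(int(0.5 * FS), -int(0.5 * FS))
        assert np.max(np.abs(env[sl] - expected[sl])) < 0.05

    def test_zero_input(self):
        assert np.all(amplitude_envelope(np.zeros(100)) == 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            amplitude_envelope(np.array([1.0, np.nan]))


class TestSymmetricOrthogonalize:
    def test_orthogonal_input_is_fixed_point(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((512, 3)))
        m = (q * np.array([3.0, 1.0, 0.5])).T
        out = symmetric_orthogonalize(m)
        np.testing.assert_allclose(out, m, atol=1e-8)

    def test_identical_rows_raise(self, rng):
        x = rng.standard_normal(256)
        with pytest.raises(ValueError, match="dependen"):
            symmetric_orthogonalize(np.vstack([x, x]))

    def test_output_rows_pairwise_orthogonal(self, rng):
        m = rng.standard_normal((3, 2048))
        out = symmetric_orthogonalize(m)
        norms = np.linalg.norm(out, axis=1)
        dots = out @ out.T / np.outer(norms, norms)
        assert np.max(np.abs(dots[~np.eye(3, dtype=bool)])) < 1e-6

    def test_beats_one_shot_polar_orthogonalization(self, rng):
        """The alternating scheme must be at least as close (Frobenius) as
        the naive single polar-factor projection."""
        m = rng.standard_normal((3, 2048)) * np.array([[5.0], [1.0], [0.2]])
        out = symmetric_orthogonalize(m)
        u, _, vt = np.linalg.svd(m.T, full_matrices=False)
        polar = (u @ vt).T  # orthonormal rows closest to m's row frame
        d = np.einsum("ij,ij->i", m, polar)
        one_shot = polar * d[:, None]
        assert np.linalg.norm(m - out) <= np.linalg.norm(m - one_shot) + 1e-9

    def test_two_signal_case_matches_rotation_grid_search(self, rng):
        """For n=2 the solution space is a rotation angle in the row plane;
        brute-force the angle and compare objective values."""
        m = rng.standard_normal((2, 64)) * np.array([[2.0], [0.7]])
        out = symmetric_orthogonalize(m)
        achieved = np.linalg.norm(m - out)

        q, _ = np.linalg.qr(m.T)  # orthonormal basis of the row plane
        best = np.inf
        for theta in np.linspace(0, np.pi, 20001):
            c, s = np.cos(theta), np.sin(theta)
            for v2 in ((-s, c), (s, -c)):
                v = np.array([[c, s], v2]) @ q.T  # orthonormal rows
                d = np.einsum("ij,ij->i", m, v)
                best = min(best, np.linalg.norm(m - v * d[:, None]))
        assert achieved <= best + 1e-6


class TestAEC:
    def test_leakage_nulling_on_scaled_copy(self):
        src = simulate_coupled_sources(BETA1, 0.5, 30, 256, seed=1, n_rois=2)
        pair = np.vstack([src[0], 0.5 * src[0]])
        orth = aec(pair, 256, [BETA1], ["A", "B"], orthogonalize=True)
        raw = aec(pair, 256, [BETA1], ["A", "B"], orthogonalize=False)
        assert abs(orth[0].values[0, 1]) < 0.05
        assert raw[0].values[0, 1] > 0.95

    def test_leakage_suppression_under_noise(self, rng):
        """Mixtures of one source plus independent noise: raw AEC is
        spuriously high; orthogonalization removes most of it.

        Symmetric (joint) orthogonalization splits residual shared signal
        between near-duplicate channels rather than deleting it from one,
        so suppression of a two-channel near-copy is strong but not total.
        """
        src = simulate_coupled_sources(BETA1, 0.5, 60, 256, seed=2, n_rois=1)[0]
        sigma = np.sqrt(np.mean(src**2) / 10)  # SNR 10
        ch = np.vstack(
            [
                src + sigma * rng.standard_normal(src.size),
                0.7 * src + sigma * rng.standard_normal(src.size),
            ]
        )
        orth = aec(ch, 256, [BETA1], ["A", "B"], orthogonalize=True)[0].values[0, 1]
        raw = aec(ch, 256, [BETA1], ["A", "B"], orthogonalize=False)[0].values[0, 1]
        assert raw > 0.8
        assert abs(orth) < 0.3
        assert raw - abs(orth) > 0.5

    def test_matches_oracle_on_planted_sources(self):
        src = simulate_coupled_sources(BETA1, 0.6, 120, 256, seed=4, n_rois=4)
        oracle = envelope_correlation_oracle(src, 256, [BETA1])[:, 0]
        mats = aec(src, 256, [BETA1], list("ABCD"), orthogonalize=False)
        pipe = matrices_to_pairs(mats)[:, 0]
        assert np.max(np.abs(pipe - oracle)) < 0.05

    def test_symmetry_range_and_scale_invariance(self):
        src = simulate_coupled_sources(BETA1, 0.4, 30, 256, seed=5, n_rois=3)
        mats = aec(src, 256, [BETA1], list("ABC"))
        v = mats[0].values
        np.testing.assert_array_equal(v, v.T)
        off = v[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) <= 1)
        scaled = src * np.array([[7.0], [1.0], [0.01]])
        v2 = aec(scaled, 256, [BETA1], list("ABC"))[0].values
        np.testing.assert_allclose(v[~np.eye(3, dtype=bool)], v2[~np.eye(3, dtype=bool)], atol=1e-6)

    def test_band_separation(self):
        """Coupling planted only in beta-1 leaves the other bands at their
        uncoupled baseline."""
        from eegaec.simulate import SimulationConfig, simulate_subject_sources

        cfg = SimulationConfig(n_per_group=2, fs=256, duration=60, n_sensors=8, seed=6)
        spec = cfg.coupling_spec["control"]
        vals = np.stack(
            [
                envelope_correlation_oracle(
                    simulate_subject_sources(cfg, spec, seed), cfg.fs, cfg.bands
                )
                for seed in range(8)
            ]
        )  # replicates x pairs x bands
        bi = [b.name for b in cfg.bands].index("beta1")
        other = np.delete(vals, bi, axis=2)
        se = other.std() / np.sqrt(other.shape[0])
        assert np.abs(other.mean(axis=0)).max() < max(2 * se, 0.1)
        assert vals[:, 3, bi].mean() > 0.15  # the planted target pair

    def test_windowed_mode_agrees_with_full_record(self):
        src = simulate_coupled_sources(BETA1, 0.7, 120, 256, seed=7, n_rois=2)
        full = aec(src, 256, [BETA1], ["A", "B"])[0].values[0, 1]
        win = aec(src, 256, [BETA1], ["A", "B"], window_s=20.0)[0].values[0, 1]
        assert abs(full - win) < 0.15

    def test_too_short_input_rejected(self, rng):
        with pytest.raises(ValueError):
            aec(rng.standard_normal((2, 600)), 256, [BETA1], ["A", "B"])


def test_cohort_connectivity_structure(mini_cohort):
    """Identical recordings give identical tensor slices; 4 ROIs -> 6 pairs."""
    from eegaec.connectivity import cohort_connectivity
    from eegaec.core import SensorRecording
    from eegaec.inverse import ROIDefinition

    c = mini_cohort
    cfg = c.config
    rois = ROIDefinition({n: [i] for i, n in enumerate(cfg.roi_names)})
    recs = [c.recordings[0], SensorRecording(c.recordings[0].data.copy(), cfg.fs)]
    tensor = cohort_connectivity(recs, c.forward, rois, cfg.bands)
    assert tensor.values.shape == (2, 6, 6)
    np.testing.assert_array_equal(tensor.values[0], tensor.values[1])
    assert tensor.pair_labels[0] == ("DLPFC_L", "DLPFC_R")


def test_cohort_connectivity_recovers_group_direction(mini_cohort):
    from eegaec.connectivity import cohort_connectivity
    from eegaec.inverse import ROIDefinition
    from eegaec.simulate import TARGET_BAND, TARGET_PAIR

    c = mini_cohort
    rois = ROIDefinition({n: [i] for i, n in enumerate(c.config.roi_names)})
    tensor = cohort_connectivity(c.recordings, c.forward, rois, c.config.bands)
    vals = tensor.cell(*TARGET_PAIR, TARGET_BAND)
    assert vals[c.labels == 0].mean() > vals[c.labels == 1].mean()


def test_tensor_frame_roundtrip(mini_cohort):
    from eegaec.connectivity import ConnectivityTensor, cohort_connectivity
    from eegaec.inverse import ROIDefinition

    c = mini_cohort
    rois = ROIDefinition({n: [i] for i, n in enumerate(c.config.roi_names)})
    tensor = cohort_connectivity(c.recordings[:2], c.forward, rois, c.config.bands)
    back = ConnectivityTensor.from_frame(tensor.to_frame())
    np.testing.assert_allclose(back.values, tensor.values)
    assert back.pair_labels == tensor.pair_labels
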
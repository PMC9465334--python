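"""Preprocessing chain: Gaussian kernel values, exclusion rule with its
10% cap, zero-phase band-pass behaviour and the ± SNR estimator."""

import numpy as np
import pytest

from ecochg import (
    EpochMatrix,
    GaussianWindowParams,
    StimulusSpec,
    SynthesisParams,
    bandpass_filter,
    cm_waveform,
    exclude_uncorrelated,
    gaussian_weighted_epochs,
    gaussian_weights,
    inject_artifacts,
    preprocess_recording,
    snr_plus_minus,
    synth_recording,
)

FS = 20000.0


def white_epochs(rng, n_ep=100, n_s=192, sd=1.0):
    return EpochMatrix(rng.normal(0, sd, size=(n_ep, n_s)), FS)


class TestGaussianWeights:
    def test_printed_kernel_values(self):
        """w(l) = exp(-0.5 (l / (0.4 * 2))^2): direct evaluation at l = 0, ±1, ±2."""
        w = gaussian_weights(GaussianWindowParams(sigma=0.4))
        assert w[2] == 1.0
        assert w[1] == w[3] == pytest.approx(np.exp(-0.78125), rel=1e-12)
        assert w[0] == w[4] == pytest.approx(np.exp(-3.125), rel=1e-12)

    def test_symmetry_and_peak(self):
        w = gaussian_weights(GaussianWindowParams(sigma=0.7, span=3))
        np.testing.assert_allclose(w, w[::-1])
        assert np.argmax(w) == 3

    def test_sigma_validation(self):
        with pytest.raises(ValueError, match="sigma"):
            GaussianWindowParams(sigma=0.0)


class TestGaussianWeightedEpochs:
    def test_constant_epochs_preserved(self):
        em = EpochMatrix(np.full((20, 64), 3.7), FS)
        out = gaussian_weighted_epochs(em)
        np.testing.assert_allclose(out.samples, 3.7, atol=1e-12)

    def test_linear_ramp_preserved_interior(self):
        """A symmetric normalized kernel leaves linear trends unchanged."""
        i = np.arange(30, dtype=float)
        em = EpochMatrix(np.tile(i[:, None], (1, 16)), FS)
        out = gaussian_weighted_epochs(em)
        np.testing.assert_allclose(out.samples[2:-2, 0], i[2:-2], atol=1e-10)

    def test_white_noise_variance_reduction(self, rng):
        """Var of a weighted epoch is sigma^2 * sum(w^2)/sum(w)^2 (interior)."""
        w = gaussian_weights()
        expected = np.sum(w**2) / np.sum(w) ** 2  # ~0.3545
        em = white_epochs(rng, n_ep=400, n_s=512)
        out = gaussian_weighted_epochs(em)
        var = out.samples[2:-2].var()
        assert var == pytest.approx(expected, rel=0.05)

    def test_epoch_count_preserved(self, rng):
        em = white_epochs(rng, n_ep=37)
        assert gaussian_weighted_epochs(em).n_epochs == 37

    def test_too_few_epochs(self, rng):
        em = EpochMatrix(rng.normal(size=(4, 32)), FS)
        with pytest.raises(ValueError, match="at least 5"):
            gaussian_weighted_epochs(em)


class TestExcludeUncorrelated:
    def _signal_ensemble(self, rng, n_flip, n_ep=100):
        s = cm_waveform(StimulusSpec(frequency=500), FS, amplitude=5.0)
        x = s[None, :] + rng.normal(0, 1.0, size=(n_ep, s.size))
        start = 40
        x[start:start + n_flip] = -s[None, :] + rng.normal(0, 1.0, size=(n_flip, s.size))
        return EpochMatrix(x, FS)

    def test_cap_at_ten_percent(self, rng):
        """15 anti-correlated epochs out of 100: exactly the 10 worst go."""
        em = self._signal_ensemble(rng, 15)
        ref = em.samples.mean(axis=0)
        kept, excluded = exclude_uncorrelated(gaussian_weighted_epochs(em), reference=ref)
        assert len(excluded) == 10
        assert kept.n_epochs == 90

    def test_under_cap_all_excluded(self, rng):
        em = self._signal_ensemble(rng, 7)
        ref = em.samples.mean(axis=0)
        kept, excluded = exclude_uncorrelated(gaussian_weighted_epochs(em), reference=ref)
        assert len(excluded) == 7

    def test_positively_correlated_kept(self, rng):
        em = self._signal_ensemble(rng, 0)
        _, excluded = exclude_uncorrelated(gaussian_weighted_epochs(em))
        assert len(excluded) == 0

    def test_never_exceeds_cap_property(self, rng):
        for frac in (0.2, 0.3, 0.45):
            n_flip = int(frac * 100)
            em = self._signal_ensemble(rng, n_flip)
            ref = em.samples.mean(axis=0)
            _, excluded = exclude_uncorrelated(gaussian_weighted_epochs(em), reference=ref)
            assert len(excluded) <= 10

    def test_zero_variance_epoch_r_zero(self, rng):
        x = rng.normal(size=(20, 64))
        x[3] = 0.0
        _, excluded = exclude_uncorrelated(EpochMatrix(x, FS), threshold=-0.2)
        assert 3 not in excluded


class TestBandpass:
    def test_dc_removed(self):
        em = EpochMatrix(np.full((5, 400), 10.0), FS)
        out = bandpass_filter(em)
        assert np.abs(out.samples).max() < 1e-6 * 10.0

    def test_inband_tone_preserved_zero_phase(self):
        t = np.arange(2000) / FS
        tone = np.sin(2 * np.pi * 500 * t)
        em = EpochMatrix(np.tile(tone, (5, 1)), FS)
        out = bandpass_filter(em)
        mid = slice(500, 1500)  # steady state
        amp = out.samples[0, mid].max()
        assert amp == pytest.approx(1.0, rel=0.05)
        # zero phase: in-band output aligns with input
        r = np.corrcoef(out.samples[0, mid], tone[mid])[0, 1]
        assert r > 0.999

    def test_symmetric_pulse_stays_symmetric(self):
        x = np.zeros((5, 2001))  # long enough for edge transients to settle
        x[:, 950:1051] = np.hanning(101)
        out = bandpass_filter(EpochMatrix(x, FS)).samples[0]
        np.testing.assert_allclose(out, out[::-1], atol=1e-8)

    def test_idempotent_in_passband(self):
        t = np.arange(2000) / FS
        tone = np.sin(2 * np.pi * 700 * t)
        em = EpochMatrix(np.tile(tone, (5, 1)), FS)
        once = bandpass_filter(em)
        twice = bandpass_filter(once)
        mid = slice(500, 1500)
        ratio = twice.samples[0, mid].max() / once.samples[0, mid].max()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_cutoff_validation(self):
        em = EpochMatrix(np.zeros((5, 100)), FS)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(em, 100.0, 10000.0)


class TestSnrPlusMinus:
    def test_identical_epochs_saturate(self):
        em = EpochMatrix(np.tile(np.sin(np.linspace(0, 6, 128)), (10, 1)), FS)
        assert snr_plus_minus(em) == 60.0

    def test_pure_noise_negative_in_expectation(self, rng):
        vals = [
            snr_plus_minus(rng.normal(size=(100, 192)))
            for _ in range(300)
        ]
        assert np.mean(vals) < 0.0

    def test_known_operating_point(self, stim500, rng):
        """True SNR 4.18 dB: the estimator is unbiased to ±0.5 dB."""
        sd, n = 1.0, 100
        target_lin = 10 ** 0.418
        u = cm_waveform(stim500, FS, 1.0)
        a = np.sqrt(target_lin * sd**2 / n / np.mean(u**2))
        vals = []
        for _ in range(500):
            x = a * u[None, :] + rng.normal(0, sd, size=(n, u.size))
            vals.append(snr_plus_minus(x))
        assert np.mean(vals) == pytest.approx(4.18, abs=0.5)

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            snr_plus_minus(np.zeros((1, 64)))


class TestPipeline:
    def test_snr_improves_with_outlier_epochs(self, stim500, rng):
        """Weighting + exclusion raises the ± SNR when 15% of epochs are
        anti-correlated bursts (directional preprocessing gain)."""
        from ecochg.synthetic import amplitude_for_snr

        amp = amplitude_for_snr(stim500, 6.0)
        wins = 0
        n_trials = 40
        for i in range(n_trials):
            rec = synth_recording(
                SynthesisParams(stimulus=stim500, cm_amplitude=amp), rng=rng
            )
            rec = inject_artifacts(rec, "outlier_epochs", fraction=0.15, seed=i)
            pre = preprocess_recording(rec)
            wins += pre.derived.snr_dB > pre.snr_raw_dB
        assert wins >= 0.9 * n_trials

    def test_exclusions_are_applied_consistently(self, stim500, rng):
        amp = 5.0
        rec = synth_recording(SynthesisParams(stimulus=stim500, cm_amplitude=amp), rng=rng)
        rec = inject_artifacts(rec, "outlier_epochs", fraction=0.1, seed=0)
        pre = preprocess_recording(rec)
        assert pre.con.n_epochs == 100 - len(pre.excluded_con)
        assert pre.con_weighted.n_epochs == pre.con.n_epochs

    def test_noise_only_recording_keeps_epochs(self, noise_recording):
        pre = preprocess_recording(noise_recording)
        assert pre.con.n_epochs >= 98  # exclusion is rare on pure noise
        assert np.isfinite(pre.derived.snr_dB)
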
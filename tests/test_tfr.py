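import numpy as np
import pandas as pd
import pytest

import alphasel as a
from conftest import make_tfrset


def _sine_epochs(freq_hz, sfreq=250.0, n_ch=2, amplitude=1.0, dur=(-1000.0, 3000.0)):
    times = np.arange(dur[0], dur[1], 1000.0 / sfreq)
    sig = amplitude * np.sin(2 * np.pi * freq_hz * times / 1000.0)
    data = np.tile(sig, (1, n_ch, 1))
    return a.EpochSet(
        data=data,
        times=times,
        sfreq=sfreq,
        channel_names=[f"CH{i}" for i in range(n_ch)],
        trial_info=pd.DataFrame({"participant_id": [0]}),
    )


class TestWaveletFamily:
    def test_geometric_grid_endpoints(self, family250):
        assert family250.n_frequencies == 26
        assert family250.frequencies[0] == pytest.approx(4.0)
        assert family250.frequencies[-1] == pytest.approx(30.0)
        assert family250.cycles[0] == pytest.approx(4.0)
        assert family250.cycles[-1] == pytest.approx(11.25)
        ratios = family250.frequencies[1:] / family250.frequencies[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_exactly_six_family_frequencies_in_alpha_band(self, family250):
        in_band = family250.subset(a.ALPHA_BAND)
        assert in_band.n_frequencies == 6

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fmin": 0.0},
            {"fmin": 40.0},
            {"fmax": 200.0},
            {"n": 1},
            {"c_first": 0.0},
            {"c_first": 12.0},
        ],
    )
    def test_invalid_family_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            a.build_wavelet_family(sfreq=250.0, **kwargs)


class TestMorletPower:
    def test_frequency_recovery_for_random_sinusoids(self, family250):
        # brute-force oracle: the argmax family frequency identifies the input
        # frequency to within one step of the geometric grid (for inputs near a
        # bin boundary either neighbour is a legitimate winner)
        rng = np.random.default_rng(42)
        mid = 500  # sample index well inside the epoch
        log_step = np.log(family250.frequencies[1] / family250.frequencies[0])
        for freq in rng.uniform(5.0, 28.0, size=20):
            tfr = a.morlet_power(_sine_epochs(freq), family250)
            argmax = tfr.power[0, 0, :, mid].argmax()
            err = abs(np.log(family250.frequencies[argmax]) - np.log(freq))
            assert err <= log_step, f"freq {freq:.2f}"

    def test_zero_input_gives_zero_power(self, family250):
        epochs = _sine_epochs(10.0, amplitude=0.0)
        tfr = a.morlet_power(epochs, family250)
        assert np.all(tfr.power == 0)

    def test_power_scales_quadratically_with_amplitude(self, family250):
        t1 = a.morlet_power(_sine_epochs(10.0, amplitude=1.0), family250)
        t3 = a.morlet_power(_sine_epochs(10.0, amplitude=3.0), family250)
        mask = t1.power > 1e-6 * t1.power.max()
        ratio = t3.power[mask] / t1.power[mask]
        assert np.allclose(ratio, 9.0, rtol=1e-3)

    def test_sampling_rate_mismatch_rejected(self, family250):
        epochs = _sine_epochs(10.0, sfreq=200.0)
        with pytest.raises(ValueError, match="mismatch"):
            a.morlet_power(epochs, family250)

    def test_time_shift_equivariance(self, family250):
        rng = np.random.default_rng(3)
        times = np.arange(-1000.0, 3000.0, 4.0)
        sig = rng.standard_normal(times.size)
        shift = 25  # samples
        shifted = np.roll(sig, shift)
        info = pd.DataFrame({"participant_id": [0]})
        e1 = a.EpochSet(sig[None, None, :], times, 250.0, ["C"], info)
        e2 = a.EpochSet(shifted[None, None, :], times, 250.0, ["C"], info)
        p1 = a.morlet_power(e1, family250).power[0, 0]
        p2 = a.morlet_power(e2, family250).power[0, 0]
        # away from edges the power time course shifts with the signal
        core = slice(300, 700)
        assert np.allclose(p1[:, core], p2[:, np.arange(300 + shift, 700 + shift)], rtol=1e-3)

    def test_decimation_keeps_every_kth_sample(self, family250):
        epochs = _sine_epochs(10.0)
        full = a.morlet_power(epochs, family250)
        dec = a.morlet_power(epochs, family250, decimate=5)
        assert np.allclose(dec.power, full.power[..., ::5], rtol=1e-6)
        assert dec.sfreq == pytest.approx(50.0)


class TestDbBaseline:
    def test_step_change_in_power_maps_to_3dB(self):
        # power exactly doubles after t=0: post-onset dB = 10*log10(2)
        times = np.arange(-200.0, 200.0, 4.0)
        power = np.ones((1, 1, 1, times.size))
        power[..., times >= 0] = 2.0
        tfr = make_tfrset(power, times, [10.0])
        out = a.db_baseline(tfr, window=(-200.0, -4.0))
        assert np.allclose(out.power[..., times >= 0], 10 * np.log10(2), atol=1e-9)
        assert np.allclose(out.power[..., times < 0], 0.0, atol=1e-9)

    def test_db_output_invariant_to_input_rescaling(self, family250):
        rng = np.random.default_rng(8)
        times = np.arange(-1000.0, 3000.0, 4.0)
        data = rng.standard_normal((3, 2, times.size))
        info = pd.DataFrame({"participant_id": [0, 0, 0]})
        for scale in (1.0, 37.5):
            epochs = a.EpochSet(scale * data, times, 250.0, ["A", "B"], info)
            out = a.db_baseline(a.morlet_power(epochs, family250, single_precision=False))
            if scale == 1.0:
                ref = out.power
        assert np.allclose(out.power, ref, atol=1e-8)

    def test_db_output_independent_of_wavelet_normalization(self, family250):
        rng = np.random.default_rng(9)
        times = np.arange(-1000.0, 3000.0, 4.0)
        data = rng.standard_normal((2, 1, times.size))
        info = pd.DataFrame({"participant_id": [0, 0]})
        epochs = a.EpochSet(data, times, 250.0, ["A"], info)
        db = {}
        for norm in ("energy", "amplitude"):
            raw = a.morlet_power(epochs, family250, normalization=norm, single_precision=False)
            db[norm] = a.db_baseline(raw).power
        assert np.allclose(db["energy"], db["amplitude"], atol=1e-8)

    def test_stationary_noise_baselines_to_zero_db_on_average(self, family250):
        # stationary input: the dB of the trial-averaged power shows neither a
        # departure from the 0 dB baseline level nor pre/post time structure
        rng = np.random.default_rng(5)
        times = np.arange(-1000.0, 3000.0, 4.0)
        data = rng.standard_normal((60, 1, times.size))
        info = pd.DataFrame({"participant_id": np.zeros(60, dtype=int)})
        epochs = a.EpochSet(data, times, 250.0, ["A"], info)
        raw = a.morlet_power(epochs, family250)
        bmask = (times >= -200) & (times <= 0)
        baseline = raw.power[..., bmask].mean(axis=(0, 3))
        trial_mean = raw.power.mean(axis=0)
        db_of_mean = 10 * np.log10(trial_mean / baseline[..., None])
        core = (times > -400) & (times < 2400)
        assert abs(db_of_mean[..., core].mean()) < 0.3
        pre = (times > -400) & (times < 0)
        post = (times > 500) & (times < 2000)
        assert abs(db_of_mean[..., pre].mean() - db_of_mean[..., post].mean()) < 0.4

    def test_baseline_requires_raw_units_and_valid_window(self):
        times = np.arange(-200.0, 200.0, 4.0)
        tfr = make_tfrset(np.ones((1, 1, 1, times.size)), times, [10.0])
        with pytest.raises(ValueError, match="outside the time axis"):
            a.db_baseline(tfr, window=(-900.0, -800.0))
        db = a.db_baseline(tfr)
        with pytest.raises(ValueError, match="raw"):
            a.db_baseline(db)

    def test_zero_baseline_power_rejected_with_channel_diagnostic(self):
        times = np.arange(-200.0, 200.0, 4.0)
        power = np.ones((2, 2, 1, times.size))
        power[:, 1] = 0.0
        tfr = make_tfrset(power, times, [10.0], ch_names=["Good", "Dead"])
        with pytest.raises(ValueError, match="Dead"):
            a.db_baseline(tfr)


class TestAgainstMne:
    def test_power_time_courses_match_mne_up_to_a_constant_scale(self, family250):
        # cross-implementation oracle: per (channel, frequency) our power and
        # mne's differ only by the wavelet amplitude convention, i.e. by a
        # constant factor over time (which dB baselining cancels)
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(17)
        times = np.arange(-1000.0, 3000.0, 4.0)
        sig = rng.standard_normal((4, 3, times.size))
        info = pd.DataFrame({"participant_id": np.zeros(4, dtype=int)})
        epochs = a.EpochSet(sig, times, 250.0, ["A", "B", "C"], info)
        ours = a.morlet_power(epochs, family250, single_precision=False).power

        theirs = mne.time_frequency.tfr_array_morlet(
            sig,
            sfreq=250.0,
            freqs=family250.frequencies,
            n_cycles=family250.cycles,
            output="power",
            zero_mean=False,
        )
        core = (times > -300) & (times < 2600)
        log_ratio = np.log10(ours[..., core] / theirs[..., core])
        spread = log_ratio.std(axis=-1)  # per trial x channel x frequency
        assert np.median(spread) < 0.005
        assert spread.max() < 0.05
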
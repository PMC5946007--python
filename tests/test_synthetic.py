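"""Ground-truth generator: trains, traces, artifacts, blanking, I/O."""

import json

import numpy as np
import pytest

from blankloss import (
    ArtifactModel,
    GammaISI,
    SpikeTrain,
    StimulationProtocol,
    apply_blanking_trace,
    apply_blanking_train,
    default_template,
    generate_spike_train,
    loss_probability_phase_averaged,
    synthesize_trace,
)
from blankloss.synthetic import (
    read_spike_train_csv,
    read_trace,
    write_spike_train_csv,
    write_trace,
)

FS = 20_000.0


def protocol_tb(f_st, t_b):
    return StimulationProtocol.from_blanking_window(f_st=f_st, t_b=t_b)


class TestGenerateSpikeTrain:
    def test_zero_duration_empty(self, tonic_model):
        train = generate_spike_train(tonic_model, 0.0, 1)
        assert len(train) == 0

    def test_negative_duration_rejected(self, tonic_model):
        with pytest.raises(ValueError):
            generate_spike_train(tonic_model, -1.0, 1)

    def test_deterministic(self, tonic_model):
        a = generate_spike_train(tonic_model, 100.0, 5)
        b = generate_spike_train(tonic_model, 100.0, 5)
        np.testing.assert_array_equal(a.times, b.times)

    def test_times_strictly_increasing_in_range(self, tonic_model):
        train = generate_spike_train(tonic_model, 500.0, 2)
        assert np.all(np.diff(train.times) > 0)
        assert train.times[0] >= 0 and train.times[-1] < 500.0

    def test_empirical_rate(self, tonic_model):
        # renewal theory: count/T -> 1/mu with SE ~ sqrt(T/mu * CV^2)/T
        duration = 10_000.0
        train = generate_spike_train(tonic_model, duration, 11)
        expected = duration * tonic_model.rate_hz
        cv2 = 1.0 / tonic_model.shape_a
        se = np.sqrt(expected * cv2)
        assert abs(len(train) - expected) < 3 * se

    def test_isi_distribution_matches_model(self, tonic_model):
        train = generate_spike_train(tonic_model, 10_000.0, 13)
        isis = np.diff(train.times)
        assert isis.mean() == pytest.approx(tonic_model.mean_isi, rel=0.05)
        assert isis.std() == pytest.approx(tonic_model.std_isi, rel=0.05)

    def test_invalid_train_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([0.2, 0.1]), duration=1.0)
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([0.5, 1.5]), duration=1.0)


class TestSynthesizeTrace:
    def test_planted_spikes_as_local_extrema(self, template):
        times = 0.5 + np.arange(50) * 0.1
        train = SpikeTrain(times=times, duration=6.0)
        trace = synthesize_trace(train, template, None, None, 0.0, FS, 0)
        x = trace.samples
        minima = np.flatnonzero(
            (x[1:-1] < -0.5 * template.amplitude)
            & (x[1:-1] < x[:-2])
            & (x[1:-1] <= x[2:])
        )
        assert minima.size == 50

    def test_sample_count(self, template, tonic_model):
        train = generate_spike_train(tonic_model, 12.34, 3)
        trace = synthesize_trace(train, template, None, None, 0.05, FS, 4)
        assert trace.samples.size == round(12.34 * FS)

    def test_pure_noise_statistics(self, template):
        quiet = default_template(FS, amplitude=0.0)
        train = SpikeTrain(times=np.array([1.0]), duration=50.0)
        trace = synthesize_trace(train, quiet, None, None, 0.3, FS, 9)
        assert trace.samples.std() == pytest.approx(0.3, rel=0.05)

    def test_artifact_onset_placement(self, template):
        protocol = protocol_tb(130.0, 2e-3)
        artifact = ArtifactModel(pulse_width=65e-6, amplitude=3.0, decay_tau=0.5e-3)
        train = SpikeTrain(times=np.empty(0), duration=1.0)
        trace = synthesize_trace(train, template, artifact, protocol, 0.0, FS, 0)
        onsets = np.flatnonzero(np.abs(trace.samples) > 0)
        expected_first = [round(k * protocol.t_st * FS) for k in range(131)]
        # every stimulus onset sample carries the artifact's first (nonzero) value
        for k, idx in enumerate(expected_first):
            if idx < trace.samples.size:
                assert trace.samples[idx] == pytest.approx(3.0)
        assert onsets[0] == expected_first[0]

    def test_low_sampling_rate_rejected(self, template, tonic_model):
        train = generate_spike_train(tonic_model, 5.0, 1)
        with pytest.raises(ValueError):
            synthesize_trace(train, template, None, None, 0.05, 1000.0, 1)

    def test_metadata_ground_truth(self, template, tonic_model):
        train = generate_spike_train(tonic_model, 30.0, 21)
        trace = synthesize_trace(train, template, None, None, 0.05, FS, 22)
        np.testing.assert_allclose(trace.metadata["spike_times_s"], train.times)
        assert trace.metadata["seed"] == 22


class TestApplyBlankingTrace:
    def test_zero_window_identity(self, template, tonic_model):
        train = generate_spike_train(tonic_model, 20.0, 2)
        trace = synthesize_trace(train, template, None, None, 0.05, FS, 3)
        blanked = apply_blanking_trace(trace, protocol_tb(130.0, 0.0))
        np.testing.assert_array_equal(blanked.samples, trace.samples)

    def test_full_tiling_all_zero(self, template, tonic_model):
        train = generate_spike_train(tonic_model, 20.0, 2)
        trace = synthesize_trace(train, template, None, None, 0.05, FS, 3)
        blanked = apply_blanking_trace(trace, protocol_tb(130.0, 1 / 130))
        assert np.all(blanked.samples == 0.0)

    def test_unblanked_samples_bit_identical(self, template, tonic_model):
        train = generate_spike_train(tonic_model, 20.0, 2)
        trace = synthesize_trace(train, template, None, None, 0.05, FS, 3)
        protocol = protocol_tb(130.0, 2e-3)
        blanked = apply_blanking_trace(trace, protocol, phase=1e-3)
        untouched = blanked.samples != 0.0
        np.testing.assert_array_equal(blanked.samples[untouched], trace.samples[untouched])
        assert blanked.metadata["blanked_intervals_s"]

    @pytest.mark.parametrize("t_b_ms, phase_ms", [(2.0, 0.0), (2.0, 3.1), (6.0, 1.0)])
    def test_blanked_fraction_matches_duty_cycle(self, template, t_b_ms, phase_ms):
        protocol = protocol_tb(130.0, t_b_ms * 1e-3)
        train = SpikeTrain(times=np.array([1.0]), duration=10.0)
        quiet = default_template(FS, amplitude=0.0)
        trace = synthesize_trace(train, quiet, None, None, 1.0, FS, 5)
        blanked = apply_blanking_trace(trace, protocol, phase=phase_ms * 1e-3)
        frac = np.mean(blanked.samples == 0.0)
        n_windows = 10.0 * protocol.f_st
        tol = n_windows / trace.samples.size  # one sample period per window
        assert abs(frac - min(1.0, protocol.t_b * protocol.f_st)) <= tol


class TestApplyBlankingTrain:
    def test_zero_window(self, tonic_model):
        train = generate_spike_train(tonic_model, 100.0, 4)
        surviving, lost = apply_blanking_train(train, protocol_tb(130.0, 0.0))
        assert lost == 0 and len(surviving) == len(train)

    def test_full_tiling_all_lost(self, tonic_model):
        train = generate_spike_train(tonic_model, 100.0, 4)
        surviving, lost = apply_blanking_train(train, protocol_tb(130.0, 1 / 130))
        assert len(surviving) == 0 and lost == len(train)

    def test_conservation_across_seeds(self, tonic_model, hfs_protocol):
        for seed in range(5):
            train = generate_spike_train(tonic_model, 200.0, seed)
            surviving, lost = apply_blanking_train(train, hfs_protocol, phase=1e-3)
            assert len(surviving) + lost == len(train)

    def test_monte_carlo_matches_analytic(self, tonic_model, hfs_protocol):
        """Peak-in-window loss converges to the phase-averaged comb sum."""
        analytic = loss_probability_phase_averaged(tonic_model, hfs_protocol, 64)
        rng = np.random.default_rng(99)
        lost_total = n_total = 0
        for seed in range(10):
            train = generate_spike_train(tonic_model, 10_000.0, seed)
            phase = rng.uniform(0, hfs_protocol.t_st)
            _, lost = apply_blanking_train(train, hfs_protocol, phase=phase)
            lost_total += lost
            n_total += len(train)
        frac = lost_total / n_total
        se = np.sqrt(analytic * (1 - analytic) / n_total)
        assert abs(frac - analytic) < 3 * se


class TestIO:
    def test_spike_train_csv_round_trip(self, tonic_model, tmp_path):
        train = generate_spike_train(tonic_model, 50.0, 12)
        path = tmp_path / "train.csv"
        write_spike_train_csv(path, train)
        assert path.read_text().splitlines()[0] == "spike_time_s"
        back = read_spike_train_csv(path, duration=50.0)
        np.testing.assert_array_equal(back.times, train.times)

    @pytest.mark.parametrize("binary", [False, True])
    def test_trace_round_trip(self, template, tonic_model, tmp_path, binary):
        train = generate_spike_train(tonic_model, 11.0, 6)
        trace = synthesize_trace(train, template, None, None, 0.05, FS, 7)
        raw, side = write_trace(tmp_path / "trace", trace, binary=binary)
        back = read_trace(raw, side)
        np.testing.assert_allclose(back.samples, trace.samples, rtol=0, atol=1e-12)
        assert back.sampling_rate == FS
        meta = json.loads(open(side).read())
        assert meta["n_samples"] == trace.samples.size

    def test_byte_identical_reruns(self, template, tonic_model, tmp_path):
        for tag in ("a", "b"):
            train = generate_spike_train(tonic_model, 15.0, 31)
            trace = synthesize_trace(train, template, None, None, 0.05, FS, 32)
            write_trace(tmp_path / f"t_{tag}", trace, binary=False)
        assert (tmp_path / "t_a.csv").read_bytes() == (tmp_path / "t_b.csv").read_bytes()
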
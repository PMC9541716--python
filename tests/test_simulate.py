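"""Synthetic-data generator: noise calibration, clock model, round trips."""

import warnings

import numpy as np
import pytest

from pacemap import (
    SimulationConfig,
    StretchProtocolSpec,
    cluster_beats,
    detect_recording,
    generate_fractal_noise,
    simulate_beats,
    simulate_recording,
    synthesize_electrograms,
)
from pacemap.dfa import dfa


@pytest.mark.parametrize("alpha", [0.5, 0.76, 1.0, 1.5])
def test_fractal_noise_dfa_recovery(alpha):
    """Spectral synthesis hits the target scaling exponent (50 seeds)."""
    est = [dfa(generate_fractal_noise(512, alpha, 1.0, seed)).alpha for seed in range(50)]
    assert abs(np.mean(est) - alpha) < 0.1


def test_fractal_noise_zero_mean_and_sd():
    x = generate_fractal_noise(1024, 1.0, 0.3, seed=5)
    assert abs(x.mean()) < 1e-12
    assert abs(x.std() - 0.3) < 1e-12


def test_fractal_noise_rejects_bad_alpha():
    with pytest.raises(ValueError):
        generate_fractal_noise(64, 2.0, 1.0, seed=0)
    with pytest.raises(ValueError):
        generate_fractal_noise(8, 1.0, 1.0, seed=0)


def test_deterministic_clock_gives_constant_ibi():
    """With zero noise every interbeat interval equals the base period."""
    cfg = SimulationConfig(n_foci=1, noise_sd=0.0, jitter_sd=0.0, duration=20.0)
    gt = simulate_beats(cfg)
    np.testing.assert_allclose(gt.ibi, cfg.base_period, rtol=1e-9)


def test_faster_focus_always_wins():
    """Two fixed-period clocks with winner-resets-all: the faster one
    fires every beat and the propagation pattern is constant."""
    cfg = SimulationConfig(
        n_foci=2,
        focus_positions=np.array([[0.0, 0.4], [0.0, -0.4]]),
        focus_period_scale=[0.9, 1.0],
        base_period=1.0,
        noise_sd=0.0,
        jitter_sd=0.0,
        duration=30.0,
    )
    gt = simulate_beats(cfg)
    assert np.all(gt.firing_focus == 0)
    np.testing.assert_allclose(gt.ibi, 0.9, rtol=1e-9)
    spread = np.ptp(gt.true_activation_times, axis=1)
    np.testing.assert_allclose(spread, spread[0], atol=1e-12)


def test_takeover_switches_focus_and_pattern(two_focus_truth):
    """With fractal noise on two foci the firing site switches, and the
    activation pattern changes at switch beats."""
    gt = two_focus_truth
    switches = np.flatnonzero(np.diff(gt.firing_focus) != 0)
    assert switches.size > 10
    # activation-time pattern (offset by mean) changes at a switch
    t = gt.true_activation_times - gt.beat_times[:, None]
    jump = np.linalg.norm(np.diff(t, axis=0), axis=1)
    assert jump[switches].mean() > 5 * np.median(jump)


@pytest.mark.parametrize("n_foci", [1, 2])
def test_mean_rate_recovery(n_foci):
    """mean(1/IBI) matches 1/base_period within 2% at small noise."""
    cfg = SimulationConfig(n_foci=n_foci, noise_sd=0.05, duration=400.0, seed=1)
    gt = simulate_beats(cfg)
    assert abs(np.mean(1.0 / gt.ibi) * cfg.base_period - 1.0) < 0.02


def test_many_foci_bias_is_fast_and_small():
    """Winner-resets-all entrainment follows the fastest clock, so the
    network rate exceeds the intrinsic rate, but only slightly."""
    gt = simulate_beats(SimulationConfig(n_foci=3, noise_sd=0.05, duration=400.0, seed=1))
    bias = np.mean(1.0 / gt.ibi) * 0.8 - 1.0
    assert 0.0 < bias < 0.05


def test_beat_times_increasing_and_spread_bounded(two_focus_truth):
    gt = two_focus_truth
    assert np.all(np.diff(gt.beat_times) > 0)
    max_dist = 0.8 * np.sqrt(2)  # cm, across the layout
    bound = max_dist / 30.0 + 6 * 0.0005  # propagation + jitter allowance
    assert np.ptp(gt.true_activation_times, axis=1).max() < bound


def test_focus_positions_on_disc_boundary():
    cfg = SimulationConfig(n_foci=5)
    radii = np.hypot(*cfg.focus_positions.T)
    np.testing.assert_allclose(radii, 0.4, atol=0.05)
    with pytest.raises(ValueError, match="disc boundary"):
        SimulationConfig(focus_positions=np.array([[0.1, 0.1]] * 3))


def test_duration_too_short_raises():
    with pytest.raises(ValueError, match="too short"):
        simulate_beats(SimulationConfig(duration=0.01, noise_sd=0.0))


def test_noiseless_round_trip_recovers_activation_times():
    """With no noise floor and no jitter, the detection pipeline recovers
    every true activation time to within one sample."""
    cfg = SimulationConfig(noise_sd=0.05, jitter_sd=0.0, noise_floor_sd=0.0,
                           duration=20.0, seed=3)
    rec, gt = simulate_recording(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = cluster_beats(detect_recording(rec))
    assert len(series) == len(gt.beat_times)
    det = np.array(
        [[b.activation_times[e] for e in rec.layout.electrode] for b in series.beats]
    )
    err = np.abs(det - gt.true_activation_times)
    assert err.max() <= 1.0 / cfg.sampling_rate


def test_empty_truth_gives_flat_recording():
    cfg = SimulationConfig(duration=2.0, noise_floor_sd=0.0, noise_sd=0.0)
    gt = simulate_beats(cfg)
    gt.beat_times = np.array([])
    gt.true_activation_times = np.empty((0, cfg.n_electrodes))
    gt.firing_focus = np.array([], dtype=int)
    rec = synthesize_electrograms(gt, cfg)
    assert np.all(rec.signals == 0)
    assert detect_recording(rec) == []


def test_fractionated_synthesis_fuses_downstream():
    """Two template copies 0.8 ms apart on one channel fuse to a single
    weighted activation under the 1-ms rule."""
    from pacemap.electrogram import condition_signal, detect_activations, fuse_fractionated
    from pacemap.simulate import _biphasic_template

    cfg = SimulationConfig()
    template, t_off, _ = _biphasic_template(cfg)
    fs = cfg.sampling_rate
    ts = np.arange(int(fs)) / fs
    t0 = 0.5
    x = template(ts - (t0 - t_off)) + 0.6 * template(ts - (t0 + 0.0008 - t_off))
    y = condition_signal(x, fs)
    events = detect_activations(y, fs)
    big = [e for e in events if e.derivative_magnitude > 0.3 * max(
        ev.derivative_magnitude for ev in events)]
    fused = fuse_fractionated(big, 0.001)
    assert len(fused) == 1
    assert t0 - 0.0002 < fused[0].time < t0 + 0.001


def test_stretch_protocol_events_and_channel():
    spec = StretchProtocolSpec(n_repeats=2, hold_duration=10.0, release_duration=10.0,
                               start_offset=5.0, motor_time=2.0)
    ev = spec.events()
    assert [e[0] for e in ev] == ["stretch", "release"] * 2
    assert ev[0][1] == 5.0 and ev[1][1] == 15.0
    cfg = SimulationConfig(duration=50.0, stretch_protocol=spec, seed=4)
    rec, gt = simulate_recording(cfg)
    fs = cfg.sampling_rate
    for _, start, end in gt.event_times:
        assert rec.event_channel[int(start * fs) + 1] == 1.0
        assert rec.event_channel[int(end * fs) + 1] == 0.0


def test_quantization_optional():
    cfg = SimulationConfig(duration=5.0, quantize_12bit=True, seed=6)
    rec, _ = simulate_recording(cfg)
    vals = np.unique(rec.signals)
    assert vals.size <= 4097
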
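"""Ground-truthed synthetic recordings of spontaneous cardiomyocyte activity.

The generator emulates the statistical structure of extracellular
recordings from disc-shaped cardiomyocyte monolayers (8 mm diameter) on a
12-electrode stretchable array:

* competing peripheral pacemaker foci, modelled as phase clocks coupled by
  a winner-resets-all rule (a caricature of mutual entrainment: the focus
  that reaches threshold first fires the beat and resets all others);
* fractal beat-to-beat variability, injected as 1/f-family noise on each
  focus's log-period with a tunable DFA exponent;
* radial propagation at a fixed conduction velocity from the firing focus
  to each electrode, plus Gaussian activation-time jitter;
* biphasic extracellular waveforms with a sub-millisecond downstroke;
* optional stretch/release protocols that transiently accelerate all foci,
  with an exponential decay back to baseline, and a motor-pulse event
  channel carrying the protocol time stamps.

Every simulation returns a :class:`GroundTruth` (true beat times, firing
focus, per-electrode activation times, protocol events) so that the whole
analysis pipeline can be validated in closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dfa import dfa
from .recording import Recording, default_layout

__all__ = [
    "SimulationConfig",
    "StretchProtocolSpec",
    "GroundTruth",
    "generate_fractal_noise",
    "simulate_beats",
    "synthesize_electrograms",
    "simulate_recording",
]

DISC_RADIUS_CM = 0.4  # cultures are 8 mm discs


@dataclass
class StretchProtocolSpec:
    """Timing and effect sizes of a repeated stretch/release protocol.

    Defaults follow the experimental protocol: strain applied and held for
    1 min, released for 2 min, repeated 4-5 times, with the motor stages
    taking ~2 s (uniaxial) or 1.5 s (biaxial) to complete a movement.  The
    transient rate acceleration after each movement decays with time
    constant ``decay_tau`` so that it dissipates within ~8 s.
    """

    hold_duration: float = 60.0        # s at target strain
    release_duration: float = 120.0    # s back at rest
    n_repeats: int = 5
    motor_time: float = 2.0            # s of stage movement (1.5 for biaxial)
    start_offset: float = 30.0         # s of undisturbed baseline before repeat 1
    rate_gain_stretch: float = 2.0     # fold acceleration at end of stretch movement
    rate_gain_release: float = 1.4     # fold acceleration at end of release movement
    decay_tau: float = 2.0             # s; e-folding of the post-movement transient

    def __post_init__(self):
        if self.hold_duration + self.release_duration <= 0:
            raise ValueError("hold_duration + release_duration must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def events(self):
        """(kind, motor_start, motor_end) triples, time-ordered."""
        out = []
        period = self.hold_duration + self.release_duration
        for k in range(self.n_repeats):
            t0 = self.start_offset + k * period
            out.append(("stretch", t0, t0 + self.motor_time))
            t1 = t0 + self.hold_duration
            out.append(("release", t1, t1 + self.motor_time))
        return out


def _default_waveform() -> dict:
    return {
        "positive_width_ms": 1.0,
        "downstroke_ms": 0.4,
        "negative_width_ms": 1.8,
        "amplitude": 1.0,
    }


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    The defaults describe a typical preparation: 12 electrodes on a 2-mm
    pitch inside the 8-mm culture disc, three peripheral foci beating near
    0.8 s, 1/f log-period noise, conduction at 30 cm/s, 10 kHz sampling.
    """

    n_electrodes: int = 12
    layout: np.ndarray | None = None          # (n, 2) positions in cm
    n_foci: int = 3
    focus_positions: np.ndarray | None = None  # points on the disc periphery
    base_period: float = 0.8                   # s
    focus_period_scale: np.ndarray | None = None  # per-focus intrinsic-rate dispersion
    noise_alpha: float = 1.0                   # target DFA exponent of log-period noise
    noise_sd: float = 0.1                      # SD of log-period fluctuations
    conduction_velocity: float = 30.0          # cm/s
    sampling_rate: float = 10_000.0            # Hz
    waveform: dict = field(default_factory=_default_waveform)
    jitter_sd: float = 0.0005                  # s, per-electrode activation jitter
    noise_floor_sd: float = 0.02               # signal units of white noise
    baseline_drift: tuple = (0.0, 10.0)        # (amplitude, period s)
    duration: float = 120.0                    # s
    takeover_enabled: bool = True              # False = single active focus
    common_mode_fraction: float = 0.0          # shared part of the focus noise
    quantize_12bit: bool = False
    stretch_protocol: StretchProtocolSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.base_period <= 0 or self.sampling_rate <= 0:
            raise ValueError("base_period and sampling_rate must be positive")
        if self.n_foci < 1:
            raise ValueError("n_foci must be >= 1")
        if self.waveform["downstroke_ms"] >= 1.0:
            raise ValueError("downstroke width must be < 1 ms")
        if self.layout is None:
            self.layout = default_layout().loc[:, ["x_cm", "y_cm"]].to_numpy()
        self.layout = np.asarray(self.layout, dtype=float)
        if self.layout.shape != (self.n_electrodes, 2):
            raise ValueError("layout must be (n_electrodes, 2)")
        if self.focus_positions is None:
            angles = 2 * np.pi * np.arange(self.n_foci) / self.n_foci + np.pi / 2
            self.focus_positions = DISC_RADIUS_CM * np.column_stack(
                [np.cos(angles), np.sin(angles)]
            )
        if self.focus_period_scale is None:
            self.focus_period_scale = np.ones(self.n_foci)
        self.focus_period_scale = np.asarray(self.focus_period_scale, dtype=float)
        if self.focus_period_scale.shape != (self.n_foci,) or np.any(
            self.focus_period_scale <= 0
        ):
            raise ValueError("focus_period_scale must be n_foci positive values")
        self.focus_positions = np.asarray(self.focus_positions, dtype=float)
        radii = np.hypot(*self.focus_positions.T)
        if not np.allclose(radii, DISC_RADIUS_CM, atol=0.05):
            raise ValueError("focus positions must lie on the disc boundary (r = 0.4 cm)")


@dataclass
class GroundTruth:
    """Simulator-side truth used to validate the analysis pipeline."""

    beat_times: np.ndarray            # mean activation time m_i per beat (s)
    firing_focus: np.ndarray          # focus index per beat
    true_activation_times: np.ndarray  # (n_beats, n_electrodes) s
    event_times: list                 # (kind, motor_start, motor_end)
    noise_series: np.ndarray          # (n_foci, n_cycles) log-period noise
    focus_positions: np.ndarray

    @property
    def ibi(self) -> np.ndarray:
        return np.diff(self.beat_times)


def generate_fractal_noise(length: int, alpha_target: float, sd: float, seed) -> np.ndarray:
    """Zero-mean noise whose DFA exponent equals ``alpha_target``.

    Spectral synthesis: Fourier coefficients are complex Gaussians scaled
    so the power spectral density goes as 1/f^beta with beta =
    2*alpha_target - 1 (beta = 0 white noise, 1 pink, 2 Brownian), then
    inverse-transformed and standardised to the requested SD.
    """
    if length < 16:
        raise ValueError("length must be >= 16")
    if not 0.3 <= alpha_target <= 1.6:
        raise ValueError("alpha_target must lie in [0.3, 1.6]")
    rng = np.random.default_rng(seed)
    beta = 2.0 * alpha_target - 1.0
    freqs = np.fft.rfftfreq(length)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    coeff = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(coeff, n=length)
    x -= x.mean()
    s = x.std()
    if s > 0 and sd > 0:
        x *= sd / s
    elif sd == 0:
        x[:] = 0.0
    return x


def _rate_gain(t: float, events, spec: StretchProtocolSpec) -> float:
    """Multiplicative acceleration g(t) >= 1 from the stretch protocol.

    During a motor movement the gain ramps linearly from 1 to the target;
    afterwards the excess decays exponentially with ``decay_tau``.
    Contributions of successive movements take the maximum (they are well
    separated in the default protocol).
    """
    g = 1.0
    for kind, start, end in events:
        if t < start:
            continue
        gain = spec.rate_gain_stretch if kind == "stretch" else spec.rate_gain_release
        if t < end:
            frac = (t - start) / (end - start)
            g = max(g, 1.0 + (gain - 1.0) * frac)
        else:
            g = max(g, 1.0 + (gain - 1.0) * np.exp(-(t - end) / spec.decay_tau))
    return g


def simulate_beats(config: SimulationConfig) -> GroundTruth:
    """Run the coupled-foci clock model and propagate beats to electrodes.

    Each focus k keeps a phase clock with instantaneous period
    ``T_k = base_period * exp(noise_k) / g(t)``; at every cycle the focus
    reaching threshold first fires the beat and resets all clocks
    (winner-resets-all entrainment).  Per-beat per-electrode activation
    time = fire time + distance(focus, electrode)/conduction_velocity +
    Gaussian jitter.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_active = cfg.n_foci if cfg.takeover_enabled else 1
    n_cycles = int(np.ceil(cfg.duration / cfg.base_period * 4)) + 64
    n_cycles = max(n_cycles, 16)

    noise = np.empty((cfg.n_foci, n_cycles))
    common = generate_fractal_noise(
        n_cycles, cfg.noise_alpha, cfg.noise_sd, rng.integers(2**31)
    )
    for k in range(cfg.n_foci):
        own = generate_fractal_noise(
            n_cycles, cfg.noise_alpha, cfg.noise_sd, rng.integers(2**31)
        )
        c = cfg.common_mode_fraction
        noise[k] = c * common + np.sqrt(max(0.0, 1 - c**2)) * own

    events = cfg.stretch_protocol.events() if cfg.stretch_protocol else []

    dists = np.linalg.norm(
        cfg.layout[None, :, :] - cfg.focus_positions[:, None, :], axis=2
    )  # (n_foci, n_electrodes)

    beat_times, firing, act_rows = [], [], []
    t = 0.0
    for cycle in range(n_cycles):
        periods = (
            cfg.base_period
            * cfg.focus_period_scale[:n_active]
            * np.exp(noise[:n_active, cycle])
        )
        if events:
            # gain varies within a cycle; evaluate it at the interval
            # midpoint by fixed-point iteration so the clock tracks g(t)
            # without a one-beat lag
            for k_f in range(periods.size):
                p = periods[k_f]
                for _ in range(3):
                    p = periods[k_f] / _rate_gain(t + p / 2, events, cfg.stretch_protocol)
                periods[k_f] = p
        k = int(np.argmin(periods))
        t = t + periods[k]
        if t > cfg.duration:
            break
        act = t + dists[k] / cfg.conduction_velocity
        if cfg.jitter_sd > 0:
            act = act + rng.normal(0.0, cfg.jitter_sd, size=act.shape)
        beat_times.append(act.mean())
        firing.append(k)
        act_rows.append(act)

    if not beat_times:
        raise ValueError("duration too short to contain one beat")
    return GroundTruth(
        beat_times=np.array(beat_times),
        firing_focus=np.array(firing, dtype=int),
        true_activation_times=np.array(act_rows),
        event_times=events,
        noise_series=noise,
        focus_positions=cfg.focus_positions.copy(),
    )


def _biphasic_template(cfg: SimulationConfig):
    """Continuous biphasic waveform w(t) and the offset of its steepest
    downstroke, both in seconds.

    Two opposed Gaussian lobes separated by the downstroke width give an
    initial positive phase, a rapid (<1 ms) downstroke and a negative
    phase.  The offset is located on a fine grid so callers can centre the
    steepest point exactly on an activation time.
    """
    w = cfg.waveform
    sp = w["positive_width_ms"] / 1000.0 / 2.355  # FWHM -> sigma
    sn = w["negative_width_ms"] / 1000.0 / 2.355
    d = w["downstroke_ms"] / 1000.0 / 2.0
    amp = w["amplitude"]

    def template(t):
        return amp * (
            np.exp(-((t + d) ** 2) / (2 * sp**2)) - np.exp(-((t - d) ** 2) / (2 * sn**2))
        )

    fine = np.arange(-0.01, 0.01, 1e-6)
    deriv = np.gradient(template(fine), fine)
    offset = fine[np.argmin(deriv)]
    half_width = 4 * max(sp, sn) + d
    return template, offset, half_width


def synthesize_electrograms(truth: GroundTruth, config: SimulationConfig) -> Recording:
    """Render a multichannel sampled recording from simulated beats.

    The biphasic template is placed so that its steepest downstroke falls
    at each true activation time; white noise and a slow sinusoidal
    baseline drift are added, and motor movements appear as rectangular
    pulses on the event channel.
    """
    cfg = config
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    fs = cfg.sampling_rate
    n_samples = int(round(cfg.duration * fs))
    n_ch = cfg.n_electrodes
    signals = np.zeros((n_ch, n_samples))

    template, t_offset, half_width = _biphasic_template(cfg)
    hw = int(np.ceil(half_width * fs))

    for act_row in truth.true_activation_times:
        for ch in range(n_ch):
            centre = act_row[ch] - t_offset  # steepest downstroke at act time
            i0 = int(np.floor((centre - half_width) * fs))
            i1 = int(np.ceil((centre + half_width) * fs)) + 1
            i0c, i1c = max(i0, 0), min(i1, n_samples)
            if i0c >= i1c:
                continue
            ts = np.arange(i0c, i1c) / fs
            signals[ch, i0c:i1c] += template(ts - centre)

    if cfg.noise_floor_sd > 0:
        signals += rng.normal(0.0, cfg.noise_floor_sd, size=signals.shape)
    drift_amp, drift_period = cfg.baseline_drift
    if drift_amp > 0:
        tt = np.arange(n_samples) / fs
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        signals += drift_amp * np.sin(
            2 * np.pi * tt[None, :] / drift_period + phases[:, None]
        )
    if cfg.quantize_12bit:
        full_scale = max(np.abs(signals).max(), 1e-12)
        lsb = 2 * full_scale / 4096
        signals = np.round(signals / lsb) * lsb

    event_channel = np.zeros(n_samples)
    for _, start, end in truth.event_times:
        a, b = int(round(start * fs)), int(round(end * fs))
        event_channel[max(a, 0): min(b, n_samples)] = 1.0

    layout = default_layout()
    layout.loc[:, ["x_cm", "y_cm"]] = cfg.layout
    return Recording(
        signals=signals,
        sampling_rate=fs,
        event_channel=event_channel,
        layout=layout,
        meta={"source": "pacemap.simulate", "seed": cfg.seed},
    )


def simulate_recording(config: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Convenience wrapper: beats then electrograms."""
    truth = simulate_beats(config)
    return synthesize_electrograms(truth, config), truth
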
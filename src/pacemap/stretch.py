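"""Stretch/release epoch analysis and strain-geometry arithmetic.

During deformation protocols the motor stages emit an electric pulse on a
dedicated acquisition channel while they move; pulse edges give precise
motor start/stop time stamps.  Each intervention's instantaneous beat
rate (IBR) is aligned on motor start, normalised to the mean rate over
the last 5 s before the movement, and averaged across the 4-5 repeats of
the protocol.  The peak response is read from the IBR bin ending at the
first bin edge at or after motor end (for a ~2-s movement and 0.5-s bins
that is the bin [1.5, 2.0) s, conventionally plotted at 1.75 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import TestResult, one_sample_or_wilcoxon

__all__ = [
    "MotorEvent",
    "ProtocolEvents",
    "EpochAverage",
    "parse_motor_events",
    "epoch_average",
    "areal_strain",
    "summarize_across_preparations",
]


@dataclass
class MotorEvent:
    kind: str           # "stretch" | "release"
    motor_start: float  # s
    motor_end: float    # s

    def __post_init__(self):
        if self.motor_end <= self.motor_start:
            raise ValueError("motor_end must exceed motor_start")


@dataclass
class ProtocolEvents:
    interventions: list

    def of_kind(self, kind: str) -> list:
        return [e for e in self.interventions if e.kind == kind]

    def __len__(self) -> int:
        return len(self.interventions)


@dataclass
class EpochAverage:
    """Per-repeat and mean normalised IBR around one kind of intervention."""

    kind: str
    time_axis: np.ndarray            # bin start times relative to motor start
    rows: np.ndarray                 # (n_repeats, n_bins) normalised IBR, NaN = missing
    baseline_per_repeat: np.ndarray  # Hz
    peak_normalized_per_repeat: np.ndarray
    excluded_repeats: list

    @property
    def mean_trace(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.rows, axis=0)

    @property
    def mean_peak(self) -> float:
        return float(np.nanmean(self.peak_normalized_per_repeat))


def parse_motor_events(event_channel, rate: float, first_kind: str = "stretch") -> ProtocolEvents:
    """Extract motor movements from the pulse channel.

    Edges are thresholded at half the pulse amplitude; consecutive
    high-phases are labelled stretch/release alternately, starting with
    ``first_kind`` (the protocol always begins with a stretch).
    """
    x = np.asarray(event_channel, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return ProtocolEvents(interventions=[])
    thresh = x.min() + 0.5 * np.ptp(x)
    high = x > thresh
    edges = np.diff(high.astype(int))
    rises = np.flatnonzero(edges == 1) + 1
    falls = np.flatnonzero(edges == -1) + 1
    if high[0]:
        rises = np.concatenate([[0], rises])
    if high[-1]:
        falls = np.concatenate([falls, [x.size]])
    if rises.size != falls.size:
        raise ValueError("unpaired pulse edges in the event channel")
    kinds = ["stretch", "release"]
    offset = kinds.index(first_kind)
    interventions = [
        MotorEvent(kinds[(i + offset) % 2], r / rate, f / rate)
        for i, (r, f) in enumerate(zip(rises, falls))
    ]
    return ProtocolEvents(interventions=interventions)


def epoch_average(
    ibr,
    events: ProtocolEvents,
    kind: str = "stretch",
    pre_s: float = 10.0,
    post_s: float = 30.0,
    baseline_window: float = 5.0,
) -> EpochAverage:
    """Align, normalise and average the IBR over repeated interventions.

    For each intervention of ``kind``, rate bins of width ``ibr.dt`` are
    re-integrated on a grid anchored at motor start (the IBR carries its
    underlying beat times, so the integral-preserving resampling is exact
    on the new grid).  Bins outside the span of observed beats are
    missing (NaN).  The baseline is the mean over [-5, 0) s before motor
    start; repeats with no usable baseline are excluded with a warning
    entry.  The peak is the normalised value of the bin ending at the
    first bin edge >= motor end.
    """
    from .beats import resample_ibr

    selected = events.of_kind(kind)
    if not selected:
        raise ValueError(f"no interventions of kind {kind!r}")
    if ibr.mean_times is None:
        raise ValueError("IBR series must carry its underlying beat times")
    dt = ibr.dt
    m = ibr.mean_times
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    time_axis = dt * np.arange(-n_pre, n_post)
    n_base = int(round(baseline_window / dt))

    rows, baselines, peaks, excluded = [], [], [], []
    for rep, ev in enumerate(selected):
        grid0 = ev.motor_start - n_pre * dt
        full = resample_ibr(m, dt=dt, anchor=grid0)
        rates = np.full(n_pre + n_post, np.nan)
        n_avail = min(full.rates.size, rates.size)
        rates[:n_avail] = full.rates[:n_avail]
        rates[:n_avail][full.partial[:n_avail]] = np.nan  # bins not fully covered

        base_bins = rates[n_pre - n_base: n_pre]
        if np.all(np.isnan(base_bins)) or np.nansum(base_bins) == 0:
            excluded.append(rep)
            continue
        baseline = float(np.nanmean(base_bins))
        norm = rates / baseline
        peak_idx = n_pre + int(np.ceil((ev.motor_end - ev.motor_start) / dt - 1e-9)) - 1
        peak = norm[peak_idx] if 0 <= peak_idx < norm.size else np.nan
        rows.append(norm)
        baselines.append(baseline)
        peaks.append(peak)

    if not rows:
        raise ValueError("no repeat had a usable baseline")
    return EpochAverage(
        kind=kind,
        time_axis=time_axis,
        rows=np.array(rows),
        baseline_per_repeat=np.array(baselines),
        peak_normalized_per_repeat=np.array(peaks),
        excluded_repeats=excluded,
    )


def areal_strain(e_xx: float, e_yy: float) -> float:
    """Percent in-plane area change for the given engineering strains.

    5% uniaxial strain with the lateral constriction compensated
    (e_yy = 0) increases the area by 5%; 2% equibiaxial strain increases
    it by (1.02^2 - 1) = 4.04%.
    """
    if e_xx <= -1 or e_yy <= -1:
        raise ValueError("strains must exceed -1")
    return 100.0 * ((1.0 + e_xx) * (1.0 + e_yy) - 1.0)


def summarize_across_preparations(peaks, null_value: float = 1.0) -> dict:
    """Median, IQR and a two-tailed test of the per-preparation mean
    fold-changes against ``null_value`` (Shapiro-Wilk gate selects
    one-sample t versus Wilcoxon signed rank)."""
    x = np.asarray(peaks, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 preparations")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    if np.ptp(x) == 0:
        test = TestResult(test="degenerate", n=int(x.size), statistic=np.nan, p=np.nan,
                          rationale="all values identical")
    else:
        test = one_sample_or_wilcoxon(x, null_value)
    return {
        "n": int(x.size),
        "median": float(med),
        "iqr": (float(q1), float(q3)),
        "test": test.to_dict(),
    }
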
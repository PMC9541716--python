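"""Full per-recording analysis: detect -> beats -> spatial -> temporal ->
stretch -> stats, driven by a config, emitting a JSON/CSV report."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .beats import cluster_beats, resample_ibr
from .dfa import dfa
from .electrogram import FilterConfig, detect_recording
from .recording import Recording, read_layout_csv
from .spatial import (
    fit_beat_slowness,
    interbeat_slowness_diff,
    pca_activation,
    slowness_entropy,
)
from .stats import spearman_quantile_correlation
from .stretch import epoch_average, parse_motor_events

__all__ = ["AnalysisConfig", "RecordingReport", "run_pipeline", "analyze_recording"]


@dataclass
class AnalysisConfig:
    """Parameters of a full pipeline run."""

    recording_path: str | None = None
    layout_path: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    cluster_gap: float = 0.05          # s
    min_electrodes: int = 4
    ibr_dt: float = 0.5                # s
    entropy_bin: float = 0.005         # s/cm
    dfa_grid: list = field(default_factory=lambda: [4, 8, 16, 32, 64, 128])
    epoch_pre: float = 10.0            # s
    epoch_post: float = 30.0           # s
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        filt = FilterConfig(**raw.pop("filters", {}))
        cfg = cls(filters=filt, **raw)
        if cfg.recording_path and not Path(cfg.recording_path).exists():
            raise FileNotFoundError(f"recording not found: {cfg.recording_path}")
        if cfg.layout_path and not Path(cfg.layout_path).exists():
            raise FileNotFoundError(f"layout not found: {cfg.layout_path}")
        return cfg


@dataclass
class RecordingReport:
    """Aggregated per-recording results with full parameter provenance."""

    n_beats: int
    mean_ibi: float
    ibi: list
    slowness_table: list              # per-beat [s_x, s_y, norm, rms] or None
    entropy: float | None
    entropy_occupied_bins: int | None
    dfa_alpha: float | None
    dfa_n: list
    dfa_df: list
    pca_variance_fractions: list
    pca_cumulative_two: float | None
    spearman_rho: float | None
    spearman_n: int | None
    epochs: dict
    parameters: dict
    warnings: list
    version: str = __version__

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=_jsonify, **kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(indent=2))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")


def analyze_recording(recording: Recording, config: AnalysisConfig | None = None) -> RecordingReport:
    """Run the full analysis on an in-memory recording."""
    cfg = config or AnalysisConfig()
    if recording.layout is None:
        raise ValueError("recording has no electrode layout")
    captured = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        events = detect_recording(recording, cfg.filters)
        series = cluster_beats(events, gap=cfg.cluster_gap, min_electrodes=cfg.min_electrodes)

        report_kwargs: dict = {
            "n_beats": len(series),
            "mean_ibi": float(series.ibi.mean()) if len(series) > 1 else float("nan"),
            "ibi": series.ibi.tolist() if len(series) > 1 else [],
        }

        vectors = fit_beat_slowness(series, recording.layout) if len(series) else []
        report_kwargs["slowness_table"] = [
            None if v is None else [v.s_x, v.s_y, v.norm, v.residual_rms] for v in vectors
        ]
        eligible = [v for v in vectors if v is not None]
        if eligible:
            ent = slowness_entropy(eligible, bin_size=cfg.entropy_bin)
            report_kwargs["entropy"] = ent.entropy
            report_kwargs["entropy_occupied_bins"] = ent.occupied_bins
        else:
            report_kwargs["entropy"] = None
            report_kwargs["entropy_occupied_bins"] = None

        try:
            pca = pca_activation(series, recording.layout)
            report_kwargs["pca_variance_fractions"] = pca.variance_fractions.tolist()
            report_kwargs["pca_cumulative_two"] = pca.cumulative_two
        except ValueError as exc:
            captured.append(f"pca: {exc}")
            report_kwargs["pca_variance_fractions"] = []
            report_kwargs["pca_cumulative_two"] = None

        try:
            res = dfa(series.ibi, n_grid=cfg.dfa_grid)
            report_kwargs["dfa_alpha"] = res.alpha
            report_kwargs["dfa_n"] = res.n_values.tolist()
            report_kwargs["dfa_df"] = res.df_values.tolist()
        except ValueError as exc:
            captured.append(f"dfa: {exc}")
            report_kwargs["dfa_alpha"] = None
            report_kwargs["dfa_n"] = []
            report_kwargs["dfa_df"] = []

        idx, diffs = interbeat_slowness_diff(vectors)
        if diffs.size >= 10 and np.ptp(diffs) > 0:
            corr = spearman_quantile_correlation(series.ibi[idx], diffs)
            report_kwargs["spearman_rho"] = corr.rho
            report_kwargs["spearman_n"] = corr.n
        else:
            captured.append("spearman: fewer than 10 usable beat pairs")
            report_kwargs["spearman_rho"] = None
            report_kwargs["spearman_n"] = None

        report_kwargs["epochs"] = {}
        if recording.event_channel is not None and len(series) > 1:
            protocol = parse_motor_events(recording.event_channel, recording.sampling_rate)
            if len(protocol):
                ibr = resample_ibr(series.mean_times, dt=cfg.ibr_dt)
                for kind in ("stretch", "release"):
                    if not protocol.of_kind(kind):
                        continue
                    try:
                        ep = epoch_average(ibr, protocol, kind,
                                           pre_s=cfg.epoch_pre, post_s=cfg.epoch_post)
                        report_kwargs["epochs"][kind] = {
                            "time_axis": ep.time_axis.tolist(),
                            "mean_trace": ep.mean_trace.tolist(),
                            "peak_per_repeat": ep.peak_normalized_per_repeat.tolist(),
                            "mean_peak": ep.mean_peak,
                            "excluded_repeats": ep.excluded_repeats,
                        }
                    except ValueError as exc:
                        captured.append(f"epoch {kind}: {exc}")

        captured.extend(str(w.message) for w in wlist)

    params = asdict(cfg)
    params["filters"] = asdict(cfg.filters)
    return RecordingReport(parameters=params, warnings=captured, **report_kwargs)


def run_pipeline(config: AnalysisConfig) -> RecordingReport:
    """Load the recording named in the config, analyse it, and write the
    report (JSON) plus beats/IBR tables (CSV) to the output directory."""
    if not config.recording_path:
        raise ValueError("config must name a recording")
    if not Path(config.recording_path).exists():
        raise FileNotFoundError(f"recording not found: {config.recording_path}")
    layout = read_layout_csv(config.layout_path) if config.layout_path else None
    rec = Recording.load(config.recording_path, layout_path=config.layout_path)
    if layout is not None:
        rec.layout = layout
    report = analyze_recording(rec, config)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out / "report.json")
    return report
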
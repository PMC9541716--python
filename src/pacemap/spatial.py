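"""Spatial characterisation of activation patterns.

With only 12 electrodes the pacemaker focus cannot be localised, so each
beat's pattern is summarised by its *slowness* vector: the spatial
gradient of activation time, obtained by least-squares fitting the plane

    t_j = t_0 + s_x * x_j + s_y * y_j

to the per-electrode activation times.  Slowness points in the direction
of propagation and has magnitude 1/|v|; conduction velocity follows as
v = s / |s|^2, which is only computed when |s| > 0 (a symmetric or
simultaneous pattern has zero slowness, and velocity would diverge).

Pattern variability over a recording is quantified two ways: Shannon
entropy of the 2-D histogram of slowness-vector tips (0.005 s/cm square
bins), and PCA of the mean-offset activation times t'_{ij} = t_{ij} - m_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SlownessVector",
    "EntropyResult",
    "PcaResult",
    "fit_slowness",
    "slowness_to_velocity",
    "fit_beat_slowness",
    "pca_activation",
    "slowness_entropy",
    "interbeat_slowness_diff",
]


@dataclass
class SlownessVector:
    s_x: float                  # s/cm
    s_y: float                  # s/cm
    intercept: float            # t_0, s
    residual_rms: float         # s
    n_points: int

    @property
    def norm(self) -> float:
        return float(np.hypot(self.s_x, self.s_y))

    @property
    def vec(self) -> np.ndarray:
        return np.array([self.s_x, self.s_y])


@dataclass
class EntropyResult:
    bin_size: float             # s/cm
    occupied_bins: int
    entropy: float              # nats


@dataclass
class PcaResult:
    component_loadings: np.ndarray   # (n_components, n_electrodes)
    variance_fractions: np.ndarray   # non-increasing, sums to 1

    @property
    def cumulative_two(self) -> float:
        return float(self.variance_fractions[:2].sum())


def fit_slowness(times, positions) -> SlownessVector:
    """Ordinary least squares of activation time on (1, x, y).

    Parameters
    ----------
    times : (n,) activation times in s
    positions : (n, 2) electrode coordinates in cm

    Raises
    ------
    ValueError
        With fewer than 4 points, or a collinear electrode subset (the
        plane is then not identifiable).
    """
    t = np.asarray(times, dtype=float)
    xy = np.asarray(positions, dtype=float)
    if t.size < 4:
        raise ValueError("slowness fit needs at least 4 electrodes")
    design = np.column_stack([np.ones(t.size), xy])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("electrode positions are collinear; plane not identifiable")
    coef, _, _, _ = np.linalg.lstsq(design, t, rcond=None)
    resid = t - design @ coef
    return SlownessVector(
        s_x=float(coef[1]),
        s_y=float(coef[2]),
        intercept=float(coef[0]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(t.size),
    )


def slowness_to_velocity(s: SlownessVector | np.ndarray) -> np.ndarray:
    """Velocity vector v = s/|s|^2 in cm/s (same direction, reciprocal
    magnitude).  Raises on zero slowness instead of returning infinity."""
    vec = s.vec if isinstance(s, SlownessVector) else np.asarray(s, dtype=float)
    norm2 = float(vec @ vec)
    if norm2 == 0:
        raise ValueError("velocity undefined for zero slowness (symmetric pattern)")
    return vec / norm2


def fit_beat_slowness(beat_series, layout) -> list:
    """Per-beat slowness fits; ineligible beats yield None.

    ``layout`` is a DataFrame with electrode/x_cm/y_cm columns.
    """
    pos = {
        row.electrode: (row.x_cm, row.y_cm) for row in layout.itertuples(index=False)
    }
    out = []
    for beat in beat_series.beats:
        if not beat.eligible:
            out.append(None)
            continue
        ids = [e for e in beat.activation_times if e in pos]
        if len(ids) < 4:
            out.append(None)
            continue
        t = [beat.activation_times[e] for e in ids]
        xy = [pos[e] for e in ids]
        try:
            out.append(fit_slowness(t, xy))
        except ValueError:
            out.append(None)
    return out


def pca_activation(beat_series, layout) -> PcaResult:
    """PCA of mean-offset activation times over complete beats.

    Beats missing any electrode are excluded (the PCA needs a complete
    beats x electrodes matrix).  Columns are centred; components come from
    the SVD of the centred matrix.
    """
    ids = layout["electrode"].tolist()
    rows = []
    for beat in beat_series.beats:
        if set(ids) <= set(beat.activation_times):
            m = beat.mean_time
            rows.append([beat.activation_times[e] - m for e in ids])
    if len(rows) < 3:
        raise ValueError("PCA needs at least 3 beats with complete electrode sets")
    X = np.array(rows)
    Xc = X - X.mean(axis=0)
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals**2
    return PcaResult(component_loadings=vt, variance_fractions=var / var.sum())


def slowness_entropy(vectors, bin_size: float = 0.005) -> EntropyResult:
    """Shannon entropy (nats) of the slowness-tip distribution.

    Tips are binned on a square grid of side ``bin_size`` anchored at the
    origin of the slowness plane (half-open bins [k*b, (k+1)*b)); entropy
    is computed over occupied bins with p = count/total.
    """
    vecs = [v.vec if isinstance(v, SlownessVector) else np.asarray(v) for v in vectors if v is not None]
    if not vecs:
        raise ValueError("need at least one slowness vector")
    tips = np.array(vecs, dtype=float)
    idx = np.floor(tips / bin_size).astype(int)
    _, counts = np.unique(idx, axis=0, return_counts=True)
    p = counts / counts.sum()
    entropy = float(-(p * np.log(p)).sum())
    return EntropyResult(bin_size=bin_size, occupied_bins=int(counts.size), entropy=entropy)


def interbeat_slowness_diff(vectors) -> tuple[np.ndarray, np.ndarray]:
    """Norms of differences between successive slowness vectors.

    ``vectors`` may contain None for ineligible beats; pairs touching one
    are dropped.  Returns ``(indices, norms)`` where ``indices[k] = i``
    means ``norms[k] = |s_{i+1} - s_i|``, aligned with IBI_i.
    """
    idx, norms = [], []
    for i in range(len(vectors) - 1):
        a, b = vectors[i], vectors[i + 1]
        if a is None or b is None:
            continue
        av = a.vec if isinstance(a, SlownessVector) else np.asarray(a, dtype=float)
        bv = b.vec if isinstance(b, SlownessVector) else np.asarray(b, dtype=float)
        idx.append(i)
        norms.append(float(np.linalg.norm(bv - av)))
    return np.array(idx, dtype=int), np.array(norms)
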
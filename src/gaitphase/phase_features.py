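"""Signal-level computation: normalization, regional sums, heel-strike
anchored phase labelling, circular sine–cosine phase encoding, centre of
pressure, causal windowing, and stride-normalized curves.

The gait phase is a single global variable in [0, 100): 0 at each right
heel strike, advancing linearly to the next strike.  For regression it is
encoded as the continuous sinusoidal pair (cos θ, sin θ) with
θ = phase · 2π/100, which removes the 0/100 wrap discontinuity; decoding
uses a four-quadrant arctangent, so it is invariant to radial scaling of
the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import (
    BACK_IDX,
    CHANNEL_NAMES,
    FORE_IDX,
    FsrRecording,
    N_CHANNELS,
    SAMPLING_RATE_HZ,
    SITE_ORDER,
    WALKING_CONDITIONS,
)
from .synthetic_gait import SensorLayout

TWO_PI = 2.0 * np.pi


class DegenerateChannelError(ValueError):
    """A channel has max == min, so min–max scaling is undefined."""


class InsufficientEventsError(ValueError):
    """Fewer than two anchor events: no complete stride to label."""


class UndefinedPhaseError(ValueError):
    """The zero CSF vector carries no phase information."""


# ---------------------------------------------------------------------------
# Normalization and regional sums
# ---------------------------------------------------------------------------

@dataclass
class NormStats:
    """Training-set normalization statistics, fit once and frozen.

    ``channel_min``/``channel_max`` drive per-channel min–max scaling;
    ``fore_max``/``back_max`` (per foot, computed on scaled data) divide the
    forefoot and backfoot regional sums.
    """

    channel_min: np.ndarray
    channel_max: np.ndarray
    fore_max: dict  # side -> float
    back_max: dict


def fit_norm_stats(recordings: list[FsrRecording]) -> NormStats:
    """Fit min–max statistics and regional-sum maxima on training data."""
    if not recordings:
        raise ValueError("need at least one training recording")
    stacked = np.concatenate([r.forces for r in recordings], axis=0)
    cmin = stacked.min(axis=0)
    cmax = stacked.max(axis=0)
    degenerate = np.isclose(cmax, cmin)
    if np.any(degenerate):
        names = [CHANNEL_NAMES[i] for i in np.flatnonzero(degenerate)]
        raise DegenerateChannelError(
            f"constant channel(s) {names}: min == max, cannot min-max scale"
        )
    scaled = (stacked - cmin) / (cmax - cmin)
    fore_max, back_max = {}, {}
    for side in ("L", "R"):
        fore_max[side] = float(scaled[:, FORE_IDX[side]].sum(axis=1).max())
        back_max[side] = float(scaled[:, BACK_IDX[side]].sum(axis=1).max())
    for side in ("L", "R"):
        if fore_max[side] <= 0 or back_max[side] <= 0:
            raise DegenerateChannelError(f"zero regional maximum on foot {side}")
    return NormStats(cmin, cmax, fore_max, back_max)


def apply_minmax(recording: FsrRecording, stats: NormStats) -> FsrRecording:
    """Min–max scale a recording with frozen training statistics.

    Held-out values outside the training range are clipped to [0, 1]; no
    smoothing or filtering is applied anywhere in the pipeline.
    """
    span = stats.channel_max - stats.channel_min
    scaled = (recording.forces - stats.channel_min) / span
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return recording.with_forces(scaled, normalized=True)


def region_sums(samples: np.ndarray, stats: NormStats) -> np.ndarray:
    """Forefoot/backfoot force sums per foot, scaled by training maxima.

    ``samples`` is (n, 10) normalized forces (a single (10,) vector is also
    accepted).  Per foot, Fore = toe + 1st-meta + 5th-meta and
    Back = cuboid + heel, each divided by its training-set maximum.
    Returns (n, 4) columns (Fore_L, Back_L, Fore_R, Back_R).
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    cols = []
    for side in ("L", "R"):
        cols.append(x[:, FORE_IDX[side]].sum(axis=1) / stats.fore_max[side])
        cols.append(x[:, BACK_IDX[side]].sum(axis=1) / stats.back_max[side])
    out = np.stack(cols, axis=1)
    return out[0] if np.ndim(samples) == 1 else out


# ---------------------------------------------------------------------------
# Heel-strike detection and phase labelling
# ---------------------------------------------------------------------------

def detect_heel_strikes(
    heel_series: np.ndarray,
    threshold: float = 0.05,
    refractory_s: float = 0.3,
    fs: float = SAMPLING_RATE_HZ,
    baseline: float = 0.02,
    max_backtrack: int = 30,
) -> np.ndarray:
    """Indices where the right-heel signal rises through ``threshold``.

    A heel strike is an upward threshold crossing; crossings within the
    refractory interval of the previous strike are suppressed, which rejects
    noise-induced double triggers at comfortable cadences.  Each crossing is
    then refined to the onset of its loading ramp by walking back along the
    monotone rise until the signal sits at or below ``baseline`` (at most
    ``max_backtrack`` samples), so the reported index marks initial contact
    rather than the instant the threshold happens to be reached.
    """
    s = np.asarray(heel_series, dtype=float)
    above = s >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings])
    refractory = int(round(refractory_s * fs))
    events = []
    last = -np.inf
    for idx in crossings:
        i, steps = int(idx), 0
        while i > 0 and steps < max_backtrack and s[i] > baseline and s[i - 1] < s[i]:
            i -= 1
            steps += 1
        if i - last >= refractory:
            events.append(i)
            last = i
    return np.asarray(events, dtype=int)


@dataclass
class GaitPhaseSeries:
    """Per-sample gait phase in [0, 100) with a validity mask.

    Samples before the first and at/after the last anchor event have no
    defined stride and are marked invalid.
    """

    values: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def label_gait_phase(series_length_or_recording, events) -> GaitPhaseSeries:
    """Linear 0–100 phase between consecutive anchor events.

    Accepts either a recording or a plain sample count.  Phase is exactly 0
    at each event sample and interpolates linearly (exclusive of 100) up to
    the next event.
    """
    if isinstance(series_length_or_recording, FsrRecording):
        n = series_length_or_recording.n_samples
    else:
        n = int(series_length_or_recording)
    events = np.asarray(events, dtype=int)
    if len(events) < 2:
        raise InsufficientEventsError(
            f"need at least 2 heel-strike events, got {len(events)}"
        )
    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for a, b in zip(events[:-1], events[1:]):
        values[a:b] = np.arange(b - a) * (100.0 / (b - a))
        valid[a:b] = True
    return GaitPhaseSeries(values=values, valid=valid)


# ---------------------------------------------------------------------------
# Continuous sinusoidal (CSF) encoding
# ---------------------------------------------------------------------------

def encode_phase(phase: np.ndarray | float) -> np.ndarray:
    """Encode phase in [0, 100) as the CSF pair (cos θ, sin θ).

    θ = phase · 2π/100.  Returns shape (..., 2); the pair is unit norm.
    """
    theta = np.asarray(phase, dtype=float) * (TWO_PI / 100.0)
    return np.stack([np.cos(theta), np.sin(theta)], axis=-1)


def decode_phase(csf: np.ndarray) -> np.ndarray | float:
    """Decode a CSF pair back to phase in [0, 100).

    Uses the four-quadrant arctangent mapped to [0, 2π), so decoding is
    invariant to any positive radial scaling of the pair (model outputs need
    not be unit norm).  Raises for the all-zero vector.
    """
    arr = np.asarray(csf, dtype=float)
    c, s = arr[..., 0], arr[..., 1]
    if np.any((c == 0.0) & (s == 0.0)):
        raise UndefinedPhaseError("zero CSF vector has no defined phase")
    theta = np.mod(np.arctan2(s, c), TWO_PI)
    phase = theta * (100.0 / TWO_PI)
    # guard against 100.0 from rounding at the wrap
    phase = np.where(phase >= 100.0, phase - 100.0, phase)
    return float(phase) if np.ndim(csf) == 1 else phase


# ---------------------------------------------------------------------------
# Centre of pressure
# ---------------------------------------------------------------------------

def compute_cop(
    samples: np.ndarray,
    layout: SensorLayout | None = None,
    eps: float = 1e-6,
) -> np.ndarray:
    """Anterior–posterior centre of pressure per foot, (n, 2) = (COP_L, COP_R).

    Force-weighted mean of the site coordinates.  During swing (total force
    below ``eps``) the last valid value is held, starting from 0 (heel).
    """
    if layout is None:
        layout = SensorLayout()
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    coords = layout.site_coords()
    out = np.zeros((x.shape[0], 2))
    for j, side in enumerate(("L", "R")):
        idx = [CHANNEL_NAMES.index(f"{side}_{s}") for s in SITE_ORDER]
        foot = x[:, idx]
        total = foot.sum(axis=1)
        ok = total >= eps
        cop = np.zeros(len(total))
        cop[ok] = foot[ok] @ coords / total[ok]
        # forward-fill through swing
        filled = np.where(ok, cop, np.nan)
        last = 0.0
        for i in range(len(filled)):
            if np.isnan(filled[i]):
                filled[i] = last
            else:
                last = filled[i]
        out[:, j] = filled
    return out[0] if np.ndim(samples) == 1 else out


# ---------------------------------------------------------------------------
# Feature assembly (input-feature ablation variants)
# ---------------------------------------------------------------------------

#: Blocks per ablation variant.  fsr = 10 channels, sums = 4 regional sums,
#: wc = 5-dim one-hot condition code, cop = 2 per-foot COP values.
VARIANT_BLOCKS: dict[int, tuple[str, ...]] = {
    1: ("fsr", "sums", "wc"),
    2: ("fsr", "sums"),
    3: ("fsr", "wc"),
    4: ("sums", "wc"),
    5: ("fsr", "sums", "wc", "cop"),
}

_BLOCK_WIDTH = {"fsr": N_CHANNELS, "sums": 4, "wc": len(WALKING_CONDITIONS), "cop": 2}


def variant_width(variant: int) -> int:
    """Input width of a feature variant (19/14/15/9/21 for variants 1-5)."""
    return sum(_BLOCK_WIDTH[b] for b in VARIANT_BLOCKS[variant])


@dataclass
class FeatureMatrix:
    """Per-sample model input for one recording under one variant."""

    values: np.ndarray
    variant: int
    columns: list = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.values.shape[1]


def wc_onehot(codes: np.ndarray) -> np.ndarray:
    """One-hot encode per-sample condition codes; unknown (-1) rows are zero."""
    codes = np.asarray(codes, dtype=int)
    out = np.zeros((len(codes), len(WALKING_CONDITIONS)))
    ok = (codes >= 0) & (codes < len(WALKING_CONDITIONS))
    out[np.flatnonzero(ok), codes[ok]] = 1.0
    return out


def build_features(
    recording: FsrRecording,
    stats: NormStats,
    variant: int = 1,
    wc_code: np.ndarray | None = None,
    layout: SensorLayout | None = None,
) -> FeatureMatrix:
    """Assemble the per-sample input matrix for one ablation variant.

    ``wc_code`` overrides the per-sample condition stream (e.g. classifier
    predictions at inference, ground truth for teacher forcing); by default
    the recording's own labels are used.  The recording must already be
    normalized.
    """
    if variant not in VARIANT_BLOCKS:
        raise ValueError(f"unknown feature variant {variant}")
    if not recording.normalized:
        raise ValueError("recording must be min-max normalized before featurising")
    blocks, names = [], []
    for block in VARIANT_BLOCKS[variant]:
        if block == "fsr":
            blocks.append(recording.forces)
            names += list(CHANNEL_NAMES)
        elif block == "sums":
            blocks.append(region_sums(recording.forces, stats))
            names += ["fore_L", "back_L", "fore_R", "back_R"]
        elif block == "wc":
            codes = recording.wc if wc_code is None else wc_code
            blocks.append(wc_onehot(codes))
            names += [f"wc_{w}" for w in WALKING_CONDITIONS]
        elif block == "cop":
            blocks.append(compute_cop(recording.forces, layout))
            names += ["cop_L", "cop_R"]
    fm = FeatureMatrix(np.concatenate(blocks, axis=1), variant, names)
    assert fm.width == variant_width(variant)
    return fm


# ---------------------------------------------------------------------------
# Windowing and stride normalization
# ---------------------------------------------------------------------------

def build_windows(
    features: np.ndarray,
    labels: np.ndarray | None,
    seq_len: int,
    hop: int = 1,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Trailing (causal) windows with the label taken at each window's end.

    Window ``k`` covers samples ``[k·hop, k·hop + seq_len)``; the number of
    windows is ``floor((n − seq_len)/hop) + 1`` (zero when ``n < seq_len``).
    Returns ``(windows, end_labels, end_indices)``.
    """
    if seq_len < 1 or hop < 1:
        raise ValueError("seq_len and hop must be >= 1")
    x = np.asarray(features)
    n = x.shape[0]
    if n < seq_len:
        empty = np.empty((0, seq_len) + x.shape[1:], dtype=x.dtype)
        return empty, (None if labels is None else np.empty((0,) + np.asarray(labels).shape[1:])), np.empty(0, int)
    n_win = (n - seq_len) // hop + 1
    starts = np.arange(n_win) * hop
    ends = starts + seq_len - 1
    windows = np.lib.stride_tricks.sliding_window_view(x, seq_len, axis=0)
    windows = np.moveaxis(windows[starts], -1, 1)  # (n_win, seq_len, width)
    end_labels = None if labels is None else np.asarray(labels)[ends]
    return np.ascontiguousarray(windows), end_labels, ends


def stride_normalize(
    recording: FsrRecording,
    events: np.ndarray,
    grid_points: int = 101,
) -> dict[str, np.ndarray]:
    """Resample each stride onto a fixed 0–100 % grid, grouped by condition.

    Every stride (between consecutive anchor events) is linearly
    interpolated to ``grid_points`` samples; strides are grouped by the
    condition label at their first sample.  Returns a mapping
    condition -> array of shape (n_strides, grid_points, 10), from which
    per-condition mean and SD curves follow directly.
    """
    events = np.asarray(events, dtype=int)
    if len(events) < 2:
        raise InsufficientEventsError("need at least 2 events to cut strides")
    grid = np.linspace(0.0, 100.0, grid_points)
    grouped: dict[str, list] = {}
    for a, b in zip(events[:-1], events[1:]):
        n = b - a
        xp = np.arange(n) * (100.0 / n)
        seg = recording.forces[a:b]
        curve = np.stack(
            [np.interp(grid, xp, seg[:, j]) for j in range(seg.shape[1])], axis=1
        )
        code = int(recording.wc[a])
        wc = WALKING_CONDITIONS[code] if code >= 0 else "NA"
        grouped.setdefault(wc, []).append(curve)
    return {wc: np.stack(curves) for wc, curves in grouped.items()}
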
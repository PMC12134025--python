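"""Temporal synchronization: gaze-vs-video latency and multi-recording clocks.

Two distinct timing problems are solved here.

**Gaze vs. scene video (VOR).**  A participant fixates a world target
while oscillating the head (shaking "no", nodding "yes", ~0.5 Hz,
about 20 deg each direction).  Because the vestibulo-ocular reflex
holds gaze on the target with essentially zero latency, the gaze point
and the target's image should move identically on the scene video; any
temporal offset between the two quasi-sinusoidal signals is the
latency of the gaze stream relative to the video.  The offset is found
by maximizing the correlation between the two signals over a shift
grid, with parabolic sub-step refinement.

**Multiple recordings.**  Independent devices start at different times
and their clocks drift at slightly different rates.  Each recording is
mapped onto one *reference recording* by an affine clock model
``t_ref = a * t + b`` fitted from the times of abrupt shared visual
transients: one transient fixes the offset (``a = 1``); two or more,
spaced well apart, additionally estimate the rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .camera import CameraCalibration, GeometryError, plane_to_pixel
from .mapping import FramePlaneObservation, GazeSample
from .planes import PlaneDefinition, TargetPoint

__all__ = [
    "PlanarSignal",
    "VORResult",
    "SyncModel",
    "extract_target_signal",
    "estimate_vor_offset",
    "apply_gaze_time_offset",
    "fit_sync_model",
    "to_reference_time",
]


@dataclass(frozen=True)
class PlanarSignal:
    """A 2-D position signal on the scene video (gaze or target track)."""

    timestamps: np.ndarray  # (N,) s, strictly increasing
    positions: np.ndarray   # (N, 2) px; NaN rows are gaps
    label: str = "gaze"

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(ts) != len(pos):
            raise ValueError("timestamps and positions differ in length")
        if len(ts) > 1 and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "positions", pos)


@dataclass(frozen=True)
class VORResult:
    offset: float            # s, amount to ADD to gaze timestamps
    peak_correlation: float
    window: float            # s, half-width of the searched shift range
    ok: bool = True
    message: str = ""


@dataclass(frozen=True)
class SyncModel:
    """Affine clock map of one recording onto the reference: t_ref = a*t + b."""

    recording: str
    reference: str
    a: float = 1.0
    b: float = 0.0
    residual_rms: float = 0.0
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("clock scale must be positive")

    @property
    def drift_warning(self) -> bool:
        return abs(self.a - 1.0) > 1e-3

    @classmethod
    def identity(cls, recording: str) -> "SyncModel":
        return cls(recording=recording, reference=recording)


# --------------------------------------------------------------------------
# target signal
# --------------------------------------------------------------------------

def extract_target_signal(
    observations: dict[int, FramePlaneObservation],
    frame_idxs: Sequence[int],
    frame_timestamps: Sequence[float],
    plane: PlaneDefinition,
    target: TargetPoint | None = None,
    calib: CameraCalibration | None = None,
) -> PlanarSignal:
    """Track a plane target's image position over frames of a sync episode.

    For every frame the target's plane point is projected to scene
    pixels through that frame's geometry; frames without a qualifying
    observation become NaN gaps.
    """
    if target is None:
        target = plane.center_target()
    P = (target.x, target.y)
    ts, pos = [], []
    any_obs = False
    for fidx, t in zip(frame_idxs, frame_timestamps):
        obs = observations.get(int(fidx))
        xy = (np.nan, np.nan)
        if obs is not None:
            try:
                if obs.pose is not None and calib is not None:
                    p = plane_to_pixel(P, pose=obs.pose, calib=calib)
                elif obs.homography is not None:
                    p = plane_to_pixel(P, homography=obs.homography)
                else:
                    p = None
                if p is not None:
                    xy = (float(p[0]), float(p[1]))
                    any_obs = True
            except GeometryError:
                pass
        ts.append(float(t))
        pos.append(xy)
    if not any_obs:
        raise ValueError("target signal empty: no plane observations in episode")
    return PlanarSignal(np.array(ts), np.array(pos), label="target")


# --------------------------------------------------------------------------
# VOR offset estimation
# --------------------------------------------------------------------------

def _resample_uniform(sig: PlanarSignal, grid: np.ndarray, max_gap: float) -> np.ndarray:
    """Linear interpolation onto ``grid``; gaps wider than ``max_gap`` stay NaN."""
    out = np.full((len(grid), 2), np.nan)
    ok = np.all(np.isfinite(sig.positions), axis=1)
    ts, pos = sig.timestamps[ok], sig.positions[ok]
    if len(ts) < 2:
        return out
    inside = (grid >= ts[0]) & (grid <= ts[-1])
    for c in range(2):
        out[inside, c] = np.interp(grid[inside], ts, pos[:, c])
    # mask interpolation across holes wider than max_gap
    gaps = np.diff(ts)
    for gi in np.nonzero(gaps > max_gap)[0]:
        bad = (grid > ts[gi]) & (grid < ts[gi + 1])
        out[bad] = np.nan
    return out


def _dominant_frequency(sig: PlanarSignal) -> float:
    """Fundamental frequency (Hz) of the signal's x channel via periodogram."""
    ok = np.all(np.isfinite(sig.positions), axis=1)
    ts, x = sig.timestamps[ok], sig.positions[ok, 0]
    if len(ts) < 8:
        return 0.0
    dt = float(np.median(np.diff(ts)))
    grid = np.arange(ts[0], ts[-1], dt)
    xs = np.interp(grid, ts, x)
    xs = xs - xs.mean()
    spec = np.abs(np.fft.rfft(xs))
    freqs = np.fft.rfftfreq(len(xs), dt)
    if len(spec) < 2:
        return 0.0
    k = 1 + int(np.argmax(spec[1:]))
    return float(freqs[k])


def estimate_vor_offset(
    gaze: PlanarSignal,
    target: PlanarSignal,
    window: float = 1.0,
    step: float = 0.001,
    interp_max_gap: float = 0.1,
) -> VORResult:
    """Estimate the gaze-vs-video latency from a VOR fixation episode.

    Both signals are resampled to a common uniform rate (the higher of
    the two native rates; linear interpolation across gaps of at most
    ``interp_max_gap`` s).  The returned offset is the shift of the
    gaze timestamps, within ``[-window, +window]`` searched at ``step``
    resolution and refined parabolically, that maximizes the mean of
    the x- and y-channel Pearson correlations with the target signal —
    i.e., the amount that must be *added* to gaze timestamps.

    With an oscillation of period T the correlation is T-periodic, so
    the window must not exceed T/2 or the peak is ambiguous; this is
    enforced against the target signal's dominant frequency.  A result
    with fewer than two oscillation cycles in the episode or a peak
    correlation below 0.5 is flagged ``ok=False``.
    """
    def rate(sig: PlanarSignal) -> float:
        d = np.diff(sig.timestamps)
        return 1.0 / float(np.median(d)) if len(d) else 0.0

    dt = 1.0 / max(rate(gaze), rate(target))
    t0 = max(gaze.timestamps[0], target.timestamps[0])
    t1 = min(gaze.timestamps[-1], target.timestamps[-1])
    if t1 - t0 <= 2 * window:
        raise ValueError("episode too short for the requested search window")

    freq = _dominant_frequency(target)
    # 5% slack absorbs periodogram bin quantization on short episodes
    if freq > 0 and window > 1.05 * 0.5 / freq:
        raise ValueError(
            f"search window ±{window} s exceeds half the oscillation period "
            f"({0.5 / freq:.3f} s at {freq:.3g} Hz); the correlation peak would be ambiguous"
        )
    grid = np.arange(t0, t1, dt)
    tgt = _resample_uniform(target, grid, interp_max_gap)

    shifts = np.arange(-window, window + step / 2, step)
    cors = np.full(len(shifts), -np.inf)
    core = (grid >= t0 + window) & (grid <= t1 - window)
    for i, s in enumerate(shifts):
        shifted = PlanarSignal(gaze.timestamps + s, gaze.positions, gaze.label)
        gz = _resample_uniform(shifted, grid, interp_max_gap)
        ok = core & np.all(np.isfinite(gz), axis=1) & np.all(np.isfinite(tgt), axis=1)
        if ok.sum() < 10:
            continue
        cs = []
        for c in range(2):
            a, b = gz[ok, c], tgt[ok, c]
            sa, sb = a.std(), b.std()
            if sa < 1e-12 or sb < 1e-12:
                continue
            cs.append(float(np.corrcoef(a, b)[0, 1]))
        if cs:
            cors[i] = float(np.mean(cs))

    k = int(np.argmax(cors))
    best, peak = shifts[k], cors[k]
    if 0 < k < len(shifts) - 1 and np.isfinite(cors[k - 1]) and np.isfinite(cors[k + 1]):
        y0, y1, y2 = cors[k - 1], cors[k], cors[k + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-15:
            best = best + 0.5 * step * (y0 - y2) / denom

    n_cycles = (t1 - t0) * freq
    ok_flag, msg = True, ""
    if n_cycles < 2:
        ok_flag, msg = False, f"unreliable estimate: only {n_cycles:.1f} oscillation cycles"
    elif peak < 0.5:
        ok_flag, msg = False, f"unreliable estimate: peak correlation {peak:.2f} < 0.5"
    return VORResult(float(best), float(peak), window, ok_flag, msg)


def apply_gaze_time_offset(
    gaze: Sequence[GazeSample], offset: float
) -> list[GazeSample]:
    """Shift all gaze timestamps by ``offset`` seconds (order-preserving)."""
    return [GazeSample(g.timestamp + offset, g.gaze_px) for g in gaze]


# --------------------------------------------------------------------------
# multi-recording clock model
# --------------------------------------------------------------------------

def fit_sync_model(
    pairs: Sequence[tuple[float, float]],
    recording: str = "recording",
    reference: str = "reference",
) -> SyncModel:
    """Fit ``t_ref = a * t_rec + b`` from shared-transient time pairs.

    One pair gives a pure offset (``a = 1``); two or more give the
    least-squares line, which also captures clock-rate drift.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one transient time pair")
    t_rec = np.array([p[0] for p in pairs], dtype=float)
    t_ref = np.array([p[1] for p in pairs], dtype=float)
    if len(pairs) == 1:
        return SyncModel(recording, reference, 1.0, float(t_ref[0] - t_rec[0]), 0.0, 1)
    if len(np.unique(t_rec)) < len(t_rec):
        raise ValueError("duplicate recording-side transient times")
    a, b = np.polyfit(t_rec, t_ref, 1)
    resid = t_ref - (a * t_rec + b)
    return SyncModel(
        recording, reference, float(a), float(b),
        float(np.sqrt(np.mean(resid**2))), len(pairs),
    )


def to_reference_time(model: SyncModel, t):
    """Map recording time(s) to reference time: ``a * t + b``."""
    return model.a * np.asarray(t, dtype=float) + model.b
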
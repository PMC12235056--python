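"""Marker-trajectory conditioning: gap filling then low-pass filtering.

The acquisition chain samples at 100 Hz; occlusion gaps are filled with
cubic splines through the surrounding visible samples, after which every
coordinate is low-pass filtered with a zero-phase (forward-backward)
second-order Butterworth at a 6 Hz cutoff.  Gap filling precedes filtering
because the filter requires contiguous data.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .mocap_io import MarkerTrajectorySet

__all__ = ["GapError", "fill_gaps", "lowpass"]

DEFAULT_FILTER_ORDER = 2
DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_MAX_GAP_S = 0.5


class GapError(ValueError):
    """Raised for boundary gaps or gaps longer than the configured maximum."""


def _gap_runs(visible: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous invisible runs as (start, stop) half-open frame intervals."""
    runs = []
    inv = ~visible
    if not inv.any():
        return runs
    edges = np.flatnonzero(np.diff(inv.astype(np.int8)))
    starts = list(edges[inv[edges + 1]] + 1)
    stops = list(edges[~inv[edges + 1]] + 1)
    if inv[0]:
        starts.insert(0, 0)
    if inv[-1]:
        stops.append(len(inv))
    return list(zip(starts, stops))


def fill_gaps(traj: MarkerTrajectorySet, max_gap_s: float = DEFAULT_MAX_GAP_S) -> MarkerTrajectorySet:
    """Cubic-spline interpolation of interior occlusion gaps.

    Every gap must have visible data on both sides and span at most
    ``max_gap_s`` seconds; violations raise :class:`GapError` naming the
    marker and frame range.  Originally visible samples are untouched.
    """
    if traj.mask.all():
        return traj
    max_frames = int(round(max_gap_s * traj.sample_rate))
    positions = traj.positions.copy()
    mask = traj.mask
    for j, label in enumerate(traj.labels):
        visible = mask[:, j]
        runs = _gap_runs(visible)
        if not runs:
            continue
        for start, stop in runs:
            if start == 0 or stop == len(visible):
                raise GapError(
                    f"marker '{label}': gap at trial boundary (frames {start}..{stop - 1})"
                )
            if stop - start > max_frames:
                raise GapError(
                    f"marker '{label}': gap of {stop - start} frames "
                    f"(frames {start}..{stop - 1}) exceeds max_gap_s={max_gap_s}"
                )
        idx = np.flatnonzero(visible)
        spline = CubicSpline(idx, positions[idx, j, :], axis=0)
        gaps = np.flatnonzero(~visible)
        positions[gaps, j, :] = spline(gaps)
    return MarkerTrajectorySet(
        sample_rate=traj.sample_rate,
        labels=list(traj.labels),
        positions=positions,
        mask=np.ones_like(mask),
    )


def lowpass(
    traj: MarkerTrajectorySet,
    order: int = DEFAULT_FILTER_ORDER,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> MarkerTrajectorySet:
    """Zero-phase Butterworth low-pass on every marker coordinate.

    Forward-backward application squares the single-pass magnitude response
    and cancels the phase, so filtered angles are not time-shifted.  DC is
    preserved exactly (constant trajectories pass through unchanged).
    """
    if not traj.mask.all():
        raise ValueError("trajectories contain occlusions; fill gaps before filtering")
    if not np.isfinite(traj.positions).all():
        raise ValueError("trajectories contain non-finite samples")
    nyquist = traj.sample_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist ({nyquist} Hz)")
    b, a = butter(order, cutoff_hz / nyquist)
    n = traj.n_frames
    padlen = 3 * max(len(a), len(b))
    if n <= 3 * padlen:
        raise ValueError(f"trial too short to filter ({n} frames)")
    flat = traj.positions.reshape(n, -1)
    # remove the mean first so edge padding works on the oscillatory part only
    mean = flat.mean(axis=0)
    filtered = filtfilt(b, a, flat - mean, axis=0, padlen=padlen) + mean
    return MarkerTrajectorySet(
        sample_rate=traj.sample_rate,
        labels=list(traj.labels),
        positions=filtered.reshape(traj.positions.shape),
        mask=traj.mask.copy(),
    )


def butterworth_gain(
    freq_hz: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    sample_rate: float | None = None,
) -> float:
    """Analytic zero-phase amplitude gain at ``freq_hz``.

    The zero-phase filter applies the Butterworth twice, so its amplitude
    gain is the squared single-pass magnitude ``1 / (1 + r**(2*order))``
    with ``r`` the frequency ratio.  With ``sample_rate`` given, ``r`` uses
    the bilinear-transform prewarped ratio ``tan(pi f/fs) / tan(pi fc/fs)``
    of the discrete filter; otherwise the analog ratio ``f / fc``.
    """
    if sample_rate is not None:
        r = np.tan(np.pi * freq_hz / sample_rate) / np.tan(np.pi * cutoff_hz / sample_rate)
    else:
        r = freq_hz / cutoff_hz
    return 1.0 / (1.0 + float(r) ** (2 * order))
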
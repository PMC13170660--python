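"""Raw-fluorescence containers and ΔF/F0 conversion.

Calcium-indicator recordings arrive as per-ROI mean-fluorescence time series
(one soma per ROI).  Before event detection the raw signal F is normalized to
ΔF/F0 = (F − F0)/F0, where the baseline F0 is estimated per ROI as the average
of the 50th percentile of the signal over consecutive 60-s windows.  A
percentile baseline is robust to sparse transients: as long as events occupy
fewer than half of the frames in each window, the window median equals the
true quiescent level.

The baseline here is a scalar per ROI (the mean of the per-window medians)
computed over non-overlapping tiled windows; a trailing partial window of at
least half the nominal length is kept as its own window, a shorter remainder
is merged into the previous one.  Percentiles use linear interpolation
between order statistics (numpy's default), and oracles in the test suite
follow the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateBaselineError,
    InvalidParameterError,
    WindowTooLongError,
)

__all__ = [
    "FluorescenceTraceSet",
    "DffTraceSet",
    "compute_baseline",
    "compute_dff",
]


@dataclass
class FluorescenceTraceSet:
    """Raw per-ROI fluorescence, shape (n_roi, n_frames), arbitrary units."""

    F: np.ndarray
    sampling_rate: float
    roi_ids: list[str]
    group_label: str = ""
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise InvalidParameterError("F must be a 2-D (roi x frame) array")
        if self.F.shape[1] < 2:
            raise InvalidParameterError("traces need at least 2 frames")
        if not np.all(np.isfinite(self.F)):
            raise InvalidParameterError("non-finite fluorescence values; no imputation is performed")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if len(self.roi_ids) != self.F.shape[0]:
            raise InvalidParameterError("roi_ids length must match number of rows in F")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise InvalidParameterError("roi_ids must be unique")

    @property
    def n_roi(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate


@dataclass
class DffTraceSet:
    """ΔF/F0 traces plus the scalar baseline F0 used per ROI."""

    dff: np.ndarray
    F0: np.ndarray
    sampling_rate: float
    roi_ids: list[str]
    window_s: float = 60.0
    group_label: str = ""
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.F0 = np.asarray(self.F0, dtype=float)
        if np.any(self.F0 <= 0):
            raise DegenerateBaselineError("F0 must be positive for every ROI")

    @property
    def n_roi(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sampling_rate


def _window_slices(n_frames: int, window_frames: int) -> list[slice]:
    """Tile ``n_frames`` into consecutive windows of ``window_frames``.

    A trailing remainder of at least half a window stands alone; a shorter
    remainder is merged into the previous window.
    """
    n_full = n_frames // window_frames
    remainder = n_frames - n_full * window_frames
    edges = [i * window_frames for i in range(n_full + 1)]
    if remainder >= (window_frames + 1) // 2 or n_full == 0:
        edges.append(n_frames)
    else:
        edges[-1] = n_frames
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def compute_baseline(traces: FluorescenceTraceSet, window_s: float = 60.0) -> np.ndarray:
    """Per-ROI scalar baseline F0: mean of per-window 50th percentiles.

    Parameters
    ----------
    traces
        Raw fluorescence traces.
    window_s
        Window length in seconds (default 60 s).

    Returns
    -------
    numpy.ndarray
        F0, shape (n_roi,).

    Raises
    ------
    WindowTooLongError
        If the recording is shorter than one window.
    DegenerateBaselineError
        If any ROI's baseline is non-positive.
    """
    if window_s <= 0:
        raise InvalidParameterError("window_s must be positive")
    window_frames = int(round(window_s * traces.sampling_rate))
    if window_frames < 1 or traces.n_frames < window_frames:
        raise WindowTooLongError(
            f"trace duration {traces.duration:.1f} s shorter than baseline window {window_s:.1f} s"
        )
    slices = _window_slices(traces.n_frames, window_frames)
    medians = np.stack([np.percentile(traces.F[:, s], 50, axis=1) for s in slices], axis=1)
    f0 = medians.mean(axis=1)
    if np.any(f0 <= 0):
        bad = [traces.roi_ids[i] for i in np.flatnonzero(f0 <= 0)]
        raise DegenerateBaselineError(f"non-positive baseline for ROI(s) {bad}")
    return f0


def compute_dff(
    traces: FluorescenceTraceSet, F0: np.ndarray | None = None, window_s: float = 60.0
) -> DffTraceSet:
    """Convert raw fluorescence to ΔF/F0 = (F − F0)/F0.

    If ``F0`` is not supplied it is computed with :func:`compute_baseline`
    using ``window_s``.
    """
    if F0 is None:
        F0 = compute_baseline(traces, window_s=window_s)
    F0 = np.asarray(F0, dtype=float)
    if F0.shape != (traces.n_roi,):
        raise InvalidParameterError("F0 must have one value per ROI")
    if np.any(F0 <= 0):
        raise DegenerateBaselineError("F0 must be positive for every ROI")
    dff = (traces.F - F0[:, None]) / F0[:, None]
    return DffTraceSet(
        dff=dff,
        F0=F0,
        sampling_rate=traces.sampling_rate,
        roi_ids=list(traces.roi_ids),
        window_s=window_s,
        group_label=traces.group_label,
        timepoint_label=traces.timepoint_label,
    )
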
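"""Template-matching calcium-transient detection and spike-rate tables.

Transients are found by sliding a window of template length along each ΔF/F0
trace and scoring each position against a library of indicator-like waveforms
(difference-of-exponentials, peak-normalized).  The similarity score is the
Pearson correlation between the mean-subtracted window and the template, so
it is amplitude-free and bounded in [−1, 1]; a position is a candidate event
when its best-template similarity reaches the similarity threshold (default
0.75) AND the peak ΔF/F0 inside the window reaches the minimum amplitude
(default 0.01).  Overlapping candidates are resolved by greedy non-maximum
suppression on similarity with a refractory window of half the template
length; ties are broken in favour of the earlier onset.

Detected events are converted to spikes/min per ROI, the unit in which
activity is classified downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InvalidParameterError
from .traces import DffTraceSet

__all__ = [
    "TemplateLibrary",
    "CalciumEvent",
    "build_template_library",
    "detect_events",
    "spike_rates",
    "events_to_frame",
]

#: Detection defaults used throughout the pipeline.
SIMILARITY_THRESHOLD = 0.75
MIN_AMPLITUDE = 0.01
DEFAULT_RISE_TAUS = (0.05, 0.1, 0.2)
DEFAULT_DECAY_TAUS = (0.3, 0.6, 1.2)
DEFAULT_TEMPLATE_LEN_S = 3.0


@dataclass
class TemplateLibrary:
    """Bank of unit-peak transient waveforms sampled at the trace rate."""

    templates: np.ndarray  # (n_templates, template_len) each with max exactly 1
    rise_taus: list[float]
    decay_taus: list[float]
    sampling_rate: float

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    @property
    def template_len(self) -> int:
        return self.templates.shape[1]


@dataclass
class CalciumEvent:
    roi_id: str
    onset_frame: int
    peak_frame: int
    amplitude: float  # peak ΔF/F0 within the matched window
    similarity: float  # Pearson correlation with the best template
    template_index: int


def kernel_waveform(rise_tau: float, decay_tau: float, sampling_rate: float, n_frames: int) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized on the grid."""
    if not (decay_tau > rise_tau > 0):
        raise InvalidParameterError(
            f"need decay_tau > rise_tau > 0, got rise={rise_tau}, decay={decay_tau}"
        )
    t = np.arange(n_frames) / sampling_rate
    w = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    peak = w.max()
    if peak <= 0:
        raise InvalidParameterError("degenerate kernel: non-positive peak on the sampling grid")
    return w / peak


def build_template_library(
    rise_taus=DEFAULT_RISE_TAUS,
    decay_taus=DEFAULT_DECAY_TAUS,
    sampling_rate: float = 8.0,
    template_len_s: float = DEFAULT_TEMPLATE_LEN_S,
) -> TemplateLibrary:
    """One template per (rise, decay) pair over the full grid."""
    if sampling_rate <= 0 or template_len_s <= 0:
        raise InvalidParameterError("sampling_rate and template_len_s must be positive")
    n = int(round(template_len_s * sampling_rate))
    if n < 3:
        raise InvalidParameterError("template must span at least 3 frames")
    rows = [kernel_waveform(r, d, sampling_rate, n) for r, d in product(rise_taus, decay_taus)]
    pairs = list(product(rise_taus, decay_taus))
    return TemplateLibrary(
        templates=np.stack(rows),
        rise_taus=[p[0] for p in pairs],
        decay_taus=[p[1] for p in pairs],
        sampling_rate=sampling_rate,
    )


def _similarity_matrix(trace: np.ndarray, templates: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson correlation of every window against every template.

    Returns (best similarity per window, best template index, window peak).
    Zero-variance windows get similarity 0.
    """
    L = templates.shape[1]
    windows = sliding_window_view(trace, L)  # (n_win, L) view
    wc = windows - windows.mean(axis=1, keepdims=True)
    wn = np.linalg.norm(wc, axis=1)
    tc = templates - templates.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tc, axis=1)
    corr = wc @ tc.T  # (n_win, n_templates)
    denom = wn[:, None] * tn[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, corr / np.where(denom > 0, denom, 1.0), 0.0)
    best = corr.max(axis=1)
    best_idx = corr.argmax(axis=1)
    return best, best_idx, windows.max(axis=1)


def detect_events(
    dff: DffTraceSet,
    library: TemplateLibrary | None = None,
    similarity_threshold: float = SIMILARITY_THRESHOLD,
    min_amplitude: float = MIN_AMPLITUDE,
) -> list[CalciumEvent]:
    """Detect calcium transients in every ROI of a ΔF/F0 trace set.

    Raises
    ------
    InvalidParameterError
        If the threshold is outside [-1, 1], the amplitude is negative, the
        template is longer than the trace, or the library's sampling rate
        does not match the traces.
    """
    if library is None:
        library = build_template_library(sampling_rate=dff.sampling_rate)
    if library.n_templates == 0:
        raise InvalidParameterError("template library is empty")
    if not -1.0 <= similarity_threshold <= 1.0:
        raise InvalidParameterError("similarity_threshold must lie in [-1, 1]")
    if min_amplitude < 0:
        raise InvalidParameterError("min_amplitude must be non-negative")
    if not np.isclose(library.sampling_rate, dff.sampling_rate):
        raise InvalidParameterError(
            f"library sampled at {library.sampling_rate} Hz but traces at {dff.sampling_rate} Hz"
        )
    L = library.template_len
    if L > dff.n_frames:
        raise InvalidParameterError("template longer than trace")

    refractory = L // 2
    events: list[CalciumEvent] = []
    for i, roi in enumerate(dff.roi_ids):
        trace = dff.dff[i]
        sim, tmpl_idx, peak = _similarity_matrix(trace, library.templates)
        cand = np.flatnonzero((sim >= similarity_threshold) & (peak >= min_amplitude))
        if cand.size == 0:
            continue
        # greedy non-maximum suppression: best similarity first, earlier onset on ties
        order = cand[np.lexsort((cand, -sim[cand]))]
        accepted: list[int] = []
        for onset in order:
            if all(abs(onset - a) >= refractory for a in accepted):
                accepted.append(int(onset))
        for onset in sorted(accepted):
            window = trace[onset : onset + L]
            events.append(
                CalciumEvent(
                    roi_id=roi,
                    onset_frame=onset,
                    peak_frame=onset + int(np.argmax(window)),
                    amplitude=float(window.max()),
                    similarity=float(sim[onset]),
                    template_index=int(tmpl_idx[onset]),
                )
            )
    return events


def spike_rates(
    events: list[CalciumEvent],
    duration: float,
    roi_ids: list[str],
    group_label: str = "",
    timepoint_label: str = "",
) -> pd.DataFrame:
    """Per-ROI spike-rate table in spikes/min.

    ROIs without events are included with rate 0.  Columns: roi_id, n_events,
    rate (spikes/min), duration_s, group, timepoint.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    counts = {roi: 0 for roi in roi_ids}
    for ev in events:
        if ev.roi_id not in counts:
            raise InvalidParameterError(f"event for unknown ROI {ev.roi_id!r}")
        counts[ev.roi_id] += 1
    return pd.DataFrame(
        {
            "roi_id": list(roi_ids),
            "n_events": [counts[r] for r in roi_ids],
            "rate": [counts[r] / (duration / 60.0) for r in roi_ids],
            "duration_s": duration,
            "group": group_label,
            "timepoint": timepoint_label,
        }
    )


def events_to_frame(events: list[CalciumEvent], sampling_rate: float) -> pd.DataFrame:
    """Events as a DataFrame with onset/peak in seconds (for CSV export)."""
    return pd.DataFrame(
        {
            "roi_id": [e.roi_id for e in events],
            "onset_s": [e.onset_frame / sampling_rate for e in events],
            "peak_s": [e.peak_frame / sampling_rate for e in events],
            "amplitude": [e.amplitude for e in events],
            "similarity": [e.similarity for e in events],
            "template_index": [e.template_index for e in events],
        }
    )
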
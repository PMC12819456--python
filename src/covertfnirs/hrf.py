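"""Canonical hemodynamic response function and task-regressor construction."""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

from .recording import EventSchedule


def canonical_hrf(sampling_rate: float, duration: float = 32.0,
                  peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Double-gamma HRF sampled at ``sampling_rate``, peak normalized to 1.

    The positive lobe is a gamma density with mode ``peak_delay`` s, the
    undershoot a gamma density with mode ``undershoot_delay`` s scaled by
    ``undershoot_ratio``; both use unit rate.
    """
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    peak = gamma_dist.pdf(t, a=peak_delay + 1.0, scale=1.0)
    under = gamma_dist.pdf(t, a=undershoot_delay + 1.0, scale=1.0)
    h = peak - undershoot_ratio * under
    return h / np.max(h)


def boxcar(events: EventSchedule, sampling_rate: float, n_samples: int) -> np.ndarray:
    """0/1 task indicator sampled on the recording grid (epochs are [on, off))."""
    t = np.arange(n_samples) / sampling_rate
    box = np.zeros(n_samples)
    for ep in events.task_epochs:
        box[(t >= ep.onset) & (t < ep.offset)] = 1.0
    return box


def task_regressor(events: EventSchedule, sampling_rate: float, n_samples: int,
                   **hrf_kw) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, truncated and peak-normalized.

    Returns an all-zero column when the schedule has no task epochs.
    """
    box = boxcar(events, sampling_rate, n_samples)
    if not np.any(box):
        return box
    h = canonical_hrf(sampling_rate, **hrf_kw)
    reg = np.convolve(box, h)[:n_samples]
    return reg / np.max(np.abs(reg))
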
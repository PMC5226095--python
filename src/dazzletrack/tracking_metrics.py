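"""Tracking-error response variable.

The response analysed throughout is the mean Euclidean distance (px)
between cursor centre and target centre over the final 4000 ms of each
5000 ms trial, natural-log transformed. Samples lie on a common 10 ms grid;
the analysis window is the half-open interval (1000, 5000] ms, i.e. 400
samples at the default grid (the endpoint convention is a documented choice
— the source protocol leaves it unstated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW_MS = (1000.0, 5000.0)


@dataclass(frozen=True)
class ErrorSummary:
    mean_error: float
    n_samples: int
    window_start: float
    window_end: float


def mean_tracking_error(
    target_xy: np.ndarray,
    cursor_xy: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> ErrorSummary:
    """Mean cursor-to-target distance over the window (w0, w1].

    Both series must share the ``times_ms`` grid; the window must lie
    within the grid's extent.
    """
    target_xy = np.asarray(target_xy, dtype=float)
    cursor_xy = np.asarray(cursor_xy, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if target_xy.shape != cursor_xy.shape or target_xy.shape[0] != times_ms.shape[0]:
        raise ValueError("target and cursor series must share one time grid")
    w0, w1 = window
    if w0 >= w1:
        raise ValueError("window must have positive length")
    if w1 > times_ms[-1] + 1e-9:
        raise ValueError("window exceeds the series extent")
    mask = (times_ms > w0) & (times_ms <= w1)
    if not np.any(mask):
        raise ValueError("window contains no samples")
    d = np.linalg.norm(target_xy[mask] - cursor_xy[mask], axis=1)
    return ErrorSummary(
        mean_error=float(d.mean()),
        n_samples=int(mask.sum()),
        window_start=float(w0),
        window_end=float(w1),
    )


def batch_mean_error(
    target_xy: np.ndarray,
    cursor_xy: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> np.ndarray:
    """Vectorized mean error for stacked series shaped (B, n_samples, 2)."""
    times_ms = np.asarray(times_ms, dtype=float)
    mask = (times_ms > window[0]) & (times_ms <= window[1])
    d = np.linalg.norm(
        np.asarray(target_xy)[:, mask] - np.asarray(cursor_xy)[:, mask], axis=2
    )
    return d.mean(axis=1)


def log_error(mean_error: float) -> float:
    """Natural log of a (strictly positive) mean tracking error."""
    if mean_error <= 0:
        raise ValueError(
            f"mean_error must be > 0 for the log transform (got {mean_error})"
        )
    return float(np.log(mean_error))
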
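"""Baseline correction and temporal smoothing.

MEG epochs are baseline-corrected on -200 to 0 ms relative to stimulus onset;
gaze epochs on -200 to 0 ms relative to cue onset (the cue precedes the
stimulus by 834 ms in the main task), which removes slow tracker drifts.
Before decoding, signals are smoothed with a 100 ms centered moving average.
Both operations are linear and act independently per trial and feature.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

from .epochs import EpochSet

__all__ = ["CUE_ONSET_S", "baseline_correct", "smooth_moving_average"]

#: Cue onset relative to stimulus onset in the main task (417 ms cue +
#: 417 ms blank before the grating).
CUE_ONSET_S = -0.834


def baseline_correct(epochs: EpochSet, window=(-0.2, 0.0),
                     reference_event: str = "stimulus") -> EpochSet:
    """Subtract the per-trial, per-feature mean over a baseline window.

    Parameters
    ----------
    window : (t0, t1)
        Closed interval in seconds relative to ``reference_event``.
    reference_event : {"stimulus", "cue"}
        ``"stimulus"`` uses the epoch time axis directly; ``"cue"`` shifts the
        window by :data:`CUE_ONSET_S`.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("baseline window must be non-empty (t1 > t0)")
    if reference_event == "cue":
        t0, t1 = t0 + CUE_ONSET_S, t1 + CUE_ONSET_S
    elif reference_event != "stimulus":
        raise ValueError(f"unknown reference_event {reference_event!r}")
    mask = epochs.time_mask(t0, t1)
    if not mask.any():
        raise ValueError(
            f"baseline window [{t0}, {t1}] s contains no samples of the epoch "
            f"({epochs.times[0]:.3f} to {epochs.times[-1]:.3f} s)"
        )
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def smooth_moving_average(epochs: EpochSet, window_s: float = 0.1) -> EpochSet:
    """Centered boxcar moving average along the time axis.

    The window length is rounded to the nearest odd number of samples so the
    filter is zero-phase.  At the epoch edges the window is truncated
    (shrinking toward the boundary), so no samples are lost and no NaNs appear.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    dt = 1.0 / epochs.sfreq
    if window_s < dt - 1e-12:
        raise ValueError("window_s must be at least one sample interval")
    n = int(round(window_s / dt))
    if n % 2 == 0:
        n += 1
    out = epochs.copy()
    if n == 1:
        return out
    # Truncated-edge mean: boxcar sum divided by the in-bounds sample count.
    summed = uniform_filter1d(out.data, size=n, axis=2, mode="constant", cval=0.0)
    counts = uniform_filter1d(
        np.ones(out.n_times), size=n, mode="constant", cval=0.0
    )
    out.data = summed / counts[None, None, :]
    return out
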
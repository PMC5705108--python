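"""Lightweight temporal operations on ROI timecourses.

These are the post-extraction steps whose influence on reproducibility is
worth probing: global signal regression, ideal (discrete-Fourier) band
filtering, and double-TR decimation. Voxel-level preprocessing (motion
correction, registration, smoothing) is out of scope; inputs are already
mean ROI timecourses.
"""

from __future__ import annotations

import numpy as np

from .records import ROITimeseries


def global_signal_regress(ts: ROITimeseries) -> ROITimeseries:
    """Regress the cross-region mean timecourse out of every region.

    The global signal (mean over regions at each timepoint) plus an
    intercept is removed from each column by least squares, leaving every
    residual column orthogonal to the global signal. A constant global
    signal degenerates to plain demeaning.
    """
    x = ts.values
    if x.shape[0] <= 2:
        raise ValueError("need more than 2 timepoints")
    g = x.mean(axis=1)
    if np.ptp(g) == 0:
        return ts.with_values(x - x.mean(axis=0, keepdims=True))
    design = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return ts.with_values(x - design @ beta)


def ideal_bandpass(
    ts: ROITimeseries, low_hz: float, high_hz: float | None = None
) -> ROITimeseries:
    """Ideal band filter in the discrete-Fourier domain.

    Fourier coefficients at frequencies strictly below ``low_hz`` or
    strictly above ``high_hz`` are zeroed and the series inverse-
    transformed; frequencies exactly at a band edge pass. The DC component
    is below any positive ``low_hz`` and is therefore removed. ``high_hz``
    of None means no upper cut (pure highpass).
    """
    x = ts.values
    t = x.shape[0]
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    hi = nyquist if high_hz is None else high_hz
    if not 0 <= low_hz < hi <= nyquist + 1e-12:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) invalid for Nyquist {nyquist:.4g} Hz"
        )
    freqs = np.fft.rfftfreq(t, d=ts.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= hi)
    if low_hz > 0:
        keep[0] = False
    if not np.any(keep & (freqs > 0)):
        raise ValueError("band excludes every nonzero frequency")
    spec = np.fft.rfft(x, axis=0)
    spec[~keep] = 0.0
    return ts.with_values(np.fft.irfft(spec, n=t, axis=0))


def decimate_double_tr(ts: ROITimeseries) -> ROITimeseries:
    """Leave out every second timepoint, doubling the repetition time.

    Keeps timepoints with even 0-based index (the first timepoint stays).
    """
    if ts.n_timepoints < 4:
        raise ValueError("need at least 4 timepoints to decimate")
    return ts.with_values(ts.values[::2], tr_seconds=2.0 * ts.tr_seconds)
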
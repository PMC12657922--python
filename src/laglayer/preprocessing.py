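"""Signal conditioning: despiking, re-referencing, high-gamma power, smoothing.

The canonical order mirrors standard intracranial pipelines: large excursions
are removed and re-imputed, the across-electrode common average is subtracted,
broadband high-gamma (70-200 Hz) power is estimated with Morlet wavelets while
skipping line-noise harmonics, and the power trace is smoothed with a short
Hamming window.  Every stage preserves the electrodes x samples shape.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import fftconvolve
from scipy.ndimage import convolve1d

from .errors import ValidationError
from .types import NeuralRecording

__all__ = ["despike", "rereference_car", "highgamma_power", "smooth_hamming"]

logger = logging.getLogger(__name__)


def _despike_row(x: np.ndarray, k: float) -> tuple:
    med = np.median(x)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    bad = np.abs(x - med) > k * iqr
    if not bad.any():
        return x, bad
    good = ~bad
    out = x.copy()
    idx = np.arange(x.size)
    if good.sum() >= 4:
        f = interp1d(idx[good], x[good], kind="cubic", bounds_error=False)
        out[bad] = f(idx[bad])
    else:
        out[bad] = np.nan
    # Flagged samples outside the interpolation support (edges) take the
    # nearest unflagged value; same fallback if too few points for a cubic.
    still = ~np.isfinite(out)
    still |= bad & (idx < idx[good][0])
    still |= bad & (idx > idx[good][-1])
    if still.any():
        nearest = interp1d(idx[good], x[good], kind="nearest", fill_value="extrapolate")
        out[still] = nearest(idx[still])
    return out, bad


def despike(recording: NeuralRecording, k: float = 4.0) -> NeuralRecording:
    """Remove large spikes and impute replacements by cubic interpolation.

    Samples farther than ``k`` interquartile ranges from an electrode's median
    are flagged; flagged runs are replaced by a cubic interpolant through the
    neighbouring unflagged samples (nearest unflagged value at the edges).
    Electrodes with more than half their samples flagged are marked suspect.
    """
    if recording.n_samples < 4:
        raise ValidationError("despike needs at least 4 samples per electrode")
    if not np.all(np.isfinite(recording.signal)):
        raise ValidationError("despike requires finite input samples")
    out = np.empty_like(recording.signal)
    suspect = list(recording.suspect)
    for e in range(recording.n_electrodes):
        out[e], bad = _despike_row(recording.signal[e], k)
        if bad.mean() > 0.5:
            eid = recording.electrode_ids[e]
            logger.warning("electrode %s: %.0f%% of samples flagged as spikes", eid,
                           100 * bad.mean())
            if eid not in suspect:
                suspect.append(eid)
    res = recording.copy_with(out)
    res.suspect = suspect
    return res


def rereference_car(recording: NeuralRecording) -> NeuralRecording:
    """Common average referencing: subtract the per-sample mean across electrodes."""
    if recording.n_electrodes < 2:
        raise ValidationError("common average referencing needs >= 2 electrodes")
    return recording.copy_with(recording.signal - recording.signal.mean(axis=0, keepdims=True))


def _morlet_kernel(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet at ``freq`` Hz, L2-normalized, ~±5 SD support."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kern = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    kern -= kern.mean()  # zero mean => insensitive to DC offsets
    return kern / np.linalg.norm(kern)


def highgamma_power(
    recording: NeuralRecording,
    band: tuple = (70.0, 200.0),
    exclude: tuple = (60.0, 120.0, 180.0),
    n_cycles: float = 6.0,
    n_freqs: int = 10,
    exclusion_guard: float = 5.0,
) -> NeuralRecording:
    """Broadband high-gamma power via Morlet wavelets, skipping line harmonics.

    Power is computed at ``n_freqs`` log-spaced frequencies inside ``band``;
    frequencies within ``exclusion_guard`` Hz of any excluded line frequency
    are dropped, and the per-frequency power traces are averaged.
    """
    lo, hi = band
    if recording.sampling_rate <= 2 * hi:
        raise ValidationError(
            f"sampling rate {recording.sampling_rate} Hz too low for a {hi} Hz band edge"
        )
    freqs = np.geomspace(lo, hi, n_freqs)
    keep = np.ones(freqs.size, dtype=bool)
    for line in exclude:
        keep &= np.abs(freqs - line) > exclusion_guard
    freqs = freqs[keep]
    if freqs.size == 0:
        raise ValidationError("no wavelet frequencies remain after line exclusion")
    out = np.zeros_like(recording.signal)
    for f in freqs:
        kern = _morlet_kernel(f, recording.sampling_rate, n_cycles)
        for e in range(recording.n_electrodes):
            conv = fftconvolve(recording.signal[e], kern, mode="same")
            out[e] += np.abs(conv) ** 2
    out /= freqs.size
    return recording.copy_with(out)


def smooth_hamming(recording: NeuralRecording, kernel_ms: float = 50.0) -> NeuralRecording:
    """Smooth each electrode with a unit-sum Hamming window of ``kernel_ms``."""
    if kernel_ms <= 0:
        raise ValidationError("kernel_ms must be positive")
    n = int(round(kernel_ms * recording.sampling_rate / 1000.0))
    n = max(n, 1)
    if n >= recording.n_samples:
        raise ValidationError("smoothing kernel longer than the recording")
    win = np.hamming(n) if n > 1 else np.ones(1)
    win = win / win.sum()
    out = convolve1d(recording.signal, win, axis=1, mode="reflect")
    return recording.copy_with(out)
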
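"""Morlet CWT scalograms of averaged DIF traces.

The averaged DIF response is mapped into a time-frequency image with a
complex Morlet continuous wavelet transform over pseudo-frequencies
spanning the analysis band (100 Hz - 5 kHz), min-max normalized and
resampled to the 224 x 224 x 3 input expected by image classifiers (the
magnitude replicated across the three channels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["Scalogram", "cwt_scalogram"]

logger = logging.getLogger(__name__)

#: Conventional Morlet center angular frequency.
DEFAULT_OMEGA0 = 6.0


@dataclass
class Scalogram:
    """A normalized time-frequency image of one DIF trace.

    ``image`` is 224 x 224 x 3 float32 in [0, 1]; rows run from the lowest
    to the highest analysis frequency (``frequencies`` gives the
    pre-resampling grid).
    """

    image: np.ndarray
    wavelet: str
    scales: np.ndarray
    frequencies: np.ndarray
    recording_id: str = ""
    all_zero: bool = False
    extra: dict = field(default_factory=dict)


def cwt_scalogram(
    dif_trace: np.ndarray,
    sampling_rate: float,
    freq_range: tuple[float, float] = (100.0, 5000.0),
    n_scales: int = 64,
    size: tuple[int, int] = (224, 224),
    omega0: float = DEFAULT_OMEGA0,
    recording_id: str = "",
) -> Scalogram:
    """Compute the Morlet CWT scalogram of an averaged DIF trace.

    ``n_scales`` log-spaced scales cover pseudo-frequencies from
    ``freq_range[0]`` to ``freq_range[1]``; the CWT magnitude is min-max
    normalized per image (an all-zero trace yields an all-zero image,
    flagged) and bilinearly resampled to ``size`` with 3 replicated
    channels.
    """
    x = np.asarray(dif_trace, float).ravel()
    if x.size < 64:
        raise ValueError(f"trace too short for a scalogram: {x.size} < 64 samples")
    fc = omega0 / (2 * np.pi)  # Morlet center frequency in cycles per unit
    wavelet = f"cmor1.0-{fc:.6f}"
    freqs = np.logspace(*np.log10(freq_range), n_scales)
    scales = fc * sampling_rate / freqs
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / sampling_rate)
    mag = np.abs(coef)  # (n_scales, T), row 0 = lowest frequency

    all_zero = not np.any(mag > 0)
    if all_zero:
        logger.warning("all-zero trace: scalogram left at zero")
        img = np.zeros(mag.shape)
    else:
        lo, hi = mag.min(), mag.max()
        img = (mag - lo) / (hi - lo) if hi > lo else np.zeros(mag.shape)
    zoomed = ndimage.zoom(
        img, (size[0] / img.shape[0], size[1] / img.shape[1]),
        order=1, mode="nearest", grid_mode=True,
    )
    zoomed = np.clip(zoomed, 0.0, 1.0)
    image = np.repeat(zoomed[:, :, None], 3, axis=2).astype(np.float32)
    return Scalogram(
        image=image,
        wavelet=wavelet,
        scales=scales,
        frequencies=freqs,
        recording_id=recording_id,
        all_zero=all_zero,
    )
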
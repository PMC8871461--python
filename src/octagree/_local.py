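"""Masked sliding-window statistics used by the spot detector and the
choroidal binarisation.  Statistics are computed from in-mask pixels only, so
structures outside a region of interest never contaminate its thresholds."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter


def masked_local_stats(
    values: np.ndarray,
    mask: np.ndarray,
    window: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window mean and standard deviation over ``mask`` pixels.

    Returns ``(mean, std)`` arrays defined wherever the window contains at
    least one mask pixel (NaN elsewhere).  Uses uniform box filters, so the
    operation is exactly translation-equivariant away from the image border.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    m = mask.astype(float)
    v = np.where(mask, values, 0.0).astype(float)
    # box sums via uniform_filter (constant-padded => true windowed sums)
    norm = window * window
    cnt = uniform_filter(m, size=window, mode="constant") * norm
    s1 = uniform_filter(v, size=window, mode="constant") * norm
    s2 = uniform_filter(v * v, size=window, mode="constant") * norm
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = s2 / cnt - mean**2
    var = np.clip(var, 0.0, None)
    std = np.sqrt(var)
    empty = cnt < 0.5
    mean[empty] = np.nan
    std[empty] = np.nan
    return mean, std
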
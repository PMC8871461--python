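"""Pair alignment, intensity normalisation, and ROI definition/transfer.

The protocol mirrors clinical practice for paired EDI/conventional B-scans:
register the pair by rigid integer translation, histogram-match the
conventional scan to the EDI scan (the EDI image is the reference because all
ROIs are outlined there), define the central 3 mm region of interest around
the fovea, and transfer every EDI-outlined mask onto the conventional frame.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .core import BScanImage, ROIMask, Registration, as_float


def _ncc_map(fixed: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of ``template`` against every same-size
    window of ``fixed`` (valid positions only).

    Cross terms come from one FFT convolution; window means and variances
    from integral images, so the full map costs one FFT regardless of the
    search radius.
    """
    th, tw = template.shape
    n = th * tw
    t0 = template - template.mean()
    t_ss = float(np.sqrt((t0**2).sum()))
    if t_ss == 0:
        raise ValueError("degenerate (constant) image: correlation undefined")
    cross = fftconvolve(fixed, t0[::-1, ::-1], mode="valid")

    # sliding-window sums of fixed and fixed^2 via padded cumulative sums
    def window_sums(a: np.ndarray) -> np.ndarray:
        s = np.cumsum(np.cumsum(a, axis=0), axis=1)
        s = np.pad(s, ((1, 0), (1, 0)))
        return (s[th:, tw:] - s[:-th, tw:] - s[th:, :-tw] + s[:-th, :-tw])

    f_sum = window_sums(fixed)
    f_ss = window_sums(fixed**2)
    f_var = np.maximum(f_ss - f_sum**2 / n, 0.0)
    denom = t_ss * np.sqrt(f_var)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = cross / denom
    ncc[denom <= 1e-12 * t_ss] = 0.0
    return ncc


def register(
    moving: BScanImage,
    fixed: BScanImage,
    search_radius_px: int = 5,
) -> Registration:
    """Estimate the integer shift mapping ``moving`` coordinates onto
    ``fixed`` coordinates (a feature at ``(r, c)`` in ``moving`` sits at
    ``(r + Δr, c + Δc)`` in ``fixed``).

    The central crop of ``moving`` (inset by the search radius) is slid over
    ``fixed``; the shift maximising the normalized cross-correlation wins.
    Ties are broken by smallest Euclidean shift magnitude, then smallest Δrow,
    then smallest Δcol.
    """
    r = int(search_radius_px)
    if r < 1:
        raise ValueError("search_radius_px must be >= 1")
    if moving.shape != fixed.shape:
        raise ValueError("images must share shape for registration")
    mov = as_float(moving)
    fix = as_float(fixed)
    template = mov[r:-r, r:-r]
    if template.std() == 0 or fix.std() == 0:
        raise ValueError("degenerate (constant) image: correlation undefined")
    scores = _ncc_map(fix, template)  # shape (2r+1, 2r+1)
    best = scores.max()
    cand = np.argwhere(scores >= best - 1e-12)
    shifts = cand - r
    order = np.lexsort((shifts[:, 1], shifts[:, 0], np.hypot(shifts[:, 0], shifts[:, 1])))
    dr, dc = (int(v) for v in shifts[order[0]])
    return Registration(shift=(dr, dc), score=float(best))


def _cdf_nodes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, counts = np.unique(values, return_counts=True)
    quantiles = np.cumsum(counts) / counts.sum()
    return vals.astype(float), quantiles


def match_histogram(
    source: BScanImage,
    reference: BScanImage,
    source_mask: np.ndarray | None = None,
    reference_mask: np.ndarray | None = None,
) -> BScanImage:
    """Histogram-match ``source`` onto ``reference`` (classical histogram
    specification with a monotone gray-level map).

    When masks are given, the gray-level mapping is *estimated* from the
    masked pixels only (e.g. the registered overlap of a pair) but applied to
    the whole source image.  Matching an image to itself is an exact identity.
    """
    src = as_float(source)
    ref = as_float(reference)
    s_px = src[source_mask] if source_mask is not None else src.ravel()
    r_px = ref[reference_mask] if reference_mask is not None else ref.ravel()
    if s_px.size == 0 or r_px.size == 0:
        raise ValueError("empty mask: cannot estimate histogram mapping")

    s_vals, s_q = _cdf_nodes(s_px)
    r_vals, r_q = _cdf_nodes(r_px)
    # monotone map: source value -> reference quantile value at matching CDF
    mapped_nodes = np.interp(s_q, r_q, r_vals)
    mapped = np.interp(src, s_vals, mapped_nodes)
    out = np.clip(np.rint(mapped), 0, 255).astype(np.uint8)
    return source.with_pixels(out)


def central_roi(image: BScanImage, fovea_x: int) -> ROIMask:
    """Full-height lateral mask spanning the central 3 mm around the fovea.

    Width is ``round(3000 / lateral_scale)`` px; the window is
    ``[fovea_x - w//2, fovea_x - w//2 + w)``.  A window that would extend past
    the image border is an error, never a silent clip.
    """
    w = int(round(3000.0 / image.lateral_scale))
    if w > image.width:
        raise ValueError(
            f"3 mm ROI needs {w} px but image is only {image.width} px wide"
        )
    if not 0 <= fovea_x < image.width:
        raise ValueError("fovea_x outside image")
    start = fovea_x - w // 2
    stop = start + w
    if start < 0 or stop > image.width:
        raise ValueError(
            f"central 3 mm ROI [{start}, {stop}) exceeds image bounds "
            f"(minimum width {w} px centred on fovea required)"
        )
    mask = np.zeros(image.shape, dtype=bool)
    mask[:, start:stop] = True
    return ROIMask(mask, kind="lateral-extent", origin_mode=image.mode,
                   col_span=(start, stop))


def transfer_roi(mask: ROIMask, reg: Registration) -> ROIMask:
    """Translate an EDI-outlined mask into the conventional frame.

    Pixels shifted outside the frame are dropped and counted; losing more
    than 5% of the mask raises a warning-level diagnostic in the result.
    """
    if mask.origin_mode != "EDI":
        raise ValueError("only EDI-outlined masks are transferred")
    dr, dc = reg.shift
    src = mask.mask
    out = np.zeros_like(src)
    h, w = src.shape
    r0s, r1s = max(-dr, 0), min(h - dr, h)
    c0s, c1s = max(-dc, 0), min(w - dc, w)
    if r0s < r1s and c0s < c1s:
        out[r0s + dr:r1s + dr, c0s + dc:c1s + dc] = src[r0s:r1s, c0s:c1s]
    dropped = int(src.sum() - out.sum())
    warnings = ()
    if src.sum() and dropped / src.sum() > 0.05:
        warnings = (f"{dropped} mask pixels (> 5%) dropped during ROI transfer",)
    span = None
    if mask.col_span is not None:
        span = (max(mask.col_span[0] + dc, 0), min(mask.col_span[1] + dc, w))
    return ROIMask(out, kind=mask.kind, origin_mode="conventional",
                   transferred=True, dropped_pixels=dropped,
                   warnings=warnings, col_span=span)
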
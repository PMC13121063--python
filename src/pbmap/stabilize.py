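"""Frame-to-frame rigid stabilization of time-lapse stacks.

Minor patient motion during the 20 s acquisition is removed before per-pixel
fitting.  The motion model is a global translation per frame (the minimal
model for a contact-positioned device); each frame's subpixel shift against
the reference frame (frame 0, which anchors the t = 0 intensity origin) is
estimated by Fourier-domain cross-correlation and undone by linear
interpolation.  Pixels that leave the field of view in any frame are flagged
invalid rather than zero-filled — zeros would corrupt the decay fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .stack_io import FrameStack

__all__ = ["ShiftTrace", "estimate_shift", "stabilize_stack"]


@dataclass
class ShiftTrace:
    """Estimated per-frame displacements and post-alignment residuals.

    ``shifts[k]`` is the (dy, dx) displacement of frame k relative to the
    reference frame; ``shifts[reference_index] == (0, 0)``.
    ``residual_metric[k]`` is 1 - normalized cross-correlation between the
    aligned frame and the reference (0 for a perfect match); NaN flags a
    degenerate (constant) frame for which no shift could be estimated.
    """

    shifts: np.ndarray           # (T, 2) of (dy, dx)
    residual_metric: np.ndarray  # (T,)
    reference_index: int = 0

    def to_jsonable(self) -> dict:
        return {
            "reference_index": self.reference_index,
            "shifts": self.shifts.tolist(),
            "residual_metric": [None if not np.isfinite(r) else float(r)
                                for r in self.residual_metric],
        }


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def estimate_shift(frame: np.ndarray, reference: np.ndarray,
                   precision: float = 0.1,
                   median_prefilter: int = 3) -> tuple[float, float]:
    """Estimate the (dy, dx) translation of ``frame`` relative to ``reference``.

    Positive dy means the frame content sits lower than in the reference.
    Subpixel resolution is ``precision`` pixels (default 0.1).  A constant
    (zero-variance) frame cannot be registered and returns (0, 0); callers
    detect this through the NaN residual in :class:`ShiftTrace`.

    ``median_prefilter`` (default 3x3, 0 disables) suppresses static
    salt-and-pepper content — dead sensels and saturated specular pixels do
    not move with the tissue and would otherwise anchor the correlation at
    zero shift.  The filter is applied only for estimation, never to the
    data that gets resampled.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have identical shapes")
    if np.ptp(reference) == 0:
        raise ValueError("reference frame is constant; cannot register against it")
    if np.ptp(frame) == 0:
        return 0.0, 0.0
    if median_prefilter and median_prefilter > 1:
        frame = ndimage.median_filter(frame, size=median_prefilter)
        reference = ndimage.median_filter(reference, size=median_prefilter)
        if np.ptp(frame) == 0 or np.ptp(reference) == 0:
            return 0.0, 0.0
    upsample = max(int(round(1.0 / precision)), 1)
    # pass 1: integer shift by plain phase correlation (robust to large motion)
    coarse, _, _ = phase_cross_correlation(frame, reference, upsample_factor=1,
                                           normalization=None)
    corrected = frame if not coarse.any() else ndimage.shift(frame, -coarse,
                                                             order=1, mode="nearest")
    # pass 2: subpixel residual on the common valid overlap (the strip the
    # integer correction could not fill is cropped away), demeaned and
    # Hann-windowed — the window suppresses the wrap-around edge mismatch
    # that otherwise biases the upsampled correlation toward zero shift
    dy, dx = (int(np.ceil(abs(c))) for c in coarse)
    h, w = frame.shape
    rows = slice(dy, h - dy) if dy else slice(None)
    cols = slice(dx, w - dx) if dx else slice(None)
    a = corrected[rows, cols]
    b = reference[rows, cols]
    if min(a.shape) < 8:  # overlap too small for refinement
        return float(coarse[0]), float(coarse[1])
    win = np.outer(np.hanning(a.shape[0]), np.hanning(a.shape[1]))
    fine, _, _ = phase_cross_correlation((a - a.mean()) * win,
                                         (b - b.mean()) * win,
                                         upsample_factor=upsample,
                                         normalization=None)
    fine = np.clip(fine, -1.5, 1.5)
    shift = coarse + fine
    return float(shift[0]), float(shift[1])


def stabilize_stack(stack: FrameStack, reference_index: int = 0,
                    precision: float = 0.1,
                    interpolation_order: int = 1) -> tuple[FrameStack, ShiftTrace]:
    """Register every frame to the reference frame and resample it back.

    Returns the stabilized stack (float data; intensities modified only by
    interpolation) and the shift trace.  The frame count and timestamps are
    unchanged.  The output stack's ``valid_mask`` is False wherever any
    resampled frame had to read outside the original field of view.
    """
    data = np.asarray(stack.data, dtype=float)
    T = data.shape[0]
    ref = data[reference_index]

    shifts = np.zeros((T, 2))
    residuals = np.zeros(T)
    out = np.empty_like(data)
    valid = np.ones(data.shape[1:], dtype=bool)
    if stack.valid_mask is not None:
        valid &= stack.valid_mask

    for k in range(T):
        if k == reference_index:
            out[k] = data[k]
            residuals[k] = 0.0 if np.ptp(data[k]) else np.nan
            continue
        if np.ptp(data[k]) == 0:
            shifts[k] = (0.0, 0.0)
            out[k] = data[k]
            residuals[k] = np.nan
            continue
        dy, dx = estimate_shift(data[k], ref, precision=precision)
        if max(abs(dy), abs(dx)) <= precision + 1e-12:
            dy = dx = 0.0  # below estimator resolution: resampling would only blur
        shifts[k] = (dy, dx)
        if dy == 0.0 and dx == 0.0:
            out[k] = data[k]
        else:
            out[k] = ndimage.shift(data[k], (-dy, -dx), order=interpolation_order,
                                   mode="constant", cval=np.nan)
            bad = ~np.isfinite(out[k])
            out[k][bad] = 0.0
            valid &= ~bad
        residuals[k] = 1.0 - _ncc(out[k], ref)

    result = FrameStack(data=out, times=stack.times.copy(),
                        source_channel=stack.source_channel,
                        bit_depth=stack.bit_depth, valid_mask=valid)
    trace = ShiftTrace(shifts=shifts, residual_metric=residuals,
                       reference_index=reference_index)
    return result, trace
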
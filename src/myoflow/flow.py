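"""Dense displacement estimation and reduction to flow traces.

Every frame ``t_i`` of a stack is registered against the reference frame
``t_0`` by block matching: the reference frame is tiled into square blocks,
each block is located in the target frame by normalized cross-correlation
within a bounded search window, and the correlation peak is refined to
subpixel precision by fitting a parabola through its three-point
neighbourhood along each axis.

The field ``V_i`` of per-block vectors is reduced to the *flow strength*

    s_i = mean over the ROI of ||v||,

the average registration effort for frame i, and to the *flow change*
``c_i = s_i - s_{i-1}``, the per-frame change in deformation.  ``s_0 = 0``
by construction (self-registration) and ``c_0 = 0`` keeps the traces
index-aligned with the stack.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .core import DisplacementField, ImageStack, Roi, Trace

__all__ = [
    "estimate_displacement_field",
    "estimate_stack_fields",
    "flow_strength",
    "flow_strength_trace",
    "cumulative_displacement",
    "smooth_trace",
    "flow_change",
]

logger = logging.getLogger(__name__)

_FLAT_STD = 1e-10


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    """Subpixel offset of a correlation peak from its three-point stencil."""
    denom = cm - 2.0 * c0 + cp
    if denom >= -1e-12:  # flat or non-concave: stay on the grid
        return 0.0
    delta = 0.5 * (cm - cp) / denom
    return float(np.clip(delta, -0.5, 0.5))


def estimate_displacement_field(
    reference: np.ndarray,
    target: np.ndarray,
    block_size: int = 16,
    search_radius: int = 10,
    reference_index: int = 0,
    target_index: int = 0,
) -> DisplacementField:
    """Block-matching displacement of ``target`` relative to ``reference``.

    Parameters
    ----------
    reference, target : 2-D arrays of identical shape.
    block_size : side of the square matching blocks, >= 8 px.
    search_radius : maximum displacement searched, >= 1 px.

    Returns
    -------
    DisplacementField at block resolution.  Blocks with (near) zero
    variance cannot be matched; they report (0, 0) and are flagged
    low-confidence rather than dropped, keeping the grid rectangular.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if reference.shape != target.shape:
        raise ValueError("reference and target frames must share shape")
    if block_size < 8:
        raise ValueError("block_size must be >= 8 px")
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1 px")

    m, n = reference.shape
    b, r = int(block_size), int(search_radius)
    n_br, n_bc = m // b, n // b
    if n_br == 0 or n_bc == 0:
        raise ValueError("frame smaller than one block")

    vx = np.zeros((n_br, n_bc))
    vy = np.zeros((n_br, n_bc))
    conf = np.ones((n_br, n_bc), dtype=bool)

    for bi in range(n_br):
        r0 = bi * b
        for bj in range(n_bc):
            c0 = bj * b
            template = reference[r0:r0 + b, c0:c0 + b]
            if template.std() < _FLAT_STD:
                vx[bi, bj] = vy[bi, bj] = 0.0
                conf[bi, bj] = False
                continue
            wr0, wr1 = max(0, r0 - r), min(m, r0 + b + r)
            wc0, wc1 = max(0, c0 - r), min(n, c0 + b + r)
            window = target[wr0:wr1, wc0:wc1]
            ncc = match_template(window, template)
            pi, pj = np.unravel_index(np.argmax(ncc), ncc.shape)
            dy = float(wr0 + pi - r0)
            dx = float(wc0 + pj - c0)
            if ncc[pi, pj] >= 1.0 - 1e-9:
                # exact match: the parabola would only add a spurious
                # offset from asymmetric correlation shoulders
                vx[bi, bj], vy[bi, bj] = dx, dy
                continue
            if 0 < pi < ncc.shape[0] - 1:
                dy += _parabolic_offset(ncc[pi - 1, pj], ncc[pi, pj], ncc[pi + 1, pj])
            if 0 < pj < ncc.shape[1] - 1:
                dx += _parabolic_offset(ncc[pi, pj - 1], ncc[pi, pj], ncc[pi, pj + 1])
            vx[bi, bj], vy[bi, bj] = dx, dy

    centers_r = np.arange(n_br) * b + (b - 1) / 2.0
    centers_c = np.arange(n_bc) * b + (b - 1) / 2.0
    return DisplacementField(
        vx=vx, vy=vy, centers_r=centers_r, centers_c=centers_c,
        block_size=b, search_radius=r,
        reference_index=reference_index, target_index=target_index,
        confident=conf,
    )


def estimate_stack_fields(
    stack: ImageStack,
    block_size: int = 16,
    search_radius: int = 10,
) -> list:
    """Displacement fields of every frame relative to frame 0.

    The field for frame 0 is all-zero by construction; the remaining
    frames are matched against frame 0 (never frame-to-frame), which is
    what the cumulative flow-strength definition requires.
    """
    reference = stack.frames[0]
    fields = []
    zero = estimate_displacement_field(
        reference, reference, block_size, search_radius, 0, 0)
    zero.vx[:] = 0.0
    zero.vy[:] = 0.0
    fields.append(zero)
    for i in range(1, stack.n_frames):
        fields.append(estimate_displacement_field(
            reference, stack.frames[i], block_size, search_radius, 0, i))
    return fields


def flow_strength(field: DisplacementField, roi: Roi, frame_shape: tuple) -> float:
    """Mean Euclidean norm of displacement vectors inside the ROI (>= 0)."""
    sel = field.block_mask(roi, frame_shape)
    if not sel.any():
        raise ValueError("ROI covers no displacement blocks")
    return float(field.norm[sel].mean())


def flow_strength_trace(
    stack: ImageStack,
    roi: Optional[Roi] = None,
    block_size: int = 16,
    search_radius: int = 10,
    fields: Optional[Sequence[DisplacementField]] = None,
) -> Trace:
    """Flow-strength trace s_i over the whole stack; s_0 = 0."""
    if roi is None:
        roi = Roi.full_frame(stack.shape)
    if fields is None:
        fields = estimate_stack_fields(stack, block_size, search_radius)
    values = [flow_strength(f, roi, stack.shape) for f in fields]
    return Trace(values=np.array(values), dt=stack.dt, t0=stack.t0,
                 name=f"flow_strength[{roi.label}]")


def cumulative_displacement(
    fields: Sequence[DisplacementField],
    roi: Roi,
    frame_shape: tuple,
    dt: float,
    t0: float = 0.0,
) -> tuple:
    """Per-frame mean x and y displacement inside the ROI.

    The fields are already relative to frame 0, so the per-frame ROI means
    are the cumulative coordinate shifts directly.
    """
    sel = fields[0].block_mask(roi, frame_shape)
    if not sel.any():
        raise ValueError("ROI covers no displacement blocks")
    xs = np.array([f.vx[sel].mean() for f in fields])
    ys = np.array([f.vy[sel].mean() for f in fields])
    return (
        Trace(values=xs, dt=dt, t0=t0, name=f"cum_x[{roi.label}]"),
        Trace(values=ys, dt=dt, t0=t0, name=f"cum_y[{roi.label}]"),
    )


def smooth_trace(trace: Trace, window: int = 5) -> Trace:
    """Centered moving-average smoothing with shrinking edge windows.

    ``window`` must be odd; window 1 returns the trace unchanged.  The
    output never extends the input's [min, max] range.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window > len(trace):
        raise ValueError("smoothing window exceeds trace length")
    if window == 1:
        return trace.with_values(trace.values.copy())
    smoothed = (
        pd.Series(trace.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return trace.with_values(smoothed, name=f"{trace.name}|ma{window}")


def flow_change(trace: Trace) -> Trace:
    """First difference c_i = s_i - s_{i-1}, with c_0 = 0.

    Telescoping identity: cumulative sum of the output recovers the input
    up to its first sample.
    """
    if len(trace) < 2:
        raise ValueError("flow_change needs at least two samples")
    c = np.empty_like(trace.values)
    c[0] = 0.0
    c[1:] = np.diff(trace.values)
    return trace.with_values(c, name=f"{trace.name}|change")
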
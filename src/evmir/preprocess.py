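"""Raw fluorescence -> analysis scale: background subtraction, per-sample
global median normalization to a fixed target (25 by default), log2.

The median used for normalization is computed over *detected, strictly
positive* values only; structural zeros (undetected probes) would otherwise
drag the median to 0 for low-detection subjects. Negatives after background
subtraction are clamped to 0 (fluorescence is non-physical below zero), and
values are floored at 1 before log2 so undetected entries map to 0 on the
log scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, InvalidInputError, ShapeError
from .matrix import IntensityMatrix

DEFAULT_TARGET_MEDIAN = 25.0


def _broadcast_background(m: IntensityMatrix, background) -> np.ndarray:
    """Accept scalar, per-sample, per-probe or full-matrix background."""
    if np.isscalar(background):
        bg = np.full(m.values.shape, float(background))
    elif isinstance(background, pd.DataFrame):
        if background.shape != m.values.shape:
            raise ShapeError(
                f"background shape {background.shape} != matrix shape {m.values.shape}"
            )
        bg = background.to_numpy(dtype=float)
    else:
        arr = np.asarray(
            background.to_numpy() if isinstance(background, pd.Series) else background,
            dtype=float,
        )
        if arr.ndim == 2:
            if arr.shape != m.values.shape:
                raise ShapeError(
                    f"background shape {arr.shape} != matrix shape {m.values.shape}"
                )
            bg = arr
        elif arr.ndim == 1:
            # per-sample when the length matches the sample axis, else per-probe
            if arr.size == m.n_samples:
                bg = np.broadcast_to(arr[None, :], m.values.shape).copy()
            elif arr.size == m.n_probes:
                bg = np.broadcast_to(arr[:, None], m.values.shape).copy()
            else:
                raise ShapeError(
                    f"background length {arr.size} matches neither {m.n_probes} probes "
                    f"nor {m.n_samples} samples"
                )
        else:
            raise ShapeError("background must be scalar, 1-D or 2-D")
    if (bg < 0).any():
        raise InvalidInputError("background values must be nonnegative")
    return bg


def subtract_background(m: IntensityMatrix, background=0.0) -> IntensityMatrix:
    """Subtract background noise from raw fluorescence, clamping at 0."""
    m.require_state("raw")
    bg = _broadcast_background(m, background)
    vals = np.maximum(m.values.to_numpy(dtype=float) - bg, 0.0)
    # undetected entries stay exactly 0
    vals[~m.mask.to_numpy()] = 0.0
    out = pd.DataFrame(vals, index=m.probe_ids, columns=m.sample_ids)
    return m.with_values(out, "background_subtracted")


def global_normalize(m: IntensityMatrix,
                     target_median: float = DEFAULT_TARGET_MEDIAN) -> IntensityMatrix:
    """Scale each sample so its median detected positive intensity equals
    ``target_median``.

    Raises
    ------
    DegenerateSampleError
        Naming any sample with no detected positive values.
    """
    m.require_state("background_subtracted")
    if target_median <= 0:
        raise InvalidInputError("target_median must be positive")
    vals = m.values.to_numpy(dtype=float)
    mask = m.mask.to_numpy()
    scaled = vals.copy()
    for j, sid in enumerate(m.sample_ids):
        col = vals[:, j]
        detected_pos = col[mask[:, j] & (col > 0)]
        if detected_pos.size == 0:
            raise DegenerateSampleError(
                f"sample {sid!r} has no detected positive values; cannot normalize"
            )
        med = np.median(detected_pos)
        scaled[:, j] = col * (target_median / med)
    out = pd.DataFrame(scaled, index=m.probe_ids, columns=m.sample_ids)
    return m.with_values(out, "normalized")


def log2_transform(m: IntensityMatrix, floor: float = 1.0) -> IntensityMatrix:
    """log2 with a positive floor applied first.

    Under the default floor of 1, undetected (zero) entries become 0 on the
    log2 scale; they remain flagged by the mask.
    """
    m.require_state("normalized")
    if floor <= 0:
        raise InvalidInputError("floor must be positive")
    vals = np.log2(np.maximum(m.values.to_numpy(dtype=float), floor))
    out = pd.DataFrame(vals, index=m.probe_ids, columns=m.sample_ids)
    return m.with_values(out, "log2")


def preprocess(m: IntensityMatrix, background=0.0,
               target_median: float = DEFAULT_TARGET_MEDIAN,
               floor: float = 1.0):
    """Full chain raw -> log2. Returns ``(normalized, log2)`` matrices —
    screening needs the linear normalized scale for fold changes and the
    log2 scale for the classifier."""
    sub = subtract_background(m, background)
    norm = global_normalize(sub, target_median)
    return norm, log2_transform(norm, floor)
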
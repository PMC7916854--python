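"""Binary FCN training targets derived from the green fluorescence channel.

The target pipeline runs, in order: per-image min-max normalization,
Gaussian smoothing, thresholding at 0.3, binary dilation, and max-pool
downsampling to the FCN output resolution.  The resulting mask is used
as the training target for every class annotated on the sample; classes
not present receive an all-zero target.

Defaults are stated at the 256x256 working resolution (smoothing sigma
2 px, dilation disk radius 3 px) and scale proportionally with image
side, so a 64x64 image is smoothed with sigma 0.5 and dilated with
radius 0 (i.e. not dilated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .classes import N_CLASSES

__all__ = [
    "TargetMask",
    "make_target_mask",
    "downsample_mask",
    "build_training_targets",
    "DEFAULT_THRESHOLD",
    "REFERENCE_SIDE",
    "REFERENCE_SIGMA",
    "REFERENCE_DILATE_RADIUS",
]

DEFAULT_THRESHOLD = 0.3
REFERENCE_SIDE = 256
REFERENCE_SIGMA = 2.0
REFERENCE_DILATE_RADIUS = 3


@dataclass
class TargetMask:
    mask: np.ndarray          # binary (out, out), values in {0, 1}
    applies_to: np.ndarray | None = None  # binary 13-vector, if known


def downsample_mask(mask: np.ndarray, out_side: int) -> np.ndarray:
    """Max-pool a binary mask to (out_side, out_side).

    An output pixel is 1 iff any input pixel of its receptive block is 1,
    so small positive regions (e.g. a centrosome dot) are never lost.
    Works for any input side >= out_side; blocks are near-equal index
    ranges when the side is not an exact multiple.
    """
    mask = np.asarray(mask)
    h, w = mask.shape
    if out_side > min(h, w):
        raise ValueError(f"out_side {out_side} exceeds input side {min(h, w)}")
    redges = np.linspace(0, h, out_side + 1).round().astype(int)
    cedges = np.linspace(0, w, out_side + 1).round().astype(int)
    out = np.zeros((out_side, out_side), dtype=np.uint8)
    for i in range(out_side):
        block = mask[redges[i] : redges[i + 1]]
        for j in range(out_side):
            out[i, j] = block[:, cedges[j] : cedges[j + 1]].any()
    return out


def make_target_mask(
    green_channel: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    smooth_scale: float | None = None,
    dilate_radius: int | None = None,
    out_side: int = 16,
) -> TargetMask:
    """Normalize -> Gaussian smooth -> threshold -> dilate -> downsample.

    ``smooth_scale`` and ``dilate_radius`` default to the 256-px reference
    values scaled by the actual image side.  A constant-zero image yields
    an all-zero mask; negative intensities are rejected.
    """
    img = np.asarray(green_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("green_channel must be 2-D")
    if img.min() < 0:
        raise ValueError("green_channel must be nonnegative")
    if out_side < 1:
        raise ValueError("out_side must be >= 1")
    side = img.shape[0]
    if smooth_scale is None:
        smooth_scale = REFERENCE_SIGMA * side / REFERENCE_SIDE
    if dilate_radius is None:
        dilate_radius = int(round(REFERENCE_DILATE_RADIUS * side / REFERENCE_SIDE))

    lo, hi = img.min(), img.max()
    if hi == lo:
        return TargetMask(np.zeros((out_side, out_side), dtype=np.uint8))
    norm = (img - lo) / (hi - lo)
    if smooth_scale > 0:
        norm = ndi.gaussian_filter(norm, smooth_scale)
    binary = norm > threshold
    if dilate_radius > 0:
        binary = ndi.binary_dilation(binary, structure=disk(dilate_radius))
    return TargetMask(downsample_mask(binary, out_side))


def build_training_targets(
    green_channel: np.ndarray, labels: np.ndarray, fcn_out_side: int, **kwargs
) -> np.ndarray:
    """Per-class target stack (13, out, out).

    Every present class receives the same spatial target derived from the
    green channel; absent classes receive zeros.
    """
    labels = np.asarray(labels)
    if labels.shape != (N_CLASSES,):
        raise ValueError(f"labels must be a {N_CLASSES}-vector")
    if labels.sum() == 0:
        raise ValueError("every sample must have at least one present class")
    tm = make_target_mask(green_channel, out_side=fcn_out_side, **kwargs)
    stack = np.zeros((N_CLASSES, fcn_out_side, fcn_out_side))
    for c in np.flatnonzero(labels):
        stack[c] = tm.mask
    return stack
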
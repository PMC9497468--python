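"""Tumor-block localization by sliding-window structural similarity.

A registered (normal, tumor) image pair is cut into overlapping blocks on
a strided grid; each aligned block pair is scored by SSIM — the product of
luminance, contrast and structure comparisons

    l = (2 mu_x mu_y + C1) / (mu_x^2 + mu_y^2 + C1)
    c = (2 sig_x sig_y + C2) / (sig_x^2 + sig_y^2 + C2)
    s = (sig_xy + C3) / (sig_x sig_y + C3)

with sample statistics (std and covariance use the H*W-1 denominator).
The block with the smallest SSIM is reported as the tumor unit.  Stride
defaults to 50 px, trading localization accuracy against the number of
block comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np


@dataclass(frozen=True)
class BlockSpec:
    """Sliding-window geometry: window (h, w) px, stride in px."""

    window: Tuple[int, int] = (128, 128)
    stride: int = 50

    def __post_init__(self):
        if self.stride < 1 or self.stride > min(self.window):
            raise ValueError("stride must satisfy 1 <= stride <= min(window)")


@dataclass(frozen=True)
class SSIMParams:
    """Stabilization constants and exponents; L is the dynamic range.

    Defaults follow the conventional choices C1=(0.01 L)^2, C2=(0.03 L)^2,
    C3=C2/2 with L=1 for unit-range images, and unit exponents.
    """

    L: float = 1.0
    C1: float = field(default=0.01**2)
    C2: float = field(default=0.03**2)
    C3: float = field(default=0.03**2 / 2)
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self):
        if min(self.C1, self.C2, self.C3) <= 0:
            raise ValueError("C1, C2, C3 must be positive")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("exponents must be >= 0")

    @classmethod
    def for_range(cls, L: float) -> "SSIMParams":
        return cls(L=L, C1=(0.01 * L) ** 2, C2=(0.03 * L) ** 2, C3=(0.03 * L) ** 2 / 2)


@dataclass
class SSIMMap:
    """Per-block scores with the argmin block and its pixel bounding box."""

    scores: np.ndarray
    boxes: List[Tuple[int, int, int, int]]
    argmin_block: int
    bbox: Tuple[int, int, int, int]  # half-open (y0, x0, y1, x1)

    @property
    def min_score(self) -> float:
        return float(self.scores[self.argmin_block])


def _anchors(extent: int, window: int, stride: int) -> List[int]:
    """Strided anchors clamped so the last block touches the border."""
    if window > extent:
        raise ValueError(f"window {window} larger than image extent {extent}")
    pos = list(range(0, extent - window + 1, stride))
    if pos[-1] != extent - window:
        pos.append(extent - window)
    return pos


def split_blocks(image: np.ndarray, spec: BlockSpec) -> List[Tuple[int, int, int, int]]:
    """Raster-order half-open block boxes (y0, x0, y1, x1) covering the image."""
    h, w = image.shape
    wh, ww = spec.window
    return [
        (y0, x0, y0 + wh, x0 + ww)
        for y0 in _anchors(h, wh, spec.stride)
        for x0 in _anchors(w, ww, spec.stride)
    ]


def ssim_components(x: np.ndarray, y: np.ndarray, params: SSIMParams = SSIMParams()):
    """Luminance, contrast and structure comparisons for one block pair."""
    if x.shape != y.shape:
        raise ValueError(f"block shapes differ: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("blocks need at least 2 pixels")
    mx, my = float(x.mean()), float(y.mean())
    sx, sy = float(x.std(ddof=1)), float(y.std(ddof=1))
    cov = float(((x - mx) * (y - my)).sum() / (x.size - 1))
    l = (2 * mx * my + params.C1) / (mx * mx + my * my + params.C1)
    c = (2 * sx * sy + params.C2) / (sx * sx + sy * sy + params.C2)
    s = (cov + params.C3) / (sx * sy + params.C3)
    return l, c, s


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Weighted SSIM product [l^alpha * c^beta * s^gamma] for one block pair."""
    l, c, s = ssim_components(x, y, params)
    out = 1.0
    for base, expo, name in ((l, params.alpha, "l"), (c, params.beta, "c"), (s, params.gamma, "s")):
        if base < 0 and expo != int(expo):
            raise ValueError(
                f"component {name}={base:.4g} is negative with fractional "
                f"exponent {expo}; use integer exponents or clamp inputs"
            )
        out *= base**expo
    return float(out)


def locate_tumor_block(
    normal: np.ndarray,
    tumor: np.ndarray,
    spec: BlockSpec = BlockSpec(),
    params: SSIMParams = SSIMParams(),
) -> SSIMMap:
    """Score all aligned block pairs; the argmin block is the tumor unit.

    Ties break toward the smallest block id (raster order).  Inputs are
    assumed registered and equally shaped.
    """
    if normal.shape != tumor.shape:
        raise ValueError(f"image shapes differ: {normal.shape} vs {tumor.shape}")
    boxes = split_blocks(normal, spec)
    scores = np.array(
        [
            ssim(normal[y0:y1, x0:x1], tumor[y0:y1, x0:x1], params)
            for (y0, x0, y1, x1) in boxes
        ]
    )
    argmin = int(np.argmin(scores))  # first minimum in raster order
    return SSIMMap(scores=scores, boxes=boxes, argmin_block=argmin, bbox=boxes[argmin])
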
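"""End-to-end tumor detection: register -> locate -> segment.

Composes the package stages: the tumor image is non-rigidly registered
onto the normal reference with Bendlet features, the registered pair is
scanned by sliding-window SSIM to find the most dissimilar block, and the
Chan-Vese wavelet-homotopy solver segments the tumor inside that block.
Restricting the level set to the located block is what keeps bright
distractors elsewhere in the frame (skull, other organs) from capturing
the contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from bendseg.cv_wavelet_solver import CVParams, SegmentationResult, segment
from bendseg.registration import (
    RegistrationConfig,
    RegistrationResult,
    register,
)
from bendseg.ssim_locator import BlockSpec, SSIMMap, SSIMParams, locate_tumor_block


@dataclass
class PipelineResult:
    mask: np.ndarray  # in the observed (tumor image) frame
    mask_aligned: np.ndarray  # in the registered (reference) frame
    registration: Optional[RegistrationResult]
    ssim_map: SSIMMap
    segmentation: SegmentationResult

    @property
    def bbox(self):
        return self.ssim_map.bbox


def _push_mask_through_warp(mask: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    """Map a mask from the warped frame back to the original frame.

    The aligned image is ``moving(x + v(x))``; a mask drawn on it
    corresponds to observed-frame points ``q = x + v(x)``.  The inverse
    map is found by fixed-point iteration (valid for the smooth, small
    displacements produced here).
    """
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    wy = np.zeros((h, w))
    wx = np.zeros((h, w))
    for _ in range(25):
        vy = ndimage.map_coordinates(displacement[0], [yy + wy, xx + wx], order=1, mode="nearest")
        vx = ndimage.map_coordinates(displacement[1], [yy + wy, xx + wx], order=1, mode="nearest")
        wy, wx = -vy, -vx
    sampled = ndimage.map_coordinates(
        mask.astype(float), [yy + wy, xx + wx], order=1, mode="nearest"
    )
    return sampled >= 0.5


def _anomaly_component(
    mask: np.ndarray, normal: np.ndarray, aligned: np.ndarray, bbox
) -> np.ndarray:
    """Keep the mask component best covering the intensity anomaly.

    Two-phase segmentation inside the block may also capture bright
    anatomy (skull rim, vessels); the tumor is the component that explains
    the difference against the registered normal reference.
    """
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    y0, x0, y1, x1 = bbox
    diff = np.zeros_like(normal)
    diff[y0:y1, x0:x1] = np.abs(aligned[y0:y1, x0:x1] - normal[y0:y1, x0:x1])
    scores = ndimage.sum_labels(diff, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(scores)))


def segment_tumor(
    normal: np.ndarray,
    tumor: np.ndarray,
    reg_config: RegistrationConfig = RegistrationConfig(),
    block_spec: BlockSpec = BlockSpec(),
    ssim_params: SSIMParams = SSIMParams(),
    cv_params: CVParams = CVParams(mu=0.05),
    register_first: bool = True,
    select_anomaly_component: bool = True,
) -> PipelineResult:
    """Run the full pipeline on a (normal, tumor) image pair.

    The returned mask lives in the registered (normal-aligned) frame.
    ``cv_params`` defaults to a smaller length weight than plain CV since
    tumor-to-tissue contrast is low in cross-sectional images.
    """
    reg = None
    aligned = tumor
    if register_first:
        reg = register(normal, tumor, reg_config)
        aligned = reg.warped
    smap = locate_tumor_block(normal, aligned, block_spec, ssim_params)
    # seed the level set at the intensity anomaly inside the block: the
    # reference image tells us where the pair actually disagrees
    y0, x0, y1, x1 = smap.bbox
    diff = ndimage.gaussian_filter(np.abs(aligned - normal), 2.0)
    block_diff = diff[y0:y1, x0:x1]
    cy, cx = np.unravel_index(np.argmax(block_diff), block_diff.shape)
    yy, xx = np.mgrid[0 : aligned.shape[0], 0 : aligned.shape[1]]
    seed_r = 0.08 * min(y1 - y0, x1 - x0)
    init_mask = np.hypot(yy - (y0 + cy), xx - (x0 + cx)) <= seed_r
    seg = segment(aligned, smap.bbox, cv_params, init_mask=init_mask)
    mask_aligned = seg.mask
    if select_anomaly_component and mask_aligned.any():
        mask_aligned = _anomaly_component(mask_aligned, normal, aligned, smap.bbox)
    # the deliverable mask lives on the observed tumor image (where any
    # manual ground truth would be drawn), so push it back through the
    # estimated warp
    if reg is not None:
        mask = _push_mask_through_warp(mask_aligned, reg.warp.displacement)
    else:
        mask = mask_aligned
    return PipelineResult(
        mask=mask,
        mask_aligned=mask_aligned,
        registration=reg,
        ssim_map=smap,
        segmentation=seg,
    )
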
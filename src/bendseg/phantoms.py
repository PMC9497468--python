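"""Seeded brain-like phantom generator.

Every stage of the pipeline is exercised on synthetic cross-sections: a
bright elliptical skull rim, mid-grey cerebral tissue with smooth texture,
dark ventricle-like structures, an optional planted lesion with known
support, and optional smooth non-rigid deformations with a known dense
displacement field.  All outputs are fully determined by ``(spec, seed)``.

The intensity regime deliberately mimics low-contrast cross-sectional
imaging: the lesion differs from surrounding tissue by a small contrast
step and its boundary may be blurred, which is exactly the regime where
whole-image region-based segmentation fails and localized segmentation is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class LesionSpec:
    """A planted circular lesion.

    center : (y, x) pixels; radius : pixels; contrast : additive intensity
    step against local tissue; blur_sigma : Gaussian blur (px) applied to
    the lesion edge only (the truth mask stays sharp).
    """

    center: Tuple[float, float]
    radius: float
    contrast: float = 0.15
    blur_sigma: float = 1.5


@dataclass(frozen=True)
class DeformationSpec:
    """A smooth random displacement field.

    control_points : number of control nodes per axis of the coarse grid;
    max_displacement : peak displacement magnitude in pixels.  The field is
    kept diffeomorphic by requiring the peak displacement to stay below
    half the control spacing.  Few control points give the large-scale,
    slowly varying fields typical of mass-effect deformation.
    radial_fraction : share of the field contributed by a radial push away
    from the lesion (mass effect); the rest is the random smooth part.
    """

    control_points: int = 3
    max_displacement: float = 6.0
    radial_fraction: float = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, int] = (256, 256)
    seed: int = 0
    texture_amplitude: float = 0.06
    skull_value: float = 0.9
    tissue_value: float = 0.4
    background_value: float = 0.05
    lesion: Optional[LesionSpec] = None
    deformation: Optional[DeformationSpec] = None


def _soft_mask(levelset: np.ndarray, width: float = 1.5) -> np.ndarray:
    """Smooth 0/1 indicator from a signed function (positive inside)."""
    return 0.5 * (1.0 + np.tanh(levelset / width))


def _ellipse_sdf(shape, center, axes) -> np.ndarray:
    """Approximate signed 'distance' (positive inside) of an ellipse, px."""
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    cy, cx = center
    ay, ax_ = axes
    r = np.sqrt(((y - cy) / ay) ** 2 + ((x - cx) / ax_) ** 2)
    return (1.0 - r) * min(ay, ax_)


def _disc_sdf(shape, center, radius) -> np.ndarray:
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return radius - np.hypot(y - center[0], x - center[1])


def _base_anatomy(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    brain = _ellipse_sdf(spec.shape, (cy, cx), (0.40 * h, 0.36 * w))
    skull = _ellipse_sdf(spec.shape, (cy, cx), (0.44 * h, 0.40 * w))

    img = np.full(spec.shape, spec.background_value)
    img += (spec.skull_value - spec.background_value) * _soft_mask(skull)
    img += (spec.tissue_value - spec.skull_value) * _soft_mask(brain)

    # ventricle-like dark structures, mirrored about the midline
    for sx in (-1.0, 1.0):
        vent = _ellipse_sdf(
            spec.shape, (cy - 0.05 * h, cx + sx * 0.10 * w), (0.11 * h, 0.035 * w)
        )
        img += (0.18 - spec.tissue_value) * _soft_mask(vent) * _soft_mask(brain)
    # a pair of off-center round structures giving curved internal edges
    for sx, r in ((-1.0, 0.060), (1.0, 0.045)):
        blob = _disc_sdf(
            spec.shape, (cy + 0.22 * h, cx + sx * 0.18 * w), r * min(h, w)
        )
        img += (0.55 - spec.tissue_value) * _soft_mask(blob) * _soft_mask(brain)

    # heterogeneity over the whole head, skull rim included: real bone and
    # tissue are textured, and perfectly clean synthetic edges would be
    # self-similar under tangential sliding in a way real images are not
    texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 2.0)
    texture /= max(np.abs(texture).max(), 1e-12)
    img += spec.texture_amplitude * texture * _soft_mask(skull)
    return np.clip(img, 0.0, 1.0)


def _check_lesion_inside(spec: PhantomSpec) -> None:
    assert spec.lesion is not None
    h, w = spec.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ly, lx = spec.lesion.center
    # lesion must sit strictly inside the brain ellipse
    margin = spec.lesion.radius
    r = np.sqrt(((ly - cy) / (0.40 * h)) ** 2 + ((lx - cx) / (0.36 * w)) ** 2)
    if r >= 1.0 - margin / (0.36 * min(h, w)):
        raise ValueError(
            f"lesion at {spec.lesion.center} radius {spec.lesion.radius} "
            "extends outside the skull"
        )


def make_phantom(spec: PhantomSpec):
    """Generate ``(normal, tumor, truth)`` for one phantom specification.

    ``normal`` and ``tumor`` are identical except for the planted lesion;
    ``truth`` is the sharp binary lesion support.  Identical specs give
    byte-identical arrays.
    """
    normal = _base_anatomy(spec)
    if spec.lesion is None:
        return normal, normal.copy(), np.zeros(spec.shape, dtype=bool)

    _check_lesion_inside(spec)
    les = spec.lesion
    sdf = _disc_sdf(spec.shape, les.center, les.radius)
    truth = sdf >= 0.0
    bump = _soft_mask(sdf, width=1.0)
    if les.blur_sigma > 0:
        bump = ndimage.gaussian_filter(bump, les.blur_sigma)
    tumor = np.clip(normal + les.contrast * bump, 0.0, 1.0)
    return normal, tumor, truth


def make_curvature_target(radius: float, shape=(256, 256)):
    """Anti-aliased bright disc plus its analytic boundary curvature 1/r.

    A disc of the given radius centred in the frame; the boundary curvature
    is ``1/radius`` (1/px) everywhere on the circle.  ``radius`` of
    ``np.inf`` produces a straight vertical edge (curvature 0).
    """
    h, w = shape
    if not np.isinf(radius) and radius < 4:
        raise ValueError("radius must be >= 4 px")
    if np.isinf(radius):
        x = np.arange(w, dtype=float)
        img = np.tile(_soft_mask(w / 2.0 - x, width=1.0), (h, 1))
        return 0.1 + 0.7 * img, 0.0
    sdf = _disc_sdf(shape, ((h - 1) / 2.0, (w - 1) / 2.0), radius)
    return 0.1 + 0.7 * _soft_mask(sdf, width=1.0), 1.0 / radius


def make_displacement_field(
    shape: Tuple[int, int],
    deform: DeformationSpec,
    seed: int,
    center: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Dense smooth displacement field (2, h, w) with peak |u| = max_displacement.

    The field is a blend of a seeded random smooth part and a radial
    mass-effect push away from ``center`` (the lesion, or the frame center
    when absent), with a Rayleigh-shaped radial profile so the push
    vanishes at the center and decays smoothly toward the frame edge.
    """
    h, w = shape
    g = deform.control_points
    spacing = min(h, w) / (g - 1)
    if deform.max_displacement >= spacing / 2.0:
        raise ValueError(
            f"max displacement {deform.max_displacement} px is not "
            f"diffeomorphic for control spacing {spacing:.1f} px"
        )
    rng = np.random.default_rng(seed)
    coarse = rng.standard_normal((2, g, g))
    field = np.stack(
        [ndimage.zoom(coarse[i], (h / g, w / g), order=3, mode="nearest") for i in range(2)]
    )
    # mass-effect deformation is globally smooth: a few control nodes and a
    # wide Gaussian keep the local stretch |grad u| small at realistic
    # amplitudes, so tissue patches translate rather than distort
    field = np.stack([ndimage.gaussian_filter(f, min(h, w) / 4.0) for f in field])
    mag = np.hypot(field[0], field[1]).max()
    if mag >= 1e-12:
        field /= mag

    frac = float(np.clip(deform.radial_fraction, 0.0, 1.0))
    if frac > 0:
        cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        dy, dx = yy - cy, xx - cx
        r = np.hypot(dy, dx)
        sigma = 0.35 * min(h, w)
        profile = (r / sigma) * np.exp(0.5 * (1.0 - (r / sigma) ** 2))  # peak 1 at r=sigma
        safe_r = np.maximum(r, 1e-9)
        radial = np.stack([profile * dy / safe_r, profile * dx / safe_r])
        field = (1.0 - frac) * field + frac * radial

    mag = np.hypot(field[0], field[1]).max()
    if mag < 1e-12:
        return np.zeros((2, h, w))
    return field * (deform.max_displacement / mag)


def warp_image(image: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Backward-warp: out(x) = image(x + u(x)), bilinear, border clamped."""
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(
        image, [yy + field[0], xx + field[1]], order=1, mode="nearest"
    )


def make_deformed_pair(spec: PhantomSpec):
    """``(fixed, moving, true_warp)`` where moving = fixed warped by true_warp.

    The convention matches the registration module: ``moving(x) =
    fixed(x + u(x))`` with ``u`` the returned field, so registering
    ``moving`` onto ``fixed`` should recover approximately ``u``... note the
    estimated warp maps moving back onto fixed.
    """
    if spec.deformation is None:
        raise ValueError("spec has no deformation")
    normal, tumor, _truth = make_phantom(spec)
    fixed = tumor if spec.lesion is not None else normal
    center = spec.lesion.center if spec.lesion is not None else None
    field = make_displacement_field(
        spec.shape, spec.deformation, spec.seed + 7919, center=center
    )
    if spec.deformation.max_displacement == 0.0:
        return fixed, fixed.copy(), np.zeros((2,) + spec.shape)
    moving = warp_image(fixed, field)
    return fixed, moving, field
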
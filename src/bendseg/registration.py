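"""Non-rigid registration driven by Bendlet coefficient features.

Feature points are local maxima of the per-scale Bendlet response (max
|coefficient| over cones, shears and bends) that persist across at least
two consecutive scales — points where some bending element agrees with
the local boundary geometry, which is exactly where the response is
large and scale-stable.  Each point carries a descriptor of pooled band
magnitudes at two scales; matches are mutual nearest neighbors passing a
Lowe-style ratio test in both directions, and the matched displacements
are densified to a full warp field by a regularized thin-plate spline.

The hemisphere use-case (registering one half of the brain onto the
mirrored other half) is served by ``mirror_hemisphere``: the midline is
taken as the vertical center column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator

from bendseg.bendlet import (
    BendletCoefficients,
    BendletSystem,
    bendlet_transform,
    build_bendlet_system,
)


class InsufficientMatchesError(RuntimeError):
    """Fewer than three usable matches: no warp can be estimated."""


@dataclass(frozen=True)
class FeaturePoint:
    location: Tuple[int, int]  # (y, x)
    scale_j: int
    response: float
    descriptor: np.ndarray

    def __post_init__(self):
        if self.response < 0:
            raise ValueError("response must be >= 0")


@dataclass(frozen=True)
class MatchPair:
    fixed_pt: FeaturePoint
    moving_pt: FeaturePoint
    score: float  # cosine similarity in [0, 1]

    @property
    def displacement(self) -> Tuple[float, float]:
        fy, fx = self.fixed_pt.location
        my, mx = self.moving_pt.location
        return (my - fy, mx - fx)


@dataclass
class WarpField:
    """Dense backward displacement (dy, dx) on the fixed grid, px."""

    displacement: np.ndarray  # (2, h, w)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.displacement.shape[1:]

    @classmethod
    def identity(cls, shape: Tuple[int, int]) -> "WarpField":
        return cls(np.zeros((2,) + tuple(shape)))


@dataclass(frozen=True)
class RegistrationConfig:
    n_scales: int = 3
    alpha: float = 0.5
    shear_grid: Optional[Tuple[float, ...]] = None
    bend_grid: Tuple[float, ...] = (0.0, 1 / 32, -1 / 32, 1 / 16, -1 / 16)
    threshold_quantile: float = 0.98
    ratio: float = 0.8
    stiffness: float = 100.0
    trim_threshold: float = 1.5  # px; drop matches deviating from the fit
    trim_rounds: int = 2
    border: int = 8  # ignore maxima this close to the frame edge
    search_radius: int = 10  # px; dense-matching search window half-size
    min_similarity: float = 0.8
    length0: Optional[float] = 16.0  # detection-oriented element size
    width0: Optional[float] = 4.0


def detect_features(
    coeffs: BendletCoefficients, threshold_quantile: float = 0.99, border: int = 8
) -> List[FeaturePoint]:
    """Scale-stable local maxima of the Bendlet response maps.

    Per scale, candidate points are 8-neighborhood local maxima of the
    max-over-(cone, shear, bend) magnitude map exceeding the given
    quantile of that map; a candidate is kept only if a candidate exists
    at the next (or previous) scale within 2 px.  Duplicates across
    scales within 2 px collapse to the strongest.  An empty list is a
    valid outcome (featureless image).
    """
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must lie in (0, 1)")
    sys_ = coeffs.system
    h, w = sys_.shape
    per_scale: List[np.ndarray] = []
    for j in range(sys_.n_scales):
        resp = coeffs.scale_response(j)
        if resp.max() <= 0:
            per_scale.append(np.empty((0, 2), dtype=int))
            continue
        thr = np.quantile(resp, threshold_quantile)
        if thr <= 0:
            per_scale.append(np.empty((0, 2), dtype=int))
            continue
        is_max = (ndimage.maximum_filter(resp, size=3) == resp) & (resp > thr)
        is_max[:border] = is_max[-border:] = False
        is_max[:, :border] = is_max[:, -border:] = False
        per_scale.append(np.argwhere(is_max))

    def has_near(pts: np.ndarray, p: np.ndarray, radius: float = 2.0) -> bool:
        if len(pts) == 0:
            return False
        return bool((np.abs(pts - p).max(axis=1) <= radius).any())

    kept: List[FeaturePoint] = []
    for j, pts in enumerate(per_scale):
        resp = coeffs.scale_response(j)
        for p in pts:
            stable = (j + 1 < sys_.n_scales and has_near(per_scale[j + 1], p)) or (
                j > 0 and has_near(per_scale[j - 1], p)
            )
            if not stable:
                continue
            kept.append(
                FeaturePoint(
                    location=(int(p[0]), int(p[1])),
                    scale_j=j,
                    response=float(resp[p[0], p[1]]),
                    descriptor=build_descriptor(coeffs, (int(p[0]), int(p[1])), j),
                )
            )
    # collapse cross-scale duplicates within 2 px, strongest response wins
    kept.sort(key=lambda f: -f.response)
    out: List[FeaturePoint] = []
    taken = np.empty((0, 2))
    for f in kept:
        p = np.array(f.location, dtype=float)
        if len(taken) and (np.abs(taken - p).max(axis=1) <= 2.0).any():
            continue
        out.append(f)
        taken = np.vstack([taken, p])
    return out


def build_descriptor(
    coeffs: BendletCoefficients, pt: Tuple[int, int], scale_j: int, window: int = 5
) -> np.ndarray:
    """Unit vector of band magnitudes around a point at two scales.

    Magnitudes of every (cone, shear, bend) band at scales {j, j+1} (or
    {j-1, j} at the finest scale) averaged over a window x window patch,
    mirror-padded at the frame border, then L2-normalized.
    """
    sys_ = coeffs.system
    h, w = sys_.shape
    y, x = pt
    if not (0 <= y < h and 0 <= x < w):
        raise ValueError(f"point {pt} outside image {sys_.shape}")
    j0 = min(scale_j, sys_.n_scales - 2) if sys_.n_scales > 1 else 0
    half = window // 2
    pad = np.abs(coeffs.values[:, j0 : j0 + 2])
    patch = pad[
        ...,
        max(0, y - half) : y + half + 1,
        max(0, x - half) : x + half + 1,
    ]
    vec = patch.mean(axis=(-2, -1)).ravel()
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


def match_features(
    fixed: Sequence[FeaturePoint],
    moving: Sequence[FeaturePoint],
    ratio: float = 0.8,
    max_displacement: Optional[float] = None,
) -> List[MatchPair]:
    """Mutual-nearest-neighbor descriptor matches with a two-sided ratio test.

    Pairs must be each other's nearest neighbor in descriptor space and
    pass the Lowe ratio test in both directions; the surviving pairs are
    kept greedily by descending similarity, each point used once.  The
    ratio test is what suppresses the aperture problem: points on a
    smooth edge have near-identical descriptors, so their best and
    second-best distances tie and the pair is discarded.  An optional
    ``max_displacement`` (px) restricts candidates to spatially plausible
    pairs.  Fewer than 3 pairs raises :class:`InsufficientMatchesError`.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    if len(fixed) == 0 or len(moving) == 0:
        raise InsufficientMatchesError("no features to match")
    A = np.stack([f.descriptor for f in fixed])
    B = np.stack([m.descriptor for m in moving])
    # unit descriptors: squared distance = 2 - 2 cos
    sim = A @ B.T
    d2 = np.maximum(2.0 - 2.0 * sim, 0.0)
    if max_displacement is not None:
        pf = np.array([f.location for f in fixed], dtype=float)
        pm = np.array([m.location for m in moving], dtype=float)
        dist = np.linalg.norm(pf[:, None, :] - pm[None, :, :], axis=2)
        d2 = np.where(dist <= max_displacement, d2, np.inf)

    def passes(d2row: np.ndarray, best: int) -> bool:
        finite = np.isfinite(d2row)
        if finite.sum() < 2:
            return bool(finite[best])
        second = np.partition(d2row[finite], 1)[1]
        return d2row[best] <= (ratio**2) * second

    pairs = []
    nn_ab = np.argmin(d2, axis=1)
    nn_ba = np.argmin(d2, axis=0)
    for i, j in enumerate(nn_ab):
        if nn_ba[j] != i or not np.isfinite(d2[i, j]):
            continue
        if not (passes(d2[i], j) and passes(d2[:, j], i)):
            continue
        pairs.append((float(np.clip(sim[i, j], 0.0, 1.0)), i, j))
    pairs.sort(key=lambda t: -t[0])
    used_i, used_j, out = set(), set(), []
    for s, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        out.append(MatchPair(fixed_pt=fixed[i], moving_pt=moving[j], score=s))
    if len(out) < 3:
        raise InsufficientMatchesError(f"only {len(out)} matches survived")
    return out


def _box_magnitudes(coeffs: BendletCoefficients, window: int) -> np.ndarray:
    """Window-averaged |coefficient| per band (sparse descriptor field)."""
    return ndimage.uniform_filter(
        np.abs(coeffs.values), size=(1, 1, 1, 1, window, window), mode="mirror"
    )


def _signed_field(coeffs: BendletCoefficients, sigma: float = 1.0) -> np.ndarray:
    """Signed coefficient field per band: dense-matching descriptors.

    Signed responses keep edge polarity and texture phase, which is what
    pins a match tangentially along an otherwise self-similar boundary;
    magnitudes alone are blind to position along an edge.
    """
    return ndimage.gaussian_filter(
        coeffs.values, sigma=(0, 0, 0, 0, sigma, sigma), mode="mirror"
    )


def match_features_dense(
    coeffs_fixed: BendletCoefficients,
    coeffs_moving: BendletCoefficients,
    features: Sequence[FeaturePoint],
    radius: int = 10,
    ratio: float = 0.8,
    window: int = 5,
    min_similarity: float = 0.8,
) -> List[MatchPair]:
    """Match fixed features against the moving descriptor field.

    For every fixed feature the descriptor is correlated with the moving
    descriptors at every offset within ``radius`` px; the best peak is
    accepted only if it beats the best peak outside its 2 px surroundings
    by the Lowe ratio (in descriptor distance), which rejects matches
    that slide along smooth edges (aperture ambiguity), and is refined to
    sub-pixel by a quadratic fit.  Matching against a dense field rather
    than detected points on the moving side removes the instability of
    edge maxima under deformation.
    """
    sys_ = coeffs_fixed.system
    h, w = sys_.shape
    n_scales = sys_.n_scales
    Bf = _signed_field(coeffs_fixed)
    Bm = _signed_field(coeffs_moving)
    matches: List[MatchPair] = []
    for f in features:
        y, x = int(f.location[0]), int(f.location[1])
        j0 = min(f.scale_j, n_scales - 2) if n_scales > 1 else 0
        df = Bf[:, j0 : j0 + 2, :, :, y, x].ravel()
        nf = np.linalg.norm(df)
        if nf <= 0:
            continue
        df = df / nf
        ys, ye = max(0, y - radius), min(h, y + radius + 1)
        xs, xe = max(0, x - radius), min(w, x + radius + 1)
        patch = Bm[:, j0 : j0 + 2, :, :, ys:ye, xs:xe]
        flat = patch.reshape(-1, patch.shape[-2], patch.shape[-1])
        norms = np.sqrt((flat**2).sum(axis=0))
        sim = np.einsum("d,dyx->yx", df, flat) / np.maximum(norms, 1e-300)
        py, px = np.unravel_index(np.argmax(sim), sim.shape)
        s_best = float(sim[py, px])
        if s_best < min_similarity:
            continue
        # reject peaks on the search border: the true peak may lie outside
        if py in (0, sim.shape[0] - 1) or px in (0, sim.shape[1] - 1):
            continue
        # Lowe margin against the best score away from the peak
        masked = sim.copy()
        masked[max(0, py - 2) : py + 3, max(0, px - 2) : px + 3] = -np.inf
        s_second = float(masked.max())
        d_best = max(2.0 - 2.0 * s_best, 0.0)
        d_second = max(2.0 - 2.0 * s_second, 0.0)
        if np.isfinite(s_second) and d_best > (ratio**2) * d_second:
            continue
        # sub-pixel quadratic refinement along each axis; an exact peak
        # (perfect correlation, e.g. self-matching) stays on the grid
        dy = dx = 0.0
        if s_best >= 1.0 - 1e-12:
            qy, qx = float(ys + py), float(xs + px)
            moving_pt = FeaturePoint((qy, qx), j0, s_best, df)
            matches.append(MatchPair(fixed_pt=f, moving_pt=moving_pt, score=1.0))
            continue
        denom_y = sim[py - 1, px] - 2 * sim[py, px] + sim[py + 1, px]
        if denom_y < -1e-12:
            dy = float(np.clip(0.5 * (sim[py - 1, px] - sim[py + 1, px]) / denom_y, -0.5, 0.5))
        denom_x = sim[py, px - 1] - 2 * sim[py, px] + sim[py, px + 1]
        if denom_x < -1e-12:
            dx = float(np.clip(0.5 * (sim[py, px - 1] - sim[py, px + 1]) / denom_x, -0.5, 0.5))
        qy, qx = ys + py + dy, xs + px + dx
        moving_pt = FeaturePoint(
            location=(qy, qx),
            scale_j=j0,
            response=s_best,
            descriptor=df,
        )
        matches.append(MatchPair(fixed_pt=f, moving_pt=moving_pt, score=float(np.clip(s_best, 0, 1))))
    if len(matches) < 3:
        raise InsufficientMatchesError(f"only {len(matches)} dense matches survived")
    return matches


def estimate_warp(
    matches: Sequence[MatchPair], shape: Tuple[int, int], stiffness: float = 1.0
) -> WarpField:
    """Thin-plate-spline densification of matched displacements.

    ``stiffness`` is the TPS smoothing parameter (0 interpolates the
    matches exactly; larger values trade fidelity for smoothness).
    Collinear control points cannot determine the affine part and raise
    ``ValueError``.
    """
    if len(matches) < 3:
        raise InsufficientMatchesError("need at least 3 matches for a warp")
    pts = np.array([m.fixed_pt.location for m in matches], dtype=float)
    disp = np.array([m.displacement for m in matches], dtype=float)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("control points are collinear; the warp is degenerate")
    rbf = RBFInterpolator(
        pts, disp, kernel="thin_plate_spline", smoothing=float(stiffness)
    )
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    dense = rbf(grid).T.reshape(2, h, w)
    return WarpField(displacement=dense)


def apply_warp(image: np.ndarray, warp: WarpField) -> np.ndarray:
    """Backward warping out(x) = image(x + u(x)); bilinear, border clamped."""
    if image.shape != warp.shape:
        raise ValueError(f"image {image.shape} vs warp {warp.shape}")
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(
        image,
        [yy + warp.displacement[0], xx + warp.displacement[1]],
        order=1,
        mode="nearest",
    )


@dataclass
class RegistrationResult:
    warped: np.ndarray
    warp: WarpField
    matches: List[MatchPair]
    n_matches: int
    mean_residual: float  # mean match displacement after warping, px


def register(
    fixed: np.ndarray,
    moving: np.ndarray,
    config: RegistrationConfig = RegistrationConfig(),
    system: Optional[BendletSystem] = None,
) -> RegistrationResult:
    """Full pipeline: detect, describe, match, fit TPS, warp.

    The reported ``mean_residual`` re-detects and re-matches features
    between the fixed image and the warped moving image; on a successful
    registration it is the mean remaining feature displacement in px.
    """
    if fixed.shape != moving.shape:
        raise ValueError(f"image shapes differ: {fixed.shape} vs {moving.shape}")
    if system is None:
        system = build_bendlet_system(
            fixed.shape,
            n_scales=config.n_scales,
            shear_grid=config.shear_grid,
            bend_grid=config.bend_grid,
            alpha=config.alpha,
            length0=config.length0,
            width0=config.width0,
        )
    cf = bendlet_transform(fixed, system)
    cm = bendlet_transform(moving, system)
    f_pts = detect_features(cf, config.threshold_quantile, config.border)
    matches = match_features_dense(
        cf,
        cm,
        f_pts,
        radius=config.search_radius,
        ratio=config.ratio,
        min_similarity=config.min_similarity,
    )
    # robust refit: matches that disagree with the smooth field (content
    # differences such as the lesion itself, or residual slides) are
    # dropped and the spline refit
    warp = estimate_warp(matches, fixed.shape, config.stiffness)
    for _ in range(max(0, config.trim_rounds)):
        resid = np.array(
            [
                np.linalg.norm(
                    np.asarray(m.displacement)
                    - warp.displacement[
                        :, int(m.fixed_pt.location[0]), int(m.fixed_pt.location[1])
                    ]
                )
                for m in matches
            ]
        )
        thr = max(config.trim_threshold, 3.0 * float(np.median(resid)))
        keep = resid <= thr
        if keep.all() or keep.sum() < 6:
            break
        matches = [m for m, k in zip(matches, keep) if k]
        warp = estimate_warp(matches, fixed.shape, config.stiffness)
    warped = apply_warp(moving, warp)

    cw = bendlet_transform(warped, system)
    try:
        post = match_features_dense(
            cf,
            cw,
            f_pts,
            radius=config.search_radius,
            ratio=config.ratio,
            min_similarity=config.min_similarity,
        )
        residual = float(np.mean([np.hypot(*m.displacement) for m in post]))
    except InsufficientMatchesError:
        residual = float("nan")
    return RegistrationResult(
        warped=warped,
        warp=warp,
        matches=matches,
        n_matches=len(matches),
        mean_residual=residual,
    )


def mirror_hemisphere(image: np.ndarray) -> np.ndarray:
    """Mirror the image about the vertical center column (midline)."""
    return image[:, ::-1].copy()
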
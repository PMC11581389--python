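"""Tabular-to-image transformation.

Each clinical feature is embedded as one point on a 2D plane and frozen there;
every patient is then rendered as a grayscale image whose pixel intensities
are that patient's (min-max normalised) feature values. The embedding treats
features as points in patient-space: the training matrix is transposed, a
Gaussian-kernel PCA of the 28 feature columns gives 2D coordinates, the convex
hull and minimum-area enclosing rectangle frame the layout, the frame is
rotated to landscape, and feature coordinates are mapped onto a pixel grid.
The whole chain is deterministic and fitted on training patients only; test
patients reuse the frozen layout.

The hull and rotating-calipers rectangle are implemented here rather than
delegated: the layout contract (vertex order, tie-breaks, angle normalisation)
is part of the transform's reproducibility guarantee.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "NormalizationParams",
    "FeatureLayout",
    "PatientImage",
    "fit_normalization",
    "apply_normalization",
    "median_heuristic_sigma",
    "kpca_embed_features",
    "convex_hull",
    "min_area_rect",
    "rasterize_layout",
    "render_image",
    "TableToImageTransformer",
    "EmbeddingError",
]


class EmbeddingError(ValueError):
    """Kernel PCA could not produce two positive-eigenvalue components."""


# --------------------------------------------------------------------------
# normalisation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature (min, max) learned on training rows only."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in normalization params")


def fit_normalization(train_values: np.ndarray) -> NormalizationParams:
    """Learn per-feature min/max from the training matrix."""
    x = np.asarray(train_values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("normalization requires complete (imputed) data")
    return NormalizationParams(mins=x.min(axis=0), maxs=x.max(axis=0))


def apply_normalization(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map x -> (x - min) / (max - min), clipping test values into [0, 1].

    Features constant on the training set map to 0 (background-valued).
    """
    x = np.asarray(values, dtype=float)
    span = params.maxs - params.mins
    out = np.zeros_like(x)
    nonconst = span > 0
    out[:, nonconst] = (x[:, nonconst] - params.mins[nonconst]) / span[nonconst]
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# kernel-PCA feature embedding
# --------------------------------------------------------------------------

def median_heuristic_sigma(feature_points: np.ndarray) -> float:
    """Median pairwise Euclidean distance among feature points (scale-free
    default kernel width)."""
    from scipy.spatial.distance import pdist

    d = pdist(feature_points)
    med = float(np.median(d))
    if med <= 0:
        return 1.0
    return med


def kpca_embed_features(
    normalized_train: np.ndarray, sigma: float | None = None
) -> tuple[np.ndarray, float]:
    """Embed the feature columns of an ``n x p`` normalised matrix into 2D.

    Each feature is a point in patient-space (a column of the matrix, i.e. a
    row of its transpose). The Gaussian kernel
    ``K_ij = exp(-||f_i - f_j||^2 / (2 sigma^2))`` is double-centered and
    eigendecomposed; the returned ``p x 2`` scores are the top-2 eigenvectors
    scaled by sqrt(eigenvalue). Sign convention: the largest-magnitude entry
    of each component is positive, so layouts are reproducible.
    """
    x = np.asarray(normalized_train, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 patients to embed features")
    points = x.T  # p feature points in patient-space
    if sigma is None:
        sigma = median_heuristic_sigma(points)
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    sq = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    kernel = np.exp(-sq / (2.0 * sigma**2))
    p = kernel.shape[0]
    centerer = np.eye(p) - np.full((p, p), 1.0 / p)
    kc = centerer @ kernel @ centerer
    eigval, eigvec = np.linalg.eigh(kc)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[1] <= 1e-12:
        raise EmbeddingError(
            "fewer than 2 positive kernel eigenvalues; try a larger sigma"
        )
    scores = eigvec[:, :2] * np.sqrt(eigval[:2])
    for k in range(2):
        j = int(np.argmax(np.abs(scores[:, k])))
        if scores[j, k] < 0:
            scores[:, k] = -scores[:, k]
    return scores, float(sigma)


# --------------------------------------------------------------------------
# geometry: convex hull and minimum-area rectangle
# --------------------------------------------------------------------------

def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull via the monotone chain, counter-clockwise.

    Collinear points interior to an edge are excluded; the vertex list starts
    at the lexicographically smallest vertex. A fully collinear input returns
    the two extreme points (degenerate hull, handled by ``min_area_rect``).
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 2 or (len(points) >= 1 and len(pts) == 1):
        raise ValueError("hull needs at least 2 distinct points")
    # np.unique sorts lexicographically by (x, y)
    if len(pts) == 2:
        return pts

    def half(seq: np.ndarray) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for p in seq:
            while len(out) >= 2 and _cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(pts)
    upper = half(pts[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) == 2:  # all collinear: two extreme points, degenerate hull
        return np.array([pts[0], pts[-1]])
    return hull


def min_area_rect(hull: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Minimum-area enclosing rectangle of a convex hull (rotating calipers).

    Returns ``(center, width, height, angle_degrees)`` where ``width`` is the
    extent along the rectangle's ``angle`` direction. The optimum is flush
    with a hull edge; the angle is normalised to [0, 90) and ties in area
    break toward the smallest angle. A 2-point degenerate hull yields a
    zero-height rectangle along the segment.
    """
    pts = np.asarray(hull, dtype=float)
    edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    edges = edges[lengths > 1e-15]
    if len(edges) == 0:
        raise ValueError("degenerate hull with no extent")

    best: tuple[float, float] | None = None  # (area, angle_rad)
    best_geom: tuple[tuple[float, float], float, float, float] | None = None
    seen: set[float] = set()
    for e in edges:
        theta = np.arctan2(e[1], e[0]) % (np.pi / 2.0)  # rectangle has 90deg symmetry
        key = round(float(theta), 12)
        if key in seen:
            continue
        seen.add(key)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, s], [-s, c]])  # rotate by -theta
        proj = pts @ rot.T
        lo, hi = proj.min(axis=0), proj.max(axis=0)
        w, h = float(hi[0] - lo[0]), float(hi[1] - lo[1])
        area = w * h
        cand = (area, float(theta))
        if best is None or cand < (best[0] - 1e-12, best[1]) or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
        ):
            center_rot = (lo + hi) / 2.0
            center = rot.T @ center_rot
            best = cand
            best_geom = ((float(center[0]), float(center[1])), w, h,
                         float(np.degrees(theta)))
    assert best_geom is not None
    return best_geom


# --------------------------------------------------------------------------
# rasterisation and rendering
# --------------------------------------------------------------------------

def _landscape_rotation(rect) -> tuple[np.ndarray, float, float]:
    """Rotation matrix sending the rectangle's longer side horizontal, plus
    the horizontal/vertical extents after rotation."""
    (cx, cy), w, h, angle = rect
    theta = np.radians(angle)
    if h > w:  # rotate the perpendicular side to horizontal instead
        theta += np.pi / 2.0
        w, h = h, w
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    return rot, w, h


def rasterize_layout(
    coords: np.ndarray, rect, grid: tuple[int, int]
) -> tuple[np.ndarray, list[list[int]]]:
    """Map feature coordinates onto a pixel grid inside the rotated rectangle.

    Rotates coordinates so the rectangle's longer side is horizontal, then
    affinely maps the rectangle onto ``grid = (rows, cols)``; pixels are the
    floor of the scaled coordinate with boundary points clamped inside. The
    top image row corresponds to the largest rotated y. Features sharing a
    pixel form one collision group.
    """
    rows, cols = grid
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    rot, w, h = _landscape_rotation(rect)
    rotated = np.asarray(coords, dtype=float) @ rot.T
    lo = rotated.min(axis=0)
    span_x = w if w > 0 else 1.0
    span_y = h if h > 0 else 1.0
    col = np.floor((rotated[:, 0] - lo[0]) / span_x * cols).astype(int)
    row = np.floor((rotated[:, 1] - lo[1]) / span_y * rows).astype(int)
    col = np.clip(col, 0, cols - 1)
    # flip vertically: larger rotated y -> smaller row index (origin top-left)
    row = rows - 1 - np.clip(row, 0, rows - 1)
    pixel_of_feature = np.column_stack([row, col])

    groups: dict[tuple[int, int], list[int]] = {}
    for j, (r, c) in enumerate(pixel_of_feature):
        groups.setdefault((int(r), int(c)), []).append(j)
    collision_groups = [sorted(g) for g in groups.values()]
    return pixel_of_feature, collision_groups


@dataclass
class FeatureLayout:
    """Frozen train-set artifact: feature coordinates, frame and pixel map."""

    coords: np.ndarray  # (p, 2)
    kernel_sigma: float
    hull: np.ndarray  # (m, 2), counter-clockwise
    rect: tuple  # ((cx, cy), width, height, angle_degrees)
    grid: tuple[int, int]
    pixel_of_feature: np.ndarray  # (p, 2) int (row, col), 0-based, origin top-left
    collision_groups: list[list[int]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coords": self.coords.tolist(),
            "kernel_sigma": self.kernel_sigma,
            "hull": self.hull.tolist(),
            "rect": {
                "center": list(self.rect[0]),
                "width": self.rect[1],
                "height": self.rect[2],
                "angle_degrees": self.rect[3],
            },
            "grid": list(self.grid),
            "pixel_of_feature": self.pixel_of_feature.tolist(),
            "collision_groups": self.collision_groups,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureLayout":
        d = json.loads(Path(path).read_text())
        rect = (
            tuple(d["rect"]["center"]),
            d["rect"]["width"],
            d["rect"]["height"],
            d["rect"]["angle_degrees"],
        )
        return cls(
            coords=np.asarray(d["coords"]),
            kernel_sigma=d["kernel_sigma"],
            hull=np.asarray(d["hull"]),
            rect=rect,
            grid=tuple(d["grid"]),
            pixel_of_feature=np.asarray(d["pixel_of_feature"], dtype=int),
            collision_groups=[list(g) for g in d["collision_groups"]],
        )


@dataclass(frozen=True)
class PatientImage:
    """Rasterised per-patient grayscale image; background pixels are exactly 0."""

    pixels: np.ndarray  # (rows, cols) in [0, 1]
    patient_id: str = ""

    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        arr = np.round(self.pixels * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)


def render_image(
    patient_row: np.ndarray, layout: FeatureLayout, patient_id: str = ""
) -> PatientImage:
    """Render one patient: each feature's pixel takes its normalised value;
    features colliding on a pixel contribute their arithmetic mean."""
    values = np.asarray(patient_row, dtype=float)
    rows, cols = layout.grid
    img = np.zeros((rows, cols))
    for group in layout.collision_groups:
        r, c = layout.pixel_of_feature[group[0]]
        img[r, c] = values[group].mean()
    return PatientImage(pixels=img, patient_id=patient_id)


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class TableToImageTransformer(TransformerMixin, BaseEstimator):
    """Fit a 2D feature layout on training patients; render patients as images.

    Parameters
    ----------
    grid : (rows, cols) pixel resolution of the rendered image, default (50, 50).
    sigma : Gaussian kernel width for the feature embedding; None selects the
        median pairwise distance among feature points (median heuristic).

    Attributes
    ----------
    norm_params_ : per-feature training min/max.
    layout_ : frozen :class:`FeatureLayout` reused verbatim at transform time.
    """

    def __init__(self, grid: tuple[int, int] = (50, 50), sigma: float | None = None):
        self.grid = grid
        self.sigma = sigma

    def fit(self, X, y=None) -> "TableToImageTransformer":
        X = check_array(X, dtype=float)
        self.norm_params_ = fit_normalization(X)
        normalized = apply_normalization(X, self.norm_params_)
        coords, sigma = kpca_embed_features(normalized, self.sigma)
        hull = convex_hull(coords)
        rect = min_area_rect(hull)
        pixel_of_feature, groups = rasterize_layout(coords, rect, tuple(self.grid))
        self.layout_ = FeatureLayout(
            coords=coords,
            kernel_sigma=sigma,
            hull=hull,
            rect=rect,
            grid=tuple(self.grid),
            pixel_of_feature=pixel_of_feature,
            collision_groups=groups,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Render each row as an image; returns ``(n, rows, cols)`` in [0, 1]."""
        check_is_fitted(self, "layout_")
        X = check_array(X, dtype=float)
        normalized = apply_normalization(X, self.norm_params_)
        return np.stack(
            [render_image(row, self.layout_).pixels for row in normalized]
        )
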
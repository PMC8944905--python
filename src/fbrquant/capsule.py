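"""Edge-aligned quantification of the foreign-body-reaction capsule.

The capsule around an implanted nerve is traced by hand as a closed contour
on the alpha-smooth-muscle-actin (aSMA) channel. Alignment across irregular
capsule shapes is achieved by reparameterizing each pixel by its depth: the
Euclidean distance to the nearest point of the traced edge. Intensity
profiles, near-edge means and capsule thickness are all computed in this
depth coordinate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

from .types import Contour, DepthMap, IntensityProfile, ThicknessResult

__all__ = [
    "compute_depth_map",
    "intensity_profile",
    "near_edge_mean",
    "normalize_to_control",
    "capsule_thickness",
    "profile_group_summary",
]


def _segment_distances(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Exact minimum distance from each point to a closed polyline.

    ``points`` is (n, 2); ``vertices`` is (m, 2) interpreted as a closed
    ring. Vectorized point-to-segment distance, chunked over points to
    bound memory.
    """
    a = vertices
    b = np.roll(vertices, -1, axis=0)
    ab = b - a  # (m, 2)
    ab_len2 = np.einsum("ij,ij->i", ab, ab)
    ab_len2 = np.where(ab_len2 == 0, 1.0, ab_len2)  # degenerate segments

    out = np.empty(len(points))
    chunk = max(1, int(4e6 // max(len(a), 1)))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]  # (c, 2)
        ap = p[:, None, :] - a[None, :, :]  # (c, m, 2)
        t = np.clip(np.einsum("cmj,mj->cm", ap, ab) / ab_len2, 0.0, 1.0)
        diff = ap - t[:, :, None] * ab[None, :, :]
        d2 = np.einsum("cmj,cmj->cm", diff, diff)
        out[s : s + chunk] = np.sqrt(d2.min(axis=1))
    return out


def compute_depth_map(image_shape: tuple[int, int], contour: Contour) -> DepthMap:
    """Per-pixel depth (um) inward from the traced contour.

    For every pixel whose center lies inside the polygon, depth is the exact
    Euclidean distance to the nearest point of the polygon boundary,
    converted to micrometres; pixels outside are NaN.
    """
    h, w = image_shape
    poly = contour.polygon  # validates simplicity via Contour invariants
    minx, miny, maxx, maxy = poly.bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise ValueError(
            f"contour extends outside the image: bounds {poly.bounds} vs shape {image_shape}"
        )

    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = shapely.points(xs.ravel(), ys.ravel())
    inside = shapely.covers(poly, pts)  # boundary pixels count as inside, depth 0

    depth = np.full(h * w, np.nan)
    coords = np.column_stack([xs.ravel()[inside], ys.ravel()[inside]])
    if len(coords):
        depth[inside] = _segment_distances(coords, contour.vertices) * contour.pixel_size_um
    return DepthMap(depth_um=depth.reshape(h, w), pixel_size_um=contour.pixel_size_um)


def intensity_profile(
    image: np.ndarray,
    depth_map: DepthMap,
    bin_width_um: float = 1.0,
    max_depth_um: float | None = None,
    stain_name: str = "",
    subject_id: str = "",
    group_label: str = "",
) -> IntensityProfile:
    """Mean intensity per depth bin: bin b covers depths [b*w, (b+1)*w).

    Empty bins yield NaN means, never zero. Pixel counts are reported so
    that group summaries can weight or audit bins.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != depth_map.shape:
        raise ValueError(f"image shape {image.shape} != depth map shape {depth_map.shape}")
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")

    depth = depth_map.depth_um
    valid = np.isfinite(depth)
    d = depth[valid]
    vals = image[valid]
    if max_depth_um is None:
        max_depth_um = float(d.max()) + bin_width_um if d.size else bin_width_um
    n_bins = int(np.ceil(max_depth_um / bin_width_um))
    keep = d < n_bins * bin_width_um
    idx = np.floor(d[keep] / bin_width_um).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins + 1) * bin_width_um
    return IntensityProfile(
        bin_edges_um=edges,
        mean_intensity=means,
        pixel_count=counts,
        stain_name=stain_name,
        subject_id=subject_id,
        group_label=group_label,
    )


def near_edge_mean(image: np.ndarray, depth_map: DepthMap, window_um: float = 25.0) -> float:
    """Pixel-weighted mean intensity over all pixels with depth <= window.

    This is a region mean over the near-edge band (25 um by default; 50 um
    is used for the macrophage marker CD68, which locates deeper), not an
    average of binned means.
    """
    if window_um <= 0:
        raise ValueError("window_um must be positive")
    image = np.asarray(image, dtype=float)
    if image.shape != depth_map.shape:
        raise ValueError("image and depth map shapes differ")
    sel = depth_map.depth_um <= window_um  # NaN compares False
    if not sel.any():
        raise ValueError(f"no pixels within {window_um} um of the contour (degenerate contour)")
    return float(image[sel].mean())


def normalize_to_control(per_subject_means: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Append a ``ratio`` column: each value divided by the control-group mean.

    Expects columns ``subject``, ``group``, ``value``. The control group's
    ratios average to exactly 1.
    """
    df = per_subject_means.copy()
    for col in ("subject", "group", "value"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    ctrl = df.loc[df["group"] == control_group, "value"]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} has no subjects")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean == 0:
        raise ValueError("control-group mean intensity is zero; cannot normalize")
    df["ratio"] = df["value"] / ctrl_mean
    return df


def capsule_thickness(
    outer: Contour,
    inner: Contour,
    n_positions: int = 360,
    subject_id: str = "",
    group_label: str = "",
) -> ThicknessResult:
    """Capsule thickness sampled along the outer contour.

    At ``n_positions`` points uniformly spaced by arc length along the outer
    contour, thickness is the distance to the nearest point of the inner
    contour. The per-sample mean is the subject-level value used for group
    statistics (one value per mouse).
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if outer.pixel_size_um != inner.pixel_size_um:
        raise ValueError("outer and inner contours have different pixel sizes")
    outer_poly = outer.polygon
    inner_poly = inner.polygon
    if not outer_poly.contains(inner_poly) or outer_poly.exterior.intersects(inner_poly.exterior):
        raise ValueError("inner contour must lie strictly inside the outer contour")

    ring = outer_poly.exterior
    inner_ring = inner_poly.exterior
    fracs = np.arange(n_positions) / n_positions
    thick = np.array(
        [ring.interpolate(f, normalized=True).distance(inner_ring) for f in fracs]
    )
    return ThicknessResult(
        per_position_thickness_um=thick * outer.pixel_size_um,
        subject_id=subject_id,
        group_label=group_label,
    )


def profile_group_summary(profiles: list[IntensityProfile]) -> pd.DataFrame:
    """Across-subject mean and SD of profiles, per group and depth bin.

    Subject-level summary: each profile contributes one value per bin. SD is
    the sample standard deviation (ddof=1); a single-subject group reports 0.
    Profiles must share bin edges.
    """
    if not profiles:
        raise ValueError("no profiles given")
    edges = profiles[0].bin_edges_um
    for p in profiles[1:]:
        if len(p.bin_edges_um) != len(edges) or not np.allclose(p.bin_edges_um, edges):
            raise ValueError("profiles have mismatched bin edges")

    rows = []
    for p in profiles:
        for b in range(len(edges) - 1):
            rows.append(
                {
                    "group": p.group_label,
                    "subject": p.subject_id,
                    "depth_bin_um": edges[b],
                    "mean_intensity": p.mean_intensity[b],
                }
            )
    long = pd.DataFrame(rows)
    out = (
        long.groupby(["group", "depth_bin_um"])["mean_intensity"]
        .agg(
            mean="mean",
            sd=lambda v: float(np.std(v.dropna(), ddof=1)) if v.dropna().size > 1 else 0.0,
            n_subjects=lambda v: int(v.dropna().size),
        )
        .reset_index()
    )
    return out
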
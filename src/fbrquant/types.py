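"""Core value types shared across the pipeline stages.

Conventions: pixel centers sit at integer coordinates, origin at the
top-left of the image, x increasing rightward (columns), y increasing
downward (rows). All indices are 0-based. Physical lengths are carried in
micrometres alongside a ``pixel_size_um`` scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

__all__ = [
    "Contour",
    "AnnotatedImage",
    "DepthMap",
    "IntensityProfile",
    "ThicknessResult",
    "SampleBox",
    "PhantomSpec",
    "ExpressionTruth",
]


@dataclass
class Contour:
    """Closed polygon traced on an image, e.g. the hand-marked capsule edge.

    ``vertices`` is an (n, 2) float array of (x, y) pixel coordinates; the
    polygon is implicitly closed (last vertex connects back to the first).
    """

    vertices: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("contour vertices must be an (n, 2) array of (x, y)")
        if len(v) < 3:
            raise ValueError(f"contour needs at least 3 vertices, got {len(v)}")
        self.vertices = v
        ring = shapely.LinearRing(v)
        if not ring.is_simple:
            raise ValueError("contour is self-intersecting")
        poly = shapely.Polygon(v)
        if poly.area <= 0:
            raise ValueError("contour encloses no area")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def perimeter_um(self) -> float:
        return self.polygon.exterior.length * self.pixel_size_um

    def area_um2(self) -> float:
        return self.polygon.area * self.pixel_size_um**2


@dataclass
class AnnotatedImage:
    """A set of single-channel grayscale images sharing one pixel grid.

    ``channels`` maps stain name (e.g. "asma", "dapi", "b3tubulin", "cd68")
    to a 2-D array. ``truth`` optionally carries the generating phantom
    parameters for synthetic images.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    truth: dict | None = None

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class DepthMap:
    """Per-pixel Euclidean distance (um) inward from a traced contour.

    ``depth_um`` holds NaN outside the contour; inside, the distance to the
    nearest point of the polygon boundary.
    """

    depth_um: np.ndarray
    pixel_size_um: float

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True for pixels inside the contour."""
        return np.isfinite(self.depth_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth_um.shape


@dataclass
class IntensityProfile:
    """Mean stain intensity per depth bin for one subject/stain."""

    bin_edges_um: np.ndarray  # length n_bins + 1, monotone
    mean_intensity: np.ndarray  # NaN where the bin is empty
    pixel_count: np.ndarray
    stain_name: str = ""
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_um, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.mean_intensity) != len(edges) - 1:
            raise ValueError("mean_intensity length must be n_bins")
        if np.any(np.asarray(self.pixel_count) < 0):
            raise ValueError("pixel counts must be non-negative")


@dataclass
class ThicknessResult:
    """Capsule thickness sampled along the outer contour for one subject."""

    per_position_thickness_um: np.ndarray
    subject_id: str = ""
    group_label: str = ""
    per_sample_mean_um: float = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.per_position_thickness_um, dtype=float)
        if np.any(t < 0):
            raise ValueError("thickness values must be non-negative")
        self.per_position_thickness_um = t
        self.per_sample_mean_um = float(t.mean())


@dataclass(frozen=True)
class SampleBox:
    """Square counting frame; ``x``, ``y`` are the top-left pixel indices."""

    x: int
    y: int
    side_px: int
    side_um: float
    box_id: int = 0

    def __post_init__(self) -> None:
        if self.side_px <= 0 or self.side_um <= 0:
            raise ValueError("box side must be positive")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.side_px), slice(self.x, self.x + self.side_px)

    @property
    def area_mm2(self) -> float:
        return (self.side_um / 1000.0) ** 2


@dataclass
class PhantomSpec:
    """Parameters of the synthetic nerve cross-section phantom.

    The phantom emulates a circular nerve disk with an annular myofibroblast
    capsule at its edge: capsule stain intensity decays exponentially with
    depth from the outer edge over ``capsule_thickness_um``; axon puncta and
    nuclei speckle are placed uniformly inside the inner boundary.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    nerve_center_px: tuple[float, float] | None = None  # defaults to image center
    nerve_radius_um: float = 200.0
    capsule_thickness_um: float = 40.0
    capsule_peak_intensity: float = 20000.0
    intensity_decay_um: float = 15.0
    axon_density_per_mm2: float = 800.0
    axon_spot_radius_um: float = 1.5
    axon_spot_intensity: float = 20000.0
    nuclei_density_per_mm2: float = 2000.0
    nuclei_spot_radius_um: float = 2.5
    nuclei_spot_intensity: float = 15000.0
    noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nerve_center_px is None:
            h, w = self.image_size_px
            self.nerve_center_px = ((w - 1) / 2.0, (h - 1) / 2.0)
        for name in (
            "pixel_size_um",
            "nerve_radius_um",
            "capsule_thickness_um",
            "intensity_decay_um",
            "axon_spot_radius_um",
            "nuclei_spot_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.capsule_thickness_um >= self.nerve_radius_um:
            raise ValueError(
                "capsule_thickness_um must be smaller than nerve_radius_um "
                f"({self.capsule_thickness_um} >= {self.nerve_radius_um})"
            )
        if self.axon_density_per_mm2 < 0 or self.nuclei_density_per_mm2 < 0:
            raise ValueError("densities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ExpressionTruth:
    """Ground truth recorded by the expression-side generators."""

    fractions: "object | None" = None  # pandas DataFrame, samples x types
    de_genes: set[str] = field(default_factory=set)
    log2fc_true: "object | None" = None  # pandas Series per gene
    size_factors_true: "object | None" = None  # pandas Series per sample
    ddct_true: "object | None" = None  # pandas DataFrame for qPCR truth
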
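"""Synthetic ground-truth generators for every pipeline stage.

The image phantom emulates a nerve cross-section as seen in stained
confocal sections: a circular nerve disk whose edge carries an annular
myofibroblast capsule (aSMA channel, intensity decaying exponentially with
depth from the edge), axonal puncta (beta-3-tubulin channel) placed
uniformly at a known density, and nuclei speckle (DAPI channel). Expression
generators produce signature/mixture pairs for deconvolution,
negative-binomial count matrices with known size factors and fold changes,
and qPCR Ct tables with known delta-delta-Ct.

Every generator is deterministic under its integer seed; sub-streams are
derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .types import AnnotatedImage, Contour, ExpressionTruth, PhantomSpec

__all__ = [
    "DEFAULT_FINE_TYPES",
    "DEFAULT_GROUPING",
    "generate_nerve_phantom",
    "generate_signature_and_mixtures",
    "generate_count_matrix",
    "generate_ct_table",
]

# 25 hematopoietic fine types grouped into the six major immune lineages.
DEFAULT_GROUPING: dict[str, str] = {
    "neutrophil": "granulocytes",
    "eosinophil": "granulocytes",
    "basophil": "granulocytes",
    "mast_cell": "granulocytes",
    "pro_b": "B cells",
    "pre_b": "B cells",
    "immature_b": "B cells",
    "mature_b": "B cells",
    "plasma_cell": "B cells",
    "cd4_naive": "T cells",
    "cd4_memory": "T cells",
    "cd8_naive": "T cells",
    "cd8_memory": "T cells",
    "treg": "T cells",
    "gamma_delta_t": "T cells",
    "nk_resting": "NK cells",
    "nk_activated": "NK cells",
    "cdc1": "dendritic cells",
    "cdc2": "dendritic cells",
    "pdc": "dendritic cells",
    "classical_monocyte": "mono/macrophages",
    "nonclassical_monocyte": "mono/macrophages",
    "m0_macrophage": "mono/macrophages",
    "m1_macrophage": "mono/macrophages",
    "m2_macrophage": "mono/macrophages",
}
DEFAULT_FINE_TYPES: list[str] = list(DEFAULT_GROUPING)


def _circle_contour(
    center: tuple[float, float], radius_px: float, pixel_size_um: float, n_vertices: int = 256
) -> Contour:
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    verts = np.column_stack(
        [center[0] + radius_px * np.cos(theta), center[1] + radius_px * np.sin(theta)]
    )
    return Contour(vertices=verts, pixel_size_um=pixel_size_um)


def _place_disjoint_points(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    radius_px: float,
    min_sep_px: float,
    max_tries: int = 200_000,
) -> np.ndarray:
    """Uniform points in a disk, rejection-sampled to pairwise min separation."""
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} disjoint points of separation {min_sep_px}px "
                f"in a disk of radius {radius_px}px"
            )
        r = radius_px * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        x, y = center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep_px**2 for px, py in pts):
            pts.append((x, y))
    return np.array(pts).reshape(n, 2)


def _render_spots(
    shape: tuple[int, int], centers: np.ndarray, radius_px: float, intensity: float
) -> np.ndarray:
    img = np.zeros(shape)
    for x, y in centers:
        rr, cc = draw_disk((y, x), radius_px, shape=shape)
        img[rr, cc] += intensity
    return img


def generate_nerve_phantom(
    spec: PhantomSpec,
) -> tuple[AnnotatedImage, Contour, Contour, dict]:
    """Render the nerve phantom and return its exact capsule contours.

    Returns ``(image, outer_contour, inner_contour, truth)``. The aSMA
    channel is ``peak * exp(-depth / decay)`` for depth within the capsule
    thickness and zero beyond; axon puncta are pairwise-disjoint disks
    placed uniformly inside the inner boundary so that ground-truth counts
    are unambiguous. Identical specs (same seed) give bitwise-identical
    output.
    """
    h, w = spec.image_size_px
    px = spec.pixel_size_um
    cx, cy = spec.nerve_center_px
    r_outer_px = spec.nerve_radius_um / px
    r_inner_px = (spec.nerve_radius_um - spec.capsule_thickness_um) / px

    ss = np.random.SeedSequence(spec.seed)
    rng_axon, rng_nuclei, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    r_px = np.hypot(xs - cx, ys - cy)
    depth_um = (r_outer_px - r_px) * px  # radial depth from the outer edge
    inside = depth_um >= 0

    capsule = np.where(
        inside & (depth_um <= spec.capsule_thickness_um),
        spec.capsule_peak_intensity * np.exp(-np.maximum(depth_um, 0) / spec.intensity_decay_um),
        0.0,
    )

    def _spot_channel(rng, density, spot_r_um, intensity):
        spot_r_px = spot_r_um / px
        r_center_px = r_inner_px - spot_r_px  # spots fully inside the inner boundary
        if density <= 0 or r_center_px <= 0:
            return np.zeros((h, w)), np.empty((0, 2)), 0.0
        area_mm2 = np.pi * (r_center_px * px / 1000.0) ** 2
        n = int(round(density * area_mm2))
        centers = _place_disjoint_points(
            rng, n, (cx, cy), r_center_px, min_sep_px=2 * spot_r_px + 2.0
        )
        return _render_spots((h, w), centers, spot_r_px, intensity), centers, area_mm2

    axon_img, axon_centers, axon_area_mm2 = _spot_channel(
        rng_axon, spec.axon_density_per_mm2, spec.axon_spot_radius_um, spec.axon_spot_intensity
    )
    nuc_img, nuc_centers, nuc_area_mm2 = _spot_channel(
        rng_nuclei,
        spec.nuclei_density_per_mm2,
        spec.nuclei_spot_radius_um,
        spec.nuclei_spot_intensity,
    )

    channels = {"asma": capsule, "b3tubulin": axon_img, "dapi": nuc_img}
    if spec.noise_sd > 0:
        for name in channels:
            noisy = channels[name] + rng_noise.normal(0, spec.noise_sd, size=(h, w))
            channels[name] = np.clip(noisy, 0, None)

    truth = {
        "spec": spec,
        "n_axons": len(axon_centers),
        "axon_centers_px": axon_centers,
        "axon_center_area_mm2": axon_area_mm2,
        "axon_density_realized_per_mm2": (
            len(axon_centers) / axon_area_mm2 if axon_area_mm2 > 0 else 0.0
        ),
        "n_nuclei": len(nuc_centers),
        "nuclei_centers_px": nuc_centers,
        "outer_radius_um": spec.nerve_radius_um,
        "inner_radius_um": spec.nerve_radius_um - spec.capsule_thickness_um,
    }
    image = AnnotatedImage(channels=channels, pixel_size_um=px, truth=truth)
    outer = _circle_contour((cx, cy), r_outer_px, px)
    inner = _circle_contour((cx, cy), r_inner_px, px)
    return image, outer, inner, truth


def generate_signature_and_mixtures(
    n_genes: int = 500,
    n_types: int = 25,
    n_samples: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
    fractions: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Signature matrix, mixed bulk profiles, and the true mixing fractions.

    Fractions are drawn from a flat Dirichlet over the cell types (unless
    given explicitly); mixtures are ``signature @ fractions`` plus Gaussian
    noise, clipped at zero. Each type receives a block of boosted marker
    genes so the signature has full column rank.
    """
    if n_genes < n_types:
        raise ValueError(f"underdetermined: n_genes={n_genes} < n_types={n_types}")
    rng = np.random.default_rng(seed)
    if n_types == len(DEFAULT_FINE_TYPES):
        type_names = DEFAULT_FINE_TYPES
    else:
        type_names = [f"type_{i:02d}" for i in range(n_types)]
    gene_names = [f"gene_{i:04d}" for i in range(n_genes)]

    sig = rng.lognormal(mean=2.0, sigma=1.0, size=(n_genes, n_types))
    for t in range(n_types):  # marker blocks: strong, nearly type-exclusive genes
        markers = np.arange(t, n_genes, n_types)
        sig[markers, :] *= 0.2
        sig[markers, t] *= 50.0
    signature = pd.DataFrame(sig, index=gene_names, columns=type_names)

    if fractions is None:
        frac = rng.dirichlet(np.ones(n_types), size=n_samples)
    else:
        frac = np.asarray(fractions, dtype=float)
        if frac.shape != (n_samples, n_types):
            raise ValueError(f"fractions must have shape ({n_samples}, {n_types})")
    sample_names = [f"sample_{i:02d}" for i in range(n_samples)]
    mix = sig @ frac.T
    if noise_sd > 0:
        mix = np.clip(mix + rng.normal(0, noise_sd, size=mix.shape), 0, None)
    mixtures = pd.DataFrame(mix, index=gene_names, columns=sample_names)
    truth = ExpressionTruth(
        fractions=pd.DataFrame(frac, index=sample_names, columns=type_names)
    )
    return signature, mixtures, truth


def generate_count_matrix(
    n_genes: int = 2000,
    groups: dict[str, int] | None = None,
    de_fraction: float = 0.0,
    lfc_sd: float = 1.0,
    dispersion: float = 0.1,
    size_factor_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
    lfc_fixed: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Negative-binomial counts with known size factors and fold changes.

    ``groups`` maps group label to sample count (first label is the
    reference). A fraction ``de_fraction`` of genes receives a true log2
    fold change in every non-reference group: drawn N(0, lfc_sd), or exactly
    ``+/-lfc_fixed`` with random sign when given. Counts have variance
    ``mu + dispersion * mu^2``. Returns (counts, metadata, truth).
    """
    if groups is None:
        groups = {"control": 6, "treated": 6}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(n < 3 for n in groups.values()):
        raise ValueError("need at least 3 samples per group")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)

    gene_names = [f"gene_{i:04d}" for i in range(n_genes)]
    labels = [g for g, n in groups.items() for _ in range(n)]
    sample_names = [f"{g}_{i}" for g, n in groups.items() for i in range(n)]
    ref_group = next(iter(groups))

    base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfc = np.zeros(n_genes)
    if n_de:
        if lfc_fixed is not None:
            lfc[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * lfc_fixed
        else:
            lfc[de_idx] = rng.normal(0, lfc_sd, size=n_de)

    lo, hi = size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(labels)))

    mu = np.empty((n_genes, len(labels)))
    for j, g in enumerate(labels):
        fold = 2.0 ** lfc if g != ref_group else 1.0
        mu[:, j] = sf[j] * base_mean * fold
    nb_n = 1.0 / dispersion  # numpy's (n, p) parameterization
    counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))

    counts_df = pd.DataFrame(counts, index=gene_names, columns=sample_names)
    meta = pd.DataFrame(
        {"group": labels, "day": 28, "RIN": 8.0}, index=pd.Index(sample_names, name="sample")
    )
    truth = ExpressionTruth(
        de_genes={gene_names[i] for i in de_idx},
        log2fc_true=pd.Series(lfc, index=gene_names),
        size_factors_true=pd.Series(sf, index=sample_names),
    )
    return counts_df, meta, truth


def generate_ct_table(
    genes: list[str],
    groups: dict[str, int],
    housekeeping_gene: str = "Gapdh",
    ddct_true: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    ct_sd: float = 0.0,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Tidy qPCR Ct table with known delta-delta-Ct per gene and group.

    ``groups`` maps group label to replicate count; the first label is the
    reference group. ``ddct_true[gene][group]`` is the true ddCt relative to
    the reference (missing entries are 0; the housekeeping gene is 0 by
    construction). Per-sample machine offsets are included so downstream
    delta-Ct computation must cancel them. In the noiseless case the
    downstream relative quantification equals ``2**(-ddct_true)`` exactly.
    """
    if housekeeping_gene in (ddct_true or {}):
        raise ValueError("housekeeping gene must have zero ddCt by construction")
    rng = np.random.default_rng(seed)
    ref_group = next(iter(groups))
    ddct_true = ddct_true or {}

    base_dct = {g: 3.0 + 0.5 * i for i, g in enumerate(genes)}  # gene-specific dCt offset
    rows = []
    for group, n_rep in groups.items():
        for rep in range(n_rep):
            sample = f"{group}_{rep}"
            hk_ct = 18.0 + rng.uniform(-1.0, 1.0)  # per-sample machine offset
            rows.append({"sample": sample, "group": group, "gene": housekeeping_gene, "ct": hk_ct})
            for gene in genes:
                ddct = ddct_true.get(gene, {}).get(group, 0.0) if group != ref_group else 0.0
                ct = hk_ct + base_dct[gene] + ddct
                if ct_sd > 0:
                    ct += rng.normal(0, ct_sd)
                rows.append({"sample": sample, "group": group, "gene": gene, "ct": ct})
    table = pd.DataFrame(rows)
    ddct_frame = pd.DataFrame(
        {g: {grp: (ddct_true.get(g, {}).get(grp, 0.0) if grp != ref_group else 0.0)
             for grp in groups} for g in genes}
    )
    truth = ExpressionTruth(ddct_true=ddct_frame)
    return table, truth
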
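"""Run configuration and end-to-end orchestration of the pipeline stages.

A run is driven by a :class:`RunConfig` (round-trippable through YAML).
Stages execute in dependency order, write tidy CSV outputs into the run
directory, and contribute to a JSON summary that records every parameter
and seed, so identical configurations give identical summaries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.draw import polygon2mask

from . import axons as ax
from . import capsule as cq
from . import deconv as dc
from . import expression as ex
from . import io as fio
from . import stats as st
from .synthetic import (
    DEFAULT_GROUPING,
    generate_count_matrix,
    generate_ct_table,
    generate_nerve_phantom,
    generate_signature_and_mixtures,
)
from .types import PhantomSpec

__all__ = ["RunConfig", "run_pipeline", "generate_demo_inputs"]

ALL_STAGES = ("capsule", "axons", "expr", "deconv", "rq", "stats")


@dataclass
class RunConfig:
    out_dir: str = "fbrquant_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    manifest_path: str | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    signature_path: str | None = None
    mixtures_path: str | None = None
    grouping_path: str | None = None
    ct_path: str | None = None
    control_group: str = "NI"
    housekeeping_gene: str = "Gapdh"
    window_um: float = 25.0
    bin_um: float = 1.0
    n_thickness_positions: int = 360
    n_boxes: int = 3
    box_side_um: float = 100.0
    min_area_px: int = 4
    rin_threshold: float = 3.0
    fc_min: float = 2.0
    base_min: float = 3.0
    padj_max: float = 0.01
    top_k_genes: int = 500
    dunnett_mc_draws: int = 100_000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {ALL_STAGES}")
        if self.window_um <= 0 or self.bin_um <= 0 or self.box_side_um <= 0:
            raise ValueError("window_um, bin_um and box_side_um must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _contour_mask(shape, contour) -> np.ndarray:
    # polygon2mask wants (row, col) vertex order
    return polygon2mask(shape, contour.vertices[:, ::-1])


def _stage_capsule(cfg: RunConfig, out: Path) -> dict:
    manifest = fio.read_manifest(cfg.manifest_path)
    rows = manifest[manifest["stain"] == "asma"]
    edge_rows, profiles, thick_rows = [], [], []
    for _, r in rows.iterrows():
        img = fio.read_image(r["image_path"], pixel_size_um=r["pixel_size_um"])
        chan = next(iter(img.channels.values()))
        outer = fio.read_contour(r["outer_contour_path"], pixel_size_um=r["pixel_size_um"])
        dm = cq.compute_depth_map(chan.shape, outer)
        prof = cq.intensity_profile(
            chan, dm, bin_width_um=cfg.bin_um, stain_name="asma",
            subject_id=str(r["subject_id"]), group_label=str(r["group"]),
        )
        profiles.append(prof)
        edge_rows.append(
            {
                "subject": r["subject_id"],
                "group": r["group"],
                "value": cq.near_edge_mean(chan, dm, window_um=cfg.window_um),
            }
        )
        if "inner_contour_path" in r and pd.notna(r.get("inner_contour_path")):
            inner = fio.read_contour(r["inner_contour_path"], pixel_size_um=r["pixel_size_um"])
            res = cq.capsule_thickness(
                outer, inner, n_positions=cfg.n_thickness_positions,
                subject_id=str(r["subject_id"]), group_label=str(r["group"]),
            )
            thick_rows.append(
                {"subject": r["subject_id"], "group": r["group"],
                 "thickness_um": res.per_sample_mean_um}
            )

    edge = cq.normalize_to_control(pd.DataFrame(edge_rows), cfg.control_group)
    edge.to_csv(out / "near_edge_intensity.csv", index=False)
    prof_long = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject": p.subject_id,
                    "group": p.group_label,
                    "depth_bin_um": p.bin_edges_um[:-1],
                    "mean_intensity": p.mean_intensity,
                    "pixel_count": p.pixel_count,
                }
            )
            for p in profiles
        ]
    )
    prof_long.to_csv(out / "intensity_profiles.csv", index=False)
    # group summary needs shared bin edges: truncate to the shortest profile
    n_common = min(len(p.mean_intensity) for p in profiles)
    from .types import IntensityProfile

    trimmed = [
        IntensityProfile(
            bin_edges_um=p.bin_edges_um[: n_common + 1],
            mean_intensity=p.mean_intensity[:n_common],
            pixel_count=p.pixel_count[:n_common],
            stain_name=p.stain_name, subject_id=p.subject_id, group_label=p.group_label,
        )
        for p in profiles
    ]
    cq.profile_group_summary(trimmed).to_csv(out / "profile_group_summary.csv", index=False)
    summary = {"n_subjects": len(edge_rows), "n_profile_bins_common": int(n_common)}
    if thick_rows:
        tdf = pd.DataFrame(thick_rows)
        tdf.to_csv(out / "capsule_thickness.csv", index=False)
        summary["thickness_group_means_um"] = {
            g: round(float(v), 6) for g, v in tdf.groupby("group")["thickness_um"].mean().items()
        }
    return summary


def _stage_axons(cfg: RunConfig, out: Path) -> dict:
    manifest = fio.read_manifest(cfg.manifest_path)
    rows = manifest[manifest["stain"] == "b3tubulin"]
    per_box_rows = []
    for i, (_, r) in enumerate(rows.iterrows()):
        img = fio.read_image(r["image_path"], pixel_size_um=r["pixel_size_um"])
        chan = next(iter(img.channels.values()))
        region = fio.read_contour(r["region_contour_path"], pixel_size_um=r["pixel_size_um"])
        mask = _contour_mask(chan.shape, region)
        boxes = ax.sample_boxes(
            mask, side_um=cfg.box_side_um, n_boxes=cfg.n_boxes,
            pixel_size_um=r["pixel_size_um"], seed=cfg.seed + i,
        )
        per_box, img_mean = ax.axon_density(
            chan, boxes, pixel_size_um=r["pixel_size_um"], min_area_px=cfg.min_area_px
        )
        per_box["subject"] = r["subject_id"]
        per_box["group"] = r["group"]
        per_box["image_id"] = r.get("image_id", r["image_path"])
        per_box_rows.append(per_box)
    per_box_all = pd.concat(per_box_rows, ignore_index=True)
    per_box_all.to_csv(out / "axon_per_box.csv", index=False)
    per_mouse = ax.density_table(per_box_all)
    per_mouse = per_mouse.merge(
        per_box_all[["subject", "group"]].drop_duplicates(), on="subject"
    )
    per_mouse.to_csv(out / "axon_per_mouse.csv", index=False)
    return {
        "n_images": int(len(rows)),
        "density_group_means_per_mm2": {
            g: round(float(v), 6)
            for g, v in per_mouse.groupby("group")["density_per_mm2"].mean().items()
        },
    }


def _stage_expr(cfg: RunConfig, out: Path) -> dict:
    counts = fio.read_counts(cfg.counts_path)
    meta = fio.read_metadata(cfg.metadata_path)
    kept = ex.filter_samples_by_rin(meta, threshold=cfg.rin_threshold) if "RIN" in meta else list(meta.index)
    counts = counts[[s for s in counts.columns if s in kept]]
    meta = meta.loc[counts.columns]
    sf = ex.size_factors(counts)
    norm = ex.normalize_counts(counts, sf)
    sf.to_csv(out / "size_factors.csv")

    groups = meta["group"]
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("expression stage needs at least two groups")
    ref = cfg.control_group if cfg.control_group in levels else levels[0]
    other = [g for g in levels if g != ref][0]
    records = ex.de_test(norm, groups, group_a=ref, group_b=other)
    records.to_csv(out / "deg_table.csv")
    degs = ex.deg_filter(records, fc_min=cfg.fc_min, base_min=cfg.base_min, padj_max=cfg.padj_max)
    pd.Series(degs, name="gene").to_csv(out / "deg_passing.csv", index=False)

    k = min(cfg.top_k_genes, len(norm))
    top = ex.top_k_variable_genes(norm, k=k)
    logm = np.log2(norm.loc[top] + 1.0)
    scores, evf = ex.pca_scores(logm, n_components=min(5, len(norm.columns) - 1))
    scores.to_csv(out / "pca_scores.csv")
    return {
        "n_samples_kept": int(len(counts.columns)),
        "n_deg": int(len(degs)),
        "comparison": f"{other} vs {ref}",
        "pc1_variance_fraction": round(float(evf[0]), 6),
    }


def _stage_deconv(cfg: RunConfig, out: Path) -> dict:
    signature = fio.read_signature(cfg.signature_path)
    mixtures = fio.read_counts(cfg.mixtures_path)
    res = dc.deconvolve(mixtures, signature)
    res.fractions.to_csv(out / "fractions_fine.csv")
    grouping = (
        fio.read_grouping(cfg.grouping_path) if cfg.grouping_path else DEFAULT_GROUPING
    )
    if all(t in grouping for t in res.fractions.columns):
        dc.aggregate_fractions(res.fractions, grouping).to_csv(out / "fractions_major.csv")
    return {
        "n_samples": int(len(res.fractions)),
        "n_genes_used": res.n_genes_used,
        "mean_residual_norm": round(float(res.residual_norm.mean()), 6),
    }


def _stage_rq(cfg: RunConfig, out: Path) -> dict:
    ct = fio.read_ct(cfg.ct_path)
    ref_group = cfg.control_group if cfg.control_group in set(ct["group"]) else ct["group"].iloc[0]
    rq = ex.compute_rq(ct, housekeeping_gene=cfg.housekeeping_gene, reference_group=ref_group)
    rq.to_csv(out / "rq_table.csv", index=False)
    return {"n_gene_group_pairs": int(len(rq)), "n_significant": int(rq["significant"].sum())}


def _stage_stats(cfg: RunConfig, out: Path) -> dict:
    """Group comparison on the subject-level capsule-thickness values."""
    path = out / "capsule_thickness.csv"
    if not path.exists():
        raise ValueError("stats stage requires the capsule stage's thickness output")
    tdf = pd.read_csv(path)
    levels = list(pd.unique(tdf["group"]))
    results: dict = {}
    if len(levels) == 2:
        a = tdf.loc[tdf["group"] == levels[0], "thickness_um"]
        b = tdf.loc[tdf["group"] == levels[1], "thickness_um"]
        t, p = st.t_test(a, b)
        results["thickness_t_test"] = {"t": round(t, 6), "p": round(p, 6)}
    else:
        aov = st.one_way_anova(tdf["thickness_um"], tdf["group"])
        results["thickness_anova"] = {"F": round(aov.f_statistic, 6), "p": round(aov.p_value, 6)}
        ctrl = cfg.control_group if cfg.control_group in levels else levels[0]
        dn = st.dunnett_test(
            tdf["thickness_um"], tdf["group"], control=ctrl,
            mc_draws=cfg.dunnett_mc_draws, seed=cfg.seed,
        )
        dn.to_csv(out / "dunnett_thickness.csv", index=False)
        results["thickness_dunnett_min_p"] = round(float(dn["p_adjusted"].min()), 6)
    with open(out / "stats_results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    return results


_STAGE_FUNCS = {
    "capsule": _stage_capsule,
    "axons": _stage_axons,
    "expr": _stage_expr,
    "deconv": _stage_deconv,
    "rq": _stage_rq,
    "stats": _stage_stats,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write the JSON run summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(cfg), "stages": {}}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            summary["stages"][stage] = _STAGE_FUNCS[stage](cfg, out)
        except (ValueError, FileNotFoundError, TypeError) as e:
            raise ValueError(f"stage {stage!r} failed: {e}") from e
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def generate_demo_inputs(data_dir: str | Path, seed: int = 0) -> RunConfig:
    """Write a complete synthetic input set and a matching RunConfig.

    Two groups of three mice each: a no-drug control ("NI") with a thick
    capsule and a drug-treated group with a thinner one, plus count, Ct,
    and signature/mixture tables — enough to exercise every stage in well
    under a minute.
    """
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    thickness = {"NI": 40.0, "drug": 18.0}
    jitter_rng = np.random.default_rng(seed)
    manifest_rows = []
    for gi, (group, thick) in enumerate(thickness.items()):
        for s in range(3):
            subj = f"{group}_m{s}"
            spec = PhantomSpec(
                image_size_px=(320, 320),
                nerve_radius_um=130.0,
                capsule_thickness_um=thick + jitter_rng.normal(0, 2.0),  # mouse-to-mouse spread
                axon_density_per_mm2=800.0,
                nuclei_density_per_mm2=1500.0,
                noise_sd=30.0,
                seed=seed * 1000 + gi * 100 + s,
            )
            img, outer, inner, _truth = generate_nerve_phantom(spec)
            paths = {}
            for chan_name, chan in img.channels.items():
                p = data_dir / f"{subj}_{chan_name}.tif"
                fio.write_image(p, chan)
                paths[chan_name] = p.name
            outer_p, inner_p = f"{subj}_outer.csv", f"{subj}_inner.csv"
            fio.write_contour(data_dir / outer_p, outer)
            fio.write_contour(data_dir / inner_p, inner)
            manifest_rows.append(
                {
                    "subject_id": subj, "group": group, "stain": "asma",
                    "image_path": paths["asma"], "outer_contour_path": outer_p,
                    "inner_contour_path": inner_p, "region_contour_path": inner_p,
                    "image_id": f"{subj}_sec0", "pixel_size_um": 1.0,
                }
            )
            manifest_rows.append(
                {
                    "subject_id": subj, "group": group, "stain": "b3tubulin",
                    "image_path": paths["b3tubulin"], "outer_contour_path": outer_p,
                    "inner_contour_path": inner_p, "region_contour_path": inner_p,
                    "image_id": f"{subj}_sec0", "pixel_size_um": 1.0,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(data_dir / "manifest.tsv", sep="\t", index=False)

    counts, meta, _ = generate_count_matrix(
        n_genes=800, groups={"NI": 4, "drug": 4}, de_fraction=0.1,
        lfc_fixed=2.0, dispersion=0.05, seed=seed + 17,
    )
    fio.write_counts(data_dir / "counts.tsv", counts)
    meta.to_csv(data_dir / "metadata.tsv", sep="\t")

    signature, mixtures, _ = generate_signature_and_mixtures(
        n_genes=150, n_types=25, n_samples=4, noise_sd=0.5, seed=seed + 29
    )
    signature.rename_axis("gene").to_csv(data_dir / "signature.tsv", sep="\t")
    fio.write_counts(data_dir / "mixtures.tsv", mixtures)
    pd.DataFrame(
        {"fine_type": list(DEFAULT_GROUPING), "major_type": list(DEFAULT_GROUPING.values())}
    ).to_csv(data_dir / "grouping.tsv", sep="\t", index=False)

    ct, _ = generate_ct_table(
        genes=["Il1b", "Nlrp3", "Tnf"], groups={"NI": 4, "drug": 4},
        ddct_true={"Il1b": {"drug": 1.5}, "Nlrp3": {"drug": 1.0}},
        seed=seed + 41, ct_sd=0.1,
    )
    fio.write_ct(data_dir / "ct.csv", ct)

    return RunConfig(
        out_dir=str(data_dir / "results"),
        seed=seed,
        manifest_path=str(data_dir / "manifest.tsv"),
        counts_path=str(data_dir / "counts.tsv"),
        metadata_path=str(data_dir / "metadata.tsv"),
        signature_path=str(data_dir / "signature.tsv"),
        mixtures_path=str(data_dir / "mixtures.tsv"),
        grouping_path=str(data_dir / "grouping.tsv"),
        ct_path=str(data_dir / "ct.csv"),
        control_group="NI",
    )
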
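"""End-to-end orchestration: VBM contrasts, severity-sequenced CaSCN with
conjunction, ROI network, synthetic demo and report.

All stages operate on in-memory cohorts (a volume stack, a subject table, a
mask); the CLI layer handles files. Every run is reproducible from the
config and its random seed, and the report records the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .cascn import (
    conjunction,
    covariate_matrix,
    order_by_severity,
    regress_covariates,
    voxelwise_cascn,
)
from .maps import StatMap
from .network import export_network, extract_rois, roiwise_cascn
from .random_field import estimate_smoothness, grf_cluster_correct
from .vbm import (
    HY_SCHEME,
    UPDRS_SCHEME,
    assign_stage,
    build_design,
    demographics_table,
    fit_group_glm,
    homogeneity_qc,
    scale_consistency,
    stack_volumes,
    t_to_z,
)
from .volumes import GMVolume, make_sphere_roi, save_volume

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_vbm", "run_cascn", "demo", "recovery_metrics"]


@dataclass
class PipelineConfig:
    """All analysis parameters; defaults are the shipped conventions
    (seed sphere at (-17, -3, 20) mm radius 5, voxel p = .001 / z > 3.09,
    cluster alpha .05, AR order 1, 18-connectivity, one-tailed atrophy
    contrast)."""

    seed_center: tuple = (-17.0, -3.0, 20.0)
    seed_radius: float = 5.0
    seed_from_vbm: bool = False
    ar_order: int = 1
    height_p: float = 0.001
    cluster_alpha: float = 0.05
    connectivity: int = 18
    contrast_tail: str = "hc_gt_pd"
    roi_min_size: int = 10
    roi_alpha: float = 0.05
    tie_break_rule: str = "other_scale,duration,subject_id"
    random_seed: int = 0
    volumes_dir: str | None = None
    subject_table: str | None = None
    mask_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("height_p", "cluster_alpha", "roi_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.seed_radius < 0:
            raise ValueError("seed_radius must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seed_center"] = list(d["seed_center"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed_center" in data:
            data["seed_center"] = tuple(data["seed_center"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _glm_contrast(vol_stack, mask, affine, table, config):
    design = build_design(table, contrast_tail=config.contrast_tail)
    tmap, resid = fit_group_glm(vol_stack, mask, design, affine=affine)
    zmap = t_to_z(tmap)
    smooth = estimate_smoothness(resid, mask, zmap.voxel_size)
    clusters = grf_cluster_correct(
        zmap, smooth, height_p=config.height_p,
        cluster_alpha=config.cluster_alpha, connectivity=config.connectivity,
    )
    return {"zmap": zmap, "clusters": clusters, "smoothness": smooth,
            "n_per_group": (int((table["group"].str.upper() == "PD").sum()),
                            int((table["group"].str.upper() == "HC").sum()))}


def run_vbm(volumes, table, mask, config: PipelineConfig, affine=None) -> dict:
    """All VBM contrasts: overall PD-vs-HC, the three H&Y and three
    UPDRS-III stage contrasts, and the dementia split (MoCA < 21).

    A subgroup with fewer than 2 subjects is skipped with a warning.
    Returns ``{contrast_name: {"zmap", "clusters", "smoothness", ...}}``.
    """
    if isinstance(volumes, np.ndarray):
        stack = volumes
        if affine is None:
            raise ValueError("affine required with array input")
    else:
        stack, affine = stack_volumes(volumes)
    mask = np.asarray(mask, dtype=bool)
    table = table.reset_index(drop=True)
    is_pd = table["group"].astype(str).str.upper() == "PD"
    hc_idx = np.flatnonzero(~is_pd)

    results = {}
    results["overall"] = _glm_contrast(stack, mask, affine, table, config)

    for scheme in (HY_SCHEME, UPDRS_SCHEME):
        scored = table[scheme.score].notna() & is_pd
        stages = pd.Series(index=table.index, dtype=object)
        for i in table.index[scored]:
            stages[i] = assign_stage(table.loc[i], scheme)
        for label in scheme.labels:
            sub_idx = np.flatnonzero(stages == label)
            name = f"{scheme.name.lower()}_{label.lower().replace(' ', '_')}"
            if len(sub_idx) < 2:
                logger.warning("skipping %s: only %d subjects", name, len(sub_idx))
                continue
            rows = np.concatenate([sub_idx, hc_idx])
            results[name] = _glm_contrast(
                stack[rows], mask, affine, table.iloc[rows], config
            )
            results[name]["n_stage"] = len(sub_idx)

    # dementia split within PD (MoCA screening cutoff 21)
    if "moca" in table.columns:
        has_moca = is_pd & table["moca"].notna()
        dem = has_moca & (table["moca"] < 21)
        nod = has_moca & (table["moca"] >= 21)
        if dem.sum() >= 2 and nod.sum() >= 2:
            sub = table[has_moca].copy()
            # reuse the two-group GLM: dementia plays the "PD" role
            sub["group"] = np.where(sub["moca"] < 21, "PD", "HC")
            rows = np.flatnonzero(has_moca)
            results["dementia"] = _glm_contrast(
                stack[rows], mask, affine, sub, config
            )
            results["dementia"]["n_per_group"] = (int(dem.sum()), int(nod.sum()))
        else:
            logger.warning(
                "skipping dementia contrast: %d vs %d subjects",
                int(dem.sum()), int(nod.sum()),
            )
    return results


def _seed_center(config, vbm_zmap: StatMap | None):
    if not config.seed_from_vbm:
        return np.asarray(config.seed_center, dtype=float)
    if vbm_zmap is None:
        raise ValueError("seed_from_vbm=True requires the overall VBM z map")
    vals = np.where(vbm_zmap.mask, vbm_zmap.values, -np.inf)
    peak = np.unravel_index(np.argmax(vals), vals.shape)
    world = vbm_zmap.affine[:3, :3] @ np.asarray(peak, float) + vbm_zmap.affine[:3, 3]
    logger.info("seed recomputed from VBM peak at %s mm", np.round(world, 1))
    return world


def _null_smoothness(stack, table, mask, affine):
    """Intrinsic (null) smoothness of the GM data for GC-map cluster
    inference.

    Estimated from covariate-residualized maps of subjects carrying no
    disease-progression signal (HC when available, otherwise all subjects):
    patient residuals contain the severity-driven atrophy pattern, which is
    structured at region scale and would inflate the estimate.
    """
    is_hc = table["group"].astype(str).str.upper() == "HC"
    rows = np.flatnonzero(is_hc) if is_hc.sum() >= 8 else np.arange(len(table))
    sub = table.iloc[rows]
    sex = (sub["sex"].astype(str).str.lower() == "male").astype(float).to_numpy()
    C = np.column_stack([np.ones(len(sub)), sex, sub["age"].to_numpy(float),
                         sub["tiv"].to_numpy(float)])
    resid_flat = regress_covariates(stack[rows][:, mask], C)
    resid = np.zeros((len(rows), *mask.shape))
    resid[:, mask] = resid_flat
    voxel_size = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    return estimate_smoothness(resid, mask, voxel_size)


def run_cascn(
    volumes,
    table,
    mask,
    config: PipelineConfig,
    affine=None,
    vbm_zmap: StatMap | None = None,
) -> dict:
    """Voxel-wise CaSCN under both severity orderings, conjunction, ROI
    extraction and the ROI-wise directed network.

    Returns a dict with per-ordering GC maps, cluster tables and surviving
    masks, the conjunction mask, the ROI set (or None if the conjunction is
    empty) and per-ordering ROI networks.
    """
    if isinstance(volumes, np.ndarray):
        stack = volumes
        if affine is None:
            raise ValueError("affine required with array input")
    else:
        stack, affine = stack_volumes(volumes)
    mask = np.asarray(mask, dtype=bool)
    table = table.reset_index(drop=True)
    id_to_row = {sid: i for i, sid in enumerate(table["subject_id"])}

    center = _seed_center(config, vbm_zmap)
    seed_roi = make_sphere_roi(center, config.seed_radius, affine, mask.shape,
                               mask=mask)

    out = {"seed_center_mm": [float(c) for c in center],
           "seed_n_voxels": seed_roi.n_voxels, "orderings": {}}
    smooth = _null_smoothness(stack, table, mask, affine)
    ordered_stacks = {}
    covariates = {}
    for score in ("HY", "UPDRS3"):
        ordering = order_by_severity(table, score=score)
        rows = [id_to_row[s] for s in ordering.subject_ids]
        sub_stack = stack[rows]
        cov = covariate_matrix(table, ordering)
        ordered_stacks[score] = sub_stack
        covariates[score] = cov
        idx = tuple(seed_roi.voxel_indices.T)
        seed_series = sub_stack[(slice(None), *idx)].mean(axis=1)
        gcmap = voxelwise_cascn(
            seed_series, sub_stack, mask, affine, order=config.ar_order,
            covariates=cov,
        )
        zmap = StatMap(values=gcmap.zscored, mask=mask, affine=affine, kind="gc_z")
        clusters = grf_cluster_correct(
            zmap, smooth, height_p=config.height_p,
            cluster_alpha=config.cluster_alpha, connectivity=config.connectivity,
        )
        out["orderings"][score] = {
            "ordering": ordering,
            "gcmap": gcmap,
            "clusters": clusters,
            "surviving_mask": clusters.surviving_mask(),
        }
    out["smoothness"] = smooth

    conj = conjunction(
        out["orderings"]["HY"]["surviving_mask"],
        out["orderings"]["UPDRS3"]["surviving_mask"],
    )
    out["conjunction_mask"] = conj

    mean_z = 0.5 * (
        out["orderings"]["HY"]["gcmap"].zscored
        + out["orderings"]["UPDRS3"]["gcmap"].zscored
    )
    out["networks"] = {}
    if conj.any():
        try:
            rois = extract_rois(conj, affine, min_size=config.roi_min_size,
                                connectivity=config.connectivity, stat=mean_z)
        except ValueError as exc:
            logger.warning("ROI extraction: %s", exc)
            rois = None
    else:
        logger.warning("empty conjunction mask: no ROI network")
        rois = None
    out["rois"] = rois
    if rois is not None and len(rois.names) >= 2:
        for score in ("HY", "UPDRS3"):
            out["networks"][score] = roiwise_cascn(
                rois, ordered_stacks[score], covariates=covariates[score],
                order=config.ar_order, alpha=config.roi_alpha,
            )
    return out


def recovery_metrics(conjunction_mask: np.ndarray, truth) -> dict:
    """Overlap of the conjunction mask with true downstream and decoy
    regions of a synthetic cohort."""
    targets = [d for _, d, _, _ in truth.true_edges]
    decoys = [n for n in truth.region_masks
              if n not in targets and n != truth.seed_region]
    hit = {n: bool((conjunction_mask & truth.region_masks[n]).any())
           for n in targets}
    decoy_hit = {n: bool((conjunction_mask & truth.region_masks[n]).any())
                 for n in decoys}
    return {
        "true_regions": targets,
        "true_hits": hit,
        "n_true_hit": sum(hit.values()),
        "n_true": len(targets),
        "decoy_hits": decoy_hit,
        "n_decoy_hit": sum(decoy_hit.values()),
        "n_decoys": len(decoys),
    }


def _cluster_md(clusters) -> str:
    surv = clusters.surviving()
    if len(surv) == 0:
        return "  (no surviving clusters)\n"
    return surv.to_markdown(index=False) + "\n"


def demo(
    seed: int = 7,
    out_dir=None,
    n_pd: int = 84,
    n_hc: int = 70,
    shape=(40, 48, 40),
    write_volumes: bool = True,
    config: PipelineConfig | None = None,
    spec=None,
) -> dict:
    """Full synthetic run: generate, QC, VBM, CaSCN, ROI network, recovery
    check and report. Returns the metrics dict; artifacts go to out_dir."""
    config = config or PipelineConfig(seed_from_vbm=True, random_seed=seed)
    volumes, table, truth = simulate.generate_cohort(
        spec, n_pd=n_pd, n_hc=n_hc, shape=shape, random_seed=seed
    )
    stack, affine = stack_volumes(volumes)
    mask = truth.brain_mask

    qc = homogeneity_qc(volumes, mask=mask)
    demo_stats = demographics_table(table)
    r_scales = scale_consistency(table)

    vbm_res = run_vbm(stack, table, mask, config, affine=affine)
    cascn_res = run_cascn(
        stack, table, mask, config, affine=affine,
        vbm_zmap=vbm_res["overall"]["zmap"],
    )
    metrics = recovery_metrics(cascn_res["conjunction_mask"], truth)
    metrics["hy_updrs_pearson_r"] = r_scales
    metrics["n_qc_flagged"] = int(qc["flagged"].sum())
    metrics["seed_center_mm"] = cascn_res["seed_center_mm"]
    metrics["config_hash"] = config.config_hash()

    edge_counts = {
        score: int(net.significant_edges().shape[0])
        for score, net in cascn_res["networks"].items()
    }
    metrics["significant_edges"] = edge_counts

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if write_volumes:
            simulate.write_cohort(volumes, table, truth, out / "cohort",
                                  overwrite=True)
        else:
            table.to_csv(out / "subjects.tsv", sep="\t", index=False)
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        demo_stats.to_csv(out / "demographics.tsv", sep="\t", index=False)
        for name, res in vbm_res.items():
            res["clusters"].to_tsv(out / f"vbm_{name}_clusters.tsv")
        for score, res in cascn_res["orderings"].items():
            res["clusters"].to_tsv(out / f"cascn_{score.lower()}_clusters.tsv")
            res["ordering"].to_frame().to_csv(
                out / f"ordering_{score.lower()}.tsv", sep="\t", index=False
            )
            save_volume(
                GMVolume(res["gcmap"].zscored, affine, subject_id=f"gcz_{score}"),
                out / f"cascn_{score.lower()}_z.nii.gz",
            )
        save_volume(
            GMVolume(cascn_res["conjunction_mask"].astype(float), affine,
                     subject_id="conjunction"),
            out / "conjunction_mask.nii.gz",
        )
        for score, net in cascn_res["networks"].items():
            export_network(net, out, prefix=f"roi_network_{score.lower()}")
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, default=str)
        _write_report(out / "report.md", config, table, qc, demo_stats,
                      vbm_res, cascn_res, metrics)
    return metrics


def _write_report(path, config, table, qc, demo_stats, vbm_res, cascn_res,
                  metrics) -> None:
    lines = ["# CaSCN pipeline report", ""]
    lines += [f"Config hash: `{config.config_hash()}`", "", "## Configuration", ""]
    for k, v in sorted(config.to_dict().items()):
        lines.append(f"- {k}: {v}")
    is_pd = table["group"].astype(str).str.upper() == "PD"
    lines += ["", "## Cohort", "",
              f"- PD subjects: {int(is_pd.sum())}",
              f"- HC subjects: {int((~is_pd).sum())}",
              f"- QC flagged: {int(qc['flagged'].sum())}",
              f"- H&Y vs UPDRS-III Pearson r: {metrics['hy_updrs_pearson_r']:.3f}",
              "", "## Demographics", "", demo_stats.to_markdown(index=False), ""]
    lines += ["## VBM contrasts", ""]
    for name, res in vbm_res.items():
        n = res.get("n_per_group")
        lines += [f"### {name} (n = {n})", "", _cluster_md(res["clusters"])]
    lines += ["## CaSCN", "",
              f"- seed center (mm): {metrics['seed_center_mm']}",
              f"- conjunction voxels: {int(cascn_res['conjunction_mask'].sum())}",
              ""]
    for score, res in cascn_res["orderings"].items():
        lines += [f"### {score}-sequenced GC clusters", "",
                  _cluster_md(res["clusters"])]
    for score, net in cascn_res["networks"].items():
        lines += [f"### {score} ROI network (alpha={net.alpha})", "",
                  net.significant_edges().to_markdown(index=False), ""]
    lines += ["## Ground-truth recovery", "",
              f"- true regions hit: {metrics['n_true_hit']}/{metrics['n_true']}",
              f"- decoys hit: {metrics['n_decoy_hit']}/{metrics['n_decoys']}", ""]
    Path(path).write_text("\n".join(lines))
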
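"""Calibration and recovery studies for the pipeline.

These are the package's standing validation experiments: agreement of the
signed-GC estimator with a direct normal-equations solve, family-wise error
of the GRF cluster correction on stationary null fields, end-to-end
ground-truth recovery of the synthetic propagation graph, and the
permutation negative control for the ROI network. Both the test suite and
the reproduction script run them; all are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .cascn import covariate_matrix, order_by_severity, signed_gc
from .maps import StatMap
from .network import ROISet, roiwise_cascn
from .pipeline import PipelineConfig, recovery_metrics, run_cascn, _glm_contrast
from .random_field import estimate_smoothness, grf_cluster_correct
from .simulate import generate_cohort
from .vbm import scale_consistency, stack_volumes

__all__ = [
    "gc_oracle_max_difference",
    "grf_fwe_rate",
    "recovery_study",
    "permutation_edge_density",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gc_oracle_max_difference(n_instances: int = 1000, length: int = 84,
                             seed: int = 0) -> float:
    """Max |signed_gc - normal-equations solve| over random series pairs.

    The reference solve builds the lag-embedded design explicitly and
    solves A'A b = A'y directly.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        x = rng.standard_normal(length)
        y = rng.standard_normal(length)
        b = signed_gc(x, y, order=1)
        A = np.column_stack([np.ones(length - 1), y[:-1], x[:-1]])
        ref = np.linalg.solve(A.T @ A, A.T @ y[1:])[2]
        worst = max(worst, abs(b - ref))
    return worst


def grf_fwe_rate(
    n_fields: int = 3000,
    shape=(32, 32, 32),
    fwhm_mm: float = 4.0,
    voxel_mm: float = 1.5,
    height_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_calibration: int = 40,
    seed: int = 0,
) -> float:
    """Family-wise rate of >=1 surviving cluster on null smooth fields.

    Stationary unit Gaussian fields are produced by smoothing white noise on
    a padded grid and cropping; field smoothness is estimated once from a
    separate calibration stack, as a pipeline estimates it from residual
    images. Each field is map-standardized before thresholding, matching
    how GC coefficient maps are handled.
    """
    rng = np.random.default_rng(seed)
    sigma = fwhm_mm * _FWHM_TO_SIGMA / voxel_mm
    pad = int(np.ceil(4 * sigma))
    big = tuple(s + 2 * pad for s in shape)
    crop = tuple(slice(pad, pad + s) for s in shape)
    mask = np.ones(shape, dtype=bool)
    affine = np.diag([voxel_mm] * 3 + [1.0])

    def field():
        return gaussian_filter(rng.standard_normal(big), sigma)[crop]

    calib = np.stack([field() for _ in range(n_calibration)])
    smooth = estimate_smoothness(calib, mask, [voxel_mm] * 3)

    hits = 0
    for _ in range(n_fields):
        f = field()
        z = (f - f.mean()) / f.std()
        table = grf_cluster_correct(
            StatMap(values=z, mask=mask, affine=affine, kind="z"),
            smooth, height_p=height_p, cluster_alpha=cluster_alpha,
        )
        hits += int(len(table.surviving()) > 0)
    return hits / n_fields


def _one_recovery_run(seed: int, config: PipelineConfig | None = None) -> dict:
    volumes, table, truth = generate_cohort(random_seed=seed)
    stack, affine = stack_volumes(volumes)
    config = config or PipelineConfig(seed_from_vbm=True, random_seed=seed)
    overall = _glm_contrast(stack, truth.brain_mask, affine, table, config)
    res = run_cascn(stack, table, truth.brain_mask, config, affine=affine,
                    vbm_zmap=overall["zmap"])
    metrics = recovery_metrics(res["conjunction_mask"], truth)
    metrics["hy_updrs_pearson_r"] = scale_consistency(table)
    return metrics


def recovery_study(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """End-to-end CaSCN recovery of the synthetic propagation graph.

    Each replicate draws a fresh default cohort, recomputes the seed sphere
    from the overall VBM atrophy peak, runs both severity orderings with
    GRF correction, intersects them, and scores overlap with the true
    downstream regions and decoys. A replicate succeeds when at least 2 of
    the 3 true regions are hit and no decoy is touched.
    """
    runs = [_one_recovery_run(base_seed + i) for i in range(n_seeds)]
    ok = [r["n_true_hit"] >= 2 and r["n_decoy_hit"] == 0 for r in runs]
    return {
        "n_seeds": n_seeds,
        "success_fraction": float(np.mean(ok)),
        "mean_true_hit": float(np.mean([r["n_true_hit"] for r in runs])),
        "mean_decoy_hit": float(np.mean([r["n_decoy_hit"] for r in runs])),
        "mean_hy_updrs_r": float(np.mean([r["hy_updrs_pearson_r"] for r in runs])),
        "runs": runs,
    }


def permutation_edge_density(n_shuffles: int = 50, cohort_seed: int = 3,
                             shuffle_seed: int = 11, alpha: float = 0.05,
                             n_cohorts: int = 10) -> dict:
    """Significant-edge density of the ROI network under shuffled orderings.

    Shuffling the severity ordering destroys the pseudo-temporal structure,
    so edge-wise significance should fire at the nominal rate. ROIs are the
    phantom's six ground-truth regions (30 ordered pairs per shuffle). The
    density is pooled over ``n_cohorts`` independent cohorts because the 30
    pair statistics within one shuffle share subjects and are correlated;
    the reported CI is the binomial band for a single cohort's
    ``n_shuffles x 30`` edge tests, the tolerance at which the rate is
    judged.
    """
    sig = total = 0
    per_run = None
    for c in range(n_cohorts):
        volumes, table, truth = generate_cohort(random_seed=cohort_seed + c)
        stack, affine = stack_volumes(volumes)
        rois = ROISet(regions=dict(truth.region_masks), affine=affine)
        ordering = order_by_severity(table, "HY")
        idr = {sid: i for i, sid in enumerate(table["subject_id"])}
        rows = np.array([idr[s] for s in ordering.subject_ids])
        cov = covariate_matrix(table, ordering)
        rng = np.random.default_rng(shuffle_seed + c)
        run_total = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(len(rows))
            net = roiwise_cascn(rois, stack[rows][perm], covariates=cov[perm],
                                alpha=alpha)
            sig += int(net.edges["significant"].sum())
            run_total += int(np.isfinite(net.edges["p"]).sum())
        total += run_total
        per_run = per_run or run_total
    half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / per_run)
    return {
        "density": sig / total,
        "n_edges": total,
        "ci_low": alpha - half_width,
        "ci_high": alpha + half_width,
    }
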
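"""Gaussian random-field smoothness estimation and cluster-level correction.

Cluster inference follows the standard stationary-field theory for 3D
Gaussian fields: the expected number of supra-threshold clusters comes from
the Euler-characteristic densities, the cluster-extent distribution from the
exp(-beta k^(2/3)) approximation, and the family-wise cluster p-value from a
Poisson clumping bound. Smoothness (per-axis FWHM) is estimated from the
first-difference autocorrelation of residual images.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.special import gamma as gamma_fn
from scipy.special import ndtr, ndtri
import pandas as pd

from .maps import ClusterTable, SmoothnessEstimate, StatMap

__all__ = [
    "estimate_smoothness",
    "grf_cluster_correct",
    "z_threshold_for_p",
    "expected_clusters",
    "connectivity_structure",
]

_FOUR_LN2 = 4.0 * np.log(2.0)


def z_threshold_for_p(p_voxel: float) -> float:
    """One-tailed Gaussian height threshold: Phi^-1(1 - p).

    p = .001 gives 3.09 (2 dp), the conventional voxel threshold.
    """
    if not 0.0 < p_voxel < 1.0:
        raise ValueError("p must be in (0, 1)")
    return float(ndtri(1.0 - p_voxel))


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structure for cluster labeling (6, 18 or 26 neighbours)."""
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be one of {6, 18, 26}") from None
    return ndimage.generate_binary_structure(3, rank)


def estimate_smoothness(residuals, mask, voxel_size) -> SmoothnessEstimate:
    """Estimate per-axis FWHM (mm) from residual images.

    The pooled ratio of first-difference power to field power along each
    axis estimates 2(1 - rho) for the lag-one autocorrelation rho. For
    well-smoothed data (rho >= 0.5) the Gaussian autocorrelation model is
    inverted exactly, sigma^2 = delta^2 / (-4 ln rho), which removes the
    finite-difference underestimate of the curvature (the raw-derivative
    convention inflates FWHM by ~5% at 2.7-voxel smoothness and makes
    cluster inference over-conservative). For rougher data the raw
    derivative-variance form FWHM = sqrt(4 ln2 / lambda) is used; it floors
    at ~1.18 voxels on unsmoothed white noise, where a Gaussian ACF fit is
    meaningless.

    Parameters
    ----------
    residuals : ndarray (n_images, nx, ny, nz) or sequence of 3D arrays
    mask : boolean 3D array
    voxel_size : length-3 sequence, mm
    """
    R = np.asarray(residuals, dtype=np.float64)
    if R.ndim == 3:
        R = R[None]
    if R.ndim != 4:
        raise ValueError("residuals must be a stack of 3D images")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    voxel_size = np.asarray(voxel_size, dtype=float)

    ss = (R**2).sum(axis=0)
    if np.any(ss[mask] <= 0):
        raise ValueError("constant (zero-variance) residuals inside mask")
    fwhm = np.empty(3)
    for a in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[a] = slice(1, None)
        sl_lo[a] = slice(None, -1)
        pair = mask[tuple(sl_hi)] & mask[tuple(sl_lo)]
        if not pair.any():
            raise ValueError(f"no in-mask voxel pairs along axis {a}")
        du = R[(slice(None), *sl_hi)] - R[(slice(None), *sl_lo)]
        # pooled ratio of first-difference power to field power over all
        # pairs and images: estimates 2(1 - rho) with no small-sample bias
        # (assumes near-stationary residual variance, true after smoothing)
        num = float((du**2).sum(axis=0)[pair].sum())
        den = 0.5 * float((ss[tuple(sl_hi)] + ss[tuple(sl_lo)])[pair].sum())
        v = num / den
        rho = 1.0 - 0.5 * v
        if rho >= 0.5:
            sigma2 = voxel_size[a] ** 2 / (-4.0 * np.log(rho))
            fwhm[a] = np.sqrt(8.0 * np.log(2.0) * sigma2)
        else:
            lam = v / voxel_size[a] ** 2
            fwhm[a] = np.sqrt(_FOUR_LN2 / lam)

    resel_count = mask.sum() * float(np.prod(voxel_size)) / float(np.prod(fwhm))
    return SmoothnessEstimate(fwhm=fwhm, resel_count=resel_count)


def _ec_densities(u: float) -> np.ndarray:
    """EC densities rho_0..rho_3 of a unit Gaussian field (resel units)."""
    e = np.exp(-0.5 * u * u)
    return np.array(
        [
            ndtr(-u),
            np.sqrt(_FOUR_LN2) / (2.0 * np.pi) * e,
            _FOUR_LN2 / (2.0 * np.pi) ** 1.5 * u * e,
            _FOUR_LN2**1.5 / (2.0 * np.pi) ** 2 * (u * u - 1.0) * e,
        ]
    )


def _resel_counts(mask: np.ndarray, voxel_size, fwhm, resel_count: float) -> np.ndarray:
    """Resel counts R_0..R_3 of an equivalent cuboid.

    The mask is modelled as a cuboid whose aspect ratio follows the mask
    bounding box and whose volume equals the true resel count; exact
    per-voxel resel counting is not needed at the accuracy cluster
    inference supports.
    """
    idx = np.nonzero(mask)
    extent_vox = np.array([i.max() - i.min() + 1 for i in idx], dtype=float)
    sides = extent_vox * np.asarray(voxel_size) / np.asarray(fwhm)
    scale = (resel_count / np.prod(sides)) ** (1.0 / 3.0)
    r = sides * scale
    return np.array(
        [
            1.0,
            r.sum(),
            r[0] * r[1] + r[0] * r[2] + r[1] * r[2],
            float(np.prod(r)),
        ]
    )


def expected_clusters(u: float, resels: np.ndarray) -> float:
    """Expected number of supra-threshold clusters at height u."""
    return float(max(resels @ _ec_densities(u), 1e-300))


def grf_cluster_correct(
    zmap: StatMap,
    smoothness: SmoothnessEstimate,
    height_p: float = 0.001,
    cluster_alpha: float = 0.05,
    connectivity: int = 18,
) -> ClusterTable:
    """Cluster-level family-wise correction of a z map.

    Voxels with z above the one-tailed height threshold are labeled into
    connected components (default 18-neighbour); each component's FWE
    p-value is 1 - exp(-E[m] P(n >= k)) with P(n >= k) = exp(-beta k^(2/3))
    in resel units. An empty supra-threshold set yields an empty table.
    """
    if zmap.kind not in ("z", "gc_z"):
        raise ValueError("cluster correction expects a z or gc_z map")
    u = z_threshold_for_p(height_p)
    values = np.where(zmap.mask, zmap.values, -np.inf)
    supra = values > u
    structure = connectivity_structure(connectivity)
    label_map, n_labels = ndimage.label(supra, structure=structure)

    cols = list(ClusterTable.COLUMNS)
    if n_labels == 0:
        return ClusterTable(
            clusters=pd.DataFrame(columns=cols),
            height_threshold_z=u,
            cluster_alpha=cluster_alpha,
            label_map=label_map,
        )

    resels = _resel_counts(zmap.mask, zmap.voxel_size, smoothness.fwhm,
                           smoothness.resel_count)
    Em = expected_clusters(u, resels)
    # expected cluster size in resels under the null
    En = resels[3] * ndtr(-u) / Em
    beta = (gamma_fn(2.5) / En) ** (2.0 / 3.0)
    resels_per_voxel = float(np.prod(zmap.voxel_size) / np.prod(smoothness.fwhm))

    sizes = ndimage.sum_labels(np.ones_like(label_map), label_map,
                               index=np.arange(1, n_labels + 1))
    peak_idx = ndimage.maximum_position(values, label_map,
                                        index=np.arange(1, n_labels + 1))
    rows = []
    for lab, k, pk in zip(range(1, n_labels + 1), sizes, peak_idx):
        k_resels = k * resels_per_voxel
        p_unc = float(np.exp(-beta * k_resels ** (2.0 / 3.0)))
        p_fwe = float(-np.expm1(-Em * p_unc))
        pk = np.asarray(pk, dtype=float)
        peak_world = zmap.affine[:3, :3] @ pk + zmap.affine[:3, 3]
        rows.append(
            {
                "label": lab,
                "peak_x_mm": peak_world[0],
                "peak_y_mm": peak_world[1],
                "peak_z_mm": peak_world[2],
                "peak_stat": float(values[tuple(pk.astype(int))]),
                "extent_voxels": int(k),
                "extent_resels": k_resels,
                "cluster_p_fwe": p_fwe,
            }
        )
    table = pd.DataFrame(rows, columns=cols).sort_values(
        "extent_voxels", ascending=False, ignore_index=True
    )
    return ClusterTable(
        clusters=table,
        height_threshold_z=u,
        cluster_alpha=cluster_alpha,
        label_map=label_map,
    )
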
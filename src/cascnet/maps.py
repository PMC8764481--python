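"""Statistic-field containers shared by the VBM and CaSCN stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StatMap", "SmoothnessEstimate", "ClusterTable"]


@dataclass
class StatMap:
    """A voxel-wise statistic field on the analysis mask.

    ``kind`` is "t" (group GLM), "z" (Gaussianized), or "gc_z"
    (z-scored Granger-coefficient map). Values outside the mask are
    undefined and stored as 0.
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    kind: str = "t"
    df: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite statistic inside mask")
        if self.kind == "t" and (self.df is None or self.df <= 0):
            raise ValueError("t map requires df > 0")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class SmoothnessEstimate:
    """Per-axis field smoothness (FWHM, mm) and mask volume in resels."""

    fwhm: np.ndarray
    resel_count: float

    def __post_init__(self) -> None:
        self.fwhm = np.asarray(self.fwhm, dtype=float)
        if np.any(self.fwhm <= 0) or self.resel_count <= 0:
            raise ValueError("FWHM and resel count must be positive")


@dataclass
class ClusterTable:
    """GRF-corrected supra-threshold clusters of a statistic field.

    ``clusters`` has one row per connected component above the height
    threshold, whether or not it survives; ``cluster_p_fwe < cluster_alpha``
    marks survivors. ``label_map`` assigns each voxel its component id
    (0 = sub-threshold), so surviving-cluster masks can be rebuilt.
    """

    clusters: pd.DataFrame
    height_threshold_z: float
    cluster_alpha: float
    label_map: np.ndarray = field(repr=False, default=None)

    COLUMNS = (
        "label",
        "peak_x_mm",
        "peak_y_mm",
        "peak_z_mm",
        "peak_stat",
        "extent_voxels",
        "extent_resels",
        "cluster_p_fwe",
    )

    def surviving(self) -> pd.DataFrame:
        return self.clusters[self.clusters["cluster_p_fwe"] < self.cluster_alpha]

    def surviving_mask(self) -> np.ndarray:
        keep = set(self.surviving()["label"].astype(int))
        if not keep or self.label_map is None:
            shape = self.label_map.shape if self.label_map is not None else ()
            return np.zeros(shape, dtype=bool)
        return np.isin(self.label_map, list(keep))

    def to_tsv(self, path) -> None:
        self.clusters.to_csv(path, sep="\t", index=False)
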
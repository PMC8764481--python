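"""ROI-to-ROI directed causal network on severity-sequenced data.

ROIs come from the conjunction of the two severity-ordered voxel-wise CaSCN
masks; every ordered ROI pair gets a signed Granger coefficient, the
coefficients are z-standardized across the pair population, and pairs with
two-sided normal p below alpha (default .05, uncorrected) form the directed
network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr, ndtri, stdtr

from .cascn import regress_covariates, signed_gc
from .random_field import connectivity_structure

__all__ = ["ROISet", "DirectedNetwork", "extract_rois", "roiwise_cascn",
           "export_network"]


@dataclass
class ROISet:
    """Named, disjoint voxel sets on the cohort grid."""

    regions: dict  # name -> boolean 3D array
    affine: np.ndarray

    def __post_init__(self) -> None:
        seen = None
        for name, m in self.regions.items():
            m = np.asarray(m, dtype=bool)
            if not m.any():
                raise ValueError(f"empty ROI {name!r}")
            self.regions[name] = m
            if seen is None:
                seen = m.copy()
            else:
                if (seen & m).any():
                    raise ValueError(f"ROI {name!r} overlaps another region")
                seen |= m
        if seen is None:
            raise ValueError("no regions")

    @property
    def names(self) -> list:
        return list(self.regions)

    def mean_series(self, volumes: np.ndarray) -> dict:
        """Per-region mean series from an (n, nx, ny, nz) volume stack."""
        return {name: volumes[:, m].mean(axis=1) for name, m in self.regions.items()}


def extract_rois(
    cluster_mask: np.ndarray,
    affine: np.ndarray,
    min_size: int = 10,
    connectivity: int = 18,
    stat: np.ndarray | None = None,
) -> ROISet:
    """Connected components of a (conjunction) mask as named ROIs.

    Components smaller than ``min_size`` voxels are dropped. Names carry the
    component's reference world coordinate — the statistic peak when a stat
    field is supplied, otherwise the centroid.
    """
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("empty cluster mask: no ROIs to extract")
    labels, n = ndimage.label(cluster_mask, structure=connectivity_structure(connectivity))
    regions = {}
    for lab in range(1, n + 1):
        m = labels == lab
        k = int(m.sum())
        if k < min_size:
            continue
        if stat is not None:
            ref_vox = np.asarray(
                ndimage.maximum_position(np.where(m, stat, -np.inf)), dtype=float
            )
        else:
            ref_vox = np.array(np.nonzero(m), dtype=float).mean(axis=1)
        world = affine[:3, :3] @ ref_vox + affine[:3, 3]
        name = "roi_{:+.0f}_{:+.0f}_{:+.0f}".format(*world)
        suffix, base = 2, name
        while name in regions:
            name = f"{base}_{suffix}"
            suffix += 1
        regions[name] = m
    if not regions:
        raise ValueError(f"no component reached min_size={min_size}")
    return ROISet(regions=regions, affine=np.asarray(affine, float))


@dataclass
class DirectedNetwork:
    """Signed, directed GC edges between ROIs with significance flags."""

    nodes: list
    edges: pd.DataFrame  # source, target, gc, z, p, significant
    alpha: float = 0.05

    COLUMNS = ("source", "target", "gc", "z", "p", "significant")

    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["significant"]]

    def adjacency(self) -> dict:
        adj = {}
        for _, row in self.significant_edges().iterrows():
            adj.setdefault(row["source"], {})[row["target"]] = float(row["gc"])
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, row in self.significant_edges().iterrows():
            g.add_edge(row["source"], row["target"], gc=float(row["gc"]),
                       z=float(row["z"]), p=float(row["p"]))
        return g


def roiwise_cascn(
    roiset: ROISet,
    volumes: np.ndarray,
    covariates: np.ndarray | None = None,
    order: int = 1,
    alpha: float = 0.05,
    method: str = "analytic",
) -> DirectedNetwork:
    """Pairwise signed GC between ROI mean series.

    ``volumes`` is the severity-ordered (n, nx, ny, nz) stack. With the
    default ``method="analytic"`` each coefficient's z value is the
    probability transform of its regression t statistic (the same
    Gaussianization used for the voxel-wise group maps), so pairs are
    judged on their own sampling uncertainty. ``method="zscore"``
    standardizes the raw coefficients across the ordered-pair population
    instead; that convention is only calibrated when the pair population is
    large and homogeneous. Significance is two-sided, uncorrected, at
    ``alpha``. Degenerate pairs (collinear lag designs) get NaN and never
    enter the significance mask.
    """
    if method not in ("analytic", "zscore"):
        raise ValueError("method must be 'analytic' or 'zscore'")
    names = roiset.names
    if len(names) < 2:
        raise ValueError("need >= 2 ROIs")
    series = roiset.mean_series(np.asarray(volumes, dtype=np.float64))
    if covariates is not None:
        series = {k: regress_covariates(v, covariates) for k, v in series.items()}
    rows = []
    for src in names:
        for dst in names:
            if src == dst:
                continue
            try:
                gc, t, df = signed_gc(series[src], series[dst], order=order,
                                      return_stats=True)
            except ValueError:
                gc, t, df = np.nan, np.nan, np.nan
            rows.append({"source": src, "target": dst, "gc": gc, "t": t,
                         "df": df})
    edges = pd.DataFrame(rows)
    if method == "analytic":
        t = edges["t"].to_numpy()
        df = edges["df"].to_numpy()
        z = np.full(len(t), np.nan)
        ok = np.isfinite(t)
        # tail-stable t -> z, as in the voxel-wise pipeline
        sf = stdtr(df[ok], -np.abs(t[ok]))
        z[ok] = -ndtri(sf) * np.sign(t[ok])
    else:
        vals = edges["gc"].to_numpy()
        ok = np.isfinite(vals)
        z = np.full(len(vals), np.nan)
        if ok.sum() >= 2 and vals[ok].std() > 0:
            z[ok] = (vals[ok] - vals[ok].mean()) / vals[ok].std()
    p = np.where(np.isfinite(z), 2.0 * ndtr(-np.abs(z)), np.nan)
    edges["z"] = z
    edges["p"] = p
    edges["significant"] = np.where(np.isfinite(p), p < alpha, False)
    edges = edges.drop(columns=["t", "df"])
    return DirectedNetwork(nodes=names, edges=edges, alpha=alpha)


def export_network(net: DirectedNetwork, out_dir, prefix: str = "roi_network") -> dict:
    """Write the edge list as TSV and the significant adjacency as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = out / f"{prefix}_edges.tsv"
    js = out / f"{prefix}_adjacency.json"
    net.edges.to_csv(tsv, sep="\t", index=False)
    with open(js, "w") as fh:
        json.dump(
            {"nodes": net.nodes, "alpha": net.alpha, "adjacency": net.adjacency()},
            fh,
            indent=2,
        )
    return {"edges_tsv": str(tsv), "adjacency_json": str(js)}
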
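"""Causal structural covariance networks (CaSCN).

Cross-sectional gray-matter maps are sequenced by clinical severity rank
(H&Y or UPDRS-III, low to high) and the resulting pseudo-time-series are
analyzed with signed-path-coefficient Granger causality: the reported value
for a seed series x and target series y is the least-squares coefficient of
the lagged seed term in

    y_t = c + sum_i a_i y_{t-i} + sum_i b_i x_{t-i} + e_t,

a positive coefficient meaning atrophy of the target lags behind atrophy of
the seed. The voxel-wise coefficient map is z-scored across the mask and
passed through the same GRF cluster machinery as the VBM stage; the two
severity orderings are intersected by conjunction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SeverityOrdering",
    "GCMap",
    "order_by_severity",
    "regress_covariates",
    "covariate_matrix",
    "signed_gc",
    "voxelwise_cascn",
    "conjunction",
]


@dataclass
class SeverityOrdering:
    """A permutation of the PD subjects, ascending in a severity score."""

    subject_ids: list
    score_used: str
    scores: np.ndarray
    tie_break_rule: str = "other_scale,duration,subject_id"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.subject_ids):
            raise ValueError("scores/subjects length mismatch")
        if np.any(np.diff(self.scores) < 0):
            raise ValueError("scores must be non-decreasing along the order")

    def __len__(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self) + 1),
                "subject_id": self.subject_ids,
                "score": self.scores,
                "tie_break_rule": self.tie_break_rule,
            }
        )


_SCORE_COLUMNS = {"HY": "hy", "UPDRS3": "updrs3"}


def order_by_severity(table: pd.DataFrame, score: str = "HY") -> SeverityOrdering:
    """Stable ascending sort of PD subjects by a clinical severity score.

    Ties are broken deterministically by the other severity scale, then
    disease duration, then subject id, so the ordering is invariant to the
    input row order.
    """
    key = _SCORE_COLUMNS.get(score.upper())
    if key is None:
        raise ValueError("score must be 'HY' or 'UPDRS3'")
    pd_rows = table[table["group"].astype(str).str.upper() == "PD"].copy()
    missing = pd_rows[pd_rows[key].isna()]["subject_id"].tolist()
    if missing:
        raise ValueError(f"missing {key} for PD subjects: {missing}")
    other = "updrs3" if key == "hy" else "hy"
    sort_cols = [key]
    for col in (other, "duration"):
        if col in pd_rows.columns:
            pd_rows[col] = pd_rows[col].fillna(np.inf)
            sort_cols.append(col)
    sort_cols.append("subject_id")
    pd_rows = pd_rows.sort_values(sort_cols, kind="mergesort")
    return SeverityOrdering(
        subject_ids=pd_rows["subject_id"].tolist(),
        score_used=score.upper(),
        scores=pd_rows[key].to_numpy(float),
    )


def covariate_matrix(table: pd.DataFrame, ordering: SeverityOrdering) -> np.ndarray:
    """[1, sex, age, tiv] covariate matrix aligned with an ordering."""
    rows = table.set_index("subject_id").loc[ordering.subject_ids]
    sex = (rows["sex"].astype(str).str.lower() == "male").astype(float).to_numpy()
    return np.column_stack(
        [np.ones(len(rows)), sex, rows["age"].to_numpy(float),
         rows["tiv"].to_numpy(float)]
    )


def regress_covariates(series: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of one or many series against covariates.

    ``series`` is (n,) or (n, k); ``covariates`` is (n, p) and must include
    the intercept and be full rank. Residuals are orthogonal to every
    covariate column.
    """
    C = np.asarray(covariates, dtype=np.float64)
    y = np.asarray(series, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != y.shape[0]:
        raise ValueError("covariate matrix must be (n, p) matching the series")
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ beta


def _lag_design(x: np.ndarray, y: np.ndarray, order: int):
    n = len(y)
    T = n - order
    cols = [np.ones(T)]
    for i in range(1, order + 1):
        cols.append(y[order - i : n - i])
    for i in range(1, order + 1):
        cols.append(x[order - i : n - i])
    return np.column_stack(cols), y[order:]


def signed_gc(x, y, order: int = 1, return_stats: bool = False):
    """Signed path coefficient of x's past in y's autoregressive model.

    For order 1 the value is the coefficient b1 of x_{t-1}; for higher
    orders the sum of the lagged-seed coefficients is returned. Raises on a
    rank-deficient lag design (e.g. x and y lags collinear).

    With ``return_stats=True`` also returns the coefficient's t statistic
    and its residual degrees of freedom (used for the ROI-level
    z-distribution transform).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(y) < order + 3:
        raise ValueError("series too short for the requested order")
    A, b = _lag_design(x, y, order)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("collinear lag design: signed GC undefined")
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    value = float(coef[1 + order :].sum())
    if not return_stats:
        return value
    resid = b - A @ coef
    df = len(b) - A.shape[1]
    sigma2 = float(resid @ resid) / df
    Ainv = np.linalg.inv(A.T @ A)
    c = np.zeros(A.shape[1])
    c[1 + order :] = 1.0
    se = np.sqrt(sigma2 * float(c @ Ainv @ c))
    t = value / se if se > 0 else np.nan
    return value, t, df


@dataclass
class GCMap:
    """Voxel-wise signed Granger-coefficient map and its z-scored form.

    ``flagged`` marks voxels whose lag design was degenerate; they are
    excluded from the z normalization. ``degenerate`` is set when the raw
    map has (near-)zero spread so z-scoring is meaningless.
    """

    raw: np.ndarray
    zscored: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    order: int = 1
    direction: str = "seed_to_voxel"
    flagged: np.ndarray = field(default=None, repr=False)
    degenerate: bool = False


def voxelwise_cascn(
    seed_series: np.ndarray,
    volumes: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    order: int = 1,
    covariates: np.ndarray | None = None,
) -> GCMap:
    """Seed-to-voxel signed GC over every in-mask voxel.

    ``volumes`` is an (n, nx, ny, nz) stack already sorted by the severity
    ordering that produced ``seed_series``. If ``covariates`` is given, both
    the seed series and every voxel series are residualized against it
    first (the shipped convention: nuisance removal by pre-regression keeps
    the GC design identical at every voxel).
    """
    volumes = np.asarray(volumes, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(seed_series, dtype=np.float64)
    n = volumes.shape[0]
    if len(x) != n:
        raise ValueError("seed series length != number of volumes")
    if n < order + 3:
        raise ValueError("too few subjects for the requested order")
    Y = volumes[:, mask]  # (n, V)
    if covariates is not None:
        x = regress_covariates(x, covariates)
        Y = regress_covariates(Y, covariates)

    T = n - order
    V = Y.shape[1]
    p = 1 + 2 * order
    ylags = np.stack([Y[order - i : n - i] for i in range(1, order + 1)])  # (o,T,V)
    xlags = np.stack([x[order - i : n - i] for i in range(1, order + 1)])  # (o,T)
    yt = Y[order:]  # (T, V)

    M = np.empty((V, p, p))
    r = np.empty((V, p))
    M[:, 0, 0] = T
    sy = ylags.sum(axis=1).T  # (V, o)
    sx = xlags.sum(axis=1)  # (o,)
    M[:, 0, 1 : 1 + order] = sy
    M[:, 1 : 1 + order, 0] = sy
    M[:, 0, 1 + order :] = sx
    M[:, 1 + order :, 0] = sx
    M[:, 1 : 1 + order, 1 : 1 + order] = np.einsum("itv,jtv->vij", ylags, ylags)
    yx = np.einsum("itv,jt->vij", ylags, xlags)
    M[:, 1 : 1 + order, 1 + order :] = yx
    M[:, 1 + order :, 1 : 1 + order] = np.transpose(yx, (0, 2, 1))
    M[:, 1 + order :, 1 + order :] = xlags @ xlags.T
    r[:, 0] = yt.sum(axis=0)
    r[:, 1 : 1 + order] = np.einsum("itv,tv->vi", ylags, yt)
    r[:, 1 + order :] = (xlags @ yt).T

    # rank screen: reciprocal condition of the per-voxel normal matrix
    scale = np.sqrt(np.einsum("vii->vi", M))
    denom = scale[:, :, None] * scale[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        Mn = np.where(denom > 0, M / denom, 0.0)
    eig = np.linalg.eigvalsh(Mn)
    good = (eig[:, 0] > 1e-10) & (eig[:, -1] > 0)

    b = np.full(V, np.nan)
    if good.any():
        coef = np.linalg.solve(M[good], r[good][..., None])[..., 0]
        b[good] = coef[:, 1 + order :].sum(axis=1)

    raw = np.zeros(mask.shape)
    raw[mask] = np.where(np.isfinite(b), b, 0.0)
    flagged = np.zeros(mask.shape, dtype=bool)
    flagged[mask] = ~np.isfinite(b)

    valid = b[np.isfinite(b)]
    z = np.zeros(mask.shape)
    degenerate = True
    if valid.size >= 2:
        mu, sd = valid.mean(), valid.std()
        # a (near-)constant coefficient map cannot be meaningfully z-scored
        if sd > 1e-6 * max(1.0, abs(mu)):
            zv = np.where(np.isfinite(b), (b - mu) / sd, 0.0)
            z[mask] = zv
            degenerate = False
    return GCMap(
        raw=raw, zscored=z, mask=mask, affine=np.asarray(affine, float),
        order=order, flagged=flagged, degenerate=degenerate,
    )


def conjunction(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxel-wise intersection of two GRF-surviving cluster masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("grid mismatch between conjunction inputs")
    return a & b
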
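"""Voxel-based morphometry: two-group GLM with nuisance covariates,
t->z conversion, severity staging, cohort QC and demographic-table tests.

The group model at each voxel is ordinary least squares on
``[intercept, group, sex, age, tiv]`` with a one-tailed atrophy contrast
(HC > PD by default, matching a z > 3.09 one-tailed height threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri, stdtr

from .maps import StatMap

__all__ = [
    "DesignMatrix",
    "StageScheme",
    "HY_SCHEME",
    "UPDRS_SCHEME",
    "MOCA_DEMENTIA_SCHEME",
    "build_design",
    "fit_group_glm",
    "t_to_z",
    "assign_stage",
    "homogeneity_qc",
    "demographics_table",
    "scale_consistency",
    "stack_volumes",
]


@dataclass
class DesignMatrix:
    """GLM design: one row per subject, group indicator plus covariates."""

    X: np.ndarray
    columns: list
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("design must be 2D")
        if len(self.contrast) != self.X.shape[1]:
            raise ValueError("contrast length must equal number of columns")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("rank-deficient design matrix")


def build_design(table: pd.DataFrame, contrast_tail: str = "hc_gt_pd") -> DesignMatrix:
    """Two-sample design with sex, age and TIV as nuisance covariates.

    ``contrast_tail`` selects the one-tailed direction: "hc_gt_pd" (atrophy
    in patients, the default) or "pd_gt_hc".
    """
    group = (table["group"].astype(str).str.upper() == "PD").astype(float).to_numpy()
    sex = (table["sex"].astype(str).str.lower() == "male").astype(float).to_numpy()
    X = np.column_stack(
        [np.ones(len(table)), group, sex,
         table["age"].to_numpy(float), table["tiv"].to_numpy(float)]
    )
    if contrast_tail == "hc_gt_pd":
        c = np.array([0.0, -1.0, 0.0, 0.0, 0.0])
    elif contrast_tail == "pd_gt_hc":
        c = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    else:
        raise ValueError("contrast_tail must be 'hc_gt_pd' or 'pd_gt_hc'")
    return DesignMatrix(X=X, columns=["intercept", "pd", "male", "age", "tiv"],
                        contrast=c)


def stack_volumes(volumes) -> tuple:
    """Stack a grid-consistent volume list into (n, nx, ny, nz) + affine."""
    volumes = list(volumes)
    ref = volumes[0]
    for v in volumes[1:]:
        if not v.same_grid(ref):
            raise ValueError(f"grid mismatch for subject {v.subject_id}")
    return np.stack([v.data for v in volumes]), ref.affine


def fit_group_glm(volumes, mask, design: DesignMatrix, affine=None):
    """Per-voxel OLS group comparison.

    Returns the t map for the design's contrast (df = n - rank) and the
    residual image stack (for smoothness estimation).
    """
    if isinstance(volumes, np.ndarray):
        Yimg = volumes
        if affine is None:
            raise ValueError("affine required with an array input")
    else:
        Yimg, affine = stack_volumes(volumes)
    mask = np.asarray(mask, dtype=bool)
    X, c = design.X, design.contrast
    n, p = X.shape
    if n != Yimg.shape[0]:
        raise ValueError("design rows != number of volumes")
    if n <= p:
        raise ValueError("more parameters than subjects")
    grp = X[:, design.columns.index("pd")] if "pd" in design.columns else None
    if grp is not None and (grp.sum() < 2 or (len(grp) - grp.sum()) < 2):
        raise ValueError("need >= 2 subjects per group")

    Y = Yimg[:, mask]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    # voxels the model fits exactly (e.g. identical maps) have no error
    # variance; their t is defined as 0 rather than 0/0
    floor = 1e-24 * np.mean(Y**2, axis=0)
    denom = np.sqrt(sigma2 * float(c @ XtX_inv @ c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sigma2 > floor, (c @ beta) / denom, 0.0)

    tmap = np.zeros(mask.shape)
    tmap[mask] = t
    resid_imgs = np.zeros((n, *mask.shape))
    resid_imgs[:, mask] = resid
    return (
        StatMap(values=tmap, mask=mask, affine=affine, kind="t", df=df),
        resid_imgs,
    )


def t_to_z(tmap: StatMap) -> StatMap:
    """Gaussianize a t map: z = Phi^-1(F_t(t; df)), tail-stable.

    Monotone in t, so voxel ranking is preserved exactly.
    """
    if tmap.kind != "t":
        raise ValueError("input must be a t map")
    df = tmap.df
    if df is None or df <= 0:
        raise ValueError("df must be positive")
    t = tmap.values[tmap.mask]
    # work in the upper tail for numerical stability at large |t|
    sf = stdtr(df, -np.abs(t))
    z = -ndtri(sf) * np.sign(t)
    zimg = np.zeros(tmap.values.shape)
    zimg[tmap.mask] = z
    return StatMap(values=zimg, mask=tmap.mask, affine=tmap.affine, kind="z")


@dataclass
class StageScheme:
    """Ordered severity bins over a clinical score.

    Shipped schemes follow the clinical conventions: modified H&Y 1-2 /
    2.5-3 / 4-5 (half-point 2.5 counted as Stage II), UPDRS-III tertiles
    1-23 / 24-40 / 41-74, and the MoCA dementia screen (score < 21).
    """

    name: str
    score: str
    bin_edges: list  # [(lo, hi)] inclusive
    labels: list

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.labels):
            raise ValueError("one label per bin")


HY_SCHEME = StageScheme(
    name="HY", score="hy",
    bin_edges=[(1.0, 2.0), (2.5, 3.0), (4.0, 5.0)],
    labels=["Stage I", "Stage II", "Stage III"],
)
UPDRS_SCHEME = StageScheme(
    name="UPDRS3", score="updrs3",
    bin_edges=[(1, 23), (24, 40), (41, 74)],
    labels=["Stage I", "Stage II", "Stage III"],
)
MOCA_DEMENTIA_SCHEME = StageScheme(
    name="MOCA_DEMENTIA", score="moca",
    bin_edges=[(0, 20.5), (20.5, 30)],
    labels=["dementia", "no dementia"],
)


def assign_stage(record, scheme: StageScheme) -> str:
    """Deterministic bin lookup of one subject's severity stage."""
    score = record[scheme.score] if not hasattr(record, "get") else record.get(scheme.score)
    if score is None or (isinstance(score, float) and np.isnan(score)):
        raise ValueError(f"score {scheme.score!r} missing on record")
    for (lo, hi), label in zip(scheme.bin_edges, scheme.labels):
        if lo <= score <= hi:
            return label
    raise ValueError(f"{scheme.score}={score} outside all bins of {scheme.name}")


def homogeneity_qc(volumes, mask=None):
    """Pairwise-correlation homogeneity QC.

    Each subject's homogeneity is the mean Pearson correlation of their GM
    map with every other map (within the mask); subjects below
    mean - 2 SD of the scores are flagged as outliers. Constant maps have
    undefined correlation and are flagged directly.
    """
    volumes = list(volumes)
    if len(volumes) < 3:
        raise ValueError("homogeneity QC needs >= 3 volumes")
    Y, _ = stack_volumes(volumes)
    if mask is None:
        mask = np.ones(Y.shape[1:], dtype=bool)
    M = Y[:, np.asarray(mask, dtype=bool)]
    sd = M.std(axis=1)
    constant = sd == 0
    Z = np.zeros_like(M)
    ok = ~constant
    Z[ok] = (M[ok] - M[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    C = (Z @ Z.T) / M.shape[1]
    np.fill_diagonal(C, np.nan)
    C[constant, :] = np.nan
    C[:, constant] = np.nan
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scores = np.nanmean(C, axis=1)
    ids = [v.subject_id or str(i) for i, v in enumerate(volumes)]
    valid = scores[ok]
    if len(valid) < 2 or np.std(valid, ddof=1) == 0:
        cut = -np.inf
    else:
        cut = valid.mean() - 2.0 * np.std(valid, ddof=1)
    rows = []
    for i, sid in enumerate(ids):
        if constant[i]:
            rows.append((sid, np.nan, True, "constant map: correlation undefined"))
        elif scores[i] < cut:
            rows.append((sid, scores[i], True, "homogeneity < mean - 2 SD"))
        else:
            rows.append((sid, scores[i], False, ""))
    return pd.DataFrame(rows, columns=["subject_id", "homogeneity", "flagged", "reason"])


def _mannwhitney(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        return np.nan, np.nan
    method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def demographics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison statistics for the cohort table.

    Sex uses the Pearson chi-square on the 2x2 contingency table without
    continuity correction; continuous scores (age, MMSE, MoCA, ...) use
    two-sided Mann-Whitney tests with row-wise available-case handling of
    missing scores.
    """
    g = table["group"].astype(str).str.upper()
    pd_rows = table[g == "PD"]
    hc_rows = table[g == "HC"]
    if len(pd_rows) == 0 or len(hc_rows) == 0:
        raise ValueError("both groups must be nonempty")

    rows = []
    counts = np.array(
        [
            [(pd_rows["sex"].str.lower() == "male").sum(),
             (pd_rows["sex"].str.lower() == "female").sum()],
            [(hc_rows["sex"].str.lower() == "male").sum(),
             (hc_rows["sex"].str.lower() == "female").sum()],
        ],
        dtype=float,
    )
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        rows.append(("sex", "chi2", np.nan, np.nan, "zero margin: chi2 undefined"))
    else:
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
        rows.append(("sex", "chi2", float(chi2), float(p), ""))

    for col in ("age", "mmse", "moca"):
        if col not in table.columns:
            continue
        u, p = _mannwhitney(pd_rows[col], hc_rows[col])
        note = "" if np.isfinite(p) else "no data in one group"
        rows.append((col, "mannwhitney_u", u, p, note))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p", "note"])


def scale_consistency(table: pd.DataFrame) -> float:
    """Pearson correlation between H&Y and UPDRS-III over PD subjects."""
    pd_rows = table[table["group"].astype(str).str.upper() == "PD"]
    sub = pd_rows[["hy", "updrs3"]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 PD subjects with both scores")
    hy = sub["hy"].to_numpy(float)
    up = sub["updrs3"].to_numpy(float)
    if hy.std() == 0 or up.std() == 0:
        raise ValueError("zero variance in a severity scale")
    return float(np.corrcoef(hy, up)[0, 1])
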
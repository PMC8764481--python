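"""Synthetic PD/HC cohorts with known atrophy-propagation ground truth.

The phantom is geometric: a smooth ellipsoidal "brain" of uniform
gray-matter density with ellipsoidal regions of elevated density. Disease
severity is a latent uniform variable; the patient ranked r on severity has
the seed region's density reduced by gain * s_(r) (s_(.) the sorted latent
severities) and each downstream region reduced by gain * s_(r - lag), i.e.
downstream atrophy is an exact rank-lagged copy of seed atrophy. Decoy
regions have identical anatomy but no severity-linked atrophy. Because the
latent severities are order statistics of a uniform sample, their spacings
are irregular: the seed pseudo-time-series carries genuine innovations that
reappear ``lag`` positions later in the target series, which is what the
lagged-prediction (Granger) stage must detect. A perfectly affine severity
ramp would make seed and target lag regressors collinear and the
coefficient unidentifiable.

Two clinical scales (H&Y, UPDRS-III) are monotone noisy transforms of the
latent severity with a configurable latent correlation, discretized to the
scales' conventional ranges. Age, sex and TIV modulate global density so
covariate regression has real work to do. Volumes are white-noise corrupted
and smoothed with a 4 mm FWHM Gaussian kernel, so random-field smoothness
assumptions hold downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import ndtri

from .volumes import BrainMask, GMVolume, save_volume

__all__ = [
    "PropagationSpec",
    "GroundTruth",
    "default_spec",
    "default_affine",
    "generate_cohort",
    "write_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# H&Y marginal used for discretization: stage sizes 32/41/11 of 84 split
# over the modified 7-point scale.
_HY_VALUES = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0])
_HY_PROBS = np.array([12, 8, 12, 20, 21, 8, 3], dtype=float) / 84.0


@dataclass
class PropagationSpec:
    """Ground-truth atrophy propagation graph on the phantom.

    ``edges`` are (source, target, lag, gain) with lag in severity-rank
    positions and gain the fractional density loss per unit severity. The
    seed region has in-degree 0; decoy regions appear in ``regions`` but in
    no edge and receive no atrophy.
    """

    regions: dict = field(default_factory=dict)  # name -> {center_mm, radius_mm}
    edges: list = field(default_factory=list)  # (src, dst, lag, gain)
    seed_region: str = "seed"
    seed_gain: float = 0.3
    noise_sd: float = 0.02
    smooth_fwhm_mm: float = 4.0
    brain_semiaxes_mm: tuple = (28.0, 34.0, 28.0)
    background_density: float = 0.5
    region_density_boost: float = 0.25
    covariate_effects: dict = field(
        default_factory=lambda: {"age": -0.003, "sex_male": -0.01, "tiv": 1e-4}
    )
    # latent consistency of the two severity scales; sequencing can only
    # resolve propagation lags of 3-8 ranks (n=84) if scale noise displaces
    # ranks by less than the lag, which requires consistency ~0.9 or better
    score_correlation: float = 0.9

    def __post_init__(self) -> None:
        targets = {dst for _, dst, _, _ in self.edges}
        if self.seed_region in targets:
            raise ValueError("seed region must have in-degree 0")
        for src, dst, lag, gain in self.edges:
            if lag < 0 or gain < 0:
                raise ValueError("lags and gains must be >= 0")
            if src not in self.regions or dst not in self.regions:
                raise ValueError(f"edge {src}->{dst} references unknown region")

    @property
    def decoys(self) -> list:
        linked = {self.seed_region} | {d for _, d, _, _ in self.edges}
        return [r for r in self.regions if r not in linked]


def default_spec() -> PropagationSpec:
    """Default study conditions: a seed, three lagged downstream regions
    (lags 3, 5, 8) and two decoys, gain 0.3, noise SD 0.02."""
    regions = {
        "seed": {"center_mm": (-17.0, -3.0, 20.0), "radius_mm": 6.0},
        "region_a": {"center_mm": (18.0, 9.0, 14.0), "radius_mm": 6.0},
        "region_b": {"center_mm": (-14.0, -24.0, -3.0), "radius_mm": 6.0},
        "region_c": {"center_mm": (12.0, -12.0, -18.0), "radius_mm": 6.0},
        "decoy_a": {"center_mm": (-15.0, 18.0, -9.0), "radius_mm": 6.0},
        "decoy_b": {"center_mm": (6.0, 27.0, 6.0), "radius_mm": 6.0},
    }
    edges = [
        ("seed", "region_a", 3, 0.3),
        ("seed", "region_b", 5, 0.3),
        ("seed", "region_c", 8, 0.3),
    ]
    return PropagationSpec(regions=regions, edges=edges)


@dataclass
class GroundTruth:
    """What the generator injected: the directed graph and region masks."""

    true_edges: list
    region_masks: dict
    seed_region: str
    brain_mask: np.ndarray
    affine: np.ndarray

    @property
    def true_atrophy_mask(self) -> np.ndarray:
        names = {self.seed_region} | {d for _, d, _, _ in self.true_edges}
        out = np.zeros(self.brain_mask.shape, dtype=bool)
        for name in names:
            out |= self.region_masks[name]
        return out

    def to_json_dict(self) -> dict:
        boxes = {}
        for name, m in self.region_masks.items():
            idx = np.nonzero(m)
            boxes[name] = {
                "bbox_vox": [[int(i.min()), int(i.max())] for i in idx],
                "n_voxels": int(m.sum()),
            }
        return {
            "edges": [
                {"src": s, "dst": d, "lag": int(l), "gain": float(g)}
                for s, d, l, g in self.true_edges
            ],
            "seed_region": self.seed_region,
            "regions": boxes,
        }


def default_affine(shape=(40, 48, 40), voxel_size=1.5) -> np.ndarray:
    """Template-like affine: isotropic voxels, world origin at grid center."""
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size
    return affine


def _ellipsoid_mask(shape, affine, center_mm, semiaxes_mm) -> np.ndarray:
    ijk = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    d = (world - np.asarray(center_mm)) / np.asarray(semiaxes_mm)
    return ((d**2).sum(axis=1) <= 1.0).reshape(shape)


def _severity_to_scores(latent, rng, spec, n):
    """Two monotone noisy transforms of latent severity, discretized."""
    sigma_l = np.sqrt(1.0 / 12.0)  # SD of Uniform(0,1)
    rho = spec.score_correlation
    if not 0.0 < rho <= 1.0:
        raise ValueError("score_correlation must be in (0, 1]")
    sigma_e = sigma_l * np.sqrt(1.0 / rho - 1.0)
    l_hy = latent + rng.normal(0.0, sigma_e, n)
    l_up = latent + rng.normal(0.0, sigma_e, n)

    # H&Y: quantile-match to the shipped 7-level marginal
    hy = np.empty(n)
    order = np.argsort(l_hy, kind="stable")
    cum = np.floor(np.cumsum(_HY_PROBS) * n + 0.5).astype(int)
    cum[-1] = n
    start = 0
    for val, stop in zip(_HY_VALUES, cum):
        hy[order[start:stop]] = val
        start = stop

    # UPDRS-III: Gaussian quantile map, mean 33, SD 17, clipped to 1..74
    pct = (np.argsort(np.argsort(l_up)) + 0.5) / n
    updrs = np.clip(np.round(33.0 + 17.0 * ndtri(pct)), 1, 74).astype(int)
    return hy, updrs


def generate_cohort(
    spec: PropagationSpec | None = None,
    n_pd: int = 84,
    n_hc: int = 70,
    shape=(40, 48, 40),
    voxel_size: float = 1.5,
    random_seed: int = 0,
):
    """Simulate a full cohort: volumes, subject table and ground truth.

    Returns ``(volumes, table, truth)`` where ``volumes`` is a list of
    :class:`GMVolume` aligned with the rows of ``table`` (PD first, then
    HC). Fully reproducible from ``random_seed``.
    """
    spec = spec or default_spec()
    if n_pd < 4:
        raise ValueError("n_pd must be >= 4")
    if n_hc < 1:
        raise ValueError("n_hc must be >= 1")
    for _, _, lag, _ in spec.edges:
        if lag >= n_pd:
            raise ValueError(f"lag {lag} >= n_pd {n_pd}: no downstream signal")
    rng = np.random.default_rng(random_seed)
    affine = default_affine(shape, voxel_size)
    sigma_vox = spec.smooth_fwhm_mm * _FWHM_TO_SIGMA / voxel_size

    brain = _ellipsoid_mask(shape, affine, (0.0, 0.0, 0.0), spec.brain_semiaxes_mm)
    region_masks = {
        name: _ellipsoid_mask(shape, affine, r["center_mm"], (r["radius_mm"],) * 3)
        & brain
        for name, r in spec.regions.items()
    }
    base = np.where(brain, spec.background_density, 0.0)
    for m in region_masks.values():
        base = base + np.where(m, spec.region_density_boost, 0.0)

    # latent severity: sorted uniform order statistics; severity ranks are
    # assigned to PD subjects in random order
    s_sorted = np.sort(rng.uniform(0.0, 1.0, n_pd))
    rank_of_subject = rng.permutation(n_pd)  # subject i has rank r_i (0-based)

    n = n_pd + n_hc
    group = np.array(["PD"] * n_pd + ["HC"] * n_hc)
    age = np.concatenate(
        [rng.normal(53.4, 10.5, n_pd), rng.normal(52.6, 10.9, n_hc)]
    ).clip(30, 85)
    sex = np.concatenate(
        [
            np.where(rng.uniform(size=n_pd) < 48 / 84, "male", "female"),
            np.where(rng.uniform(size=n_hc) < 38 / 70, "male", "female"),
        ]
    )
    tiv = rng.normal(1450.0, 130.0, n).clip(1000, 1900)

    sev_pd = s_sorted[rank_of_subject]
    hy, updrs = _severity_to_scores(
        s_sorted, rng, spec, n_pd
    )
    hy = hy[rank_of_subject]
    updrs = updrs[rank_of_subject]
    duration = (1.0 + 14.0 * sev_pd + rng.normal(0, 2.0, n_pd)).clip(0.5, 30)
    mmse = np.full(n, np.nan)
    moca = np.full(n, np.nan)
    mmse[:n_pd] = np.round(29.0 - 6.0 * sev_pd + rng.normal(0, 2.0, n_pd)).clip(10, 30)
    mmse[n_pd:] = np.round(rng.normal(27.1, 2.5, n_hc)).clip(18, 30)
    moca[:n_pd] = np.round(27.0 - 9.0 * sev_pd + rng.normal(0, 2.5, n_pd)).clip(5, 30)
    moca[n_pd:] = np.round(rng.normal(24.1, 4.0, n_hc)).clip(10, 30)
    # available-case pattern: part of the cohort has no cognitive screen
    frac = min(1.0, 72 / 84)
    mmse[rng.permutation(n_pd)[int(round(frac * n_pd)):]] = np.nan
    mmse[n_pd + rng.permutation(n_hc)[int(round(52 / 70 * n_hc)):]] = np.nan
    moca[rng.permutation(n_pd)[int(round(51 / 84 * n_pd)):]] = np.nan
    moca[n_pd + rng.permutation(n_hc)[int(round(49 / 70 * n_hc)):]] = np.nan

    eff = spec.covariate_effects
    cov_scale = (
        1.0
        + eff.get("age", 0.0) * (age - 53.0)
        + eff.get("sex_male", 0.0) * (sex == "male")
        + eff.get("tiv", 0.0) * (tiv - 1450.0)
    )

    lagged = {}
    for src, dst, lag, gain in spec.edges:
        if src != spec.seed_region:
            raise NotImplementedError("only seed-rooted propagation is generated")
        lagged[dst] = (lag, gain)

    volumes = []
    subject_ids = [f"pd{i+1:03d}" for i in range(n_pd)] + [
        f"hc{i+1:03d}" for i in range(n_hc)
    ]
    for i in range(n):
        vol = base * cov_scale[i]
        if i < n_pd:
            r = rank_of_subject[i]  # 0-based severity rank
            vol = vol * np.where(
                region_masks[spec.seed_region],
                1.0 - spec.seed_gain * s_sorted[r],
                1.0,
            )
            for dst, (lag, gain) in lagged.items():
                sev = s_sorted[r - lag] if r - lag >= 0 else 0.0
                vol = vol * np.where(region_masks[dst], 1.0 - gain * sev, 1.0)
        vol = vol + rng.normal(0.0, spec.noise_sd, shape)
        vol = gaussian_filter(vol, sigma_vox)
        volumes.append(
            GMVolume(data=np.clip(vol, 0.0, None), affine=affine,
                     subject_id=subject_ids[i])
        )

    table = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": group,
            "age": np.round(age, 1),
            "sex": sex,
            "tiv": np.round(tiv, 1),
            "hy": np.concatenate([hy, np.full(n_hc, np.nan)]),
            "updrs3": np.concatenate([updrs.astype(float), np.full(n_hc, np.nan)]),
            "mmse": mmse,
            "moca": moca,
            "duration": np.concatenate([np.round(duration, 1), np.full(n_hc, np.nan)]),
        }
    )
    truth = GroundTruth(
        true_edges=list(spec.edges),
        region_masks=region_masks,
        seed_region=spec.seed_region,
        brain_mask=brain,
        affine=affine,
    )
    return volumes, table, truth


def write_cohort(volumes, table, truth, out_dir, overwrite: bool = False) -> dict:
    """Write one NIfTI per subject, the subject TSV, the analysis mask and
    the ground-truth JSON; returns a manifest of all paths."""
    volumes = list(volumes)
    if not volumes:
        raise ValueError("empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"volumes": [], "table": str(out / "subjects.tsv"),
             "mask": str(out / "mask.nii.gz"),
             "ground_truth": str(out / "ground_truth.json")}
    for v in volumes:
        p = out / f"{v.subject_id}.nii.gz"
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists (pass overwrite=True)")
        save_volume(v, p)
        paths["volumes"].append(str(p))
    for key in ("table", "mask", "ground_truth"):
        if Path(paths[key]).exists() and not overwrite:
            raise FileExistsError(f"{paths[key]} exists (pass overwrite=True)")
    table.to_csv(paths["table"], sep="\t", index=False)
    mask_vol = GMVolume(
        data=truth.brain_mask.astype(float), affine=truth.affine, subject_id="mask"
    )
    save_volume(mask_vol, paths["mask"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2)
    return paths


def brain_mask_of(truth: GroundTruth) -> BrainMask:
    return BrainMask(data=truth.brain_mask, affine=truth.affine)
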
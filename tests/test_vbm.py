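import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import t as t_dist

from cascnet.maps import StatMap
from cascnet.random_field import z_threshold_for_p
from cascnet.simulate import default_affine
from cascnet.vbm import (
    HY_SCHEME,
    MOCA_DEMENTIA_SCHEME,
    UPDRS_SCHEME,
    assign_stage,
    build_design,
    demographics_table,
    fit_group_glm,
    homogeneity_qc,
    scale_consistency,
    t_to_z,
)
from cascnet.volumes import GMVolume


def _table(n_pd=10, n_hc=8, rng=None):
    rng = rng or np.random.default_rng(0)
    n = n_pd + n_hc
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["PD"] * n_pd + ["HC"] * n_hc,
            "age": rng.normal(55, 10, n),
            "sex": rng.choice(["male", "female"], n),
            "tiv": rng.normal(1450, 120, n),
        }
    )


class TestGroupGLM:
    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        n_pd, n_hc, shape = 12, 10, (5, 5, 4)
        table = _table(n_pd, n_hc, rng)
        design = build_design(table)
        Y = rng.normal(0.5, 0.1, (n_pd + n_hc, *shape))
        mask = np.ones(shape, dtype=bool)
        tmap, resid = fit_group_glm(Y, mask, design, affine=default_affine(shape))
        flat = Y.reshape(len(table), -1)
        for v in rng.choice(flat.shape[1], 10, replace=False):
            fit = sm.OLS(flat[:, v], design.X).fit()
            # contrast is -1 on the PD column
            assert abs(tmap.values.ravel()[v] - (-fit.tvalues[1])) < 1e-8
        assert tmap.df == len(table) - design.X.shape[1]

    def test_identical_groups_give_zero_t(self, rng):
        shape = (4, 4, 4)
        table = _table(6, 6, rng)
        base = rng.uniform(0.3, 0.8, shape)
        Y = np.stack([base] * 12)
        design = build_design(table)
        tmap, _ = fit_group_glm(Y, np.ones(shape, bool), design,
                                affine=default_affine(shape))
        assert np.allclose(tmap.values, 0.0)

    def test_covariate_centering_invariance(self, rng):
        shape = (4, 4, 3)
        table = _table(8, 8, rng)
        Y = rng.normal(0.5, 0.1, (16, *shape))
        mask = np.ones(shape, bool)
        d1 = build_design(table)
        centered = table.copy()
        centered["age"] -= centered["age"].mean()
        centered["tiv"] -= centered["tiv"].mean()
        d2 = build_design(centered)
        t1, _ = fit_group_glm(Y, mask, d1, affine=default_affine(shape))
        t2, _ = fit_group_glm(Y, mask, d2, affine=default_affine(shape))
        assert np.max(np.abs(t1.values - t2.values)) < 1e-8

    def test_null_voxelwise_error_rate(self, rng):
        # fraction of |t| above the p<.001 quantile is ~.001 under the null
        n, V = 40, 40000
        table = _table(20, 20, rng)
        design = build_design(table)
        Y = rng.normal(0, 1, (n, V)).reshape(n, 200, 200, 1)
        mask = np.ones((200, 200, 1), bool)
        tmap, _ = fit_group_glm(Y, mask, design, affine=np.eye(4))
        crit = t_dist.isf(0.0005, tmap.df)  # two-sided p < .001
        frac = np.mean(np.abs(tmap.values[mask]) > crit)
        se = np.sqrt(0.001 * 0.999 / V)
        assert abs(frac - 0.001) < 5 * se

    def test_rank_deficient_design_rejected(self):
        table = _table(6, 6)
        table["tiv"] = table["age"]  # collinear covariates
        with pytest.raises(ValueError, match="rank"):
            build_design(table)


class TestTtoZ:
    def _map(self, t_values, df):
        arr = np.asarray(t_values, float).reshape(-1, 1, 1)
        return StatMap(values=arr, mask=np.ones(arr.shape, bool),
                       affine=np.eye(4), kind="t", df=df)

    def test_zero_maps_to_zero(self):
        for df in (3, 30, 300):
            z = t_to_z(self._map([0.0], df))
            assert abs(z.values.ravel()[0]) < 1e-12

    def test_large_df_asymptote(self):
        ts = np.linspace(-3, 3, 13)
        z = t_to_z(self._map(ts, 10000)).values.ravel()
        assert np.max(np.abs(z - ts)) < 0.01

    def test_against_numeric_cdf_oracle(self):
        # oracle: integrate the t density numerically, invert Phi by bisection
        df, tv = 30, 3.5
        pdf = lambda x: t_dist.pdf(x, df)
        upper_tail, _ = quad(pdf, tv, np.inf)
        z_oracle = brentq(lambda z: ndtr(-z) - upper_tail, 0, 40)
        z = t_to_z(self._map([tv], df)).values.ravel()[0]
        assert abs(z - z_oracle) < 1e-6

    def test_preserves_ranking(self, rng):
        ts = rng.normal(0, 2, 500)
        z = t_to_z(self._map(ts, 25)).values.ravel()
        assert np.array_equal(np.argsort(ts), np.argsort(z))


class TestZThreshold:
    def test_conventional_values(self):
        assert round(z_threshold_for_p(0.001), 2) == 3.09
        assert abs(z_threshold_for_p(0.5)) < 1e-12

    def test_p05_matches_bisection_oracle(self):
        z_oracle = brentq(lambda z: (1.0 - ndtr(z)) - 0.05, -10, 10, xtol=1e-12)
        assert round(z_threshold_for_p(0.05), 4) == round(z_oracle, 4) == 1.6449

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_invalid_p(self, p):
        with pytest.raises(ValueError):
            z_threshold_for_p(p)


class TestStaging:
    @pytest.mark.parametrize(
        "scheme,score,expected",
        [
            (HY_SCHEME, 1.0, "Stage I"),
            (HY_SCHEME, 2.0, "Stage I"),
            (HY_SCHEME, 2.5, "Stage II"),
            (HY_SCHEME, 3.0, "Stage II"),
            (HY_SCHEME, 4.0, "Stage III"),
            (UPDRS_SCHEME, 23, "Stage I"),
            (UPDRS_SCHEME, 24, "Stage II"),
            (UPDRS_SCHEME, 40, "Stage II"),
            (UPDRS_SCHEME, 41, "Stage III"),
            (MOCA_DEMENTIA_SCHEME, 20, "dementia"),
            (MOCA_DEMENTIA_SCHEME, 21, "no dementia"),
        ],
    )
    def test_bin_lookup(self, scheme, score, expected):
        assert assign_stage({scheme.score: score}, scheme) == expected

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match="outside all bins"):
            assign_stage({"updrs3": 0}, UPDRS_SCHEME)

    def test_partition_of_cohort(self, default_cohort):
        _, table, _ = default_cohort
        pd_rows = table[table["group"] == "PD"]
        stages = [assign_stage(r, HY_SCHEME) for _, r in pd_rows.iterrows()]
        assert len(stages) == len(pd_rows)
        assert set(stages) <= set(HY_SCHEME.labels)


class TestHomogeneityQC:
    def _vols(self, arrays):
        affine = default_affine(arrays[0].shape)
        return [GMVolume(a, affine, subject_id=f"s{i}")
                for i, a in enumerate(arrays)]

    def test_identical_maps_score_one(self, rng):
        base = rng.uniform(0.2, 0.8, (6, 6, 6))
        rep = homogeneity_qc(self._vols([base.copy() for _ in range(5)]))
        assert np.allclose(rep["homogeneity"], 1.0)
        assert not rep["flagged"].any()

    def test_outlier_detected(self, rng):
        base = rng.uniform(0.2, 0.8, (6, 6, 6))
        arrays = [base + rng.normal(0, 0.01, base.shape) for _ in range(20)]
        arrays.append(rng.uniform(0, 1, base.shape))  # pure noise subject
        rep = homogeneity_qc(self._vols(arrays))
        flagged = rep[rep["flagged"]]["subject_id"].tolist()
        assert flagged == ["s20"]

    def test_requires_three_volumes(self, rng):
        arrays = [rng.uniform(0, 1, (4, 4, 4)) for _ in range(2)]
        with pytest.raises(ValueError, match=">= 3"):
            homogeneity_qc(self._vols(arrays))

    def test_constant_map_flagged_with_reason(self, rng):
        base = rng.uniform(0.2, 0.8, (5, 5, 5))
        arrays = [base + rng.normal(0, 0.01, base.shape) for _ in range(4)]
        arrays.append(np.full(base.shape, 0.5))
        rep = homogeneity_qc(self._vols(arrays))
        row = rep[rep["subject_id"] == "s4"].iloc[0]
        assert row["flagged"] and "constant" in row["reason"]


def _mw_exact_oracle(a, b):
    """Two-sided Mann-Whitney p by exhaustive label permutation."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()

    def ustat(idx):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        return min(u1, len(a) * len(b) - u1)

    observed = ustat(range(n1))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if ustat(idx) <= observed + 1e-12:
            count += 1
    return count / total


class TestDemographics:
    def test_sex_chi_square_reference_counts(self):
        rows = []
        for grp, males, females in (("PD", 48, 36), ("HC", 38, 32)):
            rows += [{"group": grp, "sex": "male", "age": 50.0}] * males
            rows += [{"group": grp, "sex": "female", "age": 50.0}] * females
        rep = demographics_table(pd.DataFrame(rows))
        p = rep.loc[rep["variable"] == "sex", "p"].iloc[0]
        assert round(p, 4) == 0.7222

    def test_identical_composition_chi2_zero(self):
        rows = []
        for grp in ("PD", "HC"):
            rows += [{"group": grp, "sex": "male", "age": 50.0}] * 10
            rows += [{"group": grp, "sex": "female", "age": 50.0}] * 10
        rep = demographics_table(pd.DataFrame(rows))
        row = rep[rep["variable"] == "sex"].iloc[0]
        assert row["statistic"] == 0.0 and row["p"] == 1.0

    def test_mannwhitney_matches_enumeration(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 7)
        table = pd.DataFrame(
            {
                "group": ["PD"] * 6 + ["HC"] * 7,
                "sex": ["male"] * 13,
                "age": np.concatenate([a, b]),
            }
        )
        # sex has a zero margin -> chi2 undefined but age row still computed
        rep = demographics_table(table)
        p = rep.loc[rep["variable"] == "age", "p"].iloc[0]
        assert abs(p - _mw_exact_oracle(a, b)) < 1e-10
        sex_row = rep[rep["variable"] == "sex"].iloc[0]
        assert "undefined" in sex_row["note"]


class TestScaleConsistency:
    def _pd_table(self, hy, updrs):
        return pd.DataFrame(
            {"group": ["PD"] * len(hy), "hy": hy, "updrs3": updrs}
        )

    def test_perfect_linearity(self):
        hy = np.array([1.0, 2.0, 2.5, 3.0, 4.0])
        assert scale_consistency(self._pd_table(hy, 10 * hy)) == pytest.approx(1.0)

    def test_antimonotone_is_negative(self):
        hy = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert scale_consistency(self._pd_table(hy, -3 * hy + 60)) < 0

    def test_independent_scores_stay_small(self):
        rng = np.random.default_rng(7)
        small = 0
        for _ in range(100):
            hy = rng.choice([1, 1.5, 2, 2.5, 3, 4, 5], 84)
            updrs = rng.integers(1, 75, 84)
            if abs(scale_consistency(self._pd_table(hy, updrs))) < 0.3:
                small += 1
        assert small >= 90

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            scale_consistency(self._pd_table([2, 2, 2, 2], [5, 8, 9, 11]))
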
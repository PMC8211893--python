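"""Permutation statistics: OLS core, Freedman-Lane inference, effect sizes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ccshape.stats import (Design, PointwiseStats, area_group_analysis,
                           build_design, cohens_d, fit_pointwise_glm,
                           interaction_test, permutation_inference,
                           summarize_significant)


def _cov_frame(n_per_cell=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("FES", "HC"):
        for gender in ("F", "M"):
            for i in range(n_per_cell):
                rows.append({
                    "subject_id": f"{group}-{gender}-{i:03d}", "group": group,
                    "gender": gender, "age": rng.uniform(18, 40),
                    "tiv": rng.normal(1.4e6, 8e4),
                })
    return pd.DataFrame(rows)


def _plain_design(gamma):
    gamma = np.asarray(gamma, float)
    X = np.column_stack([np.ones(len(gamma)), gamma])
    return Design(X=X, columns=["intercept", "group"], group_col=1,
                  subject_ids=[f"s{i}" for i in range(len(gamma))])


class TestGLM:
    def test_exact_linear_data_recovered(self):
        gamma = np.array([1, 1, 1, 0, 0, 0, 1, 0], float)
        Y = (2.0 + 0.5 * gamma)[:, None] * np.ones((1, 4))
        fit = fit_pointwise_glm(Y, _plain_design(gamma))
        assert np.allclose(fit["beta1"], 0.5, atol=1e-12)
        assert np.allclose(fit["residuals"], 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        cov = _cov_frame(3, seed=2)
        design = build_design(cov, scope="all")
        Y = rng.normal(size=(design.n, 6))
        fit = fit_pointwise_glm(Y, design)
        X = design.X
        beta = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(fit["beta"], beta, atol=1e-10)

    def test_constant_group_column_rejected(self):
        gamma = np.zeros(8)
        with pytest.raises(ValueError, match="collinear|constant"):
            fit_pointwise_glm(np.random.default_rng(0).normal(size=(8, 3)),
                              _plain_design(gamma))

    def test_rank_deficient_design_names_columns(self):
        cov = _cov_frame(3)
        cov["age"] = 5.0  # constant age -> collinear with intercept
        with pytest.raises(ValueError, match="age"):
            build_design(cov, scope="all")


class TestCohensD:
    def test_hand_computed_case(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0, abs=1e-12)

    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([0, 0], [0, 0])

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [2.0, 3.0])


def _exhaustive_oracle(y, gamma):
    """Independent enumeration of the two-sample permutation distribution."""
    n = len(y)
    n1 = int(gamma.sum())
    y = np.asarray(y, float)

    def tstat(g):
        a, b = y[g == 1], y[g == 0]
        va = a.var(ddof=1) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) if len(b) > 1 else 0.0
        sp = math.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (n - 2))
        se = sp * math.sqrt(1 / len(a) + 1 / len(b))
        return (a.mean() - b.mean()) / se

    t_obs = abs(tstat(gamma))
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        g = np.zeros(n)
        g[list(combo)] = 1
        total += 1
        if abs(tstat(g)) >= t_obs - 1e-12:
            count += 1
    return count / total


class TestPermutation:
    def test_exhaustive_equals_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=6) + np.array([1, 1, 1, 0, 0, 0]) * 1.2
        gamma = np.array([1, 1, 1, 0, 0, 0], float)
        st = permutation_inference(y[:, None], _plain_design(gamma),
                                   n_perm=1000, seed=0)
        assert st.method == "exhaustive"
        assert st.n_permutations == 20
        assert st.p_raw[0] == pytest.approx(_exhaustive_oracle(y, gamma), abs=1e-12)

    def test_montecarlo_close_to_exhaustive(self):
        rng = np.random.default_rng(8)
        for n_half in (3, 4):
            gamma = np.r_[np.ones(n_half), np.zeros(n_half)]
            y = rng.normal(size=2 * n_half) + gamma * 1.0
            p_ex = _exhaustive_oracle(y, gamma)
            st = permutation_inference(y[:, None], _plain_design(gamma),
                                       n_perm=4000, seed=1, method="montecarlo")
            assert st.method == "montecarlo"
            se = math.sqrt(p_ex * (1 - p_ex) / 4000)
            assert abs(st.p_raw[0] - p_ex) <= 3 * se + 1e-4

    def test_no_zero_pvalues_with_add_one(self):
        rng = np.random.default_rng(2)
        gamma = np.r_[np.ones(10), np.zeros(10)]
        y = rng.normal(size=(20, 5))
        y[:, 0] += gamma * 50  # overwhelming effect
        st = permutation_inference(y, _plain_design(gamma), n_perm=200, seed=0)
        assert st.method == "montecarlo"
        assert np.all(st.p_raw >= 1 / 201)
        assert np.all(st.p_raw > 0)

    def test_fwer_dominates_raw_and_omnibus_identity(self):
        rng = np.random.default_rng(9)
        cov = _cov_frame(6, seed=3)
        design = build_design(cov, scope="all")
        Y = rng.normal(size=(design.n, 12))
        st = permutation_inference(Y, design, n_perm=300, seed=4)
        assert np.all(st.p_fwer >= st.p_raw)
        assert st.omnibus_p == pytest.approx(st.p_fwer.min(), abs=1e-12)
        assert np.all((st.p_raw > 0) & (st.p_raw <= 1))

    def test_invariant_to_subject_ordering(self):
        rng = np.random.default_rng(11)
        cov = _cov_frame(5, seed=5)
        design = build_design(cov, scope="all")
        Y = rng.normal(size=(design.n, 8))
        st1 = permutation_inference(Y, design, n_perm=300, seed=7)
        # shuffle input rows; build_design re-sorts by subject id
        perm = rng.permutation(len(cov))
        design2 = build_design(cov.iloc[perm].reset_index(drop=True), scope="all")
        assert design2.subject_ids == design.subject_ids
        st2 = permutation_inference(Y, design2, n_perm=300, seed=7)
        assert np.allclose(st1.p_raw, st2.p_raw)
        assert np.allclose(st1.p_fwer, st2.p_fwer)

    def test_minimum_permutations(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_inference(np.zeros((6, 2)), _plain_design(np.r_[1, 1, 1, 0, 0, 0]),
                                  n_perm=50)


class TestInteraction:
    def test_female_only_effect_detected(self):
        """Direct marker-matrix simulation: the interaction term has power
        when the effect is restricted to female patients."""
        hits = 0
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            cov = _cov_frame(25, seed=seed)
            Y = rng.normal(0, 0.08, size=(len(cov), 10))
            female_fes = ((cov.group == "FES") & (cov.gender == "F")).to_numpy()
            Y[female_fes, 2:6] -= 0.10
            st = interaction_test(Y, cov, n_perm=400, seed=seed)
            hits += st.omnibus_p <= 0.05
        assert hits >= 8  # >= 2/3 power in this regime

    def test_equal_effect_has_centred_interaction(self):
        betas = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            cov = _cov_frame(12, seed=seed)
            Y = rng.normal(0, 0.1, size=(len(cov), 1))
            Y[(cov.group == "FES").to_numpy(), 0] -= 0.1  # same in both genders
            st = interaction_test(Y, cov, n_perm=200, seed=seed)
            betas.append(st.beta1[0])
        assert abs(np.mean(betas)) < 0.03

    def test_empty_cell_rejected(self):
        cov = _cov_frame(4)
        cov = cov[~((cov.group == "FES") & (cov.gender == "M"))]
        with pytest.raises(ValueError, match="cell"):
            interaction_test(np.zeros((len(cov), 2)), cov, n_perm=200)


class TestAreaAnalysis:
    def _areas(self, cov, seed, gcc_shift=0.0):
        rng = np.random.default_rng(seed)
        n = len(cov)
        fes = (cov.group == "FES").to_numpy()
        scale = (cov.tiv / cov.tiv.mean()).to_numpy() ** (2 / 3)
        g = 180 * scale + rng.normal(0, 6, n) - gcc_shift * fes
        b = 230 * scale + rng.normal(0, 6, n)
        s = 280 * scale + rng.normal(0, 6, n)
        return pd.DataFrame({"subject_id": cov.subject_id, "CC": g + b + s,
                             "gCC": g, "bCC": b, "sCC": s})

    def test_localized_effect_ranks_structures(self):
        wins = 0
        for seed in range(10):
            cov = _cov_frame(15, seed=seed)
            areas = self._areas(cov, seed, gcc_shift=8.0)
            res = area_group_analysis(areas, cov, scope="all", n_perm=300, seed=seed)
            res = res.set_index("structure")
            wins += (res.loc["gCC", "p_value"] < res.loc["bCC", "p_value"]) and (
                res.loc["gCC", "p_value"] < res.loc["sCC", "p_value"])
        assert wins >= 8

    def test_adjusted_difference_sign_convention(self):
        cov = _cov_frame(20, seed=1)
        areas = self._areas(cov, 1, gcc_shift=15.0)
        res = area_group_analysis(areas, cov, scope="all", n_perm=200, seed=1)
        res = res.set_index("structure")
        assert res.loc["gCC", "group_difference"] < 0  # FES - HC < 0

    def test_null_pvalues_uniform(self):
        """Under no effect the per-structure permutation p-values are uniform
        (KS test across replicates)."""
        from scipy.stats import kstest

        ps = []
        for seed in range(120):
            cov = _cov_frame(5, seed=seed)
            areas = self._areas(cov, seed, gcc_shift=0.0)
            res = area_group_analysis(areas, cov, scope="all", n_perm=150, seed=seed)
            ps.extend(res.p_value.tolist())
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_scope_filters_gender(self):
        cov = _cov_frame(8, seed=2)
        areas = self._areas(cov, 2)
        res = area_group_analysis(areas, cov, scope="female", n_perm=150, seed=2)
        assert len(res) == 4
        assert (res.scope == "female").all()


class TestSummarize:
    def _stats(self, p_fwer, d):
        k = len(p_fwer)
        return PointwiseStats(
            beta1=np.zeros(k), t=np.zeros(k), p_raw=np.asarray(p_fwer) / 2,
            p_fwer=np.asarray(p_fwer, float), cohens_d=np.asarray(d, float),
            omnibus_p=float(np.min(p_fwer)), sigma2=np.ones(k),
            n_permutations=100, seed=0, method="montecarlo",
            regions=np.array([1] * (k // 2) + [2] * (k - k // 2)))

    def test_empty_set(self):
        s = summarize_significant(self._stats([0.5, 0.9, 0.7], [0.1, 0.2, 0.3]))
        assert s["n_significant"] == 0
        assert s["mean_cohens_d"] is None
        assert s["clusters"] == []

    def test_all_significant_constant_d(self):
        s = summarize_significant(self._stats([0.01] * 6, [0.5] * 6))
        assert s["n_significant"] == 6
        assert s["mean_cohens_d"] == pytest.approx(0.5)
        assert s["sd_cohens_d"] == pytest.approx(0.0)
        assert s["clusters"] == [[0, 5]]

    def test_cyclic_cluster_detection(self):
        p = np.array([0.01, 0.5, 0.5, 0.5, 0.01, 0.01])
        s = summarize_significant(self._stats(p, [1] * 6))
        assert s["clusters"] == [[4, 0]]
        assert s["counts_by_region"] == {"gCC": 1, "bCC": 2, "sCC": 0}
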
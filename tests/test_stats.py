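"""Mixed-design ANOVA, normality screen, bootstrap post-hoc."""

import numpy as np
import pytest
from scipy import stats as sps

from salnet.stats import (bootstrap_posthoc, gated_network_tests,
                          normality_screen, rm_anova)


def mixed_anova_oracle(y, groups):
    """Independent sums-of-squares decomposition of the split-plot design.

    Returns (F_group, F_condition, F_interaction) with their p-values,
    computed from first principles for cross-checking the pipeline route.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n, k = y.shape
    glabels = np.unique(groups)
    g = len(glabels)
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    ss_between_subj = k * np.sum((subj_mean - grand) ** 2)
    ss_group = k * sum((groups == gl).sum()
                       * (y[groups == gl].mean() - grand) ** 2
                       for gl in glabels)
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = n * np.sum((cond_mean - grand) ** 2)
    ss_inter = 0.0
    for gl in glabels:
        sel = groups == gl
        cell = y[sel].mean(axis=0)
        ss_inter += sel.sum() * np.sum(
            (cell - y[sel].mean() - cond_mean + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_between_subj - ss_cond - ss_inter
    df_g, df_sw = g - 1, n - g
    df_c, df_i, df_e = k - 1, (g - 1) * (k - 1), (n - g) * (k - 1)
    f_g = (ss_group / df_g) / (ss_subj_within / df_sw)
    f_c = (ss_cond / df_c) / (ss_err / df_e)
    f_i = (ss_inter / df_i) / (ss_err / df_e)
    return ((f_g, sps.f.sf(f_g, df_g, df_sw)),
            (f_c, sps.f.sf(f_c, df_c, df_e)),
            (f_i, sps.f.sf(f_i, df_i, df_e)))


class TestRmAnova:
    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((31, 3))
        groups = np.array(["a"] * 14 + ["b"] * 17)
        res = rm_anova(y, groups)
        (f_g, p_g), (f_c, p_c), (f_i, p_i) = mixed_anova_oracle(y, groups)
        assert res.f_group == pytest.approx(f_g, rel=1e-8)
        assert res.p_group == pytest.approx(p_g, rel=1e-8)
        assert res.f_condition == pytest.approx(f_c, rel=1e-8)
        assert res.f_interaction == pytest.approx(f_i, rel=1e-8)
        assert res.p_interaction == pytest.approx(p_i, rel=1e-8)

    def test_gg_epsilon_bounds_and_corrected_dfs(self):
        rng = np.random.default_rng(3)
        # heterogeneous difference variances violate sphericity
        y = np.column_stack([rng.normal(0, 0.1, 40), rng.normal(0, 1, 40),
                             rng.normal(0, 5, 40)])
        groups = np.array(["a"] * 20 + ["b"] * 20)
        res = rm_anova(y, groups)
        k = 3
        assert 1.0 / (k - 1) < res.gg_epsilon <= 1.0
        expected = float(sps.f.sf(res.f_interaction,
                                  res.gg_epsilon * res.df_within[0],
                                  res.gg_epsilon * res.df_within[1]))
        assert res.p_interaction_gg == pytest.approx(expected, rel=1e-10)

    def test_correction_applied_when_mauchly_rejects(self):
        rng = np.random.default_rng(8)
        y = np.column_stack([rng.normal(0, 0.05, 60), rng.normal(0, 1, 60),
                             rng.normal(0, 8, 60)])
        groups = np.array(["a"] * 30 + ["b"] * 30)
        res = rm_anova(y, groups)
        assert res.mauchly_p < 0.05
        assert res.correction_applied
        assert res.p_interaction_reported == res.p_interaction_gg

    def test_constant_data_errors(self):
        y = np.ones((10, 3))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="constant"):
            rm_anova(y, groups)

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(5)
        n = 15
        base = rng.standard_normal((2 * n, 1)) * 0.3
        y = base + 0.2 * rng.standard_normal((2 * n, 3))
        y[:n] += np.array([1.0, 0.0, -1.0])   # group a decreasing
        y[n:] += np.array([-1.0, 0.0, 1.0])   # group b increasing
        groups = np.array(["a"] * n + ["b"] * n)
        res = rm_anova(y, groups)
        assert res.p_interaction_reported < 1e-6


class TestNormalityScreen:
    def test_gaussian_passes(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        assert normality_screen(x).passed

    def test_heavy_tails_fail(self):
        # scale mixture of normals with analytic excess kurtosis 10:
        # 5% N(0, 15.4) + 95% N(0, 1) (all moments finite, so the sample
        # kurtosis concentrates, unlike a kurtosis-10 t distribution)
        rng = np.random.default_rng(1)
        n = 400_000
        x = rng.standard_normal(n)
        wide = rng.random(n) < 0.05
        x[wide] *= np.sqrt(15.4)
        v = 0.05 * 15.4 + 0.95
        analytic_g2 = 3 * (0.05 * 15.4 ** 2 + 0.95) / v ** 2 - 3
        assert analytic_g2 == pytest.approx(10.0, abs=0.15)
        res = normality_screen(x)
        assert not res.passed
        assert abs(res.kurtosis) >= 7

    def test_constant_vector_flagged_not_passed(self):
        res = normality_screen(np.full(100, 2.5))
        assert not res.valid and not res.passed


class TestBootstrap:
    def test_identical_groups_ci_straddles_zero(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        res = bootstrap_posthoc(x, x.copy(), 3000, seed=4)
        assert res.ci_low < 0 < res.ci_high

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(15), rng.standard_normal(17)
        r1 = bootstrap_posthoc(a, b, 2000, seed=9)
        r2 = bootstrap_posthoc(a, b, 2000, seed=9)
        assert (r1.ci_low, r1.ci_high, r1.p_value) == \
            (r2.ci_low, r2.ci_high, r2.p_value)

    def test_true_difference_detected(self):
        # difference 1.0, sd 0.1, n = 15: the CI excludes 0 in essentially
        # every replicate
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(50):
            a = 1.0 + 0.1 * rng.standard_normal(15)
            b = 0.1 * rng.standard_normal(15)
            res = bootstrap_posthoc(a, b, 1000,
                                    seed=int(rng.integers(2 ** 31)))
            hits += res.ci_low > 0
        assert hits >= 50 * 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_posthoc([], [1.0, 2.0])


class TestGatedProcedure:
    def _cohort_frame(self, effect: float, seed: int):
        import pandas as pd
        rng = np.random.default_rng(seed)
        rows = []
        for gi, (group, n) in enumerate([("nrMDD", 14), ("rMDD", 17)]):
            sign = 1 if gi == 0 else -1
            for i in range(n):
                base = 0.5 + 0.05 * rng.standard_normal()
                for ci, cond in enumerate(("RS", "Std", "Dev")):
                    shift = sign * effect * (ci - 1)
                    edges = np.clip(
                        base + shift + 0.02 * rng.standard_normal(3), 0, 1)
                    rows.append({
                        "subject": f"{group}{i}", "group": group,
                        "band": "high_beta", "condition": cond,
                        "strength": float(edges.sum()),
                        "wpli_dACC_lIns": edges[0],
                        "wpli_dACC_rIns": edges[1],
                        "wpli_lIns_rIns": edges[2], "n_epochs": 45})
        return pd.DataFrame(rows)

    def test_gate_blocks_edge_tests_under_null(self):
        res = gated_network_tests(self._cohort_frame(0.0, seed=123),
                                  "high_beta", gate_p=1e-6)
        assert not res["gate_passed"]
        assert res["edges"] == {}

    def test_gate_opens_on_planted_interaction_and_runs_posthoc(self):
        res = gated_network_tests(self._cohort_frame(0.15, seed=1),
                                  "high_beta", n_bootstrap=500)
        assert res["gate_passed"]
        assert len(res["edges"]) == 3
        assert len(res["posthoc"]) > 0
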
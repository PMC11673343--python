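"""Statistical battery: closed-form oracles and frozen external references.

The `R_REF` constants were computed once with R 4.3.3 (shapiro.test,
cor.test, t.test(var.equal=TRUE), wilcox.test(exact=FALSE, correct=TRUE),
aov with a subject error stratum, emmeans Tukey-adjusted pairs) on the same
deterministically seeded samples that the tests regenerate below.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

import epimux as em

# frozen reference values (R 4.3.3)
R_REF = {
    "shapiro_a": (0.93430377855963642, 0.18678870475061091),
    "shapiro_b": (0.63748194728788821, 7.3868685067303349e-06),
    "shapiro_g1": (0.97443038629413159, 0.34704749663605455),
    "shapiro_g2": (0.98126510399041478, 0.60641223073096984),
    "pearson": (0.64173093248716861, 0.086287635106253133),
    "ttest": (-0.17256713458697878, 0.86491721636600116),
    "wilcox": (46.0, 0.79133678010066055),
    "rm_F": (8.5670187171642613, 0.017446143853043748),
    "tukey": {("r0", "r1"): (-0.81210882986069477, 0.21283652689665422),
              ("r0", "r2"): (0.93541099230722569, 0.14706670941744626),
              ("r1", "r2"): (1.7475198221679205, 0.014405069862977071)},
}

TOL = 1e-6


def _samples():
    a = np.random.default_rng(42).normal(10, 2, 20)
    b = np.random.default_rng(43).choice([0.0, 10.0], size=20)
    x = np.random.default_rng(44).normal(0, 1, 8)
    y = 0.6 * x + np.random.default_rng(45).normal(0, 0.8, 8)
    tx = np.random.default_rng(46).normal(5, 1, 10)
    ty = np.random.default_rng(47).normal(6, 1.2, 10)
    g1 = np.random.default_rng(48).normal(0, 1, 50)
    g2 = np.random.default_rng(49).normal(5, 2, 50)
    return a, b, x, y, tx, ty, g1, g2


def _rm_table():
    rngr = np.random.default_rng(50)
    subj = rngr.normal(0, 1, 4)
    reg = np.array([0.0, 1.5, -0.5])
    vals = subj[:, None] + reg[None, :] + rngr.normal(0, 0.7, (4, 3))
    return pd.DataFrame(
        [{"case_id": f"c{i}", "region": f"r{j}", "value": vals[i, j]}
         for i in range(4) for j in range(3)]
    )


class TestNormalityRoute:
    def test_heavy_two_point_sample_routes_nonparametric(self):
        a, b, *_ = _samples()
        route, results = em.normality_route({"a": a, "b": b})
        assert route == "nonparametric"
        by = {r.comparison[0]: r for r in results}
        for key, name in [("a", "shapiro_a"), ("b", "shapiro_b")]:
            w_ref, p_ref = R_REF[name]
            assert by[key].statistic == pytest.approx(w_ref, abs=TOL)
            assert by[key].p_value == pytest.approx(p_ref, abs=TOL)

    def test_gaussian_samples_route_parametric(self):
        *_, g1, g2 = _samples()
        route, results = em.normality_route({"g1": g1, "g2": g2})
        assert route == "parametric"
        for res, name in zip(results, ("shapiro_g1", "shapiro_g2")):
            assert res.statistic == pytest.approx(R_REF[name][0], abs=TOL)

    def test_small_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="tiny"):
            em.normality_route({"ok": np.arange(5.0), "tiny": np.arange(2.0)})


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = em.correlate_pearson(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        res_neg = em.correlate_pearson(x, -x)
        assert res_neg.statistic == pytest.approx(-1.0, abs=1e-12)

    def test_seeded_sample_matches_reference(self):
        _, _, x, y, *_ = _samples()
        res = em.correlate_pearson(x, y)
        r_ref, p_ref = R_REF["pearson"]
        assert res.statistic == pytest.approx(r_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_closed_form_on_the_fly(self, rng):
        x = rng.normal(size=8); y = rng.normal(size=8)
        res = em.correlate_pearson(x, y)
        r = np.corrcoef(x, y)[0, 1]
        from scipy import stats as sps
        t = r * np.sqrt(6 / (1 - r * r))
        assert res.statistic == pytest.approx(r, abs=1e-10)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), 6), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            em.correlate_pearson([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            em.correlate_pearson([1, 2, 3], [1, 2])


class TestRmAnovaTukey:
    def test_null_configuration_f_zero_p_one(self):
        table = pd.DataFrame(
            [{"case_id": f"c{i}", "region": f"r{j}", "value": 10.0 + i}
             for i in range(4) for j in range(3)]
        )
        anova, pairs = em.rm_anova_tukey(table)
        assert anova.statistic == 0.0 and anova.p_value == 1.0
        assert all(p.p_value == 1.0 for p in pairs)

    def test_matches_r_reference(self):
        anova, pairs = em.rm_anova_tukey(_rm_table())
        f_ref, p_ref = R_REF["rm_F"]
        assert anova.statistic == pytest.approx(f_ref, abs=TOL)
        assert anova.p_value == pytest.approx(p_ref, abs=TOL)
        for pr in pairs:
            d_ref, p_pair_ref = R_REF["tukey"][pr.comparison]
            assert pr.effect == pytest.approx(d_ref, abs=TOL)
            assert pr.p_value == pytest.approx(p_pair_ref, abs=TOL)

    def test_matches_explicit_sums_of_squares(self):
        table = _rm_table()
        data = table.pivot_table(index="case_id", columns="region",
                                 values="value").to_numpy()
        n, k = data.shape
        grand = data.mean()
        ss_reg = n * ((data.mean(0) - grand) ** 2).sum()
        ss_sub = k * ((data.mean(1) - grand) ** 2).sum()
        ss_err = ((data - grand) ** 2).sum() - ss_reg - ss_sub
        f_brute = (ss_reg / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        anova, _ = em.rm_anova_tukey(table)
        assert anova.statistic == pytest.approx(f_brute, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        table = _rm_table()
        res = pg.rm_anova(data=table, dv="value", within="region",
                          subject="case_id")
        anova, _ = em.rm_anova_tukey(table)
        assert anova.statistic == pytest.approx(res["F"][0], abs=TOL)
        assert anova.p_value == pytest.approx(res["p_unc"][0], abs=TOL)

    def test_two_levels_tukey_equals_anova_p(self):
        table = _rm_table()
        table = table[table["region"] != "r2"]
        anova, pairs = em.rm_anova_tukey(table)
        assert len(pairs) == 1
        assert pairs[0].p_value == pytest.approx(anova.p_value, abs=1e-9)

    def test_incomplete_cases_dropped(self):
        table = _rm_table().iloc[:-1]  # c3 misses r2
        anova, _ = em.rm_anova_tukey(table)
        assert anova.extra["n_complete"] == 3
        assert anova.extra["n_dropped"] == 1

    def test_insufficient_cases_rejected(self):
        table = _rm_table()[lambda d: d["case_id"] == "c0"]
        with pytest.raises(ValueError):
            em.rm_anova_tukey(table)


class TestTwoGroups:
    def test_identical_samples_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = em.compare_two_groups(x, x, "parametric")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_complete_separation_u_zero(self):
        res = em.compare_two_groups([1, 2, 3], [10, 11, 12], "nonparametric")
        assert res.statistic == 0.0
        assert res.extra["U_prime"] == 9.0

    def test_seeded_samples_match_reference(self):
        *_, tx, ty, _, _ = _samples()
        t_res = em.compare_two_groups(tx, ty, "parametric")
        assert t_res.statistic == pytest.approx(R_REF["ttest"][0], abs=1e-10)
        assert t_res.p_value == pytest.approx(R_REF["ttest"][1], abs=1e-10)
        u_res = em.compare_two_groups(tx, ty, "nonparametric")
        assert u_res.statistic == pytest.approx(R_REF["wilcox"][0], abs=TOL)
        assert u_res.p_value == pytest.approx(R_REF["wilcox"][1], abs=TOL)

    def test_u_matches_brute_force_pair_counting(self, rng):
        x = rng.integers(0, 20, 10).astype(float)  # ties on purpose
        y = rng.integers(0, 20, 12).astype(float)
        res = em.compare_two_groups(x, y, "nonparametric")
        u_brute = sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0)
            for xi, yi in itertools.product(x, y)
        )
        assert res.statistic == u_brute
        assert res.statistic + res.extra["U_prime"] == len(x) * len(y)

    def test_antisymmetry(self, rng):
        x = rng.normal(0, 1, 8); y = rng.normal(1, 1, 9)
        t_xy = em.compare_two_groups(x, y, "parametric")
        t_yx = em.compare_two_groups(y, x, "parametric")
        assert t_xy.statistic == pytest.approx(-t_yx.statistic, abs=1e-12)
        assert t_xy.p_value == pytest.approx(t_yx.p_value, abs=1e-12)
        u_xy = em.compare_two_groups(x, y, "nonparametric")
        u_yx = em.compare_two_groups(y, x, "nonparametric")
        assert u_xy.statistic == pytest.approx(u_yx.extra["U_prime"])
        assert u_xy.p_value == pytest.approx(u_yx.p_value, abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            em.compare_two_groups([1, 2], [3, 4, 5], "parametric")


class TestSummaries:
    def test_textbook_mean_and_sd(self):
        table = pd.DataFrame({
            "group": "PD", "region": "medulla",
            "measure": "pathology_load_pct",
            "case_id": ["a", "b", "c"], "value": [1.0, 2.0, 3.0],
        })
        out = em.summarize_cohort(table)
        assert out.loc[0, "mean"] == 2.0 and out.loc[0, "sd"] == 1.0
        assert out.loc[0, "n"] == 3
        assert out.loc[0, "formatted"] == "2.00% ± 1.00%"

    def test_single_value_flagged_sd_zero(self):
        table = pd.DataFrame({"group": ["PD"], "region": ["ION"],
                              "measure": ["m"], "case_id": ["a"],
                              "value": [5.0]})
        out = em.summarize_cohort(table)
        assert out.loc[0, "sd"] == 0.0 and bool(out.loc[0, "single_value"])

    def test_simulated_cohort_truth_summary_recomputes(self):
        cfg = em.build_preset("PD_like")
        _, _, table = em.simulate_cohort(cfg, 4, base_seed=11)
        loads = table[table["measure"] == "pathology_load_pct"]
        out = em.summarize_cohort(loads)
        row = out[out["measure"] == "pathology_load_pct"].iloc[0]
        assert row["mean"] == pytest.approx(loads["value"].mean())
        assert row["sd"] == pytest.approx(loads["value"].std(ddof=1))


def test_holm_adjustment_monotone_and_bounded():
    ps = [0.04, 0.01, 0.3, 0.002]
    adj = em.holm_adjust(ps)
    assert all(0 <= a <= 1 for a in adj)
    assert all(a >= p for a, p in zip(adj, ps))
    assert adj[3] == pytest.approx(0.008)
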
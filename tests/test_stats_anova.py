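"""Statistics battery: distribution checks, ANOVA oracles, pairwise tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gaitsym.stats import (StatsError, bonferroni_pairwise, levene, mixed_anova,
                           oneway_anova, rm_anova_oneway, shapiro_wilk)


# ---------------------------------------------------------------------------
# independent projection-matrix split-plot oracle (balanced designs)
# ---------------------------------------------------------------------------

def _hat(X):
    return X @ np.linalg.pinv(X)


def _indicator(codes):
    codes = np.asarray(codes)
    levels = pd.unique(codes)
    return np.column_stack([(codes == lv).astype(float) for lv in levels])


def brute_force_split_plot(table, dv="si"):
    """Split-plot SS via explicit projection matrices (balanced data only)."""
    tbl = table.sort_values(["participant_id", "condition"]).reset_index(drop=True)
    y = tbl[dv].to_numpy(float)
    N = len(y)
    ones = np.ones((N, 1))
    P0 = _hat(ones)
    Pg = _hat(_indicator(tbl["group"]))
    Pc = _hat(_indicator(tbl["condition"]))
    Ps = _hat(_indicator(tbl["participant_id"]))
    cells = tbl["group"].astype(str) + "|" + tbl["condition"].astype(str)
    Pgc = _hat(_indicator(cells))
    ss = {
        "group": y @ (Pg - P0) @ y,
        "subj_within": y @ (Ps - Pg) @ y,
        "condition": y @ (Pc - P0) @ y,
        "interaction": y @ (Pgc - Pg - Pc + P0) @ y,
        "error_within": y @ (np.eye(N) - Ps - Pgc + Pg) @ y,
    }
    n = tbl["participant_id"].nunique()
    j = tbl["group"].nunique()
    k = tbl["condition"].nunique()
    df = {"group": j - 1, "subj_within": n - j, "condition": k - 1,
          "interaction": (j - 1) * (k - 1), "error_within": (n - j) * (k - 1)}
    f = {
        "group": (ss["group"] / df["group"]) / (ss["subj_within"] / df["subj_within"]),
        "condition": (ss["condition"] / df["condition"]) / (ss["error_within"] / df["error_within"]),
        "interaction": (ss["interaction"] / df["interaction"]) / (ss["error_within"] / df["error_within"]),
    }
    return ss, f


def _random_balanced_table(seed, n_groups=2, n_subj=4, k=3):
    rng = np.random.default_rng(seed)
    rows = []
    for gi in range(n_groups):
        for s in range(n_subj):
            pid = f"g{gi}s{s}"
            base = rng.normal(10 * gi, 2)
            for c in range(k):
                rows.append({"participant_id": pid, "group": f"g{gi}",
                             "condition": f"c{c}",
                             "si": base + 1.5 * c + rng.normal(0, 1)})
    return pd.DataFrame(rows)


class TestChecks:
    def test_shapiro_three_linear_points(self):
        w, _p = shapiro_wilk([1.0, 2.0, 3.0])
        assert w == pytest.approx(1.0, abs=1e-6)

    def test_shapiro_power_on_lognormal(self):
        rng = np.random.default_rng(0)
        hits = sum(shapiro_wilk(np.exp(rng.normal(size=50)))[1] < 0.05
                   for _ in range(200))
        assert hits >= 190

    def test_shapiro_constant_rejected(self):
        with pytest.raises(StatsError):
            shapiro_wilk(np.ones(10))

    def test_shapiro_n_out_of_range(self):
        with pytest.raises(StatsError):
            shapiro_wilk([1.0, 2.0])

    def test_levene_identical_groups(self):
        f, _p = levene([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_levene_type_one_calibration(self):
        rng = np.random.default_rng(1)
        rej = sum(levene(rng.normal(size=30), rng.normal(size=30))[1] < 0.05
                  for _ in range(1000))
        assert 0.03 <= rej / 1000 <= 0.07

    def test_levene_power(self):
        rng = np.random.default_rng(2)
        rej = sum(levene(rng.normal(0, 1, 30), rng.normal(0, 4, 30))[1] < 0.05
                  for _ in range(200))
        assert rej / 200 > 0.9

    def test_levene_needs_two_groups(self):
        with pytest.raises(StatsError):
            levene([1, 2, 3.0])


class TestMixedAnova:
    def test_constant_dv_gives_zero_f(self):
        tbl = _random_balanced_table(0)
        tbl["si"] = 7.0
        res = mixed_anova(tbl)
        for eff in res.effects.values():
            assert eff.f == pytest.approx(0.0, abs=1e-12)

    def test_epsilon_is_one_with_two_conditions(self):
        tbl = _random_balanced_table(3, k=2)
        res = mixed_anova(tbl)
        assert res.epsilon_gg == pytest.approx(1.0)

    def test_epsilon_bounds(self):
        for seed in range(10):
            res = mixed_anova(_random_balanced_table(seed))
            k = res.k_conditions
            assert 1.0 / (k - 1) - 1e-12 <= res.epsilon_gg <= 1.0 + 1e-12

    def test_ss_additivity(self):
        for seed in range(5):
            tbl = _random_balanced_table(seed, n_groups=3, n_subj=5)
            res = mixed_anova(tbl)
            e = res.effects
            ss_sum = (e["group"].ss + e["group"].ss_error + e["condition"].ss
                      + e["interaction"].ss + e["condition"].ss_error)
            assert ss_sum == pytest.approx(res.ss_total, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_projection_matrix_oracle(self, seed):
        tbl = _random_balanced_table(seed, n_groups=2 + seed % 2, n_subj=4 + seed % 3)
        res = mixed_anova(tbl)
        ss, f = brute_force_split_plot(tbl)
        for name in ("group", "condition", "interaction"):
            assert res.effects[name].ss == pytest.approx(ss[name], rel=1e-9)
            assert res.effects[name].f == pytest.approx(f[name], rel=1e-9)
        assert res.effects["group"].ss_error == pytest.approx(ss["subj_within"], rel=1e-9)
        assert res.effects["condition"].ss_error == pytest.approx(ss["error_within"], rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        tbl = _random_balanced_table(11, n_groups=3, n_subj=6)
        res = mixed_anova(tbl)
        ref = pg.mixed_anova(data=tbl, dv="si", within="condition",
                             subject="participant_id", between="group")
        ref = ref.set_index("Source")
        assert res.effects["group"].f == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res.effects["condition"].f == pytest.approx(ref.loc["condition", "F"], rel=1e-6)
        assert res.effects["interaction"].f == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    def test_incomplete_subject_listwise_deleted(self):
        tbl = _random_balanced_table(4)
        tbl = tbl.drop(tbl[(tbl.participant_id == "g0s0")
                           & (tbl.condition == "c2")].index)
        res = mixed_anova(tbl)
        assert res.n_dropped == 1
        assert res.n_subjects == tbl.participant_id.nunique() - 1

    def test_missing_columns_rejected(self):
        with pytest.raises(StatsError):
            mixed_anova(pd.DataFrame({"si": [1.0, 2.0]}))


class TestRmAnova:
    def test_constant_dv(self):
        tbl = _random_balanced_table(0, n_groups=1)
        tbl["si"] = 3.0
        res = rm_anova_oneway(tbl)
        assert res.effects["condition"].f == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle_within_single_group(self):
        tbl = _random_balanced_table(8, n_groups=1, n_subj=7)
        res = rm_anova_oneway(tbl)
        # independent check: scipy-free classical RM computation via pingouin
        pg = pytest.importorskip("pingouin")
        ref = pg.rm_anova(data=tbl, dv="si", within="condition",
                          subject="participant_id", correction=True)
        assert res.effects["condition"].f == pytest.approx(
            float(ref["F"].iloc[0]), rel=1e-6)
        assert res.epsilon_gg == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)

    def test_epsilon_compound_symmetry(self):
        """Under compound symmetry epsilon approaches 1 for large n."""
        rng = np.random.default_rng(9)
        rows = []
        for s in range(200):
            base = rng.normal(0, 2)
            for c in range(3):
                rows.append({"participant_id": f"s{s}", "group": "all",
                             "condition": f"c{c}", "si": base + rng.normal()})
        res = rm_anova_oneway(pd.DataFrame(rows))
        assert res.epsilon_gg > 0.9


class TestOneway:
    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = oneway_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.f == pytest.approx(t.statistic ** 2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_textbook_fixture(self):
        """3 groups x 3 integer observations, SS worked by hand."""
        groups = [[1.0, 2, 3], [2.0, 3, 4], [3.0, 4, 5]]
        res = oneway_anova(groups)
        assert res.ss == pytest.approx(6.0)        # between
        assert res.ss_error == pytest.approx(6.0)  # within
        assert res.f == pytest.approx((6 / 2) / (6 / 6))

    def test_equal_groups_zero_f(self):
        res = oneway_anova([[1.0, 2, 3], [1.0, 2, 3]])
        assert res.f == pytest.approx(0.0, abs=1e-12)

    def test_scipy_agreement(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(i, 1, 10) for i in range(4)]
        res = oneway_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.f == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestBonferroni:
    def test_family_sizes(self):
        samples = {f"g{i}": np.arange(5.0) + i for i in range(7)}
        out = bonferroni_pairwise(samples)
        assert out.m == 21
        rng = np.random.default_rng(0)
        samples3 = {c: rng.normal(i, 1, 4) for i, c in enumerate("abc")}
        assert bonferroni_pairwise(samples3, paired=True).m == 3

    def test_adjustment_and_cap(self):
        rng = np.random.default_rng(5)
        samples = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10),
                   "c": rng.normal(3, 1, 10)}
        out = bonferroni_pairwise(samples)
        for _, row in out.rows.iterrows():
            assert row.p_bonferroni == pytest.approx(min(1.0, 3 * row.p_raw))
        assert (out.rows.p_bonferroni <= 1.0).all()

    def test_single_pair_unadjusted(self):
        rng = np.random.default_rng(6)
        out = bonferroni_pairwise({"a": rng.normal(size=8), "b": rng.normal(size=8)})
        row = out.rows.iloc[0]
        assert row.p_bonferroni == pytest.approx(row.p_raw)

    def test_paired_uses_rel_ttest(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=10)
        b = a + rng.normal(0.5, 0.1, 10)
        out = bonferroni_pairwise({"a": a, "b": b}, paired=True)
        ref = sps.ttest_rel(a, b)
        assert out.rows.iloc[0].t == pytest.approx(ref.statistic)

    def test_single_unit_rejected(self):
        with pytest.raises(StatsError):
            bonferroni_pairwise({"a": np.arange(3.0)})
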
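"""TMM factors, log normalization, the moderated two-group test, screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import weaknet as wn
from weaknet.expression import CASE, CONTROL


def _matrix(values, groups):
    values = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(len(values))],
        columns=[f"s{j}" for j in range(len(groups))],
    )
    return wn.LabeledExpressionMatrix(
        values, {f"s{j}": g for j, g in enumerate(groups)}
    )


def _tmm_oracle(x, j, ref, trim_m=0.30, trim_a=0.05):
    """Independent step-by-step evaluation of the doubly-trimmed weighted M mean."""
    lib = x.sum(axis=0)
    obs, refv = x[:, j], x[:, ref]
    keep = (obs > 0) & (refv > 0)
    o, r = obs[keep] / lib[j], refv[keep] / lib[ref]
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + (lib[ref] - refv[keep]) / (
        lib[ref] * refv[keep]
    )
    n = m.size
    lo_m, lo_a = int(np.floor(n * trim_m)) + 1, int(np.floor(n * trim_a)) + 1
    rm, ra = stats.rankdata(m), stats.rankdata(a)
    sel = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
    return 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))


class TestTMM:
    def test_identical_samples_get_unit_factors(self):
        m = _matrix(np.tile([[4.0], [1.0], [7.0], [2.0]], (1, 4)),
                    [CONTROL, CONTROL, CASE, CASE])
        assert np.allclose(wn.tmm_factors(m), 1.0)

    def test_global_library_scaling_is_absorbed(self):
        base = np.array([[4.0], [1.0], [7.0], [2.0]])
        m = _matrix(np.hstack([base, 2 * base, base, 2 * base]),
                    [CONTROL, CONTROL, CASE, CASE])
        assert np.allclose(wn.tmm_factors(m), 1.0, atol=1e-12)

    def test_factors_match_independent_formula_evaluation(self):
        rng = np.random.default_rng(21)
        x = rng.lognormal(2.5, 1.0, (40, 2)) * np.array([1.0, 1.7])
        m = _matrix(x, [CONTROL, CASE])
        factors = wn.tmm_factors(m)
        lib = x.sum(axis=0)
        f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(2)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        raw = np.array([_tmm_oracle(x, j, ref) for j in range(2)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(factors.to_numpy(), expected, atol=1e-10)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(22)
        m = _matrix(rng.lognormal(3, 1, (60, 6)) * rng.uniform(0.3, 3, 6),
                    [CONTROL] * 3 + [CASE] * 3)
        f = wn.tmm_factors(m).to_numpy()
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-12

    def test_all_zero_sample_is_rejected_by_name(self):
        x = np.array([[1.0, 0.0], [2.0, 0.0]])
        m = _matrix(x, [CONTROL, CASE])
        with pytest.raises(ValueError, match="s1"):
            wn.tmm_factors(m)


class TestNormalizeLog:
    @pytest.mark.parametrize(
        "value,factor,pseudo,expected",
        [(0.0, 1.0, 1.0, 0.0), (3.0, 1.0, 1.0, 2.0), (7.0, 2.0, 0.5, 2.0)],
    )
    def test_pointwise_formula(self, value, factor, pseudo, expected):
        m = _matrix([[value, value]], [CONTROL, CASE])
        factors = pd.Series([factor, factor], index=m.samples)
        out = wn.normalize_log(m, factors, pseudocount=pseudo)
        assert out.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_shape_and_labels_preserved(self, toy_matrix):
        out = wn.normalize_log(toy_matrix, wn.tmm_factors(toy_matrix))
        assert out.values.shape == toy_matrix.values.shape
        assert out.group == toy_matrix.group


class TestDifferentialTest:
    def test_identical_groups_give_zero_fc_and_p_one(self):
        x = np.array([[5.0] * 6, [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        m = _matrix(x, [CONTROL] * 3 + [CASE] * 3)
        res = wn.de_two_group(m)
        assert res.loc["g0", "log2fc"] == 0
        assert res.loc["g0", "p_value"] == pytest.approx(1.0)
        assert res.loc["g1", "log2fc"] == 0
        assert res.loc["g1", "p_value"] == pytest.approx(1.0)

    def test_unmoderated_pooled_t_matches_textbook_formula(self):
        ctrl, case = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        m = _matrix([np.concatenate([ctrl, case])], [CONTROL] * 3 + [CASE] * 3)
        res = wn.de_two_group(m, moderate=False)
        sp = np.sqrt((ctrl.var(ddof=1) * 2 + case.var(ddof=1) * 2) / 4)
        t = (case.mean() - ctrl.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), 4)
        assert res["t_stat"].iloc[0] == pytest.approx(t, abs=1e-12)
        assert res["p_value"].iloc[0] == pytest.approx(p, abs=1e-12)

    def test_welch_option_matches_scipy(self):
        rng = np.random.default_rng(31)
        x = rng.normal(5, 1, (10, 9))
        m = _matrix(x, [CONTROL] * 4 + [CASE] * 5)
        res = wn.de_two_group(m, variance="welch")
        sci = stats.ttest_ind(x[:, 4:], x[:, :4], axis=1, equal_var=False)
        np.testing.assert_allclose(res["t_stat"], sci.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p_value"], sci.pvalue, atol=1e-10)

    def test_null_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(32)
        x = rng.lognormal(3, 0.5, (2000, 40))
        m = _matrix(x, [CONTROL] * 20 + [CASE] * 20)
        res = wn.de_two_group(wn.normalize_log(m))
        frac = float((res["p_value"] <= 0.05).mean())
        assert 0.035 <= frac <= 0.065

    def test_invariant_to_sample_order_within_groups(self, default_config):
        graph, truth = wn.generate_signaling_graph(default_config)
        (cohort, *_) = wn.generate_expression_cohorts(default_config, graph, truth)
        res1 = wn.de_two_group(wn.normalize_log(cohort))
        rng = np.random.default_rng(33)
        ctrl = cohort.samples_in_group(CONTROL)
        case = cohort.samples_in_group(CASE)
        shuffled = list(rng.permutation(ctrl)) + list(rng.permutation(case))
        perm = wn.LabeledExpressionMatrix(
            cohort.values[shuffled], dict(cohort.group), cohort.cohort
        )
        res2 = wn.de_two_group(wn.normalize_log(perm))
        np.testing.assert_allclose(res1["t_stat"], res2["t_stat"], atol=1e-10)

    def test_small_group_is_rejected(self):
        m = _matrix([[1.0, 2.0, 3.0]], [CONTROL, CASE, CASE])
        with pytest.raises(ValueError, match="control"):
            wn.de_two_group(m)

    def test_sign_of_t_matches_sign_of_log2fc(self, default_config):
        graph, truth = wn.generate_signaling_graph(default_config)
        (cohort, *_) = wn.generate_expression_cohorts(default_config, graph, truth)
        res = wn.de_two_group(wn.normalize_log(cohort))
        nz = res[res["t_stat"] != 0]
        assert (np.sign(nz["t_stat"]) == np.sign(nz["log2fc"])).all()


class TestScreening:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "fc": [1.5, 1.05, 0.6, 1.2, 0.95],
                "p_value": [0.01, 0.01, 0.05, 0.5, 0.02],
            },
            index=list("abcde"),
        )

    def test_hand_set_table_is_screened_exactly(self, table):
        assert wn.screen_degs(table, 1.1, 0.1, "up") == {"a"}
        assert wn.screen_degs(table, 1.1, 0.1, "down") == {"c"}

    def test_thresholds_of_one_keep_everything_upregulated(self, table):
        assert wn.screen_degs(table, 1.0, 1.0, "up") == {"a", "b", "d"}

    def test_up_and_down_screens_are_disjoint(self, table):
        up = wn.screen_degs(table, 1.01, 1.0, "up")
        down = wn.screen_degs(table, 1.01, 1.0, "down")
        assert not up & down

    def test_power_on_planted_weak_activation(self):
        """At fc 1.25, 80 v 80, sd 0.5: most planted genes pass the weak screen."""
        cfg = wn.SimulationConfig(
            n_genes=400, n_pathways=4, pathway_size_range=(40, 60),
            n_activated_pathways=2, activation_fc_range=(1.2499, 1.25),
            n_control=80, n_case=80, dispersion=0.5, seed=34,
        )
        graph, truth = wn.generate_signaling_graph(cfg)
        (cohort, *_) = wn.generate_expression_cohorts(cfg, graph, truth)
        res = wn.de_two_group(wn.normalize_log(cohort))
        up = wn.screen_degs(res, 1.1, 0.1, "up")
        planted = {g for g, fc in truth.per_gene_fc.items() if fc > 1}
        assert len(up & planted) / len(planted) >= 0.60

    def test_intersection_semantics(self):
        assert wn.intersect_degs([{"A", "B", "C"}, {"B", "C", "D"}]) == {"B", "C"}
        assert wn.intersect_degs([{"A", "B"}]) == {"A", "B"}
        assert wn.intersect_degs([{"A"}, {"B"}]) == frozenset()
        with pytest.raises(ValueError):
            wn.intersect_degs([])
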
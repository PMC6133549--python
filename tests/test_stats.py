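"""Association models, repeated-measures ANOVA with Tukey HSD, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prestim_connect import (
    compare_network_connectivity,
    edgewise_association,
    generate_cohort,
    psfc_association,
    rm_anova,
    sensitivity_excluding_brainstem,
    stimulus_stability,
    strong_coupling_config,
    targeted_edge_config,
)
from prestim_connect.pipeline import analyse_cohort


class TestAssociation:
    def test_deterministic_linear_relation(self, rng):
        psfc = rng.uniform(0, 1, 13)
        ga = rng.uniform(38, 43, 13)
        y = 3.0 - 2.0 * psfc
        res = psfc_association(y, psfc, ga)
        assert res.beta == pytest.approx(-2.0, abs=1e-10)
        assert res.n == 13
        # exact r = -1 requires removing the sample GA leakage from both
        # sides: the partial-correlation convention
        partial = psfc_association(y, psfc, ga, partial=True)
        assert partial.adjusted_r == pytest.approx(-1.0, abs=1e-10)
        assert res.adjusted_r < -0.9

    def test_constant_psfc_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            psfc_association(rng.normal(size=10), np.ones(10), rng.normal(size=10))

    def test_too_few_infants_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            psfc_association([1, 2, 3], [0.1, 0.2, 0.3], [38, 39, 40])

    def test_missing_values_rejected(self, rng):
        y = rng.normal(size=8)
        y[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            psfc_association(y, rng.normal(size=8), rng.normal(size=8))

    def test_adjusted_r_equals_partial_r_when_ga_orthogonal(self, rng):
        # orthogonalise psFC against GA: the plain and partial conventions
        # must then agree exactly
        ga = rng.uniform(38, 43, 30)
        x = rng.normal(size=30)
        import statsmodels.api as sm

        x = np.asarray(sm.OLS(x, sm.add_constant(ga)).fit().resid)
        y = 1.0 - 0.8 * x + 0.1 * rng.normal(size=30)
        plain = psfc_association(y, x, ga)
        partial = psfc_association(y, x, ga, partial=True)
        assert plain.adjusted_r == pytest.approx(partial.adjusted_r, abs=1e-10)
        assert np.sign(plain.beta) == np.sign(plain.adjusted_r)

    def test_type_i_error_near_nominal_under_null(self, rng):
        # permutation-free analytic null: y independent of psFC
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            y = rng.normal(size=13)
            x = rng.normal(size=13)
            ga = rng.uniform(38, 43, 13)
            hits += psfc_association(y, x, ga).p_value < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)


class TestEdgewise:
    def test_edges_identical_to_network_mean_reproduce_network_beta(self, rng):
        x = rng.uniform(0, 1, 13)
        ga = rng.uniform(38, 43, 13)
        y = 2.0 - 1.5 * x + 0.05 * rng.normal(size=13)
        edges = pd.DataFrame({f"e{i}": x for i in range(15)})
        table = edgewise_association(edges, y, ga)
        network = psfc_association(y, x, ga)
        assert len(table) == 15
        assert np.allclose(table["beta"], network.beta, atol=1e-10)

    def test_bonferroni_column_clips_at_one(self, rng):
        edges = pd.DataFrame(
            {f"e{i}": rng.normal(size=13) for i in range(15)}
        )
        table = edgewise_association(edges, rng.normal(size=13), rng.uniform(38, 43, 13))
        assert (table["p_bonferroni"] <= 1.0).all()
        assert (table["p_bonferroni"] >= table["p_value"]).all()

    def test_targeted_edge_carries_largest_beta(self):
        # only ACC-PAG is coupled to the evoked amplitude; across cohorts it
        # should top the |beta| ranking nearly always
        hits = 0
        n_cohorts = 40
        for s in range(n_cohorts):
            cfg = targeted_edge_config(seed=90000 + s)
            res = analyse_cohort(generate_cohort(cfg), detect_outliers=False)
            table = edgewise_association(
                res.edge_table,
                res.infants["percent_change"],
                res.infants["ga_weeks"],
            )
            hits += table.loc[table["beta"].abs().idxmax(), "edge"] == "ACC-PAG"
        assert hits / n_cohorts >= 0.9


class TestRMAnova:
    def test_identical_columns_give_f_zero_p_one(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = rm_anova(table)
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_two_conditions_equal_paired_t_test(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        res = rm_anova(pd.DataFrame({"a": a, "b": b}))
        t, p = sps.ttest_rel(a, b)
        assert res.f_statistic == pytest.approx(t**2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_pingouin_on_random_table(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = rng.normal(size=(13, 3)) + np.array([0.0, 0.2, 0.5])
        table = pd.DataFrame(data, columns=["DPMS", "Control", "DMN"])
        res = rm_anova(table)
        long = table.reset_index().melt(
            id_vars="index", var_name="network", value_name="psfc"
        )
        pg = pingouin.rm_anova(
            data=long, dv="psfc", within="network", subject="index", detailed=True
        )
        assert res.f_statistic == pytest.approx(float(pg["F"][0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(pg["p_unc"][0]), abs=1e-8)

    def test_tukey_pair_count_and_range(self, rng):
        data = rng.normal(size=(10, 4))
        res = rm_anova(pd.DataFrame(data, columns=list("wxyz")))
        assert len(res.tukey) == 6
        assert res.tukey["p_adj"].between(0, 1).all()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova(pd.DataFrame({"a": [1.0], "b": [2.0]}))

    def test_incomplete_table_lists_missing_cells(self):
        table = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            rm_anova(table)

    def test_network_comparison_on_synthetic_cohort(self, default_cohort):
        res = analyse_cohort(default_cohort, detect_outliers=False)
        table = res.infants[["psfc_DPMS", "psfc_Control", "psfc_DMN"]]
        table = table.rename(columns=lambda c: c.removeprefix("psfc_"))
        anova = compare_network_connectivity(table)
        assert anova.levels == ("DPMS", "Control", "DMN")
        assert len(anova.tukey) == 3
        assert 0 < anova.p_value <= 1

    def test_stimulus_stability_uniform_p_under_stationarity(self):
        # stationary synthetic connectivity: stimulus number has no effect
        ps = []
        for s in range(30):
            res = analyse_cohort(
                generate_cohort(strong_coupling_config(seed=91000 + s)),
                detect_outliers=False,
            )
            ps.append(stimulus_stability(res.per_stimulus).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestSensitivity:
    def test_silent_brainstem_preserves_association_scale(self):
        # PAG/RVM carry no network fluctuation: the reduced-network psFC is
        # an undiluted version of the full mean, so the age-adjusted
        # correlations agree
        rs_full, rs_excl = [], []
        for s in range(25):
            cfg = strong_coupling_config(seed=92000 + s, silent_rois=("PAG", "RVM"))
            res = analyse_cohort(generate_cohort(cfg), detect_outliers=False)
            inf = res.infants
            full = psfc_association(
                inf["percent_change"], inf["psfc_DPMS"], inf["ga_weeks"]
            )
            excl = sensitivity_excluding_brainstem(
                inf[["psfc_DPMS_noBrainstem"]].rename(
                    columns=lambda c: c.removeprefix("psfc_")
                ),
                inf["percent_change"],
                inf["ga_weeks"],
            )["DPMS_noBrainstem"]
            rs_full.append(full.adjusted_r)
            rs_excl.append(excl.adjusted_r)
        assert np.mean(rs_full) < -0.5 and np.mean(rs_excl) < -0.5
        # the full-network mean dilutes the 6 informative edges with 9
        # noise edges, so allow a modest attenuation of the mean r
        assert abs(np.mean(rs_full) - np.mean(rs_excl)) < 0.2

    def test_brainstem_only_coupling_vanishes_when_excluded(self):
        # coupling carried solely by the PAG-RVM edge: that edge associates
        # strongly with the evoked response, while the brainstem-excluded
        # network mean carries no information and its association sits at 0
        rs_edge, rs_excl = [], []
        for s in range(25):
            cfg = targeted_edge_config(seed=93000 + s, dpms_edge=("PAG", "RVM"))
            res = analyse_cohort(generate_cohort(cfg), detect_outliers=False)
            inf = res.infants
            rs_edge.append(
                psfc_association(
                    inf["percent_change"],
                    res.edge_table["PAG-RVM"],
                    inf["ga_weeks"],
                ).adjusted_r
            )
            rs_excl.append(
                psfc_association(
                    inf["percent_change"],
                    inf["psfc_DPMS_noBrainstem"],
                    inf["ga_weeks"],
                ).adjusted_r
            )
        assert np.mean(rs_edge) < -0.5
        assert abs(np.mean(rs_excl)) < 0.1
        assert abs(np.mean(rs_excl)) < abs(np.mean(rs_edge)) / 2

    def test_reduced_network_edge_count(self, default_cohort):
        res = analyse_cohort(default_cohort, detect_outliers=False)
        assert "psfc_DPMS_noBrainstem" in res.infants.columns
        assert "psfc_Control_noPON" in res.infants.columns
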
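"""CNV ranking, spike-and-slab selection, ANCOVA and the survival screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polnet import ExpressionMatrix
from polnet.integration import (
    ClinicalTable,
    CnvDataset,
    SpikeSlabRegression,
    ancova_tumour_features,
    bayes_cnv_selection,
    build_integration_network,
    cis_cnv_correlation,
    optimal_cutoff,
    rank_cgh_probes,
    survival_screen,
)


def _clinical(n, seed=0, gleason=None, time=None, event=None):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "gleason": gleason if gleason is not None else rng.integers(6, 10, n),
            "psa": rng.uniform(1, 30, n),
            "t_stage": rng.integers(1, 4, n),
            "os_time": time if time is not None else rng.exponential(5, n),
            "os_event": event if event is not None else rng.integers(0, 2, n),
            "rfs_time": time if time is not None else rng.exponential(5, n),
            "rfs_event": event if event is not None else rng.integers(0, 2, n),
        },
        index=pd.Index([f"s{j}" for j in range(n)], name="sample"),
    )
    return ClinicalTable(frame=frame)


def _cnv(values, samples=None):
    values = np.asarray(values, dtype=float)
    n_probes = values.shape[0]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CnvDataset(
        probe_ids=[f"p{i}" for i in range(n_probes)],
        chromosome=["chr1"] * n_probes,
        position=np.arange(1, n_probes + 1) * 100,
        values=values,
        sample_ids=samples,
    )


class TestRankCghProbes:
    def test_perfectly_separated_probe_ranks_first(self):
        n = 60
        clin = _clinical(n, seed=1)
        gleason = clin.frame["gleason"].to_numpy(float)
        rng = np.random.default_rng(2)
        values = rng.standard_normal((5, n))
        values[3] = gleason * 2.0  # perfectly separated by Gleason groups
        ranked = rank_cgh_probes(_cnv(values), clin, top_m=5)
        assert ranked[0] == "p3"

    def test_anova_matches_hand_computation(self):
        """Three-group one-way ANOVA recomputed from the textbook sums of
        squares gives the same F and p as the probe ranking uses."""
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]), np.array([7.0, 8.0, 10.0])]
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = 2, 6
        f_hand = (ss_between / df_b) / (ss_within / df_w)
        p_hand = stats.f.sf(f_hand, df_b, df_w)
        res = stats.f_oneway(*groups)
        assert res.statistic == pytest.approx(f_hand, rel=1e-12)
        assert res.pvalue == pytest.approx(p_hand, rel=1e-12)

    def test_constant_probe_skipped(self):
        clin = _clinical(20, seed=3)
        values = np.vstack([np.zeros(20), np.random.default_rng(4).standard_normal(20)])
        ranked = rank_cgh_probes(_cnv(values), clin, top_m=5)
        assert "p0" not in ranked
        assert ranked == ["p1"]


class TestCisCorrelation:
    def test_expression_equal_to_cnv(self):
        rng = np.random.default_rng(5)
        cnv_values = rng.standard_normal((2, 30))
        cgh = _cnv(cnv_values)
        expr = ExpressionMatrix(
            ["gUp", "gDown"], cgh.sample_ids, np.vstack([cnv_values[0], -cnv_values[1]])
        )
        table = cis_cnv_correlation(cgh, expr, {"gUp": "p0", "gDown": "p1"})
        up = table.set_index("gene").loc["gUp"]
        down = table.set_index("gene").loc["gDown"]
        assert up["r"] == pytest.approx(1.0)
        assert down["r"] == pytest.approx(-1.0)
        assert bool(up["significant"]) and bool(down["significant"])

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(6)
        n_genes, n = 400, 50
        cgh = _cnv(rng.standard_normal((n_genes, n)))
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)], cgh.sample_ids, rng.standard_normal((n_genes, n))
        )
        table = cis_cnv_correlation(cgh, expr, {f"g{i}": f"p{i}" for i in range(n_genes)})
        rate = table["significant"].mean()
        assert rate < 0.04  # about 1% expected at p < 0.01


class TestSpikeSlab:
    def test_strong_signal_high_ppi(self):
        rng = np.random.default_rng(7)
        n, p = 100, 10
        X = rng.standard_normal((n, p))
        y = 2.0 * X[:, 3] + rng.normal(0, 0.5, n)
        res = bayes_cnv_selection(y, X, n_iter=3000, seed=8)
        assert res.ppi[3] > 0.9
        assert np.delete(res.ppi, 3).max() < 0.5

    def test_pure_noise_rarely_selects(self):
        rng = np.random.default_rng(9)
        n, p = 100, 10
        hits = 0
        for rep in range(10):
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            res = bayes_cnv_selection(y, X, n_iter=1500, seed=100 + rep)
            hits += res.ppi.max() < 0.5
        assert hits >= 9

    def test_pi_one_reduces_to_bayesian_ridge(self):
        rng = np.random.default_rng(10)
        n, p = 50, 5
        X = rng.standard_normal((n, p))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0, 0.0]) + rng.normal(0, 0.3, n)
        model = SpikeSlabRegression(y, X, pi=1.0, tau2=2.0)
        res = model.fit(n_iter=100, seed=11)
        assert (res.ppi == 1.0).all()
        Xs = (X - X.mean(0)) / X.std(0)
        ys = y - y.mean()
        ridge = np.linalg.solve(Xs.T @ Xs + np.eye(p) / 2.0, Xs.T @ ys)
        np.testing.assert_allclose(res.beta_mean, ridge, atol=1e-10)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            SpikeSlabRegression(np.array([1.0, np.nan, 0.0, 1.0, 2.0]), np.ones((5, 2)))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((60, 6))
        y = X[:, 0] + rng.standard_normal(60)
        a = bayes_cnv_selection(y, X, n_iter=500, seed=13)
        b = bayes_cnv_selection(y, X, n_iter=500, seed=13)
        np.testing.assert_array_equal(a.ppi, b.ppi)


class TestAncova:
    def test_monotone_gleason_gene_reported(self):
        n = 80
        clin = _clinical(n, seed=14)
        gleason = clin.frame["gleason"].to_numpy(float)
        rng = np.random.default_rng(15)
        expr = ExpressionMatrix(
            ["gMono", "gNull"],
            list(clin.frame.index),
            np.vstack([-1.5 * gleason + rng.normal(0, 0.5, n), rng.standard_normal(n)]),
        )
        table = ancova_tumour_features(expr, clin)
        mono = table.set_index(["gene", "feature"]).loc[("gMono", "gleason")]
        null_rows = table[table["gene"] == "gNull"]
        assert mono["correlation"] < -0.9
        assert (null_rows["correlation"] == 0.0).all()

    def test_zeroing_rule_invariant(self):
        n = 40
        clin = _clinical(n, seed=16)
        rng = np.random.default_rng(17)
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(20)], list(clin.frame.index), rng.standard_normal((20, n))
        )
        table = ancova_tumour_features(expr, clin)
        nonzero = table[table["correlation"] != 0.0]
        assert (nonzero["p"] < 0.05).all()

    def test_matches_hand_least_squares_fixture(self):
        """Coefficients and p-values agree with the normal-equation fit
        computed from scratch on a 12-sample fixture."""
        n = 12
        rng = np.random.default_rng(18)
        clin = _clinical(n, seed=18)
        y = rng.standard_normal(n)
        expr = ExpressionMatrix(["g"], list(clin.frame.index), y[None, :])
        table = ancova_tumour_features(expr, clin)
        X = np.column_stack(
            [np.ones(n)]
            + [clin.frame[c].to_numpy(float) for c in ("gleason", "psa", "t_stage")]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        t = beta / se
        p_hand = 2 * stats.t.sf(np.abs(t), df=n - 4)
        for j, feat in enumerate(("gleason", "psa", "t_stage"), start=1):
            row = table.set_index(["gene", "feature"]).loc[("g", feat)]
            assert row["p"] == pytest.approx(p_hand[j], rel=1e-9)

    def test_collinear_feature_dropped(self, caplog):
        n = 30
        clin = _clinical(n, seed=19)
        clin.frame["t_stage"] = clin.frame["gleason"] * 2  # exactly collinear
        rng = np.random.default_rng(20)
        expr = ExpressionMatrix(["g"], list(clin.frame.index), rng.standard_normal((1, n)))
        with caplog.at_level("WARNING", logger="polnet.integration"):
            table = ancova_tumour_features(expr, clin)
        assert set(table["feature"]) == {"gleason", "psa"}


class TestOptimalCutoff:
    def test_recovers_separating_threshold(self):
        rng = np.random.default_rng(21)
        n = 100
        expr = np.concatenate([rng.uniform(0, 4.8, n // 2), rng.uniform(5.2, 10, n // 2)])
        high = expr > 5.0
        time = np.where(high, 10.0, 0.5) * (1 + 0.05 * rng.random(n))
        event = np.ones(n, dtype=int)
        res = optimal_cutoff(expr, time, event)
        observed = np.sort(expr)
        idx = np.searchsorted(observed, 5.0)
        neighbourhood = observed[max(idx - 1, 0) : idx + 1]
        assert res.evaluable
        assert neighbourhood.min() - 1e-9 <= res.cutoff <= neighbourhood.max() + 1e-9

    def test_degenerate_grid_single_candidate(self):
        rng = np.random.default_rng(22)
        expr = rng.standard_normal(40)
        time = rng.exponential(1, 40)
        event = np.ones(40, dtype=int)
        res = optimal_cutoff(expr, time, event, grid_quantiles=(0.5, 0.5))
        assert res.evaluable
        assert res.cutoff == pytest.approx(np.quantile(expr, 0.5), abs=0.2)

    def test_too_few_events_not_evaluable(self):
        res = optimal_cutoff([1, 2, 3, 4], [1, 2, 3, 4], [1, 0, 0, 0])
        assert not res.evaluable


class TestSurvivalScreen:
    def test_null_calibration_before_bh(self):
        rng = np.random.default_rng(23)
        n_genes, n = 150, 120
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"s{j}" for j in range(n)],
            rng.standard_normal((n_genes, n)),
        )
        time = rng.exponential(1, n)
        event = (rng.random(n) < 0.7).astype(int)
        screen = survival_screen(expr, time, event)
        # cutoff optimisation inflates the raw p; just bound the behaviour
        rate = (screen["p"] < 0.05).mean()
        assert rate < 0.5
        ok = screen["q"].notna()
        assert (screen.loc[ok, "q"] >= screen.loc[ok, "p"] - 1e-12).all()
        # BH q monotone in p
        s = screen.loc[ok].sort_values("p")
        assert (np.diff(s["q"]) >= -1e-12).all()

    def test_degenerate_input_not_evaluable(self):
        expr = ExpressionMatrix(["g"], ["s0", "s1"], np.array([[1.0, 2.0]]))
        screen = survival_screen(expr, np.array([1.0, 2.0]), np.array([1, 0]))
        assert screen["p"].isna().all()


class TestIntegrationNetwork:
    def test_empty_inputs_empty_graph(self):
        graph = build_integration_network(
            pd.DataFrame(columns=["gene", "polarized_class"]),
            pd.DataFrame(columns=["gene", "probe", "ppi"]),
            pd.DataFrame(columns=["gene", "feature", "correlation", "p"]),
        )
        assert graph.number_of_nodes() == 0

    def test_three_node_path(self):
        pol = pd.DataFrame({"gene": ["g1"], "polarized_class": ["positive"]})
        bayes = pd.DataFrame({"gene": ["g1"], "probe": ["p1"], "ppi": [0.9]})
        ancova = pd.DataFrame(
            {"gene": ["g1"], "feature": ["gleason"], "correlation": [-0.5], "p": [0.01]}
        )
        graph = build_integration_network(pol, bayes, ancova)
        assert set(graph.nodes) == {"p1", "g1", "gleason"}
        assert graph.number_of_edges() == 2
        assert graph.nodes["g1"]["polarized_class"] == "positive"

    def test_thresholds_filter_edges(self):
        pol = pd.DataFrame({"gene": ["g1"], "polarized_class": ["positive"]})
        bayes = pd.DataFrame({"gene": ["g1"], "probe": ["p1"], "ppi": [0.3]})
        ancova = pd.DataFrame(
            {"gene": ["g1"], "feature": ["gleason"], "correlation": [0.0], "p": [0.2]}
        )
        graph = build_integration_network(pol, bayes, ancova)
        assert graph.number_of_edges() == 0
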
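"""Imputation, per-gene correlation, aggregation and permutation FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prolifsig as ps


def _ds(values, layer="protein", dataset_id="d1"):
    return ps.ExpressionDataset(dataset_id=dataset_id, layer=layer, values=values)


class TestImputeLow:
    def test_uniform_grid_quantile(self):
        # observed values 1..100; the 1% quantile under linear
        # interpolation of order statistics is 1.99
        vals = np.arange(1.0, 101.0)
        frame = pd.DataFrame(
            {"c1": vals, "c2": np.full(100, np.nan)},
            index=[f"g{i}" for i in range(100)],
        )
        out = ps.impute_low(_ds(frame), quantile=0.01)
        assert out.values["c2"].iloc[0] == pytest.approx(1.99)

    def test_no_missing_is_identity(self, small_study):
        ds = small_study.datasets[0]
        dense = ds.with_values(ds.values.fillna(0.0))
        out = ps.impute_low(dense)
        pd.testing.assert_frame_equal(out.values, dense.values)

    def test_quantile_zero_substitutes_minimum(self):
        frame = pd.DataFrame(
            {"c1": [5.0, 2.0, np.nan]}, index=["a", "b", "c"]
        )
        out = ps.impute_low(_ds(frame), quantile=0.0)
        assert out.values.loc["c", "c1"] == 2.0

    def test_fully_missing_dataset_rejected(self):
        frame = pd.DataFrame({"c1": [np.nan]}, index=["a"])
        with pytest.raises(ValueError, match="fully missing"):
            ps.impute_low(_ds(frame))


class TestGeneCorrelations:
    def _ref(self, n=12):
        return pd.Series(
            np.arange(n, dtype=float), index=[f"c{i}" for i in range(n)]
        )

    def test_identical_and_negated_references(self):
        ref = self._ref()
        frame = pd.DataFrame(
            [ref.to_numpy(), -ref.to_numpy()],
            index=["same", "opposite"],
            columns=ref.index,
        )
        out = ps.gene_correlations(_ds(frame), ref)
        assert out.loc["same", "r"] == pytest.approx(1.0)
        assert out.loc["opposite", "r"] == pytest.approx(-1.0)

    def test_matches_brute_force_sum_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x * x).sum() - x.sum() ** 2) * np.sqrt(
            n * (y * y).sum() - y.sum() ** 2
        )
        frame = pd.DataFrame([x], index=["g"], columns=[f"c{i}" for i in range(5)])
        ref = pd.Series(y, index=frame.columns)
        out = ps.gene_correlations(_ds(frame), ref, min_n=2)
        assert out.loc["g", "r"] == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_recorded_as_not_computed(self):
        ref = self._ref()
        frame = pd.DataFrame(
            [np.ones(12)], index=["flat"], columns=ref.index
        )
        out = ps.gene_correlations(_ds(frame), ref)
        assert out.loc["flat", "status"] == "zero_variance"
        assert np.isnan(out.loc["flat", "r"])

    def test_low_coverage_omitted_with_reason(self):
        ref = self._ref()
        row = ref.to_numpy().copy()
        row[5:] = np.nan
        frame = pd.DataFrame([row, ref.to_numpy()], index=["sparse", "dense"],
                             columns=ref.index)
        out = ps.gene_correlations(_ds(frame), ref, min_n=10)
        assert out.loc["sparse", "status"] == "low_coverage"
        assert np.isnan(out.loc["sparse", "r"])
        assert out.loc["dense", "status"] == "ok"

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_positive_affine_transform(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 15))
        ref = pd.Series(rng.normal(size=15), index=[f"c{i}" for i in range(15)])
        frame = pd.DataFrame(x, index=["g1", "g2", "g3"], columns=ref.index)
        r0 = ps.gene_correlations(_ds(frame), ref)["r"]
        r1 = ps.gene_correlations(_ds(frame * a + b), ref)["r"]
        assert np.allclose(r0, r1, atol=1e-9)


class TestAggregateCorrelations:
    def _table(self, genes, rs):
        return pd.DataFrame(
            {"r": rs, "n": [20] * len(genes), "status": ["ok"] * len(genes)},
            index=genes,
        )

    def test_unweighted_mean(self):
        out = ps.aggregate_correlations(
            {"d1": self._table(["g"], [0.5]), "d2": self._table(["g"], [0.7])}
        )
        assert out.loc["g", "mean_r"] == pytest.approx(0.6)
        assert out.loc["g", "n_datasets"] == 2

    def test_single_dataset_gene_dropped(self):
        out = ps.aggregate_correlations(
            {
                "d1": self._table(["only1", "both"], [0.5, 0.1]),
                "d2": self._table(["both"], [0.3]),
            }
        )
        assert "only1" not in out.index
        assert "both" in out.index

    def test_sign_cancellation_is_signed_mean(self):
        out = ps.aggregate_correlations(
            {"d1": self._table(["g"], [0.8]), "d2": self._table(["g"], [-0.8])}
        )
        assert out.loc["g", "mean_r"] == pytest.approx(0.0)
        assert out.loc["g", "abs_mean_r"] == pytest.approx(0.0)

    def test_dataset_order_invariance(self):
        tables = {
            "d1": self._table(["a", "b"], [0.2, -0.4]),
            "d2": self._table(["a", "b"], [0.6, 0.0]),
            "d3": self._table(["a"], [0.1]),
        }
        fwd = ps.aggregate_correlations(tables)
        rev = ps.aggregate_correlations(dict(reversed(tables.items())))
        pd.testing.assert_frame_equal(fwd, rev)


class TestRandomizedNull:
    def test_identity_permutation_reproduces_observed(self, small_study):
        datasets = [ps.normalize(d) for d in small_study.layer("protein")]
        markers = small_study.markers
        profiles, _ = ps.correlation_analysis(datasets, markers)
        observed = profiles[~profiles.index.isin(markers.genes)]["abs_mean_r"]
        null = ps.randomized_null(
            datasets, markers, iterations=1, seed=0, shuffle=False
        )
        assert np.allclose(np.sort(null.values), np.sort(observed.to_numpy()))

    def test_null_size_is_iterations_times_eligible_genes(self):
        cfg = ps.SimulationConfig(
            n_genes=200,
            n_cell_lines=30,
            n_datasets_protein=2,
            n_datasets_transcript=0,
            missing_rate=0.0,
            panel_overlap_fraction=1.0,
            seed=5,
        )
        study = ps.simulate_study(cfg)
        null = ps.randomized_null(study.datasets, study.markers, iterations=10, seed=1)
        # complete coverage: every non-marker gene contributes each iteration
        assert len(null) == 10 * (200 - len(study.markers))

    def test_seed_required_and_reproducible(self, small_study):
        datasets = list(small_study.layer("protein"))
        with pytest.raises(ValueError, match="seed"):
            ps.randomized_null(datasets, small_study.markers, iterations=2)
        a = ps.randomized_null(datasets, small_study.markers, iterations=2, seed=3)
        b = ps.randomized_null(datasets, small_study.markers, iterations=2, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_global_null_observed_matches_permutation_null(self):
        """On data with no true association the observed |mean r| and the
        randomized-index null are draws from the same distribution."""
        from scipy.stats import ks_2samp

        pvals = []
        for seed in range(3):
            cfg = ps.SimulationConfig(
                n_genes=600,
                n_cell_lines=40,
                n_datasets_protein=2,
                n_datasets_transcript=0,
                fraction_planted=0.0,
                missing_rate=0.0,
                panel_overlap_fraction=1.0,
                seed=seed,
            )
            study = ps.simulate_study(cfg)
            datasets = [ps.normalize(d) for d in study.datasets]
            profiles, _ = ps.correlation_analysis(datasets, study.markers)
            observed = profiles[~profiles.index.isin(study.markers.genes)][
                "abs_mean_r"
            ].to_numpy()
            null = ps.randomized_null(
                datasets, study.markers, iterations=10, seed=seed + 100
            )
            pvals.append(ks_2samp(observed, null.values).pvalue)
        assert np.median(pvals) > 0.01


class TestFdrThreshold:
    def test_order_statistics_convention(self):
        null = np.array([0.01 * k for k in range(1, 1001)])
        t = ps.fdr_threshold(null, target_fdr=0.001)
        assert 9.99 <= t <= 10.0

    def test_target_half_gives_median(self):
        null = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert ps.fdr_threshold(null, target_fdr=0.5) == pytest.approx(3.0)

    def test_threshold_monotone_in_target(self):
        rng = np.random.default_rng(1)
        null = rng.random(500)
        targets = [0.2, 0.1, 0.01, 0.001]
        thresholds = [ps.fdr_threshold(null, t) for t in targets]
        assert thresholds == sorted(thresholds)

    def test_target_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ps.fdr_threshold(np.array([0.1]), target_fdr=0.0)
        with pytest.raises(ValueError):
            ps.fdr_threshold(np.array([0.1]), target_fdr=1.0)

    def test_plugin_mode_controls_estimated_fdr(self):
        rng = np.random.default_rng(2)
        null = ps.NullDistribution(
            values=np.abs(rng.normal(0, 0.1, size=5000)), iterations=10
            , seed=2
        )
        observed = np.concatenate(
            [np.abs(rng.normal(0, 0.1, size=500)), rng.uniform(0.5, 1.0, 50)]
        )
        t = ps.fdr_threshold(null, 0.01, mode="plugin", observed=observed)
        n_obs = (observed >= t).sum()
        n_null = (null.values >= t).sum() / null.iterations
        assert n_obs > 0 and n_null / n_obs <= 0.01

    def test_plugin_requires_observed(self):
        with pytest.raises(ValueError, match="observed"):
            ps.fdr_threshold(np.array([0.1, 0.2]), mode="plugin")
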
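"""TMM normalisation, precision weights and moderated statistics."""

import numpy as np
import pandas as pd
import pytest

from cfmdna.batch_da import (
    NormalizationFactors,
    bh_adjust,
    batch_effect_flags,
    consensus_correlation,
    estimate_prior,
    fit_moderated,
    technical_variable_screen,
    tmm_factors,
    trigamma_inverse,
    voom_weights,
)
from cfmdna.tables import AsvCountTable, StudyDesign


def _table(matrix, prefix="s"):
    m = np.asarray(matrix)
    return AsvCountTable(
        pd.DataFrame(
            m,
            index=[f"a{i}" for i in range(m.shape[0])],
            columns=[f"{prefix}{j}" for j in range(m.shape[1])],
        )
    )


class TestTmm:
    def test_identical_columns(self):
        t = _table(np.tile([[10], [20], [5]], (1, 2)))
        f = tmm_factors(t).factors
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(0)
        col = rng.integers(5, 200, size=50)
        t = _table(np.column_stack([col, 2 * col]))
        f = tmm_factors(t).factors
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_geometric_mean_is_one(self, default_cohort):
        table, *_ = default_cohort
        f = tmm_factors(table).factors
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)
        assert (f > 0).all() and np.isfinite(f).all()

    def test_disjoint_sample_rejected(self):
        t = _table([[5, 0], [7, 0], [0, 3]])
        with pytest.raises(ValueError, match="co-detected"):
            tmm_factors(t, ref="s0")


class TestVoom:
    def _unit_factors(self, table):
        lib = table.library_sizes()
        return NormalizationFactors(pd.Series(1.0, index=table.sample_ids), lib)

    def test_weights_positive_finite(self, default_cohort):
        table, *_ = default_cohort
        nf = tmm_factors(table)
        vm = voom_weights(table, nf, np.ones((len(table.sample_ids), 1)))
        w = vm.weights.to_numpy()
        assert (w > 0).all() and np.isfinite(w).all()
        assert vm.logcpm.shape == vm.weights.shape

    def test_flat_trend_gives_near_constant_weights(self):
        # equal-mean Poisson counts: no mean-variance trend to exploit
        rng = np.random.default_rng(1)
        counts = rng.poisson(200, size=(150, 20))
        t = _table(counts)
        vm = voom_weights(t, self._unit_factors(t), np.ones((20, 1)))
        w = vm.weights.to_numpy()
        assert w.std() / w.mean() < 0.2

    def test_poisson_trend_decreases_with_mean(self):
        # Poisson counts spanning decades: sd of logcpm falls as mean rises
        rng = np.random.default_rng(2)
        means = np.repeat([5, 20, 80, 320, 1280], 40)
        counts = rng.poisson(means[:, None], size=(200, 16))
        t = _table(counts)
        vm = voom_weights(t, self._unit_factors(t), np.ones((16, 1)))
        grid_x, grid_y = vm.trend
        lo = np.interp(np.quantile(grid_x, 0.2), grid_x, grid_y)
        hi = np.interp(np.quantile(grid_x, 0.9), grid_x, grid_y)
        assert hi < lo


class TestConsensusCorrelation:
    def _vm(self, y):
        y = pd.DataFrame(y)
        return type("VM", (), {"logcpm": y, "weights": pd.DataFrame(np.ones_like(y))})()

    def test_independent_samples_give_near_zero(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(200, 40))
        blocks = np.repeat(np.arange(20), 2)
        rho = consensus_correlation(self._vm(y), np.ones((40, 1)), blocks)
        assert abs(rho) < 0.1

    def test_block_effect_recovered(self):
        rng = np.random.default_rng(4)
        blocks = np.repeat(np.arange(20), 2)
        block_eff = rng.normal(size=(200, 20))[:, blocks]  # ICC = 0.5
        y = block_eff + rng.normal(size=(200, 40))
        rho = consensus_correlation(self._vm(y), np.ones((40, 1)), blocks)
        assert 0.3 <= rho <= 0.7

    def test_singleton_blocks_give_zero(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(50, 10))
        with pytest.warns(UserWarning):
            rho = consensus_correlation(self._vm(y), np.ones((10, 1)), np.arange(10))
        assert rho == 0.0


class TestModeratedFit:
    def _toy_vm(self, rng, n_asv=30, n=12):
        y = rng.normal(5, 1, size=(n_asv, n))
        w = rng.uniform(0.5, 2.0, size=(n_asv, n))
        vm = type("VM", (), {})()
        vm.logcpm = pd.DataFrame(y, index=[f"a{i}" for i in range(n_asv)])
        vm.weights = pd.DataFrame(w, index=vm.logcpm.index)
        return vm

    def test_d0_zero_matches_ordinary_wls_t(self):
        """With no moderation the t statistic equals an independent
        weighted-least-squares implementation (statsmodels)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        vm = self._toy_vm(rng)
        x = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        contrast = {"slope": np.array([0.0, 1.0])}
        fit = fit_moderated(vm, x, contrast, prior=(0.0, 1.0))
        for i, asv in enumerate(vm.logcpm.index):
            res = sm.WLS(vm.logcpm.iloc[i], x, weights=vm.weights.iloc[i]).fit()
            row = fit.table[fit.table.asv_id == asv].iloc[0]
            assert row["t"] == pytest.approx(res.tvalues.iloc[1], rel=1e-8)
            assert row["logFC"] == pytest.approx(res.params.iloc[1], rel=1e-8)

    def test_d0_infinite_pools_all_variances(self):
        rng = np.random.default_rng(7)
        vm = self._toy_vm(rng)
        x = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        fit = fit_moderated(vm, x, {"c": [0, 1]}, prior=(np.inf, 2.5))
        # normal-reference p-values, all computed against the same s0
        assert fit.prior_df == np.inf and fit.prior_var == 2.5

    def test_estimated_prior_shrinks_between_bounds(self):
        rng = np.random.default_rng(8)
        vm = self._toy_vm(rng, n_asv=100)
        x = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        fit = fit_moderated(vm, x, {"c": [0, 1]})
        assert 0 < fit.prior_df < np.inf
        assert fit.prior_var > 0

    def test_prior_moment_matching_recovers_f_distribution(self):
        # s2 drawn from s0^2 * F(d, d0): the moment estimator should land
        # near the generating (d0, s0^2)
        rng = np.random.default_rng(9)
        d, d0_true, s0_true = 10.0, 8.0, 2.0
        s2 = s0_true * rng.f(d, d0_true, size=20000) * 1.0
        d0, s0 = estimate_prior(s2, np.full_like(s2, d))
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in [0.1, 1.0, 5.0, 40.0]:
            assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)


class TestBh:
    def test_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestFlags:
    def test_boundary_rule(self):
        fits = {}
        for name, fdr in [("v1", 0.04), ("v2", 0.051)]:
            t = pd.DataFrame(
                {"asv_id": ["a1"], "contrast": ["c"], "logFC": [1.0],
                 "t": [2.0], "p": [0.01], "fdr": [fdr]}
            )
            fits[name] = type("F", (), {"table": t})()
        flagged = batch_effect_flags({"v1": fits["v1"]}, ["a1", "a2"])
        assert bool(flagged["a1"]) and not bool(flagged["a2"])
        passed = batch_effect_flags({"v2": fits["v2"]}, ["a1"])
        assert not bool(passed["a1"])  # 0.051 > 0.05 passes criterion (i)

    def test_no_contrasts_all_pass_with_warning(self):
        with pytest.warns(UserWarning):
            flags = batch_effect_flags({}, ["a1", "a2"])
        assert not flags.any()


def _single_run_design(n_batches=3, n_per_batch=12):
    rows = []
    for b in range(n_batches):
        for j in range(n_per_batch):
            rows.append(
                {
                    "sample_id": f"b{b}_s{j}",
                    "sample_type": "plasma",
                    "sequencing_run": "r1",
                    "extraction_batch": f"B{b}",
                    "extraction_day": f"B{b}_d1",
                }
            )
    return StudyDesign(pd.DataFrame(rows))


class TestScreen:
    def test_contrast_families_only_within_nesting(self, default_cohort):
        """Day contrasts only compare days sharing a batch; batch contrasts
        enumerate all batch pairs."""
        from cfmdna.batch_da import technical_contrasts

        table, design, *_ = default_cohort
        plasma = design.samples_of_type("plasma")
        _x, families, _levels = technical_contrasts(design, plasma)
        assert set(families) == {"sequencing_run", "extraction_batch", "extraction_day"}
        assert len(families["extraction_batch"]) == 10  # C(5,2)
        for name in families["extraction_day"]:
            # day:<A_d1>-vs-<A_d2> share the batch prefix
            _, pair = name.split(":")
            d1, d2 = pair.split("-vs-")
            assert d1.split("_")[0] == d2.split("_")[0]

    def test_single_batch_passes_everything(self):
        rng = np.random.default_rng(11)
        design = _single_run_design(n_batches=1)
        t = _table(rng.poisson(50, size=(30, 12)), prefix="b0_s")
        with pytest.warns(UserWarning, match="no technical contrasts"):
            flags, fits = technical_variable_screen(t, design)
        assert not flags.any() and fits == {}

    def test_planted_batch_enrichment_is_flagged(self):
        """ASVs 4-fold enriched in one batch are detected with high
        sensitivity; unperturbed ASVs mostly pass."""
        rng = np.random.default_rng(12)
        design = _single_run_design(n_batches=3, n_per_batch=15)
        n_asv = 200
        mean = rng.lognormal(3.5, 1.0, size=n_asv)
        disp = 0.3
        counts = rng.negative_binomial(
            1 / disp, 1 / (1 + disp * mean[:, None]), size=(n_asv, 45)
        )
        enriched = np.arange(20)
        counts[np.ix_(enriched, np.arange(15))] = rng.negative_binomial(
            1 / disp, 1 / (1 + disp * 4 * mean[enriched, None]), size=(20, 15)
        )
        table = AsvCountTable(
            pd.DataFrame(counts, index=[f"a{i}" for i in range(n_asv)],
                         columns=list(design.frame.index))
        )
        flags, _ = technical_variable_screen(table, design)
        sens = flags.iloc[enriched].mean()
        assert sens >= 0.8
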
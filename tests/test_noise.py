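"""G1 gating, CV computation, robust trend, residual noise, comparison."""

import numpy as np
import pandas as pd
import pytest

from asreg import noise, synth
from asreg.stats import ols_line, spearman_correlation


def _uniform_events(n=20_000, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "fsc": rng.uniform(0, 1, n),
            "ssc": rng.uniform(0, 1, n),
            "gfp": rng.lognormal(5, 0.3, n),
        }
    )


class TestGate:
    def test_uniform_cloud_retains_about_ten_percent(self):
        ev = _uniform_events()
        gated = noise.gate_g1(ev)
        assert 0.09 <= len(gated) / len(ev) <= 0.13

    def test_two_cluster_gate_in_denser_cluster(self):
        rng = np.random.default_rng(1)
        dense = pd.DataFrame(
            {"fsc": rng.normal(10, 0.5, 15_000), "ssc": rng.normal(10, 0.5, 15_000)}
        )
        sparse = pd.DataFrame(
            {"fsc": rng.normal(30, 0.5, 5_000), "ssc": rng.normal(30, 0.5, 5_000)}
        )
        ev = pd.concat([dense, sparse], ignore_index=True)
        ev["gfp"] = 1.0
        gated = noise.gate_g1(ev)
        assert (gated["fsc"] < 20).all()

    def test_permutation_invariance(self):
        ev = _uniform_events(seed=2)
        rng = np.random.default_rng(3)
        shuffled = ev.iloc[rng.permutation(len(ev))]
        g1 = noise.gate_g1(ev).sort_index()
        g2 = noise.gate_g1(shuffled).sort_index()
        pd.testing.assert_frame_equal(g1, g2)

    def test_regating_keeps_subset(self):
        ev = _uniform_events(seed=4)
        once = noise.gate_g1(ev)
        twice = noise.gate_g1(once)
        assert set(twice.index) <= set(once.index)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            noise.gate_g1(_uniform_events(n=500))


class TestComputeCV:
    def test_hand_computed(self):
        mean, cv = noise.compute_cv(np.array([8.0, 10.0, 12.0]))
        assert mean == 10.0
        assert cv == pytest.approx(20.0)

    def test_constant_vector(self):
        _, cv = noise.compute_cv(np.full(10, 3.0))
        assert cv == 0.0

    def test_lognormal_closed_form(self):
        sigma = 0.25
        rng = np.random.default_rng(5)
        vals = rng.lognormal(3.0, sigma, 200_000)
        _, cv = noise.compute_cv(vals)
        expected = np.sqrt(np.exp(sigma**2) - 1) * 100
        assert cv == pytest.approx(expected, rel=0.02)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            noise.compute_cv(np.array([-1.0, -2.0]))


class TestTrendAndResidual:
    def _table(self, x, y):
        return pd.DataFrame({"log10_mean": x, "log10_cv2": y})

    def test_exact_line_zero_residuals(self):
        x = np.linspace(2, 5, 10)
        tbl = self._table(x, -x + 4)
        fit = noise.fit_cv_trend(tbl)
        assert fit.slope == pytest.approx(-1.0, abs=1e-8)
        assert fit.intercept == pytest.approx(4.0, abs=1e-8)
        res = noise.cv_residual(tbl, fit)
        assert np.allclose(res["cv_res"], 0.0, atol=1e-8)

    def test_decade_above_line(self):
        x = np.linspace(2, 5, 10)
        fit = noise.fit_cv_trend(self._table(x, -x + 4))
        point = self._table([3.0], [-3.0 + 4 + 1.0])
        assert noise.cv_residual(point, fit)["cv_res"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_mean_residual_zero_under_ols(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(2, 5, 50)
        y = -0.8 * x + 4 + 0.1 * rng.normal(size=50)
        fit = ols_line(x, y)
        res = noise.cv_residual(self._table(x, y), fit)
        assert abs(res["cv_res"].mean()) < 1e-10

    def test_residual_uncorrelated_with_abundance(self):
        panel = synth.generate_gene_panel(10, 10, 4, seed=7)
        params = synth.SimParams(seed=7, events_per_sample=20_000)
        ev = synth.simulate_facs(panel, params, [])
        tbl = noise.estimate_noise(ev)
        tbl = noise.cv_residual(tbl, noise.fit_cv_trend(tbl))
        ok = tbl.dropna(subset=["cv_res"])
        rho = spearman_correlation(ok["log10_mean"], ok["cv_res"]).rho
        assert abs(rho) <= 0.15  # small panel; acceptance checks 0.05 at scale


class TestCompareNoise:
    def test_exact_small_sample_p(self):
        tbl = pd.DataFrame(
            {
                "gene_id": list("abcdef") * 2,
                "construct": ["PHO5_T_scr"] * 6 + ["PHO5_T"] * 6,
                "cv_res": [1, 2, 3, 4, 5, 6, 0, 0, 0, 0, 0, 0],
            }
        )
        cmp_res = noise.compare_noise(tbl, regulated_gene_ids=["a", "b", "c"])
        # deltas: {1,2,3} vs {4,5,6} -> exact two-sided p = 2/20
        assert cmp_res.test.p_value == pytest.approx(0.1)
        assert cmp_res.test.method == "exact"

    def test_identical_groups_p_one(self):
        tbl = pd.DataFrame(
            {
                "gene_id": list("abcdef") * 2,
                "construct": ["PHO5_T_scr"] * 6 + ["PHO5_T"] * 6,
                "cv_res": [1, 2, 3, 1, 2, 3, 0, 0, 0, 0, 0, 0],
            }
        )
        cmp_res = noise.compare_noise(tbl, regulated_gene_ids=["a", "b", "c"])
        assert cmp_res.test.p_value == pytest.approx(1.0)

    def test_planted_denoising_detected(self):
        panel = synth.generate_gene_panel(12, 12, 0, seed=8)
        params = synth.SimParams(seed=8, events_per_sample=30_000, denoise_factor=0.5)
        reg = [g.gene_id for g in panel][:8]
        ev = synth.simulate_facs(panel, params, reg)
        tbl = noise.estimate_noise(ev)
        tbl = noise.cv_residual(tbl, noise.fit_cv_trend(tbl))
        cmp_res = noise.compare_noise(tbl, reg)
        assert cmp_res.median_regulated < 0
        assert cmp_res.test.p_value < 0.05

    def test_conclusion_robust_to_fit_choice(self):
        # same data, IRLS vs OLS vs LAD trend: the comparison conclusion holds
        import statsmodels.api as sm

        from asreg.stats import TrendFit

        def lad_fit(t):
            x = t["log10_mean"].to_numpy()
            fit = sm.QuantReg(t["log10_cv2"].to_numpy(), sm.add_constant(x)).fit(q=0.5)
            return TrendFit(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                            method="lad", weights=np.ones_like(x))

        panel = synth.generate_gene_panel(12, 12, 0, seed=9)
        params = synth.SimParams(seed=9, events_per_sample=30_000, denoise_factor=0.5)
        reg = [g.gene_id for g in panel][:8]
        ev = synth.simulate_facs(panel, params, reg)
        tbl = noise.estimate_noise(ev)
        results = []
        for fit_fn in (
            noise.fit_cv_trend,
            lambda t: ols_line(t["log10_mean"].to_numpy(), t["log10_cv2"].to_numpy()),
            lad_fit,
        ):
            resid = noise.cv_residual(tbl, fit_fn(tbl))
            cmp_res = noise.compare_noise(resid, reg)
            results.append((np.sign(cmp_res.median_regulated), cmp_res.test.p_value < 0.05))
        assert results[0] == results[1] == results[2]

    def test_empty_group_rejected(self):
        tbl = pd.DataFrame(
            {
                "gene_id": list("abcd") * 2,
                "construct": ["PHO5_T_scr"] * 4 + ["PHO5_T"] * 4,
                "cv_res": range(8),
            }
        )
        with pytest.raises(ValueError):
            noise.compare_noise(tbl, regulated_gene_ids=[])
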
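"""Regulation caller: fold-change fit, criteria, calls, condition
specificity, and screen summary."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from asreg import calling, normalization as norm, synth


def _wells_frame(gene, cond, t_vals, scr_vals, wt_vals=None):
    rows = []
    for construct, vals in (
        ("PHO5_T", t_vals), ("PHO5_T_scr", scr_vals), ("WT", wt_vals or [])
    ):
        for r, v in enumerate(vals, start=1):
            rows.append(
                {"well_id": f"{gene}|{cond}|{construct}|{r}", "gene_id": gene,
                 "construct": construct, "condition": cond, "replicate": r,
                 "n_sample_cells": 300, "n_reference_cells": 300, "sfgfp_norm": v}
            )
    return pd.DataFrame(rows)


def _expr_frame(gene, cond, t=True, scr=True, wt=True):
    return pd.DataFrame(
        {
            "gene_id": [gene] * 3,
            "condition": [cond] * 3,
            "construct": ["PHO5_T", "PHO5_T_scr", "WT"],
            "mean_sfgfp_norm": [np.nan] * 3,
            "n_wells": [2] * 3,
            "expressed": [t, scr, wt],
        }
    )


class TestFitGeneCondition:
    def test_flat_wells_give_p_one(self):
        res = calling.fit_gene_condition([1.0, 1.0], [1.0, 1.0], theta=1.0)
        assert res.log2fc == 0.0
        assert res.p_value == 1.0

    def test_matches_pooled_t_test(self):
        t_vals, scr_vals = [4.0, 4.2], [2.0, 2.1]
        res = calling.fit_gene_condition(t_vals, scr_vals, theta=1.0)
        oracle = sps.ttest_ind(np.log2(scr_vals), np.log2(t_vals), equal_var=True)
        assert res.log2fc == pytest.approx(-1.0, abs=0.02)  # ~2-fold repression
        assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-12)
        assert res.df == 2

    def test_matches_ols_construct_indicator(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        t_vals = rng.lognormal(1, 0.2, 3)
        scr_vals = rng.lognormal(0.5, 0.2, 3)
        res = calling.fit_gene_condition(t_vals, scr_vals, theta=1.0)
        y = np.log2(np.concatenate([t_vals, scr_vals]))
        x = sm.add_constant(np.r_[np.zeros(3), np.ones(3)])
        fit = sm.OLS(y, x).fit()
        assert res.log2fc == pytest.approx(fit.params[1], rel=1e-12)
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-9)

    def test_within_permutation_null(self):
        # exact permutation over all relabelings of the 2+2 wells
        t_vals, scr_vals = [4.0, 4.3], [2.0, 2.4]
        res = calling.fit_gene_condition(t_vals, scr_vals, theta=1.0)
        vals = np.log2(np.array(t_vals + scr_vals))
        diffs = []
        for idx in combinations(range(4), 2):
            scr = vals[list(idx)]
            t = vals[[i for i in range(4) if i not in idx]]
            diffs.append(scr.mean() - t.mean())
        perm_p = np.mean(np.abs(diffs) >= abs(res.log2fc) - 1e-12)
        # t-test p and exact permutation p agree on ordering of extremeness
        assert (res.p_value < 0.5) == (perm_p <= 0.5)

    def test_too_few_wells_unmeasured(self):
        assert calling.fit_gene_condition([1.0], [1.0, 1.0], theta=1.0) is None

    def test_nonpositive_floored_and_flagged(self):
        res = calling.fit_gene_condition([1.0, 1.1], [0.0, 0.1], theta=1.0)
        assert res.floored


class TestCriteria:
    @pytest.mark.parametrize(
        "scr,wt,expected",
        [(1.0, 1.5, True), (1.0, 1.51, False), (2.0, 1.4, True), (1.5, 1.0, True)],
    )
    def test_scr_wt_range(self, scr, wt, expected):
        ok, missing = calling.scr_wt_consistency(scr, wt)
        assert ok is expected
        assert not missing

    def test_wt_missing_vacuously_true_with_flag(self):
        ok, missing = calling.scr_wt_consistency(1.0, None)
        assert ok and missing

    @pytest.mark.parametrize(
        "scr,t,expected",
        [
            ([1.0, 1.0], [1.0, 1.0], False),       # 0 not > 0
            ([0.0, 0.1], [-1.0, -0.9], True),       # 1.0 > 0.1
            ([0.0, 1.0], [0.4, 0.6], False),        # 0 not > 1.0
        ],
    )
    def test_replicate_criterion(self, scr, t, expected):
        assert calling.replicate_criterion(np.array(t), np.array(scr)) is expected

    def test_missing_replicate_conservative(self):
        assert calling.replicate_criterion(np.array([1.0]), np.array([0.0, 0.1])) is False


class TestCallScreen:
    def test_threshold_strictness(self):
        wells = _wells_frame("g1", "SC", [4.0, 4.2], [2.0, 2.1], [2.05, 2.0])
        expr = _expr_frame("g1", "SC")
        calls = calling.call_screen(wells, expr, theta=1.0)
        p = calls["p_value"].iloc[0]
        at_threshold = calling.call_screen(wells, expr, theta=1.0, p_threshold=p)
        below = calling.call_screen(wells, expr, theta=1.0, p_threshold=np.nextafter(p, 1))
        assert not at_threshold["significant"].iloc[0]  # strict p < threshold
        assert below["significant"].iloc[0]

    def test_regulated_requires_all_criteria(self, called_screen):
        calls = called_screen["calls"]
        reg = calls[calls["regulated"]]
        assert (reg["significant"] & reg["scr_wt_consistent"]
                & reg["replicate_criterion"] & reg["tested"]).all()

    def test_recovers_planted_effects(self, called_screen):
        merged = called_screen["calls"].merge(
            called_screen["truth"], on=["gene_id", "condition"], suffixes=("", "_t")
        )
        truth_reg = merged["regulated_t"]
        sens = merged.loc[truth_reg, "regulated"].mean()
        fdr = (
            merged.loc[merged["regulated"], "regulated_t"].eq(False).mean()
            if merged["regulated"].any() else 0.0
        )
        assert sens >= 0.8
        assert fdr <= 0.2

    def test_label_antisymmetry(self, called_screen):
        wells = called_screen["wells"].copy()
        swap = {"PHO5_T": "PHO5_T_scr", "PHO5_T_scr": "PHO5_T", "WT": "WT"}
        wells["construct"] = wells["construct"].astype(str).map(swap)
        expr = called_screen["expr"].copy()
        expr["construct"] = expr["construct"].astype(str).map(swap)
        orig = called_screen["calls"].set_index(["gene_id", "condition"])
        swapped = calling.call_screen(
            wells, expr, called_screen["theta"]
        ).set_index(["gene_id", "condition"])
        common = orig.index.intersection(swapped.index)
        assert np.allclose(
            orig.loc[common, "log2fc"], -swapped.loc[common, "log2fc"], atol=1e-12
        )
        assert np.allclose(
            orig.loc[common, "p_value"], swapped.loc[common, "p_value"], rtol=1e-9
        )

    def test_onoff_fold_change_floored_at_theta(self, small_panel):
        params = synth.SimParams(conditions=("SC",), seed=31, frac_regulated=0.3,
                                 onoff_fraction=1.0)
        cells, truth = synth.simulate_screen(small_panel, params)
        wells = norm.normalize_wells(cells)
        theta = norm.null_reference_threshold(cells, seed=31)
        qc = norm.qc_filter(wells, theta=theta)
        expr = norm.expression_calls(qc.passing(), theta)
        calls = calling.call_screen(qc.passing(), expr, theta)
        onoff = calls[calls["onoff"]]
        assert len(onoff) > 0
        # floored fold change: log2(theta-ish) - log2(T mean); always repression
        assert (onoff["log2fc"] < 0).all()
        floor_bound = np.log2(theta) - np.log2(onoff["mean_raw_PHO5_T"])
        assert np.all(onoff["log2fc"] >= floor_bound - 1e-9)


class TestConditionSpecific:
    def test_planted_condition_specific_effect(self, small_panel):
        gid = sorted(g.gene_id for g in small_panel)[0]
        params = synth.null_params(synth.SimParams(conditions=("SC", "YPE"), seed=41))
        cells, _ = synth.simulate_screen(
            small_panel, params, effect_overrides={(gid, "SC"): 1.0}
        )
        wells = norm.normalize_wells(cells)
        theta = norm.null_reference_threshold(cells, seed=41)
        qc = norm.qc_filter(wells, theta=theta)
        expr = norm.expression_calls(qc.passing(), theta)
        calls = calling.call_screen(qc.passing(), expr, theta)
        pairs = calling.condition_specific_pairs(qc.passing(), calls, theta)
        hit = pairs[(pairs["gene_id"] == gid)]
        assert len(hit) == 1
        assert hit["condition_regulated"].iloc[0] == "SC"
        assert hit["condition_other"].iloc[0] == "YPE"

    def test_uniform_regulation_yields_no_pairs(self, called_screen):
        # single condition: no cross-condition pairs possible
        pairs = calling.condition_specific_pairs(
            called_screen["wells"], called_screen["calls"], called_screen["theta"]
        )
        assert pairs.empty


class TestSummary:
    def test_empty_screen(self):
        calls = pd.DataFrame(
            columns=["gene_id", "condition", "log2fc", "tested", "regulated", "onoff"]
        )
        s = calling.summarize_screen(calls)
        assert s["n_genes_regulated_any_condition"] == 0
        assert s["mean_abs_fold_change"] == 0.0

    def test_union_identity(self, called_screen):
        calls = called_screen["calls"]
        s = calling.summarize_screen(calls)
        union = set()
        for _, sub in calls.groupby("condition", observed=True):
            union |= set(sub.loc[sub["regulated"], "gene_id"].astype(str))
        assert set(s["genes_regulated_any_condition"]) == union
        assert s["n_genes_regulated_any_condition"] <= int(calls["regulated"].sum())
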
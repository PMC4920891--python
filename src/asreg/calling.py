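"""Calling antisense-regulated genes per growth condition.

Observations are per-well ``sfgfp_norm`` summaries on the log2 scale
(cells within a well are pseudoreplicates).  For each gene x condition an
ordinary least-squares fit of log2 value on a construct indicator — with
two wells per construct this is exactly the pooled two-sample t-test —
yields the log2 fold change (scrambled control minus terminator; negative
means antisense represses) and a two-sided p-value with n_wells - 2
degrees of freedom.

A gene x condition is called regulated when all of the following hold:
p < 0.01 (no multiple-testing correction in the call itself; BH q-values
are reported for information), the scrambled control and untagged-
terminator constructs agree within a 50% expression range, the construct
difference exceeds the replicate-to-replicate differences, and the gene is
expressed in at least one of the paired constructs.  A regulated gene
whose antisense-present construct falls below the expression threshold is
an on/off switch; its fold change is recomputed with the unexpressed
construct floored at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

P_THRESHOLD = 0.01
RANGE_FACTOR = 1.5
CONDITION_SPECIFIC_P = 0.05

_TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class FoldChangeResult:
    log2fc: float
    p_value: float
    df: int
    scr_mean: float
    t_mean: float
    floored: bool


def _log2_floored(x: np.ndarray, floor: float) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    bad = x <= 0
    return np.log2(np.where(bad, floor, x)), bool(bad.any())


def _pooled_t(t_log2: np.ndarray, scr_log2: np.ndarray) -> tuple[float, float, int]:
    """Two-sample pooled-variance t-test on log2 well values; equals the
    OLS construct-indicator coefficient test."""
    n1, n2 = t_log2.size, scr_log2.size
    df = n1 + n2 - 2
    diff = scr_log2.mean() - t_log2.mean()
    sp2 = ((n1 - 1) * t_log2.var(ddof=1) + (n2 - 1) * scr_log2.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return diff, (1.0 if diff == 0 else _TINY_P), df
    t = diff / se
    return diff, float(2.0 * sps.t.sf(abs(t), df)), df


def fit_gene_condition(
    t_sfgfp: np.ndarray, scr_sfgfp: np.ndarray, theta: float
) -> FoldChangeResult | None:
    """Fold-change fit for one gene x condition; ``None`` if unmeasured
    (fewer than two PASS wells for either construct).  Non-positive
    ``sfgfp_norm`` values are floored at theta/10 before taking logs."""
    t_sfgfp = np.asarray(t_sfgfp, dtype=float)
    scr_sfgfp = np.asarray(scr_sfgfp, dtype=float)
    if t_sfgfp.size < 2 or scr_sfgfp.size < 2:
        return None
    t_log2, f1 = _log2_floored(t_sfgfp, theta / 10.0)
    s_log2, f2 = _log2_floored(scr_sfgfp, theta / 10.0)
    log2fc, p, df = _pooled_t(t_log2, s_log2)
    return FoldChangeResult(
        log2fc=float(log2fc),
        p_value=p,
        df=df,
        scr_mean=float(scr_sfgfp.mean()),
        t_mean=float(t_sfgfp.mean()),
        floored=f1 or f2,
    )


def scr_wt_consistency(scr_mean: float, wt_mean: float | None) -> tuple[bool, bool]:
    """Scrambled-control vs untagged-construct agreement within a 50%
    expression range (ratio <= 1.5, boundary inclusive).

    Returns ``(consistent, wt_missing)``; a missing WT measurement leaves
    the criterion vacuously true but flagged.
    """
    if wt_mean is None or not np.isfinite(wt_mean):
        return True, True
    hi, lo = max(scr_mean, wt_mean), min(scr_mean, wt_mean)
    if lo <= 0:
        return False, False
    return hi / lo <= RANGE_FACTOR, False


def replicate_criterion(t_log2: np.ndarray, scr_log2: np.ndarray) -> bool:
    """Construct difference must exceed replicate-to-replicate differences.

    True iff |mean(scr) - mean(T)| on the log2 scale is strictly greater
    than the larger within-construct replicate range.  A missing replicate
    makes the criterion false (conservative).
    """
    t_log2 = np.asarray(t_log2, dtype=float)
    scr_log2 = np.asarray(scr_log2, dtype=float)
    if t_log2.size < 2 or scr_log2.size < 2:
        return False
    within = max(np.ptp(t_log2), np.ptp(scr_log2))
    return bool(abs(scr_log2.mean() - t_log2.mean()) > within)


def call_screen(
    pass_wells: pd.DataFrame,
    expr_calls: pd.DataFrame,
    theta: float,
    p_threshold: float = P_THRESHOLD,
    range_factor: float = RANGE_FACTOR,
) -> pd.DataFrame:
    """Vectorized regulation calls for the whole screen.

    ``pass_wells`` are QC-PASS well summaries; ``expr_calls`` the
    construct-level expression calls.  Returns one row per measurable
    gene x condition with the fold-change fit, criterion flags, the
    regulated / on-off calls, and BH q-values (informational).
    """
    w = pass_wells.copy()
    w["log2_norm"] = np.log2(np.where(w["sfgfp_norm"] <= 0, theta / 10.0, w["sfgfp_norm"]))

    agg = (
        w.groupby(["gene_id", "condition", "construct"], observed=True)
        .agg(
            n=("log2_norm", "size"),
            mean_log2=("log2_norm", "mean"),
            var_log2=("log2_norm", lambda v: v.var(ddof=1)),
            range_log2=("log2_norm", np.ptp),
            mean_raw=("sfgfp_norm", "mean"),
            mean_log2_floor_theta=(
                "sfgfp_norm",
                lambda v: np.mean(np.log2(np.clip(v, theta, None))),
            ),
        )
        .reset_index()
    )
    wide = agg.pivot(index=["gene_id", "condition"], columns="construct")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()

    expr = expr_calls.pivot(
        index=["gene_id", "condition"], columns="construct", values="expressed"
    )
    expr.columns = [f"expressed_{c}" for c in expr.columns]
    res = wide.merge(expr.reset_index(), on=["gene_id", "condition"], how="left")
    for c in ("expressed_PHO5_T", "expressed_PHO5_T_scr", "expressed_WT"):
        if c not in res:
            res[c] = False
        res[c] = res[c].fillna(False).astype(bool)

    n1 = res["n_PHO5_T"].fillna(0)
    n2 = res["n_PHO5_T_scr"].fillna(0)
    measurable = (n1 >= 2) & (n2 >= 2)
    res = res[measurable].reset_index(drop=True)
    n1 = res["n_PHO5_T"].to_numpy()
    n2 = res["n_PHO5_T_scr"].to_numpy()

    df = (n1 + n2 - 2).astype(int)
    diff = res["mean_log2_PHO5_T_scr"].to_numpy() - res["mean_log2_PHO5_T"].to_numpy()
    sp2 = (
        (n1 - 1) * res["var_log2_PHO5_T"].to_numpy()
        + (n2 - 1) * res["var_log2_PHO5_T_scr"].to_numpy()
    ) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df)
    p = np.where(se == 0, np.where(diff == 0, 1.0, _TINY_P), p)

    res["log2fc"] = diff
    res["p_value"] = p
    res["df"] = df
    res["significant"] = res["p_value"] < p_threshold

    scr_m = res["mean_raw_PHO5_T_scr"].to_numpy()
    wt_m = res["mean_raw_WT"].to_numpy(dtype=float) if "mean_raw_WT" in res else np.full(len(res), np.nan)
    both_expr = res["expressed_PHO5_T_scr"].to_numpy() & res["expressed_WT"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.maximum(scr_m, wt_m) / np.minimum(scr_m, wt_m)
    res["wt_missing"] = ~np.isfinite(wt_m)
    res["scr_wt_consistent"] = np.where(
        both_expr & np.isfinite(ratio), ratio <= range_factor, True
    )

    within = np.maximum(
        res["range_log2_PHO5_T"].to_numpy(), res["range_log2_PHO5_T_scr"].to_numpy()
    )
    res["replicate_criterion"] = np.abs(diff) > within

    res["tested"] = res["expressed_PHO5_T"] | res["expressed_PHO5_T_scr"]
    res["regulated"] = (
        res["significant"]
        & res["scr_wt_consistent"]
        & res["replicate_criterion"]
        & res["tested"]
    )
    res["onoff"] = (
        res["regulated"] & res["expressed_PHO5_T"] & ~res["expressed_PHO5_T_scr"]
    )
    # on/off fold change against the antisense-present construct floored at theta
    res.loc[res["onoff"], "log2fc"] = (
        res.loc[res["onoff"], "mean_log2_floor_theta_PHO5_T_scr"]
        - res.loc[res["onoff"], "mean_log2_PHO5_T"]
    )
    res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1] if len(res) else []
    keep = [
        "gene_id", "condition", "log2fc", "p_value", "q_value", "df",
        "mean_raw_PHO5_T", "mean_raw_PHO5_T_scr", "mean_raw_WT",
        "expressed_PHO5_T", "expressed_PHO5_T_scr", "expressed_WT",
        "significant", "scr_wt_consistent", "wt_missing",
        "replicate_criterion", "tested", "regulated", "onoff",
    ]
    keep = [c for c in keep if c in res]
    return res[keep]


def condition_specific_pairs(
    pass_wells: pd.DataFrame,
    calls: pd.DataFrame,
    theta: float,
    p_threshold: float = CONDITION_SPECIFIC_P,
) -> pd.DataFrame:
    """Condition pairs with differential antisense regulation.

    A pair (c1, c2) is reported for a gene when the gene is regulated in
    c1, not regulated but still tested in c2, and the two fold-change
    estimates differ (two-sided Welch test on replicate-paired well-level
    log2 differences, p < 0.05).
    """
    w = pass_wells.copy()
    w["log2_norm"] = np.log2(np.where(w["sfgfp_norm"] <= 0, theta / 10.0, w["sfgfp_norm"]))
    piv = w.pivot_table(
        index=["gene_id", "condition", "replicate"],
        columns="construct",
        values="log2_norm",
        aggfunc="mean",
        observed=True,
    )
    d = (piv["PHO5_T_scr"] - piv["PHO5_T"]).dropna().rename("d")
    call_ix = calls.set_index(["gene_id", "condition"])
    rows = []
    for gene, sub in calls.groupby("gene_id", observed=True):
        conds = sub["condition"].tolist()
        for c1, c2 in product(conds, conds):
            if c1 == c2:
                continue
            r1 = call_ix.loc[(gene, c1)]
            r2 = call_ix.loc[(gene, c2)]
            if not (bool(r1["regulated"]) and not bool(r2["regulated"]) and bool(r2["tested"])):
                continue
            try:
                d1 = d.loc[(gene, c1)].to_numpy()
                d2 = d.loc[(gene, c2)].to_numpy()
            except KeyError:
                continue
            if d1.size < 2 or d2.size < 2:
                continue
            p = sps.ttest_ind(d1, d2, equal_var=False).pvalue
            if np.isfinite(p) and p < p_threshold:
                rows.append(
                    {"gene_id": gene, "condition_regulated": c1,
                     "condition_other": c2, "p_welch": float(p)}
                )
    return pd.DataFrame(rows, columns=["gene_id", "condition_regulated", "condition_other", "p_welch"])


def summarize_screen(calls: pd.DataFrame) -> dict:
    """Screen-level summary of regulation calls."""
    per_condition = {}
    for cond, sub in calls.groupby("condition", observed=True):
        per_condition[str(cond)] = {
            "n_tested": int(sub["tested"].sum()),
            "n_regulated": int(sub["regulated"].sum()),
        }
    reg = calls.loc[calls["regulated"].astype(bool)]
    genes_any = sorted(reg["gene_id"].astype(str).unique())
    fold = 2.0 ** np.abs(reg["log2fc"].to_numpy()) if len(reg) else np.array([])
    return {
        "per_condition": per_condition,
        "genes_regulated_any_condition": genes_any,
        "n_genes_regulated_any_condition": len(genes_any),
        "mean_abs_fold_change": float(fold.mean()) if fold.size else 0.0,
        "fold_change_range": [float(fold.min()), float(fold.max())] if fold.size else [0.0, 0.0],
        "onoff_genes": sorted(calls.loc[calls["onoff"].astype(bool), "gene_id"].astype(str).unique()),
    }
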
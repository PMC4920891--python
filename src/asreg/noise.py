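"""Abundance-corrected expression noise from flow cytometry.

Noise is quantified as CV% = (SD/mean) x 100 on G1-gated GFP values.
Because CV^2 falls with abundance (approximately a/mean + b), raw CVs of
two constructs with different means are not comparable; the analysis
therefore fits a robust line to log10(CV%^2) versus log10(mean) across all
gene x construct samples and works with the residual to that trend
(``cv_res``).  The gene-wise difference in ``cv_res`` between the
antisense-present (scrambled control) and antisense-free (terminator)
constructs is compared between regulated and non-regulated genes with a
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import RankSumResult, TrendFit, irls_line, rank_sum_test

GATE_FRACTION = 0.10
GATE_BINS = 64
MIN_EVENTS = 1000


def gate_g1(events: pd.DataFrame, fraction: float = GATE_FRACTION, bins: int = GATE_BINS) -> pd.DataFrame:
    """Mode-centred density gate on the (FSC, SSC) plane.

    Events are binned on a ``bins x bins`` grid; the gate keeps the
    smallest set of densest bins that together cover at least ``fraction``
    of the events, selecting the homogeneous core of the scatter cloud
    (a stand-in for unbudded-G1 selection).  Deterministic: ties between
    equally dense bins are broken by bin index.
    """
    if len(events) < MIN_EVENTS:
        raise ValueError(f"sample has {len(events)} events; need >= {MIN_EVENTS}")
    fsc = events["fsc"].to_numpy(dtype=float)
    ssc = events["ssc"].to_numpy(dtype=float)
    counts, xe, ye = np.histogram2d(fsc, ssc, bins=bins)
    flat = counts.ravel()
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    n_keep = int(np.searchsorted(cum, fraction * len(events)) + 1)
    kept = np.zeros(flat.size, dtype=bool)
    kept[order[:n_keep]] = True

    ix = np.clip(np.searchsorted(xe, fsc, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, ssc, side="right") - 1, 0, bins - 1)
    return events[kept[ix * bins + iy]]


def compute_cv(gfp: np.ndarray) -> tuple[float, float]:
    """Mean and CV% = (SD/mean) x 100, SD with the n-1 denominator."""
    gfp = np.asarray(gfp, dtype=float)
    if gfp.size < 2:
        raise ValueError("need at least 2 values")
    mean = gfp.mean()
    if mean <= 0:
        raise ValueError("non-positive mean; sample excluded")
    return float(mean), float(gfp.std(ddof=1) / mean * 100.0)


def estimate_noise(
    events: pd.DataFrame,
    fraction: float = GATE_FRACTION,
    bins: int = GATE_BINS,
) -> pd.DataFrame:
    """Gate and summarize every gene x construct sample.

    Returns one row per sample: gated event count, mean GFP, CV%, and the
    log10 quantities used for the trend fit.  Samples with too few events
    or non-positive means are dropped with a reason column.
    """
    rows = []
    for (gene, construct), sub in events.groupby(["gene_id", "construct"], observed=True):
        try:
            gated = gate_g1(sub, fraction=fraction, bins=bins)
            mean, cv = compute_cv(gated["gfp"].to_numpy())
        except ValueError as err:
            rows.append(
                {"gene_id": gene, "construct": construct, "n_gated": 0,
                 "mean_gfp": np.nan, "cv_pct": np.nan,
                 "log10_mean": np.nan, "log10_cv2": np.nan, "excluded": str(err)}
            )
            continue
        rows.append(
            {
                "gene_id": gene,
                "construct": construct,
                "n_gated": len(gated),
                "mean_gfp": mean,
                "cv_pct": cv,
                "log10_mean": np.log10(mean),
                "log10_cv2": np.log10(cv**2),
                "excluded": "",
            }
        )
    return pd.DataFrame(rows)


def fit_cv_trend(noise_table: pd.DataFrame) -> TrendFit:
    """Robust line through (log10 mean, log10 CV%^2) over all samples."""
    ok = noise_table.dropna(subset=["log10_mean", "log10_cv2"])
    return irls_line(ok["log10_mean"].to_numpy(), ok["log10_cv2"].to_numpy())


def cv_residual(noise_table: pd.DataFrame, fit: TrendFit) -> pd.DataFrame:
    """Attach ``cv_res`` = log10 CV^2 minus the fitted trend."""
    out = noise_table.copy()
    out["cv_res"] = out["log10_cv2"] - fit.predict(out["log10_mean"].to_numpy())
    return out


@dataclass(frozen=True)
class NoiseComparison:
    test: RankSumResult
    n_regulated: int
    n_nonregulated: int
    median_regulated: float
    median_nonregulated: float
    regulated_sign: int  # sign of the regulated-group median delta


def delta_cv_res(noise_table: pd.DataFrame) -> pd.Series:
    """Gene-wise ``cv_res(PHO5_T_scr) - cv_res(PHO5_T)``."""
    piv = noise_table.pivot_table(
        index="gene_id", columns="construct", values="cv_res", observed=True
    )
    return (piv["PHO5_T_scr"] - piv["PHO5_T"]).dropna()


def compare_noise(
    noise_table: pd.DataFrame, regulated_gene_ids
) -> NoiseComparison:
    """Compare gene-wise noise deltas between regulated and non-regulated
    genes (two-sided Wilcoxon rank-sum; exact for small combined n)."""
    delta = delta_cv_res(noise_table)
    regulated = set(regulated_gene_ids)
    is_reg = delta.index.astype(str).isin(regulated)
    d_reg = delta[is_reg].to_numpy()
    d_non = delta[~is_reg].to_numpy()
    if d_reg.size < 3 or d_non.size < 3:
        raise ValueError("need at least 3 genes per group")
    test = rank_sum_test(d_reg, d_non)
    med_reg = float(np.median(d_reg))
    return NoiseComparison(
        test=test,
        n_regulated=int(d_reg.size),
        n_nonregulated=int(d_non.size),
        median_regulated=med_reg,
        median_nonregulated=float(np.median(d_non)),
        regulated_sign=int(np.sign(med_reg)),
    )
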
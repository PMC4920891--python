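"""Gene-level feature analyses around the regulation calls.

Covers the classification of antisense/TSS overlap, rank correlations of
the antisense effect with expression covariates, category enrichment
(Fisher's exact test), counting of antisense-orientation binding sites
(e.g. Nrd1), and the transcript-length comparison between regulated and
non-regulated genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import (
    FisherResult,
    RankSumResult,
    SpearmanResult,
    fisher_exact_test,
    rank_sum_test,
    spearman_correlation,
)
from .synth import GeneAnnotation

EFFECT_COVARIATES = ("antisense_level", "as_over_s_ratio", "scr_sfgfp_norm")


def classify_tss_overlap(gene: GeneAnnotation) -> str:
    """Category from coordinates: ``NO_AS`` without an antisense interval,
    ``TSS_OVERLAP`` when the (half-open) antisense interval contains the
    sense TSS, ``NO_TSS_OVERLAP`` otherwise."""
    if gene.as_start is None:
        return "NO_AS"
    if gene.as_strand == gene.sense_strand:
        raise ValueError(f"{gene.gene_id}: antisense annotated on the sense strand")
    if gene.as_start <= gene.sense_tss < gene.as_end:
        return "TSS_OVERLAP"
    return "NO_TSS_OVERLAP"


def effect_correlation(
    feature_rows: pd.DataFrame, covariate: str, effect_col: str = "log2fc"
) -> SpearmanResult:
    """Spearman correlation of the antisense effect with a covariate.

    Rows with a missing covariate or effect are dropped; at least five
    complete pairs are required.
    """
    if covariate not in feature_rows.columns:
        raise KeyError(f"unknown covariate {covariate!r}")
    sub = feature_rows[[effect_col, covariate]].dropna()
    sub = sub[np.isfinite(sub[covariate]) & np.isfinite(sub[effect_col])]
    if len(sub) < 5:
        raise ValueError("need at least 5 complete pairs")
    return spearman_correlation(sub[covariate].to_numpy(), sub[effect_col].to_numpy())


def enrichment_test(table) -> FisherResult:
    """Fisher's exact test (probability-based two-sided) on a 2x2 table of
    category membership versus regulation status."""
    return fisher_exact_test(table)


def count_antisense_sites(
    transcript_start: int,
    transcript_end: int,
    sense_strand: str,
    sites: pd.DataFrame,
    chrom: str | None = None,
) -> int:
    """Number of site intervals overlapping the transcript (half-open) on
    the strand opposite to the sense strand."""
    s = sites
    if chrom is not None and "chrom" in s.columns:
        s = s[s["chrom"] == chrom]
    opposite = "-" if sense_strand == "+" else "+"
    start = s["start"].to_numpy()
    end = s["end"].to_numpy()
    strand = s["strand"].to_numpy()
    hit = (start < transcript_end) & (end > transcript_start) & (strand == opposite)
    return int(hit.sum())


def add_site_counts(
    feature_rows: pd.DataFrame,
    panel: list[GeneAnnotation],
    sites: pd.DataFrame,
    column: str = "nrd1_antisense_sites",
) -> pd.DataFrame:
    """Attach antisense-orientation site counts per gene."""
    counts = {
        g.gene_id: count_antisense_sites(
            g.sense_start, g.sense_end, g.sense_strand, sites, chrom=g.chrom
        )
        for g in panel
    }
    out = feature_rows.copy()
    out[column] = out["gene_id"].map(counts).fillna(0).astype(int)
    return out


def compare_lengths(lengths_regulated, lengths_nonregulated) -> RankSumResult:
    """Transcript lengths, regulated versus non-regulated genes (two-sided
    Wilcoxon rank-sum; shared engine with the noise comparison)."""
    x = np.asarray(lengths_regulated, dtype=float)
    y = np.asarray(lengths_nonregulated, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 genes per group")
    return rank_sum_test(x, y)


def assemble_feature_rows(
    panel: list[GeneAnnotation],
    calls: pd.DataFrame,
    truth_or_levels: pd.DataFrame,
) -> pd.DataFrame:
    """One row per gene: category, regulation status, strongest significant
    effect, transcript-level sense/antisense abundances, and derived
    covariates for the correlation analyses.

    ``truth_or_levels`` must carry gene_id, sense_level and antisense_level
    (transcript-level measurements; with synthetic data, the truth table).
    """
    pf = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in panel],
            "category": [g.category for g in panel],
            "transcript_length": [g.length for g in panel],
        }
    )
    reg = (
        calls.groupby("gene_id", observed=True)
        .agg(regulated_any_condition=("regulated", "any"))
        .reset_index()
    )
    sig = calls[calls["significant"]]
    max_fc = (
        sig.loc[sig.groupby("gene_id", observed=True)["log2fc"].transform(
            lambda v: v.abs() == v.abs().max()
        )]
        .drop_duplicates("gene_id")[["gene_id", "log2fc"]]
        .rename(columns={"log2fc": "max_abs_log2fc"})
    )
    scr_level = (
        calls.groupby("gene_id", observed=True)["mean_raw_PHO5_T_scr"]
        .mean()
        .rename("scr_sfgfp_norm")
        .reset_index()
    )
    levels = truth_or_levels.drop_duplicates("gene_id")[
        ["gene_id", "sense_level", "antisense_level"]
    ]
    out = (
        pf.merge(reg, on="gene_id", how="left")
        .merge(max_fc, on="gene_id", how="left")
        .merge(scr_level, on="gene_id", how="left")
        .merge(levels, on="gene_id", how="left")
    )
    out["regulated_any_condition"] = out["regulated_any_condition"].fillna(False).astype(bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["as_over_s_ratio"] = np.where(
            out["sense_level"] > 0, out["antisense_level"] / out["sense_level"], np.nan
        )
    return out
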
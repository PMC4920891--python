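"""Per-well background normalization, QC, and expression calls.

Each well co-cultures GFP-tagged sample cells with non-fluorescent
reference cells.  Dividing every sample cell's intensity by the median
reference intensity of the same well cancels well-level multiplicative
factors (illumination, exposure) exactly and yields the dimensionless
per-well summary ``sfgfp_norm`` (median over sample cells); a well whose
sample distribution matches its reference has ``sfgfp_norm == 1``.

The expression threshold theta is calibrated from null wells: reference
populations split in half and normalized against themselves.  A construct
is called expressed in a gene x condition when its mean ``sfgfp_norm``
strictly exceeds theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WELL_KEYS = ["well_id", "gene_id", "construct", "condition", "replicate"]

#: QC: a well must contain strictly more than this many cells of each kind.
MIN_CELLS = 100
#: QC: replicate wells of one construct may not differ by more than this
#: factor in sfgfp_norm while both are expressed.
REPLICATE_DISCORDANCE_FACTOR = 2.0
#: quantile of null-split sfgfp_norm defining the expression threshold.
EXPRESSION_QUANTILE = 0.99


@dataclass(frozen=True)
class WellSummary:
    well_id: str
    n_sample_cells: int
    n_reference_cells: int
    sfgfp_norm: float
    normalized: np.ndarray  # per-cell normalized sample intensities


def normalize_well(sample_gfp, reference_gfp) -> WellSummary:
    """Normalize one well: per-cell ratio to the reference median.

    Raises ``ValueError`` on an empty population (the table-level driver
    turns that into a QC FAIL instead).
    """
    s = np.asarray(sample_gfp, dtype=float)
    r = np.asarray(reference_gfp, dtype=float)
    if s.size == 0 or r.size == 0:
        raise ValueError("both sample and reference populations must be non-empty")
    ref_med = np.median(r)
    if ref_med <= 0:
        raise ValueError("non-positive reference median")
    norm = s / ref_med
    return WellSummary(
        well_id="",
        n_sample_cells=s.size,
        n_reference_cells=r.size,
        sfgfp_norm=float(np.median(norm)),
        normalized=norm,
    )


def normalize_wells(
    cells: pd.DataFrame, reference_col: str = "is_reference_truth"
) -> pd.DataFrame:
    """Per-well summaries for a whole CellTable.

    Returns one row per well with cell counts and ``sfgfp_norm``;
    a missing population yields NaN (picked up by :func:`qc_filter`).
    """
    is_ref = cells[reference_col].astype(bool)
    gb_ref = cells[is_ref].groupby("well_id", observed=True)["gfp_intensity"]
    gb_smp = cells[~is_ref].groupby("well_id", observed=True)["gfp_intensity"]
    meta = cells[WELL_KEYS].drop_duplicates("well_id").set_index("well_id")
    out = meta.copy()
    out["n_sample_cells"] = gb_smp.size().reindex(meta.index).fillna(0).astype(int)
    out["n_reference_cells"] = gb_ref.size().reindex(meta.index).fillna(0).astype(int)
    ref_med = gb_ref.median().reindex(meta.index)
    smp_med = gb_smp.median().reindex(meta.index)
    out["sfgfp_norm"] = smp_med / ref_med
    return out.reset_index()


def null_split_ratios(
    cells: pd.DataFrame,
    reference_col: str = "is_reference_truth",
    seed: int = 0,
    n_splits: int = 1,
) -> np.ndarray:
    """Null ``sfgfp_norm`` values from reference-vs-reference splits.

    Every well's reference population is split at random into a pseudo
    sample and a pseudo reference half and normalized against itself,
    ``n_splits`` times with independent shuffles.
    """
    ref = cells.loc[cells[reference_col].astype(bool), ["well_id", "gfp_intensity"]].copy()
    if ref.empty:
        raise ValueError("no reference cells found")
    rng = np.random.default_rng(seed)
    ratios = []
    for _ in range(n_splits):
        shuffled = ref.iloc[rng.permutation(len(ref))]
        parity = shuffled.groupby("well_id", observed=True).cumcount() % 2
        med_a = shuffled[parity == 0].groupby("well_id", observed=True)["gfp_intensity"].median()
        med_b = shuffled[parity == 1].groupby("well_id", observed=True)["gfp_intensity"].median()
        ratios.append((med_a / med_b).dropna().to_numpy())
    out = np.concatenate(ratios) if ratios else np.array([])
    if out.size == 0:
        raise ValueError("no well had enough reference cells for a null split")
    return out


def null_reference_threshold(
    cells: pd.DataFrame,
    reference_col: str = "is_reference_truth",
    quantile: float = EXPRESSION_QUANTILE,
    seed: int = 0,
    n_splits: int = 5,
) -> float:
    """Expression threshold theta: the requested quantile of pooled
    reference-vs-reference null-split ``sfgfp_norm`` values."""
    ratios = null_split_ratios(cells, reference_col=reference_col, seed=seed,
                               n_splits=n_splits)
    return float(np.quantile(ratios, quantile))


@dataclass
class QCReport:
    wells: pd.DataFrame  # WELL_KEYS + status, reasons
    removed_fraction: float

    def passing(self) -> pd.DataFrame:
        return self.wells[self.wells["status"] == "PASS"]


def qc_filter(
    well_summaries: pd.DataFrame,
    min_cells: int = MIN_CELLS,
    discordance_factor: float = REPLICATE_DISCORDANCE_FACTOR,
    theta: float | None = None,
) -> QCReport:
    """Quality control on well summaries.

    A well FAILs when it has ``<= min_cells`` sample or reference cells,
    when a population is missing entirely, or — together with its sibling
    replicate wells — when expressed replicates of one construct disagree
    by more than ``discordance_factor`` in ``sfgfp_norm`` (a guard against
    strains carrying PCR errors).  Replicate discordance is only assessed
    when ``theta`` is given (both wells must be expressed).
    """
    w = well_summaries.reset_index(drop=True).copy()
    reasons = [[] for _ in range(len(w))]
    missing = (w["n_sample_cells"] == 0) | (w["n_reference_cells"] == 0) | w["sfgfp_norm"].isna()
    few = (w["n_sample_cells"] <= min_cells) | (w["n_reference_cells"] <= min_cells)
    for i in np.flatnonzero(missing.to_numpy()):
        reasons[i].append("missing-population")
    for i in np.flatnonzero((few & ~missing).to_numpy()):
        reasons[i].append("min-cells")

    if theta is not None:
        ok = ~(missing | few)
        grp = w[ok].groupby(["gene_id", "condition", "construct"], observed=True)
        for _, idx in grp.groups.items():
            sub = w.loc[idx]
            if len(sub) < 2:
                continue
            vals = sub["sfgfp_norm"]
            if (vals > theta).all() and vals.max() / vals.min() > discordance_factor:
                for i in sub.index:
                    reasons[i].append("replicate-discordance")

    w["reasons"] = [";".join(r) for r in reasons]
    w["status"] = np.where(w["reasons"] == "", "PASS", "FAIL")
    removed = float((w["status"] == "FAIL").mean()) if len(w) else 0.0
    return QCReport(wells=w, removed_fraction=removed)


def expression_calls(pass_wells: pd.DataFrame, theta: float) -> pd.DataFrame:
    """Construct-level expression calls per gene x condition.

    ``expressed`` is true when the mean ``sfgfp_norm`` over PASS wells
    strictly exceeds theta (a value equal to theta is not expressed).
    """
    g = pass_wells.groupby(["gene_id", "condition", "construct"], observed=True)
    out = g.agg(
        mean_sfgfp_norm=("sfgfp_norm", "mean"), n_wells=("sfgfp_norm", "size")
    ).reset_index()
    out["expressed"] = out["mean_sfgfp_norm"] > theta
    return out


def tested_mask(calls: pd.DataFrame) -> pd.DataFrame:
    """Gene x condition entry mask: tested when the terminator and/or the
    scrambled-control construct is expressed."""
    sub = calls[calls["construct"].isin(["PHO5_T", "PHO5_T_scr"])]
    t = sub.groupby(["gene_id", "condition"], observed=True)["expressed"].any()
    return t.rename("tested").reset_index()
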
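"""End-to-end orchestration: synth -> normalize -> call -> noise ->
metagene -> features, with a manifest for byte-identical re-runs.

Any stage whose input table is supplied directly in the config (e.g.
``cells_csv``) skips the corresponding synthetic generation, so real
quantification output can be dropped in at the CellTable boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__, calling, features, io, metagene, noise, normalization, synth
from .config import RunConfig

log = logging.getLogger("asreg")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: str) -> str:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sim_params_from_config(cfg: RunConfig) -> synth.SimParams:
    return synth.SimParams(
        conditions=tuple(cfg.conditions),
        replicates_per_construct=cfg.replicates_per_construct,
        cells_per_well=cfg.cells_per_well,
        frac_regulated=cfg.frac_regulated,
        onoff_fraction=cfg.onoff_fraction,
        planted_log2_effect=cfg.planted_log2_effect,
        denoise_factor=cfg.denoise_factor,
        events_per_sample=cfg.events_per_sample,
        seed=cfg.seed,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the result bundle under ``cfg.out_dir``.

    Returns the manifest (config, stage outputs, file hashes).
    """
    cfg.validate()
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    params = sim_params_from_config(cfg)
    outputs: dict[str, str] = {}

    # --- annotation + screen ------------------------------------------------
    if cfg.annotation_gff3:
        panel = io.read_panel_gff3(cfg.annotation_gff3)
    else:
        panel = synth.generate_gene_panel(
            cfg.n_tss_overlap, cfg.n_no_overlap, cfg.n_no_as, seed=cfg.seed
        )
        outputs["panel_gff3"] = io.write_panel_gff3(panel, os.path.join(out, "panel.gff3"))
        outputs["panel_bed12"] = io.write_panel_bed12(panel, os.path.join(out, "panel.bed"))

    truth = None
    if cfg.cells_csv:
        cells = io.read_cell_table(cfg.cells_csv)
        ref_col = "is_reference_truth" if "is_reference_truth" in cells else "is_reference"
    else:
        cells, truth = synth.simulate_screen(panel, params)
        ref_col = "is_reference_truth"
        outputs["truth_csv"] = io.write_csv(truth, os.path.join(out, "truth.csv"))
    log.info("screen: %d cells in %d wells", len(cells), cells["well_id"].nunique())

    # --- normalization ------------------------------------------------------
    wells = normalization.normalize_wells(cells, reference_col=ref_col)
    theta = normalization.null_reference_threshold(
        cells, reference_col=ref_col, quantile=cfg.expression_quantile, seed=cfg.seed
    )
    qc = normalization.qc_filter(
        wells, min_cells=cfg.min_cells, discordance_factor=cfg.discordance_factor, theta=theta
    )
    pass_wells = qc.passing()
    expr = normalization.expression_calls(pass_wells, theta)
    outputs["wells_csv"] = io.write_csv(qc.wells, os.path.join(out, "wells.csv"))
    outputs["qc_json"] = _write_json(
        {"theta": theta, "removed_fraction": qc.removed_fraction},
        os.path.join(out, "qc.json"),
    )
    outputs["expression_csv"] = io.write_csv(expr, os.path.join(out, "expression_calls.csv"))
    log.info("QC removed %.1f%% of wells; theta=%.3f", 100 * qc.removed_fraction, theta)

    # --- regulation calls ---------------------------------------------------
    calls = calling.call_screen(
        pass_wells, expr, theta, p_threshold=cfg.p_threshold, range_factor=cfg.range_factor
    )
    cs_pairs = calling.condition_specific_pairs(
        pass_wells, calls, theta, p_threshold=cfg.condition_specific_p
    )
    summary = calling.summarize_screen(calls)
    outputs["calls_csv"] = io.write_csv(calls, os.path.join(out, "calls.csv"))
    outputs["condition_specific_csv"] = io.write_csv(
        cs_pairs, os.path.join(out, "condition_specific.csv")
    )
    if truth is not None:
        summary["caller_vs_truth"] = caller_performance(calls, truth)
    outputs["summary_json"] = _write_json(summary, os.path.join(out, "screen_summary.json"))

    regulated_any = summary["genes_regulated_any_condition"]
    truth_regulated = (
        sorted(truth.loc[truth["regulated"], "gene_id"].unique()) if truth is not None else regulated_any
    )

    # --- noise --------------------------------------------------------------
    facs_panel = panel[: cfg.n_facs_genes]
    facs_reg = [g.gene_id for g in facs_panel if g.gene_id in set(truth_regulated)]
    events = synth.simulate_facs(facs_panel, params, facs_reg)
    noise_tbl = noise.estimate_noise(events, fraction=cfg.gate_fraction, bins=cfg.gate_bins)
    trend = noise.fit_cv_trend(noise_tbl)
    noise_tbl = noise.cv_residual(noise_tbl, trend)
    comparison = None
    reg_for_compare = [g for g in facs_reg if g in set(regulated_any)] or facs_reg
    try:
        cmp_res = noise.compare_noise(noise_tbl, reg_for_compare)
        comparison = {
            "p_value": cmp_res.test.p_value,
            "method": cmp_res.test.method,
            "median_regulated": cmp_res.median_regulated,
            "median_nonregulated": cmp_res.median_nonregulated,
            "n_regulated": cmp_res.n_regulated,
            "n_nonregulated": cmp_res.n_nonregulated,
            "trend": {"slope": trend.slope, "intercept": trend.intercept, "method": trend.method},
        }
    except ValueError as err:
        comparison = {"error": str(err)}
    outputs["noise_csv"] = io.write_csv(noise_tbl, os.path.join(out, "noise_estimates.csv"))
    outputs["noise_json"] = _write_json(comparison, os.path.join(out, "noise_comparison.json"))

    # --- metagene -----------------------------------------------------------
    tracks = synth.simulate_tracks(panel, truth_regulated, params, bin_size=cfg.bin_size)
    outputs.update(
        {f"bedgraph_{k}": v for k, v in io.write_bedgraph(tracks, os.path.join(out, "tracks")).items()}
    )
    reg_set = set(truth_regulated)
    groups = {
        "regulated": [g.gene_id for g in panel if g.gene_id in reg_set],
        "nonregulated_with_as": [
            g.gene_id for g in panel if g.gene_id not in reg_set and g.category != "NO_AS"
        ],
    }
    window = (cfg.window_up, cfg.window_down)
    prof_frames, peak_rows = [], []
    for anchor in ("TSS", "STOP"):
        for mark in ("antisense", "H3K4me2", "H3K4me3", "H3R2me2"):
            tm = metagene.align_tracks(tracks, panel, mark, anchor=anchor, window=window)
            prof = metagene.profile_table(
                tm, groups, n_boot=cfg.n_boot, smooth_bins=cfg.smooth_bins, seed=cfg.seed
            )
            prof["mark"] = mark
            prof_frames.append(prof)
            for name, gids in groups.items():
                sub = tm.group(gids)
                if sub.values.shape[0] == 0:
                    continue
                p = metagene.smoothed_median_profile(sub, cfg.smooth_bins)
                if np.isfinite(p).any():
                    pos, val = metagene.profile_peak(p, tm.positions)
                    peak_rows.append(
                        {"mark": mark, "anchor": anchor, "group": name,
                         "peak_position": pos, "peak_value": val}
                    )
    outputs["profiles_csv"] = io.write_csv(
        pd.concat(prof_frames, ignore_index=True), os.path.join(out, "metagene_profiles.csv")
    )
    outputs["peaks_csv"] = io.write_csv(pd.DataFrame(peak_rows), os.path.join(out, "metagene_peaks.csv"))

    # --- features -----------------------------------------------------------
    sites = synth.simulate_nrd1_sites(panel, truth_regulated, seed=cfg.seed)
    outputs["sites_bed"] = io.write_sites_bed(sites, os.path.join(out, "nrd1_sites.bed"))
    levels = truth if truth is not None else pd.DataFrame(
        {"gene_id": [g.gene_id for g in panel], "sense_level": np.nan, "antisense_level": np.nan}
    )
    rows = features.assemble_feature_rows(panel, calls, levels)
    rows = features.add_site_counts(rows, panel, sites)
    outputs["features_csv"] = io.write_csv(rows, os.path.join(out, "feature_rows.csv"))
    outputs["feature_stats_json"] = _write_json(
        feature_statistics(rows), os.path.join(out, "feature_stats.json")
    )

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "version": __version__,
        "outputs": {k: os.path.relpath(v, out) for k, v in outputs.items()},
        "sha256": {k: _sha256(v) for k, v in outputs.items()},
    }
    _write_json(manifest, os.path.join(out, "manifest.json"))
    return manifest


def caller_performance(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity and false-discovery rate of the calls against the
    planted per-gene x condition truth."""
    merged = calls.merge(
        truth[["gene_id", "condition", "regulated"]].rename(columns={"regulated": "true_reg"}),
        on=["gene_id", "condition"],
        how="left",
    )
    called = merged["regulated"].to_numpy(dtype=bool)
    true = merged["true_reg"].fillna(False).to_numpy(dtype=bool)
    tp = int((called & true).sum())
    fp = int((called & ~true).sum())
    fn = int((~called & true).sum())
    return {
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fdr": fp / (tp + fp) if tp + fp else 0.0,
    }


def feature_statistics(rows: pd.DataFrame) -> dict:
    """Correlations, enrichment, site-count and length comparisons on the
    assembled gene-feature table."""
    out: dict = {}
    sig = rows.dropna(subset=["max_abs_log2fc"])
    for cov in ("antisense_level", "as_over_s_ratio", "scr_sfgfp_norm"):
        try:
            r = features.effect_correlation(sig, cov, effect_col="max_abs_log2fc")
            out[f"spearman_{cov}"] = {"rho": r.rho, "p": r.p_value, "n": r.n, "method": r.method}
        except (ValueError, KeyError) as err:
            out[f"spearman_{cov}"] = {"error": str(err)}

    with_as = rows[rows["category"] != "NO_AS"]
    tab = pd.crosstab(
        with_as["category"] == "TSS_OVERLAP", with_as["regulated_any_condition"]
    )
    if tab.shape == (2, 2):
        fr = features.enrichment_test(tab.to_numpy())
        out["tss_overlap_enrichment"] = {"odds_ratio": fr.odds_ratio, "p": fr.p_value}

    reg = with_as[with_as["regulated_any_condition"]]
    non = with_as[~with_as["regulated_any_condition"]]
    if len(reg) >= 3 and len(non) >= 3:
        lt = features.compare_lengths(reg["transcript_length"], non["transcript_length"])
        out["length_comparison"] = {
            "p": lt.p_value, "method": lt.method,
            "median_regulated": lt.median_x, "median_nonregulated": lt.median_y,
        }
        nrd_tab = np.array(
            [
                [(non["nrd1_antisense_sites"] > 0).sum(), (non["nrd1_antisense_sites"] == 0).sum()],
                [(reg["nrd1_antisense_sites"] > 0).sum(), (reg["nrd1_antisense_sites"] == 0).sum()],
            ]
        )
        if (nrd_tab.sum(axis=0) > 0).all() and (nrd_tab.sum(axis=1) > 0).all():
            fr = features.enrichment_test(nrd_tab)
            out["nrd1_site_enrichment"] = {"odds_ratio": fr.odds_ratio, "p": fr.p_value}
    return out
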
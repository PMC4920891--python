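"""Generator contracts: panel geometry, planted screen effects, FACS noise
law, track geometry, and well images."""

import numpy as np
import pandas as pd
import pytest

from asreg import features, metagene, noise, synth
from conftest import brute_force_category


class TestGenePanel:
    def test_requested_counts(self):
        panel = synth.generate_gene_panel(81, 81, 26, seed=1)
        counts = pd.Series([g.category for g in panel]).value_counts()
        assert len(panel) == 188
        assert counts["TSS_OVERLAP"] == 81
        assert counts["NO_TSS_OVERLAP"] == 81
        assert counts["NO_AS"] == 26

    def test_empty_panel(self):
        assert synth.generate_gene_panel(0, 0, 0, seed=9) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_gene_panel(-1, 0, 0, seed=0)

    def test_deterministic(self):
        a = synth.generate_gene_panel(5, 5, 2, seed=3)
        b = synth.generate_gene_panel(5, 5, 2, seed=3)
        assert a == b

    def test_categories_reclassify_consistently(self, small_panel):
        for g in small_panel:
            assert features.classify_tss_overlap(g) == g.category
            assert brute_force_category(g) == g.category

    def test_no_overlap_gap_respected(self, small_panel):
        for g in small_panel:
            if g.category != "NO_TSS_OVERLAP":
                continue
            gap = (
                g.as_start - g.sense_tss
                if g.sense_strand == "+"
                else g.sense_tss - g.as_end + 1
            )
            assert gap >= synth.NO_OVERLAP_GAP

    def test_antisense_opposite_strand_and_overlapping(self, small_panel):
        for g in small_panel:
            if g.as_start is None:
                continue
            assert g.as_strand != g.sense_strand
            assert g.as_start < g.sense_end and g.as_end > g.sense_start


class TestSimulateScreen:
    def test_null_truth_and_symmetry(self, small_panel):
        params = synth.null_params(synth.SimParams(conditions=("SC",), seed=5))
        cells, truth = synth.simulate_screen(small_panel, params)
        assert (truth["planted_log2fc"] == 0).all()
        assert not truth["regulated"].any()
        means = (
            cells[~cells["is_reference_truth"]]
            .groupby(["gene_id", "construct"], observed=True)["gfp_intensity"]
            .mean()
            .unstack()
        )
        diffs = np.log2(means["PHO5_T_scr"] / means["PHO5_T"])
        assert abs(diffs.mean()) < 0.2  # centred on zero

    def test_planted_effect_closed_form(self, small_panel):
        # small noise, high expression: well-mean ratio scr/T -> 2^-effect
        params = synth.SimParams(
            conditions=("SC",), seed=6, frac_regulated=0.5, onoff_fraction=0.0,
            sigma_cell=0.02, sigma_well=0.0, sigma_condition=0.0,
            mu_log_expression=16.0, sigma_expression=0.1,
        )
        cells, truth = synth.simulate_screen(small_panel, params)
        reg = truth.loc[truth["regulated"], "gene_id"]
        sample = cells[~cells["is_reference_truth"] & cells["gene_id"].isin(reg)]
        means = (
            sample.groupby(["gene_id", "construct"], observed=True)["gfp_intensity"]
            .mean()
            .unstack()
        )
        ratios = means["PHO5_T_scr"] / means["PHO5_T"]
        assert np.allclose(ratios, 0.5, atol=0.02)

    def test_deterministic(self, small_panel):
        params = synth.SimParams(conditions=("SC",), seed=7)
        c1, t1 = synth.simulate_screen(small_panel, params)
        c2, t2 = synth.simulate_screen(small_panel, params)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_reference_cells_background_only(self, screen_sc):
        cells, _, params = screen_sc
        ref = cells[cells["is_reference_truth"]]
        # reference GFP stays near background regardless of gene expression
        assert ref["gfp_intensity"].median() < 3 * params.background_mean

    def test_effect_override(self, small_panel):
        gid = small_panel[0].gene_id
        params = synth.null_params(synth.SimParams(conditions=("SC", "YPE"), seed=8))
        _, truth = synth.simulate_screen(
            small_panel, params, effect_overrides={(gid, "SC"): 1.0}
        )
        row = truth.set_index(["gene_id", "condition"])
        assert row.loc[(gid, "SC"), "planted_log2fc"] == -1.0
        assert row.loc[(gid, "YPE"), "planted_log2fc"] == 0.0


class TestSimulateFacs:
    def test_moment_fidelity(self):
        panel = synth.generate_gene_panel(2, 2, 1, seed=10)
        params = synth.SimParams(seed=10, events_per_sample=100_000,
                                 sigma_noise_excess=0.0)
        ev = synth.simulate_facs(panel, params, [])
        for (_, _), sub in ev.groupby(["gene_id", "construct"], observed=True):
            g = sub["gfp"].to_numpy()
            m = g.mean()
            cv2 = g.var(ddof=1) / m**2
            expected = params.noise_a / m + params.noise_b
            # 3 Monte-Carlo SEs of the CV^2 estimate at n = 1e5
            assert cv2 == pytest.approx(expected, rel=0.05)

    def test_no_denoising_when_factor_one(self):
        panel = synth.generate_gene_panel(4, 4, 0, seed=11)
        params = synth.SimParams(seed=11, events_per_sample=30_000, denoise_factor=1.0)
        reg = [g.gene_id for g in panel][:4]
        ev = synth.simulate_facs(panel, params, reg)
        tbl = noise.estimate_noise(ev)
        trend = noise.fit_cv_trend(tbl)
        delta = noise.delta_cv_res(noise.cv_residual(tbl, trend))
        assert abs(delta.mean()) < 0.05

    def test_denoising_shifts_regulated_group(self):
        panel = synth.generate_gene_panel(8, 8, 0, seed=12)
        params = synth.SimParams(seed=12, events_per_sample=30_000, denoise_factor=0.5)
        reg = [g.gene_id for g in panel][:6]
        ev = synth.simulate_facs(panel, params, reg)
        tbl = noise.estimate_noise(ev)
        tbl = noise.cv_residual(tbl, noise.fit_cv_trend(tbl))
        cmp_res = noise.compare_noise(tbl, reg)
        assert cmp_res.median_regulated < cmp_res.median_nonregulated


@pytest.fixture(scope="module")
def aligned(small_panel):
    params = synth.SimParams(seed=13)
    reg = [g.gene_id for g in small_panel if g.category != "NO_AS"][:6]
    tracks = synth.simulate_tracks(small_panel, reg, params)
    return small_panel, tracks, set(reg)


class TestSimulateTracks:

    def test_regulated_peak_at_tss(self, aligned):
        panel, tracks, reg = aligned
        tm = metagene.align_tracks(tracks, panel, "antisense", anchor="TSS")
        prof = metagene.smoothed_median_profile(tm.group(sorted(reg)))
        pos, _ = metagene.profile_peak(prof, tm.positions)
        assert abs(pos) <= 2 * tracks.bin_size

    def test_nonregulated_peak_inside_cds(self, aligned):
        panel, tracks, reg = aligned
        nonreg = [g.gene_id for g in panel if g.gene_id not in reg and g.category != "NO_AS"]
        tm = metagene.align_tracks(tracks, panel, "antisense", anchor="STOP")
        prof = metagene.smoothed_median_profile(tm.group(nonreg))
        pos, _ = metagene.profile_peak(prof, tm.positions)
        assert pos < 0  # upstream of the stop codon = inside the coding region

    def test_h3k4_elevated_at_regulated_3prime(self, aligned):
        panel, tracks, reg = aligned
        nonreg = [g.gene_id for g in panel if g.gene_id not in reg and g.category != "NO_AS"]
        tm = metagene.align_tracks(tracks, panel, "H3K4me3", anchor="STOP")
        m_reg, _, _ = metagene.bootstrap_profile(tm.group(sorted(reg)), n_boot=200, seed=0)
        m_non, _, _ = metagene.bootstrap_profile(tm.group(nonreg), n_boot=200, seed=0)
        core = slice(40, 60)  # around the stop anchor
        assert np.nanmean(m_reg[core]) > np.nanmean(m_non[core])


class TestWellImage:
    def test_zero_cells(self):
        img, labels, truth = synth.simulate_well_image(
            pd.DataFrame(columns=["gfp_intensity", "marker_intensity"]),
            synth.ImageParams(), seed=0,
        )
        assert labels.max() == 0
        assert truth.empty

    def test_capacity_error(self):
        cells = pd.DataFrame(
            {"gfp_intensity": np.ones(10_000), "marker_intensity": np.ones(10_000)}
        )
        with pytest.raises(ValueError):
            synth.simulate_well_image(cells, synth.ImageParams(shape=(64, 64)), seed=0)

    def test_mask_totals_match_request(self):
        rng = np.random.default_rng(14)
        cells = pd.DataFrame(
            {
                "gfp_intensity": rng.uniform(5e3, 5e4, 20),
                "marker_intensity": rng.uniform(1e3, 1e4, 20),
            }
        )
        p = synth.ImageParams(camera_noise_sd=0.0, shading_amplitude=0.0)
        img, labels, truth = synth.simulate_well_image(cells, p, seed=14)
        for _, row in truth.iterrows():
            mask = labels == row["label"]
            integrated = img[0][mask].sum() - p.background * mask.sum()
            assert integrated == pytest.approx(row["total_gfp"], rel=1e-6)
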
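"""Synthetic data generator for the antisense-regulation screen.

Emulates every input the analysis pipeline consumes, with the statistical
structure the downstream methods assume and a known planted ground truth:

* a gene panel with three antisense-overlap categories (antisense spanning
  the sense TSS, antisense stopping short of the TSS, no annotated
  antisense), mirroring a library of tagged yeast ORFs;
* per-well single-cell fluorescence tables for paired terminator
  (``PHO5_T``, antisense abrogated) / scrambled-control (``PHO5_T_scr``,
  antisense intact) / untagged-terminator (``WT``) strains co-cultured with
  non-fluorescent reference cells, across growth conditions;
* flow-cytometry event clouds whose noise follows CV^2 = a/mean + b with a
  planted denoising of regulated genes when antisense is present;
* strand-specific antisense read-density and histone-mark tracks with the
  planted geometry (TSS-proximal antisense peak for regulated genes,
  peak shifted into the coding sequence for non-regulated ones, elevated
  H3K4me2/3 at the 3' end of regulated genes);
* two-channel well images for the imaging module, with per-cell truth.

Cell intensities are log-normal around the gene's expression level; each
well carries one multiplicative factor shared by sample and reference
cells, which the per-well reference normalization cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONSTRUCTS = ("PHO5_T", "PHO5_T_scr", "WT")
CONDITIONS = ("YPAD", "YPGal", "YPE", "SC")
CATEGORIES = ("TSS_OVERLAP", "NO_TSS_OVERLAP", "NO_AS")

#: minimum gap (bp) between a non-TSS-overlapping antisense transcript and
#: the sense TSS; the annotation convention carries no published value.
NO_OVERLAP_GAP = 50

TRACK_MARKS = ("netseq_plus", "netseq_minus", "H3K4me2", "H3K4me3", "H3R2me2")


@dataclass(frozen=True)
class GeneAnnotation:
    """Sense transcript plus (optionally) its overlapping antisense SUT.

    Coordinates are 0-based half-open.  ``sense_tss`` is the first
    transcribed base of the sense gene; ``category`` records whether the
    antisense interval covers it.
    """

    gene_id: str
    chrom: str
    sense_start: int
    sense_end: int
    sense_strand: str
    sense_tss: int
    as_start: int | None
    as_end: int | None
    as_strand: str | None
    category: str

    def __post_init__(self):
        if not self.sense_start < self.sense_end:
            raise ValueError(f"{self.gene_id}: sense_start must be < sense_end")
        if self.sense_strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.sense_strand!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.gene_id}: unknown category {self.category!r}")
        if self.as_start is not None:
            if self.as_strand == self.sense_strand:
                raise ValueError(f"{self.gene_id}: antisense must be on the opposite strand")
            if not (self.as_start < self.sense_end and self.as_end > self.sense_start):
                raise ValueError(f"{self.gene_id}: antisense does not overlap the sense gene")

    @property
    def stop_anchor(self) -> int:
        """Genomic coordinate of the sense 3' end (stop-codon anchor)."""
        return self.sense_end if self.sense_strand == "+" else self.sense_start

    @property
    def length(self) -> int:
        return self.sense_end - self.sense_start


@dataclass
class SimParams:
    """Knobs of the generator; defaults are the simulated study conditions.

    ``planted_log2_effect`` is the antisense repression in log2 units
    (1.0 = 2-fold, the screen's average effect size); ``noise_a``/``noise_b``
    parameterize the flow-cytometry noise law CV^2 = a/mean + b;
    ``denoise_factor`` scales the regulated genes' CV^2 excess above that
    trend when antisense is present (<1 plants denoising).
    """

    conditions: Sequence[str] = CONDITIONS
    replicates_per_construct: int = 2
    cells_per_well: int = 300
    mu_log_expression: float = 13.0  # log2 a.u.; median expression ~8000x a.u.
    sigma_expression: float = 1.0    # gene-to-gene spread, log2 units
    sigma_condition: float = 0.2     # gene x condition modulation, log2 units
    sigma_cell: float = 0.35         # cell-to-cell, log2 units (~25% CV)
    sigma_well: float = 0.15         # multiplicative well factor, log2 units
    background_mean: float = 100.0   # a.u., autofluorescence
    background_sd: float = 10.0
    planted_log2_effect: float = 1.0
    frac_regulated: float = 0.2
    onoff_fraction: float = 0.1      # fraction of regulated genes switched off
    noise_a: float = 400.0   # a.u.; CV^2 ~ 0.05 at the median expression
    noise_b: float = 0.01
    sigma_noise_excess: float = 0.15  # half-normal scale of log10 CV^2 excess
    denoise_factor: float = 0.5
    events_per_sample: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.replicates_per_construct < 1 or self.cells_per_well < 1:
            raise ValueError("replicates_per_construct and cells_per_well must be >= 1")
        for name in ("sigma_expression", "sigma_cell", "sigma_well", "background_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_regulated", "onoff_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_a < 0 or self.noise_b < 0:
            raise ValueError("noise_a and noise_b must be >= 0")
        if self.events_per_sample < 1:
            raise ValueError("events_per_sample must be positive")


def _spawn(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------

def generate_gene_panel(
    n_tss_overlap: int, n_no_overlap: int, n_no_as: int, seed: int
) -> list[GeneAnnotation]:
    """Lay out a gene panel on one synthetic chromosome.

    Genes alternate strand at random, are spaced far enough apart that
    metagene windows never collide, and get an antisense SUT consistent
    with the requested category.
    """
    for n in (n_tss_overlap, n_no_overlap, n_no_as):
        if n < 0:
            raise ValueError("gene counts must be non-negative")
    rng = _spawn(seed, 0)
    n_total = n_tss_overlap + n_no_overlap + n_no_as
    categories = (
        ["TSS_OVERLAP"] * n_tss_overlap
        + ["NO_TSS_OVERLAP"] * n_no_overlap
        + ["NO_AS"] * n_no_as
    )
    order = rng.permutation(n_total)
    panel: list[GeneAnnotation] = []
    cursor = 2000
    spacing = 2000
    for i in range(n_total):
        cat = categories[order[i]]
        length = int(rng.integers(600, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        s, e = cursor, cursor + length
        tss = s if strand == "+" else e - 1
        as_start = as_end = as_strand = None
        if cat != "NO_AS":
            as_strand = "-" if strand == "+" else "+"
            into = int(rng.integers(200, max(201, length - 100)))
            if cat == "TSS_OVERLAP":
                beyond = int(rng.integers(50, 250))
                if strand == "+":
                    as_start, as_end = s - beyond, s + into
                else:
                    as_start, as_end = e - into, e + beyond
            else:
                gap = NO_OVERLAP_GAP + int(rng.integers(0, 150))
                ext = int(rng.integers(200, 800))
                if strand == "+":
                    as_start, as_end = s + gap, s + gap + ext
                else:
                    as_start, as_end = e - gap - ext, e - gap
        panel.append(
            GeneAnnotation(
                gene_id=f"gene{order[i]:04d}",
                chrom="chrS",
                sense_start=s,
                sense_end=e,
                sense_strand=strand,
                sense_tss=tss,
                as_start=as_start,
                as_end=as_end,
                as_strand=as_strand,
                category=cat,
            )
        )
        cursor = e + spacing
    panel.sort(key=lambda g: g.gene_id)
    return panel


def panel_frame(panel: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Panel as a tidy DataFrame (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in panel],
            "chrom": [g.chrom for g in panel],
            "sense_start": [g.sense_start for g in panel],
            "sense_end": [g.sense_end for g in panel],
            "sense_strand": [g.sense_strand for g in panel],
            "sense_tss": [g.sense_tss for g in panel],
            "as_start": [g.as_start for g in panel],
            "as_end": [g.as_end for g in panel],
            "as_strand": [g.as_strand for g in panel],
            "category": [g.category for g in panel],
            "transcript_length": [g.length for g in panel],
        }
    )


def choose_regulated(
    panel: Sequence[GeneAnnotation], frac_regulated: float, rng: np.random.Generator
) -> list[str]:
    """Pick regulated genes among antisense-carrying genes.

    Sampling is weighted toward TSS-overlapping and shorter genes, planting
    the category enrichment and the length contrast the analysis looks for.
    """
    with_as = [g for g in panel if g.category != "NO_AS"]
    n_reg = int(round(frac_regulated * len(panel)))
    n_reg = min(n_reg, len(with_as))
    if n_reg == 0 or not with_as:
        return []
    med_len = np.median([g.length for g in with_as])
    w = np.array(
        [
            (3.0 if g.category == "TSS_OVERLAP" else 1.0) * (med_len / g.length)
            for g in with_as
        ]
    )
    idx = rng.choice(len(with_as), size=n_reg, replace=False, p=w / w.sum())
    return sorted(with_as[i].gene_id for i in idx)


# ---------------------------------------------------------------------------
# microscopy screen
# ---------------------------------------------------------------------------

def simulate_screen(
    panel: Sequence[GeneAnnotation],
    params: SimParams,
    regulated_gene_ids: Sequence[str] | None = None,
    effect_overrides: Mapping[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the microscopy screen: one well per gene x condition x
    construct x replicate, each containing sample and reference cells.

    Sample-cell GFP is ``well_factor * (background + expression * 2^N(0, sigma_cell))``;
    reference cells carry the marker channel and background-only GFP.
    ``PHO5_T_scr`` and ``WT`` share the planted antisense repression
    (expression divided by ``2^planted_log2_effect`` for regulated genes);
    ``PHO5_T`` does not.  On/off genes have antisense-present expression set
    to zero above background.  Returns the cell table and a truth table of
    planted per-gene x condition effects.

    ``effect_overrides`` maps (gene_id, condition) to a log2 effect size,
    enabling condition-specific regulation scenarios.
    """
    params.validate()
    rng = _spawn(params.seed, 1)
    genes = [g.gene_id for g in panel]
    n_genes = len(genes)
    conditions = list(params.conditions)
    if regulated_gene_ids is None:
        regulated_gene_ids = choose_regulated(panel, params.frac_regulated, rng)
    regulated = set(regulated_gene_ids)
    unknown = regulated - set(genes)
    if unknown:
        raise ValueError(f"regulated_gene_ids not in panel: {sorted(unknown)}")
    onoff = {
        g
        for g in sorted(regulated)
        if rng.random() < params.onoff_fraction
    }

    # per-gene and per-gene x condition expression (log2 a.u.)
    log2_expr_gene = params.mu_log_expression + params.sigma_expression * rng.standard_normal(
        n_genes
    )
    cond_mod = params.sigma_condition * rng.standard_normal((n_genes, len(conditions)))

    # transcript-level sense/antisense abundances for the feature analyses
    pf = panel_frame(panel)
    sense_level = 2.0 ** (log2_expr_gene - 8.0)
    antisense_level = np.where(
        pf["category"].eq("NO_AS"),
        0.0,
        2.0 ** (3.0 + 0.8 * rng.standard_normal(n_genes)),
    )
    antisense_level = antisense_level * np.where(pf["gene_id"].isin(regulated), 2.0, 1.0)

    truth_rows = []
    effect_overrides = dict(effect_overrides or {})
    eff = np.zeros((n_genes, len(conditions)))
    for i, g in enumerate(genes):
        for j, c in enumerate(conditions):
            if (g, c) in effect_overrides:
                e = effect_overrides[(g, c)]
            elif g in regulated:
                e = params.planted_log2_effect
            else:
                e = 0.0
            eff[i, j] = e
            truth_rows.append(
                {
                    "gene_id": g,
                    "condition": c,
                    "regulated": e != 0.0 or (g in onoff),
                    "onoff": g in onoff,
                    "planted_log2fc": -e,  # log2(scr/T), negative = repression
                    "log2_expression": log2_expr_gene[i] + cond_mod[i, j],
                    "sense_level": sense_level[i],
                    "antisense_level": antisense_level[i],
                }
            )
    truth = pd.DataFrame(truth_rows)

    # --- vectorized well and cell sampling -------------------------------
    n_cond, n_constr, n_rep = len(conditions), len(CONSTRUCTS), params.replicates_per_construct
    gi, ci, ki, ri = np.meshgrid(
        np.arange(n_genes), np.arange(n_cond), np.arange(n_constr), np.arange(n_rep),
        indexing="ij",
    )
    gi, ci, ki, ri = (a.ravel() for a in (gi, ci, ki, ri))
    n_wells = gi.size

    expr_gc = 2.0 ** (log2_expr_gene[gi] + cond_mod[gi, ci])
    # antisense present in PHO5_T_scr (k=1) and WT (k=2)
    as_present = ki >= 1
    expr_well = expr_gc * np.where(as_present, 2.0 ** (-eff[gi, ci]), 1.0)
    onoff_idx = np.array([g in onoff for g in genes])
    expr_well = np.where(as_present & onoff_idx[gi], 0.0, expr_well)

    well_factor = 2.0 ** (params.sigma_well * rng.standard_normal(n_wells))

    cpw = params.cells_per_well
    n_cells = n_wells * cpw

    def _background(n):
        return np.clip(
            params.background_mean + params.background_sd * rng.standard_normal(n), 0.0, None
        )

    gfp_sample = np.repeat(well_factor, cpw) * (
        _background(n_cells)
        + np.repeat(expr_well, cpw) * 2.0 ** (params.sigma_cell * rng.standard_normal(n_cells))
    )
    gfp_ref = np.repeat(well_factor, cpw) * _background(n_cells)
    marker_sample = np.clip(40.0 + 8.0 * rng.standard_normal(n_cells), 0.0, None)
    marker_ref = np.clip(4000.0 + 400.0 * rng.standard_normal(n_cells), 0.0, None)

    gene_arr = np.asarray(genes)
    cond_arr = np.asarray(conditions)
    constr_arr = np.asarray(CONSTRUCTS)
    well_gene = gene_arr[gi]
    well_cond = cond_arr[ci]
    well_constr = constr_arr[ki]
    well_rep = ri + 1
    well_id = pd.Series(well_gene).str.cat(
        [well_cond, well_constr, pd.Series(well_rep).astype(str)], sep="|"
    ).to_numpy()

    def _rep(a):
        return np.repeat(a, cpw)

    half = pd.DataFrame(
        {
            "well_id": pd.Categorical(_rep(well_id)),
            "gene_id": pd.Categorical(_rep(well_gene)),
            "construct": pd.Categorical(_rep(well_constr), categories=CONSTRUCTS),
            "condition": pd.Categorical(_rep(well_cond), categories=conditions),
            "replicate": _rep(well_rep).astype(np.int32),
        }
    )
    cells = pd.concat(
        [
            half.assign(
                cell_id=np.tile(np.arange(cpw, dtype=np.int32), n_wells),
                gfp_intensity=gfp_sample,
                marker_intensity=marker_sample,
                is_reference_truth=False,
            ),
            half.assign(
                cell_id=np.tile(np.arange(cpw, 2 * cpw, dtype=np.int32), n_wells),
                gfp_intensity=gfp_ref,
                marker_intensity=marker_ref,
                is_reference_truth=True,
            ),
        ],
        ignore_index=True,
    )
    return cells, truth


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------

def simulate_facs(
    panel: Sequence[GeneAnnotation],
    params: SimParams,
    regulated_gene_ids: Sequence[str],
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate flow-cytometry event tables per gene x construct.

    GFP means follow the planted expression (antisense-present construct
    repressed for regulated genes); CV^2 follows ``noise_a/mean + noise_b``
    times a gene-specific excess shared between constructs.  For regulated
    genes the antisense-present sample's CV^2 excess above the trend is
    scaled by ``denoise_factor``.  FSC/SSC come from one unimodal log-normal
    cloud independent of GFP, so G1 gating is exercised without altering
    the planted GFP law.
    """
    params.validate()
    rng = _spawn(params.seed if seed is None else seed, 2)
    regulated = set(regulated_gene_ids)
    n = params.events_per_sample
    frames = []
    for g in panel:
        log2_e = params.mu_log_expression + params.sigma_expression * rng.standard_normal()
        mean_t = 2.0 ** log2_e
        is_reg = g.gene_id in regulated
        mean_scr = mean_t * 2.0 ** (-params.planted_log2_effect) if is_reg else mean_t
        excess = 10.0 ** abs(params.sigma_noise_excess * rng.standard_normal())
        for construct, mean in (("PHO5_T", mean_t), ("PHO5_T_scr", mean_scr)):
            trend = params.noise_a / mean + params.noise_b
            cv2 = trend * excess
            if is_reg and construct == "PHO5_T_scr":
                cv2 = trend + params.denoise_factor * (cv2 - trend)
            sigma2 = np.log1p(cv2)
            gfp = rng.lognormal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2), size=n)
            z = rng.multivariate_normal(
                [np.log(5e4), np.log(3e4)],
                [[0.09, 0.045], [0.045, 0.0625]],
                size=n,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": pd.Categorical([g.gene_id] * n),
                        "construct": pd.Categorical([construct] * n, categories=CONSTRUCTS),
                        "event_id": np.arange(n, dtype=np.int64),
                        "fsc": np.exp(z[:, 0]),
                        "ssc": np.exp(z[:, 1]),
                        "gfp": gfp,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSet:
    """Genome-binned signal tracks (counts per bin) on one coordinate frame.

    ``signals`` maps (chrom, mark) to a 1D array of per-bin counts; NET-seq
    marks are strand-resolved (``netseq_plus``/``netseq_minus``), histone
    marks are unstranded.
    """

    bin_size: int
    chrom_sizes: dict[str, int]
    signals: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_size)


def _gauss_profile(centers_bp: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((centers_bp - center) / sigma) ** 2)


def simulate_tracks(
    panel: Sequence[GeneAnnotation],
    regulated_gene_ids: Sequence[str],
    params: SimParams,
    seed: int | None = None,
    *,
    bin_size: int = 10,
    peak_amp: float = 40.0,
    peak_sigma: float = 60.0,
    cds_shift: int = 150,
    histone_amp: float = 15.0,
) -> TrackSet:
    """Simulate antisense read-density and histone-mark tracks.

    Antisense density is a smooth peak over the sense TSS for regulated
    genes and shifted ``cds_shift`` bp inside the coding sequence at the
    stop codon for non-regulated genes with annotated antisense.  H3K4me2/3
    are elevated and H3R2me2 depressed at the 3' end of regulated genes.
    Per-bin counts carry Poisson noise.
    """
    params.validate()
    rng = _spawn(params.seed if seed is None else seed, 3)
    regulated = set(regulated_gene_ids)
    chrom_size = max(g.sense_end for g in panel) + 2000
    chroms = sorted({g.chrom for g in panel})
    ts = TrackSet(bin_size=bin_size, chrom_sizes={c: chrom_size for c in chroms})
    for c in chroms:
        nb = ts.n_bins(c)
        for mark in TRACK_MARKS:
            base = 0.2 if mark.startswith("netseq") else 3.0
            ts.signals[(c, mark)] = np.full(nb, base, dtype=float)

    for g in panel:
        centers = (np.arange(ts.n_bins(g.chrom)) + 0.5) * bin_size
        is_reg = g.gene_id in regulated
        as_strand = "-" if g.sense_strand == "+" else "+"
        netseq_mark = "netseq_plus" if as_strand == "+" else "netseq_minus"
        if is_reg:
            center = float(g.sense_tss)
        elif g.category != "NO_AS":
            inward = cds_shift if g.sense_strand == "+" else -cds_shift
            center = float(g.stop_anchor - inward)
        else:
            center = None
        if center is not None:
            ts.signals[(g.chrom, netseq_mark)] += _gauss_profile(
                centers, center, peak_sigma, peak_amp
            )
        # histone marks: elevated gene-body baseline, 3'-end bump for regulated
        body = (centers >= g.sense_start) & (centers < g.sense_end)
        stop_inside = g.stop_anchor + (-50 if g.sense_strand == "+" else 50)
        for mark in ("H3K4me2", "H3K4me3"):
            ts.signals[(g.chrom, mark)][body] += 15.0
            if is_reg:
                ts.signals[(g.chrom, mark)] += _gauss_profile(
                    centers, stop_inside, 100.0, histone_amp
                )
        ts.signals[(g.chrom, "H3R2me2")][body] += 15.0
        if is_reg:
            ts.signals[(g.chrom, "H3R2me2")] -= _gauss_profile(
                centers, stop_inside, 100.0, histone_amp * 0.7
            )

    for key, lam in ts.signals.items():
        ts.signals[key] = rng.poisson(np.clip(lam, 0.0, None)).astype(float)
    return ts


def simulate_nrd1_sites(
    panel: Sequence[GeneAnnotation],
    regulated_gene_ids: Sequence[str],
    seed: int,
    *,
    rate_regulated: float = 0.15,
    rate_nonregulated: float = 0.35,
) -> pd.DataFrame:
    """Plant Nrd1-binding-site intervals (BED-like) in antisense orientation.

    Site counts are Poisson with a per-kb rate that is higher for
    non-regulated genes, emulating the observed (non-significant) trend.
    """
    rng = _spawn(seed, 4)
    regulated = set(regulated_gene_ids)
    rows = []
    for g in panel:
        rate = rate_regulated if g.gene_id in regulated else rate_nonregulated
        n_sites = rng.poisson(rate * g.length / 1000.0)
        strand = "-" if g.sense_strand == "+" else "+"
        for _ in range(n_sites):
            s = int(rng.integers(g.sense_start, g.sense_end - 8))
            rows.append(
                {"chrom": g.chrom, "start": s, "end": s + 8, "name": "nrd1",
                 "score": 0, "strand": strand}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# well images
# ---------------------------------------------------------------------------

@dataclass
class ImageParams:
    shape: tuple[int, int] = (512, 512)
    cell_radius: int = 6
    background: float = 10.0
    camera_noise_sd: float = 2.0
    shading_amplitude: float = 0.1  # 0 disables the smooth shading field


def shading_field(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative shading: brighter centre, dimmer corners.

    Normalized to unit mean — shading fields are only defined up to scale,
    and the quantification step uses the same unit-mean convention.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy / h - 0.5) ** 2 + (xx / w - 0.5) ** 2) / 0.5
    raw = 1.0 + amplitude * (0.5 - r2)
    return raw / raw.mean()


def simulate_well_image(
    well_cells: pd.DataFrame,
    image_params: ImageParams,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one well as a 2-channel image plus ground-truth label mask.

    Cells are non-overlapping disks on a jittered grid; the GFP channel
    integrates each cell's total intensity over its area, modulated by a
    smooth shading field, with Gaussian camera noise; the marker channel is
    bright only for reference cells.  Returns ``(image (2,H,W), labels,
    truth)`` where truth holds each cell's planted totals.
    """
    p = image_params
    rng = _spawn(seed, 5)
    h, w = p.shape
    r = p.cell_radius
    pitch = 2 * r + 5
    ny, nx = (h - 2 * r) // pitch, (w - 2 * r) // pitch
    n_cells = len(well_cells)
    if n_cells > ny * nx:
        raise ValueError(f"too many cells ({n_cells}) for a {h}x{w} frame (capacity {ny * nx})")

    gfp = np.zeros((h, w))
    marker = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    slots = rng.permutation(ny * nx)[:n_cells]
    from skimage.draw import disk as _disk

    truth_rows = []
    for lab, (slot, (_, cell)) in enumerate(zip(slots, well_cells.iterrows()), start=1):
        cy = r + (slot // nx) * pitch + r + int(rng.integers(-2, 3))
        cx = r + (slot % nx) * pitch + r + int(rng.integers(-2, 3))
        rr, cc = _disk((cy, cx), r, shape=(h, w))
        area = rr.size
        gfp[rr, cc] += cell["gfp_intensity"] / area
        marker[rr, cc] += cell["marker_intensity"] / area
        labels[rr, cc] = lab
        truth_rows.append(
            {
                "label": lab,
                "cell_id": cell.get("cell_id", lab),
                "total_gfp": float(cell["gfp_intensity"]),
                "total_marker": float(cell["marker_intensity"]),
                "is_reference": bool(cell.get("is_reference_truth", False)),
                "centroid_y": cy,
                "centroid_x": cx,
            }
        )

    field_arr = shading_field((h, w), p.shading_amplitude)
    image = np.stack(
        [
            field_arr * (p.background + gfp) + p.camera_noise_sd * rng.standard_normal((h, w)),
            p.background + marker + p.camera_noise_sd * rng.standard_normal((h, w)),
        ]
    )
    return image, labels, pd.DataFrame(truth_rows)


def null_params(params: SimParams | None = None, **overrides) -> SimParams:
    """Convenience: parameters with no planted effect anywhere."""
    base = params or SimParams()
    return replace(base, planted_log2_effect=0.0, frac_regulated=0.0,
                   onoff_fraction=0.0, denoise_factor=1.0, **overrides)
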
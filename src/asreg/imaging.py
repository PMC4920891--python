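"""Cell segmentation and fluorescence quantification for 2-channel well
images (GFP + reference marker).

Segmentation is deliberately simple — global Otsu threshold, connected
components, area filter, border removal — adequate for disk-shaped
fixtures; the pipeline also accepts CellTable CSVs directly, so this stage
is bypassable for data quantified elsewhere.  Quantification corrects a
smooth multiplicative shading field (given, or estimated by a quadratic
polynomial fit to background pixels), then reports per-cell totals as the
sum of corrected pixels minus area times a local background (median over a
dilated ring around the cell).  Reference (non-fluorescent) cells are
separated from sample cells by an Otsu split of log marker totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import dilation, disk
from skimage.segmentation import clear_border

DEFAULT_MIN_AREA = 30
DEFAULT_MAX_AREA = 1000
RING_RADIUS = 3


def segment_cells(
    channel: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    max_area: int = DEFAULT_MAX_AREA,
) -> np.ndarray:
    """Label mask from a 2D intensity image.

    Otsu-threshold foreground, connected components, objects outside
    [min_area, max_area] and objects touching the border removed.  A flat
    or empty image yields an empty mask rather than an error.  Labels are
    renumbered to be contiguous.
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if img.size == 0 or np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    # threshold in the log domain: cell brightness spans decades (dim sample
    # cells vs marker-bright reference cells) while background is narrow
    logimg = np.log1p(np.clip(img - img.min(), 0, None))
    fg = logimg > threshold_otsu(logimg)
    labels = clear_border(cc_label(fg))
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for region in regionprops(labels):
        if min_area <= region.area <= max_area:
            out[labels == region.label] = nxt
            nxt += 1
    return out


def estimate_shading(image: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Quadratic-polynomial shading estimate from background pixels,
    normalized to unit mean."""
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    bg = labels == 0
    y = yy[bg].ravel() / h
    x = xx[bg].ravel() / w
    design = np.column_stack([np.ones_like(x), x, y, x * y, x**2, y**2])
    coef, *_ = np.linalg.lstsq(design, image[bg].ravel(), rcond=None)
    ya, xa = yy / h, xx / w
    field = (
        coef[0] + coef[1] * xa + coef[2] * ya + coef[3] * xa * ya
        + coef[4] * xa**2 + coef[5] * ya**2
    )
    return field / field.mean()


def quantify_cells(
    labels: np.ndarray,
    gfp: np.ndarray,
    marker: np.ndarray,
    shading: np.ndarray | str | None = "estimate",
) -> pd.DataFrame:
    """Per-cell records from a label mask and the two channels.

    ``shading`` is a field to divide the GFP channel by, ``"estimate"`` to
    fit one from background pixels, or ``None`` for no correction.  The
    per-cell total is the sum of corrected pixels minus area times the
    local background (median over a ring ``RING_RADIUS`` px outside the
    cell, excluding all cells).
    """
    if labels.shape != gfp.shape or labels.shape != marker.shape:
        raise ValueError("labels and channels must share one shape")
    if isinstance(shading, str):
        if shading != "estimate":
            raise ValueError("shading must be an array, 'estimate', or None")
        field = estimate_shading(gfp, labels)
    elif shading is None:
        field = np.ones_like(gfp, dtype=float)
    else:
        field = np.asarray(shading, dtype=float)
        if field.shape != gfp.shape:
            raise ValueError("shading field shape mismatch")
    gfp_c = gfp / field
    any_cell = labels > 0
    selem = disk(RING_RADIUS)
    rows = []
    for region in regionprops(labels):
        mask = labels == region.label
        ring = dilation(mask, selem) & ~any_cell
        rows.append(
            {
                "label": region.label,
                "area": int(region.area),
                "total_gfp": _masked_total(gfp_c, mask, ring),
                "total_marker": _masked_total(marker, mask, ring),
                "centroid_y": region.centroid[0],
                "centroid_x": region.centroid[1],
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "area", "total_gfp", "total_marker", "centroid_y", "centroid_x"]
    )


def _masked_total(img: np.ndarray, mask: np.ndarray, ring: np.ndarray) -> float:
    local_bg = float(np.median(img[ring])) if ring.any() else 0.0
    return float(img[mask].sum() - mask.sum() * local_bg)


@dataclass(frozen=True)
class ReferenceSplit:
    is_reference: np.ndarray  # bool per record
    threshold: float          # on log10 marker totals
    degenerate: bool          # one population missing / split unreliable


def classify_reference(records: pd.DataFrame, min_separation: float = 1.0) -> ReferenceSplit:
    """Split cells into reference (marker-bright) and sample populations.

    Otsu threshold on log10 marker totals.  If the two classes are not
    separated by at least ``min_separation`` decades between class means
    (or one class is empty), the well is flagged degenerate and every cell
    is assigned to the majority class.
    """
    totals = np.clip(records["total_marker"].to_numpy(dtype=float), 1e-6, None)
    logt = np.log10(totals)
    if np.ptp(logt) == 0 or len(logt) < 2:
        return ReferenceSplit(np.zeros(len(logt), dtype=bool), float("nan"), True)
    thr = float(threshold_otsu(logt))
    hi = logt > thr
    if hi.all() or (~hi).all() or (logt[hi].mean() - logt[~hi].mean()) < min_separation:
        majority_hi = hi.mean() >= 0.5
        return ReferenceSplit(np.full(len(logt), majority_hi), thr, True)
    return ReferenceSplit(hi, thr, False)


def cells_from_image(
    image: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    max_area: int = DEFAULT_MAX_AREA,
    shading: np.ndarray | str | None = "estimate",
) -> pd.DataFrame:
    """Full imaging stage: segment on GFP+marker, quantify, classify.

    Segmentation runs on the sum of both channels so that non-fluorescent
    reference cells are found too.  Returns per-cell records with an
    ``is_reference`` column and a ``degenerate_well`` flag column.
    """
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("expected an image stack of shape (2, H, W)")
    gfp, marker = image[0], image[1]
    labels = segment_cells(gfp + marker, min_area=min_area, max_area=max_area)
    records = quantify_cells(labels, gfp, marker, shading=shading)
    if records.empty:
        records["is_reference"] = pd.Series(dtype=bool)
        records["degenerate_well"] = pd.Series(dtype=bool)
        return records
    split = classify_reference(records)
    records["is_reference"] = split.is_reference
    records["degenerate_well"] = split.degenerate
    return records
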
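"""Format adapters: CSV tables, GFF3/BED12 annotations, bedGraph tracks,
16-bit TIFF well images.

Coordinate conventions are converted at the boundary: internally
everything is 0-based half-open; GFF3 is 1-based closed, BED and bedGraph
are already half-open.  Malformed records raise :class:`SchemaError` with
the offending file, line or column named.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import GeneAnnotation, TrackSet

CELL_COLUMNS = [
    "well_id", "gene_id", "construct", "condition", "replicate",
    "cell_id", "gfp_intensity", "marker_intensity",
]
WELL_COLUMNS = [
    "well_id", "gene_id", "construct", "condition", "replicate",
    "n_sample_cells", "n_reference_cells", "sfgfp_norm",
]
EVENT_COLUMNS = ["gene_id", "construct", "event_id", "fsc", "ssc", "gfp"]


class SchemaError(ValueError):
    """A table or text record does not match the expected schema."""


def require_columns(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")


def read_table(path: str, columns: Sequence[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, columns, name)
    return df


def read_cell_table(path: str) -> pd.DataFrame:
    return read_table(path, CELL_COLUMNS, "CellTable")


def read_well_table(path: str) -> pd.DataFrame:
    return read_table(path, WELL_COLUMNS, "WellSummary")


def read_event_table(path: str) -> pd.DataFrame:
    return read_table(path, EVENT_COLUMNS, "EventTable")


def write_csv(df: pd.DataFrame, path: str) -> str:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# GFF3 / BED12 annotations
# ---------------------------------------------------------------------------

def write_panel_gff3(panel: Sequence[GeneAnnotation], path: str) -> str:
    """Sense transcript and antisense SUT as separate stranded features."""
    lines = ["##gff-version 3"]
    for g in panel:
        attrs = f"ID={g.gene_id};category={g.category};tss={g.sense_tss}"
        lines.append(
            "\t".join(
                [g.chrom, "asreg", "transcript", str(g.sense_start + 1),
                 str(g.sense_end), ".", g.sense_strand, ".", attrs]
            )
        )
        if g.as_start is not None:
            lines.append(
                "\t".join(
                    [g.chrom, "asreg", "ncRNA", str(g.as_start + 1), str(g.as_end),
                     ".", g.as_strand, ".", f"ID={g.gene_id}.as;Parent={g.gene_id}"]
                )
            )
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def _parse_gff_attrs(field: str, path: str, lineno: int) -> dict:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise SchemaError(f"{path}:{lineno}: malformed attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def read_panel_gff3(path: str) -> list[GeneAnnotation]:
    sense, antisense = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise SchemaError(f"{path}:{lineno}: expected 9 GFF3 fields, got {len(parts)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: non-integer coordinates") from None
            a = _parse_gff_attrs(attrs, path, lineno)
            if ftype == "transcript":
                sense[a["ID"]] = (chrom, start0, end0, strand, a)
            elif ftype == "ncRNA":
                antisense[a["ID"].removesuffix(".as")] = (start0, end0, strand)
    panel = []
    for gid, (chrom, s, e, strand, a) in sense.items():
        as_rec = antisense.get(gid)
        panel.append(
            GeneAnnotation(
                gene_id=gid, chrom=chrom, sense_start=s, sense_end=e,
                sense_strand=strand, sense_tss=int(a.get("tss", s if strand == "+" else e - 1)),
                as_start=as_rec[0] if as_rec else None,
                as_end=as_rec[1] if as_rec else None,
                as_strand=as_rec[2] if as_rec else None,
                category=a.get("category", "NO_AS"),
            )
        )
    panel.sort(key=lambda g: g.gene_id)
    return panel


def write_panel_bed12(panel: Sequence[GeneAnnotation], path: str) -> str:
    """One BED12 record per feature; antisense records are named
    ``<gene_id>.as`` and the category travels in the itemRgb-free score-0
    convention via the name."""
    rows = []
    for g in panel:
        rows.append(
            (g.chrom, g.sense_start, g.sense_end, f"{g.gene_id}|{g.category}|{g.sense_tss}",
             0, g.sense_strand, g.sense_start, g.sense_end, "0", 1,
             g.sense_end - g.sense_start, 0)
        )
        if g.as_start is not None:
            rows.append(
                (g.chrom, g.as_start, g.as_end, f"{g.gene_id}.as", 0, g.as_strand,
                 g.as_start, g.as_end, "0", 1, g.as_end - g.as_start, 0)
            )
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path


def read_panel_bed12(path: str) -> list[GeneAnnotation]:
    sense, antisense = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise SchemaError(f"{path}:{lineno}: expected 12 BED fields, got {len(parts)}")
            chrom, start, end, name, _, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: non-integer coordinates") from None
            if name.endswith(".as"):
                antisense[name.removesuffix(".as")] = (s, e, strand)
            else:
                gid, category, tss = name.split("|")
                sense[gid] = (chrom, s, e, strand, category, int(tss))
    panel = []
    for gid, (chrom, s, e, strand, category, tss) in sense.items():
        as_rec = antisense.get(gid)
        panel.append(
            GeneAnnotation(
                gene_id=gid, chrom=chrom, sense_start=s, sense_end=e,
                sense_strand=strand, sense_tss=tss,
                as_start=as_rec[0] if as_rec else None,
                as_end=as_rec[1] if as_rec else None,
                as_strand=as_rec[2] if as_rec else None,
                category=category,
            )
        )
    panel.sort(key=lambda g: g.gene_id)
    return panel


def write_sites_bed(sites: pd.DataFrame, path: str) -> str:
    require_columns(sites, ["chrom", "start", "end", "name", "score", "strand"], "sites BED")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    sites.to_csv(path, sep="\t", header=False, index=False)
    return path


def read_sites_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if df[["start", "end"]].isna().any().any():
        raise SchemaError(f"{path}: malformed BED6 intervals")
    return df


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def write_bedgraph(tracks: TrackSet, out_dir: str) -> dict[str, str]:
    """One 4-column bedGraph per mark; zero bins are omitted."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    by_mark: dict[str, list[tuple[str, np.ndarray]]] = {}
    for (chrom, mark), sig in sorted(tracks.signals.items()):
        by_mark.setdefault(mark, []).append((chrom, sig))
    b = tracks.bin_size
    for mark, entries in by_mark.items():
        path = os.path.join(out_dir, f"{mark}.bedgraph")
        with open(path, "w") as fh:
            for chrom, sig in entries:
                nz = np.flatnonzero(sig != 0)
                for i in nz:
                    fh.write(f"{chrom}\t{i * b}\t{min((i + 1) * b, tracks.chrom_sizes[chrom])}\t{sig[i]:g}\n")
        paths[mark] = path
    return paths


def read_bedgraph(
    paths: dict[str, str], bin_size: int, chrom_sizes: dict[str, int]
) -> TrackSet:
    """Rebuild a binned TrackSet from per-mark bedGraph files.

    Interval signal is distributed over the bins it covers, weighted by
    overlap length, so bin-aligned files round-trip exactly.
    """
    ts = TrackSet(bin_size=bin_size, chrom_sizes=dict(chrom_sizes))
    for mark, path in paths.items():
        arrays = {c: np.zeros(-(-n // bin_size)) for c, n in chrom_sizes.items()}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise SchemaError(f"{path}:{lineno}: expected 4 bedGraph fields")
                chrom, start, end, value = parts
                try:
                    s, e, v = int(start), int(end), float(value)
                except ValueError:
                    raise SchemaError(f"{path}:{lineno}: malformed record") from None
                if chrom not in arrays:
                    raise SchemaError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                arr = arrays[chrom]
                b0, b1 = s // bin_size, -(-e // bin_size)
                for b in range(b0, min(b1, arr.size)):
                    ov = min(e, (b + 1) * bin_size) - max(s, b * bin_size)
                    arr[b] += v * ov / min(bin_size, e - s) if (e - s) < bin_size else v * ov / bin_size
        for chrom, arr in arrays.items():
            ts.signals[(chrom, mark)] = arr
    return ts


# ---------------------------------------------------------------------------
# TIFF images
# ---------------------------------------------------------------------------

def write_well_tiff(image: np.ndarray, path: str) -> str:
    """Store a 2-channel image as 16-bit TIFF (values clipped to uint16)."""
    import tifffile

    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    data = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    return path


def read_well_tiff(path: str) -> np.ndarray:
    import tifffile

    img = tifffile.imread(path).astype(float)
    if img.ndim != 3 or img.shape[0] != 2:
        raise SchemaError(f"{path}: expected a 2-channel image stack")
    return img
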
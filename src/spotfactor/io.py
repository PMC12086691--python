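"""Readers for spatial-transcriptomics bundles.

Handles Matrix Market triplet counts plus barcode/feature lists (plain or
gzipped, either on-disk orientation) and dense delimited tables; spot
position tables in both the header and headerless dialects; and the
scale-factor JSON descriptor.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .core import SpotExpression

__all__ = ["read_expression_bundle", "read_positions", "read_scalefactors"]


def _find_one(d: Path, stems: tuple[str, ...]) -> Path | None:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = d / (stem + suffix)
            if p.exists():
                return p
    return None


def _read_list(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        # feature lists may be multi-column (id, name, type); keep column 0
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _dedupe(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}-{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


def read_expression_bundle(path: str | Path, orientation: str = "auto") -> SpotExpression:
    """Load a count matrix as spots x genes.

    ``path`` is either a bundle directory (matrix.mtx[.gz] + barcodes +
    features lists) or a single dense delimited file (first column barcode,
    header row of gene identifiers).

    Orientation on disk (genes x spots vs spots x genes) is auto-detected by
    matching the list lengths to the matrix axes; pass ``orientation`` of
    ``"spots_by_genes"`` or ``"genes_by_spots"`` to override.
    """
    path = Path(path)
    if path.is_file():
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        values = df.to_numpy(dtype=np.float64)
        return SpotExpression(
            values=values,
            barcodes=[str(b) for b in df.index],
            gene_ids=_dedupe([str(g) for g in df.columns]),
        )

    mtx = _find_one(path, ("matrix.mtx",))
    bc = _find_one(path, ("barcodes.tsv", "barcodes.txt"))
    ft = _find_one(path, ("features.tsv", "genes.tsv", "features.txt"))
    if mtx is None or bc is None or ft is None:
        raise FileNotFoundError(
            f"bundle {path} must contain matrix.mtx[.gz], barcodes and "
            "features lists"
        )
    mat = mmread(str(mtx))
    values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat,
                        dtype=np.float64)
    barcodes = _read_list(bc)
    genes = _read_list(ft)

    nrow, ncol = values.shape
    if orientation == "auto":
        if nrow == len(barcodes) and ncol == len(genes):
            orientation = "spots_by_genes"
        elif nrow == len(genes) and ncol == len(barcodes):
            orientation = "genes_by_spots"
        else:
            raise ValueError(
                f"matrix shape {values.shape} matches neither "
                f"{len(barcodes)} barcodes x {len(genes)} features nor the "
                "transpose"
            )
    if orientation == "genes_by_spots":
        values = values.T
    elif orientation != "spots_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    if values.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {values.shape} inconsistent with {len(barcodes)} "
            f"barcodes and {len(genes)} features"
        )
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return SpotExpression(values=values, barcodes=barcodes, gene_ids=_dedupe(genes))


_POSITION_COLS = ["barcode", "in_tissue", "array_row", "array_col",
                  "pixel_row", "pixel_col"]
_HEADER_ALIASES = {
    "pxl_row_in_fullres": "pixel_row",
    "pxl_col_in_fullres": "pixel_col",
    "pxl_row": "pixel_row",
    "pxl_col": "pixel_col",
}


def read_scalefactors(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_positions(
    path: str | Path,
    scalefactors: dict | str | Path | None = None,
    image_scale: float = 1.0,
    expression_barcodes: list[str] | None = None,
) -> pd.DataFrame:
    """Parse a spot position table into (barcode, in_tissue, array_row,
    array_col, pixel_row, pixel_col) with 0-based pixel coordinates scaled
    to the supplied image's resolution.

    ``image_scale`` multiplies the full-resolution pixel coordinates (and
    the spot diameter from ``scalefactors``) when the image on hand is a
    down-sampled rendition. When ``expression_barcodes`` is given, rows are
    re-ordered to that list; position-only barcodes are dropped with a
    warning, and expression barcodes missing a position are an error.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0]
    has_header = "barcode" in first.lower()
    if has_header:
        df = pd.read_csv(path, sep=None, engine="python")
        df.columns = [_HEADER_ALIASES.get(c.strip().lower(), c.strip().lower())
                      for c in df.columns]
    else:
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        if df.shape[1] != 6:
            raise ValueError(
                f"headerless position table must have 6 columns, got {df.shape[1]}"
            )
        df.columns = _POSITION_COLS
    missing = set(_POSITION_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"position table lacks columns: {sorted(missing)}")
    df = df[_POSITION_COLS].copy()
    df["barcode"] = df["barcode"].astype(str)

    if isinstance(scalefactors, (str, Path)):
        scalefactors = read_scalefactors(scalefactors)
    if scalefactors is not None:
        df.attrs["spot_diameter_px"] = (
            float(scalefactors.get("spot_diameter_fullres", np.nan)) * image_scale
        )
    if image_scale != 1.0:
        df["pixel_row"] = df["pixel_row"] * image_scale
        df["pixel_col"] = df["pixel_col"] * image_scale

    if expression_barcodes is not None:
        expression_barcodes = [str(b) for b in expression_barcodes]
        known = set(df["barcode"])
        absent = [b for b in expression_barcodes if b not in known]
        if absent:
            raise ValueError(
                f"{len(absent)} expression barcode(s) missing from the position "
                f"table: {absent[:10]}"
            )
        extra = known - set(expression_barcodes)
        if extra:
            warnings.warn(
                f"{len(extra)} position barcode(s) absent from the expression "
                "matrix were dropped", UserWarning, stacklevel=2)
        attrs = dict(df.attrs)
        df = df.set_index("barcode").loc[expression_barcodes].reset_index()
        df.attrs.update(attrs)
    return df
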
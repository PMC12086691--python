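"""Synthetic paired expression/image data with planted shared factors.

Spots sit on a square grid split into K = k contiguous rectangular regions;
each region drives one factor of a shared half-normal score matrix, so both
the expression and the image-feature block carry the same latent structure.
Noise is additive Gaussian with a variance set from the requested
signal-to-noise ratio, clipped at zero (a Poisson option is available for
count realism).
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .core import SpotExpression, SpotImageFeatures

__all__ = [
    "SyntheticTruth",
    "simulate_joint_data",
    "simulate_tissue_image",
    "write_visium_like_bundle",
]


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated dataset."""

    W_true: np.ndarray
    H_rna_true: np.ndarray
    H_img_true: np.ndarray
    region_labels: np.ndarray      # per-spot region id in {0..K-1}
    coords: pd.DataFrame           # barcode, array_row, array_col, pixel_row, pixel_col
    snr_requested: dict[str, float]
    snr_empirical: dict[str, float]  # signal var / drawn-noise var, pre-clipping
    seed: int
    spot_diameter_px: int


def _grid_coords(m: int, spot_diameter_px: int, pitch_px: int) -> pd.DataFrame:
    side = int(np.ceil(np.sqrt(m)))
    rows, cols = np.divmod(np.arange(m), side)
    margin = spot_diameter_px  # keep full patches inside the canvas
    return pd.DataFrame(
        {
            "barcode": [f"SPOT-{i:04d}" for i in range(m)],
            "array_row": rows,
            "array_col": cols,
            "pixel_row": margin + rows * pitch_px,
            "pixel_col": margin + cols * pitch_px,
        }
    )


def _noisy_block(rng: np.random.Generator, signal: np.ndarray, snr: float,
                 noise: str) -> tuple[np.ndarray, float]:
    """Add noise at the requested SNR; returns (data, empirical pre-clip SNR)."""
    sig_var = float(signal.var())
    if noise == "poisson":
        Y = rng.poisson(signal).astype(np.float64)
        nv = float((Y - signal).var())
        return Y, sig_var / nv if nv > 0 else np.inf
    if not np.isfinite(snr):
        return signal.copy(), np.inf
    sigma = np.sqrt(sig_var / snr)
    eps = rng.normal(0.0, sigma, size=signal.shape)
    emp = sig_var / float(eps.var())
    return np.maximum(signal + eps, 0.0), emp


def simulate_joint_data(
    m: int = 100,
    n: int = 200,
    f: int = 30,
    k: int = 4,
    snr_rna: float = 10.0,
    snr_img: float = 10.0,
    seed: int = 0,
    spot_diameter_px: int = 9,
    pitch_px: int | None = None,
    noise: str = "gaussian",
) -> tuple[SpotExpression, SpotImageFeatures, SyntheticTruth]:
    """Generate a paired spot x gene / spot x feature dataset of true rank k.

    A pure function of its seed. ``noise`` is ``"gaussian"`` (zero-clipped,
    SNR-controlled) or ``"poisson"``.
    """
    if k > min(m, n, f):
        raise ValueError(f"k={k} must not exceed min(m={m}, n={n}, f={f})")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    pitch = pitch_px if pitch_px is not None else spot_diameter_px + 3
    coords = _grid_coords(m, spot_diameter_px, pitch)

    # contiguous rectangular regions: split the grid row-wise into k bands
    side = int(np.ceil(np.sqrt(m)))
    region = np.minimum(coords["array_row"].to_numpy() * k // side, k - 1)
    if len(np.unique(region)) < k:
        raise ValueError(
            f"m={m} spots cannot host {k} grid regions; increase m"
        )

    W = 0.05 * np.abs(rng.standard_normal((m, k)))
    W[np.arange(m), region] += 1.0 + 0.3 * np.abs(rng.standard_normal(m))
    H_rna = np.abs(rng.standard_normal((k, n)))
    H_img = np.abs(rng.standard_normal((k, f)))

    Y_rna, emp_r = _noisy_block(rng, W @ H_rna, snr_rna, noise)
    Y_img, emp_i = _noisy_block(rng, W @ H_img, snr_img, noise)

    barcodes = coords["barcode"].tolist()
    expr = SpotExpression(
        values=Y_rna, barcodes=barcodes,
        gene_ids=[f"gene_{j:04d}" for j in range(n)],
    )
    feats = SpotImageFeatures(
        values=Y_img, barcodes=barcodes,
        feature_names=[f"feat_{j:03d}" for j in range(f)],
    )
    truth = SyntheticTruth(
        W_true=W, H_rna_true=H_rna, H_img_true=H_img,
        region_labels=region, coords=coords,
        snr_requested={"rna": snr_rna, "img": snr_img},
        snr_empirical={"rna": emp_r, "img": emp_i},
        seed=seed, spot_diameter_px=spot_diameter_px,
    )
    return expr, feats, truth


def _palette(n_regions: int, seed: int) -> np.ndarray:
    """Distinct base colours: evenly spaced hues, seed-jittered."""
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, 1.0)
    cols = []
    for i in range(n_regions):
        h = (offset + i / n_regions) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.65, 0.85)
        cols.append((r * 255, g * 255, b * 255))
    return np.asarray(cols)


def simulate_tissue_image(
    coords: pd.DataFrame,
    region_labels: np.ndarray,
    spot_diameter_px: int = 9,
    palette_seed: int = 0,
    jitter: float = 6.0,
) -> np.ndarray:
    """Paint an 8-bit RGB canvas where each region has a distinct base
    colour (plus per-pixel jitter); every pixel takes the colour of its
    nearest spot's region, so patches from different regions separate
    cleanly by their colour histograms."""
    from scipy.spatial import cKDTree

    rows = coords["pixel_row"].to_numpy()
    cols = coords["pixel_col"].to_numpy()
    region_labels = np.asarray(region_labels)
    h = int(rows.max()) + spot_diameter_px + 1
    w = int(cols.max()) + spot_diameter_px + 1
    if rows.min() < 0 or cols.min() < 0:
        raise ValueError("spot coordinates must be non-negative")

    tree = cKDTree(np.column_stack([rows, cols]))
    py, px = np.mgrid[0:h, 0:w]
    _, nearest = tree.query(np.column_stack([py.ravel(), px.ravel()]))
    pix_region = region_labels[nearest].reshape(h, w)

    palette = _palette(int(region_labels.max()) + 1, palette_seed)
    rng = np.random.default_rng(palette_seed)
    img = palette[pix_region] + rng.normal(0.0, jitter, size=(h, w, 3))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def write_visium_like_bundle(
    out_dir: str | Path,
    expression: SpotExpression,
    image: np.ndarray | None,
    coords: pd.DataFrame,
    spot_diameter_px: float = 9.0,
    overwrite: bool = False,
) -> Path:
    """Write the on-disk bundle the readers consume: Matrix Market counts
    (genes x spots, the feature-major convention), barcode/feature lists, a
    spot-position table, a scale-factor JSON, and the image as PNG."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} exists and is not empty; pass overwrite=True to replace"
        )
    out.mkdir(parents=True, exist_ok=True)

    mat = sparse.csr_matrix(expression.values.T)  # genes x spots on disk
    mmwrite(str(out / "matrix.mtx"), mat)
    (out / "barcodes.tsv").write_text("\n".join(expression.barcodes) + "\n")
    (out / "features.tsv").write_text("\n".join(expression.gene_ids) + "\n")

    spatial = out / "spatial"
    spatial.mkdir(exist_ok=True)
    pos = pd.DataFrame(
        {
            "barcode": coords["barcode"],
            "in_tissue": 1,
            "array_row": coords["array_row"],
            "array_col": coords["array_col"],
            "pxl_row_in_fullres": coords["pixel_row"],
            "pxl_col_in_fullres": coords["pixel_col"],
        }
    )
    pos.to_csv(spatial / "tissue_positions.csv", index=False)
    (spatial / "scalefactors_json.json").write_text(
        json.dumps({"spot_diameter_fullres": spot_diameter_px,
                    "tissue_hires_scalef": 1.0})
    )
    if image is not None:
        from PIL import Image

        Image.fromarray(image).save(out / "image.png")
    return out
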
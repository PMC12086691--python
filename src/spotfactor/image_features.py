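"""Spot-wise multiscale histogram features from an H&E image.

For each spot and each scale, a square patch centred on the spot (side =
scale x spot diameter in pixels) is cut out of the image, and per-channel
pixel-intensity histograms over a fixed number of equal-width bins are
concatenated into one non-negative feature vector. Patches are clipped at
image borders; bin counts then conserve the clipped pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SpotImageFeatures

__all__ = [
    "PatchSpec",
    "FeatureConfig",
    "extract_patch",
    "histogram_features",
    "build_feature_matrix",
    "load_user_features",
    "read_image",
]


@dataclass
class PatchSpec:
    """Geometry of one square patch: centre pixel (row, col), side length."""

    centre_px: tuple[int, int]
    side_px: int
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.side_px < 1:
            raise ValueError(f"side_px must be >= 1, got {self.side_px}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @classmethod
    def from_scale(cls, centre_px: tuple[int, int], scale: float,
                   spot_diameter_px: float) -> "PatchSpec":
        side = max(1, int(round(scale * spot_diameter_px)))
        return cls(centre_px=centre_px, side_px=side, scale=scale)


@dataclass
class FeatureConfig:
    """Histogram feature settings: patch scales (in spot diameters), number
    of equal-width intensity bins per channel, and the intensity range."""

    scales: tuple[float, ...] = (0.5, 1.0, 2.0)
    n_bins: int = 10
    channels: int = 3
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales):
            raise ValueError("all scales must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @property
    def n_features(self) -> int:
        return len(self.scales) * self.channels * self.n_bins

    def feature_names(self) -> list[str]:
        chan = ["R", "G", "B"][: self.channels] + [
            f"ch{c}" for c in range(3, self.channels)
        ]
        return [
            f"scale{s:g}_{chan[c]}_bin{b}"
            for s in self.scales
            for c in range(self.channels)
            for b in range(self.n_bins)
        ]


def read_image(path: str | Path) -> np.ndarray:
    """Load a TIFF or PNG image as an (H, W, 3) uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        from PIL import Image

        img = np.asarray(Image.open(path).convert("RGB"))
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"expected a 3-channel image, got shape {img.shape}")
    return img[:, :, :3]


def extract_patch(image: np.ndarray, spec: PatchSpec,
                  spot_id: str | None = None) -> np.ndarray:
    """Cut the square block around the patch centre, clipping at borders.

    The returned block may be smaller than side_px x side_px near an edge;
    downstream histogram counts use the actual pixel count.
    """
    h, w = image.shape[:2]
    r, c = spec.centre_px
    if not (0 <= r < h and 0 <= c < w):
        who = f" for spot {spot_id!r}" if spot_id else ""
        raise ValueError(
            f"patch centre ({r}, {c}){who} lies outside the {h}x{w} image"
        )
    half = spec.side_px // 2
    r0, r1 = max(0, r - half), min(h, r - half + spec.side_px)
    c0, c1 = max(0, c - half), min(w, c - half + spec.side_px)
    return image[r0:r1, c0:c1]


def histogram_features(block: np.ndarray, n_bins: int = 10,
                       intensity_range: tuple[float, float] = (0.0, 255.0)) -> np.ndarray:
    """Per-channel pixel counts in equal-width intensity bins, concatenated
    channel-major. The last bin is right-closed (numpy histogram convention),
    so counts per channel sum to the block's pixel count."""
    block = np.asarray(block)
    if block.size == 0:
        raise ValueError("empty patch: no pixels to histogram")
    if block.ndim == 2:
        block = block[:, :, None]
    n_channels = block.shape[2]
    out = np.empty(n_channels * n_bins, dtype=np.float64)
    for c in range(n_channels):
        counts, _ = np.histogram(block[:, :, c], bins=n_bins, range=intensity_range)
        out[c * n_bins:(c + 1) * n_bins] = counts
    return out


def build_feature_matrix(
    image: np.ndarray,
    spot_table: pd.DataFrame,
    config: FeatureConfig | None = None,
    spot_diameter_px: float | None = None,
) -> SpotImageFeatures:
    """Histogram features for every spot at every configured scale.

    Parameters
    ----------
    image : (H, W, 3) uint8 array
    spot_table : DataFrame with columns ``barcode``, ``pixel_row``,
        ``pixel_col`` and optionally ``spot_diameter_px`` metadata attached
        via the ``spot_diameter_px`` argument.
    config : FeatureConfig
    spot_diameter_px : spot diameter in image pixels; required unless the
        table carries a ``spot_diameter_px`` attribute.
    """
    if config is None:
        config = FeatureConfig()
    if spot_diameter_px is None:
        spot_diameter_px = spot_table.attrs.get("spot_diameter_px")
    if spot_diameter_px is None:
        raise ValueError("spot_diameter_px is required (no scale-factor descriptor)")
    required = {"barcode", "pixel_row", "pixel_col"}
    missing = required - set(spot_table.columns)
    if missing:
        raise ValueError(f"spot table lacks columns: {sorted(missing)}")

    h, w = image.shape[:2]
    rows = spot_table["pixel_row"].to_numpy()
    cols = spot_table["pixel_col"].to_numpy()
    bad = (rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)
    if bad.any():
        offenders = spot_table.loc[bad, "barcode"].astype(str).tolist()
        raise ValueError(
            f"{len(offenders)} spot centre(s) outside the {h}x{w} image: "
            f"{offenders[:10]}"
        )

    per_scale = config.channels * config.n_bins
    values = np.empty((len(spot_table), config.n_features), dtype=np.float64)
    for i, (r, c) in enumerate(zip(rows, cols)):
        centre = (int(round(r)), int(round(c)))
        for si, scale in enumerate(config.scales):
            spec = PatchSpec.from_scale(centre, scale, spot_diameter_px)
            block = extract_patch(image, spec)
            values[i, si * per_scale:(si + 1) * per_scale] = histogram_features(
                block[:, :, : config.channels], config.n_bins, config.intensity_range
            )
    return SpotImageFeatures(
        values=values,
        barcodes=[str(b) for b in spot_table["barcode"]],
        feature_names=config.feature_names(),
    )


def load_user_features(path: str | Path, barcodes: list[str] | None = None,
                       sep: str | None = None) -> SpotImageFeatures:
    """Read a user-supplied spot x feature table (first column barcode),
    validate non-negativity, and re-order rows to the given barcode order."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     index_col=0)
    df.index = df.index.astype(str)
    values = df.to_numpy(dtype=np.float64)
    neg = values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative feature value at barcode {df.index[i]!r}, "
            f"column {df.columns[j]!r}: {values[i, j]}"
        )
    if barcodes is not None:
        barcodes = [str(b) for b in barcodes]
        missing = [b for b in barcodes if b not in df.index]
        if missing:
            raise ValueError(
                f"{len(missing)} expression barcode(s) missing from the feature "
                f"table: {missing[:10]}"
            )
        df = df.loc[barcodes]
    return SpotImageFeatures(
        values=df.to_numpy(dtype=np.float64),
        barcodes=list(df.index),
        feature_names=[str(c) for c in df.columns],
    )
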
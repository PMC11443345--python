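"""Colorimetric darkness scoring of swab photographs.

A photographed oral swab is reduced to a single *darkness score* on a
0 (white) to 1 (black) scale: crop a square block from the centre of the
image, convert it to grayscale, and take ``1 - mean(pixel)/255``.  The
score proxies how much dark rumen material the swab collected.

Luma is kept in floating point (BT.601 weights) before averaging; no
8-bit rounding is applied, so scoring a flat image of intensity ``v``
returns exactly ``1 - v/255``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights for R, G, B.
BT601_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class SwabImage:
    """Pixel matrix for one photographed swab.

    Parameters
    ----------
    pixels : ndarray
        ``H x W`` (grayscale) or ``H x W x 3`` (RGB) intensities in
        ``[0, 255]``.  Floating-point intensities are allowed so that
        grayscale conversion and synthetic rendering stay exact.
    sample_id : str
        Identifier of the swab the image belongs to.
    """

    pixels: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(
                f"image must be 2-D (gray) or 3-D (RGB); got ndim={self.pixels.ndim}"
            )
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError(
                f"3-D image must have 3 channels; got {self.pixels.shape[2]}"
            )
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
            raise ValueError("pixel intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class DarknessScore:
    """Mean-pixel darkness of a swab image: 0 = white, 1 = black."""

    value: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"darkness must lie in [0, 1]; got {self.value}")


def center_crop(image: SwabImage, size: int = 100) -> SwabImage:
    """Return the ``size x size`` block at the centre of *image*.

    The top-left corner is ``(floor(H/2) - size//2, floor(W/2) - size//2)``,
    which makes the crop deterministic for odd dimensions.
    """
    if image.height < size:
        raise ValueError(
            f"image height {image.height} < crop size {size} (sample "
            f"{image.sample_id!r})"
        )
    if image.width < size:
        raise ValueError(
            f"image width {image.width} < crop size {size} (sample "
            f"{image.sample_id!r})"
        )
    r0 = image.height // 2 - size // 2
    c0 = image.width // 2 - size // 2
    return SwabImage(image.pixels[r0 : r0 + size, c0 : c0 + size], image.sample_id)


def to_grayscale(image: SwabImage) -> SwabImage:
    """Convert RGB to single-channel luma (BT.601); gray input is returned unchanged.

    The luma ``Y = 0.299 R + 0.587 G + 0.114 B`` is kept as float — no
    rounding to 8 bits — so downstream averages are exact.
    """
    if image.n_channels == 1:
        return image
    if image.n_channels != 3:  # defensive; __post_init__ already rejects this
        raise ValueError(f"cannot convert {image.n_channels}-channel image")
    luma = image.pixels.astype(float) @ BT601_WEIGHTS
    return SwabImage(luma, image.sample_id)


def darkness_score(gray: SwabImage) -> DarknessScore:
    """Average pixel darkness of a single-channel image: ``1 - mean/255``."""
    if gray.n_channels != 1:
        raise ValueError("darkness_score requires a single-channel image")
    if gray.pixels.size == 0:
        raise ValueError("cannot score an empty image")
    return DarknessScore(1.0 - float(np.mean(gray.pixels)) / 255.0, gray.sample_id)


def score_image(image: SwabImage, crop_size: int = 100) -> DarknessScore:
    """Crop, grayscale, and score one image in a single call."""
    return darkness_score(to_grayscale(center_crop(image, crop_size)))


def load_image(path: str, sample_id: str = "") -> SwabImage:
    """Read a PNG/JPEG file into a :class:`SwabImage` (RGB or grayscale)."""
    with Image.open(path) as im:
        if im.mode in ("L", "I;16"):
            arr = np.asarray(im.convert("L"))
        else:
            arr = np.asarray(im.convert("RGB"))
    return SwabImage(arr, sample_id)


def score_swab_manifest(manifest: pd.DataFrame, crop_size: int = 100) -> pd.DataFrame:
    """Score every image in a manifest of ``sample_id`` -> ``image_path``.

    Returns a frame with columns ``sample_id``, ``darkness`` and ``error``
    (None on success), preserving manifest row order.  Rows whose image
    cannot be read or scored carry the error message and a NaN score; the
    call raises only if *every* row fails.
    """
    required = {"sample_id", "image_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rows = []
    for rec in manifest.itertuples(index=False):
        try:
            img = load_image(rec.image_path, str(rec.sample_id))
            score = score_image(img, crop_size)
            rows.append((rec.sample_id, score.value, None))
        except Exception as exc:  # noqa: BLE001 - collected per row by contract
            rows.append((rec.sample_id, np.nan, str(exc)))
    out = pd.DataFrame(rows, columns=["sample_id", "darkness", "error"])
    n_fail = out["error"].notna().sum()
    if len(out) == 0:
        logger.warning("empty image manifest: no swabs scored")
    elif n_fail == len(out):
        raise RuntimeError(f"all {n_fail} manifest rows failed to score")
    else:
        ok = out["darkness"].dropna()
        logger.info(
            "scored %d/%d swabs: darkness min=%.4f median=%.4f max=%.4f",
            len(ok), len(out), ok.min(), ok.median(), ok.max(),
        )
    return out


def read_manifest(path: str) -> pd.DataFrame:
    """Read a TSV manifest with columns ``sample_id`` and ``image_path``."""
    return pd.read_csv(path, sep="\t", dtype=str, comment="#")
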
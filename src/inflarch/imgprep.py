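"""Minimal image preprocessing for cyclic immunofluorescence stacks.

Covers the steps needed to get from raw channel images to a per-cell
table: post-bleach subtraction (cyclic staining leaves residual signal
that must be removed before quantification), an optional flat-field
illumination correction, nuclei-seeded watershed segmentation with
membrane-constrained expansion, and per-cell feature extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "ChannelStack",
    "subtract_postbleach",
    "flatfield_correct",
    "segment_cells",
    "extract_features",
]


@dataclass
class ChannelStack:
    """H x W x C intensity array with one named marker per channel."""

    pixels: np.ndarray
    marker_names: list[str]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be H x W x C")
        if self.pixels.shape[2] != len(self.marker_names):
            raise ValueError("marker_names length must match channel count")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names must be unique")
        if np.any(self.pixels < 0):
            raise ValueError("negative intensities; run subtract_postbleach first")

    def channel(self, marker: str) -> np.ndarray:
        return self.pixels[:, :, self.marker_names.index(marker)]

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            np.moveaxis(self.pixels, -1, 0).astype(np.float32),
            photometric="minisblack",
            metadata={"marker_names": self.marker_names},
        )

    @classmethod
    def from_tiff(cls, path) -> "ChannelStack":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            pixels = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        names = list(meta.get("marker_names", [f"ch{i}" for i in range(pixels.shape[0])]))
        return cls(np.moveaxis(pixels, 0, -1).astype(np.float64), names)


def subtract_postbleach(fluor: np.ndarray, postbleach: np.ndarray) -> np.ndarray:
    """Subtract the post-bleaching image from the following fluorescence
    image, clipping at zero (residual signal can exceed the new stain in
    dark areas)."""
    fluor = np.asarray(fluor, dtype=np.float64)
    postbleach = np.asarray(postbleach, dtype=np.float64)
    if fluor.shape != postbleach.shape:
        raise ValueError(f"shape mismatch: {fluor.shape} vs {postbleach.shape}")
    return np.clip(fluor - postbleach, 0.0, None)


def flatfield_correct(image: np.ndarray, sigma: float = 50.0) -> np.ndarray:
    """Divide by a heavily blurred copy of the image (normalised to unit
    mean) to remove smooth illumination gradients."""
    from skimage.filters import gaussian

    image = np.asarray(image, dtype=np.float64)
    flat = gaussian(image, sigma=sigma, preserve_range=True)
    mean = flat.mean()
    if mean <= 0:
        return image.copy()
    flat = np.maximum(flat / mean, 1e-9)
    return image / flat


def segment_cells(
    nuclei: np.ndarray,
    membrane: np.ndarray | None = None,
    min_area_px: int = 5,
    expand_px: int = 2,
    min_distance: int = 4,
) -> np.ndarray:
    """Nuclei-seeded cell segmentation.

    Otsu-thresholds the nuclear channel, removes components below
    ``min_area_px``, splits touching nuclei by watershed on the distance
    transform, then expands every nucleus by ``expand_px`` to approximate
    the cell body.  If a membrane channel is given, expansion is
    restricted to its Otsu foreground (plus the nuclei themselves).  A
    blank nuclear image yields an empty mask, not an error.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from skimage.morphology import remove_small_objects
    from skimage.segmentation import expand_labels, relabel_sequential, watershed

    nuclei = np.asarray(nuclei, dtype=np.float64)
    if membrane is not None and np.asarray(membrane).shape != nuclei.shape:
        raise ValueError("nuclei and membrane images must have the same shape")
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    if nuclei.max() == nuclei.min():
        return np.zeros(nuclei.shape, dtype=np.int32)

    fg = nuclei > threshold_otsu(nuclei)
    fg = remove_small_objects(fg, max_size=min_area_px - 1)
    if not fg.any():
        return np.zeros(nuclei.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(distance, min_distance=min_distance, labels=fg)
    seed_mask = np.zeros(fg.shape, dtype=bool)
    seed_mask[tuple(peaks.T)] = True
    markers, _ = ndi.label(seed_mask)
    if markers.max() == 0:
        markers, _ = ndi.label(fg)
    labels = watershed(-distance, markers, mask=fg)

    expanded = expand_labels(labels, distance=expand_px)
    if membrane is not None:
        membrane = np.asarray(membrane, dtype=np.float64)
        if membrane.max() > membrane.min():
            allowed = fg | (membrane > threshold_otsu(membrane))
            expanded = np.where(allowed, expanded, labels)
    relabeled, _, _ = relabel_sequential(expanded)
    return relabeled.astype(np.int32)


def extract_features(
    mask: np.ndarray,
    stack: ChannelStack | np.ndarray,
    marker_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell centroid, area and mean intensity per marker.

    Returns one row per label with columns
    ``cell_id, x, y, area, <marker...>``; x is the column coordinate,
    y the row coordinate (0-based, origin top-left).
    """
    from skimage.measure import regionprops_table

    if isinstance(stack, ChannelStack):
        pixels, names = stack.pixels, stack.marker_names
    else:
        pixels = np.asarray(stack, dtype=np.float64)
        if pixels.ndim == 2:
            pixels = pixels[:, :, None]
        names = marker_names or [f"ch{i}" for i in range(pixels.shape[2])]
    if pixels.shape[:2] != mask.shape:
        raise ValueError("mask and stack shapes differ")

    props = regionprops_table(
        mask.astype(np.int64),
        intensity_image=pixels,
        properties=("label", "centroid", "area", "intensity_mean"),
    )
    table = pd.DataFrame(
        {
            "cell_id": props["label"],
            "x": props["centroid-1"],
            "y": props["centroid-0"],
            "area": props["area"].astype(float),
        }
    )
    for i, name in enumerate(names):
        table[name] = props[f"intensity_mean-{i}"]
    return table
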
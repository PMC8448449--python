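"""Cell instance segmentation and per-cell feature extraction.

Cells are segmented on the brightfield apartment crop: foreground pixels
are darker than the chamber background, touching cells are split by
watershed seeded at smoothed distance-transform peaks (minimum peak
separation 0.6 expected cell diameters), and detections whose centroid
falls outside the apartment or trap ROI are discarded — debris in the flow
channels never enters the tables.  Per-cell features are mask-moment based:
area in um^2 (pixel count times pixel_size^2), eccentricity from the
second-order central moments, and mean intensity per fluorescence channel
over the mask.  A deterministic classical segmenter stands in for a
learned instance model behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .render import ApartmentTemplate

__all__ = [
    "RoiSpec",
    "CellDetection",
    "segment_cells",
    "cell_features",
    "classify_occupancy",
    "apartment_stain_stats",
    "detections_to_frame",
]

OCCUPANCY_CATEGORIES = ("empty", "singlet", "doublet", "multiplet")


@dataclass(frozen=True)
class RoiSpec:
    """Analysis regions of one apartment crop, (r0, c0, r1, c1) rectangles.

    Detections are kept only when their centroid lies inside the apartment
    or trap ROI; ``exclusion_zones`` (the flow channels) are asserted
    detection-free.
    """

    apartment_roi: tuple[int, int, int, int]
    trap_roi: tuple[int, int, int, int]
    exclusion_zones: tuple[tuple[int, int, int, int], ...] = ()

    @classmethod
    def from_template(cls, template: ApartmentTemplate) -> "RoiSpec":
        return cls(apartment_roi=template.apartment_roi,
                   trap_roi=template.trap_roi,
                   exclusion_zones=template.exclusion_zones)

    def contains(self, row: float, col: float) -> bool:
        for (r0, c0, r1, c1) in (self.apartment_roi, self.trap_roi):
            if r0 <= row < r1 and c0 <= col < c1:
                return True
        return False

    def in_exclusion(self, row: float, col: float) -> bool:
        return any(r0 <= row < r1 and c0 <= col < c1
                   for (r0, c0, r1, c1) in self.exclusion_zones)


@dataclass
class CellDetection:
    """One segmented cell instance."""

    centroid: tuple[float, float]
    area_um2: float
    eccentricity: float
    mask: np.ndarray               # boolean, full crop shape
    channel_means: dict[str, float] = field(default_factory=dict)
    street: int | None = None
    position: int | None = None
    timepoint: float | None = None


def _foreground(image: np.ndarray, min_area_px: int) -> np.ndarray:
    """Dark-object foreground mask with small-object cleanup."""
    bg = np.median(image)
    fg = image < 0.72 * bg
    fg = ndi.binary_closing(fg, structure=np.ones((3, 3)))
    fg = ndi.binary_fill_holes(fg)
    lab, _ = ndi.label(fg)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[lab]


def segment_cells(crop: np.ndarray, roi: RoiSpec, pixel_size: float,
                  channel_images: dict[str, np.ndarray] | None = None,
                  expected_diameter_um: float = 13.2) -> list[CellDetection]:
    """Segment cell instances in a registered apartment crop.

    ``crop`` is the brightfield image (float in [0, 1] or uint16).
    ``channel_images`` optionally maps channel names to aligned images for
    intensity measurement.  An empty list is a valid result.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    img = np.asarray(crop, dtype=float)
    if img.max() > 1.5:
        img = img / 65535.0
    diam_px = expected_diameter_um / pixel_size
    min_area_px = max(9, int(0.15 * np.pi * (diam_px / 2) ** 2))
    fg = _foreground(img, min_area_px)
    if not fg.any():
        return []

    dist = ndi.distance_transform_edt(fg)
    smooth = ndi.gaussian_filter(dist, sigma=2.0)
    min_sep = max(2, int(round(0.6 * diam_px)))
    comp_labels, _ = ndi.label(fg)
    peaks = peak_local_max(smooth, min_distance=min_sep, labels=comp_labels,
                           exclude_border=False)
    if len(peaks) == 0:
        return []
    markers = np.zeros_like(comp_labels)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-smooth, markers=markers, mask=fg)

    detections = []
    for prop in regionprops(labels):
        r, c = prop.centroid
        if not roi.contains(r, c):
            continue
        assert not roi.in_exclusion(r, c), "detection centroid in exclusion zone"
        mask = labels == prop.label
        means = {}
        if channel_images:
            for name, ch in channel_images.items():
                chf = np.asarray(ch, dtype=float)
                if chf.max() > 1.5:
                    chf = chf / 65535.0
                means[name] = float(chf[mask].mean())
        detections.append(CellDetection(
            centroid=(float(r), float(c)),
            area_um2=float(prop.area) * pixel_size ** 2,
            eccentricity=float(prop.eccentricity),
            mask=mask,
            channel_means=means,
        ))
    return detections


def cell_features(mask: np.ndarray, pixel_size: float,
                  channel_images: dict[str, np.ndarray] | None = None) -> dict:
    """Mask-moment features of a single cell mask.

    Area is the pixel count scaled by ``pixel_size**2``; eccentricity comes
    from the second-order central moments of the mask; intensities are the
    mean over the mask per channel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    props = regionprops(mask.astype(int))[0]
    out = {
        "centroid": tuple(float(x) for x in props.centroid),
        "area_um2": float(props.area) * pixel_size ** 2,
        "eccentricity": float(props.eccentricity),
    }
    for name, ch in (channel_images or {}).items():
        out[f"mean_intensity_{name}"] = float(np.asarray(ch, dtype=float)[mask].mean())
    return out


def classify_occupancy(count: int) -> str:
    """0 -> empty, 1 -> singlet, 2 -> doublet, >=3 -> multiplet."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return "empty"
    if count == 1:
        return "singlet"
    if count == 2:
        return "doublet"
    return "multiplet"


def apartment_stain_stats(detections: list[CellDetection], channel: str) -> dict:
    """Per-apartment stain-intensity distribution summary for one channel."""
    if detections and not all(channel in d.channel_means for d in detections):
        raise ValueError(f"unknown channel {channel!r}")
    values = np.array([d.channel_means[channel] for d in detections])
    n = len(values)
    return {
        "n": n,
        "values": values,
        "mean": float(values.mean()) if n else float("nan"),
        "sd": float(values.std(ddof=1)) if n > 1 else 0.0,
        "quantiles": (np.quantile(values, [0.25, 0.5, 0.75]).tolist() if n
                      else [float("nan")] * 3),
    }


def detections_to_frame(detections: list[CellDetection], fov: int | None = None,
                        street: int | None = None, position: int | None = None,
                        timepoint: float | None = None) -> pd.DataFrame:
    """Flatten detections into the canonical export table."""
    rows = []
    for d in detections:
        row = {
            "fov": fov,
            "street": street if street is not None else d.street,
            "position": position if position is not None else d.position,
            "timepoint": timepoint if timepoint is not None else d.timepoint,
            "centroid_row": d.centroid[0],
            "centroid_col": d.centroid[1],
            "area_um2": d.area_um2,
            "eccentricity": d.eccentricity,
        }
        for name, v in d.channel_means.items():
            row[f"mean_intensity_{name}"] = v
        rows.append(row)
    cols = ["fov", "street", "position", "timepoint", "centroid_row",
            "centroid_col", "area_um2", "eccentricity"]
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
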
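"""Synthetic chip-image generator with pixel-exact ground truth.

Renders multi-channel, multi-day fields of view of apartment arrays: each
apartment crop carries a fiducial marker (an etched cross), a
seven-segment-style digit address, the apartment/trap chamber outlines and
the cells themselves, drawn as shaded ellipses with a darker brightfield
rim, a luminous nucleus in the nuclear channel and a perimeter-weighted
ring in the surface-stain channel.  A field of view tiles ~20 apartments;
the whole image receives an optional rigid rotation/translation jitter and
additive Gaussian noise.  Every rendered cell is recorded in a ground-truth
table, which is what makes the downstream extraction and quantification
stages testable without real microscope data.

All geometry (marker offset, digit offsets, ROIs, cell slot grid) lives in
:class:`ApartmentTemplate` and is shared with the extraction stage: fixed
offsets are defined once and changing the template invalidates renderer and
decoder symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

from .glyphs import glyph_bank

__all__ = [
    "ApartmentTemplate",
    "SceneSpec",
    "render_apartment",
    "render_field",
    "render_experiment",
    "placement_slots",
    "place_cells",
]

CHANNELS = ("brightfield", "nuclear", "surface")


@dataclass(frozen=True)
class ApartmentTemplate:
    """Fixed per-apartment geometry, in crop coordinates (row, col).

    The marker centre, digit origins and ROIs are fixed offsets from the
    crop origin; extraction locates the marker and applies the same offsets
    in reverse.
    """

    crop_shape: tuple[int, int] = (170, 124)
    marker_center: tuple[int, int] = (14, 14)
    marker_arm: int = 5                     # cross half-length, px
    marker_thickness: int = 3
    digit_origin: tuple[int, int] = (7, 34)  # top-left of first digit
    digit_scale: int = 2
    digit_pitch: int = 14                   # column spacing between digits
    street_digits: int = 2
    position_digits: int = 2
    apartment_roi: tuple[int, int, int, int] = (40, 12, 165, 112)  # r0,c0,r1,c1
    trap_roi: tuple[int, int, int, int] = (28, 52, 40, 72)
    exclusion_zones: tuple[tuple[int, int, int, int], ...] = ((0, 0, 27, 124),)
    slot_pitch: int = 28
    slot_margin: int = 16

    @property
    def n_digits(self) -> int:
        return self.street_digits + self.position_digits

    def digit_box(self, k: int) -> tuple[int, int, int, int]:
        """Pixel box (r0, c0, r1, c1) of digit slot ``k``."""
        h, w = 7 * self.digit_scale, 5 * self.digit_scale
        r0, c0 = self.digit_origin
        c0 = c0 + k * self.digit_pitch
        return r0, c0, r0 + h, c0 + w

    def marker_mask(self) -> np.ndarray:
        """Binary cross bitmap of the fiducial marker."""
        size = 2 * self.marker_arm + 1
        m = np.zeros((size, size), dtype=bool)
        t = self.marker_thickness // 2
        c = self.marker_arm
        m[c - t:c + t + 1, :] = True
        m[:, c - t:c + t + 1] = True
        return m


@dataclass(frozen=True)
class SceneSpec:
    """Field-of-view layout, optics and noise model.

    ``pixel_size`` is um/px (0.65 at x10 magnification with a typical
    camera).  ``noise_sigma`` is the additive Gaussian sigma per channel as
    a fraction of the dynamic range.  Background/foreground levels are
    relative intensities in [0, 1]; images are written as 16-bit grayscale.
    """

    template: ApartmentTemplate = field(default_factory=ApartmentTemplate)
    fov_rows: int = 2
    fov_cols: int = 10
    pitch: tuple[int, int] = (180, 134)
    margin: tuple[int, int] = (6, 6)
    pixel_size: float = 0.65
    rotation_jitter: float = 0.0            # degrees, CCW positive
    translation_jitter: float = 0.0         # px
    noise_sigma: float = 0.0
    channels: tuple[str, ...] = CHANNELS
    background: float = 0.25                # brightfield background level
    fluor_background: float = 0.02
    wall_level: float = 0.35
    marker_level: float = 0.95
    digit_level: float = 0.85
    cell_interior: float = 0.12
    cell_rim: float = 0.045

    @property
    def apartments_per_fov(self) -> int:
        return self.fov_rows * self.fov_cols

    @property
    def fov_shape(self) -> tuple[int, int]:
        return (self.fov_rows * self.pitch[0] + 2 * self.margin[0],
                self.fov_cols * self.pitch[1] + 2 * self.margin[1])

    def crop_origin(self, slot: int) -> tuple[int, int]:
        r, c = divmod(slot, self.fov_cols)
        return (self.margin[0] + r * self.pitch[0],
                self.margin[1] + c * self.pitch[1])


def placement_slots(template: ApartmentTemplate) -> np.ndarray:
    """Grid of (row, col) cell centres inside the apartment ROI, spaced so
    that neighbouring cells stay separable."""
    r0, c0, r1, c1 = template.apartment_roi
    m, p = template.slot_margin, template.slot_pitch
    rows = np.arange(r0 + m, r1 - m + 1, p)
    cols = np.arange(c0 + m, c1 - m + 1, p)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def place_cells(template: ApartmentTemplate, n_cells: int,
                rng: np.random.Generator, jitter: float = 2.0) -> np.ndarray:
    """Choose jittered slot centres for ``n_cells``; caps at the number of
    available slots (crowded apartments cannot show every cell)."""
    slots = placement_slots(template)
    n = min(int(n_cells), len(slots))
    if n == 0:
        return np.empty((0, 2))
    pick = rng.choice(len(slots), size=n, replace=False)
    pos = slots[pick].astype(float)
    if jitter > 0:
        pos += rng.uniform(-jitter, jitter, size=pos.shape)
    return pos


def _ellipse_fields(shape: tuple[int, int], center: tuple[float, float],
                    a: float, b: float, theta: float) -> np.ndarray:
    """Normalized elliptical radius field (<=1 inside the ellipse)."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = (dc * ct + dr * st) / a
    v = (-dc * st + dr * ct) / b
    return np.sqrt(u * u + v * v)


def _draw_cell(canvas: np.ndarray, scene: SceneSpec, channel: str,
               center: tuple[float, float], area_px: float, ecc: float,
               theta: float, intensity: float) -> None:
    b_over_a = np.sqrt(1.0 - ecc ** 2)
    a = np.sqrt(area_px / (np.pi * b_over_a))
    b = a * b_over_a
    pad = int(np.ceil(a)) + 2
    r0 = max(int(center[0]) - pad, 0)
    c0 = max(int(center[1]) - pad, 0)
    r1 = min(int(center[0]) + pad + 1, canvas.shape[0])
    c1 = min(int(center[1]) + pad + 1, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    rho = _ellipse_fields((r1 - r0, c1 - c0), (center[0] - r0, center[1] - c0), a, b, theta)
    inside = rho <= 1.0
    patch = canvas[r0:r1, c0:c1]
    if channel == "brightfield":
        rim = inside & (rho > 0.72)
        patch[inside] = scene.cell_interior
        patch[rim] = scene.cell_rim
    elif channel == "nuclear":
        nucleus = rho <= 0.55
        patch[nucleus] = intensity
    elif channel == "surface":
        ring = inside & (rho > 0.70)
        patch[ring] = intensity
        body = rho <= 0.70
        patch[body] = np.maximum(patch[body], 0.35 * intensity)
    else:
        raise ValueError(f"unknown channel {channel!r}")


def render_apartment(template: ApartmentTemplate, scene: SceneSpec,
                     street: int, position: int, cells: pd.DataFrame | None,
                     channel: str) -> np.ndarray:
    """Render one apartment crop (float image in [0, 1], no jitter/noise).

    ``cells`` rows need ``row``, ``col``, ``area_px``, ``ecc``, ``theta``
    and ``intensity_<channel>`` columns (fluorescence channels).
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    h, w = template.crop_shape
    bf = channel == "brightfield"
    img = np.full((h, w), scene.background if bf else scene.fluor_background)

    if bf:
        # chamber outlines: apartment + trap ROI walls, one px thick
        for (r0, c0, r1, c1) in (template.apartment_roi, template.trap_roi):
            img[r0, c0:c1] = scene.wall_level
            img[r1 - 1, c0:c1] = scene.wall_level
            img[r0:r1, c0] = scene.wall_level
            img[r0:r1, c1 - 1] = scene.wall_level
        # fiducial marker
        mr, mc = template.marker_center
        mask = template.marker_mask()
        arm = template.marker_arm
        img[mr - arm:mr + arm + 1, mc - arm:mc + arm + 1][mask] = scene.marker_level
        # etched digit address
        digits = (list(map(int, f"{street:0{template.street_digits}d}"))
                  + list(map(int, f"{position:0{template.position_digits}d}")))
        bank = glyph_bank(template.digit_scale)
        for k, d in enumerate(digits):
            r0, c0, r1, c1 = template.digit_box(k)
            glyph = bank[d]
            img[r0:r1, c0:c1] = np.where(glyph > 0, scene.digit_level, img[r0:r1, c0:c1])

    if cells is not None and len(cells):
        for cell in cells.itertuples():
            intensity = getattr(cell, f"intensity_{channel}", 0.6)
            _draw_cell(img, scene, channel, (cell.row, cell.col),
                       cell.area_px, cell.ecc, cell.theta, intensity)
    return img


def _rigid_jitter(img: np.ndarray, angle: float, shift: tuple[float, float],
                  cval: float) -> np.ndarray:
    out = img
    if angle != 0.0:
        out = _sk_rotate(out, angle, resize=False, center=None, order=1,
                         mode="constant", cval=cval, preserve_range=True)
    if shift != (0.0, 0.0):
        dr, dc = shift
        out = np.roll(np.roll(out, int(round(dr)), axis=0), int(round(dc)), axis=1)
    return out


def rotate_point(point: tuple[float, float], shape: tuple[int, int],
                 angle_deg: float) -> tuple[float, float]:
    """Image coordinates of ``point`` after rotating the image CCW by
    ``angle_deg`` about its centre (matching ``skimage.transform.rotate``)."""
    r, c = point
    cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    th = np.deg2rad(angle_deg)
    dr, dc = r - cr, c - cc
    # skimage rotates the image CCW; pixel coordinates rotate CW
    return (cr + dr * np.cos(th) - dc * np.sin(th),
            cc + dr * np.sin(th) + dc * np.cos(th))


def render_field(scene: SceneSpec, apartments: list[dict], channel: str,
                 timepoint: float, seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one field of view.

    ``apartments`` is a list (at most ``apartments_per_fov`` long) of dicts
    with keys ``street``, ``position`` and ``cells`` (a DataFrame as for
    :func:`render_apartment`).  Returns the uint16 image and an annotation
    table holding the post-jitter marker positions and per-cell ground
    truth.
    """
    if len(apartments) > scene.apartments_per_fov:
        raise ValueError("more apartments than field-of-view slots")
    rng = np.random.default_rng(seed)
    h, w = scene.fov_shape
    img = np.full((h, w), scene.background if channel == "brightfield"
                  else scene.fluor_background)
    tmpl = scene.template

    rows = []
    for slot, apt in enumerate(apartments):
        r0, c0 = scene.crop_origin(slot)
        crop = render_apartment(tmpl, scene, apt["street"], apt["position"],
                                apt.get("cells"), channel)
        img[r0:r0 + crop.shape[0], c0:c0 + crop.shape[1]] = crop
        marker = (r0 + tmpl.marker_center[0], c0 + tmpl.marker_center[1])
        rows.append(dict(slot=slot, street=apt["street"], position=apt["position"],
                         crop_row=r0, crop_col=c0,
                         marker_row=marker[0], marker_col=marker[1]))
    ann = pd.DataFrame(rows, columns=["slot", "street", "position", "crop_row",
                                      "crop_col", "marker_row", "marker_col"])

    angle = scene.rotation_jitter
    shift = (0.0, 0.0)
    if scene.translation_jitter > 0:
        shift = tuple(rng.uniform(-scene.translation_jitter,
                                  scene.translation_jitter, size=2))
    cval = scene.background if channel == "brightfield" else scene.fluor_background
    img = _rigid_jitter(img, angle, shift, cval)
    if len(ann):
        pts = [rotate_point((r, c), (h, w), angle)
               for r, c in zip(ann.marker_row, ann.marker_col)]
        ann["marker_row"] = [p[0] + round(shift[0]) for p in pts]
        ann["marker_col"] = [p[1] + round(shift[1]) for p in pts]
    ann["rotation_deg"] = angle
    ann["timepoint"] = timepoint
    ann["channel"] = channel

    if scene.noise_sigma > 0:
        img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return (img * 65535).astype(np.uint16), ann


def cells_table(template: ApartmentTemplate, scene: SceneSpec, clone: pd.Series,
                count: int, rng: np.random.Generator) -> pd.DataFrame:
    """Instantiate per-cell render parameters for one apartment/timepoint."""
    pos = place_cells(template, count, rng)
    n = len(pos)
    area_px = (clone.area_um2 / scene.pixel_size ** 2) * np.exp(
        0.03 * rng.standard_normal(n))
    return pd.DataFrame({
        "row": pos[:, 0], "col": pos[:, 1],
        "area_px": area_px,
        "area_um2": area_px * scene.pixel_size ** 2,
        "ecc": np.clip(clone.ecc + 0.05 * rng.standard_normal(n), 0.0, 0.85),
        "theta": rng.uniform(0, np.pi, size=n),
        "intensity_nuclear": np.clip(
            clone.intensity_nuclear + 0.03 * rng.standard_normal(n), 0.05, 1.0),
        "intensity_surface": np.clip(
            clone.intensity_surface + 0.03 * rng.standard_normal(n), 0.05, 1.0),
    })


def render_experiment(clone_table: pd.DataFrame, scene: SceneSpec,
                      addresses: list[tuple[int, int]] | None = None,
                      timepoints: list[float] | None = None, seed: int = 0,
                      outdir=None) -> dict:
    """Render the full multi-day, multi-channel image bundle.

    ``clone_table`` comes from :func:`trapchip.population.sample_clone_population`
    and must have one row per apartment, aligned with ``addresses`` (one
    ``(street, position)`` per clone; generated row-major over a square-ish
    pseudo-layout when omitted).  Returns a dict with ``images`` (mapping
    ``(fov, timepoint, channel)`` to uint16 arrays — omitted when writing to
    ``outdir``), ``manifest`` (file/fov table), ``annotations`` (marker
    ground truth) and ``cells`` (per-cell ground truth).
    """
    t = list(clone_table.attrs.get("timepoints", [0, 1, 2, 3, 4])
             if timepoints is None else timepoints)
    if sorted(t) != list(t):
        raise ValueError("timepoints must be sorted")
    n_clones = len(clone_table)
    if addresses is None:
        per_street = scene.apartments_per_fov
        addresses = [(i // per_street, i % per_street) for i in range(n_clones)]
    if len(addresses) != n_clones:
        raise ValueError("need exactly one address per clone")

    rng = np.random.default_rng(seed)
    per_fov = scene.apartments_per_fov
    n_fov = int(np.ceil(n_clones / per_fov))
    images = {}
    manifest_rows, ann_frames, cell_frames = [], [], []
    count_cols = [c for c in clone_table.columns if c.startswith("count_t")]

    for ti, day in enumerate(t):
        for fov in range(n_fov):
            lo, hi = fov * per_fov, min((fov + 1) * per_fov, n_clones)
            apartments = []
            placement_rng = np.random.default_rng(
                np.random.SeedSequence([seed, ti, fov]))
            for idx in range(lo, hi):
                clone = clone_table.iloc[idx]
                count = int(clone[count_cols[ti]])
                street, position = addresses[idx]
                cells = cells_table(scene.template, scene, clone, count, placement_rng)
                apartments.append(dict(street=street, position=position, cells=cells))
                rec = cells.copy()
                rec["street"], rec["position"] = street, position
                rec["timepoint"], rec["fov"] = day, fov
                rec["clone_id"] = clone.clone_id
                cell_frames.append(rec)
            for channel in scene.channels:
                img, ann = render_field(
                    scene, apartments, channel, day,
                    seed=int(np.random.SeedSequence([seed, ti, fov, CHANNELS.index(channel)])
                             .generate_state(1)[0] % (2 ** 31)))
                ann["fov"] = fov
                fname = f"fov{fov:03d}_t{ti}_{channel}.tif"
                manifest_rows.append(dict(file=fname, fov=fov, timepoint=day,
                                          channel=channel))
                ann_frames.append(ann)
                if outdir is not None:
                    import tifffile
                    tifffile.imwrite(str(outdir / fname), img)
                else:
                    images[(fov, day, channel)] = img

    result = {
        "manifest": pd.DataFrame(manifest_rows),
        "annotations": pd.concat(ann_frames, ignore_index=True),
        "cells": (pd.concat(cell_frames, ignore_index=True) if cell_frames
                  else pd.DataFrame()),
        "timepoints": t,
        "addresses": addresses,
    }
    if outdir is None:
        result["images"] = images
    return result
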
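"""Field-of-view decomposition: markers, rotation, crops, addresses.

The first stages of the image pipeline: find the fiducial marker of every
apartment by normalized cross-correlation against the marker template,
infer the overall image rotation from the relative positions of markers in
adjacent apartments, invert it, cut registered apartment crops at fixed
offsets from each marker, and decode the etched digit address from fixed
offsets within each crop.  Classical template matching stands in for
learned detectors; the interfaces are detector-agnostic.

Coordinates are 0-based (row, col) with the origin at the top-left; angles
are counter-clockwise positive, reported in (-45, 45].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template, peak_local_max
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _sk_rotate

from .glyphs import glyph_bank
from .render import ApartmentTemplate, SceneSpec, render_apartment, rotate_point

__all__ = [
    "MarkerSet",
    "ApartmentImage",
    "ApartmentAddress",
    "marker_template",
    "detect_markers",
    "estimate_rotation",
    "extract_apartments",
    "decode_address",
]

logger = logging.getLogger(__name__)


@dataclass
class MarkerSet:
    """Detected fiducial centroids (px) with correlation scores."""

    centroids: np.ndarray          # (n, 2) float, (row, col)
    scores: np.ndarray             # (n,)

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class ApartmentImage:
    """One registered apartment crop."""

    pixels: np.ndarray
    fov: int | None
    marker: tuple[float, float]    # marker position in the source image
    rotation_deg: float
    offset: tuple[int, int]        # registration shift applied (row, col)
    origin: tuple[int, int]        # crop origin in the rotated source image


@dataclass
class ApartmentAddress:
    """Decoded (street, position) identifier with per-digit confidence."""

    street: int
    position: int
    raw: str
    confidences: list[float]
    reliable: bool


def marker_template(scene: SceneSpec) -> np.ndarray:
    """The marker appearance patch used for cross-correlation."""
    t = scene.template
    pad = 2
    size = 2 * t.marker_arm + 1 + 2 * pad
    img = np.full((size, size), scene.background)
    mask = t.marker_mask()
    img[pad:pad + mask.shape[0], pad:pad + mask.shape[1]][mask] = scene.marker_level
    return img


def detect_markers(image: np.ndarray, scene: SceneSpec,
                   threshold: float = 0.65) -> MarkerSet:
    """Find all apartment markers in a field of view.

    Normalized cross-correlation against the marker template, peak-picked
    with non-maximum suppression at half the apartment pitch.  An image
    with no detections yields an empty set and a warning, not an error.
    """
    tmpl = marker_template(scene)
    if image.shape[0] < tmpl.shape[0] or image.shape[1] < tmpl.shape[1]:
        raise ValueError("image is smaller than the marker template")
    img = np.asarray(image, dtype=float)
    if img.max() > 1.5:           # uint16 input
        img = img / 65535.0
    corr = match_template(img, tmpl, pad_input=True)
    min_dist = max(2, min(scene.pitch) // 2)
    peaks = peak_local_max(corr, min_distance=min_dist, threshold_abs=threshold,
                           exclude_border=False)
    if len(peaks) == 0:
        warnings.warn("no markers detected in field of view", stacklevel=2)
        return MarkerSet(centroids=np.empty((0, 2)), scores=np.empty(0))
    scores = corr[peaks[:, 0], peaks[:, 1]]
    refined = np.array([_subpixel_peak(corr, r, c) for r, c in peaks])
    order = np.lexsort((refined[:, 1], np.round(refined[:, 0])))
    return MarkerSet(centroids=refined[order], scores=scores[order])


def _subpixel_peak(corr: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Centroid refinement of a correlation peak over its 3x3 neighbourhood."""
    r0, r1 = max(r - 1, 0), min(r + 2, corr.shape[0])
    c0, c1 = max(c - 1, 0), min(c + 2, corr.shape[1])
    win = corr[r0:r1, c0:c1] - corr[r0:r1, c0:c1].min()
    total = win.sum()
    if total <= 0:
        return float(r), float(c)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return float((rr * win).sum() / total), float((cc * win).sum() / total)


def estimate_rotation(markers: MarkerSet, col_pitch: float = 134.0) -> float:
    """Grid angle (degrees, CCW positive) from marker geometry.

    Uses the vectors between horizontally adjacent markers (pair distance
    within [0.5, 1.5] column pitches and inclination below 45 degrees) and
    returns the median angle, which is robust to missed or spurious
    detections.
    """
    pts = markers.centroids
    if len(pts) < 2:
        raise ValueError("at least two markers are required to estimate rotation")

    def _pair_angles(max_sep: float, keep) -> list[float]:
        found = []
        for i in range(len(pts)):
            d = pts - pts[i]
            dist = np.hypot(d[:, 0], d[:, 1])
            near = (dist > 0.5 * col_pitch) & (dist < max_sep)
            for dr, dc in d[near]:
                if abs(dc) < 1e-9:
                    continue
                a = np.degrees(np.arctan2(dr, dc))
                if a > 90:
                    a -= 180
                elif a <= -90:
                    a += 180
                if keep(-a):
                    found.append(-a)  # image CCW rotation tilts rows up-right
        return found

    # pass 1: adjacent markers only (robust, coarse); pass 2: long baselines
    # within 3 degrees of the coarse estimate (precise, rejects cross-row pairs)
    angles = _pair_angles(1.5 * col_pitch, lambda a: abs(a) < 45)
    if angles:
        coarse = float(np.median(angles))
        refined = _pair_angles(np.inf, lambda a: abs(a - coarse) < 3.0)
        if refined:
            angles = refined
    if not angles:
        # two isolated markers: fall back to their direct inclination
        dr = pts[1, 0] - pts[0, 0]
        dc = pts[1, 1] - pts[0, 1]
        a = np.degrees(np.arctan2(dr, dc))
        if a > 90:
            a -= 180
        elif a <= -90:
            a += 180
        return float(-a) if abs(a) <= 45 else 0.0
    return float(np.median(angles))


def extract_apartments(image: np.ndarray, markers: MarkerSet, angle: float,
                       scene: SceneSpec, fov: int | None = None,
                       register: bool = True) -> list[ApartmentImage]:
    """Cut registered apartment crops from a field of view.

    The image is first rotated by ``-angle`` to undo the inferred rotation;
    marker coordinates are mapped through the same transform.  Each crop is
    taken at the fixed marker offset and then registered against an empty
    template rendering by integer-pixel translation (cross-correlation).
    Crops that would exceed the image bounds are skipped with a logged
    warning.
    """
    if len(markers) == 0:
        raise ValueError("marker set is empty")
    t = scene.template
    img = np.asarray(image, dtype=float)
    if img.max() > 1.5:
        img = img / 65535.0
    cval = float(np.median(img))
    if angle != 0.0:
        work = _sk_rotate(img, -angle, resize=False, order=1,
                          mode="constant", cval=cval, preserve_range=True)
    else:
        work = img
    ref = render_apartment(t, scene, 0, 0, None, "brightfield")
    h, w = t.crop_shape
    out = []
    for (mr, mc) in markers.centroids:
        rr, rc = rotate_point((mr, mc), img.shape, -angle)
        r0 = int(round(rr)) - t.marker_center[0]
        c0 = int(round(rc)) - t.marker_center[1]
        shift = (0, 0)
        crop = _take(work, r0, c0, h, w)
        if crop is None:
            logger.warning("apartment crop at marker (%.0f, %.0f) exceeds image "
                           "bounds; skipped", mr, mc)
            continue
        if register:
            est, _, _ = phase_cross_correlation(ref, crop, normalization=None)
            dr, dc = int(round(est[0])), int(round(est[1]))
            if dr or dc:
                shifted = _take(work, r0 - dr, c0 - dc, h, w)
                if shifted is not None:
                    crop = shifted
                    r0, c0 = r0 - dr, c0 - dc
                    shift = (dr, dc)
        out.append(ApartmentImage(pixels=crop, fov=fov, marker=(float(mr), float(mc)),
                                  rotation_deg=float(angle), offset=shift,
                                  origin=(r0, c0)))
    return out


def _take(img: np.ndarray, r0: int, c0: int, h: int, w: int) -> np.ndarray | None:
    if r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
        return None
    return img[r0:r0 + h, c0:c0 + w]


def _match_digit(patch: np.ndarray, bank: list[np.ndarray]) -> tuple[int, float]:
    """Best-matching digit and the margin between the top two scores."""
    p = patch - patch.mean()
    norm = np.linalg.norm(p)
    if norm < 1e-12:
        return 0, 0.0
    p = p / norm
    scores = []
    for glyph in bank:
        g = glyph - glyph.mean()
        g = g / np.linalg.norm(g)
        scores.append(float((p * g).sum()))
    order = np.argsort(scores)[::-1]
    margin = scores[order[0]] - scores[order[1]]
    return int(order[0]), margin


def decode_address(ap: ApartmentImage | np.ndarray, template: ApartmentTemplate,
                   confidence_threshold: float = 0.1,
                   layout=None) -> ApartmentAddress:
    """Read the etched digit address of a registered apartment crop.

    Each digit ROI sits at a fixed offset from the crop origin and is
    matched against the shared glyph bank by normalized correlation;
    per-digit confidence is the margin between the best and second-best
    match.  Addresses with any digit below the confidence threshold (or
    outside the layout bounds, when a layout is supplied) are flagged
    unreliable but still returned.
    """
    pixels = ap.pixels if isinstance(ap, ApartmentImage) else np.asarray(ap, dtype=float)
    bank = glyph_bank(template.digit_scale)
    digits, confs = [], []
    for k in range(template.n_digits):
        r0, c0, r1, c1 = template.digit_box(k)
        patch = pixels[r0:r1, c0:c1]
        d, conf = _match_digit(patch, bank)
        digits.append(d)
        confs.append(conf)
    raw = "".join(str(d) for d in digits)
    street = int(raw[:template.street_digits])
    position = int(raw[template.street_digits:])
    reliable = all(c >= confidence_threshold for c in confs)
    if layout is not None:
        if not (0 <= street < layout.n_streets
                and 0 <= position < layout.apartments_per_street):
            reliable = False
    return ApartmentAddress(street=street, position=position, raw=raw,
                            confidences=confs, reliable=reliable)
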
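"""Object masks and the scalar image-feature vocabulary used for gating.

Reimplements, from their textual definitions, the per-event features an
imaging-flow-cytometry analysis gates on: mask geometry (area, aspect
ratio, circularity), photometry (background-subtracted intensity, max
pixel, std dev, compactness), focus metrics (gradient RMS, contrast),
mask-restricted gray-level co-occurrence (Haralick) textures, and the
bright-detail similarity colocalization score. Absolute feature scales are
not calibrated to any commercial implementation; scale-dependent cut-offs
are meant to be recalibrated on synthetic data (see `lipogate.gating`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

from .events import ImageEvent, Mask

__all__ = [
    "EmptyMaskError",
    "FeatureConfig",
    "object_mask",
    "geometry_features",
    "intensity_features",
    "haralick_features",
    "bright_detail_similarity_r3",
    "molecules_in_sphere",
    "extract_features",
    "build_feature_table",
]

AVOGADRO = 6.02214076e23

#: GLCM pixel-pair offsets (row, col): right, down, down-right, down-left.
GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


class EmptyMaskError(ValueError):
    """Raised when a feature is requested for an empty mask."""


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the feature-extraction stage.

    mask_channel : channel used to derive the object mask.
    channels : channels for which photometric/texture features are emitted,
        suffixed ``_<channel>`` in the output table.
    bds_pairs : channel pairs scored with bright-detail similarity R3.
    """

    mask_channel: str = "membrane"
    channels: tuple[str, ...] = ("membrane", "reporter")
    bds_pairs: tuple[tuple[str, str], ...] = (("membrane", "reporter"),)
    glcm_levels: int = 32
    glcm_granularity: int = 2
    closing_radius: int = 2
    dilation_radius: int = 2
    circularity_cap: float = 100.0


# ---------------------------------------------------------------------------
# mask
# ---------------------------------------------------------------------------


def object_mask(
    event: ImageEvent, channel: str = "membrane", config: FeatureConfig | None = None
) -> Mask:
    """Segment the event: Otsu threshold, largest component, closing, hole
    filling (so the dark lumen inside a membrane ring is included) and a
    final dilation so the mask encompasses both lumen and membrane.

    Raises
    ------
    EmptyMaskError
        If no above-threshold pixels remain (event is later discarded).
    """
    cfg = config or FeatureConfig()
    img = event.channel(channel)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise EmptyMaskError(f"event {event.event_id}: constant {channel} tile")
    # Otsu alone misbehaves on these tiles: it splits background noise when
    # the object is dim, and it crops dim membrane away when a bright
    # internal structure dominates the histogram. Bound it by robust
    # background statistics (median + k*MAD over the tile).
    med = float(np.median(img))
    sigma = 1.4826 * float(np.median(np.abs(img - med)))
    # MAD collapses on noiseless tiles; keep a floor tied to dynamic range
    sigma = max(sigma, 0.02 * (float(np.percentile(img, 99.5)) - med), 1e-6)
    floor = med + 4.0 * sigma
    ceil = med + 12.0 * sigma
    thr = float(np.clip(threshold_otsu(img), floor, max(ceil, floor)))
    fg = img > thr
    if not fg.any():
        raise EmptyMaskError(f"event {event.event_id}: nothing above threshold")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    if cfg.closing_radius > 0:
        fg = ndimage.binary_closing(
            fg, structure=disk(cfg.closing_radius), border_value=0
        )
    fg = ndimage.binary_fill_holes(fg)
    if cfg.dilation_radius > 0:
        fg = ndimage.binary_dilation(fg, structure=disk(cfg.dilation_radius))
    if not fg.any():
        raise EmptyMaskError(
            f"event {event.event_id}: mask vanished during morphology"
        )
    return Mask(region=fg, source_channel=channel)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def geometry_features(mask: Mask, pixel_size: float, *, circularity_cap: float = 100.0
                      ) -> dict[str, float]:
    """Mask-only shape descriptors.

    area
        pixel count x pixel_size^2 (um^2).
    diameter
        equivalent-circle diameter 2*sqrt(area/pi) (um).
    aspect_ratio
        minor/major axis ratio of the second-moment ellipse of the mask
        (1 for a circle, lower for oblong objects).
    circularity
        mean boundary-to-centroid distance divided by its standard
        deviation; higher means rounder. Capped when the sd collapses.
    """
    if mask.is_empty:
        raise EmptyMaskError("geometry of empty mask is undefined")
    region = mask.region
    n = mask.n_pixels
    area = n * pixel_size**2
    ys, xs = np.nonzero(region)
    cy, cx = ys.mean(), xs.mean()
    dy, dx = ys - cy, xs - cx
    # second central moments -> ellipse axes
    myy, mxx, mxy = (dy**2).mean(), (dx**2).mean(), (dx * dy).mean()
    common = math.sqrt(max((myy - mxx) ** 2 + 4 * mxy**2, 0.0))
    l1 = (myy + mxx + common) / 2
    l2 = (myy + mxx - common) / 2
    aspect = math.sqrt(max(l2, 0.0) / l1) if l1 > 0 else 1.0

    boundary = region & ~ndimage.binary_erosion(region, border_value=0)
    by, bx = np.nonzero(boundary)
    dist = np.hypot(by - cy, bx - cx)
    mean_d = float(dist.mean())
    sd_d = float(dist.std())
    if sd_d < mean_d / circularity_cap or sd_d == 0:
        circ = circularity_cap
    else:
        circ = min(mean_d / sd_d, circularity_cap)
    return {
        "area": float(area),
        "diameter": float(2 * math.sqrt(area / math.pi)),
        "aspect_ratio": float(min(aspect, 1.0)),
        "circularity": float(circ),
    }


# ---------------------------------------------------------------------------
# photometry and focus
# ---------------------------------------------------------------------------


def estimate_background(img: np.ndarray, mask: Mask, margin: int = 3) -> float:
    """Median intensity outside the dilated mask (robust to neighbours)."""
    outside = ~ndimage.binary_dilation(mask.region, structure=disk(margin))
    if not outside.any():
        return 0.0
    return float(np.median(img[outside]))


def intensity_features(
    event: ImageEvent, mask: Mask, channel: str
) -> dict[str, float]:
    """Photometric and sharpness features within the mask.

    intensity
        background-subtracted summed intensity (floored at 0).
    max_pixel
        largest background-subtracted pixel value.
    std_dev
        standard deviation of the raw mask pixels.
    gradient_rms
        RMS Sobel gradient magnitude over the mask, normalized by the mean
        mask intensity, x100 — an image-sharpness/focus metric.
    contrast
        RMS 3x3 Laplacian magnitude over the mask, normalized the same way.
    compactness
        r_eq / r_gyr, the equivalent-circle radius over the
        intensity-weighted radius of gyration; higher = more condensed.
    """
    if mask.is_empty:
        raise EmptyMaskError("intensity features of empty mask are undefined")
    img = event.channel(channel)
    region = mask.region
    bg = estimate_background(img, mask)
    sub = img - bg
    vals = img[region]
    sub_vals = sub[region]

    mean_raw = float(vals.mean())
    gx = ndimage.sobel(img, axis=0)
    gy = ndimage.sobel(img, axis=1)
    gmag2 = gx**2 + gy**2
    grad_rms = math.sqrt(float(gmag2[region].mean()))
    lap = ndimage.laplace(img)
    lap_rms = math.sqrt(float((lap**2)[region].mean()))
    norm = mean_raw if mean_raw > 0 else np.nan

    w = np.clip(sub, 0.0, None) * region
    wsum = float(w.sum())
    if wsum > 0:
        ys, xs = np.indices(img.shape)
        cy = float((w * ys).sum() / wsum)
        cx = float((w * xs).sum() / wsum)
        r_gyr = math.sqrt(float((w * ((ys - cy) ** 2 + (xs - cx) ** 2)).sum() / wsum))
    else:
        r_gyr = 0.0
    r_eq = math.sqrt(mask.n_pixels / math.pi)
    compactness = r_eq / r_gyr if r_gyr > 0 else np.nan

    return {
        "intensity": float(max(sub_vals.sum(), 0.0)),
        "max_pixel": float(sub_vals.max()),
        "std_dev": float(vals.std()),
        "gradient_rms": float(100.0 * grad_rms / norm) if norm == norm else np.nan,
        "contrast": float(100.0 * lap_rms / norm) if norm == norm else np.nan,
        "compactness": float(compactness),
    }


# ---------------------------------------------------------------------------
# Haralick textures on a mask-restricted GLCM
# ---------------------------------------------------------------------------


def quantize(img: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantize the mask pixels to ``levels`` gray levels."""
    vals = img[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.intp)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def _glcm(q: np.ndarray, mask: np.ndarray, offset: tuple[int, int], levels: int
          ) -> np.ndarray | None:
    """Symmetric, normalized co-occurrence matrix for one offset, counting
    only pixel pairs that both lie inside the mask. None if no valid pair."""
    dr, dc = offset
    n0, n1 = q.shape
    r0s, r0e = max(0, -dr), min(n0, n0 - dr)
    c0s, c0e = max(0, -dc), min(n1, n1 - dc)
    if r0s >= r0e or c0s >= c0e:
        return None
    src = np.s_[r0s:r0e, c0s:c0e]
    dst = np.s_[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = mask[src] & mask[dst]
    if not valid.any():
        return None
    a = q[src][valid]
    b = q[dst][valid]
    counts = np.bincount(a * levels + b, minlength=levels * levels)
    mat = counts.reshape(levels, levels).astype(float)
    mat = mat + mat.T
    return mat / mat.sum()


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    i = np.arange(levels, dtype=float)
    diff = np.abs(i[:, None] - i[None, :])
    homogeneity = float((p / (1.0 + diff)).sum())
    contrast = float((p * diff**2).sum())
    pos = p[p > 0]
    entropy = float(-(pos * np.log(pos)).sum())
    pi = p.sum(axis=1)  # symmetric: marginals equal
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    if var > 0:
        corr = float(((i[:, None] - mu) * (i[None, :] - mu) * p).sum() / var)
    else:
        corr = 0.0  # constant texture: correlation defined as 0 by convention
    return {
        "homogeneity": homogeneity,
        "correlation": corr,
        "entropy": entropy,
        "contrast": contrast,
    }


def haralick_features(
    event: ImageEvent,
    mask: Mask,
    channel: str,
    *,
    levels: int = 32,
    granularity: int = 1,
) -> dict[str, float]:
    """Mean and std over the four GLCM offsets of homogeneity, correlation,
    entropy and contrast, computed on co-occurrences of mask pixels only.

    The image is min-max quantized to ``levels`` gray levels inside the
    mask; ``granularity`` scales the pair offsets in pixels.
    """
    if mask.n_pixels < 2:
        raise EmptyMaskError("haralick features need >= 2 mask pixels")
    img = event.channel(channel)
    q = quantize(img, mask.region, levels)
    per_offset: dict[str, list[float]] = {
        "homogeneity": [], "correlation": [], "entropy": [], "contrast": []
    }
    for dr, dc in GLCM_OFFSETS:
        p = _glcm(q, mask.region, (dr * granularity, dc * granularity), levels)
        if p is None:
            continue
        stats = _glcm_stats(p)
        for k, v in stats.items():
            per_offset[k].append(v)
    if not per_offset["homogeneity"]:
        raise EmptyMaskError("no valid pixel pair for any GLCM offset")
    out = {}
    for k, vals in per_offset.items():
        arr = np.array(vals)
        out[f"h_{k}_mean"] = float(arr.mean())
        out[f"h_{k}_std"] = float(arr.std())
    return out


# ---------------------------------------------------------------------------
# bright-detail similarity
# ---------------------------------------------------------------------------


def _bright_detail(img: np.ndarray, radius: int = 3) -> np.ndarray:
    """Small-bright-structure residue: image minus its morphological opening
    with a disk of the given radius, floored at 0."""
    return np.clip(img - opening(img, disk(radius)), 0.0, None)


def bright_detail_similarity_r3(
    event: ImageEvent,
    mask: Mask,
    channel_a: str,
    channel_b: str,
    *,
    radius: int = 3,
    eps: float = 1e-6,
) -> float:
    """Colocalization score of small bright structures in two channels.

    The bright-detail residue of each channel (opening with a disk of
    3 px radius) is correlated over the mask; the Pearson coefficient rho
    is reported as -log10(1 - min(rho, 1 - eps)), floored at 0 for
    rho <= 0. Zero-variance residues score 0 by convention.
    """
    if mask.is_empty:
        raise EmptyMaskError("bright-detail similarity of empty mask is undefined")
    a = _bright_detail(event.channel(channel_a), radius)[mask.region]
    b = _bright_detail(event.channel(channel_b), radius)[mask.region]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    rho = float(np.corrcoef(a, b)[0, 1])
    if rho <= 0:
        return 0.0
    return float(-math.log10(1.0 - min(rho, 1.0 - eps)))


# ---------------------------------------------------------------------------
# worked unit conversion
# ---------------------------------------------------------------------------


def molecules_in_sphere(concentration_molar: float, diameter_um: float) -> float:
    """Number of molecules at a molar concentration inside a sphere.

    ``concentration [mol/L] x (pi/6) d^3 [um^3 -> L] x N_A``; e.g. 500 nM in
    a 4 um liposome is about 1e4 molecules, the practical detection limit
    for a freely diffusing fluorescent reporter in the lumen.
    """
    if concentration_molar < 0:
        raise ValueError("concentration must be >= 0")
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    volume_l = (math.pi / 6.0) * diameter_um**3 * 1e-15
    return concentration_molar * volume_l * AVOGADRO


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def extract_features(
    event: ImageEvent, config: FeatureConfig | None = None
) -> dict[str, float]:
    """All configured features for one event as a flat name -> value dict.

    Channel-specific features are suffixed ``_<channel>``. Events whose
    mask is empty yield NaN features and ``mask_ok = 0`` — they are
    flagged, never dropped silently.
    """
    cfg = config or FeatureConfig()
    for ch in cfg.channels:
        if ch not in event.channels:
            raise KeyError(f"configured channel {ch!r} missing from event")
    row: dict[str, float] = {"mask_ok": 1.0}
    try:
        mask = object_mask(event, cfg.mask_channel, cfg)
        row.update(geometry_features(mask, event.pixel_size,
                                     circularity_cap=cfg.circularity_cap))
        for ch in cfg.channels:
            ints = intensity_features(event, mask, ch)
            har = haralick_features(
                event, mask, ch,
                levels=cfg.glcm_levels, granularity=cfg.glcm_granularity,
            )
            for k, v in {**ints, **har}.items():
                row[f"{k}_{ch}"] = v
        for ch_a, ch_b in cfg.bds_pairs:
            row[f"bds_r3_{ch_a}_{ch_b}"] = bright_detail_similarity_r3(
                event, mask, ch_a, ch_b
            )
    except EmptyMaskError:
        row["mask_ok"] = 0.0
    return row


def build_feature_table(
    events, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature table over an iterable of events, one row per event_id.

    Column order is stable across runs; missing features (empty masks)
    are NaN with ``mask_ok = 0``.
    """
    cfg = config or FeatureConfig()
    rows = {}
    for ev in events:
        rows[ev.event_id] = extract_features(ev, cfg)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "event_id"
    ordered = _column_order(cfg)
    cols = [c for c in ordered if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    return table.reindex(columns=cols)


def _column_order(cfg: FeatureConfig) -> list[str]:
    cols = ["mask_ok", "area", "diameter", "aspect_ratio", "circularity"]
    per_channel = [
        "intensity", "max_pixel", "std_dev", "gradient_rms", "contrast",
        "compactness",
        "h_homogeneity_mean", "h_homogeneity_std",
        "h_correlation_mean", "h_correlation_std",
        "h_entropy_mean", "h_entropy_std",
        "h_contrast_mean", "h_contrast_std",
    ]
    for ch in cfg.channels:
        cols += [f"{k}_{ch}" for k in per_channel]
    cols += [f"bds_r3_{a}_{b}" for a, b in cfg.bds_pairs]
    return cols
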
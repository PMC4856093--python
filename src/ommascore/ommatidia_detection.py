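"""Isolating ommatidia as bright blobs and localizing their centers.

Both modalities are first normalized to bright-center polarity (bright-field
reflection spots are already bright; SEM images are inverted so the dark
ommatidial centers become bright).  Inside the eye mask the image is contrast
stretched, top-hat filtered to lift blobs off the residual background, median
filtered to kill boundary reflections, and sharpened by dilation/erosion
rounds; centers are then the local intensity maxima, with a minimum-separation
rule so one ommatidium yields one center.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import morphology
from skimage.filters import rank

from .eye_localization import EyeMask, white_tophat_disk
from .image_io import GrayImage, Modality, invert


@dataclass(frozen=True)
class DetectionConfig:
    """Blob-enhancement and maxima-search parameters.

    ``min_separation=None`` selects the adaptive rule: half the lattice
    spacing, with the spacing estimated as the median nearest-neighbor
    distance of a provisional maxima pass.  That keeps detection usable
    across magnifications without retuning.
    """

    median_radius: int = 2
    se_radius_blob: int = 4
    n_morph_iterations: int = 1
    min_separation: float | None = None
    maxima_rel_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.median_radius < 1 or self.se_radius_blob < 1:
            raise ValueError("filter radii must be >= 1")
        if self.n_morph_iterations < 0:
            raise ValueError("n_morph_iterations must be >= 0")
        if self.min_separation is not None and self.min_separation < 2:
            raise ValueError("min_separation must be >= 2 px")
        if not 0.0 < self.maxima_rel_threshold < 1.0:
            raise ValueError("maxima_rel_threshold must lie in (0, 1)")

    def scaled(self, factor: float) -> "DetectionConfig":
        """Rescale pixel-valued parameters for a different magnification."""
        return replace(
            self,
            median_radius=max(1, round(self.median_radius * factor)),
            se_radius_blob=max(1, round(self.se_radius_blob * factor)),
            min_separation=(
                None if self.min_separation is None
                else max(2.0, self.min_separation * factor)
            ),
        )


@dataclass(frozen=True)
class CenterSet:
    """Detected ommatidial centers; ``Z`` (the count) is the fusion index."""

    points: np.ndarray  # (Z, 2) float array of (row, col)
    source_mask: EyeMask | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        object.__setattr__(self, "points", pts)

    @property
    def Z(self) -> int:
        return int(self.points.shape[0])


def enhance_blobs(img: GrayImage, mask: EyeMask, cfg: DetectionConfig | None = None) -> GrayImage:
    """Contrast-stretch, top-hat, median-filter and sharpen inside the mask.

    Input must already be in bright-center polarity.  Everything outside the
    mask is zeroed.
    """
    cfg = cfg or DetectionConfig()
    m = mask.mask
    if not m.any():
        raise ValueError("empty eye mask")

    f = img.pixels.astype(np.float64)
    lo = f[m].min()
    hi = f[m].max()
    if hi > lo:
        stretched = np.clip((f - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    else:
        stretched = np.zeros_like(f)
    work = np.where(m, stretched, 0.0).astype(np.uint8)

    work = white_tophat_disk(work, cfg.se_radius_blob)
    # histogram-based rank median: O(1) per pixel, radius-independent
    work = rank.median(work, footprint=morphology.disk(cfg.median_radius))
    se1 = morphology.disk(1)
    for _ in range(cfg.n_morph_iterations):
        work = morphology.dilation(work, footprint=se1)
        work = morphology.erosion(work, footprint=se1)
    work = np.where(m, work, 0).astype(np.uint8)
    return GrayImage(pixels=work, modality=img.modality)


def _plateau_maxima(px: np.ndarray, mask: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """All plateau local maxima (8-connectivity) above ``threshold`` inside the
    mask, as (points, intensities); each plateau contributes its centroid
    rounded to the nearest pixel."""
    peaks = morphology.local_maxima(px, connectivity=2, allow_borders=True)
    peaks &= mask & (px >= threshold)
    labels, n = ndi.label(peaks, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    idx = np.arange(1, n + 1)
    cents = np.asarray(ndi.center_of_mass(peaks, labels, index=idx), dtype=np.float64)
    vals = ndi.maximum(px, labels, index=idx).astype(np.float64)
    pts = np.floor(cents + 0.5)
    # a rounded plateau centroid can fall off the mask for contorted plateaus;
    # snap such points to the nearest pixel of their own plateau
    for k in range(len(pts)):
        r, c = int(pts[k, 0]), int(pts[k, 1])
        if not (0 <= r < px.shape[0] and 0 <= c < px.shape[1]) or not mask[r, c]:
            rr, cc = np.nonzero(labels == idx[k])
            j = np.argmin((rr - cents[k, 0]) ** 2 + (cc - cents[k, 1]) ** 2)
            pts[k] = (rr[j], cc[j])
    return pts, vals


def _greedy_suppress(pts: np.ndarray, vals: np.ndarray, min_sep: float) -> np.ndarray:
    """Keep maxima in decreasing-intensity order (ties: row-major), dropping
    any candidate within ``min_sep`` of an already-kept center."""
    order = np.lexsort((pts[:, 1], pts[:, 0], -vals))
    kept: list[int] = []
    kept_pts = np.empty((len(pts), 2))
    n_kept = 0
    min_sep2 = min_sep * min_sep
    for i in order:
        p = pts[i]
        if n_kept:
            d2 = ((kept_pts[:n_kept] - p) ** 2).sum(axis=1)
            if d2.min() < min_sep2:
                continue
        kept.append(i)
        kept_pts[n_kept] = p
        n_kept += 1
    return np.array(sorted(kept), dtype=int)


def find_local_maxima(img: GrayImage, mask: EyeMask, cfg: DetectionConfig | None = None) -> CenterSet:
    """Locate ommatidial centers as suppressed local maxima of the enhanced image.

    Maxima must reach ``maxima_rel_threshold`` x (max intensity inside the
    mask); greedy suppression then enforces the minimum separation, higher
    intensity winning and ties resolved in row-major order.  An image with no
    qualifying maxima yields an empty CenterSet (Z = 0), not an error.
    """
    cfg = cfg or DetectionConfig()
    m = mask.mask
    px = img.pixels
    peak = int(px[m].max()) if m.any() else 0
    if peak <= 0:
        return CenterSet(points=np.empty((0, 2)), source_mask=mask)
    thr = cfg.maxima_rel_threshold * peak
    pts, vals = _plateau_maxima(px, m, thr)
    if len(pts) == 0:
        return CenterSet(points=np.empty((0, 2)), source_mask=mask)

    if cfg.min_separation is None:
        keep = _greedy_suppress(pts, vals, 2.0)
        prov = pts[keep]
        if len(prov) >= 2:
            tree = cKDTree(prov)
            d, _ = tree.query(prov, k=2)
            spacing = float(np.median(d[:, 1]))
            min_sep = max(2.0, 0.5 * spacing)
        else:
            min_sep = 2.0
    else:
        min_sep = float(cfg.min_separation)

    keep = _greedy_suppress(pts, vals, min_sep)
    return CenterSet(points=pts[keep], source_mask=mask)


def detect_ommatidia(img: GrayImage, mask: EyeMask, cfg: DetectionConfig | None = None) -> CenterSet:
    """Full center detection: polarity normalization -> blob enhancement ->
    local-maxima search.  SEM images are inverted first so both modalities
    share the bright-center path."""
    cfg = cfg or DetectionConfig()
    if img.modality is Modality.SEM:
        img = invert(img)
    enhanced = enhance_blobs(img, mask, cfg)
    return find_local_maxima(enhanced, mask, cfg)
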
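"""Locating the eye as the region of ommatidial clustering.

Bright-field path: white top-hat (suppresses the smooth background, keeps the
reflection spots) -> Sobel edge map -> morphological closing + hole filling ->
largest connected component.  SEM path: global mean-intensity threshold ->
closing + filling -> largest component.  Both end in a single solid mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.filters import rank

from .errors import NoEyeDetected
from .image_io import GrayImage, Modality

#: Above this disk radius, grayscale/binary morphology goes through the
#: histogram-based rank filters, whose cost is radius-independent; below it,
#: plain structuring-element morphology is used.  Results agree everywhere
#: except within one radius of the image border, where rank filters crop the
#: footprint instead of padding.
_RANK_RADIUS = 12


def white_tophat_disk(pixels: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat (image minus opening) by an exact disk, uint8 in/out."""
    d = morphology.disk(radius)
    if radius >= _RANK_RADIUS:
        opened = rank.maximum(rank.minimum(pixels, footprint=d), footprint=d)
    else:
        opened = morphology.opening(pixels, footprint=d)
    return (pixels - np.minimum(opened, pixels)).astype(np.uint8)


def binary_close_disk(binary: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing by an exact disk."""
    d = morphology.disk(radius)
    if radius >= _RANK_RADIUS:
        u8 = binary.astype(np.uint8) * 255
        closed = rank.minimum(rank.maximum(u8, footprint=d), footprint=d)
        return closed > 0
    return morphology.closing(binary.astype(bool), footprint=d)


@dataclass(frozen=True)
class MorphologyConfig:
    """Structuring-element sizes and thresholds for eye localization.

    Defaults assume a lattice spacing of ~10 px: the top-hat SE is slightly
    smaller than one ommatidium so reflection spots survive the opening, and
    the closing SE is about one lattice spacing so it bridges the gaps
    between neighboring ommatidia.
    """

    se_shape: str = "disk"
    se_radius_tophat: int = 6
    se_radius_close: int = 10
    edge_threshold: float = 0.15
    min_eye_area: int = 5000
    sem_foreground: str = "bright"  # which side of the mean is the eye

    def __post_init__(self) -> None:
        if self.se_shape != "disk":
            raise ValueError("only disk structuring elements are supported")
        if self.se_radius_tophat < 1 or self.se_radius_close < 1:
            raise ValueError("structuring-element radii must be >= 1")
        if not 0.0 < self.edge_threshold < 1.0:
            raise ValueError("edge_threshold must lie in (0, 1)")
        if self.sem_foreground not in ("bright", "dark"):
            raise ValueError("sem_foreground must be 'bright' or 'dark'")

    def scaled(self, factor: float) -> "MorphologyConfig":
        """Rescale pixel-valued parameters for a different magnification."""
        return replace(
            self,
            se_radius_tophat=max(1, round(self.se_radius_tophat * factor)),
            se_radius_close=max(1, round(self.se_radius_close * factor)),
            min_eye_area=max(1, round(self.min_eye_area * factor * factor)),
        )


@dataclass(frozen=True)
class EyeMask:
    """Binary mask of the localized eye: one 8-connected, hole-free component."""

    mask: np.ndarray  # bool, congruent with the source raster
    area: int
    centroid: tuple[float, float]  # (row, col)


def tophat_enhance(img: GrayImage, cfg: MorphologyConfig) -> GrayImage:
    """White top-hat: image minus its opening by a disk.

    Structures wider than the SE (the smooth eye dome, the background) are
    suppressed toward zero; the per-ommatidium reflection spots survive.
    """
    r = cfg.se_radius_tophat
    if r > min(img.height, img.width) / 2:
        raise ValueError(
            f"top-hat SE radius {r} exceeds half the smaller image side"
        )
    out = white_tophat_disk(img.pixels, r)
    return GrayImage(pixels=out, modality=img.modality)


def detect_edges(img: GrayImage, cfg: MorphologyConfig) -> np.ndarray:
    """Binary edge map: 3x3 Sobel gradient magnitude over a relative threshold."""
    f = img.pixels.astype(np.float64)
    gr = ndi.sobel(f, axis=0)
    gc = ndi.sobel(f, axis=1)
    mag = np.hypot(gr, gc)
    peak = mag.max()
    if peak == 0:
        return np.zeros(img.pixels.shape, dtype=bool)
    return mag > cfg.edge_threshold * peak


def close_and_fill(edges: np.ndarray, cfg: MorphologyConfig) -> np.ndarray:
    """Morphological closing (disk SE) followed by hole filling.

    Bridges the gaps between edge fragments of neighboring ommatidia so the
    whole cluster becomes one solid blob.
    """
    closed = binary_close_disk(edges, cfg.se_radius_close)
    return ndi.binary_fill_holes(closed)


def threshold_sem(img: GrayImage, cfg: MorphologyConfig | None = None) -> np.ndarray:
    """Segment an SEM image by its global mean intensity.

    The eye and the mounted-specimen background separate cleanly around the
    mean; which side is the eye depends on detector polarity and is selected
    by ``cfg.sem_foreground`` (default: the brighter side).
    """
    px = img.pixels
    if px.max() == px.min():
        raise NoEyeDetected("zero-variance image: no foreground/background contrast")
    mean = px.mean()
    if cfg is not None and cfg.sem_foreground == "dark":
        return px < mean
    return px > mean


def _largest_component(binary: np.ndarray) -> np.ndarray | None:
    """Largest 8-connected component; area ties go to the component whose
    centroid is closest to the image center (deterministic)."""
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return None
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best_area = areas.max()
    tied = np.flatnonzero(areas == best_area) + 1
    if len(tied) == 1:
        keep = tied[0]
    else:
        center = (np.array(binary.shape, dtype=float) - 1) / 2.0
        cents = np.array(ndi.center_of_mass(binary, labels, index=tied))
        keep = tied[int(np.argmin(np.sum((cents - center) ** 2, axis=1)))]
    return labels == keep


def localize_eye(img: GrayImage, cfg: MorphologyConfig | None = None) -> EyeMask:
    """Localize the eye, dispatching on modality.

    Raises :class:`NoEyeDetected` if no candidate component reaches
    ``cfg.min_eye_area``.
    """
    cfg = cfg or MorphologyConfig()
    if img.modality is Modality.SEM:
        rough = threshold_sem(img, cfg)
    else:
        enhanced = tophat_enhance(img, cfg)
        rough = detect_edges(enhanced, cfg)
    solid = close_and_fill(rough, cfg)
    comp = _largest_component(solid)
    if comp is None:
        raise NoEyeDetected("no connected component found")
    comp = ndi.binary_fill_holes(comp)
    area = int(comp.sum())
    if area < cfg.min_eye_area:
        raise NoEyeDetected(
            f"largest component area {area} px is below min_eye_area "
            f"{cfg.min_eye_area}"
        )
    centroid = ndi.center_of_mass(comp)
    return EyeMask(mask=comp, area=area, centroid=(float(centroid[0]), float(centroid[1])))
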
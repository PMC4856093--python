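"""Ground-truthed synthetic eye scenes.

A wild-type compound eye is emulated as a hexagonal lattice of ~750
ommatidial centers clipped to a convex ellipse.  Disorder is injected two
ways, mirroring what rough-eye genotypes do to the real lattice:

* positional jitter — isotropic Gaussian displacement of each center
  (lattice disorganization without loss of ommatidia);
* fusion — uniform random removal of a fraction of centers (ommatidia the
  detector cannot identify, lowering the fusion index Z).

Scenes render either as bright-field images (dark background, dim convex eye
dome, one bright Gaussian reflection spot per center) or SEM-style images
(mid-gray specimen background, light eye field, one dark Gaussian dip per
center), with Gaussian read noise.  Everything is deterministic given the
scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import TooFewOmmatidia
from .image_io import GrayImage, Modality
from .ommatidia_detection import CenterSet

#: Default lattice spacing between ommatidial centers, px.
DEFAULT_SPACING = 10.0

#: Ellipse semi-axes (row, col) calibrated once so the zero-jitter lattice at
#: the default spacing holds exactly 750 centers (the typical ommatidium
#: count of a wild-type eye), then frozen.
DEFAULT_ELLIPSE_AXES = (126.5, 163.75)

DEFAULT_IMAGE_SIZE = (300, 400)
DEFAULT_ELLIPSE_CENTER = (150.0, 200.0)

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class EyeSceneSpec:
    """Full description of one synthetic eye scene."""

    lattice_spacing: float = DEFAULT_SPACING
    ellipse_axes: tuple[float, float] = DEFAULT_ELLIPSE_AXES
    ellipse_center: tuple[float, float] = DEFAULT_ELLIPSE_CENTER
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    jitter_sigma: float = 0.0
    fusion_fraction: float = 0.0
    modality: Modality = Modality.BRIGHTFIELD
    seed: int = 0
    spot_sigma: float = 2.0
    background_level: float | None = None
    foreground_level: float | None = None
    noise_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.lattice_spacing < 4:
            raise ValueError("lattice_spacing must be >= 4 px")
        if not 0.0 <= self.fusion_fraction < 1.0:
            raise ValueError("fusion_fraction must lie in [0, 1)")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        (r0, c0), (ar, ac) = self.ellipse_center, self.ellipse_axes
        h, w = self.image_size
        if r0 - ar < 10 or r0 + ar > h - 10 or c0 - ac < 10 or c0 + ac > w - 10:
            raise ValueError("ellipse must fit inside the image with a 10-px margin")
        object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def levels(self) -> tuple[float, float]:
        """(background, foreground) intensity levels, per-modality defaults."""
        if self.modality is Modality.SEM:
            bg = 80.0 if self.background_level is None else self.background_level
            fg = 200.0 if self.foreground_level is None else self.foreground_level
        else:
            bg = 20.0 if self.background_level is None else self.background_level
            fg = 230.0 if self.foreground_level is None else self.foreground_level
        return bg, fg

    def scaled(self, factor: float) -> "EyeSceneSpec":
        """The same scene at a different resolution: every length scales by
        ``factor``, the lattice topology and random draws stay identical."""
        return replace(
            self,
            lattice_spacing=self.lattice_spacing * factor,
            ellipse_axes=(self.ellipse_axes[0] * factor, self.ellipse_axes[1] * factor),
            ellipse_center=(self.ellipse_center[0] * factor, self.ellipse_center[1] * factor),
            image_size=(round(self.image_size[0] * factor), round(self.image_size[1] * factor)),
            jitter_sigma=self.jitter_sigma * factor,
            spot_sigma=self.spot_sigma * factor,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Centers actually placed in the scene (post-jitter, post-fusion)."""

    centers: CenterSet
    spec: EyeSceneSpec

    @property
    def ellipse(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return self.spec.ellipse_center, self.spec.ellipse_axes


def _hex_lattice(spec: EyeSceneSpec) -> np.ndarray:
    """Ideal hexagonal lattice clipped to the ellipse, row-major order.

    The lattice origin sits off the ellipse center by a fixed fraction of the
    spacing; a perfectly centered lattice is mirror-symmetric and can only
    produce odd point counts, which would make the even default count
    uncalibratable.
    """
    s = spec.lattice_spacing
    h = s * _SQRT3_2
    (r0, c0), (ar, ac) = spec.ellipse_center, spec.ellipse_axes
    orig_r = r0 + 0.3 * h
    orig_c = c0 + 0.3 * s
    imax = int(ar // h) + 2
    jmax = int(ac // s) + 2
    pts = []
    for i in range(-imax, imax + 1):
        r = orig_r + i * h
        off = (i % 2) * (s / 2.0)
        for j in range(-jmax, jmax + 1):
            c = orig_c + j * s + off
            if ((r - r0) / ar) ** 2 + ((c - c0) / ac) ** 2 <= 1.0:
                pts.append((r, c))
    return np.array(pts, dtype=np.float64).reshape(-1, 2)


def make_lattice(spec: EyeSceneSpec) -> GroundTruth:
    """Generate the ground-truth centers: lattice -> jitter -> fusion removal.

    Jittered points that would leave the ellipse are projected radially back
    just inside the boundary, so every center stays within the eye.  All
    randomness derives from ``spec.seed``; zero jitter reproduces the ideal
    lattice bit-exactly.
    """
    pts = _hex_lattice(spec)
    (r0, c0), (ar, ac) = spec.ellipse_center, spec.ellipse_axes

    if spec.jitter_sigma > 0:
        rng = np.random.default_rng([spec.seed, 0])
        pts = pts + rng.normal(0.0, spec.jitter_sigma, size=pts.shape)
        rho = np.sqrt(((pts[:, 0] - r0) / ar) ** 2 + ((pts[:, 1] - c0) / ac) ** 2)
        out = rho > 0.999
        if out.any():
            f = 0.999 / rho[out]
            pts[out, 0] = r0 + (pts[out, 0] - r0) * f
            pts[out, 1] = c0 + (pts[out, 1] - c0) * f

    if spec.fusion_fraction > 0:
        rng_f = np.random.default_rng([spec.seed, 1])
        k = int(np.floor(spec.fusion_fraction * len(pts)))
        drop = rng_f.choice(len(pts), size=k, replace=False)
        keep = np.setdiff1d(np.arange(len(pts)), drop)
        pts = pts[keep]

    if len(pts) < 7:
        raise TooFewOmmatidia(f"scene has only {len(pts)} centers")
    return GroundTruth(centers=CenterSet(points=pts), spec=spec)


def render(gt: GroundTruth, spec: EyeSceneSpec | None = None) -> GrayImage:
    """Render ground truth into a bright-field or SEM-style image."""
    spec = spec or gt.spec
    hgt, wid = spec.image_size
    (r0, c0), (ar, ac) = spec.ellipse_center, spec.ellipse_axes
    bg, fg = spec.levels

    rr, cc = np.meshgrid(np.arange(hgt, dtype=np.float64), np.arange(wid, dtype=np.float64), indexing="ij")
    rho2 = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2
    inside = rho2 <= 1.0
    shade = np.sqrt(np.clip(1.0 - rho2, 0.0, 1.0))  # convex-dome shading

    img = np.full((hgt, wid), bg, dtype=np.float64)
    if spec.modality is Modality.SEM:
        img[inside] = fg * (0.92 + 0.08 * shade[inside])
        amp = -0.5 * fg  # dark dip at each ommatidial center
    else:
        img[inside] = bg + (fg - bg) * (0.18 + 0.12 * shade[inside])
        amp = 0.7 * (fg - bg)  # bright reflection spot at each center

    sig = spec.spot_sigma
    half = int(np.ceil(4 * sig))
    for r, c in gt.centers.points:
        rlo, rhi = max(0, int(r) - half), min(hgt, int(r) + half + 1)
        clo, chi = max(0, int(c) - half), min(wid, int(c) + half + 1)
        wr = np.arange(rlo, rhi, dtype=np.float64) - r
        wc = np.arange(clo, chi, dtype=np.float64) - c
        g = np.exp(-(wr[:, None] ** 2 + wc[None, :] ** 2) / (2.0 * sig * sig))
        img[rlo:rhi, clo:chi] += amp * g

    if spec.noise_sigma > 0:
        rng_n = np.random.default_rng([spec.seed, 2])
        img = img + rng_n.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.floor(np.clip(img, 0.0, 255.0) + 0.5).astype(np.uint8)
    return GrayImage(pixels=img, modality=spec.modality)


def ellipse_mask(spec: EyeSceneSpec) -> np.ndarray:
    """Boolean raster of the true eye ellipse (ground truth for mask IoU)."""
    hgt, wid = spec.image_size
    (r0, c0), (ar, ac) = spec.ellipse_center, spec.ellipse_axes
    rr, cc = np.meshgrid(np.arange(hgt, dtype=np.float64), np.arange(wid, dtype=np.float64), indexing="ij")
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class MatchResult:
    recall: float
    precision: float
    mean_error: float  # px, over matched pairs
    n_matched: int


def match_centers(detected: np.ndarray | CenterSet, truth: np.ndarray | CenterSet, radius: float = 3.0) -> MatchResult:
    """Greedy one-to-one matching of detected vs ground-truth centers.

    Candidate pairs within ``radius`` are matched in ascending-distance
    order; each center participates in at most one match.
    """
    det = detected.points if isinstance(detected, CenterSet) else np.asarray(detected, dtype=float)
    tru = truth.points if isinstance(truth, CenterSet) else np.asarray(truth, dtype=float)
    if len(det) == 0 or len(tru) == 0:
        return MatchResult(0.0, 0.0, float("nan"), 0)
    diff = det[:, None, :] - tru[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    pairs = np.argwhere(d <= radius)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_d = np.zeros(len(det), dtype=bool)
    used_t = np.zeros(len(tru), dtype=bool)
    errs = []
    for k in order:
        i, j = pairs[k]
        if used_d[i] or used_t[j]:
            continue
        used_d[i] = True
        used_t[j] = True
        errs.append(d[i, j])
    n = len(errs)
    return MatchResult(
        recall=n / len(tru),
        precision=n / len(det),
        mean_error=float(np.mean(errs)) if n else float("nan"),
        n_matched=n,
    )


def make_benchmark_panel(
    out_dir,
    jitter_sigmas=(0.0,),
    fusion_fractions=(0.0,),
    n_per_cell: int = 10,
    base_seed: int = 1,
    modality: Modality | str = Modality.BRIGHTFIELD,
    scale: float = 1.0,
    noise_sigma: float = 3.0,
) -> pd.DataFrame:
    """Write a full-factorial panel of rendered scenes plus manifest.

    Creates ``<out_dir>/panel_XXXX.png`` per cell replicate, a
    ``manifest.csv`` (filename, sigma, fusion, modality, seed) and a
    ``ground_truth.csv`` (filename, row, col).  Deterministic: the same
    ``base_seed`` yields a byte-identical manifest and images.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    modality = Modality(modality)
    base = EyeSceneSpec(modality=modality, noise_sigma=noise_sigma).scaled(scale)
    rows = []
    gt_rows = []
    idx = 0
    for sigma in jitter_sigmas:
        for f in fusion_fractions:
            for _ in range(n_per_cell):
                seed = (base_seed * 100003 + idx) % (2**31 - 1)
                spec = replace(base, jitter_sigma=sigma * scale, fusion_fraction=f, seed=seed)
                gt = make_lattice(spec)
                img = render(gt, spec)
                fname = f"panel_{idx:04d}.png"
                iio.imwrite(out / fname, img.pixels)
                rows.append(
                    {"filename": fname, "sigma": sigma, "fusion": f,
                     "modality": modality.value, "seed": seed}
                )
                for r, c in gt.centers.points:
                    gt_rows.append({"filename": fname, "row": r, "col": c})
                idx += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)
    return manifest
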
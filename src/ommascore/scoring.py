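"""Phenotypic scoring of ommatidial lattice disorder.

A wild-type compound eye packs ~750 ommatidia on a near-perfect hexagonal
lattice; each ommatidium therefore has six equidistant neighbors at 60-degree
increments.  For every detected center we build the fan of vectors to its six
nearest neighbors and measure two deviations from hexagonal symmetry:

* distance disorderliness ODI_D: sum over the five non-minimal vectors of
  (|v_i| - |v_min|) / |v_min| — zero when all six neighbor distances agree;
* angle disorderliness ODI_A: sum over the six cyclically adjacent vector
  pairs of 2 * |acos(v_i . v_{i+1} / (|v_i||v_{i+1}|)) - pi/3| — zero when
  adjacent vectors are all 60 degrees apart.

Per-eye, the ommatidia are ranked by total disorderliness (ties broken by
distance to the eye center) and the N most ordered are aggregated into
ODI_T = sum log1p(ODI_D + ODI_A); a perfectly symmetric lattice has zero
entropy, so ODI_T = 0 there.  The phenotypic score is

    P = (ODI_T / N_used) / log(Z)

where Z, the fusion index, is the number of ommatidia the detector could
identify: fused ommatidia lower Z and raise P.  Higher P = rougher eye.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import PipelineError, TooFewOmmatidia
from .eye_localization import MorphologyConfig, localize_eye
from .image_io import Modality, load_image
from .ommatidia_detection import CenterSet, DetectionConfig, detect_ommatidia

logger = logging.getLogger("ommascore")

#: Default number of most-ordered ommatidia aggregated per eye.
DEFAULT_N_OMMATIDIA = 200

#: Disorderliness below this is floating-point residue on an exactly regular
#: fan (lattice row offsets involve sqrt(3)/2); clamp it to an exact zero so
#: perfect symmetry scores exactly 0.
ZERO_TOLERANCE = 1e-9

#: Floor inside the logarithm for the strict aggregation mode, which sums
#: log(d + eps) instead of log1p(d) and is otherwise -inf at perfect order.
STRICT_LOG_EPS = 1e-9

_SIXTY_DEG = np.pi / 3.0


@dataclass(frozen=True)
class NeighborFan:
    """Vectors from one ommatidium to its six nearest neighbors, sorted
    counterclockwise by polar angle (cyclic: v_6 is adjacent to v_1)."""

    center: tuple[float, float]
    vectors: np.ndarray  # (6, 2) as (drow, dcol)

    @property
    def lengths(self) -> np.ndarray:
        return np.sqrt((self.vectors**2).sum(axis=1))

    @property
    def v_min_length(self) -> float:
        return float(self.lengths.min())


@dataclass(frozen=True)
class OmmatidiumScore:
    fan: NeighborFan
    odi_d: float
    odi_a: float
    dist_to_eye_center: float

    @property
    def d_total(self) -> float:
        return self.odi_d + self.odi_a


@dataclass(frozen=True)
class PhenotypeResult:
    """Scoring summary for one eye."""

    odi_t: float
    Z: int
    N_used: int
    P: float
    per_ommatidium: list[OmmatidiumScore]


def neighbor_fan(centers: CenterSet | np.ndarray, index: int) -> NeighborFan:
    """Fan of the six nearest other centers, chosen by Euclidean distance.

    Distance ties are broken by row-major order of the tied candidates.
    Raises :class:`TooFewOmmatidia` when fewer than 7 centers exist.
    """
    pts = centers.points if isinstance(centers, CenterSet) else np.asarray(centers, dtype=float)
    n = len(pts)
    if n < 7:
        raise TooFewOmmatidia(f"need >= 7 ommatidia for six-neighbor fans, have {n}")
    p = pts[index]
    d2 = ((pts - p) ** 2).sum(axis=1)
    d2[index] = np.inf
    order = np.lexsort((pts[:, 1], pts[:, 0], d2))
    nearest = order[:6]
    vectors = pts[nearest] - p
    ang = np.arctan2(vectors[:, 0], vectors[:, 1])
    lens = np.sqrt((vectors**2).sum(axis=1))
    vectors = vectors[np.lexsort((lens, ang))]
    return NeighborFan(center=(float(p[0]), float(p[1])), vectors=vectors)


def odi_distance(fan: NeighborFan) -> float:
    """Distance disorderliness: sum of (|v_i| - |v_min|)/|v_min| over the five
    vectors other than the designated minimum (first minimal vector in
    angular order)."""
    lens = fan.lengths
    if np.any(lens == 0):
        raise ValueError("zero-length neighbor vector")
    imin = int(np.argmin(lens))  # first in angular order among minima
    vmin = lens[imin]
    others = np.delete(lens, imin)
    val = float(((others - vmin) / vmin).sum())
    return 0.0 if val < ZERO_TOLERANCE else val


def odi_angle(fan: NeighborFan) -> float:
    """Angle disorderliness: sum over the six cyclically adjacent pairs of
    2 * |angle(v_i, v_{i+1}) - 60 degrees|, in radians."""
    v = fan.vectors
    lens = fan.lengths
    nxt = np.roll(np.arange(6), -1)
    dots = (v * v[nxt]).sum(axis=1) / (lens * lens[nxt])
    theta = np.arccos(np.clip(dots, -1.0, 1.0))
    val = float((2.0 * np.abs(theta - _SIXTY_DEG)).sum())
    return 0.0 if val < ZERO_TOLERANCE else val


def rank_and_aggregate(
    scores: list[OmmatidiumScore],
    N: int = DEFAULT_N_OMMATIDIA,
    strict_log: bool = False,
) -> tuple[float, int]:
    """Aggregate the N most ordered ommatidia into ODI_T.

    Ommatidia are sorted ascending by (total disorderliness, distance to the
    eye center); the first min(N, count) contribute log1p(d_total) each — or
    log(d_total + eps) in strict mode.  Returns (ODI_T, N_used).
    """
    if not scores:
        raise ValueError("empty score list")
    if N < 1:
        raise ValueError("N must be >= 1")
    if len(scores) < N:
        warnings.warn(
            f"only {len(scores)} ommatidia available for N={N}; aggregating all",
            stacklevel=2,
        )
    d = np.array([s.d_total for s in scores])
    dist = np.array([s.dist_to_eye_center for s in scores])
    order = np.lexsort((dist, d))
    n_used = min(N, len(scores))
    top = d[order[:n_used]]
    if strict_log:
        odi_t = float(np.log(top + STRICT_LOG_EPS).sum())
    else:
        odi_t = float(np.log1p(top).sum())
    return odi_t, n_used


def phenotypic_score(odi_t: float, n_used: int, z: int) -> float:
    """P = (ODI_T / N_used) / log(Z); fusion (smaller Z) raises P."""
    if z < 7:
        raise TooFewOmmatidia(f"fusion index Z={z} is below the minimum of 7")
    if n_used < 1:
        raise ValueError("N_used must be >= 1")
    return (odi_t / n_used) / np.log(z)


def score_pointset(
    centers: CenterSet | np.ndarray,
    eye_center: tuple[float, float] | None = None,
    N: int = DEFAULT_N_OMMATIDIA,
    strict_log: bool = False,
) -> PhenotypeResult:
    """Score a bare set of ommatidial centers (no image required).

    ``eye_center`` anchors the ranking tie-break; when omitted, the centroid
    of the centers is used.
    """
    cs = centers if isinstance(centers, CenterSet) else CenterSet(points=np.asarray(centers, dtype=float))
    z = cs.Z
    if z < 7:
        raise TooFewOmmatidia(f"fusion index Z={z} is below the minimum of 7")
    pts = cs.points
    if eye_center is None:
        eye_center = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    ec = np.asarray(eye_center, dtype=float)

    tree = cKDTree(pts)
    _, nn = tree.query(pts, k=min(8, z))
    per: list[OmmatidiumScore] = []
    for i in range(z):
        # cKDTree gives candidate neighbors cheaply; neighbor_fan re-derives
        # the deterministic tie-broken choice from scratch only when needed
        fan = _fan_from_neighbors(pts, i, nn[i])
        per.append(
            OmmatidiumScore(
                fan=fan,
                odi_d=odi_distance(fan),
                odi_a=odi_angle(fan),
                dist_to_eye_center=float(np.sqrt(((pts[i] - ec) ** 2).sum())),
            )
        )
    odi_t, n_used = rank_and_aggregate(per, N=N, strict_log=strict_log)
    p = phenotypic_score(odi_t, n_used, z)
    return PhenotypeResult(odi_t=odi_t, Z=z, N_used=n_used, P=p, per_ommatidium=per)


def _fan_from_neighbors(pts: np.ndarray, i: int, candidates: np.ndarray) -> NeighborFan:
    """Build the fan for point ``i`` given KD-tree neighbor candidates,
    falling back to the exhaustive rule on a distance tie at the 6th/7th
    boundary (where row-major tie-breaking over *all* points is required)."""
    cand = candidates[candidates != i]
    p = pts[i]
    d2 = ((pts[cand] - p) ** 2).sum(axis=1)
    order = np.lexsort((pts[cand, 1], pts[cand, 0], d2))
    if len(cand) > 6 and d2[order[6]] == d2[order[5]]:
        return neighbor_fan(pts, i)
    nearest = cand[order[:6]]
    vectors = pts[nearest] - p
    ang = np.arctan2(vectors[:, 0], vectors[:, 1])
    lens = np.sqrt((vectors**2).sum(axis=1))
    vectors = vectors[np.lexsort((lens, ang))]
    return NeighborFan(center=(float(p[0]), float(p[1])), vectors=vectors)


def score_image(
    img_path,
    modality: Modality | str,
    N: int = DEFAULT_N_OMMATIDIA,
    morphology_cfg: MorphologyConfig | None = None,
    detection_cfg: DetectionConfig | None = None,
    strict_log: bool = False,
) -> PhenotypeResult:
    """Full pipeline on one image: load -> localize eye -> detect centers ->
    score, with the eye-mask centroid as the eye center.

    Any stage failure is re-raised as :class:`PipelineError` naming the stage.
    """
    stages = (
        ("load", lambda _: load_image(img_path, modality)),
        ("localize", lambda img: (img, localize_eye(img, morphology_cfg))),
        ("detect", lambda im: (im[1], detect_ommatidia(im[0], im[1], detection_cfg))),
        ("score", lambda mc: score_pointset(mc[1], eye_center=mc[0].centroid, N=N, strict_log=strict_log)),
    )
    state = None
    for name, step in stages:
        t0 = time.perf_counter()
        try:
            state = step(state)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        logger.debug("stage %-8s %.1f ms", name, 1e3 * (time.perf_counter() - t0))
    return state
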
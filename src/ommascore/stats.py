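"""Batch scoring and the group statistics used to compare genotypes.

Screens compare each genotype's phenotypic-score distribution against a
control with a two-sample t-test (Welch by default), Bonferroni-corrected
across the comparisons in one call; rank agreement with an external (e.g.
manual) severity ordering is measured by Spearman correlation.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .eye_localization import MorphologyConfig
from .image_io import Modality
from .ommatidia_detection import DetectionConfig
from .scoring import DEFAULT_N_OMMATIDIA, score_image

logger = logging.getLogger("ommascore")

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


def _config_hash(n: int, morph: MorphologyConfig | None, det: DetectionConfig | None, strict: bool) -> str:
    key = repr((n, morph or MorphologyConfig(), det or DetectionConfig(), strict))
    return hashlib.md5(key.encode()).hexdigest()[:12]


def batch_score(
    source,
    modality: Modality | str = Modality.BRIGHTFIELD,
    N: int = DEFAULT_N_OMMATIDIA,
    morphology_cfg: MorphologyConfig | None = None,
    detection_cfg: DetectionConfig | None = None,
    strict_log: bool = False,
) -> pd.DataFrame:
    """Score every image under a directory, or every row of a manifest CSV.

    A manifest must have a ``filename`` column (paths relative to the
    manifest) and may carry per-file ``modality`` and grouping columns, which
    are passed through to the output.  Per-file failures are logged and
    skipped; only zero scorable images is an error.
    """
    source = Path(source)
    extra_cols: list[dict] = []
    if source.is_dir():
        files = sorted(p for p in source.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        entries = [{"path": p, "modality": Modality(modality)} for p in files]
    else:
        manifest = pd.read_csv(source)
        if "filename" not in manifest.columns:
            raise ValueError("manifest CSV needs a 'filename' column")
        entries = []
        for _, row in manifest.iterrows():
            entries.append(
                {
                    "path": source.parent / row["filename"],
                    "modality": Modality(row["modality"]) if "modality" in manifest.columns else Modality(modality),
                }
            )
            extra_cols.append(
                {k: row[k] for k in manifest.columns if k not in ("filename", "modality")}
            )
    if not entries:
        raise RuntimeError(f"no images found under {source}")

    chash = _config_hash(N, morphology_cfg, detection_cfg, strict_log)
    rows = []
    n_failed = 0
    for k, entry in enumerate(entries):
        try:
            res = score_image(
                entry["path"],
                entry["modality"],
                N=N,
                morphology_cfg=morphology_cfg,
                detection_cfg=detection_cfg,
                strict_log=strict_log,
            )
        except Exception as exc:
            n_failed += 1
            logger.warning("skipping %s: %s", entry["path"], exc)
            continue
        row = {
            "image": entry["path"].name,
            "modality": entry["modality"].value,
            "Z": res.Z,
            "N_used": res.N_used,
            "ODI_T": res.odi_t,
            "P": res.P,
            "config_hash": chash,
        }
        if extra_cols:
            row.update(extra_cols[k])
        rows.append(row)
    if not rows:
        raise RuntimeError(f"no scorable images under {source} ({n_failed} failures)")
    if n_failed:
        logger.warning("%d of %d images failed to score", n_failed, len(entries))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_two_tailed: float
    p_corrected: float
    correction_method: str


def compare_groups(
    results: pd.DataFrame,
    group_col: str,
    reference: str,
    value_col: str = "P",
    equal_var: bool = False,
    correction: str = "bonferroni",
) -> list[GroupComparison]:
    """Two-sample t-test (Welch by default) of every group against a
    reference, two-tailed, Bonferroni-corrected across the call."""
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    groups = results.groupby(group_col)[value_col]
    if reference not in groups.groups:
        raise ValueError(f"reference group {reference!r} not present")
    ref = groups.get_group(reference).to_numpy(dtype=float)
    if len(ref) < 2:
        raise ValueError("reference group needs n >= 2")

    tested = []
    for name, vals in groups:
        if name == reference:
            continue
        v = vals.to_numpy(dtype=float)
        if len(v) < 2:
            logger.warning("skipping group %r: n=%d < 2", name, len(v))
            continue
        t, p = sps.ttest_ind(v, ref, equal_var=equal_var)
        tested.append((str(name), v, float(t), float(p)))

    m = len(tested)
    out = []
    for name, v, t, p in tested:
        p_corr = min(1.0, p * m) if correction == "bonferroni" else p
        out.append(
            GroupComparison(
                group_a=str(name),
                group_b=str(reference),
                n_a=len(v),
                n_b=len(ref),
                mean_a=float(v.mean()),
                mean_b=float(ref.mean()),
                t_statistic=t,
                p_two_tailed=p,
                p_corrected=p_corr,
                correction_method=correction,
            )
        )
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in comparisons])


def rank_correlation(
    scores: np.ndarray | pd.Series,
    external_ranks: np.ndarray | pd.Series,
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlate per-group mean scores with an external severity ranking.

    Returns (coefficient, two-tailed p).  Spearman is the default; Pearson is
    available for comparison against interval-scale external measures.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(external_ranks, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(rho), float(p)


def small_sample_separation(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n: int = 3,
) -> float:
    """Mann-Whitney p for separating two phenotype classes at small sample size.

    Emulates a sensitivity design: draw every n-image combination (with
    replacement) from each class, take the mean score of each combination,
    and compare the two distributions of means with a two-sided Mann-Whitney
    U test.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    means_a = [np.mean(c) for c in itertools.combinations_with_replacement(a, n)]
    means_b = [np.mean(c) for c in itertools.combinations_with_replacement(b, n)]
    _, p = sps.mannwhitneyu(means_a, means_b, alternative="two-sided")
    return float(p)
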
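"""Hemicord activation-map comparison.

Partitions the cord into left and right hemicords (excluding the center
voxel column where they meet), computes spatial correlations between
rater and reference z-maps inside ipsilateral / contralateral regions,
thresholds maps at Z > 2.3, and standardises the reference's voxelwise
z-statistics against the rater distribution (z̄ and SD[z]).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from cordmaskvar.errors import UndefinedMetricError
from cordmaskvar.inference import fisher_z

logger = logging.getLogger(__name__)


@dataclass
class ActivationMap:
    """A z-statistic volume restricted to an analysis mask."""

    z: np.ndarray
    analysis_mask: np.ndarray
    stimulus_side: str = "left"
    level: str = "participant"

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        self.analysis_mask = np.asarray(self.analysis_mask).astype(bool)
        if self.z.shape != self.analysis_mask.shape:
            raise ValueError("z-map and analysis mask must share a grid")
        if not np.all(np.isfinite(self.z[self.analysis_mask])):
            raise ValueError("z-statistics must be finite inside the analysis mask")


@dataclass
class HemicordPartition:
    left: np.ndarray
    right: np.ndarray
    excluded_center: np.ndarray


@dataclass
class StandardizedComparison:
    """Voxelwise standardisation of reference z against the rater spread.

    z_bar = (1/n) Σ (y_i − x̄_i)/σ_xi and sd_z its sample s.d., over the
    n voxels of one hemicord × condition region.
    """

    z_bar: float
    sd_z: float
    n_voxels: int
    per_voxel: np.ndarray = field(repr=False, default=None)


def _round_half_up(x: float) -> int:
    # np.round's banker's rounding breaks left/right mirror symmetry
    return int(np.floor(x + 0.5))


def hemicord_partition(cord) -> HemicordPartition:
    """Split the cord into left/right hemicords around the center column.

    Per slice, the excluded center is the single left-right voxel column
    at the rounded left-right center of mass of the cord mask; voxels in
    strictly smaller columns form the left hemicord, strictly larger the
    right. A slice of in-plane width 1 leaves both hemicords empty on
    that slice (warned); an entirely empty result is an error.
    """
    m = cord.data.astype(bool) if hasattr(cord, "role") else np.asarray(cord).astype(bool)
    left = np.zeros_like(m)
    right = np.zeros_like(m)
    center = np.zeros_like(m)
    any_voxel = False
    for s in range(m.shape[2]):
        sl = m[:, :, s]
        if not sl.any():
            continue
        any_voxel = True
        cols = np.nonzero(sl)[1]
        if cols.max() == cols.min():
            warnings.warn(f"cord has in-plane width 1 on slice {s}; hemicords empty there")
            center[:, :, s] = sl
            continue
        c = _round_half_up(float(cols.mean()))
        col_idx = np.arange(sl.shape[1])[None, :]
        center[:, :, s] = sl & (col_idx == c)
        left[:, :, s] = sl & (col_idx < c)
        right[:, :, s] = sl & (col_idx > c)
    if not any_voxel:
        raise UndefinedMetricError("cord mask empty on all slices")
    return HemicordPartition(left=left, right=right, excluded_center=center)


def condition_regions(partition: HemicordPartition, stimulus_side: str):
    """(ipsilateral, contralateral) hemicord masks for a stimulus side:
    left stimulus → (left, right); right stimulus → (right, left)."""
    if stimulus_side == "left":
        return partition.left, partition.right
    if stimulus_side == "right":
        return partition.right, partition.left
    raise ValueError(f"stimulus_side must be 'left' or 'right', got {stimulus_side!r}")


def spatial_correlation(a: ActivationMap, b: ActivationMap, region,
                        method: str = "pearson") -> float:
    """Fisher's z of the spatial correlation of two unthresholded z-maps.

    Pearson over the region's voxels by default (Spearman optional);
    perfectly (anti)correlated maps clamp at ±atanh(1 − 1e−7).
    """
    reg = region.data.astype(bool) if hasattr(region, "role") else np.asarray(region).astype(bool)
    if not (reg & ~a.analysis_mask).sum() == 0 or not (reg & ~b.analysis_mask).sum() == 0:
        raise ValueError("region must lie inside both analysis masks")
    va, vb = a.z[reg], b.z[reg]
    if va.size < 3:
        raise UndefinedMetricError("spatial correlation needs at least 3 voxels")
    if va.std() == 0.0 or vb.std() == 0.0:
        raise UndefinedMetricError("spatial correlation undefined: zero variance on region")
    if method == "pearson":
        r = float(np.corrcoef(va, vb)[0, 1])
    elif method == "spearman":
        r = float(stats.spearmanr(va, vb).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return fisher_z(r)


def threshold_map(amap: ActivationMap, z_thresh: float = 2.3) -> np.ndarray:
    """Active-voxel mask: z strictly greater than ``z_thresh`` within the
    analysis mask (Z > 2.3 ≈ p < 0.01 uncorrected)."""
    return (amap.z > z_thresh) & amap.analysis_mask


def standardize_reference(ref: ActivationMap, raters, region) -> StandardizedComparison:
    """Standardise the reference's z-statistics against the rater spread.

    Per region voxel i: (y_i − x̄_i)/σ_xi with x̄_i, σ_xi the mean and
    sample (n−1) s.d. over the rater maps; z̄ and SD[z] summarise the
    scores over the region. Voxels with σ_xi = 0 are dropped with a
    warning; fewer than 2 surviving voxels is an error.
    """
    reg = region.data.astype(bool) if hasattr(region, "role") else np.asarray(region).astype(bool)
    raters = list(raters)
    if len(raters) < 2:
        raise ValueError("need at least 2 rater maps")
    y = ref.z[reg]
    X = np.stack([m.z[reg] for m in raters])  # (k raters, n voxels)
    xbar = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0.0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} voxels with zero rater s.d.")
    scores = (y[keep] - xbar[keep]) / sd[keep]
    if scores.size < 2:
        raise UndefinedMetricError("fewer than 2 usable voxels after drops")
    return StandardizedComparison(
        z_bar=float(scores.mean()),
        sd_z=float(scores.std(ddof=1)),
        n_voxels=int(scores.size),
        per_voxel=scores,
    )


def summarize_fisher_table(values: pd.DataFrame, value_col: str = "fisher_z",
                           by: str | list[str] | None = None, ndigits: int = 3) -> dict:
    """Mean/min/max of a labelled collection of Fisher z values, rounded
    for reporting; optionally also per condition label."""
    if len(values) == 0:
        raise ValueError("empty Fisher z table")
    v = values[value_col].to_numpy(dtype=np.float64)
    out = {
        "mean": round(float(v.mean()), ndigits),
        "min": round(float(v.min()), ndigits),
        "max": round(float(v.max()), ndigits),
        "n": int(v.size),
    }
    if by is not None:
        out["by"] = {
            str(key): {
                "mean": round(float(g[value_col].mean()), ndigits),
                "min": round(float(g[value_col].min()), ndigits),
                "max": round(float(g[value_col].max()), ndigits),
                "n": int(len(g)),
            }
            for key, g in values.groupby(by)
        }
    return out


def load_published_group_correlations() -> pd.DataFrame:
    """Published per-rater group-level activation-map spatial correlations
    (Fisher's z) against the reference, by side and stimulus condition.

    Long table with columns rater, side, condition, fisher_z (32 rows:
    8 raters × 2 sides × {ipsilateral, contralateral}).
    """
    with resources.files("cordmaskvar.data").joinpath(
            "group_fisher_z_published.csv").open() as fh:
        return pd.read_csv(fh)
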
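"""Mask-agreement and image-quality metrics.

All metrics compare a rater mask (RM) against the reference mask (REF)
or read intensities from the temporal-mean-like image:

* ``dsc`` — Dice similarity coefficient, 2|REF∩RM| / (|REF|+|RM|),
  over the full volume or a single axial slice.
* ``logit`` — the transform applied to DSC before linear modelling.
* ``adjacent_region`` — the peri-cord region obtained by iterated
  in-plane morphological dilation of REF, minus REF itself.
* ``cv_adjacent`` / ``adjacent_sc_ratio`` — slicewise image-quality
  metrics of the adjacent region (CSF-consistency and cord/CSF contrast).
* ``gm_wm_contrast`` — ratio of mean signal in atlas gray matter to
  atlas white matter; a registration-accuracy proxy maximal under
  perfect alignment.
* ``build_tables`` — materialises the long slicewise table and the
  rater×dataset cell table for a simulated study bundle.

Masks and images may be passed as plain boolean/float arrays or as the
:class:`BinaryMask` / :class:`Volume` containers; the slice axis is
always the third array axis.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from cordmaskvar.errors import UndefinedMetricError

LOGIT_EPS = 1e-6


@dataclass
class Volume:
    """A 3-D scalar intensity lattice; slice axis is axis 2."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")


@dataclass
class BinaryMask:
    """A boolean lattice on a Volume's grid; plays the REF or RM role."""

    data: np.ndarray
    role: str = "rater"

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask data must be 3-D")


def _arr(x) -> np.ndarray:
    if isinstance(x, (Volume, BinaryMask)):
        return x.data
    return np.asarray(x)


def _mask(x) -> np.ndarray:
    return _arr(x).astype(bool)


# 8-connected in-plane structuring element, applied slice by slice.
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def dsc(ref, rm, slice_index: int | None = None) -> float:
    """Dice similarity coefficient over the volume or one axial slice.

    Symmetric in its arguments and bounded in [0, 1]. Raises
    :class:`UndefinedMetricError` when both masks are empty in scope.
    """
    a, b = _mask(ref), _mask(rm)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    if slice_index is not None:
        a, b = a[:, :, slice_index], b[:, :, slice_index]
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise UndefinedMetricError("DSC undefined: both masks empty in scope")
    return 2.0 * int((a & b).sum()) / (na + nb)


def logit(p, eps: float = LOGIT_EPS):
    """ln(p/(1-p)) with p clamped to [eps, 1-eps]; handles 0 and 1."""
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def slice_inclusion(mask_stack, n_trim: int = 1) -> np.ndarray:
    """Indices of retained slices after trimming ``n_trim`` from each end.

    The most superior and inferior slices carry the poorest image quality
    and are excluded from all slicewise analyses. ``mask_stack`` may be a
    3-D array (its slice count is used) or an integer slice count.
    """
    n_slices = int(mask_stack) if np.isscalar(mask_stack) else _arr(mask_stack).shape[2]
    if n_trim < 0:
        raise ValueError("n_trim must be nonnegative")
    if 2 * n_trim >= n_slices:
        raise ValueError(f"trimming {n_trim} from each end of {n_slices} slices leaves none")
    return np.arange(n_trim, n_slices - n_trim)


def adjacent_region(ref, n_dilate: int = 2) -> np.ndarray:
    """Peri-cord region: per-slice 8-connected dilation of REF, minus REF.

    ``n_dilate`` is the number of one-voxel dilation iterations (the
    conventional reading of an "n-voxel dilation"); dilation is strictly
    in-plane, matching the 1×1×3 mm anisotropy, and clips at image
    borders. The result is always disjoint from ``ref``.
    """
    m = _mask(ref)
    out = np.zeros_like(m)
    for s in range(m.shape[2]):
        sl = m[:, :, s]
        if not sl.any():
            continue
        dil = ndimage.binary_dilation(sl, structure=_STRUCT_8, iterations=n_dilate)
        out[:, :, s] = dil & ~sl
    return out


def cv_adjacent(image, ref, slice_index: int, n_dilate: int = 2,
                adjacent: np.ndarray | None = None) -> float:
    """Coefficient of variation of intensities adjacent to REF on a slice.

    Sample (n-1) standard deviation over mean; captures inconsistent
    peri-cord (CSF) signal. Scale-invariant under positive rescaling.
    """
    img = _arr(image)
    adj = _mask(adjacent) if adjacent is not None else adjacent_region(ref, n_dilate)
    sel = img[:, :, slice_index][adj[:, :, slice_index]]
    if sel.size < 2:
        raise UndefinedMetricError("CV undefined: fewer than 2 adjacent voxels")
    mean = float(sel.mean())
    if mean == 0.0:
        raise UndefinedMetricError("CV undefined: zero mean of adjacent intensities")
    return float(sel.std(ddof=1)) / mean


def adjacent_sc_ratio(image, ref, slice_index: int, n_dilate: int = 2,
                      adjacent: np.ndarray | None = None) -> float:
    """Mean adjacent intensity over mean cord intensity on a slice.

    Values below 1 indicate contrast breakdown (CSF darker than cord),
    which makes the cord boundary harder to contour.
    """
    img = _arr(image)
    m = _mask(ref)
    adj = _mask(adjacent) if adjacent is not None else adjacent_region(ref, n_dilate)
    cord = img[:, :, slice_index][m[:, :, slice_index]]
    near = img[:, :, slice_index][adj[:, :, slice_index]]
    if cord.size == 0 or near.size == 0:
        raise UndefinedMetricError("Adjacent:SC undefined: empty region on slice")
    cord_mean = float(cord.mean())
    if cord_mean <= 0:
        raise UndefinedMetricError("Adjacent:SC undefined: nonpositive cord mean")
    return float(near.mean()) / cord_mean


def gm_wm_contrast(image, gm, wm) -> float:
    """Mean GM intensity over mean WM intensity (atlas regions).

    Under perfect alignment of the image with the atlas this ratio is
    maximal; misregistration mixes tissue classes across the two regions
    and pulls it toward 1. The log-transform for inference is taken by
    the caller.
    """
    img, g, w = _arr(image), _mask(gm), _mask(wm)
    if not g.any() or not w.any():
        raise UndefinedMetricError("GM:WM undefined: empty atlas region")
    if (g & w).any():
        raise ValueError("GM and WM atlas regions must be disjoint")
    wm_mean = float(img[w].mean())
    if wm_mean <= 0:
        raise UndefinedMetricError("GM:WM undefined: nonpositive WM mean")
    return float(img[g].mean()) / wm_mean


# ---------------------------------------------------------------------------
# Study-level tables


def volume_dsc_from_slices(per_slice: pd.DataFrame) -> float:
    """Volume DSC from slicewise counts: (Σ 2|∩|) / (Σ (|REF|+|RM|))."""
    return 2.0 * per_slice["n_intersection"].sum() / per_slice["n_union_sizes"].sum()


def build_tables(study_dir: str | os.PathLike, n_trim: int = 1, n_dilate: int = 2,
                 registration_shift_fn=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the slicewise metric table and the rater×dataset cell table.

    Reads a study bundle written by :func:`cordmaskvar.phantom.generate_study`.
    The slicewise table has one record per (dataset, rater, included slice)
    with DSC, logit DSC, adjacent-region CV and Adjacent:SC ratio. The cell
    table has one record per rater×dataset with the mean slicewise logit
    DSC and the GM:WM contrast of the image after the rater-specific
    registration error; the reference rater appears as ``REF`` with zero
    registration error.

    ``registration_shift_fn(rater_mask, ref_mask)`` maps a rater mask to
    per-slice in-plane shifts (mm); the default derives the shift from the
    per-slice centroid offset between rater and reference mask, the
    displacement a mask-weighted registration would track.
    """
    from cordmaskvar import nifti
    from cordmaskvar.phantom import PhantomVolume, centroid_shift_mm, simulate_misregistration

    study_dir = os.fspath(study_dir)
    manifest_path = os.path.join(study_dir, "manifest.json")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"missing study manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    if registration_shift_fn is None:
        registration_shift_fn = centroid_shift_mm

    slice_rows, cell_rows = [], []
    for ds in manifest["datasets"]:
        ds_id = ds["id"]
        image, voxel_size = nifti.read_volume(os.path.join(study_dir, ds["image"]))
        ref = nifti.read_mask(os.path.join(study_dir, ds["reference_mask"]))
        gm = nifti.read_mask(os.path.join(study_dir, ds["gm_mask"]))
        wm = nifti.read_mask(os.path.join(study_dir, ds["wm_mask"]))
        included = slice_inclusion(ref.shape[2], n_trim)
        adj = adjacent_region(ref, n_dilate)

        quality = {
            s: (cv_adjacent(image, ref, s, adjacent=adj),
                adjacent_sc_ratio(image, ref, s, adjacent=adj))
            for s in included
        }

        vol = PhantomVolume.from_arrays(image, ref, gm, wm, voxel_size)
        # Reference row: perfect agreement, zero registration error.
        cell_rows.append({
            "rater": "REF", "dataset": ds_id,
            "mean_logit_dsc": logit(1.0),
            "gm_wm_ratio": gm_wm_contrast(image, gm, wm),
        })

        for rater, rel in ds["rater_masks"].items():
            rm = nifti.read_mask(os.path.join(study_dir, rel))
            logit_vals = []
            for s in included:
                cv, ratio = quality[s]
                d = dsc(ref, rm, slice_index=int(s))
                ld = logit(d)
                logit_vals.append(ld)
                slice_rows.append({
                    "dataset": ds_id, "rater": rater, "slice": int(s),
                    "dsc": d, "logit_dsc": ld,
                    "cv_adjacent": cv, "adjacent_sc_ratio": ratio,
                    "included": True,
                })
            shifts = registration_shift_fn(rm, ref, voxel_size)
            shifted = simulate_misregistration(vol, shifts, per_slice=True)
            cell_rows.append({
                "rater": rater, "dataset": ds_id,
                "mean_logit_dsc": float(np.mean(logit_vals)),
                "gm_wm_ratio": gm_wm_contrast(shifted.image, gm, wm),
            })

    slice_table = pd.DataFrame(slice_rows)
    cell_table = pd.DataFrame(cell_rows)
    cell_table["log_gm_wm"] = np.log(cell_table["gm_wm_ratio"])
    return slice_table, cell_table
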
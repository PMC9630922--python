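"""Synthetic spinal-cord phantom and rater simulator.

Generates axial-slice-stack volumes that emulate a temporal-mean
T2*-weighted functional image of the cervical cord: an elliptical cord
cross-section containing a four-lobed gray-matter "butterfly" inside
white matter, surrounded by CSF whose brightness varies along the cord
(including slices where CSF drops below cord signal, i.e. Adjacent:SC
ratio < 1). On top of the geometry it simulates:

* raters of varying skill (:class:`RaterModel`): signed morphological
  bias, per-slice contour jitter, and random boundary-voxel flips;
* imperfect spatial normalization (:func:`simulate_misregistration`):
  in-plane translation of the image relative to untouched atlas masks;
* lateralised activation z-maps (:func:`generate_activation_map`).

Everything is a pure function of its spec plus seed; per-rater,
per-dataset seeds are spawned from one master seed so adding a rater
never changes anyone else's data.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from cordmaskvar.errors import GeometryError, UndefinedMetricError

logger = logging.getLogger(__name__)

_STRUCT_8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Specs


def _per_slice(value, n_slices: int) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        return np.full(n_slices, float(arr))
    if arr.shape[0] != n_slices:
        raise ValueError(f"per-slice value has length {arr.shape[0]}, expected {n_slices}")
    return arr.astype(np.float64)


@dataclass
class PhantomSpec:
    """Geometry, contrast, and noise of one synthetic dataset.

    The grid defaults to the acquisition this emulates: 128×44 in-plane
    voxels of 1×1 mm, 25 axial slices of 3 mm. ``cord_center`` and
    ``cord_radii`` are per-slice (rows = slices) pairs in voxel units on
    the (anterior-posterior, left-right) in-plane axes; ``csf_mean``,
    ``wm_mean``, ``gm_mean`` and ``noise_sd`` may be scalars or
    per-slice arrays. Slice index increases superior → inferior.
    """

    grid_shape: tuple[int, int, int] = (128, 44, 25)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    cord_center: np.ndarray | None = None
    cord_radii: np.ndarray | tuple[float, float] = (3.7, 5.7)
    gm_scale: float = 0.45
    csf_mean: np.ndarray | float = 160.0
    wm_mean: np.ndarray | float = 100.0
    gm_mean: np.ndarray | float = 120.0
    noise_sd: np.ndarray | float = 5.0
    seed: int = 0

    def __post_init__(self):
        n = self.grid_shape[2]
        if self.cord_center is None:
            # gentle smooth drift of the cord position along the cord
            t = np.linspace(0.0, np.pi, n)
            self.cord_center = np.column_stack([
                self.grid_shape[0] / 2.0 + 1.5 * np.sin(t),
                self.grid_shape[1] / 2.0 + 1.0 * np.cos(t),
            ])
        self.cord_center = np.atleast_2d(np.asarray(self.cord_center, dtype=np.float64))
        if self.cord_center.shape[0] == 1:
            self.cord_center = np.repeat(self.cord_center, n, axis=0)
        radii = np.atleast_2d(np.asarray(self.cord_radii, dtype=np.float64))
        if radii.shape[0] == 1:
            radii = np.repeat(radii, n, axis=0)
        self.cord_radii = radii
        self.csf_mean = _per_slice(self.csf_mean, n)
        self.wm_mean = _per_slice(self.wm_mean, n)
        self.gm_mean = _per_slice(self.gm_mean, n)
        self.noise_sd = _per_slice(self.noise_sd, n)
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.gm_scale < 1.0):
            raise ValueError("gm_scale must lie in (0, 1)")
        for name in ("csf_mean", "wm_mean", "gm_mean", "noise_sd"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} must be finite and nonnegative")
        if np.any(self.cord_radii <= 0):
            raise ValueError("cord radii must be positive")
        lo = self.cord_center - self.cord_radii
        hi = self.cord_center + self.cord_radii
        dims = np.asarray(self.grid_shape[:2], dtype=np.float64)
        if np.any(lo <= 0.0) or np.any(hi >= dims - 1.0):
            raise GeometryError("cord ellipse does not fit strictly inside the grid")


@dataclass
class PhantomVolume:
    """A phantom image with its ground-truth cord / GM / WM masks."""

    image: np.ndarray
    cord_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    spec: PhantomSpec | None = None

    @classmethod
    def from_arrays(cls, image, cord, gm, wm, voxel_size_mm=(1.0, 1.0, 3.0)):
        return cls(np.asarray(image, dtype=np.float64), np.asarray(cord, dtype=bool),
                   np.asarray(gm, dtype=bool), np.asarray(wm, dtype=bool),
                   tuple(voxel_size_mm))

    def __post_init__(self):
        shapes = {self.image.shape, self.cord_mask.shape, self.gm_mask.shape, self.wm_mask.shape}
        if len(shapes) != 1:
            raise ValueError("image and masks must share one grid shape")
        if ((self.gm_mask | self.wm_mask) != self.cord_mask).any():
            raise ValueError("GM ∪ WM must equal the cord mask")
        if (self.gm_mask & self.wm_mask).any():
            raise ValueError("GM and WM must be disjoint")


@dataclass
class RaterModel:
    """Parametric stand-in for a human rater contouring the cord.

    ``bias_voxels`` applies |bias| morphological dilations (positive:
    over-segmentation) or erosions (negative) per slice;
    ``slice_jitter_mm`` is the s.d. of a random in-plane translation of
    the whole contour per slice (rounded to voxels); ``flip_rate`` is
    the per-voxel probability of flipping membership within the boundary
    band (slice-wise Chebyshev distance ≤ 1 of the mask edge) and may be
    a scalar or a per-slice array. All parameters zero reproduces the
    reference mask exactly.
    """

    name: str = "rater"
    bias_voxels: int = 0
    flip_rate: float | np.ndarray = 0.0
    slice_jitter_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.flip_rate) >= 1.0) or np.any(np.asarray(self.flip_rate) < 0.0):
            raise ValueError("flip_rate must lie in [0, 1)")
        if self.slice_jitter_mm < 0:
            raise ValueError("slice_jitter_mm must be nonnegative")


def default_rater_ladder() -> list[RaterModel]:
    """Eight raters spanning expert to novice contouring quality.

    The ladder is tuned so study-wide mean DSC spans roughly the
    0.65–0.95 range seen across raters of varying experience; two
    raters carry a systematic bias (consistent over/under-contouring)
    rather than pure noise.
    """
    return [
        RaterModel("A", 0, 0.02, 0.0),
        RaterModel("B", 0, 0.04, 0.15),
        RaterModel("C", 0, 0.06, 0.20),
        RaterModel("D", 0, 0.09, 0.25),
        RaterModel("E", 0, 0.12, 0.30),
        RaterModel("F", 1, 0.06, 0.20),
        RaterModel("G", -1, 0.18, 0.40),
        RaterModel("H", 1, 0.22, 0.50),
    ]


@dataclass
class StudyConfig:
    """Conditions of a full simulated study.

    Defaults emulate the design this pipeline analyses: 21 datasets,
    8 simulated raters plus an implicit perfect reference, 25 slices of
    which the ends are trimmed downstream, and left/right-lateralised
    activation. ``difficulty_gain`` couples each slice's flip rate to
    its constructed image quality (low Adjacent:SC contrast and high
    adjacent CV make a slice harder to contour), which is the mechanism
    behind the DSC–image-quality correlations the inference stage tests.
    """

    n_datasets: int = 21
    rater_models: list[RaterModel] = field(default_factory=default_rater_ladder)
    phantom_specs: list[PhantomSpec] | None = None
    grid_shape: tuple[int, int, int] = (128, 44, 25)
    act_amplitude: float = 3.5
    act_extent: tuple[int, int] = (8, 17)
    act_noise_sd: float = 1.0
    difficulty_gain: float = 0.6
    master_seed: int = 20221020

    @classmethod
    def demo(cls, master_seed: int = 7) -> "StudyConfig":
        """Small configuration (4 raters, 6 datasets, 12 slices) for smoke runs."""
        return cls(
            n_datasets=6,
            rater_models=default_rater_ladder()[:3] + [default_rater_ladder()[-1]],
            grid_shape=(64, 44, 12),
            act_extent=(3, 9),
            master_seed=master_seed,
        )


# ---------------------------------------------------------------------------
# Generators


def _ellipse(shape2d, center, radii) -> np.ndarray:
    rr, cc = np.ogrid[: shape2d[0], : shape2d[1]]
    u = (rr - center[0]) / radii[0]
    v = (cc - center[1]) / radii[1]
    return u * u + v * v <= 1.0


def _butterfly(shape2d, center, radii, gm_scale) -> np.ndarray:
    """Four mirrored GM lobes plus a central commissure bridge, in the
    cord ellipse's normalised coordinates."""
    s = gm_scale / 0.45
    gm = np.zeros(shape2d, dtype=bool)
    # (u offset, v offset, u semi-axis, v semi-axis) in normalised coords;
    # dorsal lobes (posterior, +u) slightly longer than ventral ones
    lobes = [
        (0.42, 0.34, 0.40, 0.30),
        (0.42, -0.34, 0.40, 0.30),
        (-0.36, 0.30, 0.34, 0.28),
        (-0.36, -0.30, 0.34, 0.28),
        (0.0, 0.0, 0.20, 0.45),  # commissure bridge
    ]
    for du, dv, au, av in lobes:
        gm |= _ellipse(
            shape2d,
            (center[0] + du * radii[0], center[1] + dv * radii[1]),
            (max(au * s * radii[0], 0.6), max(av * s * radii[1], 0.6)),
        )
    return gm


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Render a phantom volume from its spec.

    The image is the per-voxel tissue mean (CSF outside the cord, WM/GM
    inside) plus independent zero-mean Gaussian noise of per-slice s.d.
    ``noise_sd``; the masks are the noiseless geometry.
    """
    spec.validate()
    nr, nc, ns = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    image = np.empty(spec.grid_shape, dtype=np.float64)
    cord = np.zeros(spec.grid_shape, dtype=bool)
    gm = np.zeros(spec.grid_shape, dtype=bool)
    for s in range(ns):
        c, r = spec.cord_center[s], spec.cord_radii[s]
        cord_s = _ellipse((nr, nc), c, r)
        gm_s = _butterfly((nr, nc), c, r, spec.gm_scale) & cord_s
        cord[:, :, s] = cord_s
        gm[:, :, s] = gm_s
        sl = np.full((nr, nc), spec.csf_mean[s])
        sl[cord_s] = spec.wm_mean[s]
        sl[gm_s] = spec.gm_mean[s]
        if spec.noise_sd[s] > 0:
            sl = sl + rng.normal(0.0, spec.noise_sd[s], size=(nr, nc))
        image[:, :, s] = sl
    wm = cord & ~gm
    return PhantomVolume(image, cord, gm, wm, tuple(spec.voxel_size_mm), spec)


def _shift2d(plane: np.ndarray, dr: int, dc: int):
    """Integer in-plane translation with edge replication (nearest fill)."""
    if dr == 0 and dc == 0:
        return plane.copy()
    return ndimage.shift(plane, (dr, dc), order=0, mode="nearest")


def simulate_rater_mask(ref: np.ndarray, model: RaterModel,
                        voxel_size_mm=(1.0, 1.0, 3.0),
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate one rater's contour of the reference cord mask.

    Per axial slice, in order: signed morphological bias, random
    in-plane jitter translation (rounded to voxels), then independent
    flips of boundary-band voxels with probability ``flip_rate``.
    A slice emptied by erosion is replaced by a single voxel at the
    slice centroid of the reference, with a logged warning.
    """
    ref = np.asarray(ref).astype(bool)
    ns = ref.shape[2]
    if rng is None:
        rng = np.random.default_rng(model.seed)
    flip = _per_slice(model.flip_rate, ns)
    out = np.zeros_like(ref)
    for s in range(ns):
        m = ref[:, :, s].copy()
        if not m.any():
            continue
        if model.bias_voxels > 0:
            m = ndimage.binary_dilation(m, structure=_STRUCT_8, iterations=model.bias_voxels)
        elif model.bias_voxels < 0:
            eroded = ndimage.binary_erosion(m, structure=_STRUCT_8,
                                            iterations=-model.bias_voxels)
            if not eroded.any():
                rr, cc = np.nonzero(m)
                eroded = np.zeros_like(m)
                eroded[int(round(rr.mean())), int(round(cc.mean()))] = True
                logger.warning(
                    "rater %s erosion emptied slice %d; kept single centroid voxel",
                    model.name, s)
            m = eroded
        if model.slice_jitter_mm > 0:
            jitter = rng.normal(0.0, model.slice_jitter_mm, size=2)
            dr = int(np.round(jitter[0] / voxel_size_mm[0]))
            dc = int(np.round(jitter[1] / voxel_size_mm[1]))
            m = _shift2d(m, dr, dc).astype(bool)
        if flip[s] > 0:
            edge = m & ~ndimage.binary_erosion(m, structure=_STRUCT_8)
            band = ndimage.binary_dilation(edge, structure=_STRUCT_8)
            flips = band & (rng.random(m.shape) < flip[s])
            m = m ^ flips
        out[:, :, s] = m
    return out


def centroid_shift_mm(rater_mask: np.ndarray, ref_mask: np.ndarray,
                      voxel_size_mm=(1.0, 1.0, 3.0)) -> np.ndarray:
    """Per-slice in-plane displacement (mm) of the rater-mask centroid
    relative to the reference — the registration error a mask-weighted
    normalization would inherit from the contour."""
    rm = np.asarray(rater_mask).astype(bool)
    ref = np.asarray(ref_mask).astype(bool)
    ns = ref.shape[2]
    shifts = np.zeros((ns, 2))
    for s in range(ns):
        a, b = rm[:, :, s], ref[:, :, s]
        if not a.any() or not b.any():
            continue
        ca = np.array(ndimage.center_of_mass(a))
        cb = np.array(ndimage.center_of_mass(b))
        shifts[s] = (ca - cb) * np.asarray(voxel_size_mm[:2])
    return shifts


def simulate_misregistration(vol: PhantomVolume, shift_mm, per_slice: bool = False) -> PhantomVolume:
    """Translate the image in-plane relative to the untouched atlas masks.

    Nearest-neighbour (integer-voxel) resampling; ``shift_mm`` is one
    (row, col) pair, or one pair per slice when ``per_slice`` is true.
    Zero shift returns an identical copy. Raises :class:`GeometryError`
    if the cord would leave the grid.
    """
    shift_mm = np.asarray(shift_mm, dtype=np.float64)
    ns = vol.image.shape[2]
    if per_slice and shift_mm.ndim == 2:
        shifts = shift_mm
    else:
        shifts = np.repeat(np.atleast_2d(shift_mm), ns, axis=0)
    vox = np.asarray(vol.voxel_size_mm[:2])
    dvox = np.round(shifts / vox).astype(int)

    # the cord must stay inside the grid after the shift
    rr, cc, ss = np.nonzero(vol.cord_mask)
    for s in np.unique(ss):
        sel = ss == s
        dr, dc = dvox[s]
        if (rr[sel].min() + dr < 0 or rr[sel].max() + dr >= vol.image.shape[0]
                or cc[sel].min() + dc < 0 or cc[sel].max() + dc >= vol.image.shape[1]):
            raise GeometryError(f"shift pushes the cord out of the grid on slice {s}")

    image = np.empty_like(vol.image)
    for s in range(ns):
        image[:, :, s] = _shift2d(vol.image[:, :, s], int(dvox[s, 0]), int(dvox[s, 1]))
    return PhantomVolume(image, vol.cord_mask.copy(), vol.gm_mask.copy(),
                         vol.wm_mask.copy(), vol.voxel_size_mm, vol.spec)


def generate_activation_map(vol: PhantomVolume, side: str, amplitude: float,
                            extent_slices: tuple[int, int], noise_sd: float,
                            seed: int | np.random.Generator):
    """Simulate a participant-level z-statistic map with a lateralised blob.

    The map equals ``amplitude`` inside the designated hemicord over the
    slice range [extent_slices[0], extent_slices[1]) plus zero-mean
    Gaussian noise everywhere in the analysis mask (the cord).
    Returns an :class:`cordmaskvar.activation.ActivationMap`.
    """
    from cordmaskvar.activation import ActivationMap, hemicord_partition

    part = hemicord_partition(vol.cord_mask)
    hemi = part.left if side == "left" else part.right
    if not hemi.any():
        raise UndefinedMetricError(f"{side} hemicord is empty")
    lo, hi = extent_slices
    blob = hemi.copy()
    blob[:, :, :lo] = False
    blob[:, :, hi:] = False
    z = np.zeros_like(vol.image)
    z[blob] = amplitude
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        z[vol.cord_mask] += rng.normal(0.0, noise_sd, size=int(vol.cord_mask.sum()))
    return ActivationMap(z=z, analysis_mask=vol.cord_mask.copy(), stimulus_side=side,
                         level="participant")


# ---------------------------------------------------------------------------
# Full study bundles


def _dataset_spec(config: StudyConfig, d: int, rng: np.random.Generator) -> PhantomSpec:
    """Default per-dataset phantom spec: dataset-level contrast and noise
    heterogeneity on top of a shared superior→inferior CSF contrast decline."""
    nr, nc, ns = config.grid_shape
    base_csf = np.linspace(170.0, 75.0, ns)  # inferior slices lose CSF contrast
    csf = base_csf + rng.uniform(-45.0, 35.0)
    noise = rng.uniform(3.0, 7.0) * rng.uniform(0.7, 1.4, size=ns)
    radii = (rng.uniform(3.3, 4.1), rng.uniform(5.2, 6.2))
    return PhantomSpec(
        grid_shape=config.grid_shape,
        cord_radii=radii,
        csf_mean=csf,
        wm_mean=100.0,
        gm_mean=120.0,
        noise_sd=noise,
        seed=int(rng.integers(2**31)),
    )


def _difficulty_flip_rates(spec: PhantomSpec, base_rate: float, gain: float) -> np.ndarray:
    """Per-slice flip rates coupled to constructed image quality.

    Slices with low Adjacent:SC contrast (CSF ≈ cord signal, or darker)
    and high adjacent CV are harder to contour, so their flip rate
    rises; a dataset whose overall contrast is poor is harder for every
    rater, which is what lets the dataset factor carry variance in the
    downstream ANOVA.
    """
    cord_mean = 0.75 * spec.wm_mean + 0.25 * spec.gm_mean  # rough GM area fraction
    ratio = spec.csf_mean / cord_mean
    cv = spec.noise_sd / np.maximum(spec.csf_mean, 1e-9)

    def _std(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    slice_difficulty = 0.5 * (_std(cv) - _std(ratio))
    dataset_difficulty = np.clip(1.0 + 2.0 * gain * (1.15 - float(ratio.mean())), 0.4, 2.0)
    return np.clip(base_rate * dataset_difficulty * (1.0 + gain * slice_difficulty),
                   0.005, 0.45)


def generate_study(config: StudyConfig, out_dir: str | os.PathLike) -> dict:
    """Write a full study bundle to ``out_dir`` and return its manifest.

    Per dataset: phantom image, reference cord mask, GM/WM atlas masks,
    one simulated mask per rater, and left/right activation maps, all as
    NIfTI; a JSON manifest lists every file with its role and seed.
    Fully reproducible from ``master_seed``.
    """
    from cordmaskvar import nifti

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    root_ss = np.random.SeedSequence(config.master_seed)
    spec_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.master_seed, spawn_key=(0,)))

    specs = config.phantom_specs
    if specs is None:
        specs = [_dataset_spec(config, d, spec_rng) for d in range(config.n_datasets)]
    if len(specs) != config.n_datasets:
        raise ValueError("need one PhantomSpec per dataset")

    manifest = {
        "master_seed": config.master_seed,
        "n_datasets": config.n_datasets,
        "raters": [m.name for m in config.rater_models],
        "grid_shape": list(config.grid_shape),
        "activation": {
            "amplitude": config.act_amplitude,
            "extent_slices": list(config.act_extent),
            "noise_sd": config.act_noise_sd,
        },
        "datasets": [],
    }

    for d, spec in enumerate(specs):
        ds_id = f"ds{d + 1:02d}"
        ds_dir = os.path.join(out_dir, ds_id)
        os.makedirs(ds_dir, exist_ok=True)
        vol = generate_phantom(spec)
        vx = vol.voxel_size_mm
        rel = lambda name: f"{ds_id}/{name}"  # noqa: E731
        nifti.write_volume(os.path.join(ds_dir, "image.nii.gz"), vol.image, vx)
        nifti.write_mask(os.path.join(ds_dir, "cord_ref.nii.gz"), vol.cord_mask, vx)
        nifti.write_mask(os.path.join(ds_dir, "atlas_gm.nii.gz"), vol.gm_mask, vx)
        nifti.write_mask(os.path.join(ds_dir, "atlas_wm.nii.gz"), vol.wm_mask, vx)

        entry = {
            "id": ds_id,
            "image": rel("image.nii.gz"),
            "reference_mask": rel("cord_ref.nii.gz"),
            "gm_mask": rel("atlas_gm.nii.gz"),
            "wm_mask": rel("atlas_wm.nii.gz"),
            "rater_masks": {},
            "activation_maps": {},
            "seeds": {"phantom": int(spec.seed)},
        }

        for r, model in enumerate(config.rater_models):
            ss = np.random.SeedSequence(entropy=config.master_seed, spawn_key=(1, d, r))
            rater_seed = int(ss.generate_state(1)[0] % (2**31))
            flip = model.flip_rate
            if config.difficulty_gain > 0 and np.ndim(model.flip_rate) == 0:
                flip = _difficulty_flip_rates(spec, float(model.flip_rate),
                                              config.difficulty_gain)
            eff = replace(model, flip_rate=flip, seed=rater_seed)
            rm = simulate_rater_mask(vol.cord_mask, eff, vx)
            name = f"mask_rater_{model.name}.nii.gz"
            nifti.write_mask(os.path.join(ds_dir, name), rm, vx)
            entry["rater_masks"][model.name] = rel(name)
            entry["seeds"][f"rater_{model.name}"] = rater_seed

        for side in ("left", "right"):
            ss = np.random.SeedSequence(entropy=config.master_seed,
                                        spawn_key=(2, d, 0 if side == "left" else 1))
            act_seed = int(ss.generate_state(1)[0] % (2**31))
            amap = generate_activation_map(vol, side, config.act_amplitude,
                                           config.act_extent, config.act_noise_sd,
                                           act_seed)
            name = f"zmap_{side}.nii.gz"
            nifti.write_volume(os.path.join(ds_dir, name), amap.z, vx)
            entry["activation_maps"][side] = rel(name)
            entry["seeds"][f"activation_{side}"] = act_seed

        manifest["datasets"].append(entry)

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
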
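"""End-to-end orchestration: simulate → metrics → inference → activation → report.

Each stage reads only files written by earlier stages (plus the run
configuration), writes tidy CSV/JSON under the run directory with a
provenance block, and fails with a stage-tagged error. Two runs from
one configuration are byte-identical in all tabular outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from cordmaskvar import agreement, nifti
from cordmaskvar.activation import (ActivationMap, condition_regions, hemicord_partition,
                                    spatial_correlation, standardize_reference,
                                    threshold_map)
from cordmaskvar.errors import StageError
from cordmaskvar.inference import maxt_permutation, two_way_anova
from cordmaskvar.phantom import RaterModel, StudyConfig, centroid_shift_mm, generate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    out_dir: str = "results/run"
    study: StudyConfig = field(default_factory=StudyConfig)
    n_trim: int = 1
    n_dilate: int = 2
    anova_responses: tuple[str, ...] = ("mean_logit_dsc", "log_gm_wm")
    perm_outcomes: tuple[str, ...] = ("cv_adjacent", "adjacent_sc_ratio")
    n_perm: int = 5000
    perm_seed: int = 17
    z_thresh: float = 2.3
    corr_method: str = "pearson"
    rater_act_noise_sd: float = 0.5
    make_plots: bool = False

    @property
    def study_dir(self) -> str:
        return os.path.join(self.out_dir, "study")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        study_raw = raw.pop("study", {})
        raters = study_raw.pop("rater_models", None)
        study = StudyConfig(**study_raw)
        if raters is not None:
            study.rater_models = [RaterModel(**r) for r in raters]
        for key in ("anova_responses", "perm_outcomes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(study=study, **raw)

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        d["study"]["phantom_specs"] = None  # specs are derived from master_seed
        return json.loads(json.dumps(d, default=lambda o: str(o)))


@dataclass
class ReportBundle:
    """All report tables of one run (heatmap tables with margins, the
    correlation/p table, the z̄ ± SD table, and the Fisher z table)."""

    dsc_heatmap: pd.DataFrame
    gmwm_heatmap: pd.DataFrame
    activation_heatmap: pd.DataFrame
    dsc_margins: dict
    correlation_table: pd.DataFrame
    standardized_table: pd.DataFrame
    group_fisher_table: pd.DataFrame


def _write_json(path: str, payload: dict, config: RunConfig) -> None:
    payload = dict(payload)
    payload["provenance"] = config.provenance()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)


def marginal_means(table: pd.DataFrame) -> dict:
    """Row and column margins of a rater×dataset table with 95% CIs.

    CI = mean ± 1.96 · (sample s.d. / √m) over the margin of size m; a
    margin of size 1 is reported as the point value.
    """
    if table.isna().any().any():
        raise ValueError("marginal means require a complete table")

    def _margin(df: pd.DataFrame, axis: int) -> pd.DataFrame:
        mean = df.mean(axis=axis)
        m = df.shape[axis]
        if m > 1:
            half = 1.96 * df.std(axis=axis, ddof=1) / np.sqrt(m)
        else:
            half = pd.Series(0.0, index=mean.index)
        return pd.DataFrame({"mean": mean, "ci_low": mean - half, "ci_high": mean + half})

    return {"rows": _margin(table, axis=1), "cols": _margin(table, axis=0)}


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig) -> dict:
    os.makedirs(config.out_dir, exist_ok=True)
    return generate_study(config.study, config.study_dir)


def stage_metrics(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    slice_table, cell_table = agreement.build_tables(
        config.study_dir, n_trim=config.n_trim, n_dilate=config.n_dilate)
    slice_table.to_csv(os.path.join(config.out_dir, "slice_metrics.csv"), index=False)
    cell_table.to_csv(os.path.join(config.out_dir, "cell_metrics.csv"), index=False)
    return slice_table, cell_table


def stage_anova(config: RunConfig, cell_table: pd.DataFrame) -> dict:
    results = {}
    for response in config.anova_responses:
        # the DSC response compares the 8 raters to the reference, so the
        # reference's own (perfect) cells are excluded; GM:WM keeps all 9
        cells = cell_table if response == "log_gm_wm" else cell_table[cell_table["rater"] != "REF"]
        res = two_way_anova(cells, response)
        results[response] = {
            "factors": res.factors.reset_index().to_dict(orient="records"),
            "df_resid": res.df_resid,
            "ss_resid": res.ss_resid,
            "ss_total": res.ss_total,
            "degenerate": res.degenerate,
        }
        res.factors.to_csv(os.path.join(config.out_dir, f"anova_{response}.csv"))
    _write_json(os.path.join(config.out_dir, "anova.json"), results, config)
    return results


def stage_permtest(config: RunConfig, slice_table: pd.DataFrame) -> dict:
    results = {}
    for i, outcome in enumerate(config.perm_outcomes):
        res = maxt_permutation(slice_table, outcome, n_perm=config.n_perm,
                               seed=config.perm_seed + i)
        frame = res.to_frame()
        frame.to_csv(os.path.join(config.out_dir, f"permtest_{outcome}.csv"), index=False)
        res.rho_by_dataset.to_csv(
            os.path.join(config.out_dir, f"rho_by_dataset_{outcome}.csv"), index=False)
        results[outcome] = {
            "per_rater": frame.to_dict(orient="records"),
            "n_permutations": res.n_permutations,
            "n_degenerate": res.n_degenerate,
        }
    _write_json(os.path.join(config.out_dir, "permtest.json"), results, config)
    return results


def _load_reference_maps(config: RunConfig, manifest: dict):
    """Reference participant-level activation maps and cord geometry."""
    out = {}
    for ds in manifest["datasets"]:
        cord = nifti.read_mask(os.path.join(config.study_dir, ds["reference_mask"]))
        maps = {}
        for side in ("left", "right"):
            z, _ = nifti.read_volume(os.path.join(config.study_dir,
                                                  ds["activation_maps"][side]))
            maps[side] = ActivationMap(z=z, analysis_mask=cord, stimulus_side=side)
        out[ds["id"]] = {"cord": cord, "maps": maps, "entry": ds}
    return out


def _rater_activation_map(config: RunConfig, ref_map: ActivationMap, shifts_mm,
                          voxel_size, rng) -> ActivationMap:
    """Emulate a rater's participant-level z-map: the reference activation
    pattern carried through that rater's registration error, plus
    analysis noise for pipeline differences downstream of registration."""
    from cordmaskvar.phantom import _shift2d

    vox = np.asarray(voxel_size[:2])
    dvox = np.round(np.asarray(shifts_mm) / vox).astype(int)
    z = np.empty_like(ref_map.z)
    for s in range(z.shape[2]):
        z[:, :, s] = _shift2d(ref_map.z[:, :, s], int(dvox[s, 0]), int(dvox[s, 1]))
    if config.rater_act_noise_sd > 0:
        z[ref_map.analysis_mask] += rng.normal(
            0.0, config.rater_act_noise_sd, size=int(ref_map.analysis_mask.sum()))
    return ActivationMap(z=z, analysis_mask=ref_map.analysis_mask,
                         stimulus_side=ref_map.stimulus_side)


def stage_activation(config: RunConfig, manifest: dict) -> dict:
    """Participant-level Fisher z per rater×dataset×side×condition, plus
    group-level (fixed-effects) map comparison and standardisation."""
    refs = _load_reference_maps(config, manifest)
    raters = manifest["raters"]
    voxel_size = (1.0, 1.0, 3.0)

    rows = []
    group_z = {r: {"left": [], "right": []} for r in raters}
    group_ref = {"left": [], "right": []}

    act_dir = os.path.join(config.out_dir, "activation")
    os.makedirs(act_dir, exist_ok=True)

    for ds_id, bundle in refs.items():
        cord = bundle["cord"]
        part = hemicord_partition(cord)
        entry = bundle["entry"]
        ref_mask = nifti.read_mask(os.path.join(config.study_dir, entry["reference_mask"]))
        for side in ("left", "right"):
            ref_map = bundle["maps"][side]
            group_ref[side].append(ref_map.z)
            ipsi, contra = condition_regions(part, side)
            for r_idx, rater in enumerate(raters):
                rm = nifti.read_mask(os.path.join(config.study_dir,
                                                  entry["rater_masks"][rater]))
                shifts = centroid_shift_mm(rm, ref_mask, voxel_size)
                seed = entry["seeds"][f"activation_{side}"]
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(r_idx + 1,)))
                rmap = _rater_activation_map(config, ref_map, shifts, voxel_size, rng)
                group_z[rater][side].append(rmap.z)
                rows.append({
                    "dataset": ds_id, "rater": rater, "side": side,
                    "condition": "ipsilateral",
                    "fisher_z": spatial_correlation(rmap, ref_map, ipsi,
                                                    method=config.corr_method),
                })
                rows.append({
                    "dataset": ds_id, "rater": rater, "side": side,
                    "condition": "contralateral",
                    "fisher_z": spatial_correlation(rmap, ref_map, contra,
                                                    method=config.corr_method),
                })

    fz = pd.DataFrame(rows)
    fz.to_csv(os.path.join(config.out_dir, "activation_fisher_z.csv"), index=False)

    # group level: fixed-effects combination (Σ z_d / √D) of participant maps
    first = next(iter(refs.values()))
    cord = first["cord"]
    part = hemicord_partition(cord)
    n_d = len(refs)
    group_rows, std_rows = [], []
    for side in ("left", "right"):
        g_ref = ActivationMap(np.sum(group_ref[side], axis=0) / np.sqrt(n_d),
                              cord, side, level="group")
        nifti.write_mask(os.path.join(act_dir, f"active_ref_{side}.nii.gz"),
                         threshold_map(g_ref, config.z_thresh), voxel_size)
        g_raters = {
            r: ActivationMap(np.sum(group_z[r][side], axis=0) / np.sqrt(n_d),
                             cord, side, level="group")
            for r in raters
        }
        ipsi, contra = condition_regions(part, side)
        for cond, region in (("ipsilateral", ipsi), ("contralateral", contra)):
            for r in raters:
                group_rows.append({
                    "rater": r, "side": side, "condition": cond,
                    "fisher_z": spatial_correlation(g_raters[r], g_ref, region,
                                                    method=config.corr_method),
                })
            sc = standardize_reference(g_ref, list(g_raters.values()), region)
            std_rows.append({"side": side, "condition": cond, "z_bar": sc.z_bar,
                             "sd_z": sc.sd_z, "n_voxels": sc.n_voxels})

    group_table = pd.DataFrame(group_rows)
    group_table.to_csv(os.path.join(config.out_dir, "group_fisher_z.csv"), index=False)
    std_table = pd.DataFrame(std_rows)
    std_table.to_csv(os.path.join(config.out_dir, "group_standardized.csv"), index=False)
    _write_json(os.path.join(config.out_dir, "group_standardized.json"),
                {"conditions": std_rows}, config)
    return {"participant": fz, "group": group_table, "standardized": std_table}


def _sorted_heatmap(cells: pd.DataFrame, value: str, order_by: pd.DataFrame) -> pd.DataFrame:
    """Pivot rater×dataset values with both axes sorted by ascending
    marginal mean logit DSC (the reference row, if present, stays last)."""
    ref_rows = order_by[order_by["rater"] != "REF"]
    rater_order = ref_rows.groupby("rater")["mean_logit_dsc"].mean().sort_values().index.tolist()
    ds_order = ref_rows.groupby("dataset")["mean_logit_dsc"].mean().sort_values().index.tolist()
    pivot = cells.pivot(index="rater", columns="dataset", values=value)
    rows = [r for r in rater_order if r in pivot.index]
    if "REF" in pivot.index:
        rows = rows + ["REF"]
    return pivot.loc[rows, [d for d in ds_order if d in pivot.columns]]


def stage_report(config: RunConfig, slice_table: pd.DataFrame, cell_table: pd.DataFrame,
                 activation_tables: dict, permtest: dict) -> ReportBundle:
    dsc_heat = _sorted_heatmap(cell_table[cell_table["rater"] != "REF"],
                               "mean_logit_dsc", cell_table)
    gmwm_heat = _sorted_heatmap(cell_table, "gm_wm_ratio", cell_table)

    act = activation_tables["participant"]
    act_ipsi = (act[act["condition"] == "ipsilateral"]
                .groupby(["rater", "dataset"])["fisher_z"].mean().reset_index())
    act_heat = _sorted_heatmap(act_ipsi, "fisher_z", cell_table)

    margins = marginal_means(dsc_heat)
    corr_rows = []
    for outcome, res in permtest.items():
        for rec in res["per_rater"]:
            corr_rows.append({"outcome": outcome, **rec})
    corr_table = pd.DataFrame(corr_rows)

    bundle = ReportBundle(
        dsc_heatmap=dsc_heat, gmwm_heatmap=gmwm_heat, activation_heatmap=act_heat,
        dsc_margins=margins, correlation_table=corr_table,
        standardized_table=activation_tables["standardized"],
        group_fisher_table=activation_tables["group"],
    )

    report_dir = os.path.join(config.out_dir, "report")
    os.makedirs(report_dir, exist_ok=True)
    dsc_heat.to_csv(os.path.join(report_dir, "heatmap_logit_dsc.csv"))
    gmwm_heat.to_csv(os.path.join(report_dir, "heatmap_gm_wm.csv"))
    act_heat.to_csv(os.path.join(report_dir, "heatmap_activation_fisher_z.csv"))
    margins["rows"].to_csv(os.path.join(report_dir, "margins_rater_logit_dsc.csv"))
    margins["cols"].to_csv(os.path.join(report_dir, "margins_dataset_logit_dsc.csv"))
    corr_table.to_csv(os.path.join(report_dir, "correlation_table.csv"), index=False)
    bundle.standardized_table.to_csv(os.path.join(report_dir, "standardized_table.csv"),
                                     index=False)
    bundle.group_fisher_table.to_csv(os.path.join(report_dir, "group_fisher_table.csv"),
                                     index=False)

    if config.make_plots:
        _plot_heatmaps(report_dir, bundle)
    return bundle


def _plot_heatmaps(report_dir: str, bundle: ReportBundle) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, table in (("logit_dsc", bundle.dsc_heatmap),
                        ("gm_wm", bundle.gmwm_heatmap),
                        ("activation_fisher_z", bundle.activation_heatmap)):
        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(table.index)), table.index)
        ax.set_xticks(range(len(table.columns)), table.columns, rotation=90, fontsize=6)
        ax.set_xlabel("dataset (ascending mean logit DSC)")
        ax.set_ylabel("rater")
        fig.colorbar(im, ax=ax, label=name)
        fig.tight_layout()
        fig.savefig(os.path.join(report_dir, f"heatmap_{name}.png"), dpi=120)
        plt.close(fig)


def run_all(config: RunConfig) -> ReportBundle:
    """Execute every stage in order; failures carry the stage name."""
    stages = []

    def _run(name, fn, *args):
        t0 = time.time()
        try:
            out = fn(config, *args)
        except Exception as exc:  # noqa: BLE001 — re-tag with stage provenance
            raise StageError(name, str(exc)) from exc
        logger.info("stage %-10s done in %.1fs", name, time.time() - t0)
        stages.append(name)
        return out

    manifest = _run("simulate", stage_simulate)
    slice_table, cell_table = _run("metrics", stage_metrics)
    _run("anova", stage_anova, cell_table)
    permtest = _run("permtest", stage_permtest, slice_table)
    act = _run("activation", stage_activation, manifest)
    return _run("report", stage_report, slice_table, cell_table, act, permtest)
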
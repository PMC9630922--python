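"""Canned study-level experiments: each runs the pipeline's own machinery
on simulated inputs and measures one property of scientific interest
(sign recovery, registration-proxy monotonicity, rater gradients,
reference exchangeability). Shared by the validation suite and the
reproduction script.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np
import pandas as pd

from cordmaskvar import agreement
from cordmaskvar.activation import standardize_reference, ActivationMap
from cordmaskvar.inference import maxt_permutation
from cordmaskvar.phantom import (PhantomSpec, RaterModel, StudyConfig,
                                 generate_phantom, generate_study,
                                 simulate_misregistration)
from cordmaskvar.pipeline import RunConfig, stage_activation, stage_metrics, stage_simulate


def sign_recovery_study(master_seed: int, n_perm: int = 1000,
                        work_dir: str | None = None) -> dict:
    """Full simulated study; pooled DSC–image-quality correlations.

    Low-contrast, noisy slices receive noisier rater contours (the
    difficulty coupling of the study generator), so the pooled Fisher z
    should come out positive for Adjacent:SC vs DSC and negative for
    CV vs DSC.
    """
    with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
        config = RunConfig(out_dir=tmp,
                           study=StudyConfig(master_seed=master_seed),
                           n_perm=n_perm)
        stage_simulate(config)
        slice_table, _ = stage_metrics(config)
    out = {}
    for i, outcome in enumerate(("adjacent_sc_ratio", "cv_adjacent")):
        res = maxt_permutation(slice_table, outcome, n_perm=n_perm,
                               seed=master_seed + i)
        out[outcome] = {
            "per_rater_z": dict(zip(res.raters, res.mean_fisher_z.tolist())),
            "mean_z": float(res.mean_fisher_z.mean()),
            "p_adjusted": dict(zip(res.raters, res.p_adjusted.tolist())),
        }
    return out


def gmwm_shift_profile(shifts_vox=(0, 1, 2, 3)) -> list[float]:
    """GM:WM contrast of a noiseless phantom (GM 120 > WM 100) under
    increasing in-plane misregistration; maximal at zero shift."""
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    vol = generate_phantom(spec)
    out = []
    for s in shifts_vox:
        shifted = simulate_misregistration(vol, (float(s), 0.0)) if s else vol
        out.append(agreement.gm_wm_contrast(shifted.image, vol.gm_mask, vol.wm_mask))
    return out


def gradient_ladder_config(master_seed: int, flip_rates=(0.02, 0.06, 0.12, 0.20, 0.30),
                           n_datasets: int = 21) -> StudyConfig:
    """Study whose raters differ only in boundary flip rate."""
    raters = [RaterModel(f"r{i}", 0, f, 0.0) for i, f in enumerate(flip_rates)]
    return StudyConfig(n_datasets=n_datasets, rater_models=raters,
                       master_seed=master_seed)


def rater_gradient_study(master_seed: int, work_dir: str | None = None) -> dict:
    """Mean logit DSC margin and mean ipsilateral Fisher z per rung of a
    flip-rate ladder; both should fall as the flip rate rises."""
    config = gradient_ladder_config(master_seed)
    with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
        run = RunConfig(out_dir=tmp, study=config)
        manifest = stage_simulate(run)
        _, cell_table = stage_metrics(run)
        act = stage_activation(run, manifest)
    ladder = [m.name for m in config.rater_models]
    dsc_margin = (cell_table[cell_table["rater"] != "REF"]
                  .groupby("rater")["mean_logit_dsc"].mean().loc[ladder])
    ipsi = act["participant"]
    ipsi = (ipsi[ipsi["condition"] == "ipsilateral"]
            .groupby("rater")["fisher_z"].mean().loc[ladder])
    return {
        "flip_rates": [float(m.flip_rate) for m in config.rater_models],
        "mean_logit_dsc": dsc_margin.tolist(),
        "ipsi_fisher_z": ipsi.tolist(),
    }


def exchangeable_reference_coverage(n_replicates: int = 200, n_voxels: int = 1200,
                                    n_raters: int = 8, seed: int = 0) -> float:
    """Fraction of replicates with |z̄| ≤ 3·sd_z/√n when the reference
    map is drawn from the same distribution as the rater maps — the
    'distributed about 0' behaviour expected without systematic bias."""
    rng = np.random.default_rng(seed)
    shape = (n_voxels, 1, 1)
    mask = np.ones(shape, dtype=bool)
    hits = 0
    for _ in range(n_replicates):
        truth = rng.normal(0.0, 1.0, size=shape)
        ref = ActivationMap(truth + rng.normal(0, 1, size=shape), mask)
        raters = [ActivationMap(truth + rng.normal(0, 1, size=shape), mask)
                  for _ in range(n_raters)]
        sc = standardize_reference(ref, raters, mask)
        hits += abs(sc.z_bar) <= 3.0 * sc.sd_z / np.sqrt(sc.n_voxels)
    return hits / n_replicates


def anova_design_dfs(n_raters: int, n_datasets: int, seed: int = 0) -> dict:
    """Degrees of freedom of the additive two-factor ANOVA on a simulated
    complete design of the given size."""
    from cordmaskvar.inference import two_way_anova

    rng = np.random.default_rng(seed)
    rows = [{"rater": f"r{r}", "dataset": f"d{d}", "y": rng.normal()}
            for r in range(n_raters) for d in range(n_datasets)]
    res = two_way_anova(pd.DataFrame(rows), "y")
    return {
        "df_rater": int(res.factors.loc["rater", "df_effect"]),
        "df_dataset": int(res.factors.loc["dataset", "df_effect"]),
        "df_resid": res.df_resid,
    }
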
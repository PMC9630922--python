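"""Statistical layer: two-way ANOVA with η², slicewise Spearman
correlations pooled via Fisher's z, and the max-T permutation adjustment.

The max-T test asks, for each rater, whether its slicewise mask
agreement (DSC) co-varies with a slicewise image-quality outcome, while
controlling the family-wise error across raters and respecting the
dependence between them. Observed statistic per rater: the mean over
datasets of Fisher's z of Spearman's ρ between DSC and the outcome
across slices, within each rater-dataset pair. Null distribution: the
DSC values are scrambled across slices independently within every
rater-dataset pair (slices assumed exchangeable), the statistic is
recomputed per rater, and the maximum absolute value across raters is
recorded; 5,000 such replicates by default. Two-tailed adjusted p-values
use the add-one convention (1 + #{null ≥ |observed|}) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from cordmaskvar.errors import DesignError, UndefinedMetricError

logger = logging.getLogger(__name__)

FISHER_CLAMP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaResult:
    """Two-way additive ANOVA summary with per-factor effect sizes."""

    response: str
    factors: pd.DataFrame  # index: factor; columns F, df_effect, df_resid, p, eta_sq, ss
    ss_resid: float
    ss_total: float
    df_resid: int
    degenerate: bool = False

    @property
    def eta_sq_residual(self) -> float:
        return self.ss_resid / self.ss_total if self.ss_total > 0 else 1.0


def two_way_anova(cells: pd.DataFrame, response: str, rater_col: str = "rater",
                  dataset_col: str = "dataset") -> AnovaResult:
    """Additive rater + dataset ANOVA on one observation per cell.

    Requires a complete balanced design (every rater×dataset cell filled
    exactly once, ≥ 2 levels per factor). F = MS_factor / MS_resid with
    residual df (R−1)(D−1); η² = SS_factor / SS_total. A constant
    response is reported as the degenerate case with η² = 0 per factor.
    """
    counts = cells.groupby([rater_col, dataset_col]).size()
    n_r = cells[rater_col].nunique()
    n_d = cells[dataset_col].nunique()
    if n_r < 2 or n_d < 2:
        raise DesignError("need at least 2 levels of each factor")
    if len(counts) != n_r * n_d or (counts != 1).any():
        raise DesignError("design must be complete with one observation per cell")
    if not np.all(np.isfinite(cells[response])):
        raise DesignError(f"non-finite values in response '{response}'")

    df_resid = (n_r - 1) * (n_d - 1)
    y = cells[response].to_numpy(dtype=np.float64)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total <= 1e-30:
        factors = pd.DataFrame(
            {"F": [np.nan, np.nan], "df_effect": [n_r - 1, n_d - 1],
             "df_resid": [df_resid] * 2, "p": [np.nan, np.nan],
             "eta_sq": [0.0, 0.0], "ss": [0.0, 0.0]},
            index=pd.Index([rater_col, dataset_col], name="factor"))
        return AnovaResult(response, factors, 0.0, 0.0, df_resid, degenerate=True)

    model = smf.ols(f"{response} ~ C({rater_col}) + C({dataset_col})", data=cells).fit()
    aov = anova_lm(model, typ=2)
    ss_r = float(aov.loc[f"C({rater_col})", "sum_sq"])
    ss_d = float(aov.loc[f"C({dataset_col})", "sum_sq"])
    ss_e = float(aov.loc["Residual", "sum_sq"])
    factors = pd.DataFrame(
        {
            "F": [float(aov.loc[f"C({rater_col})", "F"]), float(aov.loc[f"C({dataset_col})", "F"])],
            "df_effect": [n_r - 1, n_d - 1],
            "df_resid": [df_resid, df_resid],
            "p": [float(aov.loc[f"C({rater_col})", "PR(>F)"]),
                  float(aov.loc[f"C({dataset_col})", "PR(>F)"])],
            "eta_sq": [ss_r / ss_total, ss_d / ss_total],
            "ss": [ss_r, ss_d],
        },
        index=pd.Index([rater_col, dataset_col], name="factor"),
    )
    return AnovaResult(response, factors, ss_e, ss_total, df_resid)


# ---------------------------------------------------------------------------
# Correlation primitives


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises :class:`UndefinedMetricError` for fewer than 3 complete pairs
    or zero rank variance in either variable.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise UndefinedMetricError("Spearman undefined: fewer than 3 complete pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    sxx, syy = float(rxc @ rxc), float(ryc @ ryc)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedMetricError("Spearman undefined: zero rank variance")
    return float(rxc @ ryc) / np.sqrt(sxx * syy)


def fisher_z(r):
    """Variance-stabilising atanh transform, clamped at |r| = 1 − 1e−7."""
    r = np.clip(np.asarray(r, dtype=np.float64), -FISHER_CLAMP, FISHER_CLAMP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    out = np.tanh(np.asarray(z, dtype=np.float64))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# max-T permutation adjustment


@dataclass
class PermutationResult:
    """Per-rater pooled correlations with max-T adjusted p-values."""

    outcome: str
    raters: list[str]
    rho_by_dataset: pd.DataFrame  # columns rater, dataset, rho, n_slices
    mean_fisher_z: np.ndarray  # observed, per rater
    p_adjusted: np.ndarray  # per rater, two-tailed, family-wise adjusted
    null_max_abs_z: np.ndarray  # permutation distribution, length n_perm
    n_permutations: int
    seed: int | None
    n_degenerate: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rater": self.raters,
            "mean_fisher_z": self.mean_fisher_z,
            "mean_rho": fisher_z_inv(self.mean_fisher_z),
            "p_adjusted": self.p_adjusted,
        })


def _pair_ranks(x: np.ndarray, y: np.ndarray):
    """Centered ranks and their sums of squares for one rater-dataset pair."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    return rxc, ryc, float(rxc @ rxc), float(ryc @ ryc)


def maxt_permutation_arrays(dsc: np.ndarray, outcome: np.ndarray,
                            n_perm: int = 5000,
                            rng: np.random.Generator | int | None = None,
                            chunk: int = 500) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """max-T adjustment on complete (raters, datasets, slices) arrays.

    Returns (observed mean Fisher z per rater, adjusted p per rater,
    null max-|z| distribution, number of degenerate pairs). Pairs whose
    ranks are degenerate — in the observed data or any permuted
    replicate — contribute Fisher z = 0, keeping the pooled statistic's
    dimension constant across replicates. Fast path shared by the table
    API and the calibration studies.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    dsc = np.asarray(dsc, dtype=np.float64)
    outcome = np.asarray(outcome, dtype=np.float64)
    n_r, n_d, n_s = dsc.shape
    if n_s < 3:
        raise UndefinedMetricError("need at least 3 slices per rater-dataset pair")
    P = n_r * n_d

    RX = np.empty((P, n_s))
    RY = np.empty((P, n_s))
    sxx = np.empty(P)
    syy = np.empty(P)
    for p in range(P):
        r, d = divmod(p, n_d)
        rxc, ryc, a, b = _pair_ranks(dsc[r, d], outcome[r, d])
        RX[p], RY[p], sxx[p], syy[p] = rxc, ryc, a, b
    denom = np.sqrt(sxx * syy)
    ok = denom > 0.0
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        logger.warning("%d rater-dataset pairs with degenerate ranks contribute z=0",
                       n_degenerate)
    safe = np.where(ok, denom, 1.0)

    rho_obs = np.where(ok, (RX * RY).sum(axis=1) / safe, 0.0)
    z_obs = fisher_z(rho_obs).reshape(n_r, n_d).mean(axis=1)

    null = np.empty(n_perm)
    done = 0
    pair_idx = np.arange(P)[None, :, None]
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((k, P, n_s)), axis=-1)
        xp = RX[pair_idx, perm]  # (k, P, n_s): permuted centered DSC ranks
        rho = np.where(ok[None, :], np.einsum("kps,ps->kp", xp, RY) / safe[None, :], 0.0)
        z = fisher_z(rho).reshape(k, n_r, n_d).mean(axis=2)
        null[done:done + k] = np.abs(z).max(axis=1)
        done += k

    p_adj = (1.0 + (null[None, :] >= np.abs(z_obs)[:, None]).sum(axis=1)) / (n_perm + 1.0)
    return z_obs, p_adj, null, n_degenerate


def maxt_permutation(slices: pd.DataFrame, outcome: str, n_perm: int = 5000,
                     seed: int | None = None, dsc_col: str = "dsc") -> PermutationResult:
    """max-T adjusted DSC–outcome correlation test on a slicewise table.

    ``slices`` is the long table from
    :func:`cordmaskvar.agreement.build_tables` (columns dataset, rater,
    slice, dsc, and the outcome). Every retained rater-dataset pair
    needs ≥ 3 usable slices; the design must be complete so replicates
    are exchangeable.
    """
    raters = sorted(slices["rater"].unique())
    datasets = sorted(slices["dataset"].unique())
    n_r, n_d = len(raters), len(datasets)
    counts = slices.groupby(["rater", "dataset"]).size()
    if len(counts) != n_r * n_d or counts.nunique() != 1:
        raise DesignError("slicewise table must be complete over rater × dataset")
    n_s = int(counts.iloc[0])
    if n_s < 3:
        raise UndefinedMetricError("need at least 3 slices per rater-dataset pair")

    wide = slices.sort_values(["rater", "dataset", "slice"])
    x = wide[dsc_col].to_numpy().reshape(n_r, n_d, n_s)
    y = wide[outcome].to_numpy().reshape(n_r, n_d, n_s)

    rng = np.random.default_rng(seed)
    z_obs, p_adj, null, n_deg = maxt_permutation_arrays(x, y, n_perm=n_perm, rng=rng)

    rho_rows = []
    for r, rater in enumerate(raters):
        for d, ds in enumerate(datasets):
            try:
                rho = spearman(x[r, d], y[r, d])
            except UndefinedMetricError:
                rho = 0.0
            rho_rows.append({"rater": rater, "dataset": ds, "rho": rho, "n_slices": n_s})

    return PermutationResult(
        outcome=outcome, raters=raters,
        rho_by_dataset=pd.DataFrame(rho_rows),
        mean_fisher_z=z_obs, p_adjusted=p_adj, null_max_abs_z=null,
        n_permutations=n_perm, seed=seed, n_degenerate=n_deg,
    )
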
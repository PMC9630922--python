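# cordmaskvar

Spinal-cord fMRI group analysis requires registering each participant's
functional data to a template (e.g. PAM50), and that registration is
usually informed by a manually contoured binary mask of the cord drawn
on the temporal-mean functional image. Different raters draw different
masks; this package quantifies how that variability propagates through
spatial normalization into registered image quality and, ultimately,
activation maps. It is written for spinal-cord fMRI methodologists who
want the full statistical chain — agreement metrics, image-quality
correlates, permutation-adjusted inference, and activation comparison —
as tested, reusable code, driven by a synthetic cord phantom and rater
simulator so every stage runs without access to restricted imaging data.

## What it computes

Mask agreement between a rater mask RM and the reference REF is the
Dice similarity coefficient, per volume and per axial slice,

    DSC = 2·|REF ∩ RM| / (|REF| + |RM|),

logit-transformed for all linear modelling. Image quality per slice is
measured in the peri-cord region (a 2-voxel in-plane dilation of REF,
minus REF): the coefficient of variation of its intensities (CV) and
the ratio of its mean to the cord mean (Adjacent:SC ratio; values < 1
signal contrast breakdown). Registration accuracy is proxied by GM:WM
contrast — mean signal in atlas gray matter over atlas white matter —
which is maximal under perfect alignment and is degraded by the
in-plane misregistration a noisy mask induces.

Inference follows two routes:

* a two-way additive ANOVA (rater + dataset) with η² effect sizes on
  mean logit DSC and on log GM:WM contrast;
* a max-T permutation test of the slicewise DSC–image-quality
  correlations: Spearman's ρ per rater–dataset pair across slices,
  Fisher-z transformed and averaged over datasets within each rater;
  the null scrambles DSC across slices within each pair and records the
  maximum |pooled z| across raters (5,000 permutations), giving
  two-tailed family-wise-adjusted p-values.

Activation maps (z-statistics) are compared between each rater and the
reference within the left and right hemicord (the center cord column is
excluded), ipsilaterally and contralaterally to the stimulus, via
Pearson spatial correlation on unthresholded maps (Fisher z). At the
group level the reference's voxelwise z-statistics are standardized
against the rater distribution, summarised as z̄ ± SD[z]; values near 0
mean no systematic rater-induced bias.

## Worked example

The numbered drivers under `analysis/` run the whole study (21 synthetic
datasets × 8 simulated raters of decreasing skill, A best to H worst,
plus a perfect reference):

```
python analysis/01_simulate.py
python analysis/02_mask_agreement.py
python analysis/03_inference.py
python analysis/04_activation.py
python analysis/05_report.py
```

`03_inference.py` prints, for the default master seed:

```
ANOVA on mean_logit_dsc:
  rater    F(7, 140) = 383.06, p = 5.75e-88, eta^2 = 0.92
  dataset  F(20, 140) = 5.19, p = 1.55e-09, eta^2 = 0.04

max-T permutation test, DSC vs adjacent_sc_ratio (5000 permutations):
  rater A: mean rho = +0.59, adjusted p = 0.0002
  ...
  rater G: mean rho = +0.15, adjusted p = 0.0232
```

Both factors influence agreement (the simulated rater ladder dominates
by construction); slices with better cord/CSF contrast are contoured
more consistently (positive Adjacent:SC correlation, negative CV
correlation — every adjusted p family-wise corrected). `04_activation.py`
then shows the same rater gradient in activation fidelity (mean
ipsilateral Fisher z falls from 2.08 for rater A to 1.03 for rater H)
while the standardized group-level comparison stays centred near zero
(z̄ between −0.02 and 0.12 across the four side × condition cells):
individual-level maps degrade with mask quality, but no systematic
group-level bias appears.

The same machinery is scriptable (`cordmaskvar run --demo --out DIR`,
or stage subcommands `simulate | metrics | anova | permtest |
activation`) and importable (`cordmaskvar.agreement`, `.inference`,
`.activation`, `.phantom`, `.pipeline`).

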
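# Methods

## The generative model behind the synthetic cohorts

Serum concentration of miRNA *j* in a sample from group *g* is
log-normal:

    log10(conc_ij) ~ Normal(mu_j + delta_{jg}, sigma_j)

* `mu_j` (`baseline_log10_mean`): baseline log10 concentration in fM.
  Default: evenly spread over 1–4 log10 fM across the simulated miRNAs,
  matching the span a femtomolar-calibrated qPCR assay can cover.
* `delta_{jg}` (`planted_markers`): planted log10 fold change per disease
  group; zero for controls and for all non-marker miRNAs. Effects are
  additive on the log scale, so a planted value of log10(3) means a 3×
  ratio of group geometric means (and, with equal group sigmas, of
  arithmetic means too).
* `sigma_j` (`baseline_log10_sd`): within-group biological + assay
  spread on log10 scale. Default 0.12 — see "Default noise level" below.

**Sequencing pools.** Pool members contribute equal serum volumes, so a
pool's concentration of miRNA *j* is the arithmetic mean over its
members. A library is one multinomial draw of `library_size` reads
(default 3 × 10⁶, an early short-read small-RNA run) with probabilities
proportional to pooled concentrations. Over-dispersion beyond
multinomial sampling is deliberately omitted: the screen stage's
thresholds act on a single pooled pair of libraries, and a dispersion
knob would add a parameter no part of the contract constrains.

**RT-qPCR.** Each assay has a "true" standard curve (intercept ≈ 38
cycles, slope ≈ −3.32 = −1/log10 2 with small assay-to-assay jitter,
clipped to the 80–115 % efficiency band). A replicate measurement is

    Cq = intercept + slope·log10(conc) + Normal(0, cq_noise_sd)

in triplicate per sample × miRNA; `cq_noise_sd` defaults to 0.15
cycles, a typical well-to-well SD for probe-based assays. Calibration
tables are simulated from the same curves (decade dilutions 1–10⁵ fM)
and re-fit by OLS, so the pipeline's inversion uses *fitted* curves, not
the generating ones.

**Covariates.** cTnT and CK-MB comparator scores are synthetic
stand-ins: log-normal draws moment-matched per group to representative
clinical means/SDs (e.g. cTnT 0.77 ± 0.74 ng/ml in AMI vs 0.15 ± 0.27 in
controls and 0.14 ± 0.21 in AP). They exist solely to exercise the
comparator-ROC path; nothing downstream models them.

**Randomness.** One integer seed feeds named per-stage `SeedSequence`
sub-streams (concentrations, covariates, pool counts per group, curves,
calibration, Cq), so stages can be re-run independently and a fixed
config is byte-reproducible.

### Default noise level

`baseline_log10_sd = 0.12` was chosen so that the weakest planted marker
(2.5×, i.e. 0.40 log10) remains reliably selectable at the study-shaped
training size of 20 + 20: the sampling SD of the log fold-change of
group means is then ≈ 0.09 (natural log), putting the 2× selection
boundary ≈ 2.5 SDs below the planted effect. In other words, the
generator emulates conditions under which a panel with these effect
sizes would in fact be discovered. The cost is realism in the *absolute*
discrimination numbers: real between-patient spread of serum miRNAs is
several-fold larger, which is why published single-marker AUCs sit near
0.65–0.78 while this generator's saturate near 1.0. Passing tests
therefore demonstrate correctness of the machinery and calibration of
its statistics — not that real-serum panels achieve these AUCs.

## Analysis-stage conventions

**Screen filter.** The copy-number rule uses raw patient-pool counts
(≥ 1000 by default). The fold change uses counts rescaled to the mean of
the two library depths, with a pseudocount (default 1) added to both
pools so zero control counts give finite ratios; both depth
normalization and the pseudocount are exposed because pooled designs
differ on zero handling. "5-fold" is applied bidirectionally, with
direction recorded.

**Quantification.** Replicates are aggregated as mean-of-Cq then
inverted (the geometric mean of concentrations) — the contract is
asserted by a test on an asymmetric triplicate and must not be swapped
for invert-then-mean. Wells with no amplification by cycle 40 are
imputed at the curve's Cq = 40 concentration (limit of detection) and
flagged; a replicate range > 1 cycle and inversions outside the
calibrated range raise advisory flags. No endogenous normalizer is
used; concentrations are divided by the serum volume (default 0.2 ml).

**Selection.** Fold change is reported as the ratio of group arithmetic
means on the raw scale (matching how such studies quote fold values),
while the default t-test acts on log10 concentrations with pooled
variance (log-normal data; protects the type-I error; Welch and raw-scale
variants behind flags). Selection requires fold > 2 (either direction;
`up_only` restricts) and p < 0.05, with no multiplicity correction by
default and Benjamini–Hochberg as an option. Validation requires the
training direction to reproduce with p < alpha in the independent
cohort. Selected ids are ordered by ascending p with id-lexicographic
tie-break.

**Reference limits.** "Upper 95 % reference interval" is read in the
clinical-chemistry sense: the upper bound of the central 95 % range,
i.e. the 97.5th percentile. Default is parametric on log10 values,
10^(mean + 1.96·sd); an empirical percentile (linear interpolation) is
available when the log-normal assumption is not trusted. Dichotomization
is strict: a value exactly at the threshold scores 0.

**Logistic weights.** Each marker's weight is the slope of an
intercept + indicator logistic regression fit by IRLS (tolerance 1e-8,
≤ 100 iterations); with a binary predictor this MLE equals the 2×2 log
odds ratio, which the tests exploit as a closed-form oracle. A 2×2 table
with an empty cell has no finite MLE; the weight is then the
Haldane–Anscombe (+0.5 per cell) log odds ratio with a separation flag,
keeping the RSF finite.

**Risk model fitting.** Thresholds and weights are refit per contrast
(AMI vs control, AP vs control, AMI vs AP — the second-named group is
the reference whose samples define the thresholds). By default they are
fit on the pooled training + validation samples of the contrast;
`fit_subset="training"` restricts fitting to the training phase where
both groups have training samples.

**ROC.** Thresholds are the observed unique scores plus a +inf
sentinel; the rule score ≥ threshold predicts case. Trapezoidal AUC over
the trace equals the Mann–Whitney statistic with midrank ties — asserted
exactly against pairwise enumeration. The 95 % CI uses DeLong's
placement-value variance (Hanley–McNeil behind a flag); a degenerate AUC
of 0 or 1 collapses the interval with a warning. The operating cutoff
maximizes Youden's J over observed thresholds, ties broken toward higher
specificity, then the lower threshold. Scores are assumed case-high; no
automatic re-orientation is performed, so an inverted marker shows as
AUC < 0.5 rather than being silently flipped.

**Pipeline.** The screen stage is advisory by default: selection runs on
every quantified miRNA (mirroring designs where an assay is added to the
qPCR panel on outside evidence), with `restrict_to_screen` to gate
selection on screen hits. Note the two stages see different effect
scales — a 2.5–4.5× marker passes the fold > 2 selection rule but not
the 5-fold screen rule — which is exactly why the screen is not a gate
by default. Contrast groups are validated before any stage runs; a stage
failure raises an error naming the stage and leaves a `FAILED` sentinel
next to partial outputs. Synthetic-mode reports are a pure function of
(config, seed).

## Problem sizes used in the checks

The shipped statistical checks use: 200 random fixtures (n ≤ 30 per
class) for the AUC/pairwise identity; n = 10⁴ per class for the binormal
closed form; 100 replicates of 500 controls for reference-limit
calibration; 200 replicates of 100 null miRNAs at 20 + 20 for the
selection type-I rate; and 100 seeded end-to-end runs of the default
cohort (training 20/20, validation 97/80) for planted-panel recovery.
These sizes give Monte-Carlo error comfortably inside each asserted
tolerance.

## Known limitations

* No over-dispersion, sequencing-error, adapter or isomiR structure in
  the pool model; no hemolysis or other pre-analytical confounders.
* The log-normal concentration model is an assumption, not an inference
  from data; the default noise level is conservative (see above).
* The RSF is strictly univariate-weight / binary-indicator — correlated
  markers receive no joint modeling, matching the method it implements.
* Reported DeLong CIs assume the asymptotic normal approximation;
  degenerate separation collapses them rather than widening them.
* Covariate scorers are distributional stand-ins, not models of troponin
  kinetics.
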
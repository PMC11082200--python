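# Methods

`cftnps` implements a trial-level representational-dynamics analysis of
episodic counterfactual thinking (eCFT): how the multivoxel fMRI pattern of
an autobiographical memory relates to the patterns evoked while the
participant simulates a better (upward) or worse (downward) version of that
event, and how those relations are moderated by trait anxiety. Because the
study it emulates did not deposit raw data, every stage is exercised
end-to-end on synthetic studies with known ground truth; this note records
the models, the generator, the numerical choices, and what the synthetic
results do and do not establish.

## Single-trial pattern estimation (FIR / LSS)

Each run presents ~15 trials: a 12-s recall epoch cued by a memory title,
then — on eCFT trials — a jittered 1–3-s fixation and a 12-s simulation
epoch, followed by a 1.5-s fixation and an odd/even digit filler block
(2–4 digits × 1.5 s) with button presses throughout. TR = 2 s.

For every eCFT trial a separate GLM is fitted (Least Squares Separate).
The focal trial's recall and CFT epochs are modelled with a finite impulse
response basis: three 4-s windows per epoch, i.e. an indicator column over
two TRs per window, six focal columns in all. FIR windows start at the
nearest TR boundary at or after the event onset (the 1-s and 3-s jitters
are off-grid; the interval's residual effect is handled downstream by the
nuisance residualization). All other events enter as five pooled nuisance
regressors — other recalls, other upward simulations, other downward
simulations, the odd/even task, and button presses (0.1-s duration) —
convolved with the standard double-gamma response (peak 6 s, undershoot
16 s, ratio 6) plus temporal derivatives. Per-TR confound columns (CSF,
WM, framewise displacement, DVARS, six motion parameters), one indicator
column per motion-flagged TR, discrete-cosine drift columns implementing a
100-s high-pass, and an intercept complete the design.

Voxelwise OLS is solved by pivoted QR; rank deficiency is an error naming
the offending columns. t = beta / SE with residual df = TRs − columns.
Standard errors are floored at a tiny scale (1e−10 × signal RMS) so that a
numerically exact fit yields t-maps proportional to beta maps rather than
0/0 noise. Zero-variance patterns are flagged and the affected record is
dropped, never imputed.

Trials whose focal recall *or* CFT epoch contains three or more (of six)
motion-outlier TRs are excluded. A rarer degenerate case is also excluded
and counted separately: when every TR of a focal window is censored, the
FIR column equals a sum of outlier indicators and the design is genuinely
rank deficient (`rank_deficient_design` in the accounting report).

## Similarity indices

Patterns are the per-window t-maps restricted to an ROI. Neural pattern
similarity (NPS) is the Fisher-z-transformed Pearson correlation across
voxels, with |r| clipped at 1 − 1e−7 before arctanh.

* **Recall–CFT similarity shift** (per trial, ROI):
  z(r(Recall[4–8 s], CFT[4–8 s])) − z(r(Recall[4–8 s], CFT[0–4 s])).
  Only the middle recall window is used; pairings involving the late
  recall window or the late CFT window are never computed (BOLD
  autocorrelation across the short gap inflates the former; the doubled
  temporal separation confounds the latter). The raw index is then
  residualized per ROI (pooling subjects and trials) on the categorical
  recall-to-CFT interval (1/2/3 s) and the previous trial's condition
  (upward / downward / none / no previous trial); the grand intercept is
  added back so the adjusted mean is preserved and downstream intercept
  tests keep estimating the mean shift. Nuisance levels absent from the
  data are dropped with a log note.
* **CFT–CFT similarity** (per trial, ROI): the mean NPS between the
  trial's CFT[4–8 s] pattern and every same-condition CFT[4–8 s] pattern
  from *other runs*. Same-run pairs are excluded (shared run state
  inflates them); a trial with no cross-run partner is marked unavailable
  (m = 0), not zero-filled.

## Mixed-effects inference

Each index × ROI is modelled by a REML linear mixed model: fixed effects
are the full factorial of condition (treatment coding, downward reference)
× standardized trait anxiety × standardized arousal; participants
contribute random intercepts. Wald t-tests use Satterthwaite denominator
df computed from the closed-form random-intercept REML profile likelihood
(statsmodels provides the fit; the Satterthwaite machinery is implemented
here and cross-checked against lmerTest/emmeans to ~1e−8 on a frozen
fixture). Because gradient-based MixedLM fits occasionally stall on a
boundary, variance components are polished by a direct Nelder–Mead search
of the closed-form REML surface, and β, cov(β) and the df are all
evaluated at that optimum. Benjamini–Hochberg FDR is applied per
fixed-effect term across ROIs, separately per index kind (Q = 0.05).
Simple slopes of each index on anxiety within each condition are linear
combinations of the fixed effects with their own Satterthwaite df. An
`include_nuisance` switch re-enters interval and previous-condition terms
as fixed effects, reproducing the one-step form of the two-step
residualization; on a balanced design the two give identical factorial
estimates.

## The synthetic-study generator

The generator emulates the session design: 39 subjects by default (40
in the recovery experiments), 3 runs, 45 memories split
15/15/15 across upward / downward / No-eCFT, TR 2 s, 12-s epochs, jitter
∈ {1, 2, 3} s, trait anxiety uniform on [20, 70] (the recruited spectrum
straddling the STAI-Y2 ≥ 40 high-anxiety cut), per-memory arousal ratings
1–7, motion outliers at 2% of TRs (flagged TRs carry FD > 0.5 mm /
elevated DVARS), and AR(1) voxel noise (φ = 0.3, sd 0.1 in pattern
units).

Latent patterns are fixed mixtures of Gaussian factor vectors that are
**orthonormalized within each ROI**: run-level task-network states (a
retrieval network shared by all recall epochs of a run, a simulation
state shared by all CFT epochs of a run; shared variance 0.5 each), a
subject-level template per condition, per-memory content, and per-trial
CFT residuals. Orthonormalization makes every injected sample correlation
exact, so the only stochasticity the downstream model faces is genuine
measurement noise; a merely-in-expectation construction leaves a random
per-subject-per-condition template overlap that acts as a cluster effect
the random-intercept model cannot represent and destroys its calibration.
This requires `voxels_per_roi` to exceed the factor count (~85 at default
trial counts); smaller ROIs fall back to approximate draws with a logged
warning. The default `voxels_per_roi = 250` matches a typical AAL3 parcel
at the acquisition resolution (100 is the retention floor, not the
typical size).

Injected effects, all on the Fisher-z scale: the late-window recall–CFT
correlation is arctanh(0.25) + `drift_intercept` +
`anxiety_by_condition_slope` × anxiety_z × sign(condition) + a
subject-level intercept (sd 0.09, chosen so that group-level intercept
standard errors at n ≈ 39 land in the 0.015–0.03 range typical of
trial-level NPS studies); the early
window stays at the base value, so their z-difference is the injected
shift. Within-condition cross-run CFT correlation is tanh(arctanh(0.2) +
the same moderation + a subject intercept, sd 0.03), carried by the
condition-template loading. When drift and moderation are zero the early
and late CFT patterns are *identical vectors*, so the latent shift is
exactly zero. Epoch signals are unconvolved boxcars (one pattern per 4-s
window), giving the FIR estimator an exact-recovery regime; filler and
button activity use one double-gamma-convolved pattern each, which the
matching design columns absorb exactly. A config flag can convolve epochs
for realism experiments.

What the generator does *not* emulate: anatomical geometry, physiological
noise spectra, spatial autocorrelation, task-correlated motion, and any
behaviour of real memory content. Passing tests therefore establish that
the pipeline's algebra, exclusion rules, and inference are correct under
the stated signal model — not that the scientific conclusions of any real
study are correct.

## Measurement-chain properties (measured, not assumed)

Replicate experiments with the default generator quantify what the
pipeline can and cannot recover:

* Single-trial t-patterns correlate ~0.95 with their latent patterns; the
  residual is LSS cross-talk (other trials' trial-specific signal that
  pooled nuisance regressors cannot absorb) plus acquisition noise. This
  attenuates slope-like effects by roughly 10–15%, and temporal proximity
  between the recall epoch and the early CFT window adds a small negative
  bias to the shift intercept; at the default subject heterogeneity both
  effects sit well inside the intercept's CI at n = 40.
* The Recall–CFT shift side of the pipeline is well calibrated: under a
  null generator the interaction term's FDR-positive fraction is at the
  nominal level, and the intercept's 95% CI covers the injected drift.
* The CFT–CFT similarity index carries a subject × condition cluster
  error the random-intercept model cannot see: the realized
  attenuation/soaking of each condition's template by that condition's
  pooled nuisance regressor varies with the run's timing and noise
  realization, making all of a cluster's pairwise similarities move
  together (measured cluster-level sd ≈ 0.013 against a within-cluster
  sd ≈ 0.017 over 15 trials). Condition-contrast tests on this index are
  therefore anti-conservative at trial-level dfs — a property the
  random-intercept-only specification would inherit on real data, and a
  deliberate, documented limitation of this pipeline rather than a bug.
  Directional conclusions (upward vs. downward simple-slope ordering) are
  robust; the acceptance experiments report both.

## Numerical choices

* Correlation clipping at |r| = 1 − 1e−7; undefined (zero-variance)
  correlations drop the record.
* OLS by pivoted QR; rank tolerance `max|R_ii| · max(n,k) · eps`.
* REML search over (log σ²_subject, log σ²_resid), Nelder–Mead, best of a
  statsmodels start and a moment start; σ²_subject below 1e−11 × var(y)
  is treated as the boundary (singular flag; Satterthwaite falls back to
  residual df).
* Satterthwaite df via central finite differences (relative step 1e−4) of
  the contrast variance and the REML Hessian; df is capped at the
  residual df.
* Seeded `numpy.random.default_rng` everywhere; a study is a pure
  function of its config, and the full pipeline is bit-reproducible at
  the results-CSV level.

## Experiment sizes

The bundled test suite and `scripts/acceptance.py` run the stochastic
experiments at 40 subjects × 3 runs × 15 trials/condition with 4 ROIs of
250 voxels (recovery; 5 replicates in the tests, 14 in the acceptance
script) and 15 subjects for the null-calibration replicates (8 and 14).
These sizes were chosen so a complete single-CPU run finishes in minutes
while leaving the Monte-Carlo error of the reported fractions near the
few-percent level.
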
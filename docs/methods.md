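# Methods

This note documents the models, conventions and design choices behind
`ssmrs`, in the spirit of a statistical-software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The race model and staircase

Each trial draws a planned lift time

T ~ Normal(μ + δ_c, σ),

where μ is the subject's timing mean (ms from trial onset; the indicator
crosses the target at 800 ms), σ the trial-to-trial timing SD, and δ_c an
additive context shift for the 20%/40% stop-signal-probability (SSP)
blocks. Proactive slowing is therefore a pure mean shift — the simplest
mechanism that produces a GoRT₄₀₋₂₀ difference; context effects on σ or on
the stop process are deliberately out of scope.

On a stop trial with delay SSD, the stop process finishes at
SSD + SSRT_true and the processes race independently: the stop wins iff
T ≥ SSD + SSRT_true; otherwise the subject responds at T. This independent
race is the model under which the integration-method SSRT estimator is
consistent, which is exactly why it was adopted: the simulator and the
estimator form a closed recovery loop (see §5). Failed-stop RTs are the
lower tail of the lift distribution and hence stochastically faster than go
RTs — the model reproduces this classic signature.

The SSD staircase is one-up/one-down with a fixed 33 ms step: +33 after a
successful stop, −33 after a failed one. Defaults the task itself does not
pin down:

- **initial SSD 550 ms** — near the steady-state SSDs the task produces
  (~610 ms) minus a margin, so burn-in is short but visible;
- **bounds [33, 767] ms** — the stop signal must occur on-screen, i.e.
  strictly between onset and the 800 ms crossing, on the 33 ms lattice;
- **carry-over across sessions** (default) — the second session resumes
  where the first converged; `reset_staircase_between_sessions=True`
  restores a cold start. Either way measures are computed per session.

One staircase is shared by the 20% and 40% conditions (a single mean SSD is
the natural summary); per-condition staircases can be emulated by composing
sessions.

A session is a 25-trial 0%-SSP go block followed by a 150-trial block
randomly interleaving 80 go + 20 stop trials at 20% SSP and 30 go + 20 stop
at 40% SSP; two sessions per subject give 350 trials. Go trials are subject
to configurable early-response (RT drawn uniformly in [150, 399) ms) and
omission (missing RT) rates, both defaulting to 2%.

## 2. Behavioral measures

Go trials with RT < 400 ms, RT > 1280 ms or no response are removed before
any RT statistic (the window is inclusive at both edges). Omissions are
*removed*, not replaced by the maximum RT; this follows the filtering rule
the rest of the pipeline is built around, and deviates from the consensus
recommendation of assigning omissions the slowest RT — users comparing
against that convention should expect slightly shorter SSRTs here when
omission rates are non-negligible.

Integration SSRT: with N filtered go RTs pooled over the 20% and 40%
conditions and P(inhibit) computed over all stop trials, the rank index is
n = round(N · P(inhibit)) with **half-up rounding**, clamped to [1, N];
SSRT = (n-th smallest go RT) − mean SSD. At P(inhibit) ∈ {0, 1} the
quantile is undefined and the session's SSRT is treated as missing (with a
logged warning) rather than extrapolated. Failed-stop RTs below 400 ms are
*retained* for RT_SF: the RT filter is a go-trial rule.

All measures are computed per session and averaged across sessions,
skipping sessions where a measure is undefined. GoRT₄₀₋₂₀ defaults to the
difference of session-averaged GoRT₄₀ and GoRT₂₀
(`slowing="difference-of-averages"`); the average of per-session
differences is available and identical for balanced sessions.

## 3. MRS quantification

The voxel is a GM/WM/CSF mixture. With volume fractions f_k (renormalized
to sum to 1; a mis-sum above 1e-3 warns, since segmentation output is
routinely off by rounding), relative water densities w_k and
water-content-weighted fractions f′_k = f_k w_k / Σ_j f_j w_j, the
corrected concentration of a water-referenced signal S is

C = S · C_water · Σ_k f′_k R_k / ((1 − f′_CSF) · A_met),
R_k = (1 − e^(−TR/T1_k)) · e^(−TE/T2_k).

Defaults: T1 = 1331/832/3817 ms and T2 = 110/79/503 ms for GM/WM/CSF,
TR = 2000 ms, TE = 68 ms, w = 0.78/0.65/0.97, C_water = 55 510 mM. These
T1/T2 values are canonical compartment **water** relaxation times and are
used as such inside the water term; metabolite relaxation is a separate
multiplicative attenuation A_met defaulting to 1 (no metabolite relaxation
correction). This separation is deliberate: folding literature metabolite
T1/T2 into the same constants would make the water term internally
inconsistent. Users wanting metabolite relaxation correction pass their own
A_met per metabolite.

Useful identities (all tested): the correction is linear in S; with one
compartment it reduces to S · C_water · R / A_met; at fixed S and GM/WM
ratio it is strictly increasing in f_CSF, since
C ∝ R̄_tissue + R_CSF · f′_CSF/(1 − f′_CSF).

QC: a spectrum enters quantification iff linewidth < 10 Hz **and** SNR > 5,
both strict; missing QC fields fail with reason `missing-qc`. Gating is
idempotent and order-independent. The NAA/mIns ratio is computed from
corrected concentrations and is missing whenever either input failed QC or
mIns ≤ 0.

## 4. Statistical chain

- **Group contrasts**: pooled-variance Student's t (df = n₁+n₂−2), matching
  the degrees of freedom a 25-vs-26 comparison prints (49); Welch is
  available behind `equal_var=False`. Two-tailed throughout.
- **FDR**: Benjamini–Hochberg step-up at q = 0.05 over the family of all
  metabolite/ratio × region group tests in a run; the reported critical
  value is the largest p passing its step-up threshold.
- **Screening**: Pearson r of every region × metabolite (and NAA/mIns) against
  GoRT, GoRT₄₀₋₂₀ and SSRT within each group, pairwise deletion for
  QC-missing values, candidates at uncorrected two-tailed p < 0.05. The
  screen is intentionally uncorrected — it only selects regression
  candidates, it is not an inference.
- **Regression**: OLS with listwise deletion per model. Standardized β is
  obtained by z-scoring both y and X (full standardization, so
  β_j = B_j·sd(x_j)/sd(y)). R²-change for predictor j is R²(full) −
  R²(without j), which equals the squared semipartial correlation of j
  with y. A two-step refit drops predictors with R²-change < 1% (the
  threshold is configurable) and refits once — an explicit, documented
  reduction rule in place of ad-hoc model trimming.
- **Fisher r-to-z**: z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)),
  first-named group first.

A caution on variance partitioning: squared semipartials do **not**
generally sum to ≤ R². Under suppression (predictors correlated with
opposite-sign effects) the sum can exceed R²; R²-change is a per-predictor
uniqueness measure, not an additive decomposition. The test suite contains
a counterexample-resistant formulation (each R²-change individually in
[0, R²]).

## 5. The synthetic cohort generator — what it emulates, and what not

Group defaults place the young group at μ = 815.5 ms (between-subject SD
9.5), SSRT 193 ms (SD 12.5), slowing 10.3 ms, and the older group at
821.6 ms (SD 20.6), SSRT 206 ms (SD 18.0), slowing 13.0 ms, with
trial-level σ = 50 ms and 2% early/omission rates — a cohort whose group
summaries resemble the target population (n = 25/26). Metabolite means/SDs
default to typical institutional-unit values (NAA 12±1.2, Glx 10±1,
Cr 8±0.8, Cho 2±0.25, mIns 6±0.9 mM-equivalent; NAA/mIns 2±0.3), identical
across regions; tissue fractions are drawn around (0.55, 0.35, 0.10) with
SD 0.03 and renormalized; 4% of spectra are planted as QC failures (half
low SNR, half broad linewidth). Signal levels are generated by *inverting*
the concentration correction per subject and voxel, so the corrected
concentrations equal the generated ones exactly and planted structure
survives the quantification stage by construction.

**Correlation planting.** Each planted effect targets one region ×
metabolite (or the NAA/mIns ratio) and one behavioral measure. By default
(`coupling="exact"`) the metabolite scores are built by Gram–Schmidt:
standardized anchor a, noise residualized against a and re-standardized,
combined as r·a + √(1−r²)·e⊥ — the within-sample correlation equals the
target exactly. `coupling="population"` plants r in expectation only.
Ratio effects are planted on the ratio itself (mIns drawn freely,
NAA = ratio × mIns).

The default anchor (`anchor="measured"`) is the session-averaged measure
the pipeline itself computes from the simulated trials. Rationale: a
planted pattern exists to validate the screening/regression chain, so it is
planted in the quantity that chain observes; anchoring to the latent
generating parameter (`anchor="true"`) additionally convolves the plant
with behavioral measurement reliability (≈0.8 for GoRT at 50 baseline go
trials), which turns a pattern-recovery check into a joint test of
measurement reliability and screening power. Both anchors are available;
recovery rates quoted by the test suite refer to the default.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: spectral artifacts and fitting error (QC failures are
planted labels, not modelled physics), region-specific metabolite profiles
and covariance between metabolites, non-Gaussian RT distributions and
sequential effects (post-stop slowing, fatigue, block-order effects),
context-dependent SSRT, and trigger failures. Recovery results on this
generator are statements about the estimators and the statistical chain
under the stated model, not about effect detectability in any particular
empirical dataset.

## 6. Reproducibility and problem sizes

All randomness flows from a single master seed through named
`SeedSequence` substreams (per group, behavior vs panel), so identical
configs reproduce bit-identical tables; the pipeline writes a manifest with
a config hash, versions, row counts and every exclusion (trial filter, QC,
listwise deletions).

Simulation-based checks use: 20 × 400 stop trials for staircase
convergence (burn-in 50); 5000 go / 2000 stop trials for SSRT recovery
(±10 ms band, chosen as ~3–4 Monte-Carlo SEs at that size); 10⁴ go
trials/condition for proactive-slowing recovery (±2 ms); 200 replicates of
an n = 25 single-group cohort for pattern recovery (≥90% criterion); 10⁵
draws for race-probability closed forms (±0.01). A full default run
(51 subjects × 350 trials, 7 regions × 5 metabolites) completes in a few
seconds on one CPU.

## 7. Known limitations

- The integration estimator inherits a small positive bias from staircase
  discreteness (the SSD lattice spans the 50% point rather than sitting on
  it); at the default geometry this is well under the one-step (33 ms)
  envelope and invisible at the ±10 ms recovery tolerance.
- Omission handling (removal) understates SSRT relative to the
  assign-maximum-RT convention when omission rates are high.
- The QC model is a labelling mechanism; it cannot probe how spectral
  quality interacts with quantification accuracy.
- R²-change values are not additive shares of R² (see §4).
- `validate` checks schema and logical invariants, not statistical
  plausibility; a well-formed but physiologically absurd table passes.
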
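# Methods

This note documents the models implemented in `pyruflux`, their
assumptions, the defaults that matter, what the synthetic generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Chamber flux estimation (`chamber_flux`)

**Model.** During a closure the headspace mole fraction follows
C(t) = Cs + (C0 − Cs)e^(−at): accumulation slows as the headspace
approaches the soil-gas concentration. The soil efflux corresponds to the
initial slope a(Cs − C0). Two estimators are fitted per closure after
discarding a 30 s mixing deadband (`deadband_s = 30`):

* a linear OLS fit over the first 120 s (`linear_window_s = 120`), which
  estimates the initial slope with a small negative bias of order a·T/2;
* the exponential model over the full 6.5 min closure, fitted by
  nonlinear least squares in the parameterization (C0, s0, a) with
  s0 = a(Cs − C0), which stays well conditioned as a → 0 (the ramp is
  evaluated with `expm1`). Bounds keep a in [1e−8, 1] s⁻¹ and the solver
  tolerances are tightened to 1e−14 so noise-free recovery is limited by
  conditioning, not stopping rules.

The exponential flux is used preferentially; it is replaced by the linear
flux when the fit fails, a ≤ 0, or its R² falls more than 0.05 below the
linear R² (`R2_MARGIN`). The margin operationalizes a visual
quality-control step that cannot be reproduced exactly; likewise, manual
outlier removal is replaced by a deterministic rule — within each chamber a
closure is rejected when its excess-¹³C flux deviates from a 5-point
rolling median by more than 4 robust standard deviations (1.4826·MAD).
These surrogates are documented choices, not claims of fidelity to any
particular manual screening.

**Units.** Mole-fraction rates (µmol mol⁻¹ s⁻¹) convert to areal fluxes by
the ideal gas law, F = slope·P·V/(R·T·A), with per-closure air temperature
and pressure. Water-vapour dilution is ignored (the analyser is assumed to
report dry mole fractions). Defaults: collar area 0.0318 m², chamber
volume 0.004076 m³ (a long-term opaque soil chamber); both configurable
since real systems vary.

**Isotope arithmetic.** The ¹²CO₂ and ¹³CO₂ channels are fitted separately
with the 120 s linear window (the exponential model is reserved for the
total flux); δ¹³C = ((F₁₃/F₁₂)/R_VPDB − 1)·1000 with R_VPDB = 0.0111802.
Because OLS is linear, F_total(linear) = F₁₂ + F₁₃ exactly. The
label-derived excess flux is F₁₃ − F₁₂·R_VPDB·(1 + δ_base/1000), where
δ_base is the chamber's mean pre-injection δ¹³C over a 12 h window
(`baseline_window_h`), emulating the overnight baseline measurements that
precede labelling. Negative excess values (noise around zero) are floored
at 0 and flagged — harmless for CO₂ because the labelled signal stays well
above the flux noise throughout 0–48 h.

## VOC enrichment (`voc_flux`)

The ¹³C fractional abundance a = c₁₃/(c₁₂ + c₁₃) is computed per 10 s
sample; its OLS slope over exactly the first 10 post-deadband points is
the enrichment rate. The ¹³C mass flux needed for cumulative budgets uses
the c₁₃-channel slope over the same window through the same ideal-gas
conversion. The natural-abundance contribution of the compound's baseline
emission is removed with the pre-injection baseline abundance a_b:
solving F₁₃ = a_b(F_tot − F_x) + F_x gives F_x = (F₁₃ − a_b·F_tot)/(1 − a_b),
which is exact in a forward-simulated round trip (the naive subtraction
F₁₃ − a_b·F_tot under-recovers by the factor 1 − a_b, i.e. 2–4 % for 2–4
carbon compounds). Per-compound natural abundance uses the ≥1-¹³C-atom
approximation a_nat = 1 − (1 − 0.011056)^nC.

VOC excess fluxes are *not* floored at zero: small pre-drought emissions
sit near the per-closure noise floor, and truncating the noise would bias
their cumulative effluxes upward by ~20 % and corrupt drought/pre-drought
ratios. Flooring is applied only where the signal dominates the noise (the
CO₂ channel), where it is cosmetic.

## Allocation (`allocation`)

Excess fluxes are averaged into the fixed right-closed bins
(0,3], (3,6], (6,12], …, (42,48] h for the paired per-bin biosynthesis
series (difference C1 − C2 and ratio C1/(C1+C2)), and integrated 0–48 h by
the trapezoid rule into mg ¹³C per chamber (rejected closures are dropped,
which linearly interpolates across them). The partition identities are

    pct_bio + pct_tca + pct_other = 100 (exactly, by construction)
    pct_voc_of_bio = 100 · cumVOC / (cumC1 − cumC2)

with cumVOC summing, per compound, the mean cumulative ¹³C-VOC over
C2-labelled chambers — the enriched volatiles of C2 chambers are
biosynthetic products, whereas ¹³C-acetate from C1 chambers arises from
acetogenic re-fixation of released ¹³C-CO₂ and is therefore excluded from
the biosynthesis share by default (`voc_positions=("C2",)`). A negative
biosynthesis share is reported and flagged, never clamped. Heterotrophic
CO₂ re-fixation can make all CO₂-based recoveries underestimates by up to
~5.6 %; this is treated as a sensitivity bound, not a correction.

Condition comparisons use drought/pre-drought ratios of chamber means per
label position. `compare_conditions_lme` wraps statsmodels `MixedLM` with
a fixed condition effect, a random site intercept and a chamber variance
component. The condition-specific residual variance available in nlme's
`varIdent` has no MixedLM equivalent; residuals are homoscedastic here,
and p-values use a t reference with n − n_sites − 1 degrees of freedom.
This wrapper exists for pipeline completeness and is intentionally thin.

## FTICR classification (`fticr`)

Retention requires S/N strictly greater than 7 and at least one CHONSP
candidate with |mass error| strictly below 1 ppm. Formula selection
discards candidates with P but fewer than 4 O per P, then ranks
lexicographically by (|error|, heteroatom count N+S+P, formula string);
assignments decided by the third key are flagged ambiguous. The van
Krevelen class boxes are evaluated in listing order with first-match-wins
(lipid, unsaturated hydrocarbon, protein, amino sugar, lignin, tannin,
condensed hydrocarbon); the lipid and unsaturated-hydrocarbon boxes
overlap at O:C ≤ 0.125, 1.5 ≤ H:C ≤ 2.5, and the precedence is exposed as
a switch (`order="unsaturated_first"`). The condensed-hydrocarbon upper
O:C bound is 0.95 — the stray "200" that sometimes appears typeset with
this boundary is treated as an artefact. Class profiles are count-based
relative abundances over assigned peaks (classified + unclassified sum to
1); peaks with no surviving candidate are reported separately.

## PLSR driver analysis (`plsr`)

Single-response NIPALS PLS1 on autoscaled predictors (ddof = 1 standard
deviations, matching common reference implementations; zero-variance
columns are centred to zero and carry no weight). Predictions were
verified against an independent PLS implementation to ~1e−15. Components
are selected by leave-one-out RMSECV over 0–10 components (0 = training
mean; scaling re-estimated inside every split; ties to fewer components).
VIP_j = sqrt(p·Σ_a SSY_a w_ja² / Σ_a SSY_a), so Σ VIP² = p identically.
Backward elimination removes the lowest-VIP predictor per step,
re-selecting the component count each step (a fixed-count mode is
available), and returns the recorded model with maximal training R² (ties
to fewer predictors). Model significance:
F = (SS_null/df_null)/(SS_CV/df_model), df_null = n − 1,
df_model = n − 1 − A, right-tail p from F(df_null, df_model); the df
convention is recorded in the output.

**Known limitation — null behaviour of the CV F-test.** The statistic
compares cross-validated residuals with in-sample null residuals, so it is
conservative under the null: leave-one-out inflates SS_CV, and whenever
component selection returns 0 the ratio SS_CV/SS_null equals (n/(n−1))²
deterministically, putting a point mass in the p-value distribution
(p ≈ 0.59 at n = 18). Simulation (200 null datasets, n = 18, p = 10) shows
the p-values are far from uniform (Kolmogorov–Smirnov D ≈ 0.42), and
conditioning on ≥ 1 selected component still rejects uniformity. The test
is therefore a conservative screen, not a calibrated p-value; the
corresponding uniformity check in the acceptance suite documents this by
failing.

## Synthetic data (`synthetic`)

The generator emulates the study design: paired C1/C2 chambers at 3 sites
× 3 replicates; 100 mg of sodium [¹³C]pyruvate (M = 111.03 g mol⁻¹, one
labelled position → 11.71 mg ¹³C) per collar; ~6 pre-injection closures at
2 h spacing, then 30 min spacing to 8 h and 50 min spacing to 48 h (≈ 64
post-injection closures); 390 s of usable samples per closure. Labelled
efflux follows a gamma pulse F(t) ∝ (t/τ)^s e^(−t/τ) — the simplest smooth
unimodal form with independent rise and relaxation — normalized so its
infinite-time integral equals the configured pool: injected·(f_bio+f_tca)
for C1 chambers, injected·f_tca for C2. Closures are rendered through the
same exponential headspace model the estimator assumes (curvature
5e−5 s⁻¹, mild), with i.i.d. Gaussian noise (σ = 0.05 / 0.005 µmol mol⁻¹
on the ¹²C/¹³C channels, 0.02 nmol mol⁻¹ on VOC channels, instrument-scale
values) and mean-one lognormal chamber-to-chamber variability (activity
σ = 0.08, baseline σ = 0.10). VOC pulses are configured per compound as
fractions of the biosynthesis pool (C2 chambers) plus an acetate-only
acetogenesis route from C1 chambers; VOC closures accumulate linearly at
10 s cadence.

**Scenario calibration.** The packaged `pre_drought.yaml` / `drought.yaml`
truths are the headline allocation percentages themselves (41.0/21.1/37.9
and 17.3/11.1/71.6), which simultaneously fix the cumulative ¹³C-CO₂
decreases (C1: 1 − 0.284/0.621 = 54.3 %; C2: 1 − 0.111/0.211 = 47.4 %).
The six VOC yields are solved from four ratio constraints — VOC share of
biosynthesis 0.0040 % → 0.15 %, acetone-C2 factor 25.3, acetate-C2 factor
2.6, diacetyl⁺ factor 4.0 (a representative increase; only its direction
is constrained) — plus a chosen pre-drought diacetyl⁺ yield of 4e−6 of the
biosynthesis pool. The acetate-C1 acetogenesis yield is 1e−5 → 1.9e−5 of
the injected ¹³C (factor 1.9). Pulse time constants: τ = 5 h pre-drought,
7 h drought (slower turnover under moisture limitation), shape s = 1;
VOC τ = 6–8 h.

**What the generator does not emulate.** PTR ion chemistry, fragmentation
and calibration; instrument drift and autocorrelated noise; diurnal
temperature/moisture forcing of the baseline flux; soil-gas transport
(production is mapped directly to surface efflux with a single smooth
pulse); isotopic fractionation during respiration or diffusion; CO₂
re-fixation. Passing round-trip tests therefore demonstrates correctness
of the estimators under the stated measurement model, not robustness to
every artefact of field data.

**Recovery accuracy.** Small systematic shortfalls are expected and
understood: truncating the pulse at 48 h loses 0.3–0.8 % of its integral,
and the 120 s linear window on curved closures under-reads initial slopes
by ~0.5 %. Together these keep end-to-end partition recoveries within
~1 percentage point of the configured truths (ratios between conditions
are essentially unaffected), well inside the ±2-point acceptance band.

## Problem sizes and runtimes

The packaged scenarios produce 18 chambers × 71 closures × 196 samples
(~250 k rows) per condition; the full dual-condition pipeline —
generation, ~2,500 nonlinear closure fits, VOC processing, integration and
partition — runs in ~25 s on one CPU. The statistical simulations use 100
elimination runs and 200 null datasets at the study shape (n = 18,
p = 10), and 500-replicate noise studies for the per-closure estimators.
The complete test suite runs in about a minute.
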
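# Methods

This note documents the models implemented in `cpftk`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## In vitro kinetics and whole-body scaling

Apparent Michaelis–Menten parameters are estimated by nonlinear least
squares with **proportional (relative) weighting** by default: in vitro
velocities span orders of magnitude across the concentration designs and a
constant-CV error model matches how such assays behave. Absolute weighting
is available (`relative_weighting=False`). A fit fails explicitly on
non-convergence, on all-zero velocities, or on a non-positive estimate.

Scaling constants, all overridable:

| quantity | value | note |
|---|---|---|
| MPL | 32 mg microsomal protein/g liver | standard adult value |
| VL | 0.0257 · BW | liver ≈ 2.57% of body weight |
| VB | 0.0753 · BW | back-calculated so that the plasma PON1 activity of 1844 nmol/min/ml scales to ≈ 3.21·10⁵ µmol/h at BW 70 |
| plasma fraction | 0.55 of blood volume | plasma PON1 acts in the plasma of the blood compartment |

**ISEFs.** The adopted ISEF set (0.07, 0.48, 0.21, 0.11 for CYP1A2, 2B6,
2C19, 3A4) is carried explicitly in `params` and used by default; ISEFs can
also be recomputed from the probe-substrate Vmax pairs. For CYP2C19 the
recomputed value (≈0.18) differs from the adopted 0.21 because the
two-decimal rounding of the pooled-HLM probe Vmax (0.02 nmol/min/mg) loses
most of its precision; the adopted value is treated as authoritative.

**Eadie–Hofstee biphasicity flag.** A curve is called biphasic when a
two-segment line fit of v vs v/S reduces the one-line residual sum of
squares by ≥50% *and* the Km values implied by the two segment slopes differ
by ≥10-fold. The slope criterion is essential: any smoothly curved mixture
improves under two segments, but only mixtures of affinities an order of
magnitude apart show the two-limb pattern read as biphasic in practice.
Both thresholds are arguments. With the default CPF kinetics this flags the
bioactivation pathway (Km spread ~0.14–30 µM, segment ratio ≈50) biphasic
and the detoxification pathway (Km 1.25–18 µM, ratio ≈4.5) monophasic.

## PBK model

Flow-limited perfusion model, amounts in µmol, time in hours:

* **CPF**: gut lumen → (first-order ka, fraction fa absorbed into the
  liver; the remainder leaves in faeces) → liver, fat, richly perfused,
  slowly perfused, blood. Metabolism (pathways 1 and 2) occurs in the liver
  at the liver-venous concentration.
* **CPO**: formed in liver (pathway 1), hydrolysed by hepatic PON1
  (pathway 3, liver-venous concentration) and plasma PON1 (pathway 4, blood
  compartment, total concentration by default — a switch selects unbound),
  distributes over liver, blood and a lumped rest-of-body compartment.
* **TCPy**: single body pool fed by pathways 2–4 with first-order urinary
  elimination (ke = 0.03 h⁻¹, set so that excretion is essentially complete
  by ~120 h).

Physiology: BW 70 kg; cardiac output QC = 15·BW^0.74 L/h split 25/26/5/44%
to liver/richly/fat/slowly perfused; tissue volumes 2.57/7.53/21/5/55% of BW
(liver/blood/fat/rich/slow), remainder carcass. ka = 0.46 h⁻¹; fa = 0.462,
the mean of the two reported human absorption fractions (0.224, 0.7);
fu(CPO, plasma) = 0.15; blood:plasma ratios 2.7 (CPO) and 1.3 (CPF).

Tissue:blood partition coefficients are computed from logP (CPF 4.784, CPO
3.89) with a lipid-fraction weighted octanol:water surrogate over a standard
tissue-composition table, and stored in the scenario so measured values can
be substituted. The population adjustment factors are ratios of Cmax values
and are insensitive to these coefficients to first order.

Because the compartmental backbone is a reconstruction (a standard CPF
architecture assembled from the pathway rate laws and scaling equations, not
a reprint of any specific prior parameterization), absolute concentration
predictions carry that structural uncertainty; ratio-valued outputs (HK_AF,
fold comparisons between kinetic descriptions) are the robust quantities.

**Numerics.** LSODA (stiff-capable; the CPO hydrolysis pathways impose
effective rate constants of order 10²–10³ h⁻¹ against an absorption constant
of ~0.5 h⁻¹) with rtol 1e-8/atol 1e-12 by default; Cmax is taken from the
output grid with parabolic refinement around the bracketed maximum. Mass
balance (Σ states = dose; the molar stoichiometry is 1:1 along every
pathway) is checked on every simulation; residuals are at machine precision.
The Monte Carlo uses rtol 1e-6/atol 1e-10 over a 12 h window (CPO peaks
within the first hour at reference absorption; the slowest sampled ka still
peaks well inside 12 h), which biases Cmax by <0.2% uniformly across draws
and therefore cancels in the HK_AF ratios.

## Population Monte Carlo

Every variable parameter is lognormal with the stated (mean, CV),
transformed to log space (μ_w = ln(μ/√(1+CV²)), σ_w² = ln(1+CV²)) and
truncated at ±3σ_w. **Out-of-bounds draws discard the whole run** — they
are not clipped or redrawn — so accepted-run counts fall a few percent below
nominal and are reported (≈98% in the kinetic-only scope; ≈90% in the
all-influential scope, where the absorption fraction's hard cap at 1 sits at
+1.5σ_w of its CV-0.73 distribution and dominates the rejection).

Scopes:

* `kinetic_only`: CYP abundances (recombinant route) or HLM Vmax/Km pairs
  (microsomal route), plus the PON1 pathway-3 and pathway-4 Vmax/Km, all
  independent.
* `all_influential` adds body weight (CV 0.3) — liver/blood volumes and all
  flows are recomputed from each BW draw rather than sampled separately,
  because they are functions of BW — plus ka (0.3), fa (0.73, capped at 1),
  MPL (0.46) and fu(CPO, plasma) (0.3). The CPO blood:plasma ratio is
  sampled with the *same standardized deviate* as the fu draw (its
  prediction is driven by the plasma free fraction); with equal CVs this
  makes fu_blood = fu/BP nearly invariant across draws, so protein binding
  contributes little net variance — a consequence of the stated correlation,
  not an omission.

No correlation is imposed between the four metabolic pathways, which
maximizes the spread of the predicted Cmax and makes the HK_AF conservative.
CYP2B6 (EM/PM) and CYP2C19 (EM/PM/UM) phenotypes form six combinations run
as separate strata with weights equal to the products of the phenotype
frequencies; the CYP2C19 poor-metabolizer abundance is exactly zero and that
pathway contribution vanishes for those strata.

Weighted statistics: geometric mean on log-scale weighted average;
percentiles by inverting the weighted empirical CDF with midpoint plotting
positions and linear interpolation (reduces to the Hazen quantile for equal
weights). HK_AF = P95/GM or P99/GM of the free blood Cmax of CPO at
0.47 mg/kg bw. Per-combo RNG substreams are spawned deterministically from
the seed, so results are reproducible and independent of execution order.

Reference problem size: 2000 draws per combination (12,000 runs per scope),
a few minutes on one CPU. The sampler's validation targets are the
closed-form moments of the *truncated* lognormal (truncation at ±3σ_w trims
the realized CV by ~1–4% below the nominal CV), and the identity-model
closed form HK_AF = exp(z_p·σ_w) is checked alongside every population run.

## Reverse dosimetry and benchmark dose

The in vitro unbound fraction is taken as 1 (only 0.1 mg/ml albumin is
present in the assay medium); the in vivo free blood concentration is
C_total · fu_plasma/BP ≈ C_total/18 at the default constants. The in vivo
dose axis is obtained by inverting the tabulated dose → free-Cmax map
(29 log-spaced doses, monotone PCHIP interpolation in log-log space;
round-trip error <0.5%). Response values transfer unchanged as
% inhibition = 100 − % activity, with zero background at zero dose.
Percentile curves divide the dose axis by HK_AF (P99, sensitive) or by
P1/GM (insensitive) — the standard CSAF usage of shifting the dose axis
rather than the response.

BMD analysis fits continuous exponential (a·(1−exp(−(b·d)^c))) and Hill
(T·dⁿ/(kⁿ+dⁿ)) models by least squares with a Gaussian likelihood, defines
the BMD at 10 percentage points of AChE inhibition above the zero
background, and obtains the BMDL as the one-sided 95% profile-likelihood
lower bound (the dose-scale parameter is eliminated analytically through the
BMR constraint; the remaining shape parameters are re-optimized per
candidate BMD). Model choice is by lowest AIC. This is a self-contained
continuous BMD routine, not a reimplementation of any regulatory software's
exact numerics; on model-generated smooth curves the residual variance is
near zero and BMDL ≈ BMD, which is the expected behaviour of a likelihood
bound, not an error.

## Synthetic data

Generators emulate the three assay families with multiplicative lognormal
observation noise (default CV 5%, duplicate measurements): incubation
velocity curves on the published concentration designs, a 25-individual
plasma panel whose (Vmax, Km) are drawn independently from the population
truth (1844 nmol/min/ml CV 0.29; 290 µM CV 0.33), and AChE plates whose
absorbance deltas invert the control normalization exactly. Every generator
is a bit-exact function of its seed and forms a calibrated pair with its
fitter (noiseless round trips exact to solver tolerance; noisy round trips
unbiased within Monte Carlo error).

What the synthetic data does *not* emulate: within-individual Vmax–Km
correlation (real plasma panels show a narrower CE spread, ~2.6-fold,
than the ~4–6-fold produced by independent sampling), assay drift,
plate-position effects, and chromatographic quantification error structure.
Passing round-trip tests therefore demonstrates correctness of the
estimators under the stated error model, not robustness to those real-data
features.

## Known limitations

* Adult (Caucasian reference) physiology only; single oral dosing; no
  dermal/inhalation routes and no sensitive sub-populations (pregnancy,
  children), where lower PON1 activity would shift the CPO balance.
* Partition coefficients are predicted, not measured; absolute blood
  concentration predictions should be treated as order-of-magnitude until
  calibrated against in vivo profiles.
* The single-phase (non-biphasic) microsomal mode is retained only as a
  negative control: it misses the high-affinity CYPs and underestimates CPO
  formation at realistic low exposures, and is excluded from population
  simulation.
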
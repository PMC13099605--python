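# Methods

This note documents the models, estimators and numerical choices behind
`rubiscohet`, and what the simulation-based tests do and do not establish
about real data.

## Assembly models

The holoenzyme has `n = 8` SSu sites. Under independence, the His-tagged
copy number is k ~ Binomial(8, p) with p the His-skew. Predicted
heterogeneity is `1 − p^8 − (1−p)^8`; its complement (the homogeneous
fraction) is minimized at p = 0.5, where it equals 1/128.

The departure-from-independence model fills sites sequentially: the first
site is His with probability p; thereafter the odds of repeating the species
at the previous site are multiplied by α (α > 1 favours homogeneous runs,
α < 1 favours alternation, α = 1 recovers the binomial). This is the
simplest one-parameter chain consistent with "consecutive incorporation may
not be independent"; it makes no claim about *which* sites are occupied
(spatial arrangement is out of scope). The pmf is computed by an O(n²)
dynamic programme over (previous species, count) and is verified in the
tests against brute-force enumeration of all 2⁸ ordered fill sequences.
`fit_preference_alpha` inverts predicted heterogeneity over α by bracketed
root finding on log α (default bounds 1e−3…1e3, tolerance 1e−8);
heterogeneity is monotone decreasing in α, so the root is unique, and an
unattainable target raises `NoSolutionError` rather than clamping.

## Corrected purification estimators

Inputs are band intensities per (replicate, stage, antibody), stages
soluble → post-His → post-Strep, antibodies anti-His and anti-Strep.
Optional flow-through rows are accepted and ignored.

* e_His = anti_His(post_His)/anti_His(soluble): every anti-His-positive
  complex carries a His tag, so its loss across the His column is column
  inefficiency. Likewise e_Strep = anti_Strep(post_strep)/anti_Strep(post_his).
  Ratios above 1 (densitometry noise) are capped at 1 with a warning
  (configurable); zero denominators exclude the replicate with a logged
  reason.
* Corrected dual-tagged amount: a_het = anti_Strep(post_strep)/(e_His·e_Strep),
  divided by the anti-His/anti-Strep gain ratio (default 1, i.e. both
  signals normalized to a shared standard).
* Initial totals by inclusion–exclusion:
  a_total = a_His + a_Strep − a_het, valid when every holoenzyme carries at
  least one of the two tags — true for dual-tagged constructs.
* Measured heterogeneity = a_het/a_total per replicate; replicate estimates
  are made first and then summarized as mean ± SD (n = 6 in the motivating
  design).

**Two signal conventions.** A native-PAGE band blotted with an anti-tag
antibody can scale with the number of complexes carrying ≥ 1 tag
(`per_holoenzyme`) or with the total number of tag epitopes (`per_tag`).
The heterogeneity estimator is exact under complex-count signal; the
His-skew — a tag-level fraction — is exact under tag-count signal, where
`his_skew` divides by a_His + a_Strep (its default). The
inclusion–exclusion denominator is available (`total="inclusion_exclusion"`)
and then the ratio is the His-containing-complex fraction instead. Real
immunoblots sit between the two conventions; both are implemented in the
simulator so each estimator can be validated under its own assumption.

**Known biases.**

1. *Tag-dependent capture.* If a column captures each matching tag
   independently with probability q (retention 1 − (1−q)^m for m tags), the
   efficiency estimates are dominated by tag-rich complexes while the
   dual-surviving pool is tag-poorer, and the estimator *underestimates*
   heterogeneity. This is reproduced in the noise-free validation grid for
   every (skew, q) combination tested (bias ≈ −0.0002 to −0.01).
2. *Multiplicative densitometry noise.* The corrected amount is a product
   and ratio of noisy intensities; with unit-mean lognormal noise,
   E[1/X] > 1/E[X], and the cap of efficiency estimates at 1 truncates
   their noise distribution downward. Both effects bias the estimator
   *upward* — about +0.02 at CV 0.05 and +0.2 at CV 0.15 in the default
   grid — and dominate the small tag-dependence bias at realistic noise.
   The validation study therefore reads the tag-dependence failure mode
   from its noise-free cells; noisy cells quantify the noise-induced bias.

## Synthetic-data generator

What it emulates: binomial or preference-chain assembly pools; tandem
capture with constant or per-tag column efficiencies; blot intensities
under either signal convention with multiplicative lognormal noise
(intensities are positive and errors scale with signal); deconvoluted MS
mass ladders with Gaussian mass error and a relative-abundance detection
floor; Michaelis–Menten rate tables, first-order recovery traces and
Boltzmann melt curves.

Column survival uses expected-count weights by default — each holoenzyme
contributes its retention probability — so noise-free pipelines are exactly
deterministic and conservation (retained + discarded = loaded) holds
exactly; Bernoulli sampling of survival (`sampling=True`) exists for
Monte-Carlo checks of the closed-form retention probabilities. All
generators are seed-reproducible (identical seeds give bit-identical
output); multi-replicate experiments derive per-replicate seeds from a
`SeedSequence`.

What it does not emulate: gel/blot images (inputs are already-quantified
intensities), raw m/z spectra and charge-state deconvolution (neutral
masses only), antibody cross-reactivity, partial tag occupancy within a
subunit, or three-species pools (in-planta experiments with untagged SSus
are detection-only and out of scope). Passing tests therefore establish
estimator correctness under the stated statistical model, not robustness to
these unmodelled features.

Default study conditions: 10⁵ holoenzymes per pool, 6 replicates, column
efficiencies 0.8/0.9, per-tag capture q = 0.2–0.5, densitometry CV
0–0.15, skews 0.4–0.6. The source experiments do not state their
simulation's noise or efficiency ranges; these values were chosen once to
cover realistic western-blot variability and clearly sub-unity column
capture, and the validation grid spans them rather than a single point.

## MS stoichiometry assignment

The ladder has nine rungs. Empirical mode anchors rung 0 and rung 8 on the
measured masses of the two homogeneous holoenzymes and interpolates — the
default, because measured native masses carry adducts and terminal
processing that sequence masses miss. Theoretical mode builds rungs from
the two subunit masses plus an invariant core mass; with subunit masses
15.62 and 22.48 kDa the step is 6.86 kDa, versus 6.751 kDa for the
empirical anchors 548.08/602.09 kDa — a ~0.11 kDa/step discrepancy, which
is why both modes exist. Each peak is assigned to the nearest rung;
exact ties break toward lower k with a warning; the default tolerance is
step/4 and the residual is always reported. Assignment is provably unique
when mass error < step/2, and simulated Gaussian error with SD < step/6
never misassigns in the tests. One of the four reference heterogeneous
masses (586.39 kDa) falls ≈ 2.2 kDa from its nearest rung; the assigner
reports the residual and flags it out-of-tolerance instead of forcing a
label, since the upstream matching presumably involved adduct handling not
reproducible from the printed masses alone.

## Kinetics and stability fits

* **Michaelis–Menten**: v = V·S/(K+S) per replicate by bounded (positive)
  nonlinear least squares, initialized from a Hanes–Woolf linearization;
  the "average model" is the mean of per-replicate parameters (matching a
  fit-each-replicate protocol). Non-converged or all-zero replicates are
  flagged and excluded from the summary with a log entry. At the reference
  design (six substrate levels spanning 0.1–3.2 K, n = 5, 5 % CV), median
  relative error is < 5 % for V_Cmax and < 15 % for K_m over 100
  simulations.
* **Activation energy**: two-point Arrhenius,
  E_a = R·ln(v2/v1)/(1/T1 − 1/T2), temperatures converted to kelvin.
  Replicate-paired by default; a mean-based route is available by passing
  mean V_Cmax values directly.
* **Recovery from inhibition**: default instantaneous-rate form
  v(t) = v_final·(1 − e^(−k_obs·t)) (suits activity-over-time data); the
  integrated product-accumulation form
  P(t) = v_s·t − (v_s/k_obs)(1 − e^(−k_obs·t)) is selectable. Constant
  traces are flagged unidentifiable. k_obs is invariant to activity-unit
  rescaling.
* **Melt curves**: four-parameter Boltzmann sigmoid (baselines, T_m,
  slope). The van't Hoff enthalpy uses the transition steepness,
  ΔH_vH = R·T_m²/m (m = slope in kelvin), and ΔG°_unfolding extrapolates
  to a reference temperature (default 25 °C) via Gibbs–Helmholtz with
  configurable ΔCp (default 0). ΔG(T_m) = 0 by construction. This is a
  standard two-state reconstruction — the exact thermal-shift protocol
  behind reported ΔG°_unfolding values is not specified in the source, so
  values should be compared within, not across, analysis pipelines. T_m is
  invariant to affine signal transforms.

## Group statistics

Classical (equal-variance) one-way ANOVA and Tukey HSD on the studentized
range, matching the stated figure-caption procedures; no Welch variant.
Compact letters are built by insert-and-absorb — start with one class
containing all groups; for each significantly different pair, split every
class containing both and absorb subset classes — which guarantees two
groups share a letter iff they are not significantly different. Letters are
assigned in descending order of group mean. The one-sample t-test (e.g.
His-skew vs 0.5) is two-sided and rejects degenerate inputs (n < 2 or zero
variance).

## Problem sizes in the test suite

The suite simulates 10⁵-holoenzyme pools with 6 replicates for estimator
properties, 100 simulations for kinetic parameter recovery, 10⁴ null
simulations for t-test calibration, and exhaustive enumeration (2⁸ fill
orders; all significance patterns on 3 groups, 300 sampled patterns on 4–5
groups) for the combinatorial oracles. These sizes make Monte-Carlo error
small relative to every asserted tolerance while keeping the full suite
under a minute.
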
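# rubiscohet

Quantitative analysis of small-subunit (SSu) heterogeneity in Form I
(L8S8) Rubisco.

Plant Rubisco carries eight small-subunit binding sites, and plants express
several SSu isoforms at once. When two distinguishable (affinity-tagged) SSu
species are co-expressed, a single holoenzyme can incorporate both — an
*SSu-heterogeneous* holoenzyme. This package implements the quantitative
pipeline for detecting and measuring that heterogeneity from tandem
affinity-purification experiments, native mass spectrometry, and downstream
kinetic and stability assays. It is written for biochemists analysing
stage-tracked western-blot intensities, deconvoluted MS peak lists, and
plate-reader kinetics, and for anyone who wants to stress-test the
estimators on simulated data.

## The models

**Binomial assembly.** If each of the 8 sites is filled independently by the
His-tagged species with probability *p* (the *His-skew*, the His-tagged
fraction of the incorporated SSu pool), the His-tagged copy number *k* per
holoenzyme is Binomial(8, *p*). Predicted heterogeneity is
1 − *p*⁸ − (1 − *p*)⁸; at even skew (*p* = 0.5) only 1/128 ≈ 0.78 % of
holoenzymes are homogeneous. A one-parameter *sequential-preference* chain
(odds of repeating the previous species multiplied by α) models departures
from independence, and `fit_preference_alpha` inverts it.

**Efficiency-corrected heterogeneity.** Tracking blot intensity at each
purification stage gives the column efficiencies
e_His = I_His(post-His)/I_His(soluble) and
e_Strep = I_Strep(post-Strep)/I_Strep(post-His); the corrected dual-tagged
amount is I_Strep(post-Strep)/(e_His·e_Strep), and measured heterogeneity is
its share of the inclusion–exclusion initial total. A simulation study
(`rubiscohet validate`) quantifies when this correction is unbiased and when
it underestimates (capture probability increasing with tag count).

**Mass-ladder stoichiometry.** Two SSu species of different mass give nine
possible holoenzyme masses spaced by a fixed step; each deconvoluted
native-MS peak is assigned to its nearest rung, with residuals and a
tolerance flag reported rather than forced labels.

**Kinetics and stability.** Per-replicate Michaelis–Menten fits
(V_Cmax, K_m^RuBP), two-point Arrhenius activation energy, slow-binding
inhibitor-release recovery (k_obs), and Boltzmann melt fits with a two-state
van't Hoff ΔG°_unfolding. Group comparisons use one-sample *t* tests,
one-way ANOVA and Tukey HSD with compact-letter ranking.

## Worked example

Simulate a six-replicate tandem-purification experiment in which assembly
*prefers homogeneous runs* (α = 4), then quantify it:

```sh
$ rubiscohet simulate --skew 0.5 --alpha 4 --n-holoenzymes 100000 \
    --n-replicates 6 --e-his 0.8 --e-strep 0.9 --cv 0.05 --seed 7 \
    --out records.csv
$ rubiscohet heterogeneity records.csv
His-skew: 0.5074 (n = 6)
measured heterogeneity: 0.7963 ± 0.0678
predicted heterogeneity (binomial): 0.9919
predicted − measured: +0.1956 (paired t p = 0.000885)
```

The skew is even (≈ 0.5), so the independence model predicts 99 %
heterogeneity, but the corrected estimator recovers the true simulated
value (0.790 under α = 4) — the significant gap is the signature of
non-independent SSu binding.

Assign the four heterogeneous native masses on the ladder anchored at the
measured homogeneous masses (548.08 and 602.09 kDa):

```sh
$ rubiscohet stoich peaks.csv --anchor-low 548.08 --anchor-high 602.09
 mass_kDa  k_heavy ratio_light_heavy  residual_kDa  within_tolerance
   561.63        2               6:2       0.04750              True
   586.39        6               2:6      -2.19750             False
   575.16        4               4:4       0.07500              True
   581.91        5               3:5       0.07375              True
4 distinct stoichiometries (ladder step 6.7513 kDa)
```

Four distinct SSu ratios; 586.39 kDa falls between rungs and is flagged
instead of silently relabelled.

Other subcommands: `mm`, `ea`, `kobs`, `melt` (kinetics), `compare`
(ANOVA/Tukey/letters), `validate` (estimator bias grid), `report`
(consolidated Markdown report). Everything is also available as library
functions (`rubiscohet.assembly`, `.purification`, `.ms`, `.kinetics`,
`.stats`, `.synthetic`, `.pipeline`).

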
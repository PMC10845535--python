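# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `rumensemble`.

## Residual feed-efficiency traits

Dry matter intake (DMI, kg/d) of a lactating cow is modelled as a linear
mixed model over its major energy sinks:

    DMI = β0 + β_par·multiparous + β_MBW·MBW + β_BEC·BEC + β_NES·NESec
          + u_cohort + ε

with a random intercept `u_cohort` for treatment nested within experiment
and REML estimation (statsmodels `MixedLM`). The conditional residual
`ε = DMI − fixed part − predicted cohort effect` is the **residual feed
intake (RFI)**: a cow that ate less than predicted has negative RFI and is
the more efficient animal. Milk fat and protein gross efficiencies
(MFE/MPE, g of component per kg DMI) get the analogous model with DMI as
an additional fixed effect; their residuals are oriented the other way
(larger residual = more efficient).

Supporting closed forms:

* `NESec = 9.29·fat + 5.47·protein + 3.95·lactose` (Mcal/d, yields in kg/d)
* `MBW = BW^0.75` (kg^0.75)
* `BEC = (2.88 + 1.036·BCS) · ΔBW` (Mcal/d, ΔBW in kg/d)

One widely circulated tabulation labels BEC in kg/d; the defining formula
produces an energy, so this package uses Mcal/d throughout and treats the
kg/d label as a typo.

Per-predictor importance is reported as drop-one R²:
`R²_k = (RSS_without_k − RSS_full)/TSS`, refitting the model with that one
fixed effect removed (random structure retained); the cohort share drops
the random intercept instead. These parts need not sum to the total R².
Both conditional (`1 − RSS_cond/TSS`) and marginal R² are reported; the
conditional value defines the residual share. When the REML variance
estimate hits the zero boundary the fit degenerates to OLS exactly, which
the implementation takes as an explicit branch (also available on demand
via `force_zero_variance=True`).

## Synthetic cohort generator

`simdata.generate_cohort` emulates a multi-site 454-cow study: 6
experiments, 19 treatments, 49% primiparous cows, covariates drawn with
means/SDs of NESec 27.1 ± 4.2 Mcal/d, MBW 127 ± 9.7 kg^0.75, BEC
2.60 ± 3.20 Mcal/d, BCS 3.0 ± 0.4 (clipped to [1,5] in 0.25 steps). Milk
component yields are allocated from a target NESec and realistic
composition percentages (fat 3.55%, protein 3.05%, lactose 4.75% of milk),
so the NESec identity holds exactly in the generated table. Diet fatty
acid (ether-extract proxy, 4.64 %DM) and NDF (28.6 %DM) vary at the
experiment level.

The DMI model coefficients default to parity 0.87, MBW 0.09, BEC 0.17 and
NESec 0.37; the intercept is solved so mean DMI is 22.6 kg/d. Cohort and
residual variances are derived analytically from the configured shares
(cohort R² 0.07; residual/RFI share 0.19 of DMI variance), so the
generated cohort reproduces the intended variance decomposition without
calibration runs.

Microbiome counts use a log-normal abundance model with multinomial
sampling: per-genus mean log-abundance ~ N(0, 2.0), per-sample
overdispersion SD 1.0, lognormal read depths (mean 20,000, floor 3,000 —
the usual rarefaction inclusion depth). Compositional closure happens only
at the sampling step, so the CLR of deep samples tracks the true centred
log-abundance. Planted taxa (5 per trait by default, log-scale effect 2.0
per SD of a latent cow factor) shift with the factor; the per-cow *planted
score* is the effect-weighted sum of the planted taxa's true CLR values,
standardized, and contributes a configurable fraction of the residual
variance (RFI 0.36; residual MFE 0.57; residual MPE 0.48).

Two constructional details matter for parameter recovery:

* CLR closure couples even disjoint planted sets through the per-sample
  geometric mean, and the milk-side perturbations feed into NESec. The
  realized RFI score is therefore residualized against the full
  fixed-effect design (and the milk scores and treatment indicators)
  before scaling, which makes the configured DMI coefficients the exact
  finite-sample estimand; the independent Gaussian noise channel (64% of
  the residual) still gives refits their full sampling variability.
* Milk-side planted effects are injected through the fat/protein yields
  *before* DMI is computed, so the DMI equation holds against the final
  recorded NESec. Because NESec then partially absorbs the milk-side
  planted signal, the realized variance fractions for residual MFE/MPE are
  approximate; only the RFI fraction is treated as exact.

What the generator does **not** emulate: read-level artifacts (chimeras,
denoising), longitudinal sampling, phylogenetic signal in the taxonomy,
taxon-taxon interaction structure, and real-data covariate collinearity
(covariates are drawn independently). Tests passing on these cohorts
therefore validate the pipeline's statistical machinery, not its behaviour
under every real-data pathology.

## Feature engineering

Genus counts are collapsed to the five ranks (phylum…genus) and expressed
three ways — raw count, percent relative abundance, CLR — plus 22
alpha-diversity indices computed once at the genus (leaf) level, for
`3·(total taxa across ranks) + 22` features. The CLR uses a 0.5
pseudocount (matching the Dirichlet prior in the Monte-Carlo test;
configurable). Standard CLR is already centred per sample; a description
that centres it a second time is redundant and is not reproduced.

Most indices follow their textbook forms (Shannon, bias-corrected Chao1,
inverse/Gini-Simpson, Pielou, Berger–Parker, Fisher's α by root finding on
`S = α ln(1+N/α)`). Indices whose published names lack a canonical
formula are pinned as follows, each behind its own function so alternates
can be swapped: coverage = minimal number of taxa reaching 50% abundance;
Camargo `1 − Σ_{i<j}|p_i−p_j|/S`; Evar `1 − (2/π)·arctan(var ln counts)`;
Bulla `(Σ min(p_i,1/S) − 1/S)/(1 − 1/S)`; core abundance = summed share of
taxa above 0.2% in more than half the samples; low-abundance rarity =
share below 0.2% in the sample; rare abundance = 1 − core abundance;
log-modulo skewness = `ln(|skew|+1)` of a 50-bin abundance histogram.
`dominance_dbp` and `dominance_relative` coincide under these definitions;
both columns are still emitted to preserve the 22-column contract.

## Ridge prediction with nested CV selection

Candidates are ranked by absolute univariate correlation with the trait
and accepted greedily into a ridge model (standardized columns, intercept
unpenalized, penalty re-chosen from {0.01…1000} at every step by 5-fold
CV). A candidate is accepted only when it lowers the inner-CV MSE by more
than twice the paired fold-wise standard error of the improvement; the
walk stops after 10 consecutive rejections or 50 accepted features. This
margin rule is deliberately stricter than "any MSE decrease": when
hundreds of null features are screened, fold-noise would otherwise admit
dozens of them.

Reported R²/MSE/RMSE come from an outer seeded 10-fold cross-validation
(folds stratified on the residual's sign) in which the *entire* selection
is re-run inside each training split — ranking, acceptance and penalty
choice never see the held-out fold, so a pure-noise trait yields R² ≈ 0.
The reported feature list comes from one final selection pass on all cows
(the model a user would deploy). An alternative that reports refit-on-all
R² would read higher; the out-of-fold number is the honest one.

Sign-based evaluation: residuals are split at zero (exact zeros go to the
efficient/negative class) and a confusion matrix with precision, recall
and F1 is computed; the positive class defaults to the inefficient
(positive-residual) cow and is configurable.

## Differential-abundance analogs

Four deliberately simplified two-group tests, each keeping one defining
idea (the `-like` suffix marks them as analogs, not re-implementations):

* **aldex_like** — 128 Dirichlet(counts + 0.5) Monte-Carlo instances per
  sample; CLR per instance; per-taxon Wilcoxon rank-sum (normal
  approximation); BH within instance; the reported q-value is the mean
  adjusted p over instances (an expected-BH analog).
* **ancombc_like** — `y = ln(x+1)`; per-sample sampling-fraction offsets
  estimated by alternating means (tolerance 1e-8, max 100 iterations);
  per-taxon group coefficient on the offset-corrected data; the residual
  common-mode bias (the mean shift the offsets cannot identify) is removed
  as the median of all coefficients; t-reference Wald test; BH.
* **maaslin_like** — total-sum scaling; log2(ra + half the minimum nonzero
  relative abundance); per-taxon linear model t-tests; BH q-values.
* **linda_like** — CLR (pseudocount 0.5); per-taxon group coefficients;
  compositional bias estimated as the mode of all coefficients (Gaussian
  KDE, Silverman bandwidth, argmax on a 512-point grid) and subtracted;
  t-reference Wald test; BH.

The t reference (df = n₁+n₂−2) replaces the asymptotic normal in the two
Wald-type tests because BH operates in the far tail, where the normal
approximation at 50+50 samples is visibly anti-conservative. All tests
run on taxa with prevalence strictly above 10% and declare significance at
adjusted p ≤ 0.05. Covariate adjustment and designs beyond two groups are
out of scope.

## Consensus ensemble

For one trait, up to ten votes per genus: forward-backward stepwise OLS
selection with lowest-AICc model choice (AICc = AIC + 2k(k+1)/(n−k−1)) in
each of the three representations; the ridge selector's chosen taxa in
each representation; and the four DAA tests on the 50 most vs 50 least
efficient cows. Stepwise and ridge votes use all cows; DAA votes use the
extremes only. The stepwise entry p-value is Bonferroni-adjusted for the
number of remaining candidates — with a flat 0.05 entry rule the best of
hundreds of null taxa always enters, and the AICc choice keeps it; the
drop rule stays at 0.05. Taxa significant in ≥ 4 tests form the trait's
core; core taxa are then Pearson-correlated (CLR values) with the trait
over the 100 extreme cows to attach a direction (negative r with RFI =
associated with efficiency). Whether each method × representation counts
separately (default, 10 possible votes) or collapsed per method (6 votes)
is configurable. Higher-rank features chosen by stepwise/ridge are
recorded but only genus-level identities enter the vote.

## Methane metrics

`CH4 (g/d) = (1.23·DMI − 1.45·FA% + 0.120·NDF%)/0.05565`, with yield
(g/kg DMI), intensity (g/Mcal NESec — the energy unit is adopted since
NESec is an energy), and a GFE-corrected value CH4/GFE where GFE = g milk
per g DMI. The operational definition of "corrected for GFE" is not
settled; a multiplicative yield×intensity variant is provided as
`ch4_combined_correction`. Dietary fatty-acid content uses ether extract
as a proxy when that is what a diet table provides. Selection comparisons
rank cows by a criterion, contrast the 50 most vs 50 least efficient
(Welch t, significance at p ≤ 0.05), and report percent reductions
relative to the least-efficient group. The three-way interplay table cuts
phenotypic, microbiome-predicted and genomic scores into terciles
(efficient / average / not efficient, lower = efficient; ties broken by
stable order).

## Problem sizes and numerical conventions

Simulation-based checks in the test suite use the generator's full cohort
size (n = 454) with 150–200 genera; 200 cohorts for coefficient recovery,
100 null datasets for FDR control, 50 for power, and 25 for the ensemble,
band-recovery and methane orderings — sizes at which the checked bands are
stable from run to run. The null-leakage study for the ridge selector uses
150 cows × 200 noise features over 50 seeds. All randomness flows from
named substreams of one seed (`iolayer.stage_seed`); fixed seeds reproduce
every output byte-for-byte. Tolerances: REML boundary detection at 1e-10
on the variance; offset iteration 1e-8; CLR closure asserted at 1e-9;
exact equations tested at 1e-10.

## Known limitations

* The DAA analogs trade exactness for transparency; they are calibrated on
  the generator's data model, and numerical parity with the published
  packages is a non-goal.
* Group-confounded sequencing depth (e.g. one group sequenced 4× deeper)
  is not corrected by the single additive offset of `ancombc_like` for
  zero-inflated taxa; depth should be randomized across groups.
* The mixed models support a single random intercept (treatment within
  experiment); repeated measures and genetic relatedness are out of scope.
* The sign-confusion F1 depends on the class balance of the residuals;
  with leak-free out-of-fold predictions it is systematically lower than a
  refit-on-all evaluation would suggest.
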
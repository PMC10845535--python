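# rumensemble

Tools for quantifying how much of a dairy cow's feed efficiency is
explained by her rumen microbiome. The package is aimed at animal
scientists and microbiome analysts who have a genus-level 16S count table
and per-cow performance records (intake, body weight, body condition,
milk component yields) and want to go from those to residual efficiency
traits, microbiome-based predictions, and a consensus list of the
microbial genera driving them — or who want to benchmark that whole
workflow on synthetic cohorts with known planted structure.

## The models at its core

**Residual feed intake (RFI).** Dry matter intake is regressed on the
cow's main energy sinks in a linear mixed model,

  DMI = β₀ + β₁·parity + β₂·MBW + β₃·BEC + β₄·NESec + u_cohort + ε,

where MBW = BW^0.75, BEC = (2.88 + 1.036·BCS)·ΔBW is body energy change,
NESec = 9.29·fat + 5.47·protein + 3.95·lactose is the net energy secreted
in milk (Mcal/d), and u_cohort is a random intercept for treatment nested
within experiment. The conditional residual ε is the RFI: negative RFI =
the cow ate less than predicted = more efficient. Milk fat and protein
efficiencies (g per kg DMI) are modelled the same way (plus DMI as a
covariate) to give residual MFE/MPE.

**Microbiome prediction.** Counts are expanded into a feature matrix —
five taxonomy ranks × three representations (count, relative abundance,
centred log-ratio) plus 22 alpha-diversity indices — and screened by
greedy ridge-regression feature selection under nested 10-fold
cross-validation; performance is reported as leak-free out-of-fold R²,
MSE, RMSE, and a sign-agreement F1 (does the model at least call the cow
efficient vs inefficient correctly?).

**Consensus ensemble.** Up to ten significance votes per genus — stepwise
AICc selection and the ridge selector on all cows (three representations
each), and four simplified differential-abundance tests (ALDEx2-, ANCOM-BC-,
MaAsLin2- and LinDA-style analogs) on the 50 most vs 50 least efficient
cows. Genera significant in ≥ 4 tests form the trait's *core microbiome*
and are correlated with the trait over the extremes.

**Carbon footprint.** Enteric methane is predicted per cow as
CH₄ (g/d) = (1.23·DMI − 1.45·FA% + 0.120·NDF%)/0.05565, with yield,
intensity and efficiency-corrected variants, and hypothetical
top-50/bottom-50 selection comparisons across ranking criteria (measured
RFI, microbiome-predicted RFI, genomic PTA, residual MFE/MPE).

A full account of the models, the synthetic-data generator and all design
choices is in [docs/methods.md](docs/methods.md).

## Worked example

```python
import rumensemble as r

config = r.SimConfig(seed=42)                 # 454 cows, 150 genera
cows, counts, truth = r.generate_cohort(config)
traits, reports = r.compute_traits(cows)
print(f"DMI model: total R2 = {reports['DMI']['total_r2']:.2f}, "
      f"RFI share = {reports['DMI']['residual_share']:.2f}")

features = r.build_feature_matrix(counts)     # 754 engineered features
report = r.cv_feature_select(features.values.loc[traits.index],
                             traits["RFI"], seed=42)
confusion = r.sign_confusion(traits["RFI"], report.oof_predictions)
print(f"microbiome -> RFI: out-of-fold R2 = {report.r2:.2f}, "
      f"F1 = {confusion.f1:.2f}")

consensus = r.run_ensemble(counts, traits["RFI"], seed=42)
print(f"core taxa (>=4 of 10 votes): {consensus.core_taxa}")
print(f"planted: {sorted(truth.planted_taxa['RFI'])}")
```

Output:

```
DMI model: total R2 = 0.84, RFI share = 0.16
microbiome -> RFI: out-of-fold R2 = 0.30, F1 = 0.67
core taxa (>=4 of 10 votes): ['Genus_062', 'Genus_071', 'Genus_020', 'Genus_037', 'Genus_134']
planted: ['Genus_020', 'Genus_037', 'Genus_062', 'Genus_071', 'Genus_134']
```

Reading it: the energy-sink model explains 84% of intake variance,
leaving a 16% residual (the RFI). The microbiome features recover 30% of
that residual's variance out-of-fold — close to the 36% fraction the
generator planted — and classify efficient vs inefficient cows with
F1 = 0.67. The consensus ensemble flags exactly the five genera whose
abundance was planted to covary with RFI, with no false positives.

The same stages are available from the shell:

```
rumensemble simulate --seed 42 --outdir cohort/
rumensemble traits   --cows cohort/cows.csv --out traits.csv
rumensemble features --counts cohort/counts.tsv --taxonomy cohort/taxonomy.tsv --out features.tsv
rumensemble predict  --features features.tsv --traits traits.csv --trait RFI --seed 42 --out report.json
rumensemble run      --seed 42 --outdir full_run/      # everything, with a hash manifest
```

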
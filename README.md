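# emtquad

Isoform-level prognostic analysis for tumor cohorts, built around the case
of the *ZNF71* KRAB-domain isoform in non-small-cell lung cancer (NSCLC).
The package bundles, as one tested pipeline:

- **Rank-quadrant EMT classification.** Each sample gets an aggregate
  mesenchymal score (mean log2(TPM+1) over *ZEB1*, *VIM*, *FN1*) and an
  aggregate epithelial score (mean over *CDH1*, *EPCAM*, *ESRP1*, *ESRP2*,
  *DDR1*, *CTNNB1*, *CD24*, *CLDN7*, *KRT8*, *KRT19*, *RAB25*). Median
  splits of the two scores partition the cohort into four
  epithelial–mesenchymal transition (EMT) phenotypes: Epithelial,
  Mesenchymal, High expression overlap (hybrid), Low expression overlap.
- **Expression-cutoff survival stratification.** Samples with
  TPM ≥ cutoff (default 1.5) form the high group; high vs low are compared
  with Kaplan–Meier curves, the unweighted log-rank test, and a univariate
  Cox hazard ratio HR = exp(β̂) with Wald 95% CI — overall and within each
  EMT phenotype.
- **Ternary drug-response categorization.** Per drug, a cell line is
  *resistant* if its IC50/EC50 > mean + 0.5·SD, *sensitive* if
  < mean − 0.5·SD, *partial* otherwise; resistant vs sensitive lines are
  then compared per gene with two-sided Student's t-tests on log2(TPM+1).
- **Gene-dependency normalization and calls.** Raw gene-effect scores are
  anchored per cell line by the affine map f(x) = (x − m_ne)/(m_ne − m_e),
  so non-essential controls have median 0 and essential controls median −1;
  a normalized score ≤ −0.5 is called a dependency.
- **2^−ΔΔCt quantification** of triplicate qPCR plates against a
  housekeeping gene and a reference sample.
- **Synthetic-data generators** that emulate the cohort structure all of
  the above assumes (197 tumors with 17% above the TPM 1.5 cutoff, 117
  cell lines, latent EMT axes driving the 14 markers, planted hazard
  ratios, planted drug-response expression shifts, labelled dependency
  controls), with ground truth emitted as a sidecar for recovery testing.

It is aimed at computational biologists who want to rerun or stress-test
this style of biomarker analysis without access to the original cohorts.

## Worked example

```python
import emtquad as eq

cfg = eq.SimConfig(seed=7)                       # 197 tumors, defaults
expr, clinical, truth = eq.simulate_cohort(cfg)

calls = eq.classify_emt_quadrants(expr)
print("phenotype counts:", calls["phenotype"].value_counts().to_dict())

labels, frac = eq.stratify_by_cutoff(expr.feature("ZNF71_KRAB"), 1.5)
print(f"high fraction: {frac:.3f}")

res = eq.compare_two_groups(clinical["time"], clinical["event"], labels.to_numpy())
print(f"log-rank p = {res.logrank_p:.4f}")
print(f"HR = {res.hr:.3f} [{res.hr_ci[0]:.3f}, {res.hr_ci[1]:.3f}]")
```

Output:

```
phenotype counts: {'Mesenchymal': 62, 'Epithelial': 62, 'LowOverlap': 37, 'HighOverlap': 36}
high fraction: 0.168
log-rank p = 0.0002
HR = 2.310 [1.469, 3.633]
```

The four phenotypes partition the 197 samples (the two median splits make
the pure Epithelial/Mesenchymal corners slightly larger than the overlap
corners whenever the two scores are negatively associated). About 17% of
tumors sit above the 1.5 TPM cutoff, as planted. This cohort was generated
with a planted hazard ratio of 1.686 for the high group; the single-cohort
estimate 2.31 [1.47, 3.63] covers it — averaging over many cohorts
recovers the planted value (see below).

## Command line

```bash
emtquad simulate --config cfg.yaml --out data/
emtquad classify --expr data/expression.tsv --out calls.tsv
emtquad survive  --expr data/expression.tsv --clinical data/clinical.tsv \
                 --feature ZNF71_KRAB --cutoff 1.5 --out report.json
emtquad chemo    --expr data/cell_line_expression.tsv --drugs data/drugs.csv \
                 --metric ic50 --out drug_response.tsv
emtquad depend   --scores data/dependency.tsv --threshold -0.5 --out dep_calls.tsv
emtquad run      --config cfg.yaml --out results/
```

Exit code 0 on success, 2 on any validation error. `emtquad run` is a pure
function of the config: reruns produce byte-identical reports.

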
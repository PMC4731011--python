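# pecapipe

Rate-ratio change-point analysis of paired mRNA/protein time courses.

When cells respond to a stimulus — the motivating system is the
endoplasmic-reticulum stress response, sampled at 0, 0.5, 1, 2, 8, 16, 24
and 30 h in two biological replicates — the observed protein trajectory of
a gene is shaped by regulation at two levels: transcription/mRNA
degradation (RNA-level) and translation/protein degradation
(protein-level).  `pecapipe` deconvolves paired gene × time expression
matrices into these two layers using a Bayesian protein expression control
analysis (PECA): for each gene it estimates, per inter-timepoint interval,
the log ratio θ of synthesis to degradation rates, and for each interior
time point the posterior probability that θ changed there — the change
point score (CPS) — with direct posterior FDR control across genes.

## Model

Under quasi-steady state the outcome concentration *Y* tracks the
precursor concentration *X* as *Y* ≈ (s/d)·*X*, so on the natural-log
scale the residual η_t = log *Y*_t − log *X*_t has piecewise-constant mean
θ = log(s/d), jumping only where regulation changes.  RNA-level analysis
uses a constant artificial DNA copy number as precursor (η = log RNA);
protein-level analysis uses RNA as precursor and protein as outcome
(θ = log translation:protein-degradation ratio).  Synthesis and
degradation are not separately identifiable from concentrations; the
ratio is the estimand.

Per gene with *n* = 8 observations and *m* = *n* − 2 interior candidate
change points:

- z_j ~ Bernoulli(π) change indicators at interior points (π shared across
  genes, estimated by empirical Bayes under a Beta(1, 4) hyperprior);
- segment means θ_s | σ² ~ N(m₀, g·σ²); observations η_i ~ N(θ_seg(i), σ²);
- σ² ~ Inverse-Gamma(α, β), hyperparameters fit by empirical Bayes.

The Normal–Inverse-Gamma structure gives closed-form marginal likelihoods
for every segmentation, so the posterior over all 2^m = 64 segmentations
is computed exactly by enumeration (a collapsed Gibbs sampler is provided
for longer grids and is validated against enumeration).  CPS_j =
P(z_j = 1 | η).  Significance thresholds come from the direct posterior
FDR: estFDR(c) = Σ_{CPS ≥ c} (1 − CPS) / #{CPS ≥ c}, thresholded at the
smallest observed CPS with estFDR ≤ 0.05.  Replicates are always fitted
separately.

Around the model the package implements the full pipeline: synthetic data
generators with known kinetic ground truth (quasi-steady-state and
first-order ODE modes; pulse, switch and null regulatory programs; spikes
and missing values), the bespoke preprocessing (natural-log transform,
quantile normalisation for RNA, top-5%-excluded intensity-sum
normalisation for protein, complete-case filtering, jackknife
"spikiness" TRV filter, LOWESS smoothing, replicate consistency),
phase-level summaries (early < 2 h, intermediate 2–8 h, late > 8 h),
discordance and buffering detection, divergence curves, and
correlation-distance hierarchical clustering with static and dynamic
tree cuts.

## Worked example

Simulate 500 genes in which 20% carry a switch-like protein-level program
(a permanent 1.5 log-unit rate-ratio shift at 2 h), then recover the
events:

```python
import numpy as np
from pecapipe import SimulationConfig, simulate_qss
from pecapipe.peca_model import (
    compute_residuals, fit_peca, fdr_threshold, significant_events,
)
from pecapipe.preprocess import log_transform

cfg = SimulationConfig(n_genes=500, seed=4, frac_regulated_protein=0.2,
                       frac_regulated_rna=0.0,
                       pattern_mix_protein={"switch": 1.0},
                       spike_rate=0.0, missing_rate=0.0)
rna, protein, truth = simulate_qss(cfg)

log_rna = log_transform(rna[0])
log_protein = log_transform(protein[0])
residuals = compute_residuals(log_protein, precursor=log_rna)
fit = fit_peca(residuals)

threshold = fdr_threshold(fit.cps, target_fdr=0.05)
events = significant_events(fit, threshold)
print(f"CPS threshold at FDR 0.05: {threshold:.3f}")
print(f"significant protein-level events: {len(events)}")
print(events.sort_values("cps", ascending=False).head(3).to_string(index=False))
```

prints

```
CPS threshold at FDR 0.05: 0.458
significant protein-level events: 108
gene_id  time direction      cps
G000057   2.0        up 1.000000
G000132   2.0        up 1.000000
G000015   2.0        up 0.999999
```

108 events against 100 planted changes (power is essentially complete at
this effect size; the excess are the ≤ 5% expected false discoveries plus
borderline calls).  The top calls sit at the true 2 h change point, and
the fitted trajectory for `G000057` shows the permanent shift:

```
0-0.5    3.27
0.5-1    3.27
1-2      3.27
2-8      5.02
8-16     5.02
16-24    5.02
24-30    5.02
```

i.e. θ jumps by ~1.75 log-units at 2 h and holds — a switch.  The same
objects feed the downstream stages (`pecapipe.regulation_summary`,
`pecapipe.cluster_profiles`), and the `pecapipe` command line runs the
whole chain on TSV files:

```sh
pecapipe simulate --config cfg.yaml --outdir sim/
pecapipe preprocess --rna sim/rna_r1.tsv --rna sim/rna_r2.tsv \
    --protein sim/protein_r1.tsv --protein sim/protein_r2.tsv --outdir prep/
pecapipe peca --rna prep/rna_r1.tsv --rna prep/rna_r2.tsv \
    --protein prep/protein_r1.tsv --protein prep/protein_r2.tsv --outdir fit/
pecapipe summarize --fit-dir fit/ --protein prep/protein_r1.tsv \
    --protein prep/protein_r2.tsv --outdir summary/
pecapipe cluster --rna prep/rna_r1.tsv --rna prep/rna_r2.tsv \
    --protein prep/protein_r1.tsv --protein prep/protein_r2.tsv --outdir clusters/
```

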
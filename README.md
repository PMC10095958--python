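# chronoreg

Curve registration and comparative analysis of developmental gene-expression
time courses.

## The problem

Two genotypes (or closely related species) move through the same morphological
sequence of developmental stages — for example the floral transition in
*Arabidopsis thaliana* and *Brassica rapa* — yet a naive sample-by-sample
comparison of their transcriptomes can show almost no similarity. Much of the
discrepancy is *desynchronisation*: homologous genes follow the same temporal
expression trajectory, but dilated and displaced in time, and by different
amounts for different gene groups. `chronoreg` provides the machinery to
detect, quantify and exploit this structure:

* **Registration.** For each orthologue pair, the query genotype's time axis
  is transformed by `t' = a·t + s` over a discrete grid (stretches
  `a ∈ {1, 1.5, 2}`, shifts `s ∈ [−4, +4]` days). Both profiles are centred
  and scaled on the overlapping registered timepoints, the query profile is
  linearly imputed at the reference's observed timepoints, and the candidate
  minimising the mean squared difference wins.
* **Model selection.** On the registered axis, a single 6-coefficient cubic
  spline for the pooled data (k = 2 + 6 = 8, charging the two registration
  parameters) competes against one spline per genotype (k = 2 × 6 = 12) under
  BIC = k·ln(n) − 2·logL. A smaller registered-model BIC calls the pair
  "same profile, desynchronised".
* **Significance.** A pairing permutation test re-runs the whole
  register-and-compare pipeline with randomly reshuffled orthologue partners,
  giving an empirical (and, for extreme counts, a parametric Gaussian-tail)
  p-value for the genome-wide registered-gene census.
* **Downstream structure.** Sample-level distance matrices before/after
  registration and 1-D t-SNE embeddings of developmental progression;
  Newman assortativity of the shift parameter among same-stretch genes linked
  in an interaction network, with a 100,000-fold permutation test; and CSI —
  Gaussian-process scoring of candidate regulator sets per target gene in an
  autoregressive time-course model — with an edge-recovery benchmark on
  synthetic networks of known structure.
* **Synthetic data.** A first-class generator plants gene groups with known
  (stretch, shift), count-like magnitudes, replicate noise, paralogue
  splitting and a contamination set of genuinely different profiles, so every
  stage can be validated against ground truth.

## Worked example

```python
from chronoreg import (SyntheticConfig, simulate_expression_pair,
                       filter_comparable_genes)
from chronoreg.model_selection import compare_cohort, registered_gene_census

cfg = SyntheticConfig(n_genes=200, noise_sd=0.2, count_dispersion=0.0,
                      contamination_fraction=0.35, seed=1)
expr_a, expr_b, pairs, truth = simulate_expression_pair(cfg)
kept = filter_comparable_genes(expr_a, expr_b, pairs, threshold=0.7)
regs, cmps = compare_cohort(expr_a, expr_b, kept)
n_reg, n_total = registered_gene_census(cmps)
print(f"{n_reg} of {n_total} genes favour the registered model")
print(f"planted registered fraction: {truth.genes['registered'].mean():.2f}")
```

prints

```
133 of 197 genes favour the registered model
planted registered fraction: 0.65
```

133/197 ≈ 0.68 of the analysed genes get the "registered" verdict: close to
the planted 65%, with misses (mis-registered noisy genes) and false alarms
(independent shapes that happen to superimpose inside the overlap window)
partially cancelling — the latter being exactly why the permutation test, not
the raw census, carries the significance claim.

The same pipeline is available from the shell:

```bash
chronoreg --seed 1 --outdir out simulate --n-genes 200
chronoreg --outdir out filter
chronoreg --outdir out register
chronoreg --outdir out select
```

Each stage writes TSV/JSON artefacts plus a manifest (input checksums,
parameters, seed, version) sufficient to re-run it in isolation.

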
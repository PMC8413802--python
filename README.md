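# epiiprofiles

Person-centered profiling of pandemic-related experiences from the
92-item Epidemic-Pandemic Impacts Inventory (EPII), for survey and
disaster-mental-health researchers. The package implements the full
analysis pipeline around a binary latent class model:

* **Scoring** — collapse 4-level EPII responses to dichotomous
  indicators, cumulative domain counts, and sum-scored psychosocial
  scales (PSS, PHQ-9, GAD-7, PC-PTSD-5, Duke-UNC SSQ) with screening
  cutoffs and within-scale mean imputation of rare opt-outs.
* **Indicator screening** — base-rate filter (<5%) and a one-sided
  Spearman screen against perceived stress.
* **Latent class analysis** — maximum likelihood for the mixture
  P(y) = Σ_k π_k Π_j ρ_jk^{y_j}(1−ρ_jk)^{1−y_j} by multi-start EM,
  with class enumeration and a fit battery: BIC, SABIC, CAIC, AWE,
  BIC-based Bayes factors and correct-model probabilities, relative and
  univariate entropy, average-posterior diagnostics, and a parametric
  bootstrap likelihood-ratio test of K vs K−1.
* **Distal outcomes** — 3-step comparisons of classes on outcomes kept
  out of the measurement model, correcting for modal-assignment
  misclassification (unequal-variance normal means; categorical
  probabilities), with Wald tests and Bonferroni-adjusted pairwise
  contrasts.
* **Synthetic surveys** — a generator parameterized by the published
  class structure (class proportions, conditional item probabilities,
  class-conditional screen rates), so the whole pipeline is testable
  without access to restricted respondent data.

## Worked example

```python
import epiiprofiles as ep
from epiiprofiles import selection, tables

# a synthetic survey population drawn from the published 5-class structure
data = ep.generate_lca_data(ep.SyntheticConfig(n=2000, seed=1))

fit = ep.em_fit(data.indicators.to_numpy(float), K=5,
                policy=ep.StartPolicy(n_starts=50, seed=1))
ref = ep.LCAParameters(tables.class_proportions(), tables.profile_matrix())
fit = ep.apply_alignment(fit, ep.align_labels(fit.params, ref))

print(round(selection.relative_entropy(fit.posteriors), 4))   # 0.9129
print(round(100 * fit.params.pi[2], 2))                        # 33.23
post = selection.avg_posterior_table(fit.posteriors, fit.assignments)
print(round(post.to_numpy()[0, 0], 4))                         # 0.9938
```

The three numbers are classification diagnostics of the fitted 5-class
solution: relative entropy (0.91 — respondents are assigned to classes
with little ambiguity), the recovered share of the largest class
(33.2%, generated at 31.4%), and the mean posterior probability among
respondents assigned to the best-separated class (0.99). The
`examples/` directory has one short script per capability: scoring,
screening, class enumeration, and corrected class comparisons. A thin
CLI wraps the pipeline:

```bash
epiiprofiles simulate --n 652 --seed 1 --out survey.csv
epiiprofiles run --input survey.csv --kmax 6 --seed 1 --out bundle/
```

which writes the table bundle (screening report, fit table, posterior
diagnostics, class profiles, class comparisons) plus a JSON run record
sufficient to reproduce the run exactly.

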
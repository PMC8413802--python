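"""Compare latent classes on distal outcomes with error correction.

Modal class assignment misclassifies some respondents, attenuating
between-class differences on outcomes. The 3-step correction treats the
assignment as an error-prone indicator with a known misclassification
matrix. Here a binary depression screen generated at the published
class-conditional rates is recovered and tested.
"""

import numpy as np

import epiiprofiles as ep
from epiiprofiles import selection, tables

dataset = ep.generate_lca_data(ep.SyntheticConfig(n=2000, seed=4))
fit = ep.em_fit(dataset.indicators.to_numpy(float), 5,
                ep.StartPolicy(n_starts=30, seed=4))
ref = ep.LCAParameters(tables.class_proportions(), tables.profile_matrix())
fit = ep.apply_alignment(fit, ep.align_labels(fit.params, ref))

Q = ep.classification_error_matrix(fit.posteriors, fit.assignments)
entropy = selection.relative_entropy(fit.posteriors)
y = dataset.distals["phq9_ge15"].to_numpy()
est = ep.dcat_categorical(y, fit.assignments, Q, fit.params.pi,
                          entropy=entropy)

truth = tables.distal_rates().loc["phq9_ge15", "p1":"p5"].to_numpy(float)
print("depression screen (PHQ-9 >= 15) probability by class:")
for k in range(5):
    print(f"  class {k + 1}: estimate {est.estimates[k, 1]:.3f} "
          f"(SE {est.ses[k, 1]:.3f})   generator truth {truth[k]:.3f}")
print(f"overall equality: chi2={est.overall_stat:.1f}, df={est.overall_df}, "
      f"p={est.overall_p:.2g}")
sig = est.pairwise[est.pairwise.significant]["pair"].tolist()
print(f"pairs significant at the Bonferroni-adjusted "
      f"{est.alpha_adjusted:.3f} level: {', '.join(sig)}")
print()
print("High-exposure classes (1-3) screen positive far more often than "
      "the low-risk classes (4-5); the correction keeps the estimates "
      "near the generating rates instead of shrinking them toward the "
      "overall mean.")
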
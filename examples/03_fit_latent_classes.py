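"""Enumerate latent class models and inspect the fit-index battery.

Fits K = 1..6 binary-mixture models to indicators generated from the
published 5-class structure (scaled down to n=800 so the example runs in
about a minute) and prints the fit table: information criteria, adjacent
Bayes factors, correct-model probabilities and entropy.
"""

import epiiprofiles as ep
from epiiprofiles import selection, tables

dataset = ep.generate_lca_data(ep.SyntheticConfig(n=800, seed=3))
Y = dataset.indicators.to_numpy(float)

enum = selection.class_enumeration(Y, 6, ep.StartPolicy(n_starts=30, seed=3))
cols = ["d", "LL", "BIC", "SABIC", "entropy", "BF_vs_next", "cmP", "selected"]
print(enum.table[cols].round(3).to_string())
print()
print(f"BIC selects K={enum.selected_K} (generator truth is 5 classes; "
      "smaller samples can prefer fewer). BF > 10 against the next model "
      "and the largest cmP corroborate the selection; entropy near 0.9 "
      "means respondents are classified with little ambiguity.")

fit = enum.fits[enum.selected_K]
ref = ep.LCAParameters(tables.class_proportions(), tables.profile_matrix())
if fit.params.n_classes == 5:
    aligned = ep.apply_alignment(fit, ep.align_labels(fit.params, ref))
    print("aligned class shares (%):",
          (100 * aligned.params.pi).round(1).tolist())
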
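"""Score a pandemic-experience survey: dichotomize, count, scale-score.

Generates a small synthetic survey, collapses the 4-level EPII responses
to 0/1 indicators, counts endorsed experiences per thematic domain, and
scores the psychosocial battery with screening flags.
"""

import epiiprofiles as ep

dataset = ep.generate_lca_data(ep.SyntheticConfig(n=200, seed=1))
binary = ep.dichotomize_responses(dataset.raw)
counts = ep.domain_counts(binary)
scores = ep.score_scales(dataset.raw)

print("Mean endorsed experiences per domain (of 92 items):")
print(counts.mean().round(2).to_string())
print()
print("Scale means and screen-positive rates:")
for scale in ("pss", "phq9", "gad7", "pcptsd", "ssq"):
    print(f"  {scale.upper():7s} mean total {scores[f'{scale}_total'].mean():5.1f}")
for flag in ("phq9_ge15", "gad7_ge15", "pcptsd_ge3"):
    print(f"  {flag:12s} positive {100 * scores[flag].mean():.1f}%")
print()
print("The domain counts are cumulative exposure tallies (work/home/"
      "social/health adverse experiences plus positive changes); the "
      "flags mark respondents above the standard screening cutoffs.")
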
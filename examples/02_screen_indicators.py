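"""Select latent-class indicators by base rate and stress correlation.

Two screens: items endorsed by fewer than 5% of respondents are set
aside, then only items whose Spearman correlation with the perceived-
stress total is significantly positive are retained. Also reconstructs
the published screen from the printed per-item summaries (16 exclusions,
38 indicators).
"""

import epiiprofiles as ep

dataset = ep.generate_lca_data(ep.SyntheticConfig(n=652, seed=2))
binary = ep.dichotomize_responses(dataset.raw)
scores = ep.score_scales(dataset.raw)

report = ep.spearman_screen(binary, scores["pss_total"].to_numpy())
retained = ep.select_indicators(report)
print(f"synthetic survey: excluded {int(report.excluded_low_base_rate.sum())} "
      f"low-base-rate items, retained {len(retained)} indicators")

published = ep.screen_from_published()
print(f"published summaries: excluded "
      f"{int(published.excluded_low_base_rate.sum())} items, retained "
      f"{int(published.retained_indicator.sum())} indicators")
print()
print("On synthetic data the retained set fluctuates with sampling noise "
      "around the 38 generator indicators; the published reconstruction "
      "is exact because it reuses the printed base rates and "
      "significance flags.")
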
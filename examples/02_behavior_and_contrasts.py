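"""Responder classification, behavioral statistics, and per-gene contrasts.

Splits stressed fluoxetine-treated mice into responders/nonresponders by
coat-score sum (<= 2), summarises the behavioral measures (Student t for
weight gain, exact Mann-Whitney for coat and nest scores), then computes the
stress contrast (S-C vs NS-C) on quantile-normalized blood data.
"""

import depmark as dm

matrices, behavior, truth = dm.simulate_mouse_study(dm.MouseSimConfig(seed=42))

relabeled = dm.classify_response(behavior)
print("groups after responder classification:")
print(relabeled["group"].value_counts().to_string())

summary = dm.behavior_summary(relabeled)
rows = summary[(summary["group1"] == "NS-C") & (summary["group2"] == "S-C")]
print("\nNS-C vs S-C behavioral statistics:")
for _, r in rows.iterrows():
    print(f"  {r['measure']:12s} {r['test']:13s} stat={r['stat']:8.3f} "
          f"p={r['p']:.4f} {r['stars']}")
# Stress raises weight gain and coat score and suppresses nest building, so
# all three comparisons should be significant.

label_map = relabeled.set_index("mouse")["group"]
blood = dm.quantile_normalize(matrices["blood"].with_groups(label_map))
stress = dm.contrast(blood, "S-C", "NS-C")
top = stress.nsmallest(5, "p")
print("\ntop 5 stress-contrast genes in blood (S-C vs NS-C):")
for gene, r in top.iterrows():
    cls = truth.gene_classes.get(gene, "null")
    print(f"  {gene}  t={r['t']:6.2f}  p={r['p']:.2e}  FC={r['fc']:.2f}  "
          f"planted class: {cls}")
# The strongest hits should be planted stress-responsive classes, with linear
# fold changes near 2 (the 1.0 log2 planted effect).
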
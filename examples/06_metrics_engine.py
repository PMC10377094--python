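"""Exact confusion-matrix metrics and ROC, checked against published rows.

The metrics engine uses exact rational arithmetic with half-up rounding to
4 decimals, so it reproduces published percent-scale tables bit for bit.
"""

from oralfuse import ConfusionMatrix, load_reference_metrics, metrics, roc

cm = ConfusionMatrix(tp=142, fn=11, tn=143, fp=4)
rep = metrics(cm)
print(f"counts TP={cm.tp} FN={cm.fn} TN={cm.tn} FP={cm.fp} (n={cm.total})")
print("metrics:", rep.as_dict())
# AC 95.0000, PR 97.2603, SE 92.8105, SP 97.2789, FS 94.9833 — matching the
# published row this matrix was taken from, to all four decimals.

df = load_reference_metrics()
exact = sum(
    metrics(ConfusionMatrix(r.tp, r.fn, r.tn, r.fp)).ac == float(r.ac)
    for r in df.itertuples(index=False)
)
print(f"reference fixture: {exact}/{len(df)} published accuracy cells reproduced exactly")

r = roc([0.9, 0.8, 0.4, 0.3], ["OSCC", "healthy", "OSCC", "healthy"])
print(f"ROC area {r.auc:.2f} (equals the concordant-pair probability 0.75)")
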
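"""Per-class metric tables from a confusion matrix.

Builds the report for a hand-written 3-class confusion matrix and checks two
pieces of internal arithmetic the published benchmark tables also satisfy:
the F-score is the harmonic mean of precision and recall, and the Average
row is the unweighted mean of the class rows.
"""

import numpy as np

from osteosae.metrics import ConfusionMatrix, class_metrics_table, f_score

cm = ConfusionMatrix(
    counts=np.array([[261, 3, 4], [2, 213, 5], [2, 3, 426]]),
    class_names=("VT", "NVT", "NT"),
)
table = class_metrics_table(cm)
print(table.round(2).to_string())
print()
for cls in ("VT", "NVT", "NT"):
    p, r, f = table.loc[cls, ["precision", "recall", "f_score"]]
    print(f"{cls}: harmonic mean of (P={p:.2f}, R={r:.2f}) -> {f_score(p, r):.2f} "
          f"(table prints {f:.2f})")
avg = table.loc[["VT", "NVT", "NT"]].mean()
print(f"Average row check, max deviation: "
      f"{np.abs(avg - table.loc['Average']).max():.2e}")
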
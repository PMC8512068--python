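"""Multiclass metrics and the generalized Matthews correlation (R_K).

Three canonical confusion matrices show the statistic's range: perfect
prediction gives +1, prediction independent of the truth gives 0, and a
systematic cyclic mislabeling gives a negative value.
"""

import numpy as np

from fogsense.evaluation import ConfusionMatrix, gorodkin_mcc, multiclass_metrics

cases = {
    "perfect diag(40,30,30)": np.diag([40, 30, 30]),
    "uniform (all cells 10)": np.full((3, 3), 10),
    "cyclic permutation": 30 * np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]]),
}
for name, C in cases.items():
    cm = ConfusionMatrix(C)
    print(f"{name:>24}: R_K = {gorodkin_mcc(cm):+.2f}")

rep = multiclass_metrics(ConfusionMatrix(np.array([[50, 5, 2], [4, 30, 3], [1, 2, 10]])))
print("\nexample report (weighted averages):")
for key, value in rep.as_dict().items():
    print(f"  {key:>12}: {value:.3f}")
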
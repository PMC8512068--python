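"""Balance the window classes with SMOTE.

Minority windows (FOG and especially PreFOG) are oversampled by
interpolating between same-class neighbors in raw-window space, so every
downstream representation of a synthetic window stays internally
consistent.  Original rows are preserved; counts end equal.
"""

import numpy as np

from fogsense.augmentation import LabeledMatrix, smote_balance
from fogsense.synthetic import SimulationConfig, make_balanced_windowset

windows, _ = make_balanced_windowset(SimulationConfig(n_fog_events=6, seed=42), w=2.0)
data = LabeledMatrix(windows.matrix(), windows.labels)

before = {c: int(np.sum(data.y == c)) for c in (0, 1, 2)}
balanced = smote_balance(data, k=5, seed=0)
after = {c: int(np.sum(balanced.y == c)) for c in (0, 1, 2)}

print(f"before SMOTE: {before}")
print(f"after  SMOTE: {after}")
print(f"rows added: {len(balanced) - len(data)} synthetic windows, "
      "each on a segment between two same-class originals.")
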
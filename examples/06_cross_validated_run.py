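"""A small cross-validated model comparison on simulated data.

Trains the feature-sequence BiLSTM and the recurrence-plot CNN (reduced
CPU profile) under 2-fold stratified cross validation with per-fold SMOTE,
combines them by majority vote, and prints the metric table: mean ± sd of
accuracy, weighted precision/sensitivity/specificity/F-beta and the
generalized Matthews correlation, plus per-model train+test runtime.
Runs in well under a minute on one CPU.
"""

from fogsense.synthetic import SimulationConfig
from fogsense.workflow import RunConfig, format_table, run_experiment

cfg = RunConfig(
    modalities=("features", "RP"),
    ensemble_modes=("majority",),
    K=2,
    profile="reduced",
    seed=0,
    simulation=SimulationConfig(n_fog_events=8, seed=0),
)
report = run_experiment(cfg)
print(format_table(report))
print("\nRows are models; the ensemble row combines the constituents' votes.")
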
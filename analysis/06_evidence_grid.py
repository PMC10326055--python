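"""Evidence-grid analysis: which rule explains learned confidence?

Evaluates trained networks on superimposed stimuli over a grid of
(mu_s1, mu_s2) contrast combinations and regresses per-cell mean
confidence on the balance-of-evidence predictor (mu_s2 - mu_s1) and the
response-congruent-evidence predictor (contrast of the chosen class),
with a leave-one-out noise ceiling.
"""

import warnings

warnings.filterwarnings("ignore")

from confidence_lab.harness import ExperimentConfig, report, run_experiment

cfg = ExperimentConfig(
    experiment="evidence-grid",
    seed=0,
    n_networks=3,
    out="results",
    params=dict(grid_n=12, trials_per_cell=24, n_per_class=300, epochs=3),
)
outdir = run_experiment(cfg)
print(report(outdir))
print("\n'mean_r2' compares predictors of per-cell confidence; the grid is"
      "\n12x12 here (the full design uses 100x100 = 10,000 combinations).")
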
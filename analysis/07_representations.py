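"""Population geometry of the penultimate layer.

Trains one two-choice network, records 100-unit penultimate activations
over standard-regime trials, and asks whether decisions and confidence
share a decision variable: variance explained by the top two principal
components, PC1 -> class / decision-output fits, PC2 -> correctness /
confidence fits, and the rectification relation |PC1| -> PC2.
"""

import json
import warnings
from pathlib import Path

warnings.filterwarnings("ignore")

import numpy as np
import pandas as pd

from confidence_lab.experiments import synth_test_pool, train_two_choice_cohort
from confidence_lab.networks import evaluate_trials
from confidence_lab.representations import geometry_regressions, pca_geometry
from confidence_lab.stimuli import apply_contrast_noise, sample_regime

OUT = Path("results/representations")
OUT.mkdir(parents=True, exist_ok=True)

net = train_two_choice_cohort(1, n_per_class=400, epochs=4, seed=0)[0]
imgs, labels = synth_test_pool(seed=424242)
rng = np.random.default_rng(1)
idx = rng.integers(0, len(imgs), 2000)
musig = sample_regime("standard", len(idx), rng)
x = apply_contrast_noise(imgs[idx], musig[:, 0], musig[:, 1], rng)
rec = evaluate_trials(net, x, np.asarray(labels)[idx], store_activations=True)

geom = pca_geometry(rec.activations["encoder_out"], record=rec)
fits = geometry_regressions(geom, rec)

top2 = float(geom.variance_fractions[:2].sum())
pd.DataFrame(
    {"component": np.arange(1, 11), "variance_fraction": geom.variance_fractions[:10]}
).to_csv(OUT / "variance_fractions.csv", index=False)
(OUT / "regressions.json").write_text(json.dumps({k: float(v) for k, v in fits.items()}, indent=1))

print(f"Top-2 principal components explain {top2:.1%} of penultimate-layer variance.")
for k, v in fits.items():
    print(f"  {k}: {v:.3f}")
print("\nHigh PC1->decision and |PC1|->PC2 fits indicate a single decision"
      "\nvariable read out twice: signed for the choice, rectified for"
      "\nconfidence. Tables in results/representations/.")
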
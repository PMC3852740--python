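"""Relate model predictions to observed staining by a threshold sweep.

Generates a screen in which 30% of compounds stain in a way that
contradicts the transport-model prediction, then sweeps the calling
threshold (predicted % mass in mitochondria + lysosomes) from 0 to 100%
and finds the balanced threshold where the two per-class accuracies meet.
"""

from pathlib import Path

import probeloc as pl
import probeloc.io as pio

library = pl.generate_library(8, 168, seed=11)
effects = pl.EffectTable.random(8, 168, seed=12, contradiction_fraction=0.3)
screen = pl.generate_screen(library, effect_table=effects, seed=12)

pred = screen.predictions
score = pred["frac_mito"] + pred["frac_lyso"]
observed = [
    pl.assign_observed_category(screen.true_classes[c])[0]
    for c in pred["compound_id"]
]
curve = pl.accuracy_sweep(score, observed, step=1.0)
print(f"scored compounds: {len(pred)}  observed organelle-positive: {sum(observed)}")
print(f"accuracy at threshold 0%:   {curve.accuracy[0]:.3f} (positive prevalence)")
print(f"accuracy at threshold 100%: {curve.accuracy[-1]:.3f}")
print(f"balanced threshold: {curve.balanced_threshold:.0f}% "
      f"with accuracy {curve.balanced_accuracy:.3f} "
      "(per-class accuracies equalized)")

outdir = Path("scratch/examples")
pio.write_accuracy_curve_csv(curve, outdir / "accuracy_curve.csv")
pio.write_balanced_json(curve, outdir / "balanced_threshold.json")
print(f"wrote {outdir}/accuracy_curve.csv and balanced_threshold.json")
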
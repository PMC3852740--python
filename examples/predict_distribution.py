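"""Predict steady-state subcellular distribution for the whole library.

Runs the Nernst-Planck / Henderson-Hasselbalch transport model over every
eligible compound (0 or 1 extra ionizable groups) at the baseline mammalian-
cell parameters and summarizes where the cationic, lipophilic probes are
predicted to accumulate.  Also exports ternary plot coordinates.
"""

from pathlib import Path

import probeloc as pl
import probeloc.io as pio

library = pl.generate_library(8, 168, seed=11)
predictions, exclusions = pl.predict_library(library)
print(f"simulated {len(predictions)} compounds; excluded {len(exclusions)} "
      f"with >=2 extra ionizable groups")

for col in ("frac_mito", "frac_lyso", "frac_membranes"):
    print(f"  {col:>15}: median {predictions[col].median():6.2f}%  "
          f"max {predictions[col].max():6.2f}%")
mono = predictions[
    [c.n_extra_ionizable == 0 for c in library if c.n_extra_ionizable <= 1]
]
print(f"max lysosomal fraction: {mono['frac_lyso'].max():.3f}% among permanent "
      f"monocations (no ion trapping), {predictions['frac_lyso'].max():.3f}% "
      "among protonatable compounds")
organelle = (predictions.frac_mito + predictions.frac_lyso) >= 50
print(f"{organelle.mean() * 100:.1f}% of compounds predicted mainly "
      "mitochondrial/lysosomal at the baseline membrane potentials")

outdir = Path("scratch/examples")
pio.write_predictions_csv(predictions, exclusions, outdir / "predictions.csv")
coords = pl.localization_plot_coords(predictions)
coords.to_csv(outdir / "localization_coords.csv", index=False)
print(f"wrote {outdir}/predictions.csv and localization_coords.csv "
      "(x+y+z = 100% per compound, plus a flat simplex projection)")
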
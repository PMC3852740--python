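# probeloc

Structure–localization analysis for combinatorial fluorescent-probe
libraries: given a library of cationic styryl-type dyes built from
interchangeable building blocks (a pyridinium/quinolinium "head" condensed
with an aldehyde), `probeloc` predicts where each compound should accumulate
inside a cell from first principles, quantifies where it actually stains in
fluorescence images, and relates both to the chemistry of the building
blocks.

The package is aimed at cheminformatics and high-content-screening
practitioners who want a tested, fully synthetic re-implementation of this
analysis: every stage runs on generated compounds and rendered images with
known ground truth, so the whole pipeline is verifiable end to end without
any external data.

## What it computes

**Mechanistic transport model** (`probeloc.transport`). Each compound
carries a fixed +1 charge, a logP, and 0–2 extra basic groups. Its
ionization states follow Henderson–Hasselbalch,
f(+2) = 1/(1+10^(pH−pKa)), and each species crosses membranes with the
Nernst–Planck (Goldman) flux

    J = P·N·(a_out − a_in·e^N)/(e^N − 1),   N = zFE/RT,

with Fick's law as the N→0 limit. Free aqueous activity a = γ·f·c uses a
lipid-sorption coefficient γ = 1/(w + l·10^logP); species permeability is
log10 P(cm/s) = logP − 6.7 with a −3.7 logP penalty per extra charge. With
a constant extracellular reservoir, the steady state of each compartment
(cytosol, then mitochondria and lysosomes against the cytosol) is the
unique zero-net-flux concentration, found by bracketed root finding. The
result is the fractional mass in mitochondria, lysosomes and cytoplasmic
(or plasma) membranes.

**Machine vision** (`probeloc.features`). Nuclei are segmented from the
Hoechst channel, dilated by 10 px (Euclidean disk) into a cell mask, the
FITC/TRITC/Cy5 channels are summed, the median background is subtracted
(truncated at zero), and three features are measured per image: the
cell/background intensity ratio, the cytoplasm/nucleus ratio, and the
coefficient of variation of cell-associated pixels.

**Cheminformatics** (`probeloc.similarity`). 881-bit binary fingerprints
compared by the Tanimoto coefficient Tc = C/(N1+N2−C); building blocks
ranked by Tc against a reference compound; property histograms against a
reference compound set.

**Statistics** (`probeloc.stats`). Accuracy = (TP+TN)/(TP+FP+FN+TN) swept
over calling thresholds 0–100% of predicted mass, with the balanced
threshold where per-class accuracies meet; and the additive model
f(Y) = A(i) + P(j) relating any image feature to its two building blocks,
fit by least squares with k-fold cross-validated predictive R².

**Synthetic data** (`probeloc.library`, `probeloc.render`,
`probeloc.screen`) generates the 8 × 168 combinatorial library (1,344
compounds, logP 2–6, 1,256 with ≤1 extra ionizable group) and renders
512×512 four-channel 12-bit images with organelle/membrane/nuclear staining
patterns and ground-truth masks. `probeloc.arrays` assembles similarity- or
coefficient-sorted image montages with JSON metadata.

## Worked example

```python
import probeloc as pl

library = pl.generate_library(8, 168, seed=11)     # 1344 compounds
predictions, excluded = pl.predict_library(library)
print(len(predictions), len(excluded))             # 1256 88

res = pl.fractional_masses(library[0], pl.default_cell())
print(f"{100*res.frac_mito:.1f} {100*res.frac_lyso:.3f} {100*res.frac_membranes:.1f}")
# 97.8 0.017 2.2   <- % mass in mitochondria / lysosomes / membranes
```

A lipophilic permanent cation accumulates almost entirely in mitochondria
(driven by the −160 mV matrix potential) with negligible lysosomal mass —
without a protonatable group there is no ion trapping in the acidic
lysosome. Rendering and measuring a noiseless image of each staining class:

```text
     class     QC  cell/bg  cyto/nuc     CV
 organelle   pass     4.79     6.120  0.925
  membrane   pass     4.90     2.337  0.312
   nuclear   pass     8.08     0.367  0.540
```

High CV flags punctate organelle staining; cytoplasm/nucleus ratio below 1
flags nuclear staining. The `examples/` directory contains one short script
per capability (library building, distribution prediction, image
measurement, accuracy sweeps, building-block regression, sorted arrays).

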
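# Methods

## Transport model

The distribution model treats a cell as nested well-mixed compartments —
extracellular medium ⊃ cytosol ⊃ {mitochondria, lysosome} — each with a
volume, pH, lipid volume fraction, and a membrane potential defined as
interior minus immediate exterior. A compound is a set of ionization
states ("species"): the fixed +1 cation plus, for each extra basic group,
a protonated form carrying one more charge. Species fractions follow
Henderson–Hasselbalch with independent groups; for one basic group the
protonated (+2) fraction at pH p is 1/(1+10^(p−pKa)).

Transmembrane movement is passive diffusion of each species independently,
with the Goldman (Nernst–Planck) net inward flux per unit area

    J_z = P_z · N_z · (a_out − a_in·e^{N_z}) / (e^{N_z} − 1),
    N_z = z·E/(RT/F),   RT/F = 26.73 mV at 310 K,

which reduces to Fick's law J = P(a_out − a_in) as |N| → 0 (the
implementation switches to the Fick form below |N| = 1e−6 to avoid 0/0).
Activities are free aqueous concentrations: a = γ·f·c with the sorption
coefficient γ = 1/(w + l·10^logP_z), where w and l are the compartment's
water and lipid volume fractions. Species lipophilicity sets permeability,
log10 P_z(cm/s) = logP_z − 6.7, and ionic species are penalized by
−3.7 logP units per unit charge beyond +1; both constants are module-level
and overridable. These are the conventional magnitudes for this model
family; nothing downstream is sensitive to their exact values within an
order of magnitude, because the reported quantities are mass *fractions*.

With the extracellular concentration held constant, each compartment's
steady state is the unique interior concentration where the summed species
flux vanishes. The flux is strictly decreasing in the interior
concentration, so the zero is unique; it is found with `brentq` on the
dimensionless ratio c_in/c_out (bracket grown geometrically from 1,
xtol 1e−30, rtol 1e−14 — solving in the ratio keeps the absolute tolerance
meaningful for very small concentrations). Mitochondria and lysosomes
equilibrate against the cytosolic steady state. Reported masses are
concentration × volume for mitochondria and lysosomes; "cytoplasmic (or
plasma) membranes" is by default the lipid-sorbed portion of the cytosolic
compartment's mass (the aqueous cytosolic pool is excluded; a flag includes
it). Fractions are normalized over these three compartments only.

Baseline parameters ship as `data/cell_baseline.toml` (config, not code):
4 pL cell; cytosol pH 7.2 at −60 mV; mitochondria pH 8.0 at −160 mV, 10% of
cell volume; lysosomes pH 5.0 at +10 mV, 1% of volume; 5% lipid in the
cellular compartments; extracellular pH 7.4 reservoir. These are standard
published magnitudes for an average mammalian cell. Under them a permanent
monocation is predicted ~98% mitochondrial with lysosomal mass below 0.02%,
and compounds acquire lysosomal mass only through a protonatable group (ion
trapping). A consequence worth knowing: with one shared parameter table the
predicted fractions of the library cluster tightly (mitochondria dominate
nearly everywhere), so accuracy threshold sweeps against these predictions
operate on a compressed score range. Compounds with two or more extra
ionizable groups are excluded from simulation and reported separately.

## Synthetic library

The generator enumerates every (head, aldehyde) pair. Per-block logP
contributions are drawn uniformly (heads 0.8–2.0, aldehydes 1.2–4.0) so
compound logP lands in 2–6; block contributions add exactly, which is what
the building-block regression exploits. Two of eight heads and 44 of 168
aldehydes carry one extra basic group (pKa uniform in 4–10), giving
744/512/88 compounds with 0/1/2 extra groups — i.e. 1,256 of 1,344 eligible
for the transport model. Under a strictly block-additive construction the
0-group and ≤1-group counts cannot be set independently; the generator
pins the 1,256 eligible count, which is the one that drives the analysis.

Fingerprints are 881-bit substructure-key stand-ins: a 10-bit scaffold
shared by all compounds plus 30-bit per-block signature windows that slide
with block index (stride 3 for aldehydes, 6 for heads). Overlap between
two blocks' windows decays with index distance, so block-to-block Tanimoto
similarity falls smoothly from 1.0 (self) through the 0.4 and 0.25 regimes
used to define similar/dissimilar subsets, reaching the scaffold-only floor
for distant blocks. No real chemistry is involved: there is no SMILES
parsing and no descriptor computation, by design.

## Image renderer

Fields are 512×512, 12-bit, four channels. Nuclei are random ellipses
(full axes 15–30 px, ≥75 px apart); the cell is the nuclear mask dilated by
18–26 px, so a 10-px analysis dilation stays strictly inside the cell.
Signal amplitude is 2000·intensity_scale split over FITC/TRITC/Cy5 by a
Dirichlet(2, 6, 2) draw (TRITC-heavy, as for red-shifted styryl dyes),
over a camera baseline of 50 counts per channel. Patterns: *organelle* —
nucleus at 5% of amplitude, cytoplasm 25%, ~20 Gaussian foci per cell
(σ 1–2 px, peak ~amplitude); *membrane* — cytoplasm 35%, nucleus 15%, 3-px
peripheral rim at full amplitude; *nuclear* — nucleus 90% plus two
nucleolar spots, cytosolic pool 35%. Noise is Poisson on the signal plus
Gaussian read noise of sd `noise_sd`, both disabled at `noise_sd = 0` so
noiseless renders are bit-reproducible; pixels are clipped to [0, 4095].

What the renderer does *not* emulate: cell-to-cell expression variability,
focus drift, uneven illumination, mitotic/rounded cells, bleed-through,
or saturation under normal settings. Passing tests therefore demonstrate
the correctness of the measurement pipeline on controlled geometry, not
robustness to real-microscope artifacts.

## Feature pipeline

Segmentation is Otsu thresholding of Hoechst, hole filling, and removal of
components under 50 px; dilation uses the exact Euclidean distance
transform (a single pixel dilated by radius 10 yields the 317-point lattice
disk). QC excludes images whose mean cell-mask intensity is within 10% of
the background median (`signal_margin 0.10`) or with >5% of cell pixels
saturated in any probe channel; both thresholds are arguments. The
cell/background ratio uses pre-subtraction intensities (post-subtraction
the background median is ~0 and the ratio degenerates); the
cytoplasm/nucleus ratio and CV use the corrected image. Features are
pooled per image over the combined cell mask rather than per cell, matching
the per-image exclusion logic; a labeled per-nucleus mask is retained
internally. Means (not medians) summarize cell-associated intensity.

## Screens and statistics

A screen gives each compound 12 images — 6 incubation plus 6 washout, the
washout signal scaled by a class retention factor (organelle 0.8, membrane
0.3, nuclear 0.6) — and ground-truth feature values generated exactly as
f(Y) = base + A(i) + P(j) + Gaussian noise. Images render lazily from
per-image seeds derived via `SeedSequence(master, compound, image)`, so a
full 8×168 screen (16,128 image sets) is enumerable without materializing
~33 GB of pixels. True classes follow the transport prediction (organelle
when predicted mitochondrial+lysosomal mass ≥ 50%), with a configurable
contradiction fraction reassigning compounds to a class that disagrees with
the prediction; at fraction 1.0 the observed organelle labels invert
exactly, so the accuracy curve becomes the complement of the
contradiction-free curve. An alternative rule assigns class by the sign of
the aldehyde effect, for experiments that need class–coefficient coupling.

The confusion matrix uses the standard convention (observed-positive below
threshold = false negative); overall accuracy is unaffected by the naming
since correct = TP+TN. The sweep uses a 1% grid by default — accuracy is a
step function changing only at observed scores, so any grid containing the
data's quantization is exact — and the balanced threshold minimizes
|acc_pos − acc_neg| with ties to the lowest threshold. The additive fit
solves least squares on head dummies plus first-level-dropped aldehyde
dummies, then re-expresses coefficients under Σ_i A(i) = 0 with the
intercept absorbed into the head effects; unbalanced designs and missing
cells are handled by construction, and cross-validation folds partition
design cells (never splitting a compound's replicates), flagging held-out
cells with untrained levels as non-estimable.

## Arrays and export

Montages place one representative image per compound (first passing-QC
incubation image; `crop_mode="cell"` crops 96 px around the largest
nucleus) into a grid sorted by the chosen statistic, with the reference at
the upper-left. Cell labels carry the class letter (o/m/n), an asterisk
for compounds excluded from regression, or "blank" where no image exists.
Grey-scale PNGs are 12-bit intensities scaled into 8 bits; all metadata
(orders, header values, labels) lives in a JSON sidecar that reconstructs
the array specification byte-identically.

## Problem sizes and limitations

Tests run the full 1,344-compound library through the transport model
(sub-second) and the full 8×168 regression; Monte-Carlo checks
(replicate-count RMSE) use an 8×40 design over five seeds, a size at which
the expected √6 RMSE separation is unambiguous. Known limitations: the
transport model has no active transport, no macromolecular binding and no
kinetics (steady state only); the fingerprints are constructed surrogates
whose similarity structure is index-based, not chemical; and the renderer's
idealizations listed above.
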
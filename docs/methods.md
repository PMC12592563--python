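# Methods

## Overview

`dia-librarian` turns a single wide-window DIA run plus its peptide
detection report into experiment-specific fragment-intensity and
retention-time models, and from them into a filtered spectral library.
The core difficulty is that DIA MS2 spectra are chimeric: a matched
fragment peak can carry intensity from several analytes. The package
therefore (i) labels every matched peak as shared or clean with two
independent detectors, (ii) trains with a masked L1 loss so shared and
unobservable peaks never enter the objective, and (iii) evaluates with
rank correlations restricted to clean peaks, entrapment FDP bounds and
spectral-entropy NCE calibration.

## Annotation model

Fragment intensities live in a fixed tabular layout: rows are the L−1
backbone cleavage sites of a length-L peptide; columns are fragment
species with charge (`b1+`, `b2+`, `y1+`, `y2+`, plus −98 Da
phosphoric-acid neutral-loss variants in phospho mode). Row k holds
b_(k+1) and y_(L−k−1). Matrices are always full-shape; a per-cell mask
carries `use` / `shared` / `out_of_range`. Cells are `out_of_range` when
the theoretical m/z falls outside the acquired scan window, when the
column's fragment charge exceeds what a singly charged precursor can
produce, or when a loss column does not apply (no phosphosite spanned).

Fragment charges are {1} for 1+ precursors and {1, 2} otherwise.
Matching takes the nearest centroided peak within ±10 ppm (configurable;
30 ppm suits TOF-like data); a peak claimed by two fragment ions of the
same peptide marks both cells ambiguous, which feeds the shared union.

Constants: monoisotopic residue masses, proton 1.007276466, water
18.010565, phospho neutral loss 97.976896 (the nominal "−98 Da").

## Shared-peak detection

*Spectrum-centric.* For each apex spectrum, every detected precursor
whose isolation window covers the spectrum and whose peak boundaries
span its RT is annotated against it; a peak index matched by ≥2
precursors marks all involved cells shared. This route needs the
co-eluting peptide to have been detected.

*Peptide-centric.* For each matched fragment, the XIC over the
precursor's reported peak boundaries is extracted from the covering
spectra (nearest peak within tolerance per cycle, 0 when absent) and
smoothed (Savitzky-Golay, window 5 clipped to the series length,
polynomial order 2; a triangular 3-point weighted moving average is
available as an alternative). Pairwise Pearson correlations give each
fragment an aggregate score (sum of correlations to the others); a
fragment is shared when its correlation to the top-scoring fragment is
< 0.8, or when the correlation passes but its peak-shape score is 2. The
shape score counts boundaries where the trace fails to return to
baseline: a boundary scores when its intensity exceeds both the median
of all fragment traces at that time point and 10% of the trace's own
apex (25% when this trace's apex is below half the highest apex among
the fragments). Zero-variance traces carry no shape evidence and are
conservatively labeled shared; traces with fewer than 3 points are not
scorable and are left unlabeled. The final label is the union of the two
routes and the ambiguity flags.

Numerical choices that were genuinely open: correlations are computed on
smoothed XICs restricted to the reported boundaries; the boundary median
comparison uses smoothed values; ties in apex-spectrum selection go to
the earlier spectrum; report boundaries are taken verbatim (no
refinement).

## Training data

Per surviving annotation, matched intensities are normalized so the
highest matched peak is 1; unmatched in-range cells become zero targets;
shared cells are masked. A spectrum is rejected when it has no matched
peaks, when its highest matched peak is shared, or when the shared
fraction among matched peaks exceeds 50% (out-of-range cells sit in
neither numerator nor denominator). RT examples are deduplicated per
peptidoform — the precursor with the lowest q-value supplies the apex
RT — and divided by the normalization factor (the run's maximum RT, or a
user value). Train/test splitting operates on peptidoforms, never on
precursors, so charge states stay together.

## Models

Both models are compact feed-forward networks implemented on numpy with
hand-written backpropagation; this keeps the package dependency-light
and desk-scale while preserving the piece that matters: the masked L1
objective, under which shared and out-of-range cells contribute exactly
nothing to loss or gradient.

*Intensity.* One shared network maps each cleavage site's feature row to
the fragment columns — weight sharing across positions, i.e. a 1-D
convolutional regressor. Features: one-hot residue identities at the
four positions flanking the cleavage site (with a padding token),
per-position modification mass (scaled), relative cleavage position,
peptide length (capped at 35), precursor charge (one-hot 1–4 plus
scaled), NCE (scaled, plus its square), and the instrument category.
Unseen instruments map to the first vocabulary entry, a surrogate
category. Hidden layers default to 64×64 ReLU.

*RT.* Composition features (residue fractions, length, modification
load) through a 48×48 ReLU network to one output, clamped non-negative
at prediction.

Optimization is Adam (β₁ 0.9, β₂ 0.999) with a linear warmup to the
target rate over the warmup epochs, then constant. Two schedules ship:
the fine-tuning schedule (intensity: 20 epochs, warmup 10, lr 1e-4,
batch 512; RT: 40 epochs, warmup 10, lr 1e-4, batch 1024), suited to
warm starts via the optional `init_weights` import; and `desk_scale()`
(intensity: 200 epochs, lr 2e-3, batch 256; RT: 400 epochs, lr 5e-3,
batch 128), suited to training the compact networks from scratch on a
few hundred simulated examples — all tests and benchmarks use it.
Training is bit-reproducible for a fixed seed on one thread; a
non-finite loss raises a training error naming the epoch. Prediction
applies no masking, clips negatives, zeroes inapplicable cells and
renormalizes each matrix to max 1.

## Library generation

Trypsin/P digestion (cleave after K/R, no proline suppression, no
N-terminal-M excision), ≤1 missed cleavage, length 7–35, fixed
carbamidomethyl C, optional ≤1 variable phospho on S/T/Y, charges 2+–4+.
Precursors outside the training run's m/z scan range are dropped;
fragment cells outside the range are dropped *before* the top-20
selection (the order matters when more than 20 candidates are in range;
filtering first means the library never contains unobservable ions);
kept fragments are renormalized to max 1. Predicted RTs are multiplied
by the stored normalization factor. Peptides carry semicolon-joined
protein ids; there is no protein inference and no decoy generation.

## Evaluation utilities

*Unmasked Spearman*: rank correlation over `use` cells only (average
ranks on ties), undefined below 3 cells.

*Entrapment FDP*: with N_T/N_E the discovered original-target and
entrapment counts at score cutoff s, N_{E≥s>T} the discovered
entrapments whose partner missed the cutoff, and N_{E>T≥s} those that
outscored a discovered partner:
upper = (N_E + N_{E≥s>T} + 2·N_{E>T≥s})/(N_T + N_E),
lower = N_E/(N_T + N_E). Entrapment sequences shuffle the prefix with
the C-terminal residue fixed, after I→L conversion; targets with no
distinct permutation (e.g. "LK") are dropped and logged.

*Spectral entropy similarity*: both spectra normalized to sum 1, peaks
merged into common dimensions within a ppm tolerance (unmatched peaks
stay distinct), similarity = 1 − (2·H(½A+½B) − H(A) − H(B))/ln 4 with
Shannon entropy H. NCE calibration grid-searches 20–40 and takes the
argmax of the median similarity over examples' unshared peaks, ties to
the lowest NCE.

## The simulator

The simulator defines the study conditions for every benchmark. Default
configuration: 20 random proteins of 80–160 residues; isolation windows
of 24 m/z tiling 400–1000; fragment scan range 200–1700; 30-minute
gradient at a 3-second cycle (windows staggered within the cycle);
Gaussian elution with 18 s FWHM; 2% multiplicative intensity noise;
NCE 27. Peak boundaries are reported at the 5%-of-apex crossing;
synthetic q-values are uniform(0, 0.01), emulating a 1% FDR-filtered
report.

The ground truth is a smooth deterministic surrogate for the unknown
fragmentation/elution processes: fragment intensity is a logistic
function of the hydropathy coefficients of the residues flanking the
cleavage site, relative position and charge, modulated by a Gaussian
NCE response whose optimum shifts with residue identity; RT is a
logistic function of mean hydropathy and length, spanning 6–94% of the
gradient. Both are functions of exactly the features the models encode,
so they are learnable — passing benchmarks show the pipeline recovers a
recoverable process, not that real fragmentation is this simple.

Interference is injected at the peak level: each precursor draws an
interference level from Beta(2r, 2(1−r)) with mean r =
`interference_rate` (burstiness — crowded windows and RT regions are
hit much harder than quiet ones, which is what lets training sets
survive average shared fractions near 50%), and each fragment then
receives, with that probability, a co-eluting contaminant trace at the
same m/z with apex offset 1.2–2.5 elution sigmas and amplitude 0.8–2.0×
the fragment's apex. These offsets make the contaminant both visible in
the XIC shape (detectable) and non-negligible at the apex spectrum
(harmful if unmasked). Chance m/z collisions — two co-eluting fragment
ions within the 10 ppm centroiding width, across or within peptides —
are genuine two-ion peaks; they are labeled shared and additionally
tracked as collision cells so clean-run checks can exclude them. What
the simulator does not model: isotope envelopes, MS1, profile mode,
staggered windows, ion mobility, additive noise floors, and
retention-time drift.

## Benchmark problem sizes

Chosen as the package's desk-scale defaults: shared-peak recovery on 300
precursors at rate 0.3; learnability on 200 clean examples; the masking
ablation on 700 precursors at rate 0.4 (≈150 surviving training spectra)
with evaluation on all non-training precursors against the noise-free
truth, three seeds; RT on 500 peptidoforms with a 10% hold-out; NCE
recovery with training NCEs 20–40 step 2 and observations at 30. The
masking ablation trains both arms on the same surviving spectra and
differs only in whether shared masks enter the loss, mirroring how
masking is a loss-level switch rather than a data filter.

## Known limitations

- The interference ground truth is injected, not emergent from a full
  background proteome; the spectrum-centric route consequently sees few
  true positives (only chance collisions between detected peptides),
  matching its minority share of real shared peaks but exercising it
  less thoroughly than the peptide-centric route.
- The models are intentionally small; they capture local-context
  fragmentation rules and composition-level RT, not long-range sequence
  effects. The architecture is not meant to compete with
  transformer-scale predictors on real data — the training procedure
  (interference-aware masking) is the point.
- Only b/y ions with charges ≤2 and the −98 loss are modeled; no a/c/x/z
  ions, internal fragments or isotope peaks.
- The Skyline report dialect is a documented column mapping; the library
  writer emits the TSV dialect only.
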
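# Methods

## Peptide and modification model

Peptides live in pandas DataFrames with `sequence`, `mods` (semicolon-
joined modification names in `Name@Site` notation, e.g. `Phospho@S`),
`mod_sites` (semicolon-joined positions: 1-based residue index, 0 for the
protein/peptide N-terminus, −1 for the C-terminus), `charge` and
metadata columns. Fragment data live in a second table whose rows are
the concatenated cleavage positions of all peptides; each peptide stores
`frag_start_idx`/`frag_end_idx` into it. The fragment table has exactly
eight columns — b⁺, b⁺⁺, y⁺, y⁺⁺ and the four corresponding neutral-loss
channels — holding either m/z values or relative intensities in [0,1].

Masses are monoisotopic only and always derived from the element table:
a modification's mass is the sum of its elemental composition (written
`H(1)O(3)P(1)`; counts of 1 may be omitted, negative counts allowed),
and a peptide's mass is residues + water + modification deltas. The
element table covers 28 symbols: C, H, N, O, S, P first, then 22 further
symbols (stable-isotope labels ¹³C/¹⁵N/²H/¹⁸O, halogens, common metals,
Se, Mo, B) chosen to cover the compositions that occur in widely used
UniMod entries. Element monoisotopic masses come from the NIST table
shipped with pyteomics. Residues without a defined default mass
(B, J, O, U, X, Z) are rejected rather than guessed.

Neutral-loss semantics: a loss channel is populated only when the
fragment (prefix for b, suffix for y) contains a loss-capable
modification; a single loss event is applied using the largest loss mass
present in the fragment. Combined losses from multiple PTMs in one
fragment are not modelled.

## Encodings

Amino acids map to integers by alphabet position (vocabulary 27, 0 =
padding). PTMs are encoded per position as raw element-count vectors
over the frozen 28-element vocabulary; inside every model the first six
(CHNOSP) channels pass through unchanged and the remaining 22 are
compressed by a learned bias-free linear map to 2 channels, giving the
8-D PTM embedding. Metadata vectors concatenate a charge one-hot capped
at 10 (larger charges clamp with a warning), NCE scaled by 1/100, and an
instrument one-hot over {QE, Lumos, timsTOF, SciexTOF, unknown} with
unknown strings falling back to the last token.

## Architectures and frozen dimensions

The four production models reproduce fixed trainable-parameter totals
(3,988,974 MS2; 708,224 RT; 713,452 CCS; 1,669,697 HLA). The published
description of each architecture leaves several widths free (embedding
sizes, convolution channels, feed-forward width, meta width, charge
embedding sizes); those were fixed once, by exhaustive search under the
structural constraints, so that every total is met exactly, and are
frozen in `src/deeppep/config/frozen_dims.yaml` together with the
layer-by-layer arithmetic. They are a design contract of this package:
changing any of them changes the totals.

Shared conventions: LSTMs carry both input-hidden and hidden-hidden
biases (the convention of mainstream DL libraries, so counts are
comparable); decoders are `Linear(in→64) → PReLU(64) → Linear(64→out)`;
convolutions are same-padded with bias and their output is concatenated
with their input (a residual multi-scale input for the recurrent stack);
pooling is a plain sum over the length dimension with padded positions
masked out. Embedded inputs are zeroed at padding positions before the
convolution so predictions are independent of the batch pad length; the
transformer achieves the same through its attention mask. The reverse
LSTM direction flips each sequence by its true length. The positional
encoder is fixed sinusoidal (parameter-free).

The "hidden layer size" of a bidirectional LSTM is per direction (RT/CCS:
128/direction, 256-wide output). For the HLA classifier, 256-wide
bidirectional layers are arithmetically incompatible with its parameter
total, so its two LSTM layers are unidirectional with hidden size 256.
The CCS model injects charge twice: a 2-D charge embedding concatenated
at every input position and a 24-D charge embedding concatenated to the
pooled representation before the decoder. The MS2 model's modloss branch
(one extra transformer layer + its own decoder) always exists;
`mask_modloss=True` zeroes its outputs without removing weights, so the
parameter count is independent of the flag.

## Training

The universal trainer applies Adam (default moments, no weight decay or
gradient clipping) under a warmup + cosine schedule: the learning rate
ramps linearly from 0 to the peak over the warmup epochs, then decays as
`peak · ½(1 + cos(π·progress))` to zero. Losses: L1 for MS2/RT/CCS,
binary cross-entropy for classifiers. Mini-batches are bucketed by
sequence length (each batch is padded to its own maximum) with a size
cap; bucket order is shuffled per epoch from the config seed, and all
dropout randomness is reseeded from the same seed at the start of
training, so a run is a pure function of (initial weights, table, config).
Non-finite losses abort with a diagnostic. MS2 training masks positions
beyond a peptide's n−1 cleavages, and excludes the neutral-loss channels
from the loss when they are masked. Production training recipes
(epochs/warmup/lr/dropout for the three MS2 phases, RT/CCS, HLA and the
fine-tuning variants) ship as named presets in
`deeppep.model_shop.TRAIN_PRESETS`.

Snapshots are single HDF5 files holding every named weight array, the
verbatim source text of the architecture class, the build hyperparameters
as JSON and a format version; loading rejects unknown versions and
reports the first parameter whose shape disagrees. Transfer learning
loads a snapshot and continues training on a small table. Batched
prediction buckets rows by length, restores input order, and reports the
failing row indices if any row cannot be encoded.

## Pre/post-processing

Matched fragment intensities are normalized per spectrum by the highest
matched intensity; predicted MS2 intensities are clipped to [0,1], and
neutral-loss outputs are structurally zeroed for fragments without a
loss-capable modification. Predicted RT is gradient-normalized;
multiplying by the gradient length de-normalizes, and a least-squares
line through reference peptides with known iRT values maps predictions
onto the iRT scale (degenerate references — fewer than two, or all
identical — are rejected). CCS converts to 1/K₀ by the Mason–Schamp
relation `1/K₀ = CCS·√(mM/(m+M)) / (C·z)` with ion mass `m = z·(m/z) −
z·m_proton`, nitrogen gas mass M = 28.00615 Da and C = 1059.62245 for
CCS in Å² and K₀ in cm²V⁻¹s⁻¹; the inverse composes to identity.

## Rescoring

Fine-tune sampling caps the project-specific subset at 5,000 unmodified
target PSMs from at most eight raw files, plus at most 100 PSMs for each
of the ten most frequent modifications. Fragment matching takes the most
intense centroid within ±20 ppm of each theoretical m/z (the window
maximum is the tie policy). The feature extractor emits exactly 61
columns per PSM (the `FEATURE_NAMES` tuple in `deeppep.rescore` is the
authoritative ordered list): 24 similarity features between predicted
and matched intensity vectors (Pearson/Spearman/cosine/normalized
spectral angle over all ions, b-only, y-only, charge-1/2 subsets, top-3/
6/12 predicted fragments, and √-transformed variants), 14 coverage
features (expected/matched counts and fractions overall and per series,
mean matched intensity, strong-but-unmatched counts, base-peak flag,
matched-intensity entropy), 5 RT features (predicted, observed, signed/
absolute difference, difference in minutes), 5 mobility features
(predicted, observed, signed/absolute difference, and a missingness flag
— absent mobilities are 0-imputed with the flag set), 11 precursor/
peptide features (search score, length, charge, precursor m/z, signed/
absolute mass error, modification counts, basic-residue fraction,
internal K/R count, NCE) and 2 spectrum-size features. Non-finite values
are imputed as 0.

Percolator rescoring assigns peptides (not PSMs) to K = 2 folds, so no
PSM is ever scored by a classifier that saw any PSM of its peptide. Per
fold: features are z-scored on the training folds, and for five
iterations an L2-regularized logistic regression (C = 1) is fit with
positives = target PSMs at ≤1% q-value under the current score
(initially the search score; if fewer than two qualify, all targets) and
negatives = decoys, then the training folds are rescored. The held-out
fold is scored by the final model and each fold's scores are centered
and scaled on its held-out decoy distribution so scores are comparable
across folds. q-values use the standard target–decoy estimate — FDR(t) =
#decoys≥t / #targets≥t, with tied scores sharing their group's worst
FDR — and the running minimum over decreasing score; they match a
brute-force enumeration over all thresholds exactly.

## HLA pipeline

Proteins concatenate into one string with `$` separators; the unspecific
digest enumerates every distinct substring of length 8–14 via a suffix
array (prefix doubling) with Kasai's LCP array — for each suffix, new
substrings are those longer than the LCP with the preceding suffix, so
each distinct peptide is emitted exactly once — and stores only (start,
end) index pairs. Peptides containing `$` or a non-standard residue are
excluded; equivalence to brute-force substring enumeration is the
contract and is tested on random proteomes. Negative training examples
are unique proteome substrings sampled to match the positives' length
histogram exactly, never crossing `$` and never colliding with a
positive. Candidates pass the filter when the classifier probability
strictly exceeds 0.7 (ties at the threshold are excluded); sequences are
decoded from the index chunk-wise, never materialized at once.

## Spectral libraries

Precursors expand over charges 1–3 and are kept inside a 300–1800
precursor m/z window; per precursor the 12 most intense b/y fragments at
charge 1–2 inside 200–1800 m/z are retained (ties toward lower m/z;
neutral-loss channels are never exported), and retained intensities are
re-normalized so the strongest is 1 — a convention DIA tools expect.
The iRT column uses the calibration line when reference peptides are
supplied, else 100 × normalized RT. The TSV dialect writes one row per
fragment with bracketed modification names (`AAS[Phospho]DK`,
`[Acetyl]-M...`); the HDF container round-trips both tables losslessly.

## Synthetic data

The generator emulates every input the pipeline consumes, as pure
functions of (config, seed). Ground-truth rules are smooth surrogates
chosen to be learnable by small networks, not physical simulations:

* RT: affine in the summed Kyte–Doolittle hydropathy (0.35 min per unit
  around a 30-min midpoint), saturating at the edges of a 60-min
  gradient — monotone hydrophobicity structure, not real chromatography.
* CCS: `0.5·(m/z) + 30·z + 100` Å² — the observed near-linearity of CCS
  in m/z at fixed charge, without conformer effects.
* MS2: b/y intensity at cleavage i is a Gaussian in i/n whose center
  shifts with charge (+0.1 per unit above 2) and NCE (+1/200 per unit
  above 30), weighted by fixed proton-affinity values of the residues
  flanking the cleavage (proline suppressing, K/R/H enhancing), with 2+
  fragments at 40% of 1+ and phospho neutral losses at 50% of their
  backbone channel; the matrix is max-normalized.

Spectra add multiplicative log-normal intensity jitter (default 10%) and
uniform spurious peaks (default 30% of the real peak count); PSM tables
mix true targets (own spectrum), false targets and pseudo-reversed
decoys (both paired with other peptides' spectra) with overlapping score
distributions, and record the ground-truth label. Default generator
conditions: tryptic peptides of length 7–30, charges 1–4 weighted toward
2–3, NCE 25–35, fixed carbamidomethyl-C plus probabilistic Met oxidation
and Ser/Thr phosphorylation; the rescoring benchmark uses 1,500 true +
500 false targets + 1,500 decoys at those noise levels. Passing tests on
this generator demonstrates that the models can learn smooth
sequence-to-property rules and that the pipeline's bookkeeping is
correct; it does not demonstrate accuracy on real spectra, real
chromatography or real ion mobility.

## Problem sizes and numerical choices

The test suite trains reduced-dimension models: RT (embed 16, conv 24,
one 24-wide BiLSTM layer) on 1,500 peptides for 40 epochs; MS2 (d=64,
2+1 transformer layers) on 500 peptides for 60 epochs; the HLA
classifier (embed 16, conv 16, one 24-wide LSTM) on 3,200 samples for 15
epochs; transfer learning uses 50 RT peptides and 100 motif peptides.
These sizes keep the full suite in a few minutes on one CPU while
leaving clear margins over the recovery thresholds. Further fixed
choices: fragment matching tolerance 20 ppm; q-value tie handling as
above; decoy-spread alignment threshold 10⁻⁹ (degenerate spreads divide
by 1); clipping rather than sigmoid for MS2 outputs; Xavier-uniform
initialization; float64 throughout.

## Known limitations

The NumPy backend is single-threaded per operation and loops over LSTM
time steps in Python, so production-dimension training is impractical —
the full-size models exist to realize the architecture contract and for
forward prediction; practical training targets the reduced dimensions.
Fragment types beyond b/y±loss (a/c/x/z ions, water/ammonia losses) and
isotope envelopes are out of scope, as are average masses and glycan
structures. The Percolator implementation uses logistic regression only,
and mzML reading is not included (MGF is the peak-list interchange
format).
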
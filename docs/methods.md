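# Methods

## Problem and model

`nabind` predicts, per residue of a protein sequence, whether the residue
contacts a bound DNA or RNA molecule. Ground truth comes from complex
structures: a residue is *binding* iff at least one of its heavy atoms lies
within 4.5 Å (inclusive) of any atom of a nucleic-acid chain. Dataset
chains must come from X-ray structures with resolution strictly better
than 3 Å, be at least 40 residues long, carry at least five binding
residues, and pairwise sequence identity within a dataset is capped at 30%
(greedy reduction in input order; identity is computed from a global
alignment with match +1, mismatch 0, gap open −10, extend −0.5, and is
divided by the alignment length — a "shorter sequence" denominator is
available since reduction conventions differ between studies).

Three predictors share one contract (per-residue scores in [0, 1]):

* **Feature arm.** An RBF-kernel SVM (C = 10, γ = 0.1) over sliding-window
  vectors: for each residue, the per-residue descriptor blocks of window
  offsets −5…+5 are concatenated (out-of-chain offsets are zero-padded)
  and a 21-dimensional chain-global block is appended; with all families
  enabled the vector is 11·40 + 21 = 461 wide. Probability outputs come
  from Platt-sigmoid calibration fitted on 5-fold cross-validated margins
  and applied as a single monotone sigmoid over the final model's margin;
  this preserves the SVM's ranking, which an earlier per-fold internal
  calibration variant did not. Two training regimes are supported:
  *unbalanced* (all residues) and *balanced* (all positives plus an
  equally sized seeded negative sample). Naive-Bayes, k-NN and
  random-forest engines satisfy the same train/predict contract for
  comparison experiments.
* **Template arm.** The query profile is searched against a library of
  labeled training chains; hits carry a 0–100 similarity probability
  (HHscore). The single top-scoring hit (ties: first in engine order)
  transfers annotations across matched alignment columns: Tscore 1 for a
  query residue aligned to a binding template residue, else 0; unaligned
  residues score 0. A chain without any usable hit is flagged
  "no template" (serialized as NA, never as 0).
* **Hybrid.** Cscore = 0.6·Fscore + 0.4·Tscore when the top template's
  HHscore ≥ 85 (equality takes the combined branch), otherwise Cscore =
  Fscore; a below-cutoff template is recorded but unused. Calls are
  Cscore ≥ 0.5 (boundary calls binding). α = 1 reduces the system exactly
  to the feature arm; α = 0 with cutoff 0 reduces it to the template arm
  on templated chains.

## Feature families and constants

| family | width | notes |
|---|---|---|
| profile | 20 | logistic-squashed raw PSSM elements |
| conservation | 3 | SE, RE, JSD from weighted observed percentages (WOP) |
| structure | 7 | one-hot H/E/C, RSA/maxASA clamped to [0,1], φ/180, ψ/180, disorder |
| physicochemical | 5 | per-type scales, logistic-squashed |
| propensity | 1 | min–max-normalised interface/overall frequency ratio |
| sequential position | 4 | terminus (first/last three), helix-, strand-segment, coil |
| global (per chain) | 21 | length/1000 and 20-type composition ('X' excluded) |

Conservation uses base-2 logarithms (configurable); the background q is
the BLOSUM62 amino-acid frequency table shipped as named constants. WOP
rows are renormalised to frequencies; all-zero rows (gap-dominated profile
columns) fall back to p = q, giving SE(q), RE = 0, JSD = 0 — this avoids
NaNs without discarding residues. With λ = 0.5 and base 2, JSD is
symmetric and bounded by 1. Maximum accessible surface areas are the
theoretical per-residue values of Tien et al. (2013). The five
physicochemical scales are Kyte–Doolittle hydrophobicity, Hopp–Woods
hydrophilicity, net formal charge, potential hydrogen-bond count, and the
Zimmerman isoelectric point. Secondary-structure segment indicators
require runs of ≥3 identical states intersecting the residue's 11-wide
window. Interface propensity is always computed on training chains only.

## Search engines

`hhr_engine` parses externally produced HHR-style reports (probability
score plus query/template alignment blocks; gap columns are excluded,
inconsistent residue numbering is a format error) and filters hits to the
library. For a self-contained pipeline, `ToyProfileSearchEngine` aligns
per-column frequency profiles globally (Gotoh affine gaps, open 1.0 /
extend 0.1; column score Σₐ fq(a)·ft(a) centred so two background columns
score 0) and maps the length-normalised alignment score through a logistic
(midpoint 0.025, scale 0.004) onto 0–100. The mapping is calibrated so
that an exact profile copy scores >99 and unrelated random profiles score
<1; it makes no claim to emulate any external tool's probability model.

## Synthetic data generator

The generator is the package's study-condition definition, not a
convenience: defaults are 50 chains of 50–90 residues, binding fraction
0.12 (at least five binding residues per chain, matching the dataset
filter). For each chain it emits:

* a profile whose binding-residue columns shift 70% of their weight onto
  the basic-residue block (R, K) — the planted "interface conservation"
  signal — with per-column Dirichlet noise (total concentration 20,
  giving realistically peaky columns) and integer WOP rows summing to
  100; log-odds are 2·log2 ratios against the background, clipped to ±6;
* a predicted-structure table with Markov-segment secondary structure,
  Ramachandran-basin dihedrals per state, and AR(1)-smooth accessibility
  and disorder (emulating the autocorrelation of real predictors);
* a PDB file placing one Cα per residue 3.8 Å apart on a line and one
  nucleic phosphate 3.0 Å from each binding residue, so the 4.5 Å rule
  reproduces the planted labels exactly (the nearest non-binding residue
  sits at 4.84 Å) and labels are invariant to rigid-body transforms;
* a template-library entry: an exact copy, a seeded point-mutated copy at
  a target identity, or nothing.

In *complementary* mode the profile signal covers alternate binding
residues and the template labels exactly the others — a controlled
version of the situation where feature and template evidence disagree.
A single seed drives all sub-generators through a splittable seed
sequence.

What the generator does **not** emulate: real evolutionary correlation
between profile columns, BLOSUM-structured substitution noise, genuine
secondary-structure/accessibility coupling to binding sites, or realistic
complex geometry. Passing tests therefore demonstrate the correctness and
internal consistency of the pipeline under known ground truth, not
benchmark performance on real proteins.

## Numerical and protocol choices

* Internal indices are 0-based; all file formats keep their native
  1-based conventions.
* Alternate locations in PDB input resolve to the highest-occupancy
  conformer; hydrogens are dropped; chains are nucleic when most residue
  names fall in {A,C,G,U,T,DA,DC,DG,DT,DU}.
* Undefined precision (no positive calls) reports 0; undefined MCC (zero
  denominator) reports 0 and is flagged, so chain averages stay total.
  Chain-level AUC averages only chains containing both classes.
* AUC is the Mann–Whitney statistic with midrank ties.
* Predictor comparison: Shapiro–Wilk on paired per-chain MCC differences
  at 0.05 gates paired t-test vs Wilcoxon signed-rank; all-zero
  differences short-circuit to a "no difference" report.
* Cross-validation folds are chain-level (seeded shuffle, round-robin),
  never residue-level, so no chain contributes to both training and test;
  interface propensity and the classifier are refit per fold.
* Binary call threshold 0.5 on the final score (configurable).

## Problem sizes

The shipped experiments use 50-chain datasets (≈3 400 residues) for the
template-exactness and complementary-fusion studies, 30 chains with a
50/50 chain-level holdout for the planted-signal and permutation-null
classifier checks, and 12 chains for the end-to-end determinism check;
the complementary study is replicated over ten seeds. These sizes give
stable metrics (binomial noise on pooled MCC well below the effects being
demonstrated) while keeping a full run in minutes on one CPU.

## Known limitations

* The toy search engine's HHscore is a calibrated logistic, not a
  probability model; its absolute values are only meaningful relative to
  its own calibration.
* Real PSI-BLAST checkpoint profiles, mmCIF structures, and biological
  assemblies are out of scope; the ASCII PSSM dialect and plain PDB
  coordinate files are the supported inputs.
* α and the HHscore cutoff are fixed defaults, not fitted; refitting them
  requires external benchmark data.
* The identity denominator used by the original dataset reductions is
  unknowable from the protocol description; both conventions are
  implemented and the choice is recorded per run.
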
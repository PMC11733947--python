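# Methods

## Model

### Bin scheme and label encoding

The pKa axis is discretized into `n = 12/w` half-open, lower-inclusive
interior bins `[w·(i−1), w·i)` covering `[0, 12)`, plus two open
catch-all bins for `pKa < 0` and `pKa ≥ 12`, giving `n + 2` output
labels (14 at the default w = 1). Interior bins are represented by their
midpoints; the catch-alls by `−w/2` and `12 + w/2`, so the expected
value of any output distribution lies in `[−w/2, 12 + w/2]` — exactly
`[−0.5, 12.5]` at w = 1. The half-open convention is applied uniformly
(a label of exactly 0.0 is interior; exactly 12.0 is the high
catch-all); boundary labels have measure zero under the generator, so no
result depends on the convention. Any label below 0 (including the base
negative sentinel −5) encodes to the low catch-all and any label ≥ 12
(including the acid sentinel 50) to the high catch-all, which makes the
encoding indifferent to the sentinel's exact magnitude.

A training label is the one-hot vector over these bins; the model's
output is a softmax distribution over them (per-bin local positive
predictive values). Point prediction = median-weighted expected value;
confidence = the distribution's standard deviation (σ = 0 iff one-hot).

### Featurization (Mol2D)

Each heavy atom maps to an atomic-environment key:
center `(element, formal charge, aromatic flag, implicit-H count)` and
the sorted multiset of `(bond order glyph, neighbor element, neighbor
aromatic flag)` over its one-bond neighbors. The implicit-H count is
part of the center because ionization chemistry is hydrogen-sensitive
(−OH and −O⁻ must differ); neighbor charges and ring sizes are *not*
encoded — the minimal chemically faithful reading of a one-bond
neighborhood. Counts are raw integers (no normalization), which keeps
the locality property crisp: a single-atom perturbation that leaves ring
perception intact changes at most `1 + degree` count positions in each
direction. Environments absent from the training vocabulary accumulate
in one extra "unknown" descriptor position, preserving the invariant
`Σ counts + unknown = heavy atoms` and giving the classifier an explicit
novel-chemistry signal in leave-class-out settings. Vocabulary order is
the lexicographic order of canonical key strings, so descriptor
positions are stable across runs.

Hydrogens are implicit throughout; explicit H atoms in input are folded
into implicit counts on read. Multi-fragment inputs (salts) keep only
the largest fragment, standard QSPR practice.

### Classifier

One hidden ReLU layer (256 units), inverted dropout 0.25 on the hidden
activations during training only, softmax head, cross-entropy loss,
Adam (lr 1e−3, β = 0.9/0.999), mini-batches of 32, and a fixed 250
epochs with no early stopping — dropout makes early stopping
unnecessary, and a fixed epoch count keeps runs bit-reproducible for a
given seed (one `numpy` generator drives initialization, shuffling and
dropout masks). All hyperparameters are configurable
(`TrainingConfig`); this is the smallest standard MLP consistent with
the method, implemented directly in NumPy for exact reproducibility and
control of the dropout/epoch semantics. Acid and base are fully
independent models sharing the code path. Inputs are raw counts; with
druglike molecule sizes the counts are O(10), so no feature scaling is
applied.

The bin-width sweep harness accepts w ∈ {0.5, 1, 2, 3}; the MAE
ordering across widths is data-dependent and not asserted.

### Atomic sensitivity analysis

With P the parent's output distribution and P′_a the distribution after
replacing heteroatom *a* with carbon:

- `D_a = D(P′_a ‖ P) = Σ_j p′_j ln(p′_j/p_j)` in nats. Natural log is a
  convention; the base only rescales τ and the cutoff. Smoothing: bins
  below ε = 1e−9 are clipped up to ε and both distributions
  renormalized. Clipping (rather than adding ε everywhere) leaves
  strictly positive distributions bit-identical, so the smoothed value
  agrees with the analytic KL exactly whenever no underflow occurred,
  while still keeping D finite when softmax outputs underflow to 0.
- `ASA(a) = 5·(e^{D_a} − 1)` if `D_a ≥ τ`, else 0, with τ = 0.05 nats.
  The floor zeroes perturbations that barely move the distribution; the
  exponential widens true/false-positive separation; subtracting 1
  anchors D = 0 at score 0; the coefficient 5 is an empirical
  signal-processing choice, not an optimum. The transform is monotone
  non-decreasing and continuous except at τ.
- The perturbation swaps the heteroatom for a *neutral* carbon (formal
  charge reset to 0) with valence refilled by implicit hydrogens;
  incident bond orders are preserved; aromatic systems broken by the
  swap are kekulized and re-perceived rather than rejected, so every
  heteroatom of an aromatic heterocycle can be scored. Atoms with no
  valid carbon completion (e.g. hexavalent sulfone sulfur) are skipped
  and reported as such — distinguishable from carbons, which are marked
  `not-heteroatom`. Heteroatom means any non-C, non-H heavy atom,
  halogens included.
- Site selection returns the maximal-score atom if its score clears the
  cutoff (default 1.5), ties broken by lowest atom index; ASA reports
  magnitude only, not the direction of the pKa change.
- If a perturbed molecule featurizes identically to the parent (a
  symmetric copy of the perturbed environment persists, or the whole
  neighborhood falls outside the vocabulary so parent and perturbed
  collapse onto the unknown position), the distributions are
  bit-identical and the score is exactly 0 — a known masking effect.

## Synthetic data generator

The generator emulates the training regime the model is designed for:
monoprotic druglike molecules whose pKa is set by one functional group.

- **Positives**: a random scaffold — linear alkyl chain (1–6 heavy
  atoms, optional methyl branch), or a single saturated ring — decorated
  with exactly one group from the rule table. Group pKa means/sds are
  textbook values (generator parameters, not claims): carboxylic acid
  4.0 ± 0.5, phenol 9.9 ± 0.7, thiol 10.5 ± 0.5, primary sulfonamide
  10.0 ± 0.5 (acid); primary aliphatic amine 10.6 ± 0.6, pyridine
  5.2 ± 0.5, imidazole 7.0 ± 0.4, aniline 4.6 ± 0.5 (base). Labels are
  normal draws truncated to mean ± 2 sd and to the open interval of the
  0–12 axis. Scaffolds may carry one non-ionizable ether oxygen
  (p = 0.35) or a fluorine (p = 0.15): these decoy heteroatoms make
  atom-level ASA specificity measurable and the top-1 site criterion
  non-vacuous (with purely alkyl scaffolds the group heteroatoms would
  be the only candidates). Each record stores the heteroatom indices of
  the installed group and its principal ionizable atom, verified against
  the group's SMARTS on the emitted molecule.
- **Negatives** (default 20% of a training draw): hydrocarbon/ether
  chains and rings matching no rule, labeled with the task sentinel
  (acid 50, base −5). Molecules sit in a 3–12 heavy-atom window.
- One `numpy` generator seeded by the caller drives every choice;
  regeneration with the same seed is byte-identical.

What the generator does **not** emulate: multiprotic molecules,
tautomers, charged input species, aromatic hydrocarbon negatives, ring
assortment beyond single saturated rings, and any realistic
structure–pKa physics beyond "group determines the distribution".
Passing the recovery tests therefore shows that the pipeline can learn a
group-determined mapping through Mol2D features and that ASA localizes
the learned signal — not that the model predicts experimental pKa. One
visible consequence: because all aromatic positives in the acid set are
phenol-bearing, an aromatic ring itself correlates with phenol-like
acidity, so deleting the phenol OH moves the output distribution less
than deleting a carboxyl oxygen, and phenol ASA scores can fall below
the site-selection cutoff.

## Evaluation machinery

- **MAE** = mean |E[P_i] − pKa_i|; **Brier** = per-molecule mean of
  Σ_j (p_ij − r_ij)² against the one-hot label (range [0, 2]; 1 − 1/K
  for a uniform prediction over K bins). Per-molecule averaging for the
  Brier score mirrors the MAE's 1/M normalization.
- **Pathological confidence**: records with σ ≤ 1.0 *and* absolute
  error > 1.0 pKa units — confidently wrong predictions; both
  thresholds are parameters.
- **Leave-class-out splits**: one fold per SMARTS pattern; a record is
  held out of fold k iff it matches pattern k (a record can be held out
  of several folds); the default pattern list is the eight generator
  groups plus secondary amine, aromatic nitrogen and aliphatic alcohol.
- **Matched-pair direction accuracy**: fraction of pairs where the sign
  of the predicted pKa difference matches the true sign; predicted ties
  count as incorrect (a constant predictor scores 0).
- **ASA site metrics**: atom-level confusion counts at the score cutoff
  over all scored atoms (sensitivity, specificity, NPV) and per-molecule
  top-1 accuracy (maximal-score atom, provided its score is nonzero,
  inside the annotated group).
- Model evaluation draws use positives only: negatives carry the
  sentinel label 50/−5, which no bounded-output model can approach, so
  an MAE against sentinels would measure the encoding convention, not
  the model.

## Problem sizes and numerical choices

The recovery studies train on 2,000 generated acid records (20%
negatives, 250 epochs, fixed seed) and evaluate on a fresh 500-record
monoprotic draw; ASA site recovery uses 200 of those. At these sizes the
vocabulary holds ≈ 100–200 environments and a full training run takes a
few seconds on one CPU; held-out MAE lands well inside the bin-width
floor (w = 1) and per-group mean recovery within 0.5 pKa units.
Distribution validity is enforced at 1e−9 on the probability sum;
negative variances from floating-point cancellation are clipped to 0
before the square root. Degenerate inputs (empty record lists,
single-class labels, feature-dimension mismatches, non-finite labels)
raise `ValueError` rather than propagating NaNs.

## Known limitations

- Monoprotic regime only: a molecule with several acidic (or several
  basic) sites yields one blended distribution per task; such molecules
  are out of scope.
- ASA indicates magnitude, not direction, of the pKa change, and is
  blind to symmetry-masked perturbations (score exactly 0 by design).
- The synthetic generator's chemistry is narrow (see above); results on
  it upper-bound nothing about experimental datasets.
- No tautomer enumeration, protonation-state standardization, or 3D
  structure handling; the descriptors are strictly 2D.
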
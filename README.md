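# pkasense

Small-molecule pKa prediction by **multitask classification over ordinal
pKa bins**, with **atomic sensitivity analysis (ASA)** that locates the
ionizable atom driving each prediction — no model retraining required.

Most machine-learned pKa predictors regress a single number and say
nothing about *which* atom ionizes or how sure the model is. This package
takes a different route, aimed at medicinal-chemistry workflows where both
the value and the site matter (e.g. deciding which heteroatom to modify
in a lead series):

1. **Featurization.** A molecule is encoded as *Mol2D* counts: for every
   heavy atom, the atomic environment (AE) — the atom's element, formal
   charge, aromaticity and implicit-H count, its incident bonds, and its
   neighbors one bond away — is reduced to a canonical key, and the
   molecule is the integer count vector of its AEs over a training-set
   vocabulary (plus one position counting unknown AEs).
2. **Classification instead of regression.** The pKa axis is cut into
   half-open interior bins `[w·(i−1), w·i)` for `0 ≤ pKa < 12` (default
   width w = 1) plus two open catch-all bins `pKa < 0` and `pKa ≥ 12`.
   An MLP with softmax output assigns each molecule a probability
   distribution P over the `12/w + 2` bins. The point prediction is the
   median-weighted expected value `E[P] = Σ_j median_j · p_j` and the
   model's confidence is the standard deviation σ of that distribution.
   At w = 1 the attainable output range is exactly **[−0.5, 12.5]**.
   Separate, independent models handle the most-acidic and most-basic
   pKa (tasks `acid` / `base`); nonionizable "negative" molecules are
   trained with sentinel labels (acid 50, base −5) that land in the
   catch-all bins.
3. **Atomic sensitivity analysis.** Each heteroatom `a` of a parent
   molecule is replaced — independently, never compounding — by a
   correctly hybridized neutral carbon, the perturbed molecule is
   rescored, and the output shift is measured by the KL divergence
   `D_a = D(P′_a ‖ P)`. Scores are denoised with
   `ASA(a) = 5·(e^{D_a} − 1)` for `D_a ≥ τ` (else 0, τ = 0.05 nats);
   the highest-scoring atom above a cutoff (default 1.5) is reported as
   the ionization site.

A seeded synthetic-molecule generator (`benchlab`) emulates the
monoprotic druglike training regime — alkyl/ring scaffolds decorated with
one ionizable group (carboxylic acid, phenol, thiol, sulfonamide, primary
amine, pyridine, imidazole, aniline) with textbook group pKa
distributions, plus hydrocarbon/ether negatives — and provides the
evaluation machinery: MAE, Brier score, pathological-confidence
detection (σ ≤ 1 but error > 1), leave-class-out splits, matched-pair
direction accuracy, and atom-level ASA site metrics.

## Worked example

Generate a synthetic acid training set, train, predict, and run ASA:

```bash
pkasense generate --task acid -n 2000 --seed 11 --out train.csv
pkasense train --data train.csv --task acid --seed 11 --out model.json
printf 'CCC(=O)O\tpropionic_acid\nOc1ccc(CC)cc1\t4-ethylphenol\nCCOCCS\tthioether_thiol\n' > probe.smi
pkasense predict --model model.json --molecules probe.smi --out pred.csv
pkasense asa --model model.json --molecules probe.smi --out asa.csv
```

`pred.csv` (name, expected pKa, σ, then one localPPV column per bin):

```
           name  expected_pka    sigma
 propionic_acid      4.072382 0.495834
  4-ethylphenol      9.839138 0.749759
thioether_thiol     10.714573 0.727663
```

The carboxylic acid lands near its group mean (~4), the phenol near
~9.9, and the thiol near ~10.5, each with sub-unit σ (confident
predictions). `asa.csv` holds one row per atom:

```
           name  atom_index element      d_kl    asa_score status
 propionic_acid           3       O  9.756777 8.634941e+04 scored
 propionic_acid           4       O 10.896162 2.698391e+05 scored
  4-ethylphenol           0       O  0.102922 5.420275e-01 scored
thioether_thiol           2       O  0.158333 8.577801e-01 scored
thioether_thiol           5       S 20.327269 3.365045e+09 scored
```

For propionic acid both carboxyl oxygens dominate (the hydroxyl oxygen,
atom 4, highest); for the thiol the sulfur towers over the decoy ether
oxygen. The phenol oxygen scores below the 1.5 selection cutoff here —
removing the OH still leaves an aromatic ring the model associates with
phenol-like acidity — so `asa.sites.csv` reports a site for the acid
(atom 4) and the thiol (atom 5) but abstains on the phenol.

The same workflow is available as a library: `PkaPredictor.train(...)`,
`predict_distribution`, `asa_profile`, `select_ionization_site`; the
featurizer (`Mol2DFeaturizer`) and classifier (`PkaBinClassifier`) are
sklearn-style estimators usable in pipelines.

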
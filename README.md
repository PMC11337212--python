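# dilinet

Stacked proxy-endpoint ("FeatureNet") pipeline for predicting drug-induced
liver injury (DILI) from chemical structure alone.

Level-1 random-forest models are trained on a panel of binary proxy
endpoints (in vitro / in vivo liver-toxicity assays) and two plasma-Cmax
regression targets. Their predictions, concatenated with variance-selected
structural fingerprints (Morgan 2048-bit radius-2 + 166-bit MACCS = 2,214
bits before selection) and 2D descriptors plus 15 physicochemical
parameters, feed a level-2 DILI classifier with a Youden-J calibrated
decision threshold, evaluated under scaffold-aware Butina splits and
repeated nested cross-validation, with per-compound tree-path attribution
and MACCS substructure highlighting.

## Modules

| module | role |
| --- | --- |
| `dilinet.chemprep` | SMILES filtering, iterative standardization, pH-7.0 protonation (bundled pKa rule table), 14-char structure keys, deduplication |
| `dilinet.featurization` | Morgan/MACCS fingerprints, 2D descriptor catalogue, 15 physchem parameters, variance-threshold selection masks |
| `dilinet.data_model` | gold-standard assembly, proxy panel with leak-proof overlap removal, Cohen's-kappa concordance |
| `dilinet.splitting` | Butina sphere-exclusion clustering (Tanimoto distance 0.70), whole-cluster train/test split, nearest-neighbour similarity |
| `dilinet.endpoint_models` | level-1 classifiers/regressors, halving random search, Youden-J thresholds, 9x9 cross-predictivity |
| `dilinet.featurenet` | stacked features with leak guard, repeated nested CV, final model, prediction, attribution |
| `dilinet.evaluation` | full metric panel (BA, MCC, F1, PPV, LR+, AP, AUC-ROC), top-k LR+ curve, Jaccard, kappa |
| `dilinet.synthetic_fixtures` | self-contained synthetic panel with planted toxicophores and ground-truth manifest |

## CLI

```bash
dilinet make-fixtures --out fixtures/ --seed 1          # synthetic panel
dilinet standardize --in raw.csv --out std.csv          # chemprep pipeline
dilinet split --in fixtures/ --cutoff 0.70 --test-fraction 0.2 --out split.json
dilinet train --panel fixtures/ --split split.json --combo all --fast --repeats 2 --out bundle/
dilinet predict --model bundle/ --smiles in.smi --out pred.csv
dilinet explain --model bundle/ --smiles "c1ccccc1[N+](=O)[O-]"
dilinet evaluate --model bundle/ --test test.csv --out report.json --topk-curve curve.csv
```

## Notes

- The Butina cutoff 0.70 is a Tanimoto **distance** cutoff (1 − similarity).
- A probability exactly at a decision threshold is a **positive** call.
- Undefined metrics (zero-denominator LR+, single-class AUC) are reported as
  flagged nulls, never silently as 0.
- The nested-CV protocol is 5 outer folds x 10 repeats = 50 evaluations.
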
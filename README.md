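# riskstack

Bagged stacking ensembles with hybrid resampling for imbalanced three-class
risk prediction on tabular inspection records.

The pipeline, end to end:

1. **Synthetic data** — a seeded generator for inspection-record tables
   (categorical-heavy schema, ~7% high-risk rows by default) plus a
   stratified train/test splitter with exact largest-remainder allocation.
2. **Features** — cyclical month encoding, shelf-life binning, one-hot
   encoding, zero-variance filtering; fitted schemas replay exactly at
   prediction time.
3. **Resampling** — per-bag stratified bootstrap, multi-class SMOTE
   interpolation up to the majority count, Tomek-link boundary cleaning.
4. **Stacking** — per-bag 3-fold out-of-fold probability meta-features from
   heterogeneous base learners (RF, GB and three gradient-boosting variants
   by default), fused by a logistic meta-learner.
5. **Ensemble** — B bags soft-voted, with an independent high-risk
   probability threshold: a sample is high-risk iff its averaged high-risk
   probability strictly exceeds `tau`; otherwise the label is the argmax
   over the two remaining classes.
6. **Thresholding & metrics** — threshold sweeps with minimal-best-F1
   selection, one-vs-rest PR curves, and the full metric set (accuracy,
   per-class precision/recall/F1/AUC, macro/weighted F1, macro AUC).

If `xgboost`/`lightgbm`/`catboost` are installed they back the registry
entries of the same name; otherwise equivalently configured scikit-learn
`HistGradientBoostingClassifier` models are used, so the package has no
hard dependency beyond the scientific Python stack.

## CLI

```sh
riskstack simulate --n 792 --seed 7 --out records.csv
riskstack featurize --in records.csv --schema schema.json --out features.csv
riskstack fit --train features.csv --config config.yaml --out model_dir/
riskstack predict --model model_dir/ --in features.csv --out preds.csv
riskstack tune-threshold --model model_dir/ --val features.csv --out curve.csv
riskstack benchmark --config exp.yaml --out results/
riskstack robustness --config exp.yaml --fractions 0.1,0.2,0.4 --out results/
```

Example `config.yaml`:

```yaml
ensemble:
  bagging: {B: 5, bootstrap: true}
  stacking:
    k: 3
    base: [RF, GB, XGBoost, CatBoost, LightGBM]
    meta: {name: LR}
  smote: {k_neighbors: 5}
  decision: {tau: 0.5, rule: threshold}
  seed: 42
```

## Library

```python
from riskstack import (
    GeneratorConfig, generate_inspection_records, stratified_split,
    build_feature_matrix, EnsembleConfig, fit_bagging_stacking,
)
from riskstack.ensemble import predict

records = generate_inspection_records(GeneratorConfig(n_records=792, seed=7))
train, test = stratified_split(records, 0.2, seed=0)
ft, schema = build_feature_matrix(train, fit=True)
ft_test = build_feature_matrix(test, schema=schema, fit=False)

model = fit_bagging_stacking(ft, EnsembleConfig(seed=42))
pred = predict(model, ft_test.X)   # labels + soft-voted probabilities
```

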
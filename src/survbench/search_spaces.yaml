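# Declared hyperparameter search spaces for random grid search, one
# document section per tunable adapter. Unpenalized Cox regression is
# deliberately absent: it has nothing to tune.
#
# Types: loguniform (sampled on log scale), uniform, int_uniform
# (inclusive bounds), choice (uniform over listed values).

ridge_cox:
  alpha: {type: loguniform, low: 1.0e-3, high: 1.0e+3}

lasso_cox:
  alpha: {type: loguniform, low: 1.0e-4, high: 1.0e+1}

en_cox:
  alpha: {type: loguniform, low: 1.0e-4, high: 1.0e+1}
  l1_ratio: {type: uniform, low: 0.05, high: 0.95}

surv_tree:
  max_depth: {type: int_uniform, low: 2, high: 8}
  min_samples_leaf: {type: int_uniform, low: 10, high: 60}

rsf:
  n_estimators: {type: int_uniform, low: 50, high: 150}
  min_samples_leaf: {type: int_uniform, low: 10, high: 40}
  max_features: {type: choice, values: [sqrt, 0.3, 0.5]}

ssvm:
  alpha: {type: loguniform, low: 2.44140625e-4, high: 64.0}

snn:
  n_hidden: {type: int_uniform, low: 8, high: 64}
  n_layers: {type: choice, values: [1, 2]}
  dropout: {type: uniform, low: 0.0, high: 0.5}
  lr: {type: loguniform, low: 1.0e-4, high: 1.0e-2}

xgboost:
  max_depth: {type: int_uniform, low: 2, high: 6}
  learning_rate: {type: loguniform, low: 0.01, high: 0.3}
  n_rounds: {type: int_uniform, low: 50, high: 300}
  subsample: {type: uniform, low: 0.5, high: 1.0}
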
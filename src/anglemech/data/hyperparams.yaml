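# Pinned hyperparameters for the five classifier families.
# Library defaults except where noted; seeds are injected at train time.
RF:
  n_estimators: 200
  n_jobs: 1
GBDT:
  n_estimators: 100
  learning_rate: 0.1
  max_depth: 3
XGB:
  n_estimators: 200
  max_depth: 4
  learning_rate: 0.1
  eval_metric: logloss
  n_jobs: 1
SVM:
  C: 1.0
  kernel: rbf
  gamma: scale
LR:
  C: 1.0
  max_iter: 1000
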
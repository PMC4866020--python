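# moawave

Mode-of-action (MOA) classification of chemicals from real-time cell-analysis
(RTCA) time-concentration response curves (TCRCs).

The pipeline: raw impedance or cell-index well traces are normalized to the
pre-treatment value and resampled onto a uniform hourly 0–72 h grid; the 11
concentration curves of a chemical (plus the negative control) are
concatenated and compressed by a multilevel discrete wavelet transform with
coarse-to-fine coefficient pruning; Gaussian-kernel SVMs (or a small
feedforward ANN) are trained on the pruned coefficients and scored by
repeated stratified 70/30 random splits; binary classifiers compose into
trees for multi-cluster tasks; and dose-response-curve (DRC) profiles give
an SR-versus-time series from which a favourable time window can be selected
to restrict the curves before featurization.

Because no public per-well dataset ships with this repository, a synthetic
generator (`moawave.synthetic`) produces labeled datasets with the same
structure: hourly 0–72 h sampling, 11 concentrations in a 1:3 dilution
series plus negative control, cluster-specific concentration- and
time-dependent kill dynamics, and imbalanced cluster sizes (20/5/4/5/6/10/13
compounds in the default preset).

## Command line

```sh
moawave simulate --preset default --seed 1 --out tcrc.csv
moawave featurize --tcrc tcrc.csv --preset svm11 --out features.csv
moawave train --features features.csv --classifier svm --out model.joblib
moawave evaluate --tcrc tcrc.csv --clusters C1,C10 --combine --seed 1 --out results/
moawave tree --tcrc tcrc.csv --structure '[["C1","C3"],"C10"]' --out tree.csv
moawave drc --tcrc tcrc.csv --clusters C1,C10 --out profile.csv
moawave report --results results/
```

`preprocess` converts raw long-format recordings (`well,time_h,value` plus a
plate map `well,chemical_id,concentration,role,label`) into the TCRC CSV the
other commands consume. Featurization presets: `svm11` = the four coarsest
coefficient blocks of a 5-level decomposition of all 11 curves plus NC (229
values), `svm1` = the full 5-level coefficient set of the highest
concentration plus NC (157 values), `raw11` = the unreduced 876-value
concatenation.

## Layout

```
src/moawave/
  preprocess.py    cell-index normalization, cubic-spline hourly resampling
  wavelets.py      concatenation, multilevel DWT, coefficient pruning
  classifiers.py   RBF SVM and 24-12-6 feedforward ANN wrappers
  evaluation.py    stratified repeated random splits, SR / error statistics
  multicluster.py  recursive binary classification trees
  drc.py           toxicity-effect profiles, SR-vs-time, window selection
  synthetic.py     labeled TCRC dataset generator and presets
  io.py            delimited-text readers/writers
  config.py, cli.py
```
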
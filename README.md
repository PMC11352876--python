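# szdetect

Classification of epileptic-seizure vs. non-seizure single-channel EEG
segments, built around four ideas: random data augmentation of labeled
segments, rational-dilation wavelet preprocessing, fuzzy C-means feature
extraction, and LSTM classifiers whose hyperparameters are tuned by
population metaheuristics (particle swarm optimization or a parrot-flock
optimizer with Lévy-flight steps).

Three pipeline variants are provided:

| variant       | features                        | tuner | CV folds |
|---------------|---------------------------------|-------|----------|
| `fcm_ps_lstm` | statistics + FCM selection/memberships | PSO   | 10 |
| `ps_lstm`     | windowed statistics             | PSO   | 10 |
| `po_lstm`     | windowed statistics             | parrot optimizer | 5 |

Everything runs on plain numpy/scipy/scikit-learn; the LSTM, the wavelet
bank, fuzzy C-means and both optimizers are implemented in this package.

## Data

Segments are read in the Bonn ASCII dialect: one amplitude per line, one
file per segment, set directories `A`-`E` (set `E` = seizure, `D` =
non-seizure, others unlabeled). No download is required: the
`szdetect.data.synth_dataset` generator produces Bonn-shaped synthetic
datasets (pink-noise background; 10 Hz rhythm for non-seizure;
spike-wave bursts plus elevated 20-30 Hz band power for seizure) and every
pipeline command accepts `--data synthetic`.

## CLI

```sh
szdetect synth --out ds/ --n-per-class 100 --seed 1
szdetect preprocess --data ds/ --out filtered/
szdetect augment --data ds/ --out augmented/ --factor 2 --seed 1
szdetect features --data ds/ --out features.tsv
szdetect run --method ps_lstm --data synthetic --seed 7 --out results/
szdetect compare --method ps_lstm --data synthetic --factor 3 --seed 7
szdetect report --in results/result.json
```

`run` executes one variant end to end (filtering, wavelet round-trip,
optional augmentation of the training side, feature extraction,
hyperparameter search over cross-validated fitness, final training) and
prints the nine-metric report (accuracy, sensitivity, specificity,
precision, F1, MCC, kappa, CSI, FM index). `compare` performs the paired
before/after-augmentation experiment on an identical train/test split.

By default augmentation happens *after* the stratified 70/30 split and only
on the training side, so augmented variants can never leak information
across the split; `RunConfig(paper_ordering=True)` restores the
augment-then-split ordering for comparison.

## Layout

```
src/szdetect/
  data.py        Bonn I/O, synthetic generator
  preprocess.py  band-pass, median, rational-dilation wavelet bank
  augment.py     random data augmentation (amplitude / shift / width)
  fuzzyfeat.py   windowed statistics, fuzzy C-means, feature selection
  optim.py       PSO, parrot optimizer, Lévy flight, search-space codec
  lstm.py        numpy LSTM classifier, CV fitness
  metrics.py     confusion matrix and the nine-metric report
  pipeline.py    end-to-end orchestration, BDA/ARDA comparison
  cli.py         command-line interface
```
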
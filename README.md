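# misinfonet

Classifying short health-related social-media texts as **trustworthy
information** versus **misinformation**, for public-health informatics
researchers who need a complete, reproducible fact-checking pipeline:
multi-source label harmonization, tweet-style preprocessing, paragraph-level
embedding matrices, cosine-similarity augmentation of the scarce trustworthy
class, a four-pathway 2-D convolutional classifier (with decision tree,
random forest, SVM, stacking, GRU and LSTM comparison models), and a full
evaluation protocol. A synthetic tweet-corpus generator stands in for
non-redistributable social-media data, so every stage runs and is tested
offline.

## The method

**Class rebalancing by similarity injection.** Given a small verified seed
sample (by default 180 trustworthy + 70 misinformation documents), each
unlabeled candidate document *d* is scored by its nearest verified
trustworthy example under smoothed TF-IDF cosine similarity,

    score(d) = max_{s in seeds} (w_d . w_s) / (||w_d|| ||w_s||),

and every candidate with score strictly above a threshold t* is added to
the corpus as trustworthy. t* is calibrated on the verified sample: for
each threshold t in {0.1, ..., 0.4}, precision(t) = TP(t) / (TP(t) + FP(t))
counts verified-trustworthy versus verified-misinformation documents above
t, and t* maximizes precision with ties broken toward larger injection.

**The classifier.** Each document becomes a 100 x 100 matrix (first 100
tokens x 100-dimensional word vectors). Four parallel convolutional
pathways with kernels 12x12, 2x2 (inter-sentence) and 11x2, 1x3
(intra-sentence) each stack three same-padded convolutions, dropout (0.5)
*before* a single ReLU, and 2x2 max pooling; their concatenated features
feed a 128-unit dense layer and a sigmoid output P(misinformation).
Training: Adam, binary cross-entropy, learning rate 1e-4, batch size 128,
5 epochs. The numerical backend is an in-package numpy autodiff engine
(gradient-checked; FFT and direct convolution paths agree to float
tolerance), so no deep-learning framework is required.

See `docs/methods.md` for the full model account, design decisions and
limitations.

## Worked example

```python
from misinfonet.pipeline import desk_run

result = desk_run(seed=1)   # 2,000 docs, 15% trustworthy, purity 0.9
print(result.threshold, result.n_injected)
print(round(result.minority_share_before, 4), "->", round(result.minority_share_after, 4))
print(round(result.report.accuracy, 4), round(result.report.roc_auc, 4))
print(round(result.minority_recall, 4), round(result.control_minority_recall, 4))
```

prints (one CPU core, ~8 minutes including the unaugmented control arm):

```
0.25 915
0.15 -> 0.4168
0.9777 0.9972
0.9835 0.0
```

Reading: calibration chose similarity threshold 0.25 and injected 915
candidate documents, lifting the trustworthy share from 15% to 41.7%. The
classifier then reaches 97.8% accuracy (ROC AUC 0.997) on the held-out
split, against a 58.3% majority baseline. The last line is what the
augmentation buys: with injection the trustworthy class is recovered at
98.4% recall, while the unaugmented control collapses to majority-class
prediction and finds none of it.

The same stages are scriptable individually:

```sh
misinfonet --seed 1 --out-dir runs/sim simulate --n-docs 2000
misinfonet --seed 1 --out-dir runs/cal calibrate \
    --corpus runs/sim/corpus.csv --verified runs/sim/verified.csv \
    --pool runs/sim/pool.csv
misinfonet --seed 1 --out-dir runs/aug augment \
    --corpus runs/sim/corpus.csv --verified runs/sim/verified.csv \
    --pool runs/sim/pool.csv
misinfonet --seed 1 --out-dir runs/fit train \
    --corpus runs/aug/augmented.csv --model textconvonet
misinfonet --seed 1 --out-dir runs/eval evaluate \
    --corpus runs/aug/augmented.csv --model-file runs/fit/model_textconvonet.pkl
```

Every run directory receives a `resolved_config.yaml` recording the exact
settings used.

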
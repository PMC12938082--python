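"""Train each classifier configuration on a small synthetic cycle corpus.

Uses 20 cycles per class to keep the demo quick; the full protocol uses 100
per class. Features (gammatonegram -> frozen tiny backbone) are computed
once and shared by all three heads.
"""

import warnings

import numpy as np

from lungsounds.classify import TrainConfig, predict, train_model
from lungsounds.evaluate import SplitConfig, featurize_corpus, split_dataset
from lungsounds.synth import generate_cycle_corpus

warnings.filterwarnings("ignore")

corpus = generate_cycle_corpus(20, seed=5, snr_db=15)
fmaps, labels = featurize_corpus(corpus, "gammatone")
train_idx, val_idx, test_idx = split_dataset(labels, SplitConfig(seed=0))
print(f"{len(corpus)} cycles -> {len(train_idx)} train / {len(val_idx)} val / {len(test_idx)} test\n")

for kind in ("cnn", "cnn_svm", "cnn_lstm"):
    model = train_model(
        (fmaps[train_idx], labels[train_idx]),
        (fmaps[val_idx], labels[val_idx]),
        kind=kind,
        config=TrainConfig(seed=1),
    )
    pred, _ = predict(model, fmaps[test_idx])
    acc = float((pred == labels[test_idx]).mean())
    epochs = len(model.log.val_loss) if model.log.val_loss else "-"
    print(f"{kind:9s} test accuracy {acc:.2f}  (epochs run: {epochs})")
# The CNN head trains a small MLP on the frozen feature map; the LSTM head
# consumes the 9x64 region sequence; the SVM fits a linear boundary on
# pooled features with no trainable backbone parameters at all.
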
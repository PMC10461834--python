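# medcnn

Prediction of DNA methylation sites (4mC / 5hmC / 6mA) from
multi-dimensional sequence feature encoding with a dual-convolution,
dual-fully-connected attention network.

Given fixed-length DNA windows `S = D_1 … D_L` centered on a candidate
site, the package encodes each window in three complementary dimensions —
one-hot position features (**BPF**, 4×L), nucleotide chemical properties
(**NCP**, 3×L: ring count, hydrogen-bond strength, amino/keto group) and
min-max-normalized dinucleotide step parameters (**DPCP**, 6×L: Twist,
Tilt, Roll, Shift, Slide, Rise) — runs one convolutional branch with
channel- and position-attention per encoding, and fuses the branch
embeddings by an augmented tensor product

    Z = [Z₁; 1] ⊗ [Z₂; 1] ⊗ [Z₃; 1]

before two fully connected layers and a sigmoid output, trained with
binary cross-entropy. Evaluation reports SN, SP, ACC, MCC and the
rank-sum AUC

    AUC = (Σ_{i∈pos} rank_i − n₊(n₊+1)/2) / (n₊ n₋),

and paired Wilcoxon signed-rank utilities compare methods or encodings
across benchmark datasets. A seeded synthetic-data module generates
motif- and dinucleotide-composition datasets so the whole pipeline is
testable without downloads. Intended users: computational epigenomics
groups benchmarking methylation site predictors on iDNA-MS-style window
corpora.

The network runs on a small numpy reverse-mode autodiff backend bundled
with the package; training is CPU-only and deterministic per seed.

## Worked example

```python
from medcnn import (MedcnnClassifier, SplitSpec, evaluate,
                    motif_preset, split_dataset)

# 2000 windows of length 41; positives carry a consensus motif at the site
ds = motif_preset(n_pos=1000, n_neg=1000, seed=1)
train, val, test = split_dataset(ds, SplitSpec(test_fraction=0.3,
                                               validation_fraction_of_train=0.1,
                                               seed=1))
clf = MedcnnClassifier(conv_channels=(16, 32), embed_dim=4, fc_width=64,
                       max_epochs=40, patience=8, random_state=1)
clf.fit(train, validation_data=(val, None))
report = evaluate(clf.predict_proba(test)[:, 1], test.labels)
print(report.to_row("motif"))
```

prints

```
motif	300	300	1.000000	0.990000	0.995000	0.990050	0.994589
```

i.e. on the 600 held-out windows (300 per class) the fused model reaches
sensitivity 1.000, specificity 0.990, accuracy 0.995, MCC 0.990 and AUC
0.995 — the planted positional signal is recovered almost perfectly.

The same workflow is available from the shell:

```bash
medcnn simulate --preset motif --n-pos 1000 --n-neg 1000 --seed 1 --out-dir data/
medcnn train --pos data/motif_pos.fasta --neg data/motif_neg.fasta \
             --seed 1 --out-dir run/
medcnn predict --model run/checkpoint.npz --input data/motif_pos.fasta --out preds.tsv
```

plus `encode`, `evaluate`, `ablate` (BPF/NCP/DPCP/Multi-Fe on one shared
split) and `cross-species` (train on one species, test on all).

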
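# Methods

## Problem and model

The package classifies fixed-length DNA windows centered on a candidate
methylation site (4mC, 5hmC or 6mA) as methylated or not. Each window
`S = D_1 ... D_L` over {A, C, G, T} is represented in three feature
dimensions:

* **BPF** — one-hot position features, a 4×L binary matrix with row order
  (A, T, G, C); each column sums to 1.
* **NCP** — nucleotide chemical properties, a 3×L binary matrix whose
  rows indicate ring count (purines G/A), hydrogen-bond strength (the
  weakly paired T/A) and amino/keto group (A/C), giving A=(1,1,1),
  G=(1,0,0), C=(0,0,1), T=(0,1,0).
* **DPCP** — dinucleotide physicochemical properties: six helical step
  parameters (Twist, Tilt, Roll, Shift, Slide, Rise), min-max normalized
  per property over the 16 dimers, `X_nom = (X − X_min)/(X_max − X_min)`.
  Position i averages its two flanking dimers,
  `DPCP(i) = (X(D_{i−1}D_i) + X(D_i D_{i+1}))/2`, and the terminal
  positions carry their single flanking dimer's value, so the matrix is
  6×L like the other two encodings. (The flanking-dimer reading of the
  sliding dimer window is the only one under which the end columns depend
  solely on the end dimers; it is adopted here.)

The classifier (`MedcnnClassifier`) runs one convolutional branch per
encoding: two `conv → ReLU` layers, a CBAM-style attention block
(channel weights from average- and max-pooled descriptors through a
shared bottleneck MLP, then position weights from channel-wise
average/max maps through a 1-D convolution, both sigmoid-gated and
multiplied onto the feature map), global average pooling, and a linear
projection to a branch embedding `Z_k` of length `d_k`. The three
embeddings, each augmented with a constant 1, are fused by an outer
product

    Z = [Z_1; 1] ⊗ [Z_2; 1] ⊗ [Z_3; 1],

a (d_1+1)×(d_2+1)×(d_3+1) tensor containing every cross-term while
preserving each unimodal embedding in a corner fiber. The flattened
tensor feeds two fully connected layers ending in a single sigmoid
logit. Training minimizes the mean binary cross-entropy

    L = −(1/N) Σ_n [ y⁽ⁿ⁾ log p⁽ⁿ⁾ + (1−y⁽ⁿ⁾) log(1−p⁽ⁿ⁾) ]

by minibatch Adam, with early stopping on validation loss and restoration
of the best-validation checkpoint. With a single selected encoding the
branch embedding feeds the fully connected head directly (no fusion);
`("multi",)` trains a single trunk on the stacked 13×L input.

### Design choices where the architecture was open

* The cube `Z` enters the fully connected head by flattening (the
  simplest order-preserving map; a contraction would discard cross-terms
  the fusion exists to create).
* Attention is applied once per branch, after the second convolution,
  where the feature map is richest.
* The output head is a single sigmoid logit with binary cross-entropy —
  the two-class form consistent with the loss above.
* Global pooling is average pooling over positions: spatial attention has
  already reweighted positions, so a mean preserves that weighting.
* Probabilities inside the loss are clamped at ε = 1e−7.
* Mid-ranks are used for tied scores in the rank-sum AUC, making it equal
  to the tie-corrected Mann–Whitney probability; mid-ranks are likewise
  used on tied absolute differences in the signed-rank test, whose
  statistic is min(W+, W−) with zero differences dropped and a two-sided
  p-value (exact for small tie-free samples, otherwise a
  continuity-corrected normal approximation with tie correction).
* MCC with a vanishing marginal is reported as 0 with a warning rather
  than an error, the conventional continuity choice.
* Metrics are proportions in [0, 1]; percent scaling is presentation-only.

## Numerical backend

The network runs on a small reverse-mode automatic-differentiation
engine over float64 numpy arrays written for this package
(`medcnn._autodiff`): broadcast arithmetic, matmul, a fused 1-D
convolution (im2col forward, scatter backward), reductions with
tie-splitting max, and the shape operations the fusion needs. Every op is
verified against central finite differences in the test suite. Runs are
deterministic for a fixed seed up to platform floating-point behavior;
training is CPU-only.

## Default hyperparameters

Pinned in `medcnn/data/default_config.yaml`: conv channels (32, 64),
kernel length 5, ReLU, attention reduction 8, spatial kernel 7,
d_k = 16, FC widths (128, 1), dropout 0.3, Adam at 1e−3, batch 64, at
most 100 epochs with patience 10, decision threshold 0.5. The default
window length is L = 41 with the candidate site at (1-based) position
21, the convention of the benchmark family this tool targets; L is never
hard-coded.

Tests and the acceptance script use a reduced *desk-scale* configuration
— conv channels (16, 32), d_k = 4, FC width 64, at most 40 epochs with
patience 8 — chosen during development by validation loss (the small
fused head reached a better validation optimum than wider ones on the
synthetic conditions) and sized so the whole suite trains in a few
CPU-minutes at the problem sizes below.

## Dinucleotide property table

The bundled 6×16 table (`medcnn/data/dinuc_step_params.tsv`) transcribes
B-DNA dimer step averages in the lineage of crystallographic surveys
(Olson et al. 1998, PNAS 95:11163): Twist/Tilt/Roll in degrees,
Shift/Slide/Rise in ångströms, obeying reverse-complement symmetry
(Twist, Roll, Slide, Rise invariant; Tilt and Shift negate). Because
every property row is min-max normalized before use, downstream behavior
depends only on the relative spacing of the values, not their scale.
User tables in the same TSV format are accepted; golden tests pin the
bundled table.

## Data splitting

`split_dataset` draws `round(N · test_fraction)` test records and then
`round(n_remaining · validation_fraction)` validation records from the
rest, allocating both across the label strata by largest remainder, so
stratified label proportions match the full dataset within one record
per partition. Splits are uniform within strata given the seed; no
sequence-similarity-aware splitting is attempted (redundancy filtering
of source corpora is upstream of this package).

## Synthetic study conditions

The generator emulates the statistical skeleton of a methylation
benchmark, not real genomes:

* **positional-motif preset** — negatives i.i.d. from a background base
  distribution (default uniform); positives identical except inside a
  6-bp consensus footprint (`GAGGCT`) straddling the central site, where
  each column is `(1−strength)·background + strength·PWM`. At strength 1
  every positive carries the consensus verbatim.
* **dinucleotide preset** — positives follow a first-order Markov chain
  with CpG/GpC steps enriched (default boost 0.35) and no positional
  anchor; negatives are background i.i.d. This gives the
  dinucleotide-property branch a regime where composition, not position,
  carries the signal.

Sizes used by the tests and the acceptance script: n = 2000 windows
(1000 per class, L = 41) for the held-out-AUC, label-shuffling and
strength-sweep checks; n = 2000 for each encoding-ablation run; two
species of n = 600 for cross-species transfer. One numpy Generator
stream per dataset makes FASTA output byte-identical across runs.

What passing these conditions does **not** show: performance on real
genomes, whose k-mer statistics, GC structure, class imbalance and
sequence redundancy the generator deliberately omits. The published
multi-species benchmark results require the external 17-dataset corpus
and long training sweeps; this package verifies the machinery (encoding
fidelity, metric and test oracles, fusion algebra, learning and transfer
behavior under known ground truth) rather than those numbers.

## Degenerate inputs and edge rules

Sequences outside A/C/G/T are rejected (position-reporting errors), or
dropped with a count under `skip_invalid`. DPCP requires L ≥ 2.
A constant property row cannot be normalized and errors. Training
rejects single-class training sets and non-finite losses (reported with
the epoch). `max_epochs = 0` leaves the seeded initial weights as the
checkpoint with an empty trajectory. AUC is undefined (error) on
single-class label sets; it is *not* clamped to [0.5, 1] — a bad model
may genuinely score below 0.5.

## Known limitations

* The autodiff backend is single-threaded numpy; at benchmark scale
  (tens of thousands of windows, 100 epochs) training takes hours, which
  is out of scope for the test suite.
* Early stopping with a small validation slice (10% of training) is
  noisy; the best-validation checkpoint can be a few epochs away from
  the test-optimal one.
* The signed-rank p-value conventions (two-sided, zero-drop, mid-ranks)
  are one standard choice; software differs in zero/tie handling, so
  statistics computed on external result tables may differ slightly from
  other implementations.
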
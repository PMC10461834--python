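"""Shared fixtures.

The heavy training runs (learning-sanity checks on the synthetic study
conditions) are session-scoped so each is trained exactly once per test
session; the model configuration used for them is the package's pinned
desk-scale configuration: reduced channel/embedding widths chosen by
validation loss during development, sized so the whole suite trains on a
single CPU in a few minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from medcnn import (
    LabeledDataset,
    MedcnnClassifier,
    ModelConfig,
    SequenceRecord,
    SplitSpec,
    auc_rank,
    cross_species_matrix,
    encoding_ablation,
    load_property_table,
    motif_preset,
    dinucleotide_preset,
    split_dataset,
)

#: Desk-scale training configuration used by every learning test.
FAST_PARAMS = dict(
    conv_channels=(16, 32), embed_dim=4, fc_width=64,
    max_epochs=40, patience=8,
)


@pytest.fixture(scope="session")
def property_table():
    return load_property_table()


@pytest.fixture(scope="session")
def fast_params():
    return dict(FAST_PARAMS)


def _fit_heldout_auc(ds: LabeledDataset, seed: int) -> float:
    tr, va, te = split_dataset(ds, SplitSpec(seed=seed))
    est = MedcnnClassifier(random_state=seed, **FAST_PARAMS)
    est.fit(tr, validation_data=(va, None))
    return auc_rank(est.predict_proba(te)[:, 1], te.labels)


@pytest.fixture(scope="session")
def motif_heldout_auc() -> float:
    """Held-out AUC on the full-strength positional-motif condition (n=2000)."""
    return _fit_heldout_auc(motif_preset(n_pos=1000, n_neg=1000, seed=1), seed=1)


@pytest.fixture(scope="session")
def shuffled_heldout_auc() -> float:
    """Held-out AUC after destroying the labels by permutation (leakage control)."""
    ds = motif_preset(n_pos=1000, n_neg=1000, seed=1)
    rng = np.random.default_rng(1)
    perm = rng.permutation([r.label for r in ds.records])
    shuffled = LabeledDataset(
        [SequenceRecord(r.id, r.sequence, label=int(lab))
         for r, lab in zip(ds.records, perm)],
        name="shuffled",
    )
    return _fit_heldout_auc(shuffled, seed=1)


@pytest.fixture(scope="session")
def strength_sweep_aucs() -> list[float]:
    """Held-out AUC at motif strengths 0, 0.3, 0.6, 1.0 (pinned seed)."""
    return [
        _fit_heldout_auc(
            motif_preset(n_pos=1000, n_neg=1000, strength=s, seed=2), seed=2
        )
        for s in (0.0, 0.3, 0.6, 1.0)
    ]


@pytest.fixture(scope="session")
def ablation_motif():
    cfg = ModelConfig(seed=3, **FAST_PARAMS)
    ds = motif_preset(n_pos=1000, n_neg=1000, seed=3, name="motif")
    return encoding_ablation(ds, cfg)


@pytest.fixture(scope="session")
def ablation_dinuc():
    cfg = ModelConfig(seed=3, **FAST_PARAMS)
    ds = dinucleotide_preset(n_pos=1000, n_neg=1000, seed=3, name="dinuc")
    return encoding_ablation(ds, cfg)


@pytest.fixture(scope="session")
def cross_species_shared():
    """Two synthetic species sharing one planted motif."""
    cfg = ModelConfig(seed=4, **FAST_PARAMS)
    datasets = {
        "sp1": motif_preset(300, 300, seed=41, name="sp1"),
        "sp2": motif_preset(300, 300, seed=42, name="sp2"),
    }
    return cross_species_matrix(datasets, cfg)


@pytest.fixture(scope="session")
def cross_species_disjoint():
    """Two synthetic species with disjoint motifs."""
    cfg = ModelConfig(seed=4, **FAST_PARAMS)
    datasets = {
        "sp1": motif_preset(300, 300, seed=43, name="sp1"),
        "sp2": motif_preset(300, 300, seed=44, consensus="TTCAAG", name="sp2"),
    }
    return cross_species_matrix(datasets, cfg)


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """Six 8-mers, 3 per class, for plumbing tests."""
    seqs_pos = ["ACGTACGT", "AAGTACGA", "ACGGACGT"]
    seqs_neg = ["TTTTCCCC", "GGGGTTTT", "CCCCAAAA"]
    records = [
        SequenceRecord(f"p{i}", s, label=1) for i, s in enumerate(seqs_pos)
    ] + [
        SequenceRecord(f"n{i}", s, label=0) for i, s in enumerate(seqs_neg)
    ]
    return LabeledDataset(records, name="tiny")
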
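"""Seeded generators of labeled methylation-window datasets.

Two presets emulate the two kinds of signal the encoders are built to
capture:

* **positional motif** — negatives are i.i.d. draws from a background base
  distribution; positives match the background except inside a motif
  footprint near the center of the window, where each column is drawn
  from ``(1 - strength) * background + strength * PWM column``. This is
  the consensus-near-the-site structure of real methylation benchmarks
  and is the regime where positional encodings (BPF/NCP) carry the
  signal.
* **dinucleotide composition** — positives are a first-order Markov chain
  with specific dimer steps enriched genome-wide (no positional anchor);
  negatives are background i.i.d. This exercises the dinucleotide
  physicochemical (DPCP) branch specifically.

A single numpy Generator stream (from the config seed) drives everything,
so identical configs produce byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import LabeledDataset, SequenceRecord

__all__ = [
    "MotifSpec",
    "GeneratorConfig",
    "generate_dataset",
    "generate_dinucleotide_dataset",
    "empirical_base_frequencies",
    "motif_preset",
    "dinucleotide_preset",
]

#: Row order of PWM and background vectors.
BASE_ORDER = "ACGT"

#: Default consensus motif (one-hot PWM columns for "GAGGCT") used by the
#: positional preset; at strength 1 every positive carries it verbatim.
_DEFAULT_CONSENSUS = "GAGGCT"

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class MotifSpec:
    """A position weight matrix planted near the window center.

    ``pwm`` is 4 x w, column-stochastic, rows in A/C/G/T order;
    ``center_offset`` shifts the motif start relative to centered
    placement; ``strength`` interpolates between background (0) and the
    PWM (1) at the motif columns.
    """

    pwm: np.ndarray
    center_offset: int = 0
    strength: float = 1.0

    def __post_init__(self):
        pwm = np.asarray(self.pwm, dtype=np.float64)
        object.__setattr__(self, "pwm", pwm)
        if pwm.ndim != 2 or pwm.shape[0] != 4:
            raise ValueError("pwm must be 4 x w")
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    def start(self, L: int) -> int:
        """0-based start so the motif straddles the central site."""
        start = (L - self.width) // 2 + self.center_offset
        if start < 0 or start + self.width > L:
            raise ValueError(
                f"motif of width {self.width} does not fit window of "
                f"length {L} at offset {self.center_offset}"
            )
        return start


def consensus_motif(consensus: str = _DEFAULT_CONSENSUS,
                    strength: float = 1.0) -> MotifSpec:
    """One-hot PWM for a consensus string."""
    pwm = np.zeros((4, len(consensus)))
    for j, ch in enumerate(consensus):
        pwm[BASE_ORDER.index(ch), j] = 1.0
    return MotifSpec(pwm=pwm, strength=strength)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic dataset draw."""

    n_pos: int = 1000
    n_neg: int = 1000
    L: int = 41
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND
    motif: MotifSpec = field(default_factory=consensus_motif)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("counts must be positive")
        bg = np.asarray(self.background, dtype=np.float64)
        if abs(bg.sum() - 1.0) > 1e-12:
            raise ValueError("background must sum to 1")
        if self.motif.width > self.L:
            raise ValueError("motif wider than the window")


def _draw(rng: np.random.Generator, probs: np.ndarray, n: int, L: int
          ) -> np.ndarray:
    """n x L base indices; probs is either (4,) or (L, 4) column-wise."""
    if probs.ndim == 1:
        probs = np.broadcast_to(probs, (L, 4))
    u = rng.random((n, L))
    cdf = np.cumsum(probs, axis=1)  # (L, 4)
    return (u[:, :, None] > cdf[None, :, :]).sum(axis=2)


def _to_records(pos_idx: np.ndarray, neg_idx: np.ndarray, name: str
                ) -> LabeledDataset:
    bases = np.array(list(BASE_ORDER))
    records = [
        SequenceRecord(f"{name}_pos_{i:05d}", "".join(bases[row]), label=1)
        for i, row in enumerate(pos_idx)
    ] + [
        SequenceRecord(f"{name}_neg_{i:05d}", "".join(bases[row]), label=0)
        for i, row in enumerate(neg_idx)
    ]
    return LabeledDataset(records, name=name)


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Draw the positional-motif dataset described by ``config``.

    Negatives are i.i.d. background; positives replace the motif columns
    with the strength-interpolated PWM distribution. Positives first,
    then negatives, in generation order.
    """
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background, dtype=np.float64)
    motif = config.motif
    start = motif.start(config.L)

    col_probs = np.broadcast_to(bg, (config.L, 4)).copy()
    mixed = (1.0 - motif.strength) * bg[None, :] \
        + motif.strength * motif.pwm.T  # (w, 4)
    col_probs[start : start + motif.width] = mixed

    pos = _draw(rng, col_probs, config.n_pos, config.L)
    neg = _draw(rng, bg, config.n_neg, config.L)
    return _to_records(pos, neg, config.name)


def generate_dinucleotide_dataset(config: GeneratorConfig,
                                  enriched_dimers: tuple[str, ...] = ("CG", "GC"),
                                  enrichment: float = 0.35) -> LabeledDataset:
    """Draw the dinucleotide-composition preset.

    Positives follow a first-order Markov chain whose transition rows move
    ``enrichment`` probability mass (scaled by the motif ``strength``)
    toward the successors that complete the enriched dimers; negatives are
    i.i.d. background. There is no positional anchor, so the signal lives
    purely in dimer frequencies.
    """
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background, dtype=np.float64)
    strength = config.motif.strength

    transition = np.broadcast_to(bg, (4, 4)).copy()
    boost = enrichment * strength
    for dimer in enriched_dimers:
        i, j = BASE_ORDER.index(dimer[0]), BASE_ORDER.index(dimer[1])
        transition[i] = transition[i] * (1.0 - boost)
        transition[i, j] += boost
    transition /= transition.sum(axis=1, keepdims=True)

    pos = np.empty((config.n_pos, config.L), dtype=int)
    pos[:, 0] = _draw(rng, bg, config.n_pos, 1)[:, 0]
    cdf = np.cumsum(transition, axis=1)
    for t in range(1, config.L):
        u = rng.random(config.n_pos)
        pos[:, t] = (u[:, None] > cdf[pos[:, t - 1]]).sum(axis=1)

    neg = _draw(rng, bg, config.n_neg, config.L)
    return _to_records(pos, neg, config.name)


def empirical_base_frequencies(ds: LabeledDataset) -> np.ndarray:
    """Observed A/C/G/T proportions over all records (sums to 1)."""
    if not len(ds):
        raise ValueError("empty dataset")
    counts = np.zeros(4)
    for r in ds.records:
        for i, b in enumerate(BASE_ORDER):
            counts[i] += r.sequence.count(b)
    return counts / counts.sum()


def motif_preset(n_pos: int = 1000, n_neg: int = 1000, L: int = 41,
                 strength: float = 1.0, seed: int = 0,
                 consensus: str = _DEFAULT_CONSENSUS,
                 name: str = "motif") -> LabeledDataset:
    """The positional-motif study condition (balanced, uniform background)."""
    config = GeneratorConfig(
        n_pos=n_pos, n_neg=n_neg, L=L,
        motif=consensus_motif(consensus, strength=strength), seed=seed,
        name=name,
    )
    return generate_dataset(config)


def dinucleotide_preset(n_pos: int = 1000, n_neg: int = 1000, L: int = 41,
                        strength: float = 1.0, seed: int = 0,
                        name: str = "dinuc") -> LabeledDataset:
    """The dimer-composition study condition (CpG/GpC enrichment)."""
    config = GeneratorConfig(
        n_pos=n_pos, n_neg=n_neg, L=L,
        motif=consensus_motif(strength=strength), seed=seed, name=name,
    )
    return generate_dinucleotide_dataset(config)
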
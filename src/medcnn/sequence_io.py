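"""Reading, writing and splitting labeled DNA methylation window datasets.

Datasets are fixed-length DNA windows centered on a candidate methylation
site. The canonical on-disk layout is a positive/negative FASTA pair (the
convention of the iDNA-MS-style benchmarks); a single-file mode accepts a
``|label=1`` (or ``|label=0``) token in the header. Splitting follows the
train/test redistribution protocol with an additional validation slice
carved from the training portion, stratified by label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

#: Default window length: 41-mer with the candidate site at (1-based)
#: position 21, the convention of the iDNA-MS benchmark family.
DEFAULT_WINDOW_LENGTH = 41


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the A/C/G/T alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length DNA window centered on a candidate site."""

    id: str
    sequence: str
    label: int | None = None
    species: str | None = None
    methyl_type: str | None = None  # one of {"4mC", "5hmC", "6mA"} when known

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 2:
            raise SequenceValidationError(
                f"record {self.id!r}: sequence length must be >= 2"
            )
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_BASES:
                raise SequenceValidationError(
                    f"record {self.id!r}: invalid character {ch!r} at position {pos}"
                )


@dataclass
class LabeledDataset:
    """An ordered collection of labeled, equal-length windows."""

    records: list[SequenceRecord]
    name: str = "dataset"

    def __post_init__(self):
        if self.records:
            L = len(self.records[0].sequence)
            for r in self.records:
                if len(r.sequence) != L:
                    raise ValueError(
                        f"length mismatch: record {r.id!r} has length "
                        f"{len(r.sequence)}, expected {L}"
                    )
            ids = [r.id for r in self.records]
            if len(set(ids)) != len(ids):
                dup = next(i for i in ids if ids.count(i) > 1)
                raise ValueError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def L(self) -> int:
        if not self.records:
            raise ValueError("empty dataset has no window length")
        return len(self.records[0].sequence)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def subset(self, indices, name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices], name=name or self.name
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partitioning parameters.

    ``test_fraction`` follows the 7:3 / 8:2 redistribution convention;
    ``validation_fraction_of_train`` is the share of the remaining training
    portion set aside for early stopping (10% in the reference protocol).
    """

    test_fraction: float = 0.3
    validation_fraction_of_train: float = 0.1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if not 0.0 <= self.validation_fraction_of_train < 1.0:
            raise ValueError("validation_fraction_of_train must be in [0, 1)")


def _parse_header(header: str) -> tuple[str, int | None]:
    """First whitespace token is the id; a ``|label=X`` suffix carries a label."""
    token = header.split()[0] if header.split() else header
    label = None
    if "|label=" in token:
        token, _, lab = token.rpartition("|label=")
        label = int(lab)
        if label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {label}")
    return token, label


def read_fasta(path, skip_invalid: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are uppercase-normalized. Characters outside A/C/G/T raise
    :class:`SequenceValidationError` unless ``skip_invalid`` is set, in
    which case offending records are dropped with a logged count.
    """
    path = Path(path)
    # pre-scan for sequence-before-header malformation, with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []

    records: list[SequenceRecord] = []
    n_skipped = 0
    seen_ids: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid, label = _parse_header(entry.id)
        seq = str(entry.seq).upper()
        try:
            rec = SequenceRecord(id=rid, sequence=seq, label=label)
        except SequenceValidationError:
            if skip_invalid:
                n_skipped += 1
                continue
            raise
        if rid in seen_ids:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen_ids.add(rid)
        records.append(rec)
    if n_skipped:
        warnings.warn(
            f"{path}: dropped {n_skipped} record(s) with non-ACGT characters",
            stacklevel=2,
        )
    return records


def write_fasta(records, path) -> None:
    """Write records as FASTA, embedding labels as ``|label=X`` when present."""
    entries = []
    for r in records:
        rid = r.id if r.label is None else f"{r.id}|label={r.label}"
        entries.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
    SeqIO.write(entries, str(path), "fasta-2line")


def load_labeled_dataset(pos_path, neg_path, name: str | None = None,
                         skip_invalid: bool = False) -> LabeledDataset:
    """Assemble a dataset from a positive/negative FASTA pair.

    Positives are labeled 1, negatives 0, in that order; all windows must
    share one length.
    """
    pos = read_fasta(pos_path, skip_invalid=skip_invalid)
    neg = read_fasta(neg_path, skip_invalid=skip_invalid)
    if not pos:
        raise ValueError(f"no positive records in {pos_path}")
    if not neg:
        raise ValueError(f"no negative records in {neg_path}")
    records = [
        SequenceRecord(r.id, r.sequence, label=1, species=r.species,
                       methyl_type=r.methyl_type)
        for r in pos
    ] + [
        SequenceRecord(r.id, r.sequence, label=0, species=r.species,
                       methyl_type=r.methyl_type)
        for r in neg
    ]
    if name is None:
        name = Path(pos_path).stem
    return LabeledDataset(records, name=name)


def _allocate(counts: np.ndarray, fraction: float, total_target: int) -> np.ndarray:
    """Largest-remainder allocation of ``total_target`` draws across strata."""
    ideal = counts * fraction
    base = np.floor(ideal).astype(int)
    remainder = total_target - base.sum()
    if remainder > 0:
        order = np.argsort(-(ideal - base), kind="stable")
        for i in order[:remainder]:
            base[i] += 1
    elif remainder < 0:
        order = np.argsort(ideal - base, kind="stable")
        for i in order[: -remainder]:
            base[i] = max(base[i] - 1, 0)
    return np.minimum(base, counts)


def split_dataset(ds: LabeledDataset, spec: SplitSpec
                  ) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Partition a dataset into disjoint train/validation/test subsets.

    The test set has ``round(N * test_fraction)`` records; the validation
    set has ``round(n_remaining * validation_fraction_of_train)`` records
    carved from the training portion. With ``stratified=True`` both targets
    are distributed across the label strata by largest remainder, so the
    label proportions match the full dataset within rounding. Deterministic
    for a fixed seed.
    """
    labels = ds.labels
    n = len(ds)
    rng = np.random.default_rng(spec.seed)

    if spec.stratified:
        strata = [np.flatnonzero(labels == lab) for lab in (1, 0)]
    else:
        strata = [np.arange(n)]
    counts = np.array([len(s) for s in strata])

    n_test = int(round(n * spec.test_fraction))
    test_alloc = _allocate(counts, spec.test_fraction, n_test)
    n_remaining = n - test_alloc.sum()
    n_val = int(round(n_remaining * spec.validation_fraction_of_train))
    remaining_counts = counts - test_alloc
    val_alloc = _allocate(
        remaining_counts, spec.validation_fraction_of_train, n_val
    )

    test_idx, val_idx, train_idx = [], [], []
    for stratum, nt, nv in zip(strata, test_alloc, val_alloc):
        perm = rng.permutation(stratum)
        test_idx.extend(perm[:nt])
        val_idx.extend(perm[nt : nt + nv])
        train_idx.extend(perm[nt + nv :])

    for part_name, alloc in (("test", test_alloc), ("validation", val_alloc)):
        if spec.stratified and any(a == 0 for a in alloc) and sum(alloc) > 0:
            lab = 1 if alloc[0] == 0 else 0
            warnings.warn(
                f"{part_name} partition has no records of class {lab}",
                stacklevel=2,
            )

    train = ds.subset(sorted(train_idx), name=f"{ds.name}_train")
    val = ds.subset(sorted(val_idx), name=f"{ds.name}_val")
    test = ds.subset(sorted(test_idx), name=f"{ds.name}_test")

    train_labels = train.labels
    if len(train) and (train_labels.sum() == 0 or train_labels.sum() == len(train)):
        raise ValueError(
            "training partition is single-class; use stratified=True or "
            "adjust the fractions"
        )
    return train, val, test


def write_dataset(ds: LabeledDataset, out_dir, seed: int | None = None) -> dict:
    """Export a dataset as a positive/negative FASTA pair plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos = [r for r in ds.records if r.label == 1]
    neg = [r for r in ds.records if r.label == 0]
    write_fasta([SequenceRecord(r.id, r.sequence) for r in pos],
                out_dir / f"{ds.name}_pos.fasta")
    write_fasta([SequenceRecord(r.id, r.sequence) for r in neg],
                out_dir / f"{ds.name}_neg.fasta")
    manifest = {
        "name": ds.name,
        "L": ds.L,
        "n_pos": len(pos),
        "n_neg": len(neg),
        "split_seed": seed,
    }
    with open(out_dir / f"{ds.name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
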
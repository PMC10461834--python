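"""The three DNA window encodings and their stacked multi-dimensional form.

Each fixed-length window S = D_1 D_2 ... D_L over {A,C,G,T} is mapped to a
channels x L numeric matrix in three complementary feature dimensions:

* **BPF** (binary position feature, one-hot): 4 x L, row order (A, T, G, C).
  Column i is the indicator of D_i — pure positional information.
* **NCP** (nucleotide chemical property): 3 x L. Row 1 marks the purines
  (two-ring bases G/A), row 2 the weak-hydrogen-bond pair T/A, row 3 the
  amino-group bases A/C, so A=(1,1,1), G=(1,0,0), C=(0,0,1), T=(0,1,0).
* **DPCP** (dinucleotide physicochemical properties): 6 x L from six
  helical step parameters (Twist, Tilt, Roll, Shift, Slide, Rise) of the
  adjacent-base dimers, min-max normalized per property across the 16
  dimers. Interior position i averages the two dimers flanking it,
  (X(D_{i-1}D_i) + X(D_i D_{i+1})) / 2; the end columns carry their single
  flanking dimer's value, so the matrix has L columns like the other two.

The stacked **MULTI** representation is the 13 x L row-wise concatenation
[BPF; NCP; DPCP], sliceable by channel name into per-encoding blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import LabeledDataset, SequenceValidationError, VALID_BASES

#: BPF row order (one-hot case order): A, T, G, C.
BPF_BASES = "ATGC"
#: NCP channel names, in order.
NCP_CHANNELS = ("ring", "hbond", "amino")
#: DPCP property order, matching the bundled table.
DPCP_PROPERTIES = ("Twist", "Tilt", "Roll", "Shift", "Slide", "Rise")
#: The 16 dinucleotides in lexicographic order.
DINUCLEOTIDES = tuple("".join(p) for p in product("ACGT", repeat=2))

_NCP_CODE = {
    "A": (1, 1, 1),
    "G": (1, 0, 0),
    "C": (0, 0, 1),
    "T": (0, 1, 0),
}


@dataclass(frozen=True)
class EncodedMatrix:
    """A channels x L feature matrix produced by one encoder (or the stack)."""

    values: np.ndarray
    encoding: str  # one of {"BPF", "NCP", "DPCP", "MULTI"}
    channel_names: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (channels x L)")
        if v.shape[0] != len(self.channel_names):
            raise ValueError("channel_names must match the row count")

    @property
    def L(self) -> int:
        return self.values.shape[1]

    def rows(self, prefix: str) -> np.ndarray:
        """Return the sub-matrix of channels whose names start with ``prefix``."""
        idx = [i for i, n in enumerate(self.channel_names) if n.startswith(prefix)]
        if not idx:
            raise KeyError(f"no channels with prefix {prefix!r}")
        return self.values[idx]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.channel_names)).to_csv(
            path, sep="\t", header=False
        )


@dataclass(frozen=True)
class DinucPropertyTable:
    """Six helical step parameters for the 16 dinucleotides.

    ``raw`` holds the literature values; ``normalized`` holds the per-property
    min-max rescaling to [0, 1] (each property row attains 0 and 1 exactly).
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame | None = None
    source_citation: str = ""

    def __post_init__(self):
        if list(self.raw.index) != list(DPCP_PROPERTIES):
            raise ValueError(f"table must have rows {DPCP_PROPERTIES}")
        if sorted(self.raw.columns) != sorted(DINUCLEOTIDES):
            raise ValueError("table must have the 16 dinucleotide columns")

    @property
    def is_normalized(self) -> bool:
        return self.normalized is not None

    def lookup(self, dimer: str) -> np.ndarray:
        """Normalized 6-vector for one dinucleotide."""
        if self.normalized is None:
            raise ValueError("table is not normalized; call normalize_property_table")
        return self.normalized[dimer].to_numpy()


def _validate(seq: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in VALID_BASES:
            raise SequenceValidationError(
                f"invalid character {ch!r} at position {pos}"
            )
    return seq


def load_property_table(path=None) -> DinucPropertyTable:
    """Load (and normalize) a dinucleotide property table.

    Without ``path`` the bundled table is used: B-DNA dimer step parameters
    (Twist, Tilt, Roll in degrees; Shift, Slide, Rise in angstroms)
    transcribed from crystallographic averages in the Olson et al. (1998,
    PNAS 95:11163) lineage, obeying reverse-complement symmetry. The exact
    raw scale is immaterial downstream because every property row is
    min-max normalized over the 16 dimers.
    """
    if path is None:
        with resources.as_file(
            resources.files("medcnn.data") / "dinuc_step_params.tsv"
        ) as p:
            raw = pd.read_csv(p, sep="\t", index_col=0)
        citation = "B-DNA dimer step averages (Olson et al. 1998 lineage)"
    else:
        raw = pd.read_csv(Path(path), sep="\t", index_col=0)
        citation = str(path)
    raw.index.name = "property"
    table = DinucPropertyTable(raw=raw.astype(float), source_citation=citation)
    return normalize_property_table(table)


def normalize_property_table(table: DinucPropertyTable) -> DinucPropertyTable:
    """Min-max rescale each property row to [0, 1] across the 16 dimers."""
    raw = table.raw
    mins = raw.min(axis=1)
    maxs = raw.max(axis=1)
    constant = mins.index[(maxs - mins) == 0]
    if len(constant):
        raise ValueError(
            f"property {constant[0]!r} is constant across dinucleotides; "
            "cannot min-max normalize"
        )
    normalized = raw.sub(mins, axis=0).div(maxs - mins, axis=0)
    return replace(table, normalized=normalized)


def encode_bpf(seq: str, source_id: str = "") -> EncodedMatrix:
    """One-hot 4 x L matrix with row order (A, T, G, C)."""
    seq = _validate(seq)
    L = len(seq)
    values = np.zeros((4, L))
    for i, ch in enumerate(seq):
        values[BPF_BASES.index(ch), i] = 1.0
    names = tuple(f"bpf_{b}" for b in BPF_BASES)
    return EncodedMatrix(values, "BPF", names, source_id)


def decode_bpf(matrix: EncodedMatrix) -> str:
    """Invert :func:`encode_bpf`; every column must be exactly one-hot."""
    v = matrix.values
    if v.shape[0] != 4:
        raise ValueError("BPF matrix must have 4 rows")
    onehot = (v == 1.0).sum(axis=0) == 1
    binary = np.isin(v, (0.0, 1.0)).all(axis=0)
    bad = np.flatnonzero(~(onehot & binary & (v.sum(axis=0) == 1.0)))
    if bad.size:
        raise ValueError(f"column {bad[0] + 1} is not one-hot")
    return "".join(BPF_BASES[int(np.argmax(v[:, i]))] for i in range(v.shape[1]))


def encode_ncp(seq: str, source_id: str = "") -> EncodedMatrix:
    """Chemical-property 3 x L matrix (ring count, H-bond strength, amino/keto)."""
    seq = _validate(seq)
    values = np.array([_NCP_CODE[ch] for ch in seq], dtype=np.float64).T
    if values.size == 0:
        values = values.reshape(3, 0)
    return EncodedMatrix(values, "NCP", tuple(f"ncp_{n}" for n in NCP_CHANNELS),
                         source_id)


def encode_dpcp(seq: str, table: DinucPropertyTable,
                source_id: str = "") -> EncodedMatrix:
    """Dinucleotide-property 6 x L matrix via the sliding flanking-dimer window.

    Interior columns average the normalized property vectors of the two
    dimers flanking the position; the first and last columns take the
    single flanking dimer's vector.
    """
    seq = _validate(seq)
    L = len(seq)
    if L < 2:
        raise ValueError("DPCP requires length >= 2 (no dimer exists)")
    if not table.is_normalized:
        raise ValueError("property table must be normalized")
    dimers = np.stack(
        [table.lookup(seq[i : i + 2]) for i in range(L - 1)], axis=1
    )  # 6 x (L-1)
    values = np.empty((6, L))
    values[:, 0] = dimers[:, 0]
    values[:, -1] = dimers[:, -1]
    if L > 2:
        values[:, 1:-1] = 0.5 * (dimers[:, :-1] + dimers[:, 1:])
    return EncodedMatrix(values, "DPCP",
                         tuple(f"dpcp_{p}" for p in DPCP_PROPERTIES), source_id)


def encode_multi(seq: str, table: DinucPropertyTable,
                 source_id: str = "") -> EncodedMatrix:
    """Stacked 13 x L matrix [BPF; NCP; DPCP] with provenance channel names."""
    bpf = encode_bpf(seq, source_id)
    ncp = encode_ncp(seq, source_id)
    dpcp = encode_dpcp(seq, table, source_id)
    values = np.vstack([bpf.values, ncp.values, dpcp.values])
    names = bpf.channel_names + ncp.channel_names + dpcp.channel_names
    return EncodedMatrix(values, "MULTI", names, source_id)


_ENCODERS = {
    "bpf": lambda seq, table, sid: encode_bpf(seq, sid),
    "ncp": lambda seq, table, sid: encode_ncp(seq, sid),
    "dpcp": encode_dpcp,
    "multi": encode_multi,
}


def batch_encode(ds: LabeledDataset, which: str,
                 table: DinucPropertyTable | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Encode every record of a dataset, preserving order.

    Returns ``(X, y)`` with ``X`` of shape N x channels x L and ``y`` the
    label vector.
    """
    if not which:
        raise ValueError("no encoding selected")
    key = which.lower()
    if key not in _ENCODERS:
        raise ValueError(f"unknown encoding {which!r}; choose from "
                         f"{sorted(_ENCODERS)}")
    if key in ("dpcp", "multi") and table is None:
        table = load_property_table()
    X = np.stack(
        [_ENCODERS[key](r.sequence, table, r.id).values for r in ds.records]
    )
    return X, ds.labels
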
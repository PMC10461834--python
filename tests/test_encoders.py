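"""Encoder fidelity: one-hot position features, chemical properties,
dinucleotide step parameters and the stacked representation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medcnn.encoders import (
    DINUCLEOTIDES,
    DPCP_PROPERTIES,
    DinucPropertyTable,
    batch_encode,
    decode_bpf,
    encode_bpf,
    encode_dpcp,
    encode_multi,
    encode_ncp,
    load_property_table,
    normalize_property_table,
)
from medcnn.sequence_io import SequenceValidationError

dna = st.text(alphabet="ACGT", min_size=2, max_size=60)

#: Printed one-hot codes, row order (A, T, G, C).
BPF_CODES = {
    "A": (1, 0, 0, 0),
    "T": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "C": (0, 0, 0, 1),
}
#: Printed chemical-property codes (ring, H-bond, amino).
NCP_CODES = {
    "A": (1, 1, 1),
    "G": (1, 0, 0),
    "C": (0, 0, 1),
    "T": (0, 1, 0),
}


class TestBPF:
    @pytest.mark.parametrize("base,code", BPF_CODES.items())
    def test_printed_codes(self, base, code):
        m = encode_bpf(base + "A")  # pad to satisfy the L >= 1 column check
        assert tuple(m.values[:, 0]) == code

    def test_shape_and_column_sums(self):
        m = encode_bpf("ACGT" * 10 + "A")
        assert m.values.shape == (4, 41)
        np.testing.assert_array_equal(m.values.sum(axis=0), np.ones(41))

    def test_invalid_character_position(self):
        with pytest.raises(SequenceValidationError, match="position 3"):
            encode_bpf("ACNT")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seq=dna)
    def test_decode_inverts_encode(self, seq):
        assert decode_bpf(encode_bpf(seq)) == seq

    def test_decode_rejects_non_onehot(self):
        m = encode_bpf("ACGT")
        bad = m.values.copy()
        bad[:, 1] = [1, 1, 0, 0]
        from dataclasses import replace

        with pytest.raises(ValueError, match="column 2 is not one-hot"):
            decode_bpf(replace(m, values=bad))


class TestNCP:
    @pytest.mark.parametrize("base,code", NCP_CODES.items())
    def test_printed_codes(self, base, code):
        m = encode_ncp(base + base)
        assert tuple(m.values[:, 0]) == code

    def test_gatc_matrix(self):
        m = encode_ncp("GATC")
        expected = np.array([[1, 0, 0], [1, 1, 1], [0, 1, 0], [0, 0, 1]]).T
        np.testing.assert_array_equal(m.values, expected)

    def test_codes_pairwise_distinct(self):
        assert len(set(NCP_CODES.values())) == 4

    def test_matches_set_membership_reimplementation(self):
        """Cross-check against independent per-base membership indicators."""
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            seq = "".join(rng.choice(bases, size=10))
            m = encode_ncp(seq).values
            brute = np.array(
                [
                    [1 if ch in "GA" else 0 for ch in seq],
                    [1 if ch in "TA" else 0 for ch in seq],
                    [1 if ch in "AC" else 0 for ch in seq],
                ]
            )
            np.testing.assert_array_equal(m, brute)


def toy_table(values_ac=0.2, values_ca=0.6) -> DinucPropertyTable:
    """A raw table where one property separates AC/CA for hand checks."""
    raw = pd.DataFrame(
        np.linspace(0.0, 1.0, 16)[None, :].repeat(6, axis=0),
        index=list(DPCP_PROPERTIES),
        columns=list(DINUCLEOTIDES),
    )
    raw.loc["Twist"] = 0.0
    raw.loc["Twist", "AC"] = values_ac
    raw.loc["Twist", "CA"] = values_ca
    raw.loc["Twist", "TT"] = 1.0  # keep max at 1 so normalization is identity
    return normalize_property_table(
        DinucPropertyTable(raw=raw, source_citation="toy")
    )


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        table = load_property_table()
        for prop in DPCP_PROPERTIES:
            row_raw = table.raw.loc[prop]
            row = table.normalized.loc[prop]
            assert row[row_raw.idxmin()] == 0.0
            assert row[row_raw.idxmax()] == 1.0
        # linearity: a synthetic midpoint value maps to 0.5 (AA is neither
        # the row min nor max, so the endpoints are untouched)
        raw = table.raw.copy()
        mid = (raw.loc["Twist"].min() + raw.loc["Twist"].max()) / 2
        raw.loc["Twist", "AA"] = mid
        renorm = normalize_property_table(DinucPropertyTable(raw=raw))
        assert renorm.normalized.loc["Twist", "AA"] == pytest.approx(0.5)

    def test_constant_row_rejected(self):
        raw = load_property_table().raw.copy()
        raw.loc["Rise"] = 3.3
        with pytest.raises(ValueError, match="Rise"):
            normalize_property_table(DinucPropertyTable(raw=raw))

    def test_bundled_table_reverse_complement_symmetry(self):
        """Twist/Roll/Slide/Rise invariant, Tilt/Shift negated under RC."""
        table = load_property_table()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for dimer in DINUCLEOTIDES:
            rc = comp[dimer[1]] + comp[dimer[0]]
            for prop in ("Twist", "Roll", "Slide", "Rise"):
                assert table.raw.loc[prop, dimer] == table.raw.loc[prop, rc]
            for prop in ("Tilt", "Shift"):
                assert table.raw.loc[prop, dimer] == -table.raw.loc[prop, rc]


class TestDPCP:
    def test_homopolymer_columns_constant(self):
        table = load_property_table()
        m = encode_dpcp("AAAA", table)
        np.testing.assert_allclose(m.values, m.values[:, :1].repeat(4, axis=1))
        np.testing.assert_allclose(m.values[:, 0], table.lookup("AA"))

    def test_hand_worked_aca_window(self):
        """ACA with X(AC)=0.2, X(CA)=0.6: columns 0.2, 0.4, 0.6."""
        m = encode_dpcp("ACA", toy_table())
        twist = m.values[list(DPCP_PROPERTIES).index("Twist")]
        np.testing.assert_allclose(twist, [0.2, 0.4, 0.6])

    def test_shape_and_range(self):
        table = load_property_table()
        m = encode_dpcp("ACGT" * 10 + "A", table)
        assert m.values.shape == (6, 41)
        assert (m.values >= 0).all() and (m.values <= 1).all()

    def test_length_one_rejected(self):
        with pytest.raises(ValueError, match="length >= 2"):
            encode_dpcp("A", load_property_table())

    def test_unnormalized_table_rejected(self):
        table = load_property_table()
        raw_only = DinucPropertyTable(raw=table.raw)
        with pytest.raises(ValueError, match="normalized"):
            encode_dpcp("ACGT", raw_only)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seq=dna)
    def test_reverse_sequence_consistency(self, seq):
        """Reversing the sequence and the columns matches evaluating the
        window rule with reversed-dimer lookups."""
        table = load_property_table()
        reversed_raw = table.raw.copy()
        for dimer in DINUCLEOTIDES:
            reversed_raw[dimer] = table.raw[dimer[::-1]]
        reversed_table = normalize_property_table(
            DinucPropertyTable(raw=reversed_raw)
        )
        lhs = encode_dpcp(seq[::-1], reversed_table).values[:, ::-1]
        rhs = encode_dpcp(seq, table).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestMulti:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seq=dna)
    def test_stack_slices_match_individual_encoders(self, seq):
        table = load_property_table()
        m = encode_multi(seq, table)
        assert m.values.shape == (13, len(seq))
        np.testing.assert_array_equal(m.rows("bpf"), encode_bpf(seq).values)
        np.testing.assert_array_equal(m.rows("ncp"), encode_ncp(seq).values)
        np.testing.assert_allclose(m.rows("dpcp"),
                                   encode_dpcp(seq, table).values)


class TestBatchEncode:
    def test_shapes_and_order(self, tiny_dataset, property_table):
        X, y = batch_encode(tiny_dataset, "multi", property_table)
        assert X.shape == (6, 13, 8)
        np.testing.assert_array_equal(y, tiny_dataset.labels)
        rec = tiny_dataset.records[2]
        np.testing.assert_allclose(
            X[2], encode_multi(rec.sequence, property_table).values
        )

    def test_empty_selection_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="no encoding selected"):
            batch_encode(tiny_dataset, "")

    def test_unknown_selection_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="unknown encoding"):
            batch_encode(tiny_dataset, "kmer")
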
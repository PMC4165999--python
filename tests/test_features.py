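"""Descriptor extractors against brute-force counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_sequence
from dnabind.features import (
    ExtractorSpec,
    PropertyPartition,
    aa_composition,
    class_composition,
    class_distribution,
    class_transitions,
    ctd_feature_names,
    default_partitions,
    extract_ctd188,
    extract_matrix,
    extract_ngram,
    extract_pseaac,
    load_partitions,
    segment_bounds,
)
from dnabind.seqio import AMINO_ACIDS, ProteinRecord

PARTS = default_partitions()
HYDRO = PARTS[0]  # hydrophobicity: RKEDQN / GASTPHY / CLVIMFW


# ---------------------------------------------------------------- oracles
def oracle_composition(seq):
    return np.array([seq.count(aa) / len(seq) for aa in AMINO_ACIDS])


def oracle_class_composition(seq, p):
    classes = [p.class1, p.class2, p.class3]
    return np.array([sum(c in cl for c in seq) / len(seq) for cl in classes])


def oracle_transitions(seq, p):
    cls = p.class_of()
    pairs = [(0, 1), (0, 2), (1, 2)]
    counts = [0, 0, 0]
    for a, b in zip(seq, seq[1:]):
        key = tuple(sorted((cls[a], cls[b])))
        if key in pairs:
            counts[pairs.index(key)] += 1
    return np.array(counts) / (len(seq) - 1)


def oracle_distribution(seq, p):
    cls = p.class_of()
    L = len(seq)
    out = []
    for c in range(3):
        for s in range(5):
            lo, hi = L * s // 5, L * (s + 1) // 5
            seg = seq[lo:hi]
            out.append(sum(cls[ch] == c for ch in seg) / len(seg))
    return np.array(out)


def oracle_dipeptides(seq):
    out = np.zeros(400)
    for i in range(len(seq) - 1):
        a, b = AMINO_ACIDS.index(seq[i]), AMINO_ACIDS.index(seq[i + 1])
        out[a * 20 + b] += 1
    return out / (len(seq) - 1)


# ---------------------------------------------------------------- partitions
class TestPropertyPartition:
    def test_defaults_are_eight_valid_partitions(self):
        assert len(PARTS) == 8
        for p in PARTS:
            assert p.class1 | p.class2 | p.class3 == frozenset(AMINO_ACIDS)

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError):
            PropertyPartition.from_strings(
                "bad", "ACDEFGHIK", "KLMNPQRST", "VWY"
            )

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValueError):
            PropertyPartition.from_strings("bad", "ACD", "EFG", "HIK")

    def test_json_load_matches_defaults(self, tmp_path):
        import importlib.resources as res

        text = res.files("dnabind.data").joinpath("property_partitions.json").read_text()
        p = tmp_path / "parts.json"
        p.write_text(text)
        assert load_partitions(p) == PARTS


# ---------------------------------------------------------------- composition
class TestComposition:
    def test_homopolymer(self):
        v = aa_composition("AAAA")
        assert v[0] == 1.0
        assert v[1:].sum() == 0.0

    def test_uniform_alphabet(self):
        assert np.allclose(aa_composition(AMINO_ACIDS), 0.05)

    def test_matches_counting_oracle(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, int(rng.integers(50, 600)))
            assert np.allclose(aa_composition(seq), oracle_composition(seq))

    def test_invalid_letter_raises(self):
        with pytest.raises(ValueError):
            aa_composition("MKVX")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=200))
    def test_sums_to_one_and_shuffle_invariant(self, seq):
        v = aa_composition(seq)
        assert v.sum() == pytest.approx(1.0)
        shuffled = "".join(sorted(seq))
        assert np.allclose(aa_composition(shuffled), v)


class TestClassDescriptors:
    def test_class_composition_homopolymer(self):
        v = class_composition("RRRR", HYDRO)  # R is hydrophobicity class 1
        assert np.allclose(v, [1, 0, 0])

    def test_class_composition_equal_thirds(self):
        seq = "RRGG" + "CC"  # 2 polar, 2 neutral, 2 hydrophobic
        assert np.allclose(class_composition(seq, HYDRO), [1 / 3, 1 / 3, 1 / 3])

    def test_class_composition_oracle(self, rng):
        for p in PARTS:
            for _ in range(15):
                seq = random_sequence(rng, 200)
                assert np.allclose(
                    class_composition(seq, p), oracle_class_composition(seq, p)
                )

    def test_transitions_homopolymer_zero(self):
        assert np.allclose(class_transitions("GGGGG", HYDRO), 0.0)

    def test_transitions_strict_alternation(self):
        # R (class1) and G (class2) alternating: every adjacent pair is a 1-2 change
        v = class_transitions("RGRGRGRG", HYDRO)
        assert np.allclose(v, [1.0, 0.0, 0.0])

    def test_transitions_single_residue_is_zero_vector(self):
        assert np.allclose(class_transitions("R", HYDRO), 0.0)

    def test_transitions_oracle(self, rng):
        for p in PARTS:
            for _ in range(15):
                seq = random_sequence(rng, 200)
                assert np.allclose(
                    class_transitions(seq, p), oracle_transitions(seq, p)
                )

    def test_distribution_homopolymer(self):
        v = class_distribution("R" * 100, HYDRO)
        assert np.allclose(v[:5], 1.0)  # class 1 everywhere
        assert np.allclose(v[5:], 0.0)

    def test_distribution_two_block_sequence(self):
        # L=10: segments are [0,2) [2,4) [4,6) [6,8) [8,10); first half class-1
        # (R), second half class-2 (G) => segment 3 straddles the boundary.
        v = class_distribution("R" * 5 + "G" * 5, HYDRO)
        expected_c1 = [1.0, 1.0, 0.5, 0.0, 0.0]
        expected_c2 = [0.0, 0.0, 0.5, 1.0, 1.0]
        assert np.allclose(v[:5], expected_c1)
        assert np.allclose(v[5:10], expected_c2)
        assert np.allclose(v[10:], 0.0)

    def test_distribution_classes_sum_to_one_per_segment(self, rng):
        seq = random_sequence(rng, 137)
        v = class_distribution(seq, HYDRO).reshape(3, 5)
        assert np.allclose(v.sum(axis=0), 1.0)

    def test_distribution_oracle(self, rng):
        for p in PARTS:
            for _ in range(15):
                seq = random_sequence(rng, int(rng.integers(50, 400)))
                assert np.allclose(
                    class_distribution(seq, p), oracle_distribution(seq, p)
                )

    def test_distribution_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            class_distribution("MKVL", HYDRO)

    def test_segment_bounds_cover_sequence(self):
        for L in (5, 7, 10, 99, 100, 103):
            bounds = segment_bounds(L)
            assert bounds[0][0] == 0 and bounds[-1][1] == L
            for (a, b), (c, d) in zip(bounds, bounds[1:]):
                assert b == c


class TestCtd188:
    def test_dimension_contract(self, rng):
        seq = random_sequence(rng, 100)
        assert extract_ctd188(seq).shape == (188,)

    def test_block_structure(self):
        names = ctd_feature_names(PARTS)
        assert len(names) == 188
        assert sum(n.startswith("comp.") for n in names) == 20
        for p in PARTS:
            assert sum(n.startswith(p.property_name + ".") for n in names) == 21
        # the physicochemical portion totals 168
        assert 188 - 20 == 168

    def test_first_20_equal_1gram(self, rng):
        seq = random_sequence(rng, 150)
        assert np.array_equal(extract_ctd188(seq)[:20], extract_ngram(seq, {1}))

    def test_wrong_partition_count_raises(self):
        with pytest.raises(ValueError, match="8"):
            extract_ctd188("MKVLA" * 20, PARTS[:5])

    def test_shuffle_changes_transitions_not_composition(self, rng):
        seq = random_sequence(rng, 200)
        shuffled = "".join(rng.permutation(list(seq)))
        a, b = extract_ctd188(seq), extract_ctd188(shuffled)
        assert np.allclose(a[:20], b[:20])  # composition invariant
        # transition+distribution blocks essentially always differ
        assert not np.allclose(a[20:], b[20:])


class TestNgram:
    def test_420_dims(self, rng):
        assert extract_ngram(random_sequence(rng, 80), {1, 2}).shape == (420,)

    def test_acac_dipeptides(self):
        v = extract_ngram("ACAC", {2})
        ac = AMINO_ACIDS.index("A") * 20 + AMINO_ACIDS.index("C")
        ca = AMINO_ACIDS.index("C") * 20 + AMINO_ACIDS.index("A")
        assert v[ac] == pytest.approx(2 / 3)
        assert v[ca] == pytest.approx(1 / 3)
        assert v.sum() == pytest.approx(1.0)

    def test_homopolymer_dipeptide(self):
        v = extract_ngram("AAAAA", {2})
        assert v[0] == 1.0

    def test_each_block_sums_to_one(self, rng):
        seq = random_sequence(rng, 90)
        v = extract_ngram(seq, {1, 2})
        assert v[:20].sum() == pytest.approx(1.0)
        assert v[20:].sum() == pytest.approx(1.0)

    def test_2gram_oracle(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, int(rng.integers(50, 300)))
            assert np.allclose(extract_ngram(seq, {2}), oracle_dipeptides(seq))

    def test_unsupported_n_raises(self):
        with pytest.raises(ValueError):
            extract_ngram("MKVLA", {3})


class TestPseaac:
    def test_lambda_zero_is_composition(self, rng):
        seq = random_sequence(rng, 70)
        assert np.allclose(extract_pseaac(seq, 0), aa_composition(seq))

    def test_output_length(self, rng):
        for lam in (0, 1, 10, 25):
            seq = random_sequence(rng, 60)
            assert extract_pseaac(seq, lam).shape == (20 + lam,)

    def test_homopolymer_correlations_vanish(self):
        v = extract_pseaac("K" * 60, 10)
        assert np.allclose(v[20:], 0.0)
        assert v[AMINO_ACIDS.index("K")] == pytest.approx(1.0)

    def test_normalized_to_one(self, rng):
        seq = random_sequence(rng, 120)
        assert extract_pseaac(seq, 15, 0.1).sum() == pytest.approx(1.0)

    def test_sequence_not_longer_than_lambda_raises(self):
        with pytest.raises(ValueError):
            extract_pseaac("MKVLA", 5)


class TestExtractMatrix:
    def test_ctd_matrix_shape(self, small_records):
        m = extract_matrix(small_records, ExtractorSpec(method="ctd188"))
        assert m.shape == (3, 188)
        assert list(m.index) == ["a", "b", "c"]

    def test_empty_input_keeps_columns(self):
        m = extract_matrix([], ExtractorSpec(method="ctd188"))
        assert m.shape == (0, 188)

    def test_deterministic(self, small_records):
        a = extract_matrix(small_records)
        b = extract_matrix(small_records)
        assert a.equals(b)

    def test_error_names_offending_record(self):
        recs = [ProteinRecord("tiny", "", "MKV")]
        with pytest.raises(ValueError, match="tiny"):
            extract_matrix(recs, ExtractorSpec(method="ctd188"))

    def test_all_values_finite(self, small_records):
        for method in ("ctd188", "ngram", "pseaac"):
            m = extract_matrix(small_records, ExtractorSpec(method=method))
            assert np.isfinite(m.to_numpy()).all()
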
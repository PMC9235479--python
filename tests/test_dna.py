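"""2-bit alphabet, reverse complement, and the packed string store."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import minidex as mx
from minidex.dna import PackedStrings, decode, encode

dna_text = st.text(alphabet="ACGT", min_size=1, max_size=200)


@pytest.mark.parametrize("base,code", [("A", 0), ("C", 1), ("G", 2), ("T", 3)])
def test_encoding_fixed_mapping(base, code):
    assert mx.encode_base(base) == code
    assert mx.encode_base(base.lower()) == code
    # complement is XOR 3 under this mapping
    assert mx.encode_base(mx.revcomp(base)) == code ^ 3


def test_encode_decode_roundtrip():
    assert decode(encode("GATTACA")) == "GATTACA"
    assert decode(encode("gattaca")) == "GATTACA"


def test_invalid_base_carries_position():
    with pytest.raises(mx.InvalidBaseError) as exc:
        encode("ACGTNACGT")
    assert exc.value.position == 4
    assert exc.value.char == "N"


def test_try_encode_marks_invalid():
    codes = mx.dna.try_encode("ACNGT")
    assert list(codes) == [0, 1, 255, 2, 3]


@pytest.mark.parametrize("s,rc", [("ACGT", "ACGT"), ("AAA", "TTT"),
                                  ("GATTACA", "TGTAATC")])
def test_revcomp_examples(s, rc):
    assert mx.revcomp(s) == rc


@settings(max_examples=300, deadline=None, derandomize=True)
@given(dna_text)
def test_revcomp_involution(s):
    assert mx.revcomp(mx.revcomp(s)) == s
    # agrees with the naive per-base oracle
    naive = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in s[::-1])
    assert mx.revcomp(s) == naive


def test_revcomp_codes_matches_string_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        codes = rng.integers(0, 4, 31).astype(np.uint8)
        assert decode(mx.dna.revcomp_codes(codes)) == mx.revcomp(decode(codes))


def test_packed_roundtrip_and_bit_length():
    strings = ["ACGTACGT", "TTTTGGGGCCCCAAAA", "ACGT"]
    ps = PackedStrings.from_strings(strings)
    assert ps.decode_all() == strings
    assert ps.nbits == 2 * sum(map(len, strings))
    assert ps.n_strings == 3
    # disk packing (4 bases/byte) inverts exactly
    codes = PackedStrings.unpack_bytes(ps.packed_bytes(), ps.n_bases)
    assert np.array_equal(codes, ps.codes)


def test_endpoints_invariants_enforced():
    with pytest.raises(mx.ShortStringError):
        PackedStrings.from_strings(["ACGTACGT", "ACG"], k=4)
    ps = PackedStrings.from_strings(["ACGTACGT", "ACGG"], k=4)
    E = ps.endpoints
    assert E[0] == 0 and E[-1] == ps.n_bases
    assert (np.diff(E) >= 4).all()


def test_kmer_at_and_alien_windows():
    ps = PackedStrings.from_strings(["ACGTACGT"])
    assert ps.kmer_at(0, 4) == "ACGT"
    assert ps.kmer_at(4, 4) == "ACGT"
    rng = np.random.default_rng(1)
    two = ["".join("ACGT"[c] for c in rng.integers(0, 4, 31)) for _ in range(2)]
    ps2 = PackedStrings.from_strings(two, k=31)
    assert ps2.kmer_at(31, 31) == two[1]
    with pytest.raises(mx.AlienWindowError):
        ps2.kmer_at(1, 31)


def test_kmer_at_agrees_with_slicing_oracle():
    rng = np.random.default_rng(2)
    strings = ["".join("ACGT"[c] for c in rng.integers(0, 4, n))
               for n in (40, 95, 330)]
    ps = PackedStrings.from_strings(strings, k=9)
    offset = 0
    for s in strings:
        for t in range(len(s) - 8):
            assert ps.kmer_at(offset + t, 9) == s[t : t + 9]
        offset += len(s)


def test_canonical_key_identifies_strands():
    rng = np.random.default_rng(3)
    for k in (15, 31, 33, 47):  # both single-word and fingerprint paths
        codes = rng.integers(0, 4, k).astype(np.uint8)
        rc = mx.dna.revcomp_codes(codes)
        assert mx.canonical_key(codes) == mx.canonical_key(rc)
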
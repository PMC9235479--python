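"""2-bit DNA alphabet handling and the packed concatenated string store.

The whole dictionary rests on a fixed 2-bit encoding A=0, C=1, G=2, T=3,
chosen so that the complement of a code is ``code XOR 3`` (branch-free).
Cover strings are stored concatenated as one code vector of N bases (2N
bits when packed on disk) together with the monotone *endpoints* sequence
E[0..p], E[0]=0, E[p]=N, which delimits the individual strings.  A k-mer
window that crosses an endpoint is *alien*: it spells a string that was
never part of the input and must never be reported as a member.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .errors import AlienWindowError, InvalidBaseError, ShortStringError

#: index -> base character
BASES = "ACGT"

_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(BASES):
    _CODE_OF[ord(_c)] = _i
    _CODE_OF[ord(_c.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode_base(c: str) -> int:
    """Map a single base to its 2-bit code (A=0, C=1, G=2, T=3)."""
    code = _CODE_OF[ord(c)] if len(c) == 1 else 255
    if code == 255:
        raise InvalidBaseError(c, 0)
    return int(code)


def decode_base(code: int) -> str:
    return BASES[code]


def encode(s: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array; error on non-ACGT.

    The raised :class:`InvalidBaseError` carries the 0-based position of
    the first offending character.
    """
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    codes = _CODE_OF[raw]
    bad = np.flatnonzero(codes == 255)
    if bad.size:
        pos = int(bad[0])
        raise InvalidBaseError(s[pos], pos)
    return codes


def try_encode(s: str) -> np.ndarray:
    """Encode a query string leniently: non-ACGT positions get code 255.

    Query patterns (e.g. real FASTQ with N calls) are tolerated; every
    k-mer window touching a 255 code is reported as not found upstream.
    """
    raw = np.frombuffer(s.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE_OF[raw]


def decode(codes: Sequence[int] | np.ndarray) -> str:
    arr = np.asarray(codes, dtype=np.uint8)
    return "".join(BASES[c] for c in arr)


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string (involution)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(s.upper()))
    except KeyError as exc:
        raise InvalidBaseError(str(exc.args[0]), s.upper().rindex(exc.args[0])) from None


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on the 2-bit code representation."""
    return (codes[::-1] ^ 3).astype(np.uint8)


def pack_codes(codes: np.ndarray) -> int:
    """Pack a code array into one integer, first base in the top 2 bits.

    With this (big-endian) convention integer order on packed values
    coincides with lexicographic order on the strings.
    """
    v = 0
    for c in codes:
        v = (v << 2) | int(c)
    return v


def unpack_codes(value: int, length: int) -> np.ndarray:
    out = np.empty(length, dtype=np.uint8)
    for i in range(length - 1, -1, -1):
        out[i] = value & 3
        value >>= 2
    return out


def revcomp_packed(value: int, length: int) -> int:
    """Reverse complement directly on a packed 2-bit integer."""
    out = 0
    for _ in range(length):
        out = (out << 2) | ((value & 3) ^ 3)
        value >>= 2
    return out


def canonical_key(codes: np.ndarray) -> int:
    """64-bit key identifying a k-mer with its reverse complement.

    For k <= 32 this is the smaller of the two packed orientations, hence
    collision-free.  For larger k a 64-bit fingerprint of the smaller
    orientation is used; fingerprint collisions only ever add spurious
    candidates that a verifying scan rejects.
    """
    rc = revcomp_codes(codes)
    fwd, bwd = codes, rc
    # lexicographically smaller orientation
    for a, b in zip(fwd, bwd):
        if a < b:
            chosen = fwd
            break
        if b < a:
            chosen = bwd
            break
    else:
        chosen = fwd
    if len(chosen) <= 32:
        return pack_codes(chosen)
    from .minimizers import mix64  # avoid import cycle at module load

    h = 0x27D4EB2F165667C5
    v = 0
    nb = 0
    for c in chosen:
        v = (v << 2) | int(c)
        nb += 1
        if nb == 32:
            h = mix64(h ^ v)
            v, nb = 0, 0
    if nb:
        h = mix64(h ^ ((v << 1) | 1))
    return h


class PackedStrings:
    """All cover strings concatenated in 2-bit form, plus their endpoints.

    Attributes
    ----------
    codes : np.ndarray of uint8
        One code per base, length N (the working representation; the
        serialized form packs 4 bases per byte, i.e. exactly 2N bits).
    endpoints : np.ndarray of int64
        E[0..p] with E[0]=0 and E[j] the cumulative length of the first
        j strings.
    """

    def __init__(self, codes: np.ndarray, endpoints: np.ndarray):
        self.codes = np.ascontiguousarray(codes, dtype=np.uint8)
        self.endpoints = np.ascontiguousarray(endpoints, dtype=np.int64)
        if self.endpoints[0] != 0 or self.endpoints[-1] != len(self.codes):
            raise ValueError("endpoints must start at 0 and end at N")

    @classmethod
    def from_strings(cls, strings: Iterable[str], k: int | None = None) -> "PackedStrings":
        parts = []
        ends = [0]
        total = 0
        for idx, s in enumerate(strings):
            if k is not None and len(s) < k:
                raise ShortStringError(
                    f"string {idx} has length {len(s)} < k={k}"
                )
            try:
                parts.append(encode(s.upper()))
            except InvalidBaseError as exc:
                raise InvalidBaseError(exc.char, exc.position) from None
            total += len(s)
            ends.append(total)
        if not parts:
            raise ValueError("empty input collection")
        return cls(np.concatenate(parts), np.asarray(ends, dtype=np.int64))

    # -- basic geometry ----------------------------------------------------
    @property
    def n_bases(self) -> int:
        return len(self.codes)

    @property
    def n_strings(self) -> int:
        return len(self.endpoints) - 1

    @property
    def nbits(self) -> int:
        """Size of the 2-bit payload: exactly 2N bits."""
        return 2 * self.n_bases

    def string_of(self, t: int) -> int:
        """Index j of the string containing absolute position t."""
        if not 0 <= t < self.n_bases:
            raise IndexError(f"position {t} out of [0,{self.n_bases})")
        return int(np.searchsorted(self.endpoints, t, side="right")) - 1

    def is_valid_window(self, t: int, k: int) -> bool:
        """True iff [t, t+k) lies within a single string."""
        if t < 0 or t + k > self.n_bases:
            return False
        j = self.string_of(t)
        return t + k <= int(self.endpoints[j + 1])

    def kmer_at(self, t: int, k: int) -> str:
        """Decode the k bases at absolute offset t; alien windows error."""
        if not self.is_valid_window(t, k):
            raise AlienWindowError(
                f"window [{t},{t + k}) crosses a string boundary"
            )
        return decode(self.codes[t : t + k])

    def string(self, j: int) -> str:
        lo, hi = int(self.endpoints[j]), int(self.endpoints[j + 1])
        return decode(self.codes[lo:hi])

    def decode_all(self) -> list[str]:
        return [self.string(j) for j in range(self.n_strings)]

    # -- serialization -----------------------------------------------------
    def packed_bytes(self) -> bytes:
        """2-bit packing, 4 bases per byte, first base in the low 2 bits."""
        n = self.n_bases
        padded = np.zeros((n + 3) // 4 * 4, dtype=np.uint8)
        padded[:n] = self.codes
        quads = padded.reshape(-1, 4)
        b = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
        return b.astype(np.uint8).tobytes()

    @staticmethod
    def unpack_bytes(data: bytes, n: int) -> np.ndarray:
        b = np.frombuffer(data, dtype=np.uint8)
        out = np.empty(len(b) * 4, dtype=np.uint8)
        out[0::4] = b & 3
        out[1::4] = (b >> 2) & 3
        out[2::4] = (b >> 4) & 3
        out[3::4] = (b >> 6) & 3
        return out[:n]
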
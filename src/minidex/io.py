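"""FASTA/FASTQ reading and the binary index file format.

Sequence files are read through Biopython; gzip compression is detected
from the ``.gz`` suffix.  The index is a single self-contained file:

    magic "SSHX" | version | config (k, m, modality, ell, L, seed)
    | stats block (n, p, N, z, M, max bucket)
    | PackedStrings | Endpoints EF | minimizer MPHF | Sizes EF
    | Offsets | SkewIndex

All integers little-endian; sections 8-byte aligned; saving a loaded
index reproduces the file byte for byte.
"""

from __future__ import annotations

import gzip
import struct
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from .bits import CompactVector
from .dictionary import DictConfig, Dictionary
from .dna import PackedStrings
from .efseq import EFSequence
from .errors import IndexFormatError
from .mphf import Mphf
from .skew_index import SkewIndex

MAGIC = b"SSHX"
VERSION = 1

_FASTQ_EXT = {".fq", ".fastq"}


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt"), path.with_suffix("").suffix.lower()
    return open(path, "rt"), path.suffix.lower()


def read_sequences(path) -> Iterator[tuple[str, str]]:
    """Yield (record id, uppercased sequence) from FASTA or FASTQ (.gz ok)."""
    handle, ext = _open_text(path)
    fmt = "fastq" if ext in _FASTQ_EXT else "fasta"
    with handle:
        for rec in SeqIO.parse(handle, fmt):
            yield rec.id, str(rec.seq).upper()


def write_fasta(path, sequences, prefix: str = "seq") -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, s in enumerate(sequences):
            fh.write(f">{prefix}{i}\n{s}\n")


def _pad8(b: bytes) -> bytes:
    return b + b"\0" * (-len(b) % 8)


def save_index(d: Dictionary, path) -> None:
    cfg = d.config
    header = struct.pack(
        "<4sIIIIIIIQ",
        MAGIC, VERSION, cfg.k, cfg.m, int(cfg.canonical), cfg.ell, cfg.L,
        0,  # reserved; keeps the header 8-byte aligned
        cfg.seed,
    )
    statsblk = struct.pack("<6Q", d.n, d.p, d.N, d.z, d.M, d.max_bucket)
    ps = d.strings
    ps_blk = struct.pack("<QQ", ps.n_bases, ps.n_strings) + _pad8(ps.packed_bytes())
    sections = [
        header, statsblk, ps_blk,
        _pad8(d.endpoints_ef.to_bytes()),
        _pad8(d.minimizer_mphf.to_bytes()),
        _pad8(d.sizes.to_bytes()),
        _pad8(d.offsets.to_bytes()),
        _pad8(d.skew.to_bytes()),
    ]
    Path(path).write_bytes(b"".join(sections))


def load_index(path) -> Dictionary:
    data = Path(path).read_bytes()
    buf = memoryview(data)
    if data[:4] != MAGIC:
        raise IndexFormatError("bad magic, not an index file", offset=0)
    try:
        (_, version, k, m, canonical, ell, L, _res, seed) = struct.unpack_from(
            "<4sIIIIIIIQ", buf, 0
        )
    except struct.error as exc:
        raise IndexFormatError(f"truncated header: {exc}", offset=0) from None
    if version != VERSION:
        raise IndexFormatError(f"unsupported index version {version}", offset=4)
    off = struct.calcsize("<4sIIIIIIIQ")
    n, p, N, z, M, max_bucket = struct.unpack_from("<6Q", buf, off)
    off += 48
    try:
        nb, ns = struct.unpack_from("<QQ", buf, off)
        off += 16
        packed_len = (nb + 3) // 4
        codes = PackedStrings.unpack_bytes(bytes(buf[off : off + packed_len]), nb)
        off += packed_len + (-packed_len % 8)
        endpoints_ef, off = EFSequence.from_buffer(buf, off)
        off += -off % 8
        mphf, off = Mphf.from_buffer(buf, off)
        off += -off % 8
        sizes, off = EFSequence.from_buffer(buf, off)
        off += -off % 8
        offsets, off = CompactVector.from_buffer(buf, off)
        off += -off % 8
        skew, off = SkewIndex.from_buffer(buf, off)
    except (struct.error, ValueError) as exc:
        raise IndexFormatError(f"corrupt index: {exc}", offset=off) from None
    ps = PackedStrings(codes, endpoints_ef.to_array())
    cfg = DictConfig(k=k, m=m, canonical=bool(canonical), ell=ell, L=L, seed=seed)
    d = Dictionary(cfg, ps, endpoints_ef, mphf, sizes, offsets, skew)
    if (d.n, d.p, d.N, d.z, d.M) != (n, p, N, z, M):
        raise IndexFormatError("stats block does not match payload", offset=off)
    return d
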
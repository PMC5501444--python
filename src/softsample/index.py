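"""Fixed-sampled k'-mer index with inverted occurrence lists.

The index is a dictionary mapping each 2-bit-encodable k'-mer (over ACGT)
to the list of its *sampled* occurrences in the database.  An occurrence is
an ordered pair (sequence, end position) where the position is the 0-based
index of the k'-mer's **last** character.  With sampling step ``w``, only
occurrences ending at positions ``k'-1, k'-1+w, k'-1+2w, ...`` of each
sequence are stored; the sampling phase restarts at every sequence
boundary.  Windows containing an ambiguous base (N) are skipped entirely.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .records import SequenceRecord

_MAGIC = b"SSKI"
_VERSION = 1

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

# byte-value lookup: A/C/G/T -> 0..3, anything else (incl. N) -> 255
_BYTE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _BYTE_CODE[ord(_b)] = _c


class IndexError_(ValueError):
    """Raised for invalid index operations or corrupt index files."""


def encode_kmer(kmer: str) -> int:
    """2-bit-pack a k-mer over ACGT into an integer (A=0, C=1, G=2, T=3)."""
    code = 0
    for ch in kmer:
        try:
            code = (code << 2) | _BASE_CODE[ch]
        except KeyError:
            raise IndexError_(f"k-mer contains non-ACGT character: {ch!r}")
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_CODE_BASE[(code >> shift) & 3])
    return "".join(out)


@dataclass(frozen=True)
class Occurrence:
    """A sampled k'-mer occurrence: (sequence id, last-character position)."""

    seq_id: str
    end_pos: int


def _encode_all_kmers(residues: str, kprime: int) -> np.ndarray:
    """Codes of every k'-mer of ``residues``; -1 where the window holds an N.

    Vectorised: k' shifted adds over the 2-bit base array, with a windowed
    N-count to invalidate ambiguous windows.
    """
    vals = _BYTE_CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    n = len(vals)
    nk = n - kprime + 1
    if nk <= 0:
        return np.empty(0, dtype=np.int64)
    invalid = vals == 255
    safe = np.where(invalid, 0, vals).astype(np.int64)
    codes = np.zeros(nk, dtype=np.int64)
    for j in range(kprime):
        codes = (codes << 2) | safe[j:j + nk]
    # a window is invalid iff it contains any N
    csum = np.concatenate(([0], np.cumsum(invalid)))
    bad = (csum[kprime:] - csum[:-kprime]) > 0
    codes[bad] = -1
    return codes


@dataclass
class KmerIndex:
    """Dictionary of k'-mers with fixed-sampled occurrence lists.

    ``dictionary`` maps the 2-bit code of a k'-mer to a list of
    ``(sequence_index, end_pos)`` pairs sorted by (sequence, position).
    ``sequence_table`` records (id, length) of every indexed sequence.
    """

    kprime: int
    w: int
    sequence_table: list[tuple[str, int]] = field(default_factory=list)
    dictionary: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def lookup(self, kmer: str) -> list[Occurrence]:
        """Exact occurrence list of ``kmer`` (possibly empty).

        Raises :class:`IndexError_` if the k-mer has the wrong length or
        contains an ambiguous character.
        """
        if len(kmer) != self.kprime:
            raise IndexError_(
                f"k-mer length {len(kmer)} != index kprime {self.kprime}"
            )
        code = encode_kmer(kmer)
        return [
            Occurrence(self.sequence_table[si][0], pos)
            for si, pos in self.dictionary.get(code, [])
        ]

    def lookup_code(self, code: int) -> list[tuple[int, int]]:
        """Raw occurrence list ``(seq_index, end_pos)`` for an encoded k-mer."""
        return self.dictionary.get(code, [])

    def size(self) -> tuple[int, int]:
        """(distinct stored k'-mers, total stored occurrences)."""
        return (
            len(self.dictionary),
            sum(len(v) for v in self.dictionary.values()),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerIndex):
            return NotImplemented
        return (
            self.kprime == other.kprime
            and self.w == other.w
            and self.sequence_table == other.sequence_table
            and self.dictionary == other.dictionary
        )


def build_index(db: Sequence[SequenceRecord], kprime: int, w: int) -> KmerIndex:
    """Build a fixed-sampled k'-mer index over ``db``.

    For each sequence, k'-mers ending at positions ``k'-1, k'-1+w, ...`` are
    stored.  Sampled windows containing an N are skipped (not stored, not
    substituted).  Sequences shorter than k' contribute nothing.
    """
    if not 1 <= kprime <= 16:
        raise IndexError_("kprime must be in [1, 16] (2-bit-packable key)")
    if w < 1:
        raise IndexError_("w must be >= 1")
    if not db:
        raise IndexError_("empty database")

    index = KmerIndex(kprime=kprime, w=w)
    for si, rec in enumerate(db):
        index.sequence_table.append((rec.id, len(rec.residues)))
        codes = _encode_all_kmers(rec.residues, kprime)
        # sampled start offsets 0, w, 2w, ... (end positions k'-1 + j*w)
        sampled = codes[::w]
        for off, code in enumerate(sampled):
            if code >= 0:
                index.dictionary.setdefault(int(code), []).append(
                    (si, off * w + kprime - 1)
                )
    return index


def index_size(index: KmerIndex) -> tuple[int, int]:
    """(dictionary_entries, occurrence_count) of a built index."""
    return index.size()


def predicted_index_size(
    D: int,
    S: int,
    kprime: int,
    w: int,
    numerator: str = "printed",
) -> float:
    """Closed-form predicted size of a sampled index.

    The prediction charges a full dictionary of ``4^k'`` entries plus
    ``(D - S·(k'+1)) / w`` stored occurrences, where D is the total database
    length in bp and S the number of sequences.  The quotient is returned as
    a real number (no rounding).

    ``numerator="per_sequence_kmers"`` substitutes ``D - S·(k'-1)``, the
    exact count of k'-mers summed over the sequences, which matches a
    constructed index exactly whenever w divides each ``n_i - k' + 1``.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    if numerator == "printed":
        num = D - S * (kprime + 1)
    elif numerator == "per_sequence_kmers":
        num = D - S * (kprime - 1)
    else:
        raise ValueError(f"unknown numerator variant: {numerator!r}")
    if num < 0:
        raise ValueError(
            f"negative occurrence numerator ({num}); database too small "
            f"for this prediction"
        )
    return 4 ** kprime + num / w


# ---------------------------------------------------------------------------
# on-disk format: little-endian, magic "SSKI", version, kprime, w,
# sequence table, then per-k-mer (code, list length, delta-encoded positions)
# ---------------------------------------------------------------------------


def save_index(index: KmerIndex, path: str | Path) -> None:
    """Serialize an index; ``load_index`` restores an equal object."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<HBIQ", _VERSION, index.kprime, index.w,
                             len(index.sequence_table)))
        for sid, length in index.sequence_table:
            sid_b = sid.encode("utf-8")
            fh.write(struct.pack("<H", len(sid_b)))
            fh.write(sid_b)
            fh.write(struct.pack("<Q", length))
        fh.write(struct.pack("<Q", len(index.dictionary)))
        for code in sorted(index.dictionary):
            occs = index.dictionary[code]
            fh.write(struct.pack("<IQ", code, len(occs)))
            prev_si, prev_pos = -1, 0
            for si, pos in occs:
                delta = pos - prev_pos if si == prev_si else pos
                fh.write(struct.pack("<II", si, delta))
                prev_si, prev_pos = si, pos


def _read_exact(fh, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise IndexError_("truncated index file")
    return data


def load_index(path: str | Path) -> KmerIndex:
    """Load an index written by :func:`save_index`.

    Refuses files with a wrong magic or version; truncation raises an
    integrity error.
    """
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise IndexError_(
                f"{path}: not a softsample index (bad magic {magic!r})"
            )
        version, kprime, w, nseq = struct.unpack("<HBIQ", _read_exact(fh, 15))
        if version != _VERSION:
            raise IndexError_(
                f"{path}: unsupported index version {version} "
                f"(expected {_VERSION})"
            )
        table: list[tuple[str, int]] = []
        for _ in range(nseq):
            (slen,) = struct.unpack("<H", _read_exact(fh, 2))
            sid = _read_exact(fh, slen).decode("utf-8")
            (length,) = struct.unpack("<Q", _read_exact(fh, 8))
            table.append((sid, length))
        (ndict,) = struct.unpack("<Q", _read_exact(fh, 8))
        dictionary: dict[int, list[tuple[int, int]]] = {}
        for _ in range(ndict):
            code, nocc = struct.unpack("<IQ", _read_exact(fh, 12))
            occs: list[tuple[int, int]] = []
            prev_si, prev_pos = -1, 0
            for _ in range(nocc):
                si, delta = struct.unpack("<II", _read_exact(fh, 8))
                pos = prev_pos + delta if si == prev_si else delta
                occs.append((si, pos))
                prev_si, prev_pos = si, pos
            dictionary[code] = occs
        if fh.read(1):
            raise IndexError_(f"{path}: trailing bytes after index data")
    return KmerIndex(kprime=kprime, w=w, sequence_table=table,
                     dictionary=dictionary)


def iter_occurrences(index: KmerIndex) -> Iterator[tuple[int, int, int]]:
    """Yield (code, seq_index, end_pos) over the whole index."""
    for code, occs in index.dictionary.items():
        for si, pos in occs:
            yield code, si, pos
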
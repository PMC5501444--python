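"""Two-phase seed-and-extend search for highly similar local alignments.

Phase 1 looks up every query k'-mer in the sampled index and extends each
shared occurrence in both directions into a maximal exact match (MEM).
MEMs shorter than the threshold ``k*`` are discarded.  Phase 2 extends each
surviving MEM outward with banded unit-cost dynamic programming, allowing
mismatches and gaps, and keeps the longest alignment whose match percentage
stays at or above ``t``.

Alignment bookkeeping follows the (x, y, m) formalism: for database span x
and query span y with ``map`` aligned position pairs of which ``match`` are
identical, the alignment length is ``|A| = |x| + |y| - map``, the match
percentage ``mp = match/|A|`` and the error count ``E = |A| - match``
(mismatches plus gap characters).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from math import ceil
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .index import KmerIndex, encode_kmer
from .params import SamplingParams, compute_kstar, compute_w0, mismatch_budget
from .records import SequenceRecord

__all__ = [
    "Mem",
    "LocalAlignment",
    "compute_kstar",
    "compute_w0",
    "extract_query_kmers",
    "extend_to_mem",
    "find_mems",
    "gapped_extend",
    "dedup_alignments",
    "search_hsla",
]


@dataclass(frozen=True)
class Mem:
    """A maximal exact match between a database sequence and the query."""

    seq_id: str
    db_start: int
    q_start: int
    length: int

    @property
    def db_end(self) -> int:
        return self.db_start + self.length

    @property
    def q_end(self) -> int:
        return self.q_start + self.length

    @property
    def diagonal(self) -> int:
        return self.db_start - self.q_start


@dataclass(frozen=True)
class LocalAlignment:
    """A scored local alignment between a database sequence and a query.

    ``db_interval`` and ``q_interval`` are 0-based half-open spans (the x
    and y of the alignment); ``map_count`` is the number of aligned position
    pairs and ``match_count`` the number of identical pairs.
    """

    seq_id: str
    db_interval: tuple[int, int]
    q_interval: tuple[int, int]
    map_count: int
    match_count: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.match_count <= self.map_count):
            raise ValueError("need 0 <= match_count <= map_count")
        if self.map_count > min(self.db_span, self.q_span):
            raise ValueError("map_count exceeds interval lengths")

    @property
    def db_span(self) -> int:
        return self.db_interval[1] - self.db_interval[0]

    @property
    def q_span(self) -> int:
        return self.q_interval[1] - self.q_interval[0]

    @property
    def length(self) -> int:
        """Alignment length |A| = |x| + |y| - map."""
        return self.db_span + self.q_span - self.map_count

    @property
    def mp(self) -> Fraction:
        """Match percentage match/|A| as an exact rational."""
        return Fraction(self.match_count, self.length)

    @property
    def errors(self) -> int:
        """E(A) = |A| - match: mismatches plus gap characters."""
        return self.length - self.match_count

    def key(self) -> tuple:
        return (self.seq_id, self.db_interval, self.q_interval, self.strand)


def extract_query_kmers(q: SequenceRecord, kprime: int) -> list[tuple[str, int]]:
    """All (k-mer, end position) pairs of the query; N windows skipped.

    The query side is never sampled: every position is a potential seed.
    """
    out = []
    res = q.residues
    for end in range(kprime - 1, len(res)):
        kmer = res[end - kprime + 1:end + 1]
        if "N" not in kmer:
            out.append((kmer, end))
    return out


def extend_to_mem(
    s: SequenceRecord,
    q: SequenceRecord,
    seq_id: str,
    db_end_pos: int,
    q_end_pos: int,
    kprime: int,
) -> Mem:
    """Extend a shared k'-mer occurrence into a maximal exact match.

    The seed is given by the 0-based positions of the k'-mer's *last*
    character in the database sequence and in the query.  The k' seed
    characters must be identical; a mismatch here indicates an index/query
    inconsistency and raises ``ValueError``.
    """
    sres, qres = s.residues, q.residues
    i0, j0 = db_end_pos - kprime + 1, q_end_pos - kprime + 1
    if sres[i0:db_end_pos + 1] != qres[j0:q_end_pos + 1]:
        raise ValueError("seed characters differ between database and query")
    i, j = i0, j0
    while i > 0 and j > 0 and sres[i - 1] == qres[j - 1] \
            and sres[i - 1] != "N":
        i -= 1
        j -= 1
    a, b = db_end_pos + 1, q_end_pos + 1
    n, m = len(sres), len(qres)
    while a < n and b < m and sres[a] == qres[b] and sres[a] != "N":
        a += 1
        b += 1
    return Mem(seq_id=seq_id, db_start=i, q_start=j, length=a - i)


def find_mems(
    index: KmerIndex,
    db: Sequence[SequenceRecord],
    q: SequenceRecord,
    kstar: int,
) -> list[Mem]:
    """All MEMs of length >= k* seeded by sampled k'-mer hits.

    Every (query k'-mer x stored occurrence) pair is extended; MEMs are
    de-duplicated (two seeds inside one MEM yield it once) and returned
    sorted by (seq_id, db_start, q_start).
    """
    kprime = index.kprime
    found: dict[tuple, Mem] = {}
    # per (seq index, diagonal): intervals of already-extended MEMs, used to
    # skip seeds that fall inside a known MEM
    covered: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for kmer, q_end in extract_query_kmers(q, kprime):
        code = encode_kmer(kmer)
        for si, db_end in index.lookup_code(code):
            diag = (db_end - kprime + 1) - (q_end - kprime + 1)
            spans = covered.get((si, diag))
            if spans is not None:
                db_start0 = db_end - kprime + 1
                if any(a <= db_start0 and db_end < b for a, b in spans):
                    continue
            mem = extend_to_mem(db[si], q, db[si].id, db_end, q_end, kprime)
            covered.setdefault((si, diag), []).append((mem.db_start, mem.db_end))
            if mem.length >= kstar:
                found[(si, mem.db_start, mem.q_start, mem.length)] = mem
    order = {rec.id: i for i, rec in enumerate(db)}
    return sorted(
        found.values(),
        key=lambda m: (order[m.seq_id], m.db_start, m.q_start),
    )


_N_BYTE = ord("N")


@njit(nogil=True)
def _extension_kernel(
    sext: np.ndarray,
    qext: np.ndarray,
    emax: int,
    band: int,
    lmax: int,
) -> np.ndarray:  # pragma: no cover - exercised through gapped_extend
    """Banded unit-cost DP for one-sided extensions (see _half_extensions)."""
    LS = min(len(sext), lmax)
    LQ = min(len(qext), lmax)
    width = 2 * band + 1
    NEG = np.int32(-1)
    # C[e, i, col]: max matches aligning sext[:i] with qext[:j] using exactly
    # e errors, col = j - i + band; D: same but the last step is an aligned
    # pair (match or mismatch), so the extension does not end in a gap
    C = np.full((emax + 1, LS + 1, width), NEG, dtype=np.int32)
    D = np.full((emax + 1, LS + 1, width), NEG, dtype=np.int32)
    for e in range(emax + 1):
        for i in range(LS + 1):
            lo = band - i
            if lo < 0:
                lo = 0
            hi = LQ - i + band
            if hi > width - 1:
                hi = width - 1
            for col in range(lo, hi + 1):
                j = i + col - band
                best = NEG
                bestd = NEG
                if i > 0 and j > 0:
                    sc = sext[i - 1]
                    qc = qext[j - 1]
                    if sc == qc and sc != _N_BYTE:
                        prev = C[e, i - 1, col]
                        if prev >= 0:
                            bestd = prev + 1
                    elif e > 0:
                        prev = C[e - 1, i - 1, col]
                        if prev >= 0:
                            bestd = prev
                    best = bestd
                if e > 0:
                    # gaps may start anywhere inside a half extension: the
                    # anchor MEM supplies the aligned pair they must follow
                    if i > 0 and col + 1 < width:
                        p = C[e - 1, i - 1, col + 1]  # delete db character
                        if p > best:
                            best = p
                    if j > 0 and col - 1 >= 0:
                        p = C[e - 1, i, col - 1]  # insert query character
                        if p > best:
                            best = p
                if e == 0 and i == 0 and j == 0 and best < 0:
                    best = 0  # empty extension
                C[e, i, col] = best
                D[e, i, col] = bestd
    # best aligned-pair-ended extension per exact error count:
    # max match, then max consumed characters (fewest gaps), then min i
    out = np.full((emax + 1, 3), -1, dtype=np.int64)
    for e in range(emax + 1):
        bm = -1
        bs = -1
        bi = -1
        for i in range(LS + 1):
            for col in range(width):
                v = D[e, i, col]
                if v >= 0:
                    j = i + col - band
                    if (v > bm or (v == bm and i + j > bs)
                            or (v == bm and i + j == bs and i < bi)):
                        bm = v
                        bs = i + j
                        bi = i
                        out[e, 0] = v
                        out[e, 1] = i
                        out[e, 2] = j
        if e == 0 and bm < 0:
            out[0, 0] = 0
            out[0, 1] = 0
            out[0, 2] = 0
    return out


def _half_extensions(
    sext: str,
    qext: str,
    emax: int,
    band: int,
    lmax: int,
) -> list[Optional[tuple[int, int, int]]]:
    """Best one-sided extensions of an anchor into (sext, qext).

    Aligns prefixes of ``sext`` (database side) against prefixes of ``qext``
    (query side) with unit-cost mismatches and gaps, within diagonal ``band``
    and at most ``emax`` errors, consuming at most ``lmax`` characters per
    side.  An extension never ends in a gap (the anchor supplies the aligned
    pair on its inner side), so terminal gap padding cannot inflate the
    alignment length.  Returns, for each exact error count e,
    the tuple ``(match, i, j)`` maximizing the match count (ties: more
    consumed characters, then smaller i), or None.

    For an extension consuming (i, j) characters with m matches and e
    errors, the contributed alignment length is exactly ``m + e`` and the
    contributed map count is ``i + j - m - e``.
    """
    s = np.frombuffer(sext.encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(qext.encode("ascii"), dtype=np.uint8)
    out = _extension_kernel(s, q, emax, band, lmax)
    result: list[Optional[tuple[int, int, int]]] = []
    for e in range(emax + 1):
        if out[e, 0] < 0:
            result.append(None)
        else:
            result.append((int(out[e, 0]), int(out[e, 1]), int(out[e, 2])))
    return result


def gapped_extend(
    s: SequenceRecord,
    q: SequenceRecord,
    mem: Mem,
    l: int,
    t: float | Fraction,
    band: int | None = None,
    kstar: int | None = None,
) -> Optional[LocalAlignment]:
    """Extend a MEM into the best containing alignment with mp >= t.

    Banded unit-cost dynamic programming runs outward from both MEM ends.
    Among all alignments containing the MEM whose match percentage is at
    least ``t``, the one maximizing (|A|, then mp) is returned.  If its
    length reaches ``l`` it is a true HSLA; otherwise the best candidate of
    length >= k* (a potential false positive) is returned; the MEM itself
    is always such a candidate when ``mem.length >= k*``.
    """
    tfrac = Fraction(t)
    if band is None:
        band = ceil((1 - tfrac) * l) + 2
    if band < 0:
        raise ValueError("band must be >= 0")
    if kstar is None:
        kstar = compute_kstar(l, t)
    emax = max(band, mismatch_budget(l, tfrac))
    lmax = l + band

    sres, qres = s.residues, q.residues
    left = _half_extensions(
        sres[:mem.db_start][::-1], qres[:mem.q_start][::-1], emax, band, lmax
    )
    right = _half_extensions(
        sres[mem.db_end:], qres[mem.q_end:], emax, band, lmax
    )

    best = None
    best_key = None
    for eL, optL in enumerate(left):
        if optL is None:
            continue
        mL, iL, jL = optL
        for eR, optR in enumerate(right):
            if optR is None:
                continue
            mR, iR, jR = optR
            match = mem.length + mL + mR
            length = mem.length + (mL + eL) + (mR + eR)
            if match < tfrac * length:
                continue
            # ties on (|A|, mp) break toward the alignment with the larger
            # map count, i.e. substitutions preferred over gap pairs
            map_c = mem.length + (iL + jL - mL - eL) + (iR + jR - mR - eR)
            key = (length, Fraction(match, length), map_c)
            if best_key is None or key > best_key:
                best_key = key
                best = (match, length, eL, mL, iL, jL, eR, mR, iR, jR)
    if best is None:
        return None
    match, length, eL, mL, iL, jL, eR, mR, iR, jR = best
    if length < kstar:
        return None
    # map of a half extension consuming (i, j) characters with m matches and
    # e errors is i + j - m - e, which keeps |A| = |x| + |y| - map exact
    map_count = mem.length \
        + (iL + jL - mL - eL) \
        + (iR + jR - mR - eR)
    return LocalAlignment(
        seq_id=mem.seq_id,
        db_interval=(mem.db_start - iL, mem.db_end + iR),
        q_interval=(mem.q_start - jL, mem.q_end + jR),
        map_count=map_count,
        match_count=match,
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _highly_overlapping(a: LocalAlignment, b: LocalAlignment) -> bool:
    """Spans overlap by >= 50% of the shorter span on both sequences."""
    if a.seq_id != b.seq_id or a.strand != b.strand:
        return False
    for ia, ib, span_a, span_b in (
        (a.db_interval, b.db_interval, a.db_span, b.db_span),
        (a.q_interval, b.q_interval, a.q_span, b.q_span),
    ):
        shorter = min(span_a, span_b)
        if shorter <= 0 or 2 * _overlap(ia, ib) < shorter:
            return False
    return True


def dedup_alignments(alignments: Sequence[LocalAlignment]) -> list[LocalAlignment]:
    """Keep one survivor per group of highly overlapping alignments.

    Groups are the transitive closure of pairwise >= 50% mutual overlap
    (of the shorter span, on both the database and the query side).  The
    survivor is the longest |A|; ties break by higher mp, then smaller
    db_start, then smaller q_start.
    """
    n = len(alignments)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _highly_overlapping(alignments[i], alignments[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[LocalAlignment]] = {}
    for i, a in enumerate(alignments):
        groups.setdefault(find(i), []).append(a)

    survivors = []
    for members in groups.values():
        members.sort(
            key=lambda a: (-a.length, -a.mp, a.db_interval[0], a.q_interval[0])
        )
        survivors.append(members[0])
    survivors.sort(
        key=lambda a: (a.seq_id, a.db_interval[0], a.q_interval[0])
    )
    return survivors


def search_hsla(
    index: KmerIndex,
    db: Sequence[SequenceRecord],
    q: SequenceRecord,
    params: SamplingParams,
    both_strands: bool = False,
) -> tuple[list[LocalAlignment], int]:
    """Full seed-and-extend search of one query against the indexed database.

    Returns the de-duplicated alignments with |A| >= l and mp >= t, plus the
    count of de-duplicated false positives: alignments that pass the k*
    seeding stage (|A| >= k*, mp >= t) but cannot be extended to length l.
    """
    if index.kprime != params.kprime or index.w != params.w:
        raise ValueError(
            f"index built with (kprime={index.kprime}, w={index.w}) but "
            f"params say (kprime={params.kprime}, w={params.w})"
        )
    by_id = {rec.id: rec for rec in db}

    queries = [(q, "+")]
    if both_strands:
        queries.append((q.reverse_complement(), "-"))

    hslas: list[LocalAlignment] = []
    fps: list[LocalAlignment] = []
    for query, strand in queries:
        seen: set[tuple] = set()
        accepted: dict[str, list[LocalAlignment]] = {}
        for mem in find_mems(index, db, query, params.kstar):
            # a MEM wholly inside an already-extended alignment re-derives
            # that alignment; skip the extension
            if any(
                a.db_interval[0] <= mem.db_start
                and mem.db_end <= a.db_interval[1]
                and a.q_interval[0] <= mem.q_start
                and mem.q_end <= a.q_interval[1]
                for a in accepted.get(mem.seq_id, ())
            ):
                continue
            aln = gapped_extend(
                by_id[mem.seq_id], query, mem, params.l, params.t,
                kstar=params.kstar,
            )
            if aln is None:
                continue
            accepted.setdefault(aln.seq_id, []).append(aln)
            if strand == "-":
                aln = replace(aln, strand="-")
            if aln.key() in seen:
                continue
            seen.add(aln.key())
            if aln.length >= params.l:
                hslas.append(aln)
            else:
                fps.append(aln)
    return dedup_alignments(hslas), len(dedup_alignments(fps))
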
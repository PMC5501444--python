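"""Evaluation metrics for sampled-index searches, plus brute-force oracles.

All set-valued metrics identify an alignment by exact coordinates
(sequence id, database interval, query interval): the synthetic planted
truths are non-overlapping, so fuzzier matching is unnecessary.  Per-query
ratios whose denominator is zero are *undefined* and never enter an
average; a metric with no defined query at all is reported as ``None``.
"""

from __future__ import annotations

import time
from fractions import Fraction
from statistics import median
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .index import KmerIndex
from .records import SequenceRecord
from .search import LocalAlignment, Mem, dedup_alignments

__all__ = [
    "alignment_key",
    "retention_rate",
    "retention_rate_short",
    "false_positive_reduction",
    "size_reduction",
    "mapping_retention",
    "brute_force_mems",
    "brute_force_hslas",
    "median_query_time",
]

AlignmentSets = Mapping[str, Iterable[LocalAlignment]]


def alignment_key(a: LocalAlignment) -> tuple:
    return a.key()


def _keyset(alignments: Iterable[LocalAlignment]) -> set[tuple]:
    return {alignment_key(a) for a in alignments}


def retention_rate(found: AlignmentSets, baseline: AlignmentSets) -> Optional[float]:
    """Mean per-query percentage of baseline alignments still found.

    ``found`` and ``baseline`` map query ids to alignment collections (the
    search output at step w and at the hard-sampling baseline w0).  Queries
    with an empty baseline are excluded; returns ``None`` if no query has a
    non-empty baseline.
    """
    ratios = []
    for qid, base in baseline.items():
        base_keys = _keyset(base)
        if not base_keys:
            continue
        found_keys = _keyset(found.get(qid, ()))
        ratios.append(len(found_keys & base_keys) / len(base_keys))
    if not ratios:
        return None
    return 100.0 * sum(ratios) / len(ratios)


def _filter_short(
    sets: AlignmentSets, l: int, t: float | Fraction
) -> dict[str, list[LocalAlignment]]:
    upper = (2 - Fraction(t)) * l
    return {
        qid: [a for a in alns if l <= a.length <= upper]
        for qid, alns in sets.items()
    }


def retention_rate_short(
    found: AlignmentSets,
    baseline: AlignmentSets,
    l: int,
    t: float | Fraction,
) -> Optional[float]:
    """Retention rate restricted to short HSLAs, ``l <= |A| <= (2-t)·l``.

    Short HSLAs are the hardest true matches to retain and are the set the
    analytical models predict.
    """
    return retention_rate(
        _filter_short(found, l, t), _filter_short(baseline, l, t)
    )


def false_positive_reduction(
    fp_w: Mapping[str, int], fp_w0: Mapping[str, int]
) -> Optional[float]:
    """Mean per-query ratio FP(q, w) / FP(q, w0); zero-baseline queries excluded."""
    ratios = [
        fp_w.get(qid, 0) / n0 for qid, n0 in fp_w0.items() if n0 > 0
    ]
    if not ratios:
        return None
    return sum(ratios) / len(ratios)


def size_reduction(
    index_w: KmerIndex | Sequence[KmerIndex],
    index_w0: KmerIndex | Sequence[KmerIndex],
) -> float:
    """Index size ratio |SI(w)| / |SI(w0)|.

    Index size is dictionary entries plus total occurrences.  A multi-volume
    database may be given as a sequence of indexes: dictionaries are
    unioned, occurrence counts summed.
    """

    def totals(ix: KmerIndex | Sequence[KmerIndex]) -> tuple[int, int, int]:
        if isinstance(ix, KmerIndex):
            ix = [ix]
        kprimes = {i.kprime for i in ix}
        if len(kprimes) != 1:
            raise ValueError("all volumes must share one kprime")
        dict_union: set[int] = set()
        occ = 0
        for i in ix:
            dict_union |= i.dictionary.keys()
            occ += sum(len(v) for v in i.dictionary.values())
        return len(dict_union), occ, kprimes.pop()

    dw, ow, kw = totals(index_w)
    d0, o0, k0 = totals(index_w0)
    if kw != k0:
        raise ValueError(f"kprime mismatch between indexes: {kw} != {k0}")
    return (dw + ow) / (d0 + o0)


def mapping_retention(
    truth: AlignmentSets, found: AlignmentSets
) -> Optional[float]:
    """Percentage of mappable queries whose *entire* HSLA set is found.

    A query is mappable if its truth set is non-empty; it is retained only
    if the found set equals the truth set exactly — losing a single HSLA
    loses the query (the mapping result can no longer be guaranteed).
    """
    mappable = {qid: _keyset(t) for qid, t in truth.items() if _keyset(t)}
    if not mappable:
        return None
    kept = sum(
        1 for qid, tk in mappable.items()
        if _keyset(found.get(qid, ())) == tk
    )
    return 100.0 * kept / len(mappable)


# ---------------------------------------------------------------------------
# brute-force oracles (testing only; quadratic or worse)
# ---------------------------------------------------------------------------


def brute_force_mems(
    s: SequenceRecord,
    q: SequenceRecord,
    min_length: int = 1,
    cap: int = 10 ** 7,
) -> list[Mem]:
    """All maximal exact matches of length >= min_length, by diagonal scan."""
    sres, qres = s.residues, q.residues
    n, m = len(sres), len(qres)
    if n * m > cap:
        raise ValueError(f"|s|*|q| = {n * m} exceeds oracle cap {cap}")
    out = []
    for diag in range(-(m - 1), n):
        i = max(0, diag)
        j = i - diag
        run = 0
        while i <= n and j <= m:
            at_end = i == n or j == m
            matches = (not at_end and sres[i] == qres[j] and sres[i] != "N")
            if matches:
                run += 1
            else:
                if run >= min_length:
                    out.append(Mem(s.id, i - run, j - run, run))
                run = 0
            if at_end:
                break
            i += 1
            j += 1
    out.sort(key=lambda mm: (mm.db_start, mm.q_start))
    return out


def brute_force_hslas(
    s: SequenceRecord,
    q: SequenceRecord,
    l: int,
    t: float | Fraction,
    max_len: int = 60,
    emax: int | None = None,
) -> list[LocalAlignment]:
    """All de-dup-surviving alignments with |A| >= l and mp >= t.

    Exhaustive unbanded local-alignment dynamic programming over every
    cell and error count: completely independent of the seed-and-extend
    path (no index, no k* seeding, no band).  The same alignment conventions
    apply: gaps only between aligned pairs, never terminal.  Limited to
    sequences of at most ``max_len`` bp.
    """
    sres, qres = s.residues, q.residues
    n, m = len(sres), len(qres)
    if n > max_len or m > max_len:
        raise ValueError(f"oracle limited to sequences of <= {max_len} bp")
    tfrac = Fraction(t)
    if emax is None:
        emax = int((1 - tfrac) * (n + m)) + 1

    # L[i][j][e] = max matches over alignments ending at (i, j) with exactly
    # e errors (mismatches + gap characters); alignments may start anywhere.
    L = [[[-1] * (emax + 1) for _ in range(m + 1)] for _ in range(n + 1)]
    for i in range(n + 1):
        for j in range(m + 1):
            cell = L[i][j]
            cell[0] = max(cell[0], 0)  # empty alignment starting here
            for e in range(emax + 1):
                v = cell[e]
                if i > 0 and j > 0:
                    prev = L[i - 1][j - 1]
                    if sres[i - 1] == qres[j - 1] and sres[i - 1] != "N":
                        if prev[e] >= 0 and prev[e] + 1 > v:
                            v = prev[e] + 1
                    elif e > 0 and prev[e - 1] > v:
                        v = prev[e - 1]
                # gap characters only after the first aligned pair; any
                # non-empty state (v >= 1 or e >= 1) starts with one
                if e > 0 and i > 0:
                    p = L[i - 1][j][e - 1]
                    if p > v and (p >= 1 or e - 1 >= 1):
                        v = p
                if e > 0 and j > 0:
                    p = L[i][j - 1][e - 1]
                    if p > v and (p >= 1 or e - 1 >= 1):
                        v = p
                cell[e] = v

    def traceback(i: int, j: int, e: int) -> tuple[int, int]:
        """Start cell (a, c) of one optimal alignment ending at (i, j, e)."""
        v = L[i][j][e]
        while v > 0 or e > 0:
            if i > 0 and j > 0:
                prev = L[i - 1][j - 1]
                if sres[i - 1] == qres[j - 1] and sres[i - 1] != "N":
                    if v > 0 and prev[e] == v - 1:
                        i, j, v = i - 1, j - 1, v - 1
                        continue
                elif e > 0 and prev[e - 1] == v:
                    i, j, e = i - 1, j - 1, e - 1
                    continue
            if e > 0 and i > 0 and (v >= 1 or e - 1 >= 1) \
                    and L[i - 1][j][e - 1] == v:
                i, e = i - 1, e - 1
                continue
            if e > 0 and j > 0 and (v >= 1 or e - 1 >= 1) \
                    and L[i][j - 1][e - 1] == v:
                j, e = j - 1, e - 1
                continue
            raise AssertionError("traceback failed")  # pragma: no cover
        return i, j

    def ends_on_aligned_pair(i: int, j: int, e: int, match: int) -> bool:
        if i == 0 or j == 0:
            return False
        prev = L[i - 1][j - 1]
        if sres[i - 1] == qres[j - 1] and sres[i - 1] != "N":
            return match >= 1 and prev[e] == match - 1
        return e > 0 and prev[e - 1] == match

    candidates = []
    for i in range(n + 1):
        for j in range(m + 1):
            for e in range(emax + 1):
                match = L[i][j][e]
                if match < 0:
                    continue
                length = match + e
                if length < l or match < tfrac * length:
                    continue
                if not ends_on_aligned_pair(i, j, e, match):
                    continue
                a, c = traceback(i, j, e)
                map_count = (i - a) + (j - c) - length
                candidates.append(
                    LocalAlignment(
                        seq_id=s.id,
                        db_interval=(a, i),
                        q_interval=(c, j),
                        map_count=map_count,
                        match_count=match,
                    )
                )
    return dedup_alignments(candidates)


def median_query_time(
    run: Callable[[], object], repeats: int = 5
) -> float:
    """Median-of-``repeats`` wall-clock time of ``run`` in seconds.

    Supports the query-time-reduction protocol; wall-clock results are
    hardware-dependent and are not part of any automated check.
    """
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        run()
        times.append(time.perf_counter() - t0)
    return median(times)
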
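"""Synthetic genomes, planted alignments, and MAX-MEM distributions.

The generator emulates the study conditions the search and the analytical
models are evaluated under: i.i.d. random genomes, queries that are copies
of genome windows carrying exactly m substitutions (and optionally
single-base indels), and ensembles of uniformly placed mismatch sets whose
longest mismatch-free run — the MAX-MEM, the longest maximal exact match
inside the alignment — is tabulated either by exhaustive enumeration of
all C(l, m) placements or by Monte-Carlo simulation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional

import numpy as np

from .params import SamplingParams
from .records import SequenceRecord
from .search import LocalAlignment

__all__ = [
    "PlantedInstance",
    "MaxMemDistribution",
    "generate_genome",
    "plant_alignment",
    "plant_suite",
    "place_mismatches",
    "max_mem_length",
    "maxmem_enumerate",
    "maxmem_montecarlo",
]

_BASES = "ACGT"
_ALTERNATIVES = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass
class PlantedInstance:
    """A genome/query pair with known ground-truth alignments."""

    genome: SequenceRecord
    query: SequenceRecord
    truth: list[LocalAlignment]
    seed: Optional[int] = None
    params: Optional[SamplingParams] = None


@dataclass
class MaxMemDistribution:
    """Histogram of MAX-MEM lengths over an ensemble of mismatch placements."""

    histogram: dict[int, int]
    total: int
    mode: str  # "enumeration" | "montecarlo"
    l: int
    m: int

    def __post_init__(self) -> None:
        if sum(self.histogram.values()) != self.total:
            raise ValueError("histogram counts do not sum to total")

    def probabilities(self) -> dict[int, float]:
        return {k: v / self.total for k, v in sorted(self.histogram.items())}

    def tv_distance(self, other: "MaxMemDistribution") -> float:
        """Total-variation distance between the two length distributions."""
        p, q = self.probabilities(), other.probabilities()
        keys = set(p) | set(q)
        return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


def generate_genome(
    length: int,
    gc: float = 0.5,
    seed: int | np.random.Generator | None = None,
    seq_id: str = "genome",
) -> SequenceRecord:
    """An i.i.d. random genome with P(G) = P(C) = gc/2.

    Reproducible for a given integer seed (numpy PCG64 generator).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]  # A C G T
    bases = rng.choice(list(_BASES), size=length, p=probs)
    return SequenceRecord(seq_id, "".join(bases))


def place_mismatches(l: int, m: int, rng: random.Random) -> set[int]:
    """A uniform m-subset of {0, ..., l-1} drawn by rejection.

    Positions are drawn uniformly with replacement and duplicates are
    rejected until m distinct positions accumulate.
    """
    if not 0 <= m <= l:
        raise ValueError("need 0 <= m <= l")
    S: set[int] = set()
    while len(S) < m:
        p = rng.randrange(l)
        if p not in S:
            S.add(p)
    return S


def max_mem_length(l: int, mismatches: set[int]) -> int:
    """Longest run of mismatch-free positions in an alignment of length l.

    Alignment boundaries terminate runs, so an empty mismatch set gives l.
    """
    longest = 0
    prev = -1
    for pos in sorted(mismatches):
        if not 0 <= pos < l:
            raise ValueError(f"mismatch position {pos} outside [0, {l})")
        longest = max(longest, pos - prev - 1)
        prev = pos
    return max(longest, l - prev - 1)


def maxmem_enumerate(l: int, m: int, cap: int = 10 ** 8) -> MaxMemDistribution:
    """Exact MAX-MEM distribution over all C(l, m) mismatch placements."""
    total = comb(l, m)
    if total > cap:
        raise ValueError(
            f"C({l}, {m}) = {total} exceeds the enumeration cap {cap}; "
            f"use maxmem_montecarlo instead"
        )
    hist: dict[int, int] = {}
    for positions in combinations(range(l), m):
        length = max_mem_length(l, set(positions))
        hist[length] = hist.get(length, 0) + 1
    return MaxMemDistribution(hist, total, "enumeration", l, m)


def maxmem_montecarlo(
    l: int,
    m: int,
    reps: int = 10 ** 6,
    seed: int | None = None,
) -> MaxMemDistribution:
    """Monte-Carlo MAX-MEM distribution from ``reps`` independent placements."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = random.Random(seed)
    hist: dict[int, int] = {}
    for _ in range(reps):
        length = max_mem_length(l, place_mismatches(l, m, rng))
        hist[length] = hist.get(length, 0) + 1
    return MaxMemDistribution(hist, reps, "montecarlo", l, m)


def _mutate_window(
    window: str,
    m: int,
    indels: int,
    rng: random.Random,
) -> tuple[str, int, int, int, int]:
    """Apply m substitutions and ``indels`` single-base edits to ``window``.

    Returns (query_string, map_count, match_count, n_insertions,
    n_deletions).  Substitution positions are uniform and distinct;
    substituted bases are drawn from the 3 alternatives so a planted
    mismatch can never silently match.  Indel positions are interior and
    distinct from substitution positions.
    """
    l = len(window)
    subs = place_mismatches(l, m, rng)
    available = [p for p in range(1, l - 1) if p not in subs]
    if indels > len(available):
        raise ValueError("too many indels for this window length")
    indel_pos = set(rng.sample(available, indels)) if indels else set()

    out: list[str] = []
    n_ins = n_del = 0
    for pos, base in enumerate(window):
        if pos in subs:
            out.append(rng.choice(_ALTERNATIVES[base]))
        elif pos in indel_pos:
            if rng.random() < 0.5:
                out.append(rng.choice(_BASES))  # insertion before this base
                out.append(base)
                n_ins += 1
            else:
                n_del += 1  # deletion: drop this base
        else:
            out.append(base)
    map_count = l - n_del
    match_count = l - n_del - m
    return "".join(out), map_count, match_count, n_ins, n_del


def plant_alignment(
    genome: SequenceRecord,
    l: int,
    m: int,
    indels: int = 0,
    seed: int | random.Random | None = None,
    params: Optional[SamplingParams] = None,
    query_id: str = "query",
    window_start: Optional[int] = None,
    isolate: bool = True,
) -> PlantedInstance:
    """Copy a genome window into a query with exactly m substitutions.

    The query is a contiguous (EST-like) copy of a uniformly chosen
    length-l genome window with m substitutions at uniform distinct
    positions and ``indels`` single-base insertions/deletions at interior
    positions.  The exact ground-truth alignment — coordinates, map and
    match counts — is recorded; with substitutions only it has |A| = l and
    mp = (l - m)/l.

    With ``isolate=True`` (default) the genome bases flanking the window
    are re-drawn to differ from the query's edge bases, so the planted
    alignment cannot be extended past the window boundary and the recorded
    truth is exactly the optimal alignment.  The (possibly modified) genome
    is the one carried by the returned instance.
    """
    if l > len(genome.residues):
        raise ValueError("window longer than genome")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    g = window_start if window_start is not None \
        else rng.randrange(len(genome.residues) - l + 1)
    window = genome.residues[g:g + l]
    qstr, map_count, match_count, n_ins, n_del = _mutate_window(
        window, m, indels, rng
    )
    if isolate:
        res = genome.residues
        if g > 0 and res[g - 1] == qstr[0]:
            res = res[:g - 1] + rng.choice(_ALTERNATIVES[qstr[0]]) + res[g:]
        if g + l < len(res) and res[g + l] == qstr[-1]:
            res = (res[:g + l] + rng.choice(_ALTERNATIVES[qstr[-1]])
                   + res[g + l + 1:])
        genome = SequenceRecord(genome.id, res)
    truth = LocalAlignment(
        seq_id=genome.id,
        db_interval=(g, g + l),
        q_interval=(0, len(qstr)),
        map_count=map_count,
        match_count=match_count,
    )
    return PlantedInstance(
        genome=genome,
        query=SequenceRecord(query_id, qstr),
        truth=[truth],
        seed=seed if isinstance(seed, int) else None,
        params=params,
    )


def plant_suite(
    n_queries: int,
    l: int,
    m: int,
    indels: int = 0,
    gc: float = 0.5,
    seed: int | None = None,
    params: Optional[SamplingParams] = None,
) -> tuple[SequenceRecord, list[PlantedInstance]]:
    """A shared genome with ``n_queries`` planted, well-separated alignments.

    Windows are placed in disjoint slots with at least l bp separation, so
    every ground-truth alignment is unambiguous under the overlap de-dup
    rule.  Returns the final genome (flank isolation may adjust single
    bases next to each window) and one :class:`PlantedInstance` per query;
    all instances share the returned genome.
    """
    rng = random.Random(seed)
    slot = 3 * l  # window + jitter range l + >= l separation
    genome = generate_genome(
        n_queries * slot + l, gc=gc,
        seed=np.random.default_rng(rng.randrange(2 ** 31)),
    )
    instances: list[PlantedInstance] = []
    for i in range(n_queries):
        start = i * slot + rng.randrange(l + 1)
        inst = plant_alignment(
            genome, l, m, indels=indels, seed=rng,
            params=params, query_id=f"query_{i}", window_start=start,
        )
        genome = inst.genome
        instances.append(inst)
    for inst in instances:
        inst.genome = genome
    return genome, instances
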
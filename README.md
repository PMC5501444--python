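# softsample

Soft fixed sampling of k′-mer indexes for finding highly similar local
alignments (HSLAs) in nucleotide databases.

## The problem

Seed-and-extend search tools keep a *k′-mer index*: for every word of k′
consecutive bases in the database, an inverted list of its occurrence
positions.  For genome-scale databases these lists dominate memory, so
indexes are *sampled* — only occurrences ending at every w-th position are
stored.  When the goal is to find every local alignment A with length
|A| ≥ l and match percentage mp(A) = match(A)/|A| ≥ t, a true alignment is
guaranteed to contain a maximal exact match (MEM) of length at least

    k* = ⌊ l / (1 + ⌊(1−t)·l⌋) ⌋,

so any step w ≤ w₀ = k* − k′ + 1 (*hard sampling*) still seeds every true
alignment and loses nothing.  *Soft sampling* deliberately chooses w > w₀:
the index shrinks by roughly a factor w and queries run faster, at the risk
of skipping over the seed of an occasional alignment.  This package
implements the sampled index, the two-phase search (shared k′-mer →
MEM ≥ k* → banded gapped extension), and the analytics that predict what
soft sampling costs:

* **Kent's retention model** — E[RR_K] = 1 − (1 − t^k*)^T with
  T = ⌊(|x|−k*+1)/w⌋, which treats the sampled word as the full k*-mer;
* a **BLAST-style retention model** — E[RR_B] = 1 − p(T_f)(1−p′)^{T_f} −
  p(T_c)(1−p′)^{T_c}, which seeds with a k′-mer that must extend to a MEM
  of length k* (success probability p′) and replaces the floor window count
  by the exact mixture over sampling phases T_f = ⌊(|x|−k*+1)/w⌋,
  T_c = ⌈(|x|−k*+1)/w⌉;
* the **index-size prediction** 4^k′ + (D − S(k′+1))/w;
* the **MAX-MEM distribution** (longest MEM inside an alignment with m
  uniformly placed mismatches), by exhaustive enumeration over C(l, m)
  placements or Monte-Carlo simulation;
* the **binomial exceedance** P(Bin(l, 1−t) > ⌊(1−t)l⌋), which quantifies a
  known weakness of the independent-positions assumption behind both models.

Evaluation metrics (retention rate RR, short-HSLA retention RR_short,
false-positive reduction FPR, index size ratio SIR, and the all-or-nothing
mapping retention RR_map used for EST-style mapping) compare a soft-sampled
run against its hard-sampled baseline.  A synthetic-data module generates
genomes and queries with planted ground-truth alignments so every claim is
testable end to end without external data.

## Worked example

```sh
softsample simulate --n-queries 20 --l 50 --t 96 --seed 1 \
    --genome-out g.fa --query-out q.fa --truth-out truth.tsv
softsample index g.fa -o g.idx -w 5          # w0 = 16 - 12 + 1 = 5
softsample search --index g.idx --db g.fa --query q.fa \
    --min-length 50 --perc-identity 96 -o found.tsv
head -4 found.tsv
```

```
# softsample v0.1.0 l=50 t=0.96 kprime=12 kstar=16 w=5 band=None both_strands=False false_positives=0
query_id  subject_id  q_start  q_end  s_start  s_end  length  match  mp     E  strand
query_0   genome      1        50     37       86     50      48     96.00  2  +
query_1   genome      1        50     182      231    50      48     96.00  2  +
```

Each planted query carries exactly ⌊(1−0.96)·50⌋ = 2 substitutions, so the
search reports one alignment per query with |A| = 50, 48 matches and
mp = 96.00% — exactly at the acceptance threshold — and E = 2 errors.
Coordinates are 1-based inclusive in the TSV.

The analytical models, tabulated over sampling steps:

```sh
softsample predict --l 100 --t 97 --w 14 --w 22 --w 45 --w 64
```

```
l    t       kprime  kstar  w   w0  E_RR_K  E_RR_B  P_exceed
100  0.9700  12      25     14  14  0.9570  0.9953  0.3528
100  0.9700  12      25     22  14  0.8486  0.9654  0.3528
100  0.9700  12      25     45  14  0.4670  0.7947  0.3528
100  0.9700  12      25     64  14  0.4670  0.6785  0.3528
```

Kent's model predicts 46.70% retention at both w = 45 and w = 64 (the floor
in T makes it piecewise constant), while the BLAST model separates the two
steps and predicts higher retention throughout.

The same machinery is available as a library:

```python
from softsample import (SamplingParams, build_index, plant_suite,
                        search_hsla)

genome, instances = plant_suite(20, l=50, m=2, seed=1)
params = SamplingParams(l=50, t=0.96)          # k*=16, w defaults to w0=5
index = build_index([genome], params.kprime, params.w)
hslas, n_false_positives = search_hsla(index, [genome],
                                       instances[0].query, params)
```

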
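"""Tab-separated alignment tables.

One alignment per row: query id, subject id, 1-based inclusive query and
subject coordinates, alignment length |A|, match count, match percentage
(two decimals), error count E and strand.  Comment lines starting with
``#`` carry provenance (version and parameters) and are skipped on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, TextIO

from .search import LocalAlignment

COLUMNS = [
    "query_id", "subject_id", "q_start", "q_end", "s_start", "s_end",
    "length", "match", "mp", "E", "strand",
]


def format_alignment_row(query_id: str, a: LocalAlignment) -> str:
    return "\t".join(
        str(v) for v in (
            query_id,
            a.seq_id,
            a.q_interval[0] + 1,
            a.q_interval[1],
            a.db_interval[0] + 1,
            a.db_interval[1],
            a.length,
            a.match_count,
            f"{float(100 * a.mp):.2f}",
            a.errors,
            a.strand,
        )
    )


def write_alignments_tsv(
    per_query: Mapping[str, Iterable[LocalAlignment]],
    out: TextIO,
    header_comment: str | None = None,
) -> None:
    if header_comment:
        out.write(f"# {header_comment}\n")
    out.write("\t".join(COLUMNS) + "\n")
    for qid in per_query:
        for a in per_query[qid]:
            out.write(format_alignment_row(qid, a) + "\n")


def read_alignments_tsv(path: str | Path) -> dict[str, list[LocalAlignment]]:
    """Read a table written by :func:`write_alignments_tsv`.

    The map count is reconstructed from |A| = |x| + |y| - map.
    """
    per_query: dict[str, list[LocalAlignment]] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != COLUMNS:
                    raise ValueError(
                        f"{path}: unexpected columns {header!r}"
                    )
                continue
            row = dict(zip(COLUMNS, line.split("\t")))
            q_iv = (int(row["q_start"]) - 1, int(row["q_end"]))
            s_iv = (int(row["s_start"]) - 1, int(row["s_end"]))
            length = int(row["length"])
            span_sum = (q_iv[1] - q_iv[0]) + (s_iv[1] - s_iv[0])
            aln = LocalAlignment(
                seq_id=row["subject_id"],
                db_interval=s_iv,
                q_interval=q_iv,
                map_count=span_sum - length,
                match_count=int(row["match"]),
                strand=row["strand"],
            )
            per_query.setdefault(row["query_id"], []).append(aln)
    return per_query
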
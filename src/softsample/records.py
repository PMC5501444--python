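"""Nucleotide sequence records and FASTA input/output.

Sequences are plain upper-case strings over the alphabet {A, C, G, T, N}.
``N`` marks an ambiguous base: it is carried through parsing but never
indexed and never matched during search.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaError(ValueError):
    """Raised for malformed FASTA input (bad header or illegal residue)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence.

    Parameters
    ----------
    id : str
        Sequence identifier (the first word of the FASTA header).
    residues : str
        Upper-case bases over {A, C, G, T, N}; never empty.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_BASES
        if bad:
            raise FastaError(
                f"sequence {self.id!r} contains illegal characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.residues.translate(_COMPLEMENT)[::-1])


def _find_bad_line(path: Path, bad_chars: set[str]) -> int | None:
    """Locate the first line containing any of ``bad_chars`` (1-based)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if bad_chars & set(line.strip().upper()):
                return lineno
    return None


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into a list of :class:`SequenceRecord`.

    Residues are upper-cased; record order is preserved.  A header that does
    not start with ``>`` or a residue outside {A, C, G, T, N} raises
    :class:`FastaError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}:{lineno}: expected FASTA header starting "
                        f"with '>'"
                    )
                break
        else:
            raise FastaError(f"{path}: no FASTA records found")

    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - VALID_BASES
        if bad:
            lineno = _find_bad_line(path, bad)
            where = f"{path}:{lineno}" if lineno else str(path)
            raise FastaError(
                f"{where}: illegal character(s) {sorted(bad)} in sequence "
                f"{rec.id!r}"
            )
        if not residues:
            raise FastaError(f"{path}: sequence {rec.id!r} is empty")
        records.append(SequenceRecord(rec.id, residues))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records to ``path`` in FASTA format."""
    bio = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
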
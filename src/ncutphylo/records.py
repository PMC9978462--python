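"""Protein sequence records and FASTA I/O.

Sequences are restricted to the 20 canonical amino acids plus ``X`` for
anything unknown; gaps are stripped on load and ambiguity codes are mapped
to ``X`` with a warning, so every downstream module can assume a clean
alphabet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_VALID = set(AA_ALPHABET) | {"X"}
_GAP_CHARS = "-."
# B/Z/J are two-residue ambiguities, U/O the rare non-canonical residues,
# * a stop: all collapse to X.
_AMBIGUOUS = set("BZJUO*")


class InputError(ValueError):
    """Invalid user-supplied input (sequences, labels, matrices)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A labeled protein sequence.

    Parameters
    ----------
    id : str
        Non-empty label, unique within a sequence set.
    residues : str
        Amino-acid string over ``ARNDCQEGHILKMFPSTWYVX``, length >= 1.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence id must be non-empty")
        if not self.residues:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}; "
                "use clean_residues() / read_fasta() to normalise raw input"
            )

    def __len__(self) -> int:
        return len(self.residues)


def clean_residues(raw: str, label: str = "<sequence>") -> str:
    """Uppercase, strip gaps, and map non-canonical residues to ``X``."""
    s = raw.upper()
    for g in _GAP_CHARS:
        s = s.replace(g, "")
    if not s:
        raise InputError(f"sequence {label!r} is empty after gap removal")
    unknown = (set(s) - _VALID) | (set(s) & _AMBIGUOUS)
    if unknown:
        warnings.warn(
            f"sequence {label!r}: mapping non-canonical residues "
            f"{sorted(unknown)} to X",
            stacklevel=2,
        )
        s = "".join("X" if ch in unknown or ch not in _VALID else ch for ch in s)
    return s


def make_record(id: str, raw_residues: str) -> SequenceRecord:
    """Build a :class:`SequenceRecord` from raw (possibly gapped) residues."""
    return SequenceRecord(id=id, residues=clean_residues(raw_residues, id))


def check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise InputError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record protein FASTA into validated records."""
    records = [make_record(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    check_unique_ids(records)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqio_records, str(path), "fasta")
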
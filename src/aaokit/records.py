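"""Protein sequence records and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with identifier and optional kingdom hint."""

    id: str
    sequence: str
    kingdom: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, kingdom: str | None = None) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    A per-record kingdom hint may be embedded in the description as
    ``kingdom=<name>``; an explicit *kingdom* argument overrides it.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kd = kingdom
        if kd is None:
            for token in rec.description.split():
                if token.startswith("kingdom="):
                    kd = token.split("=", 1)[1]
        records.append(
            ProteinRecord(rec.id, str(rec.seq), kingdom=kd, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA."""
    seqs = []
    for r in records:
        desc = r.description
        if r.kingdom and f"kingdom={r.kingdom}" not in desc:
            desc = (desc + f" kingdom={r.kingdom}").strip()
        seqs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)
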
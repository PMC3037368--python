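"""Protein sequence records and FASTA / TSV I/O.

Positions are 1-based inclusive everywhere in this package, matching
the residue numbering conventions of the structural biology literature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = STANDARD_AA | {"X"}


@dataclass
class ProteinRecord:
    """A named amino-acid sequence with free-form annotations."""

    id: str
    sequence: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("sequence must be nonempty")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """1-based residue lookup."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} out of bounds")
        return self.sequence[position - 1]

    def subsequence(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise IndexError(f"span ({start}, {end}) out of bounds")
        return self.sequence[start - 1:end]


def read_fasta(path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq),
                                     annotations={"description": rec.description}))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=str(r.annotations.get("description", "")))
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    # normalize wrapping deterministically (SeqIO already wraps at 60)
    _ = width


MOTIF_TSV_COLUMNS = ("record_id", "motif_type", "start", "end", "phase",
                     "score", "details")


def write_motif_tsv(rows, path) -> None:
    """Write motif hits as TSV with a single '#'-prefixed header line.

    Each row is a mapping with the MOTIF_TSV_COLUMNS keys; ``details``
    may be any JSON-serializable object.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(MOTIF_TSV_COLUMNS) + "\n")
        for row in rows:
            details = row.get("details", {})
            fh.write("\t".join([
                str(row["record_id"]), str(row["motif_type"]),
                str(row["start"]), str(row["end"]),
                str(row.get("phase", "")), str(row.get("score", "")),
                json.dumps(details, sort_keys=True),
            ]) + "\n")
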
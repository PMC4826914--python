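"""A minimal multiple-sequence-alignment container with FASTA IO."""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Alignment:
    """Equal-length rows indexed by sequence id (protein or nucleotide)."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in number")
        if len(self.seqs) < 2:
            raise ValueError("alignment needs at least 2 rows")
        n = len(self.seqs[0])
        if any(len(s) != n for s in self.seqs):
            raise ValueError("alignment rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def reordered(self, ids: list[str]) -> "Alignment":
        return Alignment(ids=list(ids), seqs=[self.row(i) for i in ids])

    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(ids=[r.id for r in records], seqs=[str(r.seq).upper() for r in records])

    def write_fasta(self, path) -> None:
        records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)]
        SeqIO.write(records, str(path), "fasta")
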
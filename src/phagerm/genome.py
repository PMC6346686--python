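"""Genome records and sequence file I/O (FASTA / GenBank via Biopython)."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif_model import IUPAC_ALPHABET, IUPAC_COMPLEMENT

__all__ = ["Topology", "GenomeRecord", "read_genome", "write_fasta", "reverse_complement"]


class Topology(str, enum.Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


def reverse_complement(seq: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))


@dataclass(frozen=True)
class GenomeRecord:
    """A DNA sequence with an explicit topology.

    Phage genomes are linear by default (an infecting phage chromosome is a
    linear duplex; terminal repeats, if any, are left as deposited).
    """

    identifier: str
    sequence: str
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.identifier}: empty sequence")
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - IUPAC_ALPHABET
        if bad:
            raise ValueError(f"{self.identifier}: non-IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "GenomeRecord":
        return GenomeRecord(self.identifier, reverse_complement(self.sequence), self.topology)

    def rotated(self, offset: int) -> "GenomeRecord":
        """Rotate the sequence origin (only meaningful for circular genomes)."""
        k = offset % len(self.sequence)
        return GenomeRecord(self.identifier, self.sequence[k:] + self.sequence[:k], self.topology)


def read_genome(path: str | Path, topology: Topology | str | None = None) -> GenomeRecord:
    """Read the first record of a FASTA or GenBank file.

    Topology comes from the GenBank LOCUS line when present; for FASTA it
    must be given explicitly or defaults to linear (reported, never silent:
    callers echo the topology into every report).
    """
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    record = next(SeqIO.parse(str(path), fmt))
    if topology is None:
        gb_topology = record.annotations.get("topology") if fmt == "genbank" else None
        topology = Topology.CIRCULAR if gb_topology == "circular" else Topology.LINEAR
    elif isinstance(topology, str):
        topology = Topology(topology)
    return GenomeRecord(record.id, str(record.seq), topology)


def write_fasta(genome: GenomeRecord, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.identifier,
                       description=f"topology={genome.topology.value}")
    SeqIO.write([record], str(path), "fasta")
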
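"""Circular DNA molecules with wraparound coordinate semantics.

Plant mitochondrial genomes are conventionally assembled and reported as a
single circular "master" molecule.  Every coordinate-taking operation in this
package therefore works modulo the molecule length when the topology is
circular, and plain linear slicing otherwise.

Internal coordinates are 0-based half-open; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A DNA molecule, circular by default.

    Attributes
    ----------
    id : str
        Molecule identifier (FASTA header word).
    sequence : str
        Uppercase sequence over ``{A, C, G, T, N}``.
    topology : str
        ``"circular"`` or ``"linear"``.
    """

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {self.topology!r}")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise ValueError(f"invalid characters in sequence {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, length: int) -> str:
        """Sequence of given length starting at ``start`` (0-based).

        On a circular molecule the slice wraps around the origin; ``start``
        may be any integer and is normalised modulo the length.  ``length``
        may not exceed the molecule length (one full wrap).
        """
        n = len(self)
        if length < 0 or length > n:
            raise ValueError(f"fetch length {length} outside [0, {n}]")
        if not self.is_circular:
            if start < 0 or start + length > n:
                raise ValueError(
                    f"slice [{start}, {start + length}) outside linear molecule of {n} bp"
                )
            return self.sequence[start : start + length]
        start %= n
        end = start + length
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]

    def fetch_interval(self, start: int, end: int) -> str:
        """Sequence of the half-open interval [start, end); wraps if end <= start."""
        n = len(self)
        if self.is_circular:
            length = (end - start) % n
            if length == 0 and end != start:
                length = n
            return self.fetch(start, length)
        return self.fetch(start, end - start)

    def rotate(self, offset: int) -> "CircularSequence":
        """The same circle re-linearised to start at ``offset``."""
        if not self.is_circular:
            raise ValueError("cannot rotate a linear molecule")
        n = len(self)
        offset %= n
        return CircularSequence(self.id, self.sequence[offset:] + self.sequence[:offset])

    def reverse_complement(self) -> "CircularSequence":
        return CircularSequence(self.id + "_rc", revcomp(self.sequence), self.topology)


def read_fasta(path: str | Path, topology: str = "circular") -> list[CircularSequence]:
    """Load all records of a FASTA file as :class:`CircularSequence`."""
    return [
        CircularSequence(rec.id, str(rec.seq).upper(), topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(
    molecules: Iterable[CircularSequence],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    records = [
        SeqRecord(
            Seq(m.sequence),
            id=m.id,
            description=(descriptions or {}).get(m.id, ""),
        )
        for m in molecules
    ]
    SeqIO.write(records, str(path), "fasta")
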
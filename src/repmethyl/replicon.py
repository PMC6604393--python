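"""Replicon container and coordinate helpers.

All public coordinates in this package are 1-based inclusive, matching how
positions are printed in the bacterial-genomics literature (e.g. a motif
"starting at 7392" occupies 7392..7397).  Circular replicons wrap: position
N+1 is position 1.  On-disk interchange formats that are 0-based half-open
(BED) convert at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")


@dataclass(frozen=True)
class Replicon:
    """A named DNA sequence, linear or circular.

    Parameters
    ----------
    name : str
        Record identifier (FASTA header / SAM reference name).
    sequence : str
        Uppercase DNA; ``N`` is permitted and never matches a motif letter.
    circular : bool
        Whether coordinates wrap modulo the length.
    """

    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def wrap(self, pos: int) -> int:
        """Map a possibly out-of-range 1-based position onto the replicon."""
        n = len(self.sequence)
        if self.circular:
            return (pos - 1) % n + 1
        if not 1 <= pos <= n:
            raise IndexError(f"position {pos} outside linear replicon of length {n}")
        return pos

    def base(self, pos: int) -> str:
        return self.sequence[self.wrap(pos) - 1]

    def fetch(self, start: int, length: int) -> str:
        """Extract ``length`` nt beginning at 1-based ``start``, wrapping if circular."""
        n = len(self.sequence)
        if length < 0:
            raise ValueError("negative length")
        if self.circular:
            start0 = (start - 1) % n
            doubled = self.sequence + self.sequence
            if length > n:
                raise ValueError("fetch longer than circular replicon")
            return doubled[start0 : start0 + length]
        if start < 1 or start + length - 1 > n:
            raise IndexError(
                f"interval {start}..{start + length - 1} outside linear replicon of length {n}"
            )
        return self.sequence[start - 1 : start - 1 + length]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path) -> list[Replicon]:
    """Read replicons from FASTA; ``circular=true`` in the description marks circularity."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circ = "circular=true" in rec.description.lower()
        out.append(Replicon(rec.id, str(rec.seq), circular=circ))
    return out


def write_fasta(replicons, path) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.name,
            description=f"circular={'true' if r.circular else 'false'} length={len(r)}",
        )
        for r in replicons
    ]
    SeqIO.write(records, str(path), "fasta")
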
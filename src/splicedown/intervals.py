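"""Genomic intervals and strand-aware sequence access.

All coordinates are 0-based half-open throughout the package, matching the
rMATS ``exonStart_0base``/``exonEnd`` convention and BED output. GTF input
(1-based inclusive) is converted at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

try:  # pyfaidx.Fasta is the usual on-disk backend
    from pyfaidx import Fasta as _Fasta
except ImportError:  # pragma: no cover
    _Fasta = None

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

STRANDS = ("+", "-")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA sequence (U treated as T's partner A)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}: must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


class GenomeSource:
    """Contig -> sequence lookup backed by a dict or a FASTA file.

    ``fetch`` returns the forward-strand slice; ``extract_sequence`` applies
    strand orientation.
    """

    def __init__(self, source: Union[str, Mapping[str, str]]):
        if isinstance(source, (str,)) and _Fasta is not None:
            self._fasta = _Fasta(source, as_raw=True, sequence_always_upper=True)
            self._dict = None
        else:
            self._fasta = None
            self._dict = {k: str(v).upper() for k, v in dict(source).items()}

    def contig_length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def __contains__(self, chrom: str) -> bool:
        try:
            self.contig_length(chrom)
            return True
        except KeyError:
            return False

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self:
            raise KeyError(f"contig {chrom!r} not in genome")
        n = self.contig_length(chrom)
        if start < 0 or end > n or start >= end:
            raise ValueError(
                f"region {chrom}:{start}-{end} out of bounds for contig of length {n}"
            )
        if self._dict is not None:
            return self._dict[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()


def extract_sequence(genome: GenomeSource, region: GenomicInterval) -> str:
    """Strand-oriented sequence of ``region``: reverse complement on '-'.

    Length always equals ``end - start``. Out-of-bounds regions raise with
    the offending contig and coordinates in the message.
    """
    seq = genome.fetch(region.chrom, region.start, region.end)
    if region.strand == "-":
        seq = reverse_complement(seq)
    return seq
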
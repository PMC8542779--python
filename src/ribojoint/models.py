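"""Core domain types shared across the pipeline.

A :class:`TranscriptModel` is a deliberately simple, single-exon gene model:
a 5'UTR, a CDS and a 3'UTR laid out contiguously on the genome.  It drives
both footprint simulation and P-site region assignment, so both sides of the
package agree exactly on where each region starts and ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple


class SampleName(NamedTuple):
    """Parsed ``GROUP_ASSAY_REP`` column name, e.g. ``M_ribo_1``."""

    group: str
    assay: str
    replicate: int

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.group}_{self.assay}_{self.replicate}"


def parse_sample(name: str) -> SampleName:
    """Parse a sample column name of the form ``GROUP_ASSAY_REP``."""
    parts = name.split("_")
    if len(parts) != 3:
        raise ValueError(
            f"sample name {name!r} is not of the form GROUP_ASSAY_REP (e.g. M_ribo_1)"
        )
    group, assay, rep = parts
    if assay not in ("rna", "ribo", "te"):
        raise ValueError(f"sample {name!r}: unknown assay {assay!r}")
    return SampleName(group, assay, int(rep))


@dataclass(frozen=True)
class TranscriptModel:
    """One gene's transcript: 5'UTR + CDS + 3'UTR on a single strand.

    Coordinates are genomic and 1-based inclusive (GTF convention);
    ``tx_start`` is the leftmost genomic base regardless of strand.  The
    transcript 5' end is ``tx_start`` on ``+`` and ``tx_end`` on ``-``.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.gene_id}: UTR lengths must be >= 0")
        if self.cds_len <= 0:
            raise ValueError(f"{self.gene_id}: CDS length must be > 0")
        if self.cds_len % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length must be a multiple of 3")

    @property
    def total_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def tx_end(self) -> int:
        """Rightmost genomic base, 1-based inclusive."""
        return self.tx_start + self.total_len - 1

    def region_of(self, tx_pos: int) -> str:
        """Region containing a 0-based transcript-coordinate position.

        Transcript coordinates run 5'->3' (i.e. reversed relative to the
        genome on the ``-`` strand).
        """
        if tx_pos < 0 or tx_pos >= self.total_len:
            raise ValueError(f"{self.gene_id}: position {tx_pos} outside transcript")
        if tx_pos < self.utr5_len:
            return "utr5"
        if tx_pos < self.utr5_len + self.cds_len:
            return "cds"
        return "utr3"

    def genomic_to_tx(self, gpos: int) -> int:
        """Map a 1-based genomic position to a 0-based transcript position."""
        if gpos < self.tx_start or gpos > self.tx_end:
            raise ValueError(f"{self.gene_id}: genomic {gpos} outside transcript")
        if self.strand == "+":
            return gpos - self.tx_start
        return self.tx_end - gpos

    def tx_to_genomic(self, tx_pos: int) -> int:
        """Map a 0-based transcript position to a 1-based genomic position."""
        if tx_pos < 0 or tx_pos >= self.total_len:
            raise ValueError(f"{self.gene_id}: position {tx_pos} outside transcript")
        if self.strand == "+":
            return self.tx_start + tx_pos
        return self.tx_end - tx_pos


@dataclass(frozen=True)
class FootprintRecord:
    """One ribosome-protected fragment as a BED6-style interval.

    ``start`` is 0-based, ``end`` exclusive; ``length == end - start``.
    """

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("footprint end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime_end(self) -> int:
        """1-based genomic coordinate of the fragment's 5' end."""
        return self.start + 1 if self.strand == "+" else self.end
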
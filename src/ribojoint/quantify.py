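"""Footprint assignment, RPKM normalisation and library-level QC.

Footprints are assigned to genes by their inferred P-site: the position
``offset`` nt downstream of the fragment 5' end (strand-aware), with a
default offset of 12 nt, the field-standard value for 28-31 nt fragments.
A fragment is counted to the single gene whose transcript model contains
the P-site, and to the 5'UTR/CDS/3'UTR region it lands in.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import FootprintRecord, TranscriptModel, parse_sample

logger = logging.getLogger(__name__)

#: Admissible footprint length window (inclusive); records outside it are
#: tallied as unassigned but never counted to a gene.
DEFAULT_LENGTH_WINDOW = (25, 35)
DEFAULT_PSITE_OFFSET = 12

REGIONS = ("utr5", "cds", "utr3")


@dataclass
class RegionTally:
    """Per-sample bookkeeping of where footprints landed."""

    utr5: int = 0
    cds: int = 0
    utr3: int = 0
    unassigned: int = 0
    malformed: int = 0
    #: subset of ``unassigned`` rejected by the length window
    length_filtered: int = 0

    @property
    def assigned(self) -> int:
        return self.utr5 + self.cds + self.utr3

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned + self.malformed

    def as_dict(self) -> dict[str, int]:
        return {
            "utr5": self.utr5, "cds": self.cds, "utr3": self.utr3,
            "unassigned": self.unassigned, "malformed": self.malformed,
            "length_filtered": self.length_filtered,
        }


class _ChromIndex:
    """Sorted non-overlapping intervals per chromosome for P-site lookup."""

    def __init__(self, models: list[TranscriptModel]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[TranscriptModel]]] = {}
        for chrom in sorted({m.chrom for m in models}):
            # ties in start cannot occur (non-overlap), but sort by gene_id
            # as a secondary key so the index is deterministic regardless
            cms = sorted(
                (m for m in models if m.chrom == chrom),
                key=lambda m: (m.tx_start, m.gene_id),
            )
            starts = [m.tx_start for m in cms]
            ends = [m.tx_end for m in cms]
            if any(ends[i] >= starts[i + 1] for i in range(len(cms) - 1)):
                raise ValueError(f"overlapping transcript models on {chrom}")
            self._by_chrom[chrom] = (starts, ends, cms)

    def lookup(self, chrom: str, gpos: int) -> TranscriptModel | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, cms = entry
        i = bisect_right(starts, gpos) - 1
        if i >= 0 and gpos <= ends[i]:
            return cms[i]
        return None


def psite_position(fp: FootprintRecord, offset: int) -> int:
    """1-based genomic coordinate of the inferred P-site."""
    if fp.strand == "+":
        return fp.start + 1 + offset
    return fp.end - offset


def assign_footprints(
    footprints: list[FootprintRecord],
    annotation: list[TranscriptModel],
    offset: int = DEFAULT_PSITE_OFFSET,
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    n_malformed: int = 0,
) -> tuple[pd.Series, RegionTally]:
    """Count footprints per gene and per region by P-site containment.

    Returns an integer Series over all annotated genes (zeros included) and
    the :class:`RegionTally`.  ``n_malformed`` (from BED reading) is folded
    into the tally so the conservation invariant
    ``assigned + unassigned + malformed == records read`` holds end to end.
    """
    if offset < 0:
        raise ValueError("P-site offset must be >= 0")
    index = _ChromIndex(annotation)
    counts = {m.gene_id: 0 for m in annotation}
    tally = RegionTally(malformed=n_malformed)
    lo, hi = length_window
    for fp in footprints:
        if not (lo <= fp.length <= hi):
            tally.unassigned += 1
            tally.length_filtered += 1
            continue
        gpos = psite_position(fp, offset)
        m = index.lookup(fp.chrom, gpos)
        if m is None:
            tally.unassigned += 1
            continue
        region = m.region_of(m.genomic_to_tx(gpos))
        counts[m.gene_id] += 1
        setattr(tally, region, getattr(tally, region) + 1)
    series = pd.Series(counts, name="count", dtype=np.int64)
    series.index.name = "gene_id"
    return series, tally


# ---------------------------------------------------------------------------
# RPKM


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM(g, s) = count(g, s) / ((length_g / 1e3) * (total_s / 1e6)).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"gene {bad!r} has non-positive length")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


# ---------------------------------------------------------------------------
# QC summaries


def length_histogram(footprints: list[FootprintRecord]) -> tuple[pd.Series, int]:
    """Footprint length frequencies and the modal length.

    Frequencies sum to 1; on ties the smallest length is reported as mode.
    """
    if not footprints:
        raise ValueError("no footprints: length histogram undefined")
    lengths = pd.Series([fp.length for fp in footprints])
    freq = lengths.value_counts(normalize=True).sort_index()
    mode = int(freq.index[np.argmax(freq.to_numpy())])  # argmax -> first/smallest
    freq.index.name = "length"
    freq.name = "frequency"
    return freq, mode


def region_ratios(tally: RegionTally) -> dict[str, float]:
    """Percentage of assigned footprints per region (sums to 100)."""
    total = tally.assigned
    if total <= 0:
        raise ValueError("no assigned footprints: region ratios undefined")
    return {r: 100.0 * getattr(tally, r) / total for r in REGIONS}


def expressed_gene_count(expr: pd.DataFrame, group: str) -> int:
    """Genes with RPKM > 0 in at least one replicate of ``group``."""
    cols = [c for c in expr.columns if parse_sample(c).group == group]
    if not cols:
        raise ValueError(f"no samples for group {group!r}")
    return int((expr[cols] > 0).any(axis=1).sum())


def group_correlation(
    expr: pd.DataFrame,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> float:
    """Squared Pearson correlation of log2(mean RPKM + c) between groups.

    Computed over genes expressed (mean RPKM > 0) in both groups, mirroring
    how between-group reproducibility is usually summarised for matched
    transcriptome/translatome libraries.
    """
    cols_a = [c for c in expr.columns if parse_sample(c).group == group_a]
    cols_b = [c for c in expr.columns if parse_sample(c).group == group_b]
    if not cols_a or not cols_b:
        raise ValueError("both groups must have >= 1 sample")
    mean_a = expr[cols_a].mean(axis=1)
    mean_b = expr[cols_b].mean(axis=1)
    keep = (mean_a > 0) & (mean_b > 0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 genes expressed in both groups")
    x = np.log2(mean_a[keep].to_numpy() + pseudocount)
    y = np.log2(mean_b[keep].to_numpy() + pseudocount)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class QCReport:
    """Bundle of the per-run QC summaries, serialisable to JSON."""

    length_histogram: dict[int, float] = field(default_factory=dict)
    modal_length: int | None = None
    region_ratios: dict[str, dict[str, float]] = field(default_factory=dict)
    region_tallies: dict[str, dict[str, int]] = field(default_factory=dict)
    expressed_genes: dict[str, dict[str, int]] = field(default_factory=dict)
    r_squared: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "length_histogram": {str(k): v for k, v in self.length_histogram.items()},
            "modal_length": self.modal_length,
            "region_ratios": self.region_ratios,
            "region_tallies": self.region_tallies,
            "expressed_genes": self.expressed_genes,
            "r_squared": self.r_squared,
        }
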
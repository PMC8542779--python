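"""Readers and writers for the plain-text formats the pipeline exchanges.

GTF is 1-based inclusive; BED6 is 0-based half-open with the footprint
length in the score column and the source gene in the name column.  Count
and expression matrices are TSVs with ``gene_id`` as the row key and
``GROUP_ASSAY_REP`` column names.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .models import FootprintRecord, TranscriptModel, parse_sample

logger = logging.getLogger(__name__)

GTF_HEADER = "##gff-version 2\n##source ribojoint\n"


def write_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF with explicit UTR/CDS features."""
    lines = [GTF_HEADER]
    for m in models:
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'

        def row(feature: str, start: int, end: int, frame: str = ".") -> str:
            return (
                f"{m.chrom}\tribojoint\t{feature}\t{start}\t{end}\t.\t"
                f"{m.strand}\t{frame}\t{attrs}\n"
            )

        lines.append(row("gene", m.tx_start, m.tx_end))
        lines.append(row("transcript", m.tx_start, m.tx_end))
        # Genomic extents of the three regions depend on strand.
        if m.strand == "+":
            u5 = (m.tx_start, m.tx_start + m.utr5_len - 1)
            cds = (m.tx_start + m.utr5_len, m.tx_start + m.utr5_len + m.cds_len - 1)
            u3 = (cds[1] + 1, m.tx_end)
        else:
            u5 = (m.tx_end - m.utr5_len + 1, m.tx_end)
            cds = (m.tx_end - m.utr5_len - m.cds_len + 1, m.tx_end - m.utr5_len)
            u3 = (m.tx_start, cds[0] - 1)
        if m.utr5_len > 0:
            lines.append(row("five_prime_utr", u5[0], u5[1]))
        lines.append(row("CDS", cds[0], cds[1], frame="0"))
        if m.utr3_len > 0:
            lines.append(row("three_prime_utr", u3[0], u3[1]))
    Path(path).write_text("".join(lines))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Reconstruct transcript models from a GTF written by :func:`write_gtf`.

    Only ``gene`` and ``CDS`` features are needed: UTR lengths follow from
    the gene extent, the CDS extent and the strand.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes["gene_id"][0]
        cds = [f for f in db.children(gene, featuretype="CDS")]
        if len(cds) != 1:
            raise ValueError(f"{gene_id}: expected exactly one CDS feature, got {len(cds)}")
        c = cds[0]
        if gene.strand == "+":
            utr5 = c.start - gene.start
            utr3 = gene.end - c.end
        else:
            utr5 = gene.end - c.end
            utr3 = c.start - gene.start
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=gene.start,
                utr5_len=utr5,
                cds_len=c.end - c.start + 1,
                utr3_len=utr3,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.tx_start))
    return models


def write_bed(records: Iterable[FootprintRecord], path: str | Path) -> int:
    """Write footprints as BED6 (score = fragment length). Returns count."""
    n = 0
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t{r.length}\t{r.strand}\n"
            )
            n += 1
    return n


def read_bed(path: str | Path) -> tuple[list[FootprintRecord], int]:
    """Read BED6 footprints; malformed lines are skipped and counted.

    Returns ``(records, n_malformed)``.  A line is malformed if it has
    fewer than six tab-separated fields, non-integer coordinates, an empty
    interval, or a strand other than ``+``/``-``.
    """
    records: list[FootprintRecord] = []
    malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                malformed += 1
                logger.warning("%s:%d: malformed BED line (need 6 fields)", path, lineno)
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5]
                if end <= start or strand not in ("+", "-"):
                    raise ValueError
                records.append(
                    FootprintRecord(
                        chrom=fields[0], start=start, end=end,
                        gene_id=fields[3], strand=strand,
                    )
                )
            except ValueError:
                malformed += 1
                logger.warning("%s:%d: malformed BED line", path, lineno)
    return records, malformed


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count/expression TSV; validates column names."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    for col in df.columns:
        parse_sample(col)
    return df


def write_sidecar(path: str | Path, payload: dict) -> None:
    """Write a JSON sidecar (``<path>.json``) recording config and seed."""
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
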
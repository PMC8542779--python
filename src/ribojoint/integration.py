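"""Nine-class joint classification of transcriptome and translatome status.

Each gene tested at both levels gets a status pair
(transcriptome, translatome) with each status in {down, ns, up}, and the
pair maps to one of nine classes A-I laid out row-major on the quadrant
grid: rows are translatome status (up / ns / down, top to bottom), columns
are transcriptome status (down / ns / up, left to right).

    A = (tx down, ribo up)    B = (ns, up)     C = (up, up)
    D = (down, ns)            E = (ns, ns)     F = (up, ns)
    G = (down, down)          H = (ns, down)   I = (up, down)

E collects genes unchanged at both levels, C/G the concordant ones, and
the remaining six cells the discordant ones.  The mapping is exposed as a
configurable table since other layouts of the same grid exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CLASS_LABELS = tuple("ABCDEFGHI")

#: (transcriptome status, translatome status) -> class label.
DEFAULT_CLASS_GRID: dict[tuple[str, str], str] = {
    ("down", "up"): "A", ("ns", "up"): "B", ("up", "up"): "C",
    ("down", "ns"): "D", ("ns", "ns"): "E", ("up", "ns"): "F",
    ("down", "down"): "G", ("ns", "down"): "H", ("up", "down"): "I",
}

DISCORDANT_CLASSES = ("A", "B", "D", "F", "H", "I")
CONCORDANT_CLASSES = ("C", "G")


def classify_gene(
    tx_direction: str,
    ribo_direction: str,
    grid: dict[tuple[str, str], str] | None = None,
) -> str:
    """Map one gene's (transcriptome, translatome) status pair to a class."""
    grid = grid or DEFAULT_CLASS_GRID
    key = (tx_direction, ribo_direction)
    if key not in grid:
        raise ValueError(f"invalid status pair {key!r}")
    return grid[key]


def classify_genes(
    tx: pd.DataFrame,
    ribo: pd.DataFrame,
    grid: dict[tuple[str, str], str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Classify every gene present with a direction at both levels.

    ``tx`` and ``ribo`` are outputs of DEG calling (must carry a
    ``direction`` column).  Returns a DataFrame (gene, tx_direction,
    ribo_direction, reg_class) over the intersection, plus the sorted list
    of genes seen at only one level (tallied, never silently dropped).
    """
    common = tx.index.intersection(ribo.index)
    unclassified = sorted(set(tx.index).symmetric_difference(set(ribo.index)))
    out = pd.DataFrame(
        {
            "tx_direction": tx.loc[common, "direction"],
            "ribo_direction": ribo.loc[common, "direction"],
        },
        index=common,
    )
    out["reg_class"] = [
        classify_gene(a, b, grid)
        for a, b in zip(out["tx_direction"], out["ribo_direction"])
    ]
    out.index.name = "gene_id"
    return out, unclassified


@dataclass
class QuadrantSummary:
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    total: int = 0
    discordant_count: int = 0
    discordant_percent: float = 0.0
    unclassified: int = 0

    def as_dict(self) -> dict:
        return {
            "counts": self.counts,
            "percentages": self.percentages,
            "total": self.total,
            "discordant_count": self.discordant_count,
            "discordant_percent": self.discordant_percent,
            "unclassified": self.unclassified,
        }


def quadrant_summary(classes: pd.Series | pd.DataFrame, unclassified: int = 0) -> QuadrantSummary:
    """Class occupancy: per-class counts and percentages of classified genes.

    Also aggregates the six discordant classes (A, B, D, F, H, I).
    """
    if isinstance(classes, pd.DataFrame):
        classes = classes["reg_class"]
    total = int(len(classes))
    if total == 0:
        raise ValueError("no classified genes")
    counts = {lab: int((classes == lab).sum()) for lab in CLASS_LABELS}
    percentages = {lab: 100.0 * c / total for lab, c in counts.items()}
    disc = sum(counts[lab] for lab in DISCORDANT_CLASSES)
    return QuadrantSummary(
        counts=counts,
        percentages=percentages,
        total=total,
        discordant_count=disc,
        discordant_percent=100.0 * disc / total,
        unclassified=unclassified,
    )


def coordinate_overlap(
    tx: pd.DataFrame, ribo: pd.DataFrame
) -> tuple[set[str], set[str]]:
    """Genes differential in the same direction at both levels.

    Returns (up-up genes, down-down genes); by construction these equal
    the class-C and class-G sets of :func:`classify_genes` on the same
    input.
    """
    def directed(df: pd.DataFrame, d: str) -> set[str]:
        return set(df.index[df["direction"] == d])

    up = directed(tx, "up") & directed(ribo, "up")
    down = directed(tx, "down") & directed(ribo, "down")
    return up, down
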
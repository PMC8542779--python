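"""Gene-set statistics: GSEA running-sum enrichment and over-representation.

The enrichment score (ES) is the signed maximal deviation of the classic
weighted Kolmogorov-Smirnov running sum over a ranked gene list: each set
member ("hit") increments the sum by |score|^weight (normalised over hits),
each non-member decrements it by 1/(N - Nh).  At weight 0 the ES is the
plain KS statistic and is bounded by 1 in absolute value.  Significance
uses a gene-label permutation null (set membership reassigned uniformly at
the same set size), the only feasible null when each phenotype group has
just two samples.  Over-representation of a study list in a set is the
hypergeometric upper-tail probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> description <tab> members...).

    Duplicate members within a line are deduplicated with a warning; a
    line with fewer than three fields is an error naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                logger.warning(
                    "%s:%d: %d duplicate members in set %s removed",
                    path, lineno, len(members) - len(uniq), name,
                )
            sets.append(GeneSet(name, desc, frozenset(uniq)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# over-representation


def overrep_test(study: set[str], gene_set: GeneSet | set[str], universe: set[str]) -> float:
    """Hypergeometric upper-tail p for the study/set overlap.

    p = P(X >= k) with X ~ Hypergeom(N = |universe|, K = |set & universe|,
    n = |study|) and k the observed overlap.  The study list must be a
    subset of the universe; the set is intersected with the universe first.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else set(gene_set)
    study = set(study)
    universe = set(universe)
    if not study <= universe:
        extra = sorted(study - universe)[:3]
        raise ValueError(f"study genes not in universe: {extra}")
    big_n = len(universe)
    big_k = len(members & universe)
    n = len(study)
    k = len(study & members & universe)
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


# ---------------------------------------------------------------------------
# GSEA


def _es_from_hits(hits: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximal running-sum deviation for a given hit mask."""
    n = hits.size
    nh = int(hits.sum())
    hit_mass = np.where(hits, weights, 0.0)
    denom = hit_mass.sum()
    if denom <= 0:
        raise ValueError("hit weights sum to zero")
    step = hit_mass / denom - np.where(hits, 0.0, 1.0 / (n - nh))
    run = np.cumsum(step)
    return float(run[np.argmax(np.abs(run))])


def _prepare(ranked: pd.Series, members: frozenset[str] | set[str], weight: float):
    if weight < 0:
        raise ValueError("weight must be >= 0")
    scores = ranked.to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    genes = ranked.index.to_numpy()
    hits = np.isin(genes, list(members))
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == len(genes):
        raise ValueError("gene set covers the entire ranked list")
    weights = np.abs(scores) ** weight if weight > 0 else np.ones_like(scores)
    return hits, weights


def gsea_es(ranked: pd.Series, gene_set: GeneSet | set[str], weight: float = 1.0) -> float:
    """Enrichment score of a gene set on a ranked list.

    ``ranked`` maps gene_id -> score, ordered from most up- to most
    down-regulated; a positive ES means the set concentrates at the top
    (up-regulated), negative at the bottom.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else gene_set
    ranked = ranked.sort_values(ascending=False)
    hits, weights = _prepare(ranked, members, weight)
    return _es_from_hits(hits, weights)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    n_perm: int


def gsea_significance(
    ranked: pd.Series,
    gene_set: GeneSet | set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation p-value and normalised ES for one gene set.

    The null reassigns set membership uniformly at random over the ranked
    genes (same set size).  With S = permutations whose null ES shares the
    observed sign, p = (1 + #{|ES_null| >= |ES_obs| among S}) / (1 + |S|)
    and NES = ES / mean(|ES_null| over S); the +1 keeps p > 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members = gene_set.members if isinstance(gene_set, GeneSet) else gene_set
    ranked = ranked.sort_values(ascending=False)
    hits, weights = _prepare(ranked, members, weight)
    es_obs = _es_from_hits(hits, weights)
    nh = int(hits.sum())
    n = hits.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        mask[:] = False
        mask[rng.choice(n, size=nh, replace=False)] = True
        null[i] = _es_from_hits(mask, weights)
    same_sign = null * np.sign(es_obs) > 0 if es_obs != 0 else np.ones(n_perm, bool)
    n_same = int(same_sign.sum())
    exceed = int((np.abs(null[same_sign]) >= abs(es_obs)).sum())
    p = (1 + exceed) / (1 + n_same)
    mean_null = float(np.abs(null[same_sign]).mean()) if n_same else np.nan
    nes = es_obs / mean_null if n_same and mean_null > 0 else np.nan
    name = gene_set.name if isinstance(gene_set, GeneSet) else "gene_set"
    return EnrichmentResult(name, nh, es_obs, float(nes), float(p), n_perm)


def gsea_batch(
    ranked: pd.Series,
    sets: list[GeneSet],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`gsea_significance` over a GMT collection; BH-adjust."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for i, s in enumerate(sets):
        try:
            r = gsea_significance(ranked, s, weight=weight, n_perm=n_perm, seed=seed + i)
        except ValueError as exc:
            logger.warning("set %s skipped: %s", s.name, exc)
            continue
        rows.append((r.name, r.size, r.es, r.nes, r.p_value))
    df = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "p_value"]).set_index("set")
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df
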
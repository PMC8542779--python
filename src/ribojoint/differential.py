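"""Two-level differential expression and translational-efficiency testing.

Differential expression at each level (transcriptome = RNA-seq,
translatome = Ribo-seq) uses an exact conditional negative-binomial test
on library-size-equalised counts with a single method-of-moments common
dispersion.  Conditioning on the total count makes the null distribution
of the group-B sum free of the unknown gene mean; at dispersion 0 the
conditional law is exactly binomial.

Translational efficiency TE(g, s) = RPKM_ribo / RPKM_rna is compared
between groups with an unpaired two-tailed pooled-variance t-test on
log2 TE; differential-TE genes (DTEGs) satisfy |log2FC TE| > 2 and
p < 0.05 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .models import parse_sample

logger = logging.getLogger(__name__)

#: Flagging thresholds per level: (|log2FC| cut, p cut).
LEVEL_THRESHOLDS: dict[str, tuple[float, float]] = {
    "transcriptome": (1.0, 0.001),
    "translatome": (1.0, 0.05),
}
DEFAULT_TE_LFC_CUT = 2.0
DEFAULT_TE_P_CUT = 0.05
DEFAULT_PSEUDOCOUNT = 1.0  # RPKM units


def log2_fold_change(mean_b: float, mean_m: float, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2((mean_B + c) / (mean_M + c)); vectorised over array inputs."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mean_b = np.asarray(mean_b, dtype=float)
    mean_m = np.asarray(mean_m, dtype=float)
    if (mean_b < 0).any() or (mean_m < 0).any():
        raise ValueError("means must be >= 0")
    out = np.log2(mean_b + pseudocount) - np.log2(mean_m + pseudocount)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# exact NB test


def equalize_counts(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Scale each sample's counts to the mean library size and round.

    A quantile-free analogue of edgeR-style count equalisation: after
    scaling, samples are exchangeable in depth and the conditional exact
    test applies.
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes.reindex(counts.columns)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    target = float(lib_sizes.mean())
    scaled = counts.mul(target / lib_sizes, axis=1)
    return scaled.round().astype(np.int64)


def _conditional_log_pmf(s: int, n_b: int, n_m: int, dispersion: float) -> np.ndarray:
    """log P(Y_B = y | Y_B + Y_M = s) for y = 0..s under the two-group NB null.

    With per-sample mean mu and dispersion phi, the group sums are
    NB(n*mu, phi/n); conditioned on the total, mu cancels and
    P(y|s) propto C(y + r_B - 1, y) * C(s - y + r_M - 1, s - y) with
    r = n / phi.  At phi = 0 this degenerates to Binomial(s, n_B/(n_B+n_M)).
    """
    y = np.arange(s + 1)
    if dispersion < 1e-12:
        logit = np.log(n_b) - np.log(n_m)
        logp = (
            gammaln(s + 1) - gammaln(y + 1) - gammaln(s - y + 1)
            + y * logit
        )
    else:
        r_b = n_b / dispersion
        r_m = n_m / dispersion
        logp = (
            gammaln(y + r_b) - gammaln(y + 1)
            + gammaln(s - y + r_m) - gammaln(s - y + 1)
        )
    return logp - logsumexp(logp)


def nb_exact_test(
    counts_g,
    groups,
    dispersion: float,
    lib_sizes=None,
) -> float:
    """Two-sided exact conditional NB test for one gene.

    ``counts_g`` are per-sample integer counts; ``groups`` the matching
    "M"/"B" labels.  If ``lib_sizes`` is given, counts are first equalised
    to the mean library size.  The two-sided p-value is the total
    conditional probability of outcomes no more likely than the observed
    one (minimum-likelihood rule).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    counts_g = np.asarray(counts_g, dtype=float)
    groups = np.asarray(groups)
    is_b = groups == "B"
    n_b, n_m = int(is_b.sum()), int((~is_b).sum())
    if n_b == 0 or n_m == 0:
        raise ValueError("both groups must be non-empty")
    if lib_sizes is not None:
        lib_sizes = np.asarray(lib_sizes, dtype=float)
        counts_g = np.round(counts_g * (lib_sizes.mean() / lib_sizes))
    y_b = int(round(counts_g[is_b].sum()))
    s = y_b + int(round(counts_g[~is_b].sum()))
    if s == 0:
        logger.debug("all counts zero; p = 1 by convention")
        return 1.0
    logp = _conditional_log_pmf(s, n_b, n_m, dispersion)
    obs = logp[y_b]
    mask = logp <= obs + 1e-10  # tolerate fp ties
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def estimate_common_dispersion(counts: pd.DataFrame, groups) -> float:
    """Method-of-moments common NB dispersion on equalised counts.

    Pools within-group sums of squares across genes and solves
    E[SS] = sum (n_g - 1) * (mu + phi * mu^2) for a single phi, clamped
    at 0.
    """
    eq = equalize_counts(counts)
    groups = np.asarray(groups)
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        sub = eq.loc[:, groups == g].to_numpy(dtype=float)
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        ss = ((sub - m[:, None]) ** 2).sum(axis=1)
        num += float((ss - (n - 1) * m).sum())
        den += float(((n - 1) * m**2).sum())
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


# ---------------------------------------------------------------------------
# DEG calling


def call_degs(records: pd.DataFrame, level: str) -> pd.DataFrame:
    """Flag records at the level's thresholds (strict inequalities).

    Adds ``significant`` and ``direction`` ("up"/"down"/"ns") columns.
    Transcriptome: |log2FC| > 1 and p < 0.001; translatome: |log2FC| > 1
    and p < 0.05.
    """
    if level not in LEVEL_THRESHOLDS:
        raise ValueError(f"unknown level {level!r}")
    lfc_cut, p_cut = LEVEL_THRESHOLDS[level]
    out = records.copy()
    sig = (out["log2fc"].abs() > lfc_cut) & (out["p_value"] < p_cut)
    out["significant"] = sig
    out["direction"] = np.where(
        sig & (out["log2fc"] > 0), "up", np.where(sig & (out["log2fc"] < 0), "down", "ns")
    )
    out["level"] = level
    return out


def differential_expression(
    counts: pd.DataFrame,
    lengths: pd.Series,
    level: str,
    dispersion: float | str = "auto",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    lfc_cut: float | None = None,
    p_cut: float | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between groups B and M.

    Fold changes are computed on group-mean RPKM with a pseudocount;
    p-values come from the exact conditional NB test on equalised counts
    with a common dispersion (estimated by method of moments when
    ``dispersion="auto"``).  BH-adjusted q-values are reported alongside
    but flagging uses raw p, per the stated thresholds.
    """
    from .quantify import compute_rpkm  # local import to avoid cycle

    groups = np.array([parse_sample(c).group for c in counts.columns])
    rpkm = compute_rpkm(counts, lengths)
    mean_m = rpkm.loc[:, groups == "M"].mean(axis=1)
    mean_b = rpkm.loc[:, groups == "B"].mean(axis=1)
    lfc = log2_fold_change(mean_b.to_numpy(), mean_m.to_numpy(), pseudocount)
    if dispersion == "auto":
        dispersion = estimate_common_dispersion(counts, groups)
        logger.info("%s: common dispersion (MoM) = %.4g", level, dispersion)
    eq = equalize_counts(counts)
    pvals = np.array(
        [nb_exact_test(eq.loc[g].to_numpy(), groups, float(dispersion)) for g in eq.index]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    res = pd.DataFrame(
        {
            "mean_rpkm_M": mean_m,
            "mean_rpkm_B": mean_b,
            "log2fc": lfc,
            "p_value": pvals,
            "q_value": qvals,
        },
        index=counts.index,
    )
    res = call_degs(res, level)
    if lfc_cut is not None or p_cut is not None:
        lc = lfc_cut if lfc_cut is not None else LEVEL_THRESHOLDS[level][0]
        pc = p_cut if p_cut is not None else LEVEL_THRESHOLDS[level][1]
        sig = (res["log2fc"].abs() > lc) & (res["p_value"] < pc)
        res["significant"] = sig
        res["direction"] = np.where(
            sig & (res["log2fc"] > 0), "up",
            np.where(sig & (res["log2fc"] < 0), "down", "ns"),
        )
    return res


# ---------------------------------------------------------------------------
# translational efficiency


def compute_te(rpkm_ribo: pd.DataFrame, rpkm_rna: pd.DataFrame) -> pd.DataFrame:
    """TE(g, s) = RPKM_ribo / RPKM_rna per matched (group, replicate) pair.

    Entries where RPKM_rna = 0 are NaN (undefined) and excluded downstream.
    Columns are renamed ``GROUP_te_REP``.
    """
    if not rpkm_ribo.index.equals(rpkm_rna.index):
        raise ValueError("ribo and rna matrices must share the same genes in order")
    ribo_keys = {(s.group, s.replicate): c for c in rpkm_ribo.columns
                 for s in [parse_sample(c)]}
    rna_keys = {(s.group, s.replicate): c for c in rpkm_rna.columns
                for s in [parse_sample(c)]}
    if set(ribo_keys) != set(rna_keys):
        raise ValueError(
            f"sample pairing mismatch: ribo {sorted(ribo_keys)} vs rna {sorted(rna_keys)}"
        )
    te = {}
    for key in sorted(ribo_keys):
        group, rep = key
        rna = rpkm_rna[rna_keys[key]].to_numpy(dtype=float)
        ribo = rpkm_ribo[ribo_keys[key]].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(rna > 0, ribo / np.where(rna > 0, rna, 1.0), np.nan)
        te[f"{group}_te_{rep}"] = vals
    return pd.DataFrame(te, index=rpkm_ribo.index)


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    p_value: float
    df: int


def pooled_ttest(x_b: np.ndarray, x_m: np.ndarray) -> TTestResult:
    """Unpaired two-tailed equal-variance t-test.

    Degenerate case: zero pooled variance with a nonzero mean difference
    yields the smallest positive representable p (never exactly 0), with
    t = +/-inf; zero variance and zero difference yields t = 0, p = 1.
    """
    n_b, n_m = len(x_b), len(x_m)
    if n_b < 2 or n_m < 2:
        raise ValueError("need >= 2 values per group")
    df = n_b + n_m - 2
    diff = float(np.mean(x_b) - np.mean(x_m))
    sp2 = (
        (n_b - 1) * float(np.var(x_b, ddof=1)) + (n_m - 1) * float(np.var(x_m, ddof=1))
    ) / df
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 1.0, df)
        return TTestResult(float(np.copysign(np.inf, diff)), float(np.nextafter(0.0, 1.0)), df)
    t = diff / np.sqrt(sp2 * (1.0 / n_b + 1.0 / n_m))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return TTestResult(float(t), min(1.0, p), df)


def dteg_test(
    te: pd.DataFrame,
    lfc_cut: float = DEFAULT_TE_LFC_CUT,
    p_cut: float = DEFAULT_TE_P_CUT,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Differential-TE testing between groups B and M.

    Per gene: defined TE values (finite, > 0 for the log scale) are split
    by group; with >= 2 values per group an unpaired two-tailed pooled
    t-test runs on log2 TE (or raw TE when ``log_scale=False``).  The TE
    fold change is mean(log2 TE)_B - mean(log2 TE)_M.  Genes with fewer
    than 2 defined values in either group are reported untested (NaN
    statistics) and never flagged.
    """
    groups = np.array([parse_sample(c).group for c in te.columns])
    cols_b = te.columns[groups == "B"]
    cols_m = te.columns[groups == "M"]
    if len(cols_b) + len(cols_m) - 2 <= 2:
        logger.warning(
            "TE t-test with df = %d: very low power", len(cols_b) + len(cols_m) - 2
        )
    rows = []
    for gene in te.index:
        vb = te.loc[gene, cols_b].to_numpy(dtype=float)
        vm = te.loc[gene, cols_m].to_numpy(dtype=float)
        if log_scale:
            vb = np.log2(vb[np.isfinite(vb) & (vb > 0)])
            vm = np.log2(vm[np.isfinite(vm) & (vm > 0)])
        else:
            vb = vb[np.isfinite(vb)]
            vm = vm[np.isfinite(vm)]
        if len(vb) < 2 or len(vm) < 2:
            rows.append((gene, np.nan, np.nan, np.nan, False, len(vm), len(vb)))
            continue
        if log_scale:
            lfc = float(np.mean(vb) - np.mean(vm))
        else:
            mb, mm = float(np.mean(vb)), float(np.mean(vm))
            lfc = float(np.log2(mb / mm)) if mb > 0 and mm > 0 else np.nan
        res = pooled_ttest(vb, vm)
        is_dteg = bool(
            np.isfinite(lfc) and abs(lfc) > lfc_cut and res.p_value < p_cut
        )
        rows.append((gene, lfc, res.t_stat, res.p_value, is_dteg, len(vm), len(vb)))
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "log2fc_te", "t_stat", "p_value", "is_dteg", "n_M", "n_B"],
    ).set_index("gene_id")
    tested = out["p_value"].notna()
    out["q_value"] = np.nan
    if tested.any():
        out.loc[tested, "q_value"] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out
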
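"""End-to-end orchestration: quantify -> differential -> integrate -> enrich.

A run is driven by a plain YAML config naming the inputs (GTF annotation,
RNA count TSV, Ribo count TSV or per-sample footprint BEDs, optional GMT),
the thresholds, and the options (P-site offset, pseudocount, dispersion,
seed, permutations).  All outputs are TSV/JSON written under ``outdir``,
plus a manifest recording the resolved config, its hash and the package
version, which suffices to reproduce the bundle byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import (
    compute_te,
    differential_expression,
    dteg_test,
)
from .enrichment import gsea_batch, overrep_test, read_gmt
from .integration import classify_genes, coordinate_overlap, quadrant_summary
from .io import read_bed, read_counts, read_gtf
from .models import parse_sample
from .quantify import (
    QCReport,
    assign_footprints,
    compute_rpkm,
    expressed_gene_count,
    group_correlation,
    length_histogram,
    region_ratios,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

DEFAULT_OPTIONS = {
    "pseudocount": 1.0,
    "offset": 12,
    "dispersion": "auto",
    "seed": 0,
    "n_perm": 500,
    "gsea_weight": 1.0,
}
DEFAULT_THRESHOLDS = {
    "lfc": 1.0,
    "p_transcriptome": 0.001,
    "p_translatome": 0.05,
    "te_lfc": 2.0,
    "te_p": 0.05,
}


@dataclass
class ResultBundle:
    """In-memory handles to everything a pipeline run produced."""

    outdir: Path
    rpkm_rna: pd.DataFrame
    rpkm_ribo: pd.DataFrame
    qc: QCReport
    deg_transcriptome: pd.DataFrame
    deg_translatome: pd.DataFrame
    te: pd.DataFrame
    dteg: pd.DataFrame
    classes: pd.DataFrame
    summary: dict
    coordinate_up: set[str]
    coordinate_down: set[str]
    gsea: pd.DataFrame | None
    overrep: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _resolve(cfg: dict, base: Path) -> dict:
    """Fill defaults and make input paths absolute relative to the config."""
    out = dict(cfg)
    out["options"] = {**DEFAULT_OPTIONS, **cfg.get("options", {})}
    out["thresholds"] = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    for key in ("annotation", "rna_counts", "ribo_counts", "gmt", "sample_sheet"):
        if out.get(key):
            out[key] = str((base / out[key]).resolve())
    if out.get("ribo_bed"):
        out["ribo_bed"] = {
            s: str((base / p).resolve()) for s, p in out["ribo_bed"].items()
        }
    return out


def _check_inputs(cfg: dict) -> None:
    """Fail fast, before any output is written, naming the missing path."""
    required = [("annotation", cfg.get("annotation")), ("rna_counts", cfg.get("rna_counts"))]
    if not cfg.get("ribo_bed") and not cfg.get("ribo_counts"):
        raise ValueError("config must provide ribo_counts or ribo_bed")
    for key in ("ribo_counts", "gmt", "sample_sheet"):
        if cfg.get(key):
            required.append((key, cfg[key]))
    for sample, p in (cfg.get("ribo_bed") or {}).items():
        required.append((f"ribo_bed[{sample}]", p))
    for key, p in required:
        if p is None:
            raise ValueError(f"config missing required input {key!r}")
        if not Path(p).exists():
            raise FileNotFoundError(f"{key}: no such file: {p}")


def _check_sample_sheet(cfg: dict, columns: list[str]) -> None:
    sheet_path = cfg.get("sample_sheet")
    if not sheet_path:
        return
    sheet = pd.read_csv(sheet_path, sep="\t")
    declared = set(sheet["sample"])
    for col in columns:
        if col not in declared:
            raise ValueError(f"sample {col!r} not declared in sample sheet {sheet_path}")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> ResultBundle:
    """Execute all stages on the configured inputs and write the bundle."""
    if isinstance(config, (str, Path)):
        base = Path(config).resolve().parent
        raw_cfg = load_config(config)
    else:
        base = Path.cwd()
        raw_cfg = dict(config)
    cfg = _resolve(raw_cfg, base)
    _check_inputs(cfg)
    opts = cfg["options"]
    thr = cfg["thresholds"]
    outdir = Path(outdir or cfg.get("outdir", "ribojoint_results"))

    annotation = read_gtf(cfg["annotation"])
    lengths = pd.Series(
        {m.gene_id: m.total_len for m in annotation}, name="length", dtype=float
    )
    lengths.index.name = "gene_id"
    rna_counts = read_counts(cfg["rna_counts"])
    _check_sample_sheet(cfg, list(rna_counts.columns))

    qc = QCReport()
    if cfg.get("ribo_bed"):
        cols = {}
        all_footprints = []
        for sample in sorted(cfg["ribo_bed"]):
            parse_sample(sample)
            records, n_malformed = read_bed(cfg["ribo_bed"][sample])
            counts_s, tally = assign_footprints(
                records, annotation, offset=int(opts["offset"]), n_malformed=n_malformed
            )
            cols[sample] = counts_s
            qc.region_tallies[sample] = tally.as_dict()
            qc.region_ratios[sample] = region_ratios(tally)
            all_footprints.extend(records)
            logger.info(
                "%s: %d records, %d assigned, %d unassigned, %d malformed",
                sample, tally.total, tally.assigned, tally.unassigned, tally.malformed,
            )
        ribo_counts = pd.DataFrame(cols)
        if all_footprints:
            hist, mode = length_histogram(all_footprints)
            qc.length_histogram = {int(k): float(v) for k, v in hist.items()}
            qc.modal_length = mode
    else:
        ribo_counts = read_counts(cfg["ribo_counts"])
    _check_sample_sheet(cfg, list(ribo_counts.columns))

    rpkm_rna = compute_rpkm(rna_counts, lengths)
    rpkm_ribo = compute_rpkm(ribo_counts, lengths)
    for assay, mat in (("rna", rpkm_rna), ("ribo", rpkm_ribo)):
        groups = sorted({parse_sample(c).group for c in mat.columns})
        qc.expressed_genes[assay] = {
            g: expressed_gene_count(mat, g) for g in groups
        }
        if len(groups) == 2:
            qc.r_squared[assay] = group_correlation(mat, groups[0], groups[1])

    deg_tx = differential_expression(
        rna_counts, lengths, "transcriptome",
        dispersion=opts["dispersion"], pseudocount=float(opts["pseudocount"]),
        lfc_cut=float(thr["lfc"]), p_cut=float(thr["p_transcriptome"]),
    )
    deg_ribo = differential_expression(
        ribo_counts, lengths, "translatome",
        dispersion=opts["dispersion"], pseudocount=float(opts["pseudocount"]),
        lfc_cut=float(thr["lfc"]), p_cut=float(thr["p_translatome"]),
    )

    te = compute_te(rpkm_ribo, rpkm_rna)
    dteg = dteg_test(te, lfc_cut=float(thr["te_lfc"]), p_cut=float(thr["te_p"]))

    classes, unclassified = classify_genes(deg_tx, deg_ribo)
    summary = quadrant_summary(classes, unclassified=len(unclassified))
    co_up, co_down = coordinate_overlap(deg_tx, deg_ribo)

    gsea_df = None
    overrep_df = None
    if cfg.get("gmt"):
        sets = read_gmt(cfg["gmt"])
        ranking = deg_tx["log2fc"].sort_values(ascending=False)
        gsea_df = gsea_batch(
            ranking, sets, weight=float(opts["gsea_weight"]),
            n_perm=int(opts["n_perm"]), seed=int(opts["seed"]),
        )
        universe = set(deg_ribo.index)
        study = set(deg_ribo.index[deg_ribo["significant"]])
        rows = []
        for s in sets:
            if study:
                p = overrep_test(study, s, universe)
                k = len(study & s.members & universe)
            else:
                p, k = 1.0, 0
            rows.append((s.name, len(s.members & universe), len(study), k, p))
        overrep_df = pd.DataFrame(
            rows, columns=["set", "set_size", "study_size", "overlap", "p_value"]
        ).set_index("set")

    # --- write bundle -----------------------------------------------------
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(rpkm_rna, outdir / "rpkm_rna.tsv")
    _write_tsv(rpkm_ribo, outdir / "rpkm_ribo.tsv")
    _write_tsv(deg_tx, outdir / "deg_transcriptome.tsv")
    _write_tsv(deg_ribo, outdir / "deg_translatome.tsv")
    _write_tsv(te, outdir / "te.tsv")
    _write_tsv(dteg, outdir / "dteg.tsv")
    _write_tsv(classes, outdir / "classes.tsv")
    scatter = pd.DataFrame(
        {
            "log2fc_tx": deg_tx.loc[classes.index, "log2fc"],
            "log2fc_ribo": deg_ribo.loc[classes.index, "log2fc"],
            "reg_class": classes["reg_class"],
        }
    )
    scatter.index.name = "gene_id"
    _write_tsv(scatter, outdir / "quadrant_scatter.tsv")
    (outdir / "quadrant_summary.json").write_text(
        json.dumps(summary.as_dict(), indent=2, sort_keys=True) + "\n"
    )
    (outdir / "qc.json").write_text(json.dumps(qc.as_dict(), indent=2, sort_keys=True) + "\n")
    if gsea_df is not None:
        _write_tsv(gsea_df, outdir / "gsea.tsv")
    if overrep_df is not None:
        _write_tsv(overrep_df, outdir / "overrep.tsv")
    coord = pd.DataFrame(
        sorted([(g, "up") for g in co_up] + [(g, "down") for g in co_down]),
        columns=["gene_id", "direction"],
    ).set_index("gene_id")
    _write_tsv(coord, outdir / "coordinate_degs.tsv")

    n_tested_te = int(dteg["p_value"].notna().sum())
    # record the config as written (relative paths), so a bundle is
    # byte-identical wherever the run directory lives
    manifest = {
        "config": raw_cfg,
        "config_sha256": _config_hash(raw_cfg),
        "seed": int(opts["seed"]),
        "version": __version__,
        "n_genes_annotation": len(annotation),
        "n_genes_counts": int(len(rna_counts)),
        "n_classified": int(len(classes)),
        "n_unclassified": len(unclassified),
        "n_te_tested": n_tested_te,
        "n_te_untested": int(len(dteg) - n_tested_te),
        "n_dteg": int(dteg["is_dteg"].sum()),
        "n_coordinate_up": len(co_up),
        "n_coordinate_down": len(co_down),
    }
    if manifest["n_classified"] + manifest["n_unclassified"] != manifest["n_genes_counts"]:
        raise AssertionError("gene reconciliation failed: classified + unclassified != input")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )

    return ResultBundle(
        outdir=outdir, rpkm_rna=rpkm_rna, rpkm_ribo=rpkm_ribo, qc=qc,
        deg_transcriptome=deg_tx, deg_translatome=deg_ribo, te=te, dteg=dteg,
        classes=classes, summary=summary.as_dict(),
        coordinate_up=co_up, coordinate_down=co_down,
        gsea=gsea_df, overrep=overrep_df, manifest=manifest,
    )


# ---------------------------------------------------------------------------
# demo fixture


def make_demo(outdir: str | Path, seed: int = 42, n_genes: int = 300) -> Path:
    """Write a complete small scenario plus a ready-to-run config.

    ~300 genes, 2 groups x 4 replicates x 2 assays, footprint BEDs for the
    Ribo-seq samples, a GMT built from the simulation truth (one set of
    transcriptionally induced genes, one of TE-responsive genes, two
    random sets) and ``config.yaml``.  Returns the config path.
    """
    from .synthetic import SimulationConfig, write_dataset
    from .enrichment import GeneSet, write_gmt

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create demo directory {outdir}: {exc}") from exc
    config = SimulationConfig(
        n_genes=n_genes, n_reps=4, lib_size=5e5, dispersion=0.05, seed=seed
    )
    paths = write_dataset(outdir, config, footprints=True)

    truth = pd.read_csv(paths["truth"], sep="\t", index_col="gene_id")
    rng = np.random.default_rng(seed + 1000)
    genes = truth.index.to_numpy()
    tx_up = sorted(truth.index[truth["tx_log2fc"] > 0])
    te_resp = sorted(truth.index[truth["te_log2fc"] != 0])
    sets = [
        GeneSet("tx_up_truth", "transcriptionally induced genes", frozenset(tx_up)),
        GeneSet("te_responsive_truth", "TE-shifted genes", frozenset(te_resp)),
        GeneSet("random_a", "random control set", frozenset(rng.choice(genes, 25, replace=False))),
        GeneSet("random_b", "random control set", frozenset(rng.choice(genes, 25, replace=False))),
    ]
    write_gmt(sets, outdir / "sets.gmt")

    samples = []
    for assay, counts_path in (("rna", paths["rna_counts"]), ("ribo", paths["ribo_counts"])):
        for col in read_counts(counts_path).columns:
            s = parse_sample(col)
            samples.append((col, s.group, s.assay, s.replicate))
    pd.DataFrame(samples, columns=["sample", "group", "assay", "replicate"]).to_csv(
        outdir / "samples.tsv", sep="\t", index=False
    )

    demo_cfg = {
        "annotation": "annotation.gtf",
        "rna_counts": "rna_counts.tsv",
        "ribo_bed": {s: f"footprints/{s}.bed" for s in read_counts(paths["ribo_counts"]).columns},
        "gmt": "sets.gmt",
        "sample_sheet": "samples.tsv",
        "outdir": "results",
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "options": {**DEFAULT_OPTIONS, "seed": seed},
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(demo_cfg, sort_keys=True))
    return cfg_path
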
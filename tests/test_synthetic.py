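"""Generator invariants: structure, determinism, conservation, recovery."""

import numpy as np
import pandas as pd
import pytest

from ribojoint import (
    SimulationConfig,
    assign_footprints,
    generate_annotation,
    generate_truth,
    length_histogram,
    region_ratios,
    simulate_counts,
    simulate_dataset,
    simulate_footprints,
    true_class,
)
from ribojoint.io import write_gtf, GTF_HEADER


class TestAnnotation:
    def test_models_are_wellformed_and_nonoverlapping(self):
        models = generate_annotation(50, cds_mean=900, seed=3)
        assert len(models) == 50
        for m in models:
            assert m.cds_len % 3 == 0
            assert m.total_len == m.utr5_len + m.cds_len + m.utr3_len
        ordered = sorted(models, key=lambda m: m.tx_start)
        assert all(
            a.tx_end < b.tx_start for a, b in zip(ordered, ordered[1:])
        )

    def test_empty_annotation(self, tmp_path):
        path = tmp_path / "empty.gtf"
        models = generate_annotation(0, seed=1, gtf_path=path)
        assert models == []
        assert path.read_text() == GTF_HEADER

    def test_seed_determinism_byte_identical_gtf(self, tmp_path):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        generate_annotation(100, seed=7, gtf_path=p1)
        generate_annotation(100, seed=7, gtf_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_rejects_negative_length_means(self):
        with pytest.raises(ValueError, match="positive"):
            generate_annotation(10, cds_mean=-5)


class TestTruth:
    def test_null_scenario_is_all_class_e(self):
        t = generate_truth(20, 0, 0, 0, 0)
        assert (t["tx_log2fc"] == 0).all()
        assert (t["te_log2fc"] == 0).all()
        assert (t["true_class"] == "E").all()

    def test_exact_effect_allocation(self):
        t = generate_truth(100, frac_tx_up=0.1, frac_tx_down=0, frac_te_up=0,
                           frac_te_down=0, tx_effect=2.0, seed=5)
        assert (t["tx_log2fc"] == 2.0).sum() == 10
        assert (t["tx_log2fc"] == 0).sum() == 90

    def test_effect_groups_are_disjoint(self):
        t = generate_truth(200, 0.1, 0.1, 0.1, 0.1, seed=2)
        both = (t["tx_log2fc"] != 0) & (t["te_log2fc"] != 0)
        assert not both.any()
        assert (t["tx_log2fc"] > 0).sum() == 20
        assert (t["te_log2fc"] < 0).sum() == 20

    def test_seed_determinism(self):
        a = generate_truth(50, 0.1, 0.1, 0.1, 0.1, seed=9)
        b = generate_truth(50, 0.1, 0.1, 0.1, 0.1, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_fractions_over_one(self):
        with pytest.raises(ValueError, match="sum"):
            generate_truth(10, 0.5, 0.5, 0.5, 0.0)

    @pytest.mark.parametrize(
        "tx,te,expected",
        [
            (0, 0, "E"),
            (0, 3, "B"),       # TE-only up: translatome up, transcriptome ns
            (0, -3, "H"),
            (2, 0, "C"),       # transcriptional up propagates to the translatome
            (-2, 0, "G"),
            (2, -5, "I"),      # opposing effects, translation wins downward
            (-2, 5, "A"),
            (2, -2, "F"),      # TE exactly cancels the ribo change
            (-2, 2, "D"),
        ],
    )
    def test_true_class_mapping(self, tx, te, expected):
        assert true_class(tx, te) == expected


class TestCounts:
    def test_zero_base_expression_gives_zero_counts(self):
        cfg = SimulationConfig(n_genes=5, n_reps=2, seed=1)
        ann = generate_annotation(5, seed=1)
        truth = generate_truth(5, 0, 0, 0, 0, seed=1)
        truth.loc[truth.index[0], "base_expression"] = 0.0
        rna, ribo = simulate_counts(truth, ann, cfg)
        assert (rna.iloc[0] == 0).all()
        assert (ribo.iloc[0] == 0).all()

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_genes=30, n_reps=2, seed=4)
        ann, truth, rna1, ribo1 = simulate_dataset(cfg)
        _, _, rna2, ribo2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(rna1, rna2)
        pd.testing.assert_frame_equal(ribo1, ribo2)

    def test_rejects_negative_dispersion(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimulationConfig(n_genes=5, dispersion=-0.1)

    def test_te_effect_recovery_at_low_dispersion(self):
        # At near-zero dispersion and transcriptome-scale effect composition,
        # the empirical group TE shift converges to the generative te_log2fc.
        cfg = SimulationConfig(
            n_genes=10000, n_reps=2, dispersion=1e-6, lib_size=5e6,
            frac_tx_up=0, frac_tx_down=0, frac_te_up=0.02, frac_te_down=0.02,
            te_effect=2.0, seed=9,
        )
        from ribojoint import compute_rpkm, compute_te

        ann, truth, rna, ribo = simulate_dataset(cfg)
        lengths = pd.Series({m.gene_id: m.total_len for m in ann}, dtype=float)
        te = compute_te(compute_rpkm(ribo, lengths), compute_rpkm(rna, lengths))
        lt = np.log2(te.where(te > 0))
        cols_b = [c for c in te.columns if c.startswith("B")]
        cols_m = [c for c in te.columns if c.startswith("M")]
        shift = lt[cols_b].mean(axis=1) - lt[cols_m].mean(axis=1)
        up = truth["te_log2fc"] == 2.0
        assert up.sum() == 200
        assert abs(shift[up].mean() - 2.0) < 0.1


@pytest.fixture(scope="module")
def small():
    cfg = SimulationConfig(n_genes=40, n_reps=2, lib_size=2e5, seed=6)
    ann, truth, rna, ribo = simulate_dataset(cfg)
    return cfg, ann, ribo


class TestFootprints:

    def test_record_count_conservation(self, small):
        cfg, ann, ribo = small
        sample = "M_ribo_1"
        fps = simulate_footprints(ribo, ann, cfg, sample)
        assert len(fps) == ribo[sample].sum()
        per_gene = pd.Series([f.gene_id for f in fps]).value_counts()
        for gene, n in ribo[sample].items():
            assert per_gene.get(gene, 0) == n

    def test_degenerate_region_mix_all_cds(self, small):
        cfg, ann, ribo = small
        cfg_cds = SimulationConfig(
            n_genes=cfg.n_genes, n_reps=2, lib_size=2e5, seed=6,
            region_mix=(0.0, 1.0, 0.0),
        )
        fps = simulate_footprints(ribo, ann, cfg_cds, "B_ribo_1")
        _, tally = assign_footprints(fps, ann, offset=cfg_cds.psite_offset)
        assert tally.cds == len(fps)
        assert tally.utr5 == tally.utr3 == tally.unassigned == 0

    def test_bed_output_deterministic(self, small, tmp_path):
        cfg, ann, ribo = small
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        simulate_footprints(ribo, ann, cfg, "M_ribo_2", bed_path=p1)
        simulate_footprints(ribo, ann, cfg, "M_ribo_2", bed_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_overlong_footprints_are_redrawn(self, caplog):
        from ribojoint.models import TranscriptModel

        tiny = TranscriptModel("g1", "chr1", "+", 1000, utr5_len=0, cds_len=30, utr3_len=0)
        counts = pd.DataFrame({"M_ribo_1": [50]}, index=pd.Index(["g1"], name="gene_id"))
        cfg = SimulationConfig(
            n_genes=1, seed=0,
            length_dist={29: 0.5, 45: 0.5},  # 45 nt cannot fit a 30 nt transcript
            region_mix=(0.0, 1.0, 0.0),
        )
        with caplog.at_level("WARNING", logger="ribojoint.synthetic"):
            fps = simulate_footprints(counts, [tiny], cfg, "M_ribo_1")
        assert len(fps) == 50  # conservation despite redraws
        assert all(f.length == 29 for f in fps)
        assert any("longer than transcript" in r.message for r in caplog.records)

    def test_modal_length_and_region_recovery_at_scale(self):
        # 1e5 footprints: mode must sit at 31 nt and the empirical region
        # proportions within 2 points of the configured mixture.
        cfg = SimulationConfig(seed=3)
        ann = generate_annotation(500, seed=3)
        counts = pd.DataFrame(
            {"M_ribo_1": np.full(500, 200)},
            index=pd.Index([m.gene_id for m in ann], name="gene_id"),
        )
        fps = simulate_footprints(counts, ann, cfg, "M_ribo_1")
        assert len(fps) == 100000
        _, mode = length_histogram(fps)
        assert mode == 31
        _, tally = assign_footprints(fps, ann, offset=cfg.psite_offset)
        ratios = region_ratios(tally)
        for region, expected in zip(("utr5", "cds", "utr3"), cfg.region_mix):
            assert abs(ratios[region] - 100 * expected) < 2.0
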
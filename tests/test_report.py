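"""Population summaries, the purity screen, and the end-to-end pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import rohscan as rs
from rohscan.genotypes import MISSING

from conftest import make_matrix


def summary_row(population, mean_count):
    return pd.Series({"population": population, "roh_count_mean": mean_count})


class TestPurityCall:
    @pytest.mark.parametrize(
        "mean_count, verdict",
        [
            (63.9, "purebred-like"),   # deeply inbred fancy-breed profile
            (4.3, "crossbred-like"),   # two-way F1 profile
            (10.0, "indeterminate"),   # between the screen thresholds
            (20.0, "indeterminate"),   # boundaries are strict
            (6.0, "indeterminate"),
        ],
    )
    def test_screen_thresholds(self, mean_count, verdict):
        call = rs.purity_call(summary_row("X", mean_count))
        assert call.call == verdict
        assert call.mean_roh_count == mean_count


class TestSummarize:
    def test_single_population_single_row(self, default_panel_roh):
        g, truth, segments, froh = default_panel_roh
        keep = [s.sample_id for s in g.samples if s.population == "BR1"]
        sub = g.subset(sample_keep=keep)
        segs = [x for x in segments if x.sample_id in set(keep)]
        fr = [x for x in froh if x.sample_id in set(keep)]
        table = rs.summarize(sub, segs, fr)
        assert len(table) == 1
        assert table.loc[0, "population"] == "BR1"
        assert table.loc[0, "n"] == len(keep)

    def test_inbred_exceeds_its_f1_cross(self, default_panel_roh):
        g, truth, segments, froh = default_panel_roh
        table = rs.summarize(g, segments, froh).set_index("population")
        for col in ("roh_count_mean", "roh_length_kb_mean", "froh_mean"):
            assert table.loc["BR1", col] > table.loc["BR1xBR2", col]
            assert table.loc["BR2", col] > table.loc["BR1xBR2", col]

    def test_population_without_roh_reports_zeros(self, default_panel_roh):
        g, truth, segments, froh = default_panel_roh
        table = rs.summarize(g, segments, froh).set_index("population")
        row = table.loc["BR3x(BR1xBR2)"]  # three-way F1: no ROH at all
        assert row["roh_count_mean"] == 0.0
        assert row["roh_length_kb_mean"] == 0.0
        assert row["froh_mean"] == 0.0

    def test_all_defaults_screen_cleanly(self, default_panel_roh):
        # the headline in-silico claim: every purebred line screens
        # differently from every F1 cross on the default panel
        g, truth, segments, froh = default_panel_roh
        table = rs.summarize(g, segments, froh)
        purity = rs.purity_table(table).set_index("population")
        for pop in ("BR1", "BR2", "BR3", "BR4"):
            assert purity.loc[pop, "call"] != "crossbred-like"
        for pop in ("BR1xBR2", "BR3xBR4", "BR3x(BR1xBR2)"):
            assert purity.loc[pop, "call"] == "crossbred-like"

    def test_invariant_to_sample_order(self, default_panel_roh):
        g, truth, segments, froh = default_panel_roh
        table = rs.summarize(g, segments, froh)
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_samples)
        g2 = rs.GenotypeMatrix(
            [g.samples[i] for i in perm], g.snps, g.calls[perm]
        )
        table2 = rs.summarize(g2, segments, froh)
        pd.testing.assert_frame_equal(table, table2)

    def test_orphan_samples_rejected(self, default_panel_roh):
        g, truth, segments, froh = default_panel_roh
        labels = g.population_map()
        labels.pop(g.sample_ids[0])
        with pytest.raises(KeyError, match=g.sample_ids[0]):
            rs.summarize(g, segments, froh, labels=labels)


class TestRunPipeline:
    CONFIG = {
        "simulate": {
            "breeds": [
                {"name": "B1", "n_founders": 4, "n_generations": 8,
                 "census_size": 12},
                {"name": "B2", "n_founders": 4, "n_generations": 8,
                 "census_size": 12},
            ],
            "crosses": [
                {"name": "B1xB2", "expression": "B1 x B2", "n_offspring": 8}
            ],
            "n_chrom": 2,
            "chrom_length_bp": 20_000_000,
            "snp_spacing_bp": 25_000,
            "seed": 5,
        },
    }

    def test_end_to_end_artifacts_and_determinism(self, tmp_path):
        res1 = rs.run_pipeline(self.CONFIG, tmp_path / "run1")
        for fname in (
            "panel.ped",
            "qc_report.tsv",
            "roh_segments.tsv",
            "froh.tsv",
            "ld_pairs.tsv",
            "ibs_distances.tsv",
            "mds_coordinates.tsv",
            "fst_matrix.tsv",
            "nj_tree.nwk",
            "population_summary.tsv",
            "purity_calls.tsv",
            "run_log.txt",
        ):
            assert (tmp_path / "run1" / fname).exists(), fname
        log = (tmp_path / "run1" / "run_log.txt").read_text()
        assert "seed 5" in log and "finished" in log

        res2 = rs.run_pipeline(self.CONFIG, tmp_path / "run2")
        for fname in ("population_summary.tsv", "froh.tsv", "fst_matrix.tsv"):
            assert (tmp_path / "run1" / fname).read_bytes() == (
                tmp_path / "run2" / fname
            ).read_bytes()
        pd.testing.assert_frame_equal(res1["summary"], res2["summary"])

    def test_yaml_config_accepted(self, tmp_path):
        import yaml

        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(self.CONFIG))
        res = rs.run_pipeline(cfg_path, tmp_path / "run")
        assert set(res["summary"]["population"]) == {"B1", "B2", "B1xB2"}

    def test_qc_toggle_controls_low_maf_snp(self, tmp_path):
        # a rare-variant SNP (maf 0.01) survives only when QC is disabled
        rng = np.random.default_rng(2)
        n = 50
        cols = []
        for j in range(30):
            p = rng.uniform(0.3, 0.7)
            cols.append(
                (rng.random(n) < p).astype(int) + (rng.random(n) < p).astype(int)
            )
        rare = np.zeros(n, dtype=int)
        rare[0] = 1  # 1 of 100 alleles
        calls = np.column_stack(cols + [rare])
        g = make_matrix(
            calls,
            populations=["P1"] * 25 + ["P2"] * 25,
            chroms=["1"] * 16 + ["2"] * 15,
        )
        rs.write_genotypes(g, tmp_path / "in", format="bed")
        base = {
            "input": {"path_prefix": str(tmp_path / "in"), "format": "bed"},
            "roh": {"min_snps": 5, "min_length_kb": 2,
                    "min_density_kb_per_snp": 5000, "window_snps": 4},
        }
        rare_id = g.snps[-1].snp_id
        with_qc = rs.run_pipeline(base | {"qc": {"enabled": True}},
                                  tmp_path / "qc_on")
        without_qc = rs.run_pipeline(base | {"qc": {"enabled": False}},
                                     tmp_path / "qc_off")

        def ld_snps(res):
            out = set()
            for pop_res in res["ld"].values():
                out |= set(pop_res.pairs["snp_a"]) | set(pop_res.pairs["snp_b"])
            return out

        assert rare_id not in ld_snps(with_qc)
        assert rare_id in ld_snps(without_qc)

    def test_failure_names_the_stage(self, tmp_path):
        cfg = {"input": {"path_prefix": str(tmp_path / "missing")}}
        with pytest.raises(RuntimeError, match="stage load"):
            rs.run_pipeline(cfg, tmp_path / "run")
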
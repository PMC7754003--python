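"""Simulator contracts: read anatomy, error injection rates, determinism."""

import gzip
import math

import numpy as np
import pysam
import pytest

from abscount.simulate import (
    CASE_SUBPOPS,
    CONTROL_SUBPOPS,
    SimulationConfig,
    simulate_cohort,
    simulate_label_depths,
    simulate_run,
)
from abscount.whitelists import UMI_START


def small_config(**kw):
    defaults = dict(n_cells=50, n_noise_labels=0, seed=4)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def read_fastq(path):
    with pysam.FastxFile(str(path)) as fh:
        return [(r.name, r.sequence, r.quality) for r in fh]


class TestReadAnatomy:
    def test_single_read_per_molecule_matches_truth_sum(
        self, whitelists, sim_panel, tmp_path
    ):
        cfg = small_config(reads_per_molecule=1)
        r1, r2, gt = simulate_run(cfg, whitelists, sim_panel, tmp_path)
        reads = read_fastq(r1)
        assert len(reads) == gt.truth_matrix.values.sum()
        assert len(reads) == len(read_fastq(r2))

    def test_fixed_reads_per_molecule_multiplies(
        self, whitelists, sim_panel, tmp_path
    ):
        cfg = small_config(reads_per_molecule=5)
        r1, _, gt = simulate_run(cfg, whitelists, sim_panel, tmp_path)
        assert len(read_fastq(r1)) == 5 * gt.truth_matrix.values.sum()

    def test_r1_layout(self, whitelists, sim_panel, tmp_path):
        cfg = small_config(n_cells=5)
        r1, _, gt = simulate_run(cfg, whitelists, sim_panel, tmp_path)
        true_seqs = {
            whitelists.label_sequence(lab) for lab in gt.true_cell_labels
        }
        for _, seq, qual in read_fastq(r1):
            assert len(seq) == cfg.r1_length
            assert seq[:52] in true_seqs
            assert seq[UMI_START + 8 :] == "T" * 10
            assert set(qual) == {chr(30 + 33)}

    def test_r2_is_feature_substring(self, whitelists, sim_panel, tmp_path):
        cfg = small_config(n_cells=5)
        _, r2, _ = simulate_run(cfg, whitelists, sim_panel, tmp_path)
        seqs = [f.sequence for f in sim_panel.countable_features]
        for _, seq, _ in read_fastq(r2):
            assert len(seq) >= 61
            assert any(seq in fs for fs in seqs)


class TestErrorInjection:
    def test_cls_substitution_rate_binomial(self, whitelists, sim_panel, tmp_path):
        cfg = small_config(n_cells=100, cls_substitution_rate=0.05, seed=8)
        r1, _, gt = simulate_run(cfg, whitelists, sim_panel, tmp_path)
        n = gt.n_reads
        n_err = sum(
            1 for e in gt.error_ledger if "cls_substitution" in e["errors"]
        )
        sd = math.sqrt(n * 0.05 * 0.95)
        assert abs(n_err - 0.05 * n) <= 3 * sd

    def test_low_quality_fraction_gets_bad_phred(
        self, whitelists, sim_panel, tmp_path
    ):
        cfg = small_config(n_cells=20, bad_read_fraction=0.3, seed=9)
        r1, _, gt = simulate_run(cfg, whitelists, sim_panel, tmp_path)
        bad_ids = {
            e["read_id"] for e in gt.error_ledger if "low_quality" in e["errors"]
        }
        assert bad_ids
        for name, _, qual in read_fastq(r1):
            expected = chr(15 + 33) if name in bad_ids else chr(30 + 33)
            assert set(qual) == {expected}

    def test_ambient_decoy_requires_decoy_in_panel(
        self, whitelists, sim_panel, tmp_path
    ):
        cfg = small_config(ambient_decoy_rate=0.1)
        with pytest.raises(ValueError, match="decoy"):
            simulate_run(cfg, whitelists, sim_panel, tmp_path)

    def test_decoy_reads_emitted(self, whitelists, toy_panel, tmp_path):
        cfg = small_config(n_cells=50, ambient_decoy_rate=0.2, seed=10)
        _, r2, gt = simulate_run(cfg, whitelists, toy_panel, tmp_path)
        decoy_ids = {
            e["read_id"] for e in gt.error_ledger if "ambient_decoy" in e["errors"]
        }
        assert decoy_ids
        decoy_seq = toy_panel.feature_by_name("phiX174").sequence
        for name, seq, _ in read_fastq(r2):
            if name in decoy_ids:
                assert seq in decoy_seq


class TestDeterminism:
    def test_same_seed_byte_identical(self, whitelists, sim_panel, tmp_path):
        cfg = small_config(n_cells=20, cls_substitution_rate=0.02)
        a = tmp_path / "a"
        b = tmp_path / "b"
        r1a, r2a, _ = simulate_run(cfg, whitelists, sim_panel, a)
        r1b, r2b, _ = simulate_run(cfg, whitelists, sim_panel, b)
        assert r1a.read_bytes() == r1b.read_bytes()
        assert r2a.read_bytes() == r2b.read_bytes()

    def test_noise_labels_disjoint_from_cells(self, whitelists, sim_panel, tmp_path):
        cfg = small_config(n_cells=30, n_noise_labels=300)
        _, _, gt = simulate_run(
            cfg, whitelists, sim_panel, tmp_path, emit_fastq=False
        )
        assert not (set(gt.noise_labels) & set(gt.true_cell_labels))
        assert len(set(gt.noise_labels)) == 300

    def test_truth_files_roundtrip(self, whitelists, sim_panel, tmp_path):
        cfg = small_config(n_cells=10)
        _, _, gt = simulate_run(cfg, whitelists, sim_panel, tmp_path)
        paths = gt.write(tmp_path)
        assert all(p.exists() for p in paths.values())


class TestConfigValidation:
    def test_rates_bounded(self):
        with pytest.raises(ValueError):
            SimulationConfig(cls_substitution_rate=1.2)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(subpop_proportions={"a": 0.5, "b": 0.4})

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cells=0)


class TestCohort:
    def test_shifted_subpopulations_within_sampling_error(
        self, whitelists, sim_panel, tmp_path
    ):
        case = SimulationConfig(
            n_cells=2000, n_noise_labels=0,
            subpop_proportions={"0": 0.30, "rest": 0.70}, seed=31,
        )
        ctrl = SimulationConfig(
            n_cells=2000, n_noise_labels=0,
            subpop_proportions={"0": 0.09, "rest": 0.91}, seed=32,
        )
        res = simulate_cohort(
            case, ctrl, whitelists, sim_panel, tmp_path, emit_fastq=False
        )
        df = res["assignments"]
        for group, p in (("case", 0.30), ("control", 0.09)):
            sub = df[df.group == group]
            frac = (sub.cluster == "0").mean()
            se = math.sqrt(p * (1 - p) / 2000)
            assert abs(frac - p) <= 3 * se

    def test_identical_configs_fold_change_near_one(
        self, whitelists, sim_panel, tmp_path
    ):
        cfg_a = SimulationConfig(
            n_cells=1500, n_noise_labels=0,
            subpop_proportions={"0": 0.5, "1": 0.5}, seed=41,
        )
        cfg_b = SimulationConfig(
            n_cells=1500, n_noise_labels=0,
            subpop_proportions={"0": 0.5, "1": 0.5}, seed=42,
        )
        res = simulate_cohort(
            cfg_a, cfg_b, whitelists, sim_panel, tmp_path, emit_fastq=False
        )
        df = res["assignments"]
        p_case = (df[df.group == "case"].cluster == "0").mean()
        p_ctrl = (df[df.group == "control"].cluster == "0").mean()
        assert p_case / p_ctrl == pytest.approx(1.0, abs=0.15)

    def test_single_subpopulation_all_assigned(self, whitelists, sim_panel, tmp_path):
        cfg = SimulationConfig(n_cells=100, n_noise_labels=0, seed=5)
        _, _, gt = simulate_run(
            cfg, whitelists, sim_panel, tmp_path, emit_fastq=False
        )
        assert set(gt.subpop_of_cell.values()) == {"0"}

    def test_default_cohort_proportions_sum(self):
        assert sum(CASE_SUBPOPS.values()) == pytest.approx(1.0)
        assert sum(CONTROL_SUBPOPS.values()) == pytest.approx(1.0)


class TestLabelDepths:
    def test_counts_and_determinism(self):
        a, true_a = simulate_label_depths(100, (5.0, 0.3), 400, (2.0, 0.5), seed=3)
        b, _ = simulate_label_depths(100, (5.0, 0.3), 400, (2.0, 0.5), seed=3)
        assert a == b
        assert len(a) == 500 and len(true_a) == 100
        assert all(v >= 1 for v in a.values())
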
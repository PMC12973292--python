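"""Simulator contracts: kinetic closed forms, monotonicity, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from afdip.io_quant import write_peptide_table
from afdip.simulate import (
    SimConfig,
    expected_cog,
    export_ground_truth,
    interval_yields,
    read_config,
    read_ground_truth,
    simulate_conc_mode,
    simulate_time_mode,
    write_config,
)
from afdip.timecourse import center_of_gravity

HOURS = tuple(range(1, 9))


class TestIntervalYields:
    def test_half_life_one_hour_is_geometric(self):
        y = interval_yields(math.log(2), HOURS)
        assert y == pytest.approx([2.0 ** -(j + 1) for j in range(8)])
        assert center_of_gravity(HOURS, y) == pytest.approx(1.9686, abs=1e-4)

    def test_conservation(self):
        """Noiseless yields over the course sum to A(1 - exp(-k t_n))."""
        for k in (0.05, 0.3, 1.7):
            y = interval_yields(k, HOURS, amplitude=2.5)
            assert y.sum() == pytest.approx(2.5 * (1 - math.exp(-8 * k)))

    def test_delta_cog_decreasing_in_protection_factor(self):
        """Slower digestion (rho < 1) shifts CoG later; the noiseless shift is
        strictly decreasing in rho and crosses zero at rho = 1."""
        k = 0.6
        rhos = [0.2, 0.5, 0.8, 1.0, 1.5, 2.5]
        shifts = [expected_cog(rho * k, HOURS) - expected_cog(k, HOURS) for rho in rhos]
        assert all(a > b for a, b in zip(shifts, shifts[1:]))
        assert shifts[rhos.index(1.0)] == pytest.approx(0.0, abs=1e-12)
        assert shifts[0] > 0 > shifts[-1]


class TestSimulateTimeMode:
    def test_protected_shift_positive_without_noise(self):
        cfg = SimConfig(
            n_proteins=10, peptides_per_protein=4, target_fraction=0.3,
            noise_sigma=0.0, missing_rate=0.0, seed=3,
        )
        records, design, truth = simulate_time_mode(cfg)
        label = truth.label_of()
        grid = np.array(cfg.time_grid)
        for rec in records:
            chans = design.channels_for("control", 1)
            cog_c = center_of_gravity(grid, [rec.intensities[e.channel] for e in chans])
            chans = design.channels_for("treated", 1)
            cog_t = center_of_gravity(grid, [rec.intensities[e.channel] for e in chans])
            if label[rec.sequence] == "protected":
                assert cog_t > cog_c
            elif label[rec.sequence] == "flexibilized":
                assert cog_t < cog_c
            else:
                assert cog_t == pytest.approx(cog_c, abs=1e-9)

    def test_same_seed_identical_tables(self, tmp_path):
        cfg = SimConfig(n_proteins=5, seed=42)
        for run in ("a", "b"):
            records, design, _ = simulate_time_mode(cfg)
            write_peptide_table(records, design, tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_labels_partition_and_match_config(self):
        cfg = SimConfig(n_proteins=30, peptides_per_protein=8, target_fraction=0.1,
                        protected_per_target=3, flexibilized_per_target=2, seed=9)
        _, _, truth = simulate_time_mode(cfg)
        counts = truth.peptides.label.value_counts()
        n_targets = truth.proteins.is_target.sum()
        assert n_targets == 3
        assert counts.get("protected", 0) == 3 * n_targets
        assert counts.get("flexibilized", 0) == 2 * n_targets
        assert set(truth.peptides.label) <= {"null", "protected", "flexibilized"}
        # treated rate differs from control exactly on affected peptides
        affected = truth.peptides.label != "null"
        assert (truth.peptides.k_control != truth.peptides.k_treated).equals(affected)

    def test_missing_rate_produces_gaps(self):
        cfg = SimConfig(n_proteins=20, peptides_per_protein=5, missing_rate=0.3, seed=1)
        records, design, _ = simulate_time_mode(cfg)
        n_cells = len(records) * len(design.channels)
        observed = sum(len(r.intensities) for r in records)
        assert 0.6 < observed / n_cells < 0.8


class TestSimulateConcMode:
    def test_vehicle_channel_equals_untreated_expectation(self):
        cfg = SimConfig(n_proteins=5, peptides_per_protein=2, target_fraction=0.5,
                        noise_sigma=0.0, missing_rate=0.0, seed=4)
        records, design, truth = simulate_conc_mode(cfg)
        label = truth.label_of()
        k_of = dict(zip(truth.peptides.sequence, truth.peptides.k_control))
        amp_of = dict(zip(truth.peptides.sequence, truth.peptides.amplitude))
        t_dig = cfg.digestion_time_conc_mode
        for rec in records:
            vehicle = [e for e in design.channels_for("treated", 1) if e.axis_value == 0]
            val = rec.intensities[vehicle[0].channel]
            expect = amp_of[rec.sequence] * (1 - math.exp(-k_of[rec.sequence] * t_dig))
            assert val == pytest.approx(expect, rel=1e-9)

    def test_protected_monotone_decreasing_without_noise(self):
        cfg = SimConfig(n_proteins=10, peptides_per_protein=3, target_fraction=0.3,
                        noise_sigma=0.0, missing_rate=0.0, seed=8)
        records, design, truth = simulate_conc_mode(cfg)
        label = truth.label_of()
        chans = design.channels_for("treated", 1)
        for rec in records:
            series = [rec.intensities[e.channel] for e in chans]
            if label[rec.sequence] == "protected":
                assert all(a > b for a, b in zip(series[1:], series[2:]))
            elif label[rec.sequence] == "null":
                assert np.ptp(series) == pytest.approx(0.0, abs=1e-9 * max(series))


class TestNullRunFalsePositives:
    def test_bonferroni_hits_absent_in_95_percent_of_null_runs(self):
        """Under the global null ~95% of full-pipeline runs should yield zero
        Bonferroni-corrected protein hits.  With 20 runs the claim is
        rejected only if hit-runs exceed the one-sided binomial bound
        (P(X >= 4 | n=20, p=0.05) < 0.02)."""
        from afdip.model import TimeCourseAFDIP

        runs_with_hits = 0
        for seed in range(100, 120):
            cfg = SimConfig(
                n_proteins=200, peptides_per_protein=5, target_fraction=0.0,
                noise_sigma=0.1, n_replicates=3, missing_rate=0.0, seed=seed,
            )
            model, _ = TimeCourseAFDIP.from_simulation(cfg)
            results = model.fit()
            if (results.proteins.bonferroni_p < 0.05).any():
                runs_with_hits += 1
        assert runs_with_hits <= 3


class TestGroundTruthIO:
    def test_round_trip(self, tmp_path):
        _, _, truth = simulate_time_mode(SimConfig(n_proteins=4, seed=0))
        path = tmp_path / "truth.tsv"
        export_ground_truth(truth, path)
        back = read_ground_truth(path)
        pd.testing.assert_frame_equal(back, truth.peptides)

    def test_config_round_trip(self, tmp_path):
        cfg = SimConfig(n_proteins=7, peptides_per_protein=(3, 6), seed=13,
                        time_grid=(1.0, 2.0, 4.0, 8.0))
        path = tmp_path / "config.txt"
        write_config(cfg, path)
        assert read_config(path) == cfg
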
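"""Planted-truth calibration and determinism of the synthetic generator."""

import json

import numpy as np
import pandas as pd
import pytest

from oescreen.cognition import normalize_scores
from oescreen.core_stats import spearman_rho, welch_t
from oescreen.de import run_de
from oescreen.io_model import DOMAINS
from oescreen.qpcr import fit_all_curves, quantify_relative
from oescreen.synthetic import (
    GroundTruth,
    SimulationParams,
    emit_fixture,
    simulate_cohort,
    simulate_expression_pair,
    simulate_qpcr_plate,
    spearman_to_pearson,
)


class TestCohort:
    def test_fixed_seed_reproducible(self, small_params):
        s1, n1 = simulate_cohort(small_params, seed=5)
        s2, n2 = simulate_cohort(small_params, seed=5)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(n1, n2)

    def test_composite_is_mean_of_domains(self, cohort):
        _, neuro = cohort
        np.testing.assert_allclose(neuro["composite"],
                                   neuro[list(DOMAINS)].mean(axis=1),
                                   atol=1e-9)

    def test_null_pattern_gives_equal_group_means(self):
        """With no group effect the composite difference averages to zero."""
        flat = {d: (10.0, 2.0, 10.0, 2.0) for d in DOMAINS}
        params = SimulationParams(domain_pattern=flat, sex_effect=0.0,
                                  education_effect=0.0, n_probes=10,
                                  n_de_probes=0, n_cognition_linked=0,
                                  n_coregulated_pairs=0)
        diffs = []
        for rep in range(120):
            s, n = simulate_cohort(params, seed=rep)
            sz = n.loc[s["group"] == "SZ", "composite"].mean()
            ct = n.loc[s["group"] == "control", "composite"].mean()
            diffs.append(sz - ct)
        # mean diff ~ N(0, sd/sqrt(reps)); composite sd ~ 1.5
        assert abs(np.mean(diffs)) < 3 * 1.5 / np.sqrt(120 * 31 / 4)

    def test_group_deficit_power_matches_design_effect(self, small_params):
        """Composite deficit d ~ 0.84 at 16/15 gives Welch power near 0.63."""
        hits = 0
        reps = 250
        for rep in range(reps):
            s, n = simulate_cohort(small_params, seed=10_000 + rep)
            a = n.loc[s["group"] == "SZ", "composite"]
            b = n.loc[s["group"] == "control", "composite"]
            hits += welch_t(a, b).p_value < 0.05
        power = hits / reps
        assert 0.45 <= power <= 0.80


class TestExpression:
    def test_planted_fold_change_unbiased(self):
        """Realized log2 group differences track the planted shifts."""
        params = SimulationParams(n_probes=40, n_de_probes=20,
                                  n_cognition_linked=0, n_coregulated_pairs=0,
                                  fc_range=(2.0, 2.0))
        errs = []
        for rep in range(200):
            s, n = simulate_cohort(params, seed=rep)
            oe, _, truth = simulate_expression_pair(params, s, n, seed=rep)
            de = run_de(oe, s).set_index("probe_id")
            for probe, fc in truth.de_fold_changes.items():
                planted = np.log2(abs(fc)) * np.sign(fc)
                realized = (de.loc[probe, "mean_log2_sz"]
                            - de.loc[probe, "mean_log2_ctrl"])
                errs.append(realized - planted)
        assert abs(np.mean(errs)) < 0.05

    def test_planted_rho_realized_in_band(self, small_params):
        """Planted cognition links land within [0.5, 0.85] at n=16."""
        params = SimulationParams(n_probes=60, n_de_probes=5,
                                  n_cognition_linked=14, rho_range=(0.7, 0.7),
                                  n_coregulated_pairs=0)
        in_band = total = 0
        for rep in range(25):
            s, n = simulate_cohort(params, seed=500 + rep)
            oe, _, truth = simulate_expression_pair(params, s, n, seed=500 + rep)
            z = normalize_scores(n, s).z
            sz = z.index.tolist()
            idx = [oe.sample_ids.index(x) for x in sz]
            for probe, info in truth.cognition_links.items():
                x = oe.values[oe.probe_ids.index(probe), idx]
                r = abs(spearman_rho(x, z[info["domain"]].to_numpy()))
                in_band += 0.5 <= r <= 0.85
                total += 1
        assert in_band / total >= 0.90

    def test_coregulated_pairs_exceed_cutoff(self, small_params, cohort):
        s, n = cohort
        oe, _, truth = simulate_expression_pair(small_params, s, n, seed=11)
        pos = {p: i for i, p in enumerate(oe.probe_ids)}
        for a, b, r_target in truth.coregulated_pairs:
            r = np.corrcoef(oe.values[pos[a]], oe.values[pos[b]])[0, 1]
            assert abs(r) >= 0.75
            assert np.sign(r) == np.sign(r_target)

    def test_paired_lb_has_no_planted_effects(self, small_params, cohort):
        """Candidate probes stay FDR-insignificant in the null lymphoblasts."""
        s, n = cohort
        clean = total = 0
        for rep in range(30):
            s, n = simulate_cohort(small_params, seed=900 + rep)
            _, lb, truth = simulate_expression_pair(small_params, s, n,
                                                    seed=900 + rep)
            lb_groups = {sid: g for sid, g in zip(s["sample_id"], s["group"])
                         if sid in lb.sample_ids}
            de = run_de(lb, lb_groups).set_index("probe_id")
            planted = (set(truth.de_fold_changes)
                       | set(truth.cognition_links))
            clean += (de.loc[sorted(planted), "q_value"] >= 0.05).all()
            total += 1
        assert clean / total >= 0.95

    def test_spearman_pearson_conversion(self):
        assert spearman_to_pearson(0.0) == 0.0
        assert spearman_to_pearson(0.7) == pytest.approx(0.7167, abs=1e-4)


class TestQpcr:
    def test_zero_noise_recovers_truth_exactly(self, small_params, cohort):
        s, _ = cohort
        params = SimulationParams(qpcr_ct_noise_sd=0.0,
                                  qpcr_standard_noise_sd=0.0)
        plate, truth = simulate_qpcr_plate(params, s, seed=3)
        curves = fit_all_curves(plate)
        for g, c in curves.items():
            assert c.slope == pytest.approx(params.qpcr_slope, abs=1e-9)
            assert c.r_squared == pytest.approx(1.0, abs=1e-12)
        rel = quantify_relative(plate, curves)
        for _, row in rel.iterrows():
            expected = truth.qpcr_sample_ratio[row["gene"]][row["sample_id"]]
            assert row["ratio"] == pytest.approx(expected, abs=1e-9)

    def test_fixed_seed_identical_plate(self, small_params, cohort):
        s, _ = cohort
        p1, _ = simulate_qpcr_plate(small_params, s, seed=9)
        p2, _ = simulate_qpcr_plate(small_params, s, seed=9)
        pd.testing.assert_frame_equal(p1.measurements, p2.measurements)
        pd.testing.assert_frame_equal(p1.standards, p2.standards)


class TestEmit:
    def test_fixture_files_and_manifest(self, fixture_dir):
        names = {p.name for p in fixture_dir.iterdir()}
        assert {"expression_oe.tsv", "expression_lb_paired.tsv",
                "expression_lb_nonpaired.tsv", "samples.tsv", "neuropsych.tsv",
                "gene_map.tsv", "qpcr_measurements.tsv", "qpcr_standards.tsv",
                "ground_truth.json", "manifest.json"} <= names
        manifest = json.loads((fixture_dir / "manifest.json").read_text())
        assert manifest["seed"] == 11
        truth = GroundTruth.from_json(fixture_dir / "ground_truth.json")
        assert len(truth.de_fold_changes) == 30

    def test_same_seed_byte_identical(self, small_params, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        emit_fixture(small_params, d1, seed=21)
        emit_fixture(small_params, d2, seed=21)
        for p in sorted(d1.iterdir()):
            assert p.read_bytes() == (d2 / p.name).read_bytes(), p.name

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SimulationParams(n_probes=5, n_de_probes=10)
        with pytest.raises(ValueError):
            SimulationParams(qpcr_slope=1.0)
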
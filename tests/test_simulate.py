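"""Synthetic cohort generator: determinism, planted-signal recovery, outcomes."""

import json

import numpy as np
import pytest

from dyssync.curves import ALL_KINDS, MeasurementKind, SegmentId
from dyssync.metrics import FEATURE_COLUMNS, compute_features, global_strain
from dyssync.simulate import (
    CohortConfig,
    DEFAULT_PHENOTYPES,
    PhenotypeSpec,
    generate_cohort,
    generate_curve,
    generate_outcomes,
    simulate_cohort,
    simulate_ventricle,
    solve_baseline_hazard,
)


def _phenotype(**overrides) -> PhenotypeSpec:
    base = dict(
        name="test", mixing=1.0, ttp_sd_ms=0.0, wall_delay_ms=0.0,
        base_apex_delay_ms=0.0, gcs_pct=-15.0, grs_pct=22.0,
        edvi=(100.0, 10.0), ef=(55.0, 5.0), qrs=(100.0, 10.0),
        age=(15.0, 5.0), male_prob=0.5,
        morphology_probs={"LV": 1.0, "RV": 0.0, "mixed": 0.0}, hazard_ratio=1.0,
    )
    base.update(overrides)
    return PhenotypeSpec(**base)


class TestCurveGeneration:
    def test_synchrony_limit_gives_zero_metrics(self):
        rng = np.random.default_rng(0)
        ds = simulate_ventricle("s", _phenotype(), 80.0, 5, rng,
                                rel_noise=0.0, subject_scatter=0.0,
                                amplitude_scatter=0.0)
        feats = compute_features(ds)
        for col in FEATURE_COLUMNS:
            assert feats.metrics[col] == pytest.approx(0.0, abs=1e-6)

    def test_planted_wall_delay_recovered_noise_free(self):
        rng = np.random.default_rng(1)
        spec = _phenotype(wall_delay_ms=60.0, ttp_sd_ms=0.0)
        ds = simulate_ventricle("s", spec, 82.0, 6, rng, rel_noise=0.0,
                                subject_scatter=0.0, amplitude_scatter=0.0)
        feats = compute_features(ds)
        for kind in ALL_KINDS:
            assert feats.metrics[f"mowd_{kind.abbrev}"] == pytest.approx(60.0, abs=1.0)

    def test_planted_base_apex_delay_recovered(self):
        rng = np.random.default_rng(2)
        spec = _phenotype(base_apex_delay_ms=45.0)
        ds = simulate_ventricle("s", spec, 75.0, 7, rng, rel_noise=0.0,
                                subject_scatter=0.0, amplitude_scatter=0.0)
        feats = compute_features(ds)
        assert feats.metrics["bad_cs"] == pytest.approx(45.0, abs=1.0)

    def test_planted_dispersion_recovered_within_ten_percent(self):
        rng = np.random.default_rng(3)
        spec = _phenotype(ttp_sd_ms=60.0)
        ds = simulate_ventricle("s", spec, 82.0, 7, rng, rel_noise=0.0,
                                subject_scatter=0.0, amplitude_scatter=0.0)
        feats = compute_features(ds)
        assert ds.n_segments == 42
        assert feats.metrics["sdttp_cs"] == pytest.approx(60.0, rel=0.10)

    def test_amplitude_sets_global_strain(self):
        rng = np.random.default_rng(4)
        ds = simulate_ventricle("s", _phenotype(), 80.0, 5, rng, rel_noise=0.0,
                                subject_scatter=0.0, amplitude_scatter=0.0)
        assert global_strain(ds, MeasurementKind.CIRC_STRAIN) == pytest.approx(-15.0, abs=0.1)
        assert global_strain(ds, MeasurementKind.RAD_STRAIN) == pytest.approx(22.0, abs=0.15)

    def test_generate_curve_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            generate_curve(MeasurementKind.CIRC_STRAIN, SegmentId(0, 1), 0.0,
                           -15.0, 80.0, -0.1, np.random.default_rng(0))

    def test_strain_rate_is_consistent_with_strain_timing(self):
        rng = np.random.default_rng(5)
        ds = simulate_ventricle("s", _phenotype(), 80.0, 4, rng, rel_noise=0.0,
                                subject_scatter=0.0, amplitude_scatter=0.0)
        from dyssync.metrics import time_to_peak

        strain_ttp = time_to_peak(ds.curve(MeasurementKind.CIRC_STRAIN, SegmentId(0, 1)))
        rate_ttp = time_to_peak(ds.curve(MeasurementKind.CIRC_STRAIN_RATE, SegmentId(0, 1)))
        # systolic rate peak precedes the strain peak by a quarter bump width
        L = ds.cycle_length_ms
        assert strain_ttp - rate_ttp == pytest.approx(0.175 * L, abs=3.0)


class TestOutcomes:
    def test_baseline_hazard_hits_target_event_fraction(self):
        lam = solve_baseline_hazard(DEFAULT_PHENOTYPES, 0.115, 12.0)
        rng = np.random.default_rng(0)
        labels = 1 + rng.choice(4, size=10_000,
                                p=[p.mixing for p in DEFAULT_PHENOTYPES])
        event, follow = generate_outcomes(
            labels, [p.hazard_ratio for p in DEFAULT_PHENOTYPES], lam, 12.0, rng)
        assert event.mean() == pytest.approx(0.115, abs=0.02)
        assert (follow >= 0).all()

    def test_event_rate_ratio_matches_planted_hazard(self):
        rng = np.random.default_rng(1)
        n = 100_000
        labels = np.r_[np.ones(n // 2, int), np.full(n // 2, 4)]
        event, follow = generate_outcomes(labels, [1.0, 1.0, 1.0, 6.4], 0.01,
                                          12.0, rng)
        rate1 = event[labels == 1].sum() / follow[labels == 1].sum()
        rate4 = event[labels == 4].sum() / follow[labels == 4].sum()
        assert rate4 / rate1 == pytest.approx(6.4, rel=0.05)

    def test_invalid_hazards_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            generate_outcomes(np.array([1]), [0.0], 0.01, 12.0, rng)
        with pytest.raises(ValueError):
            generate_outcomes(np.array([1]), [1.0], -0.5, 12.0, rng)


class TestCohort:
    def test_default_sizes(self, default_cohort):
        groups = [r.group for r in default_cohort.records]
        assert groups.count("fontan") == 512
        assert groups.count("control") == 42

    def test_controls_come_from_synchronous_phenotypes(self, default_cohort):
        controls = [(r, l) for r, l in
                    zip(default_cohort.records, default_cohort.planted_labels)
                    if r.group == "control"]
        assert controls and all(l in (1, 2) for _, l in controls)
        assert all(r.morphology == "control_LV" and r.event == 0 for r, _ in controls)

    def test_same_seed_reproduces_cohort(self):
        cfg = CohortConfig(n_patients=6, n_controls=2, seed=99)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert [r.subject_id for r in a.records] == [r.subject_id for r in b.records]
        np.testing.assert_array_equal(a.planted_labels, b.planted_labels)
        for da, db in zip(a.datasets, b.datasets):
            for kind in ALL_KINDS:
                np.testing.assert_array_equal(da.values[kind], db.values[kind])
        assert a.records == b.records

    def test_different_seed_changes_curves(self):
        a = simulate_cohort(CohortConfig(n_patients=3, n_controls=0, seed=1))
        b = simulate_cohort(CohortConfig(n_patients=3, n_controls=0, seed=2))
        assert not np.array_equal(
            a.datasets[0].values[MeasurementKind.CIRC_STRAIN],
            b.datasets[0].values[MeasurementKind.CIRC_STRAIN])

    def test_generate_cohort_writes_files_and_echo(self, tmp_path):
        cfg = CohortConfig(n_patients=4, n_controls=2, seed=7)
        paths = generate_cohort(cfg, tmp_path)
        assert paths["curves"].exists() and paths["subjects"].exists()
        echo = json.loads(paths["echo"].read_text())
        assert echo["seed"] == 7 and len(echo["planted_labels"]) == 6
        from dyssync.curves import read_cohort

        datasets, records = read_cohort(paths["curves"], paths["subjects"])
        assert len(records) == 6
        slices = {d.n_slices for d in datasets}
        assert slices <= set(range(4, 9))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(event_fraction=0.0)
        with pytest.raises(ValueError):
            CohortConfig(rel_noise=-1.0)
        bad = list(DEFAULT_PHENOTYPES)
        bad[0] = _phenotype(mixing=0.9)
        with pytest.raises(ValueError):
            CohortConfig(phenotypes=tuple(bad))
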
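import numpy as np
import pytest

from strokemrs.core import ppm_to_index
from strokemrs.preprocess import normalize_cohort
from strokemrs.simulate import (
    PeakSpec,
    SimConfig,
    default_config,
    lognormal_from_median_iqr,
    lorentzian,
    simulate_cohort,
    simulate_spectrum,
)


class TestLognormalParameterization:
    def test_median_and_quartile_ratio_roundtrip(self):
        mu, sigma = lognormal_from_median_iqr(5.0, 3.0, 8.0)
        z = 0.6744897501960817
        assert np.exp(mu) == pytest.approx(5.0)
        assert np.exp(2 * z * sigma) == pytest.approx(8.0 / 3.0)

    def test_sampled_median_converges(self):
        mu, sigma = lognormal_from_median_iqr(19.88, 10.38, 22.11)
        r = np.random.default_rng(0)
        samples = np.exp(r.normal(mu, sigma, 200_000))
        assert np.median(samples) == pytest.approx(19.88, rel=0.02)

    def test_invalid_quartiles_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_median_iqr(5.0, 8.0, 3.0)


class TestDefaultConfig:
    @pytest.mark.parametrize("scenario", ["infarct_evolution", "brain_regions"])
    def test_three_classes_and_targets(self, scenario):
        cfg = default_config(scenario)
        assert len(cfg.class_labels) == 3
        assert cfg.n_points == 1383
        assert cfg.water_amplitude > 0
        assert len(cfg.diagnostic_targets) == 3

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            default_config("lesion_load")

    def test_control_noiseless_norm_is_100(self):
        """The calibration pins the noiseless control spectrum at norm 100,
        which is what contralateral self-normalization enforces."""
        from strokemrs.simulate import _noiseless_spectrum

        for scenario in ("infarct_evolution", "brain_regions"):
            cfg = default_config(scenario)
            s = _noiseless_spectrum(cfg, cfg.class_labels[0])
            assert np.linalg.norm(s) == pytest.approx(100.0, rel=1e-3)


class TestSimulateSpectrum:
    def _single_peak_config(self):
        peak = PeakSpec("TCr", 3.03, "lorentzian", 0.05)
        peak.amplitudes = {"non_infarcted": (np.log(5.0), 0.0)}
        return SimConfig(
            scenario="infarct_evolution",
            class_labels=["non_infarcted"],
            peaks=[peak],
            class_sizes=(4,),
            noise_sd=0.0,
            shift_jitter_sd=0.0,
            baseline_amplitude=0.0,
            mm_amplitude=0.0,
            water_amplitude=0.0,
            water_sigma=0.0,
        )

    def test_noiseless_peak_maximum_at_center(self):
        cfg = self._single_peak_config()
        rec = simulate_spectrum("non_infarcted", cfg, np.random.default_rng(0))
        assert int(np.argmax(rec.intensities)) == ppm_to_index(cfg.axis, 3.03)
        assert rec.intensities.max() == pytest.approx(5.0, rel=0.01)

    def test_same_seed_identical(self):
        cfg = default_config("infarct_evolution", seed=3)
        a = simulate_spectrum("acute", cfg, np.random.default_rng(42))
        b = simulate_spectrum("acute", cfg, np.random.default_rng(42))
        assert np.array_equal(a.intensities, b.intensities)

    def test_empirical_medians_match_targets(self):
        """Post-UL2CA class medians at the diagnostic datapoints sit within
        15% of the configured targets (Monte-Carlo calibration check)."""
        cfg = default_config("infarct_evolution", seed=0)
        rng = np.random.default_rng(99)
        axis = cfg.axis
        n = 300
        for cls in cfg.class_labels:
            cols = {ppm: np.empty(n) for _, ppm, _ in cfg.diagnostic_targets}
            for i in range(n):
                s = simulate_spectrum(cls, cfg, rng)
                ref = simulate_spectrum(cfg.class_labels[0], cfg, rng)
                v = 100.0 * s.intensities / np.linalg.norm(ref.intensities)
                for _, ppm, _ in cfg.diagnostic_targets:
                    cols[ppm][i] = v[ppm_to_index(axis, ppm)]
            for _, ppm, per_class in cfg.diagnostic_targets:
                target = per_class[cls][0]
                assert np.median(cols[ppm]) == pytest.approx(target, rel=0.15)


class TestSimulateCohort:
    def test_study_sized_cohort(self):
        cfg = default_config("infarct_evolution", seed=1)
        cohort = simulate_cohort(cfg)
        assert len(cohort) == 82
        assert cohort.class_sizes() == {"non_infarcted": 48, "acute": 20, "subacute": 14}

    def test_every_record_has_reference(self):
        cfg = default_config("brain_regions", seed=2, class_sizes=(10, 14, 6))
        cohort = simulate_cohort(cfg)
        ids = {r.spectrum_id for r in cohort.records}
        for r in cohort.records:
            assert cohort.contralateral_map[r.spectrum_id] in ids

    def test_split_is_chronological_and_balanced(self):
        cfg = default_config("infarct_evolution", seed=1)
        cohort = simulate_cohort(cfg)
        train = cohort.subset("train")
        frac = len(train) / len(cohort)
        assert 0.55 < frac < 0.8
        max_train = max(float(r.animal_id) for r in train.records)
        min_test = min(float(r.animal_id) for r in cohort.subset("test").records)
        assert max_train < min_test

    def test_same_seed_reproducible(self):
        cfg = default_config("infarct_evolution", seed=9, class_sizes=(6, 4, 3))
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.intensities, rb.intensities)

    def test_different_seeds_differ(self):
        a = simulate_cohort(default_config("infarct_evolution", seed=1, class_sizes=(6, 4, 3)))
        b = simulate_cohort(default_config("infarct_evolution", seed=2, class_sizes=(6, 4, 3)))
        assert not np.array_equal(a.records[0].intensities, b.records[0].intensities)

    def test_normalized_controls_have_norm_100(self):
        cfg = default_config("infarct_evolution", seed=4, class_sizes=(8, 5, 4))
        cohort = simulate_cohort(cfg)
        normalized, reports = normalize_cohort(cohort)
        for r in normalized.records:
            if cohort.contralateral_map[r.spectrum_id] == r.spectrum_id:
                assert np.linalg.norm(r.intensities) == pytest.approx(100.0)
        assert all(rep.norm_constant > 0 for rep in reports)
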
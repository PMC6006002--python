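"""Cohort generation, measurement simulation, oracle, and the voxel phantom."""

import numpy as np
import pytest

from prrtdose import (CohortConfig, DomainError, LU177_LAMBDA_H, PhantomGrid,
                      default_phantom, generate_cohort, misreg_recovery_error,
                      patient_rng, run_course, simulate_course_samples,
                      simulate_measurements, true_dose)


class TestGenerateCohort:
    def test_same_seed_identical_cohorts(self):
        config = CohortConfig(n_patients=6, seed=5)
        assert generate_cohort(config) == generate_cohort(config)

    def test_patient_identity_independent_of_cohort_size(self):
        small = generate_cohort(CohortConfig(n_patients=3, seed=5))
        large = generate_cohort(CohortConfig(n_patients=10, seed=5))
        assert small == large[:3]

    def test_cycle_counts_within_range(self):
        cohort = generate_cohort(CohortConfig(n_patients=24, seed=1))
        total = sum(p.n_cycles for p in cohort)
        assert 24 <= total <= 96
        assert all(1 <= p.n_cycles <= 4 for p in cohort)

    def test_lambda_never_below_physical_bound(self):
        cohort = generate_cohort(CohortConfig(n_patients=1000, seed=2))
        for patient in cohort:
            for kin in patient.kinetics.values():
                assert kin.lambda_eff >= LU177_LAMBDA_H

    def test_invalid_config_rejected(self):
        with pytest.raises(DomainError):
            CohortConfig(n_patients=0)
        with pytest.raises(DomainError):
            CohortConfig(cycles_range=(0, 4))
        with pytest.raises(DomainError):
            CohortConfig(noise_sd=-0.1)

    def test_patient_rng_is_reproducible(self):
        a = patient_rng(9, 3).random(4)
        b = patient_rng(9, 3).random(4)
        assert np.array_equal(a, b)


class TestSimulateMeasurements:
    def test_zero_noise_samples_lie_on_true_curve(self, noiseless_cohort):
        patient = noiseless_cohort[0]
        rng = np.random.default_rng(0)
        samples = simulate_measurements(patient, 1, "classical", rng,
                                        noise_sd=0.0, blood_noise_sd=0.0,
                                        perturbation_sd=0.0)
        for s in samples:
            assert s.conc == pytest.approx(
                patient.true_conc(s.organ, 1, s.time_h), rel=1e-12)

    def test_cycle1_schedule(self, noiseless_cohort):
        samples = simulate_measurements(
            noiseless_cohort[0], 1, "classical", np.random.default_rng(0))
        organ_times = {s.time_h for s in samples if s.organ != "blood"}
        blood_times = {s.time_h for s in samples if s.organ == "blood"}
        assert organ_times == {18.0, 25.0, 168.0}
        assert blood_times == {18.0, 25.0}

    def test_later_cycle_single_time_point(self):
        cohort = generate_cohort(CohortConfig(n_patients=8, seed=3))
        patient = next(p for p in cohort if p.n_cycles >= 2)
        samples = simulate_measurements(patient, 2, "classical",
                                        np.random.default_rng(0))
        assert {s.time_h for s in samples} == {20.0}
        assert sum(s.organ == "blood" for s in samples) == 1

    def test_fixed_perturbation_biases_organs_not_blood(self, noiseless_cohort):
        patient = next(p for p in noiseless_cohort if p.n_cycles >= 2)
        samples = simulate_measurements(
            patient, 2, "single_ct", np.random.default_rng(0),
            noise_sd=0.0, blood_noise_sd=0.0, perturbation_factor=1.06)
        for s in samples:
            truth = patient.true_conc(s.organ, 2, s.time_h)
            expected = truth if s.organ == "blood" else truth * 1.06
            assert s.conc == pytest.approx(expected, rel=1e-12)

    def test_cycle1_unperturbed_under_single_ct(self, noiseless_cohort):
        patient = noiseless_cohort[0]
        samples = simulate_measurements(
            patient, 1, "single_ct", np.random.default_rng(0),
            noise_sd=0.0, blood_noise_sd=0.0, perturbation_factor=1.06)
        for s in samples:
            assert s.conc == pytest.approx(
                patient.true_conc(s.organ, 1, s.time_h), rel=1e-12)

    def test_unknown_cycle_rejected(self, noiseless_cohort):
        patient = noiseless_cohort[0]
        with pytest.raises(Exception):
            simulate_measurements(patient, patient.n_cycles + 1, "classical",
                                  np.random.default_rng(0))


class TestTrueDoseOracle:
    def test_single_organ_hand_computation(self, table):
        from prrtdose.synthetic import OrganKinetics, TruePatient
        patient = TruePatient(
            patient_id="HAND", sex="male",
            kinetics={"kidneys": OrganKinetics(c0=300.0, lambda_eff=0.012),
                      "liver": OrganKinetics(c0=1e-12, lambda_eff=0.01),
                      "spleen": OrganKinetics(c0=1e-12, lambda_eff=0.01),
                      "remainder": OrganKinetics(c0=1e-12, lambda_eff=0.01),
                      "tumor": OrganKinetics(c0=1e-12, lambda_eff=0.01),
                      "blood": OrganKinetics(c0=1e-12, lambda_eff=0.01)},
            voi_mass_kg={"kidneys": 0.3, "liver": 1.8, "spleen": 0.2,
                         "tumor": 0.1},
            a_adm_MBq=[7400.0])
        doses = true_dose(patient, table)
        t_r = 300.0 * 3600 / (0.012 * 7400)
        s_self = table.get("kidneys", "kidneys").value
        expected = 7400 * t_r * s_self * table.phantom_mass_kg("kidneys")
        assert doses[0]["kidneys"] == pytest.approx(expected, rel=1e-9)

    def test_linear_in_administered_activity(self, noiseless_cohort, table):
        patient = noiseless_cohort[0]
        doubled = type(patient)(
            patient_id="X2", sex=patient.sex, kinetics=patient.kinetics,
            voi_mass_kg=patient.voi_mass_kg,
            a_adm_MBq=[2 * a for a in patient.a_adm_MBq])
        base = true_dose(patient, table)
        scaled = true_dose(doubled, table)
        for d0, d1 in zip(base, scaled):
            for organ in d0:
                assert d1[organ] == pytest.approx(2 * d0[organ], rel=1e-12)

    def test_pipeline_equals_oracle_on_noiseless_data(self, noiseless_cohort,
                                                      table):
        patient = noiseless_cohort[2]
        samples = simulate_course_samples(patient, "classical", 0,
                                          noise_sd=0.0, blood_noise_sd=0.0,
                                          perturbation_sd=0.0)
        voi = {c: dict(patient.voi_mass_kg)
               for c in range(1, patient.n_cycles + 1)}
        a_adm = {c: patient.a_adm_MBq[c - 1]
                 for c in range(1, patient.n_cycles + 1)}
        course = run_course(samples, voi, a_adm, table)
        oracle = true_dose(patient, table)
        for rec, truth in zip(course.cycles, oracle):
            for organ, dose in rec.dose_mGy.items():
                assert dose == pytest.approx(truth[organ], rel=1e-6)


class TestRecoveryUnderNoise:
    def test_kidney_dose_recovery_at_5pct_noise(self, table):
        # 200 patients, 5% SPECT noise: small median error, near-zero bias
        cohort = generate_cohort(CohortConfig(n_patients=200, seed=11))
        errors = []
        for patient in cohort:
            samples = simulate_course_samples(patient, "classical",
                                              1000 + patient.seed,
                                              noise_sd=0.05,
                                              perturbation_sd=0.0)
            voi = {c: dict(patient.voi_mass_kg)
                   for c in range(1, patient.n_cycles + 1)}
            a_adm = {c: patient.a_adm_MBq[c - 1]
                     for c in range(1, patient.n_cycles + 1)}
            with np.errstate(all="ignore"):
                course = run_course(samples, voi, a_adm, table,
                                    patient_id=patient.patient_id)
            oracle = true_dose(patient, table)
            n = len(course.cycles)
            est = sum(r.dose_mGy["kidneys"] for r in course.cycles)
            truth = sum(d["kidneys"] for d in oracle[:n])
            errors.append((est - truth) / truth)
        errors = np.asarray(errors)
        assert np.median(np.abs(errors)) < 0.10
        assert abs(errors.mean()) < 0.02

    def test_small_perturbation_gives_better_concordance_than_large(self, table):
        # ordering property: 6% single-CT perturbation disturbs management
        # decisions less than a 50% perturbation, over seeded cohorts
        def discordance(perturbation_sd, n_cohorts=100):
            total = 0
            for c in range(n_cohorts):
                cohort = generate_cohort(CohortConfig(n_patients=24,
                                                      seed=3000 + c))
                decisions = {"classical": [], "single_ct": []}
                for patient in cohort:
                    for protocol in ("classical", "single_ct"):
                        samples = simulate_course_samples(
                            patient, protocol, 500 + patient.seed + 100 * c,
                            noise_sd=0.05,
                            perturbation_sd=perturbation_sd)
                        voi = {cy: dict(patient.voi_mass_kg)
                               for cy in range(1, patient.n_cycles + 1)}
                        a_adm = {cy: patient.a_adm_MBq[cy - 1]
                                 for cy in range(1, patient.n_cycles + 1)}
                        course = run_course(samples, voi, a_adm, table)
                        decisions[protocol].append(course.final_decision)
                total += sum(x != y for x, y in zip(decisions["classical"],
                                                   decisions["single_ct"]))
            return total

        assert discordance(0.06) < discordance(0.50)


@pytest.fixture(scope="module")
def phantom():
    return default_phantom()


class TestMisregistrationPhantom:
    def test_zero_shift_zero_error(self, phantom):
        assert misreg_recovery_error(phantom, 0.0, "fixed_voi") == 0.0
        assert misreg_recovery_error(phantom, 0.0, "threshold_voi") == 0.0

    def test_zero_shift_no_blur_fixed_voi(self):
        sharp = PhantomGrid(blur_fwhm_mm=0.0)
        assert misreg_recovery_error(sharp, 0.0, "fixed_voi") == 0.0

    def test_fixed_voi_error_magnitude_nondecreasing(self, phantom):
        errors = [abs(misreg_recovery_error(phantom, s, "fixed_voi"))
                  for s in (2.0, 6.0, 10.0, 20.0)]
        assert errors == sorted(errors)
        assert errors[-1] > 0.0  # strictly positive at 20 mm

    def test_threshold_voi_more_robust_at_large_shifts(self, phantom):
        for shift in (6.0, 10.0, 20.0):
            fixed = abs(misreg_recovery_error(phantom, shift, "fixed_voi"))
            thresh = abs(misreg_recovery_error(phantom, shift,
                                               "threshold_voi"))
            assert thresh <= fixed

    def test_threshold_voi_matches_bruteforce_voxel_sum(self, phantom):
        # oracle: explicit per-voxel loops replaced by direct summation
        for shift in (0.0, 10.0):
            vol = phantom.shifted_map(shift)
            mask = vol >= 0.5 * vol.max()
            expected = vol[mask].sum() / mask.sum()
            ref_vol = phantom.shifted_map(0.0)
            ref_mask = ref_vol >= 0.5 * ref_vol.max()
            ref = ref_vol[ref_mask].sum() / ref_mask.sum()
            assert misreg_recovery_error(phantom, shift, "threshold_voi"
                                         ) == pytest.approx(
                (expected - ref) / ref, abs=1e-12)

    def test_shift_outside_grid_rejected(self, phantom):
        with pytest.raises(DomainError):
            misreg_recovery_error(phantom, 1000.0, "fixed_voi")

    def test_non_voxel_multiple_shift_interpolates(self, phantom):
        err = misreg_recovery_error(phantom, 3.0, "fixed_voi")
        lo = misreg_recovery_error(phantom, 2.0, "fixed_voi")
        hi = misreg_recovery_error(phantom, 4.0, "fixed_voi")
        assert min(lo, hi) - 1e-6 <= err <= max(lo, hi) + 1e-6
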
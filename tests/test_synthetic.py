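"""Synthetic generator: determinism, ground-truth fidelity, recovery bounds."""

import numpy as np
import pytest

from tonguecolor.colorimetry import LabColor, ciede2000, rgb_to_lab
from tonguecolor.comparison import compare_patient, summarize_cohort, PositionMeasurement
from tonguecolor.biometrics import pearson_r
from tonguecolor.segmentation import region_mean_lab
from tonguecolor.synthetic import (
    DEFAULT_REGION_COLORS,
    AssociationSpec,
    CohortSpec,
    GamutError,
    TongueShapeParams,
    generate_paired_cohort,
    generate_tongue_image,
    lab_displacement_for_de00,
    slope_for_target_r,
)

SMALL_SHAPE = TongueShapeParams(height=40, width=30)


class TestGenerateTongueImage:
    def test_noiseless_pixels_round_trip_to_region_color(self):
        img, _, part = generate_tongue_image(
            DEFAULT_REGION_COLORS, SMALL_SHAPE, pixel_noise_sd=0.0, seed=0
        )
        edge_lab = rgb_to_lab(img[part.region_mask("edge")])
        target = np.asarray(DEFAULT_REGION_COLORS["edge"])
        assert np.max(np.abs(edge_lab - target)) <= 0.01

    def test_same_seed_bit_identical(self):
        a, _, _ = generate_tongue_image(DEFAULT_REGION_COLORS, SMALL_SHAPE, seed=5)
        b, _, _ = generate_tongue_image(DEFAULT_REGION_COLORS, SMALL_SHAPE, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_out_of_gamut_region_color_names_region(self):
        bad = dict(DEFAULT_REGION_COLORS, apex=LabColor(50.0, 120.0, -120.0))
        with pytest.raises(GamutError, match="apex"):
            generate_tongue_image(bad, SMALL_SHAPE, seed=0)

    def test_region_mean_recovery_rate_across_replicates(self):
        """3*sigma/sqrt(N) per-channel bound holds in >=99% of replicates."""
        sigma = 2.0
        shape = TongueShapeParams(height=80, width=60)
        ok = 0
        total = 0
        for seed in range(100):
            img, _, part = generate_tongue_image(
                DEFAULT_REGION_COLORS, shape, pixel_noise_sd=sigma, seed=seed
            )
            n = int(part.region_mask("edge").sum())
            got = np.asarray(region_mean_lab(img, part, "edge"))
            true = np.asarray(DEFAULT_REGION_COLORS["edge"])
            bound = 3 * sigma / np.sqrt(n) + 0.02  # + conversion round-off
            total += 3
            ok += int(np.sum(np.abs(got - true) <= bound))
        assert ok / total >= 0.99


class TestLabDisplacement:
    def test_displacement_hits_requested_distance(self, rng):
        base = LabColor(42.9, 27.1, 5.3)
        for target in (0.5, 1.0, 2.34, 4.1, 6.8):
            d = rng.normal(size=3)
            shift = lab_displacement_for_de00(base, tuple(d), target)
            moved = LabColor(*(np.asarray(base) + shift))
            assert ciede2000(base, moved).dE00 == pytest.approx(target, abs=1e-8)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            lab_displacement_for_de00(LabColor(50, 20, 5), (0, 0, 0), 2.0)


class TestGeneratePairedCohort:
    def test_determinism_full_bundle(self):
        spec = CohortSpec(n_patients=3, shape=SMALL_SHAPE, seed=42)
        a = generate_paired_cohort(spec)
        b = generate_paired_cohort(spec)
        for pid in a.images:
            for pos in ("sitting", "supine"):
                np.testing.assert_array_equal(a.images[pid][pos], b.images[pid][pos])
        assert a.biometrics.equals(b.biometrics)
        assert a.truth == b.truth

    def test_truth_distance_matches_recorded_colors(self):
        cohort = generate_paired_cohort(
            CohortSpec(n_patients=5, shape=SMALL_SHAPE, seed=3)
        )
        for t in cohort.truth:
            d = ciede2000(t.sitting_edge, t.supine_edge).dE00
            assert d == pytest.approx(t.true_dE00, abs=1e-8)

    def test_noiseless_pipeline_recovers_true_de00(self):
        """Noise-free cohort: recovered dE00 within 0.02 of the truth."""
        cohort = generate_paired_cohort(
            CohortSpec(n_patients=6, pixel_noise_sd=0.0, seed=9)
        )
        for t in cohort.truth:
            imgs = cohort.images[t.patient_id]
            sit = region_mean_lab(imgs["sitting"], cohort.partition, "edge")
            sup = region_mean_lab(imgs["supine"], cohort.partition, "edge")
            rec = ciede2000(sit, sup).dE00
            assert rec == pytest.approx(t.true_dE00, abs=0.02)

    def test_end_to_end_recovery_bound_at_default_noise(self):
        """|recovered - true| dE00 <= 0.2 in >=95% of seeded replicates
        (sigma = 2, edge region > 2000 px)."""
        hits = 0
        total = 0
        for seed in (101, 202):
            cohort = generate_paired_cohort(CohortSpec(n_patients=10, seed=seed))
            assert cohort.partition.region_sizes()["edge"] >= 2000
            for t in cohort.truth:
                imgs = cohort.images[t.patient_id]
                sit = region_mean_lab(imgs["sitting"], cohort.partition, "edge")
                sup = region_mean_lab(imgs["supine"], cohort.partition, "edge")
                rec = ciede2000(sit, sup).dE00
                total += 1
                hits += int(abs(rec - t.true_dE00) <= 0.2)
        assert hits / total >= 0.95

    def test_cohort_tuned_to_study_conditions_reproduces_split_on_truths(self):
        """Default spec draws ~14/18 below 4.1 on the recorded truths."""
        below = []
        for seed in range(30):
            cohort = generate_paired_cohort(
                CohortSpec(n_patients=18, shape=SMALL_SHAPE, seed=seed)
            )
            below.append(sum(t.true_dE00 < 4.1 for t in cohort.truth))
        assert 12 <= np.mean(below) <= 16  # centered near the 14/18 condition

    def test_association_slope_zero_keeps_r_small(self):
        """Null association: |r| stays within the n=18 null sampling
        distribution, for which P(|r| < 0.4) = 0.90 exactly (t transform,
        16 df); assert above a 3-sigma binomial lower bound."""
        ok = 0
        n_rep = 100
        for seed in range(n_rep):
            cohort = generate_paired_cohort(
                CohortSpec(
                    n_patients=18,
                    shape=SMALL_SHAPE,
                    association=AssociationSpec("fpg", slope=0.0, noise_sd=25.0,
                                               intercept=117.0),
                    seed=seed,
                )
            )
            r = pearson_r(
                [t.true_dE00 for t in cohort.truth],
                cohort.biometrics["fpg"].tolist(),
            ).value
            ok += int(abs(r) < 0.4)
        assert ok / n_rep >= 0.81  # 0.90 - 3*sqrt(0.9*0.1/100)

    def test_biometrics_table_has_full_schema(self):
        cohort = generate_paired_cohort(CohortSpec(n_patients=2, shape=SMALL_SHAPE, seed=0))
        expected = {"patient_id", "age", "sex", "bmi", "smoking", "cvd_drug",
                    "sbp", "dbp", "tg", "hdl_c", "ldl_c", "hba1c", "fpg"}
        assert expected <= set(cohort.biometrics.columns)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=0)
        with pytest.raises(ValueError):
            CohortSpec(pixel_noise_sd=-1.0)
        with pytest.raises(ValueError):
            CohortSpec(region_colors={"edge": LabColor(42, 26, 5)})


class TestSlopeForTargetR:
    def test_induced_population_r(self):
        b = slope_for_target_r(0.55, value_sd=1.8, noise_sd=20.0)
        implied = b * 1.8 / np.hypot(b * 1.8, 20.0)
        assert implied == pytest.approx(0.55, abs=1e-12)

    def test_injected_association_recovered_across_cohorts(self):
        """r = 0.55 injected at n = 18: the sampling distribution of the
        recovered r over 200 cohorts covers 0.55 in its central 95% range."""
        # lognormal(median 2.34, log-sd 0.73) has sd ~ 2.1 in dE00 units
        shift_sd = float(np.std(np.random.default_rng(0).lognormal(
            np.log(2.34), 0.73, 200_000)))
        slope = slope_for_target_r(0.55, value_sd=shift_sd, noise_sd=25.0)
        rs = []
        for seed in range(200):
            cohort = generate_paired_cohort(
                CohortSpec(
                    n_patients=18,
                    shape=SMALL_SHAPE,
                    association=AssociationSpec("fpg", slope=slope, noise_sd=25.0,
                                               intercept=117.0),
                    seed=seed,
                )
            )
            rs.append(
                pearson_r(
                    [t.true_dE00 for t in cohort.truth],
                    cohort.biometrics["fpg"].tolist(),
                ).value
            )
        lo, hi = np.percentile(rs, [2.5, 97.5])
        assert lo <= 0.55 <= hi
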
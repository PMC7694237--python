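import itertools

import numpy as np
import pytest

from dummyrun import FractionationScheme, GridGeometry, mask_volume_cc
from dummyrun.cohort import (
    CASE_A,
    CASE_S,
    CaseSpec,
    CohortConfig,
    InstitutionParams,
    corrupt_mask,
    default_scheme_pool,
    generate_cohort,
    generate_phantom,
    generate_plan,
    read_cohort,
    write_cohort,
)
from dummyrun.dosimetry import mean_structure_dose

GRID = GridGeometry((96, 96, 96), (2.5, 2.5, 2.5))
COARSE = GridGeometry((48, 48, 48), (5.0, 5.0, 5.0))


def centroid_mm(mask):
    idx = np.argwhere(mask.values)
    sp = np.array(mask.geometry.spacing)
    return idx.mean(axis=0) * sp + np.array(mask.geometry.origin)


class TestPhantom:
    def test_same_seed_is_bit_identical(self):
        a = generate_phantom(CASE_A, COARSE, seed=5)
        b = generate_phantom(CASE_A, COARSE, seed=5)
        for name, mask in a.items():
            assert np.array_equal(mask.values, b[name].values)

    def test_structures_pairwise_disjoint(self):
        s = generate_phantom(CASE_S, COARSE, seed=2)
        for (na, ma), (nb, mb) in itertools.combinations(s.items(), 2):
            assert not (ma.values & mb.values).any(), (na, nb)

    def test_all_structures_present_and_nonempty(self):
        s = generate_phantom(CASE_A, GRID, seed=1)
        for name in ("BREAST", "LUNG_IPSI", "HEART", "ALN_I", "ALN_II", "ALN_III", "SCN", "IMN"):
            assert name in s
            assert mask_volume_cc(s[name]) > 0

    def test_left_sided_heart_is_nearer_the_breast(self):
        a = generate_phantom(CASE_A, GRID, seed=3)
        s = generate_phantom(CASE_S, GRID, seed=3)
        dist_a = np.linalg.norm(centroid_mm(a["HEART"]) - centroid_mm(a["BREAST"]))
        dist_s = np.linalg.norm(centroid_mm(s["HEART"]) - centroid_mm(s["BREAST"]))
        assert dist_s < dist_a

    def test_too_small_grid_rejected(self):
        tiny = GridGeometry((16, 16, 16), (2.5, 2.5, 2.5))
        with pytest.raises(ValueError, match="grid"):
            generate_phantom(CASE_A, tiny, seed=0)

    def test_case_preset_enforced(self):
        with pytest.raises(ValueError):
            CaseSpec("A", "left", "ALND")


def _params(margin=12.5, bump=0.1, imn=False, scheme=None):
    return InstitutionParams(
        institution_id="INST01",
        scheme=scheme or FractionationScheme(50.0, 25),
        margin_mm=margin,
        junction_bump=bump,
        includes_imn=imn,
    )


@pytest.fixture(scope="module")
def anatomy():
    return generate_phantom(CASE_A, GRID, seed=1)


@pytest.fixture(scope="module")
def cohort8():
    return generate_cohort(
        CohortConfig(n_institutions=8, n_imn_institutions=3, grid=COARSE, seed=11)
    )


class TestPlanGeneration:
    def test_wbi_covers_the_breast(self, anatomy):
        config = CohortConfig(dose_noise_sd=0.0)
        plan, _ = generate_plan(anatomy, CASE_A, "WBI", _params(), config, seed=0)
        mean = mean_structure_dose(plan.dose, anatomy["BREAST"])
        assert mean >= 0.95 * plan.scheme.total_dose

    def test_scn_cold_in_wbi_hot_in_rni(self, anatomy):
        config = CohortConfig(dose_noise_sd=0.0)
        p = _params()
        wbi, _ = generate_plan(anatomy, CASE_A, "WBI", p, config, seed=0)
        rni, _ = generate_plan(anatomy, CASE_A, "WBI_RNI", p, config, seed=0)
        scn = anatomy["SCN"]
        rnd_wbi = mean_structure_dose(wbi.dose, scn) / wbi.scheme.total_dose
        rnd_rni = mean_structure_dose(rni.dose, scn) / rni.scheme.total_dose
        assert rnd_wbi < 0.2
        assert rnd_rni > 0.9

    def test_deterministic_given_seed(self, anatomy):
        config = CohortConfig()
        a, _ = generate_plan(anatomy, CASE_A, "WBI_RNI", _params(imn=True), config, seed=7)
        b, _ = generate_plan(anatomy, CASE_A, "WBI_RNI", _params(imn=True), config, seed=7)
        assert np.array_equal(a.dose.values, b.dose.values)

    def test_larger_margin_never_decreases_structure_dose(self, anatomy):
        config = CohortConfig()
        lo, _ = generate_plan(anatomy, CASE_A, "WBI", _params(margin=8.0), config, seed=3)
        hi, _ = generate_plan(anatomy, CASE_A, "WBI", _params(margin=14.0), config, seed=3)
        for name, mask in anatomy.items():
            assert mean_structure_dose(hi.dose, mask) >= mean_structure_dose(lo.dose, mask)

    def test_unknown_arm_rejected(self, anatomy):
        with pytest.raises(ValueError, match="arm"):
            generate_plan(anatomy, CASE_A, "PBI", _params(), CohortConfig(), seed=0)


class TestRaterCorruption:
    def test_empirical_sensitivity_specificity(self):
        anatomy = generate_phantom(CASE_A, GRID, seed=4)
        truth = anatomy["BREAST"]
        rng = np.random.default_rng(0)
        rater = corrupt_mask(truth, 0.95, 0.98, rng)
        tv, rv = truth.values, rater.values
        sens = (rv & tv).sum() / tv.sum()
        spec = (~rv & ~tv).sum() / (~tv).sum()
        assert sens == pytest.approx(0.95, abs=0.01)
        assert spec == pytest.approx(0.98, abs=0.01)


class TestCohortAssembly:
    def test_plan_count_is_institutions_x_cases_x_arms(self, cohort8):
        assert len(cohort8.plans) == 8 * 2 * 2

    def test_imn_inclusion_count_per_case(self, cohort8):
        for case_id in ("A", "S"):
            flags = [
                p.includes_imn
                for p in cohort8.plans
                if p.case_id == case_id and p.arm == "WBI_RNI"
            ]
            assert sum(flags) == 3
        # WBI plans never flag IMN inclusion
        assert not any(p.includes_imn for p in cohort8.plans if p.arm == "WBI")

    def test_scheme_multiset_matches_pool(self, cohort8):
        expanded = [s for s, mult in default_scheme_pool() for _ in range(mult)][:8]
        assigned = sorted(
            (p.scheme.total_dose, p.scheme.n_fractions)
            for p in cohort8.plans
            if p.case_id == "A" and p.arm == "WBI"
        )
        assert assigned == sorted((s.total_dose, s.n_fractions) for s in expanded)

    def test_same_seed_reproduces_doses_bit_exactly(self, cohort8):
        again = generate_cohort(
            CohortConfig(n_institutions=8, n_imn_institutions=3, grid=COARSE, seed=11)
        )
        for p1, p2 in zip(cohort8.plans[:4], again.plans[:4]):
            assert np.array_equal(p1.dose.values, p2.dose.values)

    def test_ground_truth_masks_match_plans(self, cohort8):
        from dummyrun import extract_isodose_mask

        p = cohort8.plans[0]
        key = (p.institution_id, p.case_id, p.arm)
        expected = extract_isodose_mask(p.dose, p.scheme, 0.9)
        assert np.array_equal(
            cohort8.truth.plan_truth[key].isodose_mask.values, expected.values
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_institutions=4, n_imn_institutions=5)
        with pytest.raises(ValueError):
            CohortConfig(rater_sensitivity=0.3)


class TestManifestRoundTrip:
    def test_write_then_read_preserves_plans(self, tmp_path):
        cohort = generate_cohort(
            CohortConfig(n_institutions=3, n_imn_institutions=1, grid=COARSE, seed=5)
        )
        write_cohort(cohort, tmp_path)
        loaded = read_cohort(tmp_path, load_truth=True)
        assert len(loaded.plans) == len(cohort.plans)
        for orig in cohort.plans[:3]:
            got = loaded.plan(orig.institution_id, orig.case_id, orig.arm)
            np.testing.assert_allclose(got.dose.values, orig.dose.values, rtol=1e-6)
            assert got.scheme == orig.scheme
        assert loaded.truth is not None
        key = (cohort.plans[0].institution_id, cohort.plans[0].case_id, cohort.plans[0].arm)
        assert key in loaded.truth.plan_truth

    def test_missing_dose_file_error_names_path(self, tmp_path):
        cohort = generate_cohort(
            CohortConfig(n_institutions=2, n_imn_institutions=0, grid=COARSE, seed=6)
        )
        write_cohort(cohort, tmp_path)
        victim = next((tmp_path / "doses").iterdir())
        victim.unlink()
        with pytest.raises(FileNotFoundError, match=victim.name):
            read_cohort(tmp_path)
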
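"""Liebermeister test, lesion maps, power maps and atlas association."""

import itertools

import numpy as np
import pytest
from scipy import integrate, stats

from transsacc.errors import DataError, NotTestableError
from transsacc.lesionsim import (
    LesionCohortSpec,
    generate_lesion_cohort,
    make_synthetic_atlas,
)
from transsacc.vlsm import (
    ContingencyTable,
    label_association,
    liebermeister_test,
    overlap_map,
    power_map,
    subtraction_map,
    vlsm_map,
)


def bayes_oracle(a, b, c, d):
    """P(rate_lesioned <= rate_spared | data) under independent uniform priors.

    rate_lesioned ~ Beta(a+1, c+1) (impairment rate among lesioned),
    rate_spared ~ Beta(b+1, d+1); the probability is E[F_lesioned(theta)]
    over the spared posterior, evaluated by numerical integration.
    """
    f = lambda x: stats.beta.pdf(x, b + 1, d + 1) * stats.beta.cdf(x, a + 1, c + 1)
    val, _ = integrate.quad(f, 0, 1, limit=200, epsabs=1e-12, epsrel=1e-12)
    return val


def fisher_one_sided(a, b, c, d):
    return float(stats.hypergeom(a + b + c + d, a + b, a + c).sf(a - 1))


def all_tables(max_n):
    for a, b, c, d in itertools.product(range(max_n + 1), repeat=4):
        if 2 <= a + b + c + d <= max_n:
            if a + c > 0 and b + d > 0 and a + b > 0 and c + d > 0:
                yield a, b, c, d


class TestLiebermeister:
    def test_concordant_example(self):
        p, z = liebermeister_test(ContingencyTable(3, 0, 0, 3))
        assert p == pytest.approx(1 / 70, abs=1e-12)
        # less conservative than Fisher on the raw table (1/20)
        assert p < fisher_one_sided(3, 0, 0, 3)
        assert z > 0

    def test_balanced_table_uninformative(self):
        p, z = liebermeister_test(ContingencyTable(1, 1, 1, 1))
        assert p == pytest.approx(0.5, abs=1e-12)
        assert z == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelated_table_large_p(self):
        p, z = liebermeister_test(ContingencyTable(0, 3, 3, 0))
        assert p > 0.9 and z < 0

    @pytest.mark.parametrize("table", [(0, 0, 2, 2), (2, 2, 0, 0), (3, 3, 0, 0)])
    def test_degenerate_margins(self, table):
        with pytest.raises(NotTestableError):
            liebermeister_test(ContingencyTable(*table))

    def test_two_sided_at_most_twice_one_sided(self):
        for table in [(4, 0, 1, 3), (1, 3, 4, 0), (2, 2, 1, 3)]:
            p1, _ = liebermeister_test(ContingencyTable(*table), "one_sided")
            p2, _ = liebermeister_test(ContingencyTable(*table), "two_sided")
            assert p2 <= min(1.0, 2 * p1) + 1e-12

    def test_exhaustive_bayes_identity_and_fisher_bound(self):
        # every testable 2x2 table with n <= 12: the augmented
        # hypergeometric tail equals the uniform-prior Bayesian probability
        # and never exceeds Fisher's one-sided p
        for a, b, c, d in all_tables(12):
            p, _ = liebermeister_test(ContingencyTable(a, b, c, d))
            assert p == pytest.approx(bayes_oracle(a, b, c, d), abs=1e-8), (a, b, c, d)
            assert p <= fisher_one_sided(a, b, c, d) + 1e-12, (a, b, c, d)


class TestMaps:
    @staticmethod
    def _tiny_cohort():
        masks = np.zeros((4, 5, 5, 5), dtype=np.uint8)
        masks[0, 1:3, 1:3, 1:3] = 1
        masks[1, 1:4, 1:3, 1:3] = 1
        masks[2, 3:5, 3:5, 3:5] = 1
        masks[3, 0:2, 3:5, 0:2] = 1
        labels = np.array([1, 1, 0, 0])
        return masks, labels

    def test_overlap_single_patient(self):
        masks, _ = self._tiny_cohort()
        assert np.array_equal(overlap_map(masks, [0]), masks[0].astype(np.int32))

    def test_overlap_disjoint_masks(self):
        masks, _ = self._tiny_cohort()
        assert overlap_map(masks, [2, 3]).max() == 1

    def test_overlap_equals_bruteforce_sum(self):
        cohort = generate_lesion_cohort(LesionCohortSpec(), 0)
        expected = np.zeros(cohort.masks.shape[1:], dtype=int)
        for m in cohort.masks:
            expected += m
        assert np.array_equal(overlap_map(cohort.masks), expected)

    def test_subtraction_extremes_and_threshold(self):
        masks, labels = self._tiny_cohort()
        diff = subtraction_map(masks, [0, 1], [2, 3], threshold_pct=15.0)
        assert diff[1, 1, 1] == pytest.approx(100.0)  # both impaired, no unimpaired
        assert diff[4, 4, 4] == pytest.approx(-50.0)  # one unimpaired only
        # antisymmetry under group swap
        swapped = subtraction_map(masks, [2, 3], [0, 1], threshold_pct=15.0)
        assert np.allclose(diff, -swapped)

    def test_subtraction_masks_small_differences(self):
        masks = np.zeros((4, 3, 3, 3), dtype=np.uint8)
        masks[:, 0, 0, 0] = 1  # lesioned in everyone: difference 0
        diff = subtraction_map(masks, [0, 1], [2, 3])
        assert diff[0, 0, 0] == 0.0

    def test_vlsm_min_lesion_masking(self):
        masks, labels = self._tiny_cohort()
        res = vlsm_map(masks, labels, min_lesioned=2)
        count = overlap_map(masks)
        assert not res.included_mask[count < 2].any()
        # the doubly-lesioned impaired-only voxels are the peak
        assert count[res.peak_voxel] >= 2

    def test_vlsm_equal_labels_empty(self):
        masks, _ = self._tiny_cohort()
        res = vlsm_map(masks, np.ones(4, dtype=int))
        assert res.empty and res.peak_voxel is None

    def test_vlsm_permutation_equivariance(self):
        cohort = generate_lesion_cohort(LesionCohortSpec(), 3)
        res = vlsm_map(cohort.masks, cohort.labels)
        perm = np.random.default_rng(0).permutation(cohort.n_patients)
        res_p = vlsm_map(cohort.masks[perm], cohort.labels[perm])
        assert np.array_equal(np.isnan(res.z_map), np.isnan(res_p.z_map))
        assert np.allclose(res.z_map, res_p.z_map, equal_nan=True)
        assert res.peak_voxel == res_p.peak_voxel

    def test_planted_region_recovery(self):
        spec = LesionCohortSpec(impairment_noise=0.0)
        crit = np.array(spec.critical_region)
        hits = 0
        for seed in range(10):
            cohort = generate_lesion_cohort(spec, seed)
            res = vlsm_map(cohort.masks, cohort.labels, affine=cohort.affine)
            dist = np.abs(crit - np.array(res.peak_voxel)).max(axis=1).min()
            hits += dist <= 1
        assert hits >= 9

    def test_label_noise_degrades_recovery_monotonically(self):
        crit = np.array(LesionCohortSpec().critical_region)
        rates = []
        for noise in (0.0, 0.1, 0.3):
            spec = LesionCohortSpec(impairment_noise=noise)
            hits = 0
            for seed in range(10):
                cohort = generate_lesion_cohort(spec, 50 + seed)
                res = vlsm_map(cohort.masks, cohort.labels)
                if res.peak_voxel is not None:
                    hits += np.abs(crit - np.array(res.peak_voxel)).max(axis=1).min() <= 1
            rates.append(hits)
        assert rates[0] >= rates[1] >= rates[2] or (rates[0] >= rates[2])

    def test_power_contains_significant_set(self):
        for seed in range(10):
            cohort = generate_lesion_cohort(LesionCohortSpec(), 200 + seed)
            res = vlsm_map(cohort.masks, cohort.labels)
            assert not (res.significant_mask & ~res.power_map).any()

    def test_fully_lesioned_voxel_unpowered(self):
        masks, labels = self._tiny_cohort()
        masks[:, 2, 2, 2] = 1
        p_min = power_map(masks, labels)
        assert np.isnan(p_min[2, 2, 2])


class TestLabelAssociation:
    def test_perfectly_confounded_label(self):
        # n = 14 with a 7/7 split and lesion status identical to impairment
        masks = np.zeros((14, 4, 4, 4), dtype=np.uint8)
        labels = np.array([1] * 7 + [0] * 7)
        masks[labels == 1, 0, 0, 0] = 1
        masks[labels == 0, 3, 3, 3] = 1
        atlas = np.zeros((4, 4, 4), dtype=int)
        atlas[0, 0, 0] = 1
        out = label_association(masks, labels, atlas).set_index("label")
        assert out.loc[1, "chi2"] == pytest.approx(14.0)

    def test_untouched_label_skipped(self):
        masks = np.zeros((4, 3, 3, 3), dtype=np.uint8)
        masks[:, 0, 0, 0] = 1
        atlas = np.zeros((3, 3, 3), dtype=int)
        atlas[2, 2, 2] = 5
        out = label_association(masks, np.array([1, 1, 0, 0]), atlas)
        assert out.set_index("label").loc[5, "skipped"]

    def test_chi2_matches_closed_form_on_random_tables(self):
        # Pearson chi-square for a 2x2 table: n (ad - bc)^2 / product of margins
        rng = np.random.default_rng(8)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 8, size=4)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            masks = np.zeros((n, 2, 1, 1), dtype=np.uint8)
            labels = np.r_[np.ones(a + b, int), np.zeros(c + d, int)]
            lesioned = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)].astype(bool)
            masks[lesioned, 0, 0, 0] = 1
            masks[:, 1, 0, 0] = 1  # dummy second voxel so shapes stay 3-D
            atlas = np.zeros((2, 1, 1), dtype=int)
            atlas[0, 0, 0] = 1
            out = label_association(masks, labels, atlas).set_index("label")
            assert out.loc[1, "chi2"] == pytest.approx(expected, abs=1e-9)

    def test_synthetic_atlas_covers_critical_region(self):
        spec = LesionCohortSpec()
        atlas, names = make_synthetic_atlas(spec)
        assert names[1] == "critical_nucleus"
        for vox in spec.critical_region:
            assert atlas[vox] == 1
        assert set(np.unique(atlas)) >= {0, 1, 2, 3}
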
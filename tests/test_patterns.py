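"""Component ranking, segment genotype calls, patient classification and
covariate association."""

import numpy as np
import pytest
from scipy import stats

from cospec import (
    GenomicBin,
    ProfileMatrix,
    Segment,
    SegmentSet,
    classify_patients,
    classify_segments,
    correlate_patients,
    covariate_association,
    gsvd_matrices,
    orient_component,
    rank_components,
)


class TestRankComponents:
    def test_diagonal_case_most_exclusive(self):
        res = gsvd_matrices(np.diag([2.0, 1.0]), np.eye(2))
        rk = rank_components(res, theta_min=0.2, p_min=0.01)
        assert rk.exclusive_to_1[0] and not rk.exclusive_to_1[1]
        assert rk.selected == 0
        assert rk.theta[0] == pytest.approx(np.arctan(2) - np.pi / 4, abs=1e-10)

    def test_identical_inputs_nothing_exclusive(self, rng):
        d = rng.normal(size=(6, 3))
        res = gsvd_matrices(d, d)
        rk = rank_components(res, theta_min=0.05)
        assert not rk.exclusive_to_1.any() and not rk.exclusive_to_2.any()

    def test_no_significant_component_warns(self):
        res = gsvd_matrices(np.diag([2.0, 1.0]), np.eye(2))
        with pytest.warns(UserWarning, match="significant"):
            rk = rank_components(res, p_min=1.1)
        assert rk.selected is None

    def test_significance_fractions_sum_to_one(self, random_pair):
        res = gsvd_matrices(*random_pair)
        rk = rank_components(res)
        assert rk.significance1.sum() == pytest.approx(1.0)
        assert rk.significance2.sum() == pytest.approx(1.0)


def _segment_setup():
    """120 bins on one chromosome; arm A bins 0-79, arm B bins 80-119."""
    bins = [GenomicBin("chr1", i * 100, (i + 1) * 100) for i in range(120)]
    segments = SegmentSet(
        [
            Segment("chr1", 0, 8000, "armA_span", "A"),
            Segment("chr1", 8000, 12000, "armB_span", "B"),
        ]
    )
    return bins, segments


def test_segment_equal_to_arm_median_is_unaltered(rng):
    bins, _ = _segment_setup()
    pattern = rng.normal(size=120)
    segs = SegmentSet(
        [
            Segment("chr1", 0, 12000, "whole", "A"),
            Segment("chr1", 0, 12000, "whole2", "B"),
        ]
    )
    # one segment spanning its whole arm: segment median == arm median
    calls = classify_segments(pattern, bins, SegmentSet([segs.segments[0]]))
    assert calls[0].call == "unaltered"
    assert calls[0].delta_in_mads == pytest.approx(0.0, abs=1e-12)


def test_constructed_amplification_and_probe_filter(rng):
    """A 40-bin segment raised well above the construction's MAD is called
    amplified; a 20-bin one is filtered by the >30-probe rule.  The reported
    delta matches an independent median/MAD computation."""
    n = 400
    bins = [GenomicBin("chr1", i * 100, (i + 1) * 100) for i in range(n)]
    pattern = rng.normal(0.0, 0.05, size=n)
    pattern[100:140] += 0.5  # 40-bin raised segment
    pattern[150:170] += 0.5  # 20-bin raised segment
    segments = SegmentSet(
        [
            Segment("chr1", 0, 10000, "left", "A"),
            Segment("chr1", 10000, 14000, "amp40", "A"),
            Segment("chr1", 15000, 17000, "amp20", "A"),
            Segment("chr1", 17000, 40000, "right", "A"),
        ]
    )
    calls = {c.label: c for c in classify_segments(pattern, bins, segments, t_mad=3.0)}
    # independent oracle for the delta of amp40
    pooled_med = np.median(pattern)
    mad = stats.median_abs_deviation(pattern, scale=1.0)
    expected = (np.median(pattern[100:140]) - pooled_med) / mad
    assert calls["amp40"].delta_in_mads == pytest.approx(expected, rel=1e-12)
    assert expected > 3.0
    assert calls["amp40"].call == "amplified"
    assert calls["amp40"].retained
    assert calls["amp20"].call == "amplified"
    assert not calls["amp20"].retained  # 20 probes <= min_probes 30
    assert calls["left"].call == "unaltered"


def test_segment_calls_shift_invariant(rng):
    bins, segments = _segment_setup()
    pattern = rng.normal(size=120)
    pattern[80:120] += 2.0
    a = classify_segments(pattern, bins, segments)
    b = classify_segments(pattern + 7.3, bins, segments)
    assert [c.call for c in a] == [c.call for c in b]
    np.testing.assert_allclose(
        [c.delta_in_mads for c in a], [c.delta_in_mads for c in b], atol=1e-10
    )


def test_segment_without_bins_is_an_error(rng):
    bins, _ = _segment_setup()
    segs = SegmentSet([Segment("chr2", 0, 100, "nowhere", "A")])
    with pytest.raises(ValueError, match="nowhere"):
        classify_segments(rng.normal(size=120), bins, segs,
                          arm_spans={"A": ("chr1", 0, 12000)})


def _tumor_matrix(values):
    k = values.shape[0]
    bins = [GenomicBin("chr1", i * 10, i * 10 + 10) for i in range(k)]
    patients = [f"P{j}" for j in range(values.shape[1])]
    return ProfileMatrix(bins=bins, patients=patients, values=values)


class TestCorrelatePatients:
    def test_perfect_agreement_and_inversion(self, rng):
        pattern = rng.normal(size=30)
        tumor = _tumor_matrix(np.column_stack([pattern, -pattern]))
        corr = correlate_patients(pattern, tumor)
        np.testing.assert_allclose(corr, [1.0, -1.0], atol=1e-12)

    def test_matches_rank_then_pearson_oracle(self, rng):
        pattern = rng.normal(size=50)
        col = rng.normal(size=50)
        tumor = _tumor_matrix(col[:, None])
        got = correlate_patients(pattern, tumor)[0]
        oracle = stats.pearsonr(stats.rankdata(pattern), stats.rankdata(col))[0]
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        pattern = rng.normal(size=40)
        tumor = _tumor_matrix(rng.normal(size=(40, 3)))
        a = correlate_patients(pattern, tumor)
        b = correlate_patients(np.exp(2.0 * pattern) + 5, tumor)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_column_is_missing(self, rng):
        pattern = rng.normal(size=10)
        tumor = _tumor_matrix(np.ones((10, 1)))
        assert np.isnan(correlate_patients(pattern, tumor)[0])


class TestClassifyPatients:
    def test_threshold_rule(self):
        cls = classify_patients(
            np.array([0.5, 0.2, 0.4]), np.array([0.1, 0.0, 0.05]), corr_cutoff=0.35
        )
        assert set(np.flatnonzero(cls.high_by_correlation)) == {0, 2}

    def test_coeff_cutoff_from_frobenius_norm(self):
        corr = np.array([2.0, 0.0, 0.0])  # Euclidean norm 2.0
        cls = classify_patients(corr, np.zeros(3), corr_cutoff=0.35)
        assert cls.coeff_cutoff == pytest.approx(0.175)

    def test_multiply_convention(self):
        corr = np.array([2.0, 0.0, 0.0])
        cls = classify_patients(corr, np.zeros(3), scaling="multiply")
        assert cls.coeff_cutoff == pytest.approx(0.70)

    def test_flags_reproducible_from_stored_cutoffs(self, rng):
        corr = rng.uniform(-1, 1, size=20)
        coef = rng.normal(size=20)
        cls = classify_patients(corr, coef)
        np.testing.assert_array_equal(
            cls.high_by_correlation, cls.correlations > cls.corr_cutoff
        )
        np.testing.assert_array_equal(
            cls.high_by_coefficient, cls.coefficients > cls.coeff_cutoff
        )

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_patients(np.array([np.nan, np.nan]), np.zeros(2))


def test_orient_component_flips_negative_tail(rng):
    corr = np.concatenate([rng.normal(0, 0.05, 40), -0.6 + rng.normal(0, 0.05, 8)])
    coef = corr / np.linalg.norm(corr)
    c2, r2, sign = orient_component(coef, corr)
    assert sign == -1
    assert stats.skew(r2) > 0


class TestCovariateAssociation:
    def test_identical_groups_p_one(self):
        vector = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        assoc = covariate_association(vector, labels)
        assert assoc.mww_p == pytest.approx(1.0)

    def test_hypergeometric_exact_extreme(self):
        """High set equal to a 3-of-10 category: P = 1/C(10,3)."""
        labels = np.array(["x"] * 3 + ["y"] * 7)
        vector = np.arange(10.0)
        assoc = covariate_association(vector, labels, high_set={0, 1, 2})
        assert assoc.hypergeom_p == pytest.approx(1.0 / 120.0)

    def test_self_correlation(self, rng):
        v = rng.normal(size=25)
        assoc = covariate_association(v, v.copy(), high_set=set(range(5)))
        assert assoc.pearson == pytest.approx(1.0)
        assert assoc.spearman == pytest.approx(1.0)
        assert assoc.mww_p is not None

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            covariate_association(rng.normal(size=4), rng.normal(size=5))
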
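"""Kaplan-Meier, log-rank, Cox and PFS-subset contracts.

The fixed fixtures are worked by hand from the product-limit formula and
the log-rank observed-minus-expected table, so these tests are independent
of the delegated estimator.
"""

import numpy as np
import pytest
from scipy import stats

from cospec import (
    GroundTruth,
    SurvivalRecord,
    SyntheticConfig,
    cox_fit,
    generate_survival,
    km_curves,
    logrank,
    pfs_subset,
)


def _rec(pid, t, e, pfs=None):
    return SurvivalRecord(patient_id=pid, os_months=t, os_event=e, pfs_months=pfs)


def _truth(carriers, cfg):
    z = np.zeros(1)
    return GroundTruth(z, z, carriers, z, z, np.zeros(len(carriers)),
                       np.zeros(len(carriers)), cfg.baseline_hazard,
                       cfg.hazard_ratio, cfg.censoring_rate)


class TestKM:
    def test_all_events_at_same_time(self):
        recs = [_rec(f"p{i}", 10.0, True) for i in range(4)]
        (curve,) = km_curves(recs, {r.patient_id: "g" for r in recs})
        assert curve.median_survival_months == pytest.approx(10.0)

    def test_all_censored_median_undefined(self):
        recs = [_rec(f"p{i}", 10.0 + i, False) for i in range(4)]
        (curve,) = km_curves(recs, {r.patient_id: "g" for r in recs})
        assert curve.median_survival_months is None

    def test_hand_worked_product_limit(self):
        """Events at 2, 6, 11 with censorings at 4, 9, 14:
        S = 5/6 after t=2, 5/6 * 3/4 = 5/8 after t=6, 5/16 after t=11;
        the median (first time S <= 0.5) is 11."""
        times = [(2, True), (4, False), (6, True), (9, False), (11, True),
                 (14, False)]
        recs = [_rec(f"p{i}", float(t), e) for i, (t, e) in enumerate(times)]
        (curve,) = km_curves(recs, {r.patient_id: "g" for r in recs})
        sf = dict(zip(curve.step_times, curve.survival))
        assert sf[2.0] == pytest.approx(5 / 6)
        assert sf[6.0] == pytest.approx(5 / 8)
        assert sf[11.0] == pytest.approx(5 / 16)
        assert curve.median_survival_months == pytest.approx(11.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(12.0, size=30).round(3)
        recs = [_rec(f"p{i}", float(ti), True) for i, ti in enumerate(t)]
        (curve,) = km_curves(recs, {r.patient_id: "g" for r in recs})
        for tt, s in zip(curve.step_times, curve.survival):
            assert s == pytest.approx(np.mean(t > tt))

    def test_empty_group_is_an_error(self):
        recs = [_rec("p0", 5.0, True)]
        with pytest.raises(ValueError):
            km_curves(recs, {})


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        base = [(3.0, True), (5.0, False), (8.0, True)]
        recs = [_rec(f"a{i}", t, e) for i, (t, e) in enumerate(base)]
        recs += [_rec(f"b{i}", t, e) for i, (t, e) in enumerate(base)]
        groups = {r.patient_id: r.patient_id[0] for r in recs}
        res = logrank(recs, groups)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_hand_worked_o_minus_e(self):
        """Group A events at 1 and 3, group B event at 5 and censoring at 7:
        E_A = 2/4 + 1/3 = 5/6, O_A = 2, Var = 1/4 + 2/9 = 17/36, so the
        chi-square statistic is (2 - 5/6)^2 / (17/36) = 49/17."""
        recs = [
            _rec("a0", 1.0, True), _rec("a1", 3.0, True),
            _rec("b0", 5.0, True), _rec("b1", 7.0, False),
        ]
        groups = {r.patient_id: r.patient_id[0] for r in recs}
        res = logrank(recs, groups)
        assert res["statistic"] == pytest.approx(49 / 17, rel=1e-10)
        assert res["p_value"] == pytest.approx(
            stats.chi2.sf(49 / 17, df=1), rel=1e-10
        )

    def test_label_swap_invariance(self, rng):
        recs = [
            _rec(f"p{i}", float(t), bool(e))
            for i, (t, e) in enumerate(
                zip(rng.exponential(10, 12).round(2), rng.random(12) < 0.7)
            )
        ]
        g1 = {r.patient_id: ("A" if i < 5 else "B") for i, r in enumerate(recs)}
        g2 = {k: ("B" if v == "A" else "A") for k, v in g1.items()}
        a, b = logrank(recs, g1), logrank(recs, g2)
        assert a["statistic"] == pytest.approx(b["statistic"], rel=1e-12)
        assert a["p_value"] == pytest.approx(b["p_value"], rel=1e-12)

    def test_zero_events_undefined(self):
        recs = [_rec("a0", 3.0, False), _rec("b0", 4.0, False)]
        res = logrank(recs, {"a0": "A", "b0": "B"})
        assert res["p_value"] is None


class TestCox:
    @pytest.mark.filterwarnings("ignore::Warning")  # complete separation
    def test_perfect_risk_ordering_concordance_one(self):
        # risk scores perfectly order the event times, no ties, no censoring
        recs = [_rec(f"p{i}", float(10 - i), True) for i in range(8)]
        cov = {"risk": {f"p{i}": float(i) for i in range(8)}}
        fit = cox_fit(recs, cov)
        assert fit.concordance == pytest.approx(1.0)

    def test_binary_relabeling_inverts_hazard_ratio(self):
        rng = np.random.default_rng(11)
        cfg = SyntheticConfig(k1=600, k2=600, l=200, m=1, seed=11)
        carriers = np.zeros(200, dtype=bool)
        carriers[rng.choice(200, 60, replace=False)] = True
        recs = generate_survival(_truth(carriers, cfg), cfg)
        hi = {r.patient_id: float(carriers[i]) for i, r in enumerate(recs)}
        lo = {k: 1.0 - v for k, v in hi.items()}
        a = cox_fit(recs, {"g": hi})
        b = cox_fit(recs, {"g": lo})
        assert a.hazard_ratios["g"] == pytest.approx(
            1.0 / b.hazard_ratios["g"], rel=1e-6
        )

    def test_constant_covariate_rejected(self):
        recs = [_rec(f"p{i}", float(i + 1), True) for i in range(5)]
        with pytest.raises(ValueError, match="constant"):
            cox_fit(recs, {"g": {r.patient_id: 1.0 for r in recs}})

    def test_bivariate_with_stage(self):
        rng = np.random.default_rng(4)
        cfg = SyntheticConfig(k1=900, k2=900, l=300, m=1, seed=4)
        carriers = np.zeros(300, dtype=bool)
        carriers[rng.choice(300, 80, replace=False)] = True
        recs = generate_survival(_truth(carriers, cfg), cfg)
        covs = {
            "pattern_high": {r.patient_id: float(carriers[i])
                             for i, r in enumerate(recs)},
            "stage": {r.patient_id: float(r.stage) for r in recs},
        }
        fit = cox_fit(recs, covs)
        assert set(fit.hazard_ratios) == {"pattern_high", "stage"}
        for c in fit.covariates:
            assert fit.ci_lower[c] <= fit.hazard_ratios[c] <= fit.ci_upper[c]
        assert 0.0 <= fit.concordance <= 1.0


class TestPfsSubset:
    def test_threshold_zero_keeps_recorded_pfs(self):
        recs = [_rec("a", 10, True, 4.0), _rec("b", 12, False, None),
                _rec("c", 20, True, 0.0)]
        out = pfs_subset(recs, 0.0)
        assert [r.patient_id for r in out] == ["a", "c"]

    def test_threshold_above_all_is_empty(self):
        recs = [_rec("a", 10, True, 4.0)]
        assert pfs_subset(recs, 100.0) == []

    def test_nested(self, rng):
        recs = [
            _rec(f"p{i}", float(t), True, float(p))
            for i, (t, p) in enumerate(
                zip(rng.uniform(10, 50, 20), rng.uniform(0, 20, 20))
            )
        ]
        small = {r.patient_id for r in pfs_subset(recs, 11.0)}
        big = {r.patient_id for r in pfs_subset(recs, 0.0)}
        assert small <= big
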
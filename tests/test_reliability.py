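import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import precimap as pm
from precimap.labels import LabelMap, LabelTable


def contingency_nmi(a, b):
    """Hand-built contingency-table NMI oracle (natural log, 2I/(H1+H2))."""
    a, b = np.asarray(a), np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    n = a.size
    counts = np.array([[np.sum((a == x) & (b == y)) for y in ub] for x in ua])
    pxy = counts / n
    px, py = pxy.sum(1), pxy.sum(0)
    h = lambda p: -sum(v * np.log(v) for v in p if v > 0)
    mi = sum(
        pxy[i, j] * np.log(pxy[i, j] / (px[i] * py[j]))
        for i in range(len(ua)) for j in range(len(ub)) if pxy[i, j] > 0
    )
    if h(px) + h(py) == 0:
        return 1.0
    return 2 * mi / (h(px) + h(py))


class TestNmi:
    def test_identical_maps(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        assert pm.nmi(a, a) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        b = np.array([3, 3, 1, 1, 2, 2])
        assert pm.nmi(a, b) == pytest.approx(1.0)

    def test_independent_pattern_is_zero(self):
        assert pm.nmi(np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2])) == pytest.approx(
            0.0
        )

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_matches_contingency_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            a = rng.integers(1, 4, n)
            b = rng.integers(1, 4, n)
            assert pm.nmi(a, b) == pytest.approx(contingency_nmi(a, b), abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        a = rng.integers(1, 6, 500)
        b = rng.integers(1, 6, 500)
        assert pm.nmi(a, b) == pytest.approx(
            sklearn_metrics.normalized_mutual_info_score(a, b), abs=1e-10
        )

    def test_unassigned_excluded(self):
        a = np.array([1, 1, 2, 2, 0, 0])
        b = np.array([1, 1, 2, 2, 1, 2])
        kept = pm.nmi(a, b)
        assert kept == pytest.approx(1.0)   # the jointly assigned part agrees

    def test_no_joint_assignment_errors(self):
        with pytest.raises(ValueError):
            pm.nmi(np.array([0, 0, 1]), np.array([1, 1, 0]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 5), min_size=2, max_size=40), st.data())
    def test_symmetric_and_bounded(self, a, data):
        b = data.draw(st.lists(st.integers(1, 5), min_size=len(a), max_size=len(a)))
        a, b = np.array(a), np.array(b)
        ab, ba = pm.nmi(a, b), pm.nmi(b, a)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 1.0

    def test_independent_relabeling_near_zero_at_scale(self):
        """At G=2000 the finite-sample bias of NMI is small but nonzero."""
        rng = np.random.default_rng(1)
        vals = [
            pm.nmi(rng.integers(1, 15, 2000), rng.integers(1, 15, 2000))
            for _ in range(10)
        ]
        assert np.mean(vals) == pytest.approx(0.0, abs=0.05)


def _tm_setup(cohort):
    weights = pm.gaussian_smoothing_weights(cohort.mesh, 2.25)
    per_subject, processed = [], []
    for sub in cohort.subjects:
        s = pm.smooth_series(sub.series, cohort.mesh, 2.25, weights=weights)
        s = pm.censor_frames(s, sub.fd, 0.3)
        processed.append(s)
        per_subject.append(pm.subject_seed_maps(s, cohort.group_truth))
    tset = pm.average_and_threshold(per_subject, cohort.group_truth.table)
    return pm.TemplateMatchingMapper(tset, cohort.mesh, sigma_mm=0), processed


class TestSplitHalfReliability:
    def test_identical_halves_give_unit_nmi(self, grid100):
        rng = np.random.default_rng(0)
        block = rng.standard_normal((50, 100))
        series = pm.GrayordinateSeries(np.vstack([block, block]), 0.8)
        truth = pm.plant_group_parcellation(grid100, 4, seed=0)
        cfg = pm.SimulationConfig(n_grayordinates=100, n_networks=4,
                                  within_network_signal_fraction=0.9)
        bold = pm.simulate_bold(truth, pm.NetworkCoupling.identity(4), cfg,
                                seed=1, duration_minutes=2.0)
        doubled = pm.GrayordinateSeries(
            np.vstack([bold.data, bold.data]), 0.8
        )
        per = [pm.subject_seed_maps(bold, truth)]
        tset = pm.average_and_threshold(per, truth.table)
        mapper = pm.TemplateMatchingMapper(tset, grid100, sigma_mm=0)
        rec, _ = pm.split_half_reliability(doubled, mapper, "s1",
                                           min_retained_minutes=0)
        assert rec.nmi_within == pytest.approx(1.0)

    def test_minutes_conservation(self, tiny_cohort):
        mapper, processed = _tm_setup(tiny_cohort)
        series = processed[0]
        rec, _ = pm.split_half_reliability(series, mapper, "s",
                                           min_retained_minutes=0)
        assert rec.minutes_half1 + rec.minutes_half2 == pytest.approx(
            series.retained_minutes
        )

    def test_inclusion_rule_skips(self, tiny_cohort):
        mapper, processed = _tm_setup(tiny_cohort)
        rec, halves = pm.split_half_reliability(processed[0], mapper, "s",
                                                min_retained_minutes=60.0)
        assert rec is None and halves is None

    def test_within_exceeds_inter_on_cohort(self, tiny_cohort):
        mapper, processed = _tm_setup(tiny_cohort)
        recs, half_maps = [], []
        for idx, series in enumerate(processed):
            rec, halves = pm.split_half_reliability(series, mapper, str(idx),
                                                    min_retained_minutes=0)
            recs.append(rec)
            half_maps.append(halves)
        null = pm.inter_subject_null(half_maps)
        assert np.mean([r.nmi_within for r in recs]) > null.mean


class TestInterSubjectNull:
    def _fake_halves(self, labelings):
        table = LabelTable.default(3)
        return [
            (LabelMap(np.array(a), table), LabelMap(np.array(b), table))
            for a, b in labelings
        ]

    def test_two_subjects_two_cross_pairs(self):
        halves = self._fake_halves(
            [([1, 1, 2, 3], [1, 1, 2, 3]), ([1, 2, 2, 3], [1, 2, 2, 3])]
        )
        null = pm.inter_subject_null(halves)
        assert null.values.size == 2

    def test_identical_subjects_degenerate_null(self):
        halves = self._fake_halves(
            [([1, 1, 2, 3], [1, 1, 2, 3])] * 3
        )
        null = pm.inter_subject_null(halves)
        assert np.allclose(null.values, 1.0)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            pm.inter_subject_null(self._fake_halves([([1, 2, 3], [1, 2, 3])]))


class TestSamplingCurve:
    def test_full_half_single_repetition_matches_split_half(self, tiny_cohort):
        mapper, processed = _tm_setup(tiny_cohort)
        series = processed[0]
        rec, (map1, map2) = pm.split_half_reliability(series, mapper, "s",
                                                      min_retained_minutes=0)
        h1, h2 = pm.split_halves(series)
        # sample exactly the full half-1 retained amount, continuously
        curve = pm.sampling_curve(h1, map2, mapper,
                                  minutes_grid=(h1.retained_minutes,),
                                  mode="continuous", repetitions=1, seed=0)
        assert curve.mean_nmi[0] == pytest.approx(rec.nmi_within)

    def test_infeasible_point_recorded_missing(self, tiny_cohort):
        mapper, processed = _tm_setup(tiny_cohort)
        h1, _ = pm.split_halves(processed[0])
        curve = pm.sampling_curve(h1, mapper(h1), mapper,
                                  minutes_grid=(1.0, 500.0),
                                  mode="random", repetitions=2, seed=0)
        assert curve.mean_nmi[0] is not None
        assert curve.mean_nmi[1] is None


class TestRegression:
    def test_exactly_linear_records(self):
        recs = [
            pm.ReliabilityRecord(f"s{i}", 0.3 + 0.01 * m, m, m)
            for i, m in enumerate([5, 10, 15, 20, 25])
        ]
        fit = pm.regress_nmi_on_minutes(recs)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(0.01)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = np.array([4.0, 7.0, 9.0, 12.0, 18.0, 25.0])
        y = 0.3 + 0.008 * x + rng.normal(0, 0.02, 6)
        recs = [pm.ReliabilityRecord(f"s{i}", yi, xi, xi)
                for i, (xi, yi) in enumerate(zip(x, y))]
        fit = pm.regress_nmi_on_minutes(recs)
        # closed-form OLS via the normal equations
        xm = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
        resid = y - xm @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit["intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert fit["slope"] == pytest.approx(beta[1], abs=1e-10)
        assert fit["r_squared"] == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_predictor_errors(self):
        recs = [pm.ReliabilityRecord(f"s{i}", 0.5, 10.0, 10.0) for i in range(4)]
        with pytest.raises(ValueError):
            pm.regress_nmi_on_minutes(recs)
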
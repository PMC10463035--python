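"""Normality-gated paired comparisons, omnibus tests and correlations."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xedwi import CohortTable, ParameterError, correlate, normality_gate, zone_omnibus
from xedwi.stats import (_paired_from_arrays, hodges_lehmann, longitudinal_report,
                         paired_compare, signed_rank_ci)


def make_table(rows, covariates=None, visits=None):
    return CohortTable(pd.DataFrame(rows), covariates=covariates, visits=visits)


def cohort_rows(values_by_visit, metric="ADC", region="global"):
    rows = []
    for visit, vals in values_by_visit.items():
        for i, v in enumerate(vals):
            rows.append(dict(subject=f"S{i:02d}", visit=visit, region=region,
                             metric=metric, mean=v, median=v, sd=0.0, n_voxels=10))
    return rows


class TestNormalityGate:
    def test_normal_samples_route_parametric(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 20)
            hits += normality_gate(x).route == "parametric"
        assert hits >= 90

    def test_heavy_tails_route_nonparametric(self):
        """Shapiro-Wilk power against Cauchy tails at n=20 is ~85%."""
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_cauchy(20)
            hits += normality_gate(x).route == "nonparametric"
        assert hits >= 80

    def test_constant_vector_degenerate(self):
        g = normality_gate(np.full(10, 3.0))
        assert g.route == "nonparametric" and g.degenerate

    def test_tiny_sample_forced_nonparametric(self):
        g = normality_gate([1.0, 2.0])
        assert g.route == "nonparametric" and "n < 3" in g.note


class TestPairedCompare:
    def test_identical_vectors_degenerate(self):
        x = np.arange(5.0)
        r = _paired_from_arrays(x, x)
        assert r.degenerate and r.p == 1.0 and r.estimate == 0.0

    def test_t_route_matches_textbook_formula(self):
        """Fixed printed pairs against the hand-computed paired-t p-value."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.2, 2.1, 3.4, 4.1, 5.6])
        r = _paired_from_arrays(a, b)
        d = b - a
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p = 2 * sps.t.sf(abs(t), 4)
        assert r.test == "paired-t"
        assert r.statistic == pytest.approx(t, abs=1e-12)
        assert r.p == pytest.approx(p, abs=1e-10)
        assert r.ci_low < r.estimate < r.ci_high

    def test_effect_sign_agrees_across_routes(self):
        """t and Wilcoxon effect estimates share their sign on shifted data."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = rng.exponential(1.0, 15)
            shift = rng.choice([-0.5, 0.5])
            b = a + shift + rng.normal(0, 0.05, 15)
            rt = _paired_from_arrays(a, b)
            d = b - a
            assert np.sign(rt.estimate) == np.sign(np.median(d))

    def test_ci_coverage_near_nominal(self):
        """95% CI covers the true mean difference ~95% of the time (n=20)."""
        cover = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, 20)
            b = a + 0.5 + rng.normal(0.0, 1.0, 20)
            r = _paired_from_arrays(a, b)
            cover += r.ci_low <= 0.5 <= r.ci_high
        assert 0.93 <= cover / n_rep <= 0.97

    def test_missing_visit_subjects_excluded_and_counted(self):
        rows = cohort_rows({"v0": [1, 2, 3, 4], "v1": [1.1, 2.2, 3.1, 4.4]})
        rows = [r for r in rows if not (r["subject"] == "S03" and r["visit"] == "v1")]
        table = make_table(rows, visits=("v0", "v1"))
        r = paired_compare(table, "ADC", "global", "v0", "v1")
        assert r.n == 3 and r.extras["n_excluded"] == 1

    def test_too_few_pairs(self):
        table = make_table(cohort_rows({"v0": [1.0], "v1": [1.2]}), visits=("v0", "v1"))
        with pytest.raises(ParameterError):
            paired_compare(table, "ADC", "global", "v0", "v1")

    def test_hodges_lehmann_and_ci(self):
        d = np.array([0.1, 0.3, -0.2, 0.4, 0.25, 0.15, 0.05, 0.35])
        hl = hodges_lehmann(d)
        lo, hi = signed_rank_ci(d)
        assert lo <= hl <= hi
        i, j = np.triu_indices(d.size)
        assert hl == pytest.approx(np.median((d[i] + d[j]) / 2))


class TestZoneOmnibus:
    def zone_table(self, offsets=(0.0, 0.003, 0.001), n=12, noise=0.001, seed=1):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            base = rng.normal(0.044, 0.006)
            for z, off in zip(("upper", "middle", "lower"), offsets):
                v = base + off + rng.normal(0, noise)
                rows.append(dict(subject=f"S{i:02d}", visit="v0", region=z,
                                 metric="ADC", mean=v, median=v, sd=0.0, n_voxels=10))
        return make_table(rows, visits=("v0",))

    def test_identical_zones_degenerate(self):
        table = self.zone_table(offsets=(0.0, 0.0, 0.0), noise=0.0)
        omnibus, pairs = zone_omnibus(table, "ADC", "v0")
        assert omnibus.degenerate and omnibus.p == 1.0

    def test_separated_zones_detected_with_posthoc(self):
        omnibus, pairs = zone_omnibus(self.zone_table(), "ADC", "v0")
        assert omnibus.p < 0.05
        assert set(pairs) == {"upper-vs-middle", "upper-vs-lower", "middle-vs-lower"}
        assert pairs["upper-vs-middle"].p < 0.05

    def test_holm_column_optional(self):
        _, pairs = zone_omnibus(self.zone_table(), "ADC", "v0", holm=True)
        for r in pairs.values():
            assert r.extras["p_holm"] >= r.p

    def test_needs_three_complete_subjects(self):
        table = self.zone_table(n=2)
        with pytest.raises(ParameterError):
            zone_omnibus(table, "ADC", "v0")


class TestCorrelate:
    def corr_table(self, x, y):
        rows = cohort_rows({"v0": x})
        cov = pd.DataFrame({"subject": [f"S{i:02d}" for i in range(len(y))],
                            "visit": "v0", "kco": y})
        return make_table(rows, covariates=cov, visits=("v0",))

    def test_perfect_linear(self):
        x = np.linspace(1, 2, 10)
        r = correlate(self.corr_table(x, 2 * x), "ADC", "kco", visit="v0")
        assert r.estimate == pytest.approx(1.0)
        assert r.p < 1e-6

    def test_near_perfect_negative(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.044, 0.006, 25)
        r = correlate(self.corr_table(x, -x + rng.normal(0, 1e-5, 25)), "ADC", "kco",
                      visit="v0")
        assert r.estimate == pytest.approx(-1.0, abs=0.01)

    def test_affine_invariance_pearson(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 40)
        y = 0.5 * x + rng.normal(0, 0.5, 40)
        r1 = correlate(self.corr_table(x, y), "ADC", "kco", visit="v0")
        r2 = correlate(self.corr_table(100 * x + 7, -3 * y + 2), "ADC", "kco", visit="v0")
        assert r1.test == r2.test == "pearson"
        assert abs(r2.estimate) == pytest.approx(abs(r1.estimate), rel=1e-12)
        assert r2.p == pytest.approx(r1.p, rel=1e-9)

    def test_zero_variance_degenerate(self):
        r = correlate(self.corr_table(np.full(10, 1.0), np.arange(10.0)),
                      "ADC", "kco", visit="v0")
        assert r.degenerate

    def test_fisher_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 31)
        y = -0.7 * x + rng.normal(0, 0.7, 31)
        r = correlate(self.corr_table(x, y), "ADC", "kco", visit="v0")
        if r.test == "pearson":
            assert r.ci_low < r.estimate < r.ci_high


class TestLongitudinalReport:
    def two_visit_table(self, n=10, effect=0.004, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for metric in ("ADC", "LmD"):
            scale = 1.0 if metric == "ADC" else 7000.0
            for region in ("global", "upper", "middle", "lower"):
                eff = effect if region == "lower" else 0.0
                for i in range(n):
                    base = rng.normal(0.044, 0.006)
                    for visit, off in (("v0", 0.0), ("v1", eff)):
                        v = (base + off + rng.normal(0, 0.001)) * scale
                        rows.append(dict(subject=f"S{i:02d}", visit=visit, region=region,
                                         metric=metric, mean=v, median=v, sd=0.0,
                                         n_voxels=10))
        return make_table(rows, visits=("v0", "v1"))

    def test_row_count_is_metrics_times_regions(self):
        frame, _ = longitudinal_report(self.two_visit_table())
        assert len(frame) == 2 * 4

    def test_zero_effect_table_all_degenerate(self):
        table = self.two_visit_table(effect=0.0, seed=1)
        # make the two visits exactly equal
        m = table.measurements
        v0 = m[m.visit == "v0"].copy()
        v1 = v0.copy()
        v1["visit"] = "v1"
        table = make_table(pd.concat([v0, v1]), visits=("v0", "v1"))
        frame, _ = longitudinal_report(table)
        assert (frame["difference"] == 0).all()
        assert frame["degenerate"].all()

    def test_deterministic_regeneration(self):
        t = self.two_visit_table(seed=3)
        f1, txt1 = longitudinal_report(t)
        f2, txt2 = longitudinal_report(t)
        pd.testing.assert_frame_equal(f1, f2)
        assert txt1 == txt2

    def test_requires_two_visits(self):
        table = make_table(cohort_rows({"v0": [1, 2, 3]}), visits=("v0",))
        with pytest.raises(ParameterError):
            longitudinal_report(table)
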
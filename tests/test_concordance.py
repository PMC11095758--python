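"""Regression, contingency and variance-gated tests against closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from pidher2.concordance import (
    adjacent_class_comparisons,
    compare_groups,
    contingency,
    fit_score_regression,
    full_report,
    reproducibility,
)
from pidher2.io import DAB_CLASSES, CoreRecord
from .conftest import make_records


class TestRegression:
    def test_perfect_line_gives_r2_one(self):
        records = make_records({"0": [1.0], "1+": [2.0], "2+": [3.0], "3+": [4.0]})
        report = fit_score_regression(records)
        assert report.r_squared == pytest.approx(1.0)
        assert report.slope == pytest.approx(1.0)
        assert report.intercept == pytest.approx(1.0)

    def test_identical_scores_undefined_not_zero(self):
        records = make_records({"1+": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="undefined"):
            fit_score_regression(records)

    def test_permuted_labels_give_r2_near_zero(self, rng):
        values = rng.uniform(0, 50, 400)
        classes = rng.choice(DAB_CLASSES, 400)  # labels independent of values
        records = make_records({c: values[classes == c] for c in DAB_CLASSES})
        report = fit_score_regression(records)
        assert report.r_squared < 0.03

    def test_r2_matches_closed_form_oracle(self, rng):
        """Independent oracle: R^2 from raw sums, not the fitting route."""
        values = {c: rng.uniform(i * 10, i * 10 + 8, 15) for i, c in enumerate(DAB_CLASSES)}
        records = make_records(values)
        report = fit_score_regression(records)
        x = np.concatenate([[i] * 15 for i in range(4)]).astype(float)
        y = np.concatenate([values[c] for c in DAB_CLASSES])
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        r2 = sxy**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert report.r_squared == pytest.approx(r2, abs=1e-12)

    def test_r2_invariant_under_affine_rescaling(self, rng):
        values = {c: rng.uniform(i * 10, i * 10 + 8, 10) for i, c in enumerate(DAB_CLASSES)}
        base = fit_score_regression(make_records(values)).r_squared
        scaled = fit_score_regression(
            make_records({c: 0.37 * v + 5.0 for c, v in values.items()})
        ).r_squared
        assert scaled == pytest.approx(base, abs=1e-12)


class TestContingency:
    def add_scores(self, records, scores):
        for r, s in zip(records, scores):
            r.pid_score = s
        return records

    def test_perfect_concordance_diagonal(self):
        records = make_records({c: [float(i * 10 + 1)] * 5 for i, c in enumerate(DAB_CLASSES)})
        self.add_scores(records, [r.dab_consensus for r in records])
        report = contingency(records)
        assert np.array_equal(np.diag(report.table.to_numpy()), [5, 5, 5, 5])
        assert report.table.to_numpy().sum() == 20
        assert np.allclose(np.diag(report.pv_percent.to_numpy()), 100.0)

    def test_matches_brute_force_pair_counting(self, rng):
        records = make_records({c: rng.uniform(1, 50, 25) for c in DAB_CLASSES})
        scores = rng.choice(DAB_CLASSES, len(records))
        self.add_scores(records, scores)
        report = contingency(records)
        for a in DAB_CLASSES:
            for b in DAB_CLASSES:
                expected = sum(1 for r in records if r.dab_consensus == a and r.pid_score == b)
                assert report.table.loc[a, b] == expected

    def test_row_percentages_sum_to_100(self, rng):
        records = make_records({c: rng.uniform(1, 50, 10) for c in DAB_CLASSES})
        self.add_scores(records, rng.choice(DAB_CLASSES, len(records)))
        report = contingency(records)
        sums = report.pv_percent.sum(axis=1).to_numpy()
        assert np.allclose(sums[~np.isnan(sums)], 100.0)

    def test_marginals_match_class_counts(self, rng):
        counts = {"0": 7, "1+": 5, "2+": 3, "3+": 2}
        records = make_records({c: rng.uniform(1, 50, n) for c, n in counts.items()})
        self.add_scores(records, rng.choice(DAB_CLASSES, len(records)))
        report = contingency(records)
        assert report.table.sum(axis=1).to_dict() == counts


def oracle_student_t(a, b):
    """Textbook pooled two-sample t-test."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def oracle_welch_t(a, b):
    """Textbook Welch t-test with Welch-Satterthwaite degrees of freedom."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestCompareGroups:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        result = compare_groups(a, a.copy())
        assert result.t_statistic == 0.0
        assert result.t_p == pytest.approx(1.0)
        assert result.test_used == "student"  # equal variances to machine precision

    def test_equal_variance_matches_student_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.8, 1.0, 28)
        result = compare_groups(a, b)
        assert result.test_used == "student"
        t, p = oracle_student_t(a, b)
        assert result.t_statistic == pytest.approx(t, abs=1e-10)
        assert result.t_p == pytest.approx(p, abs=1e-10)

    def test_unequal_variance_matches_welch_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(1.0, 6.0, 25)
        result = compare_groups(a, b)
        assert result.test_used == "welch"
        t, p = oracle_welch_t(a, b)
        assert result.t_statistic == pytest.approx(t, abs=1e-10)
        assert result.t_p == pytest.approx(p, abs=1e-10)

    def test_f_statistic_matches_distribution_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 10.0, 20)  # variance ratio ~100
        b = rng.normal(0, 1.0, 20)
        result = compare_groups(a, b)
        f = np.var(a, ddof=1) / np.var(b, ddof=1)
        assert result.f_statistic == pytest.approx(f, abs=1e-10)
        assert result.f_p == pytest.approx(min(1.0, 2 * stats.f.sf(f, 19, 19)), abs=1e-12)
        assert result.test_used == "welch"
        assert result.f_p < 0.05

    def test_welch_selected_exactly_when_f_rejects(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            a = rng.normal(0, rng.uniform(0.5, 3.0), 15)
            b = rng.normal(0, rng.uniform(0.5, 3.0), 17)
            result = compare_groups(a, b)
            assert (result.test_used == "welch") == (result.f_p < 0.05)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            compare_groups([1.0], [2.0, 3.0])


class TestReproducibility:
    def run_records(self, rng, noise_sd):
        truth = {c: rng.uniform(i * 12 + 1, i * 12 + 8, 12) for i, c in enumerate(DAB_CLASSES)}
        return make_records({c: v + rng.normal(0, noise_sd, len(v)) for c, v in truth.items()}), truth

    def test_identical_runs_fully_reproducible(self, rng):
        run, _ = self.run_records(rng, 0.0)
        import copy

        result = reproducibility([run, copy.deepcopy(run)])
        assert result["per_run_r_squared"][0] == result["per_run_r_squared"][1]
        assert result["between_run_correlation"]["run1_run2"] == pytest.approx(1.0)

    def test_correlation_increases_as_noise_vanishes(self):
        rng = np.random.default_rng(0)
        truth = {c: rng.uniform(i * 12 + 1, i * 12 + 8, 12) for i, c in enumerate(DAB_CLASSES)}
        cors = []
        for noise in (6.0, 1.0, 0.01):
            runs = [
                make_records({c: v + rng.normal(0, noise, len(v)) for c, v in truth.items()})
                for _ in range(2)
            ]
            cors.append(reproducibility(runs)["between_run_correlation"]["run1_run2"])
        assert cors[0] < cors[2]
        assert cors[2] > 0.999

    def test_permuted_values_uncorrelated(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 50, 200)
        runs = []
        for _ in range(3):
            perm = rng.permutation(base)
            runs.append(make_records({c: perm[i * 50 : (i + 1) * 50] for i, c in enumerate(DAB_CLASSES)}))
        result = reproducibility(runs)
        assert all(abs(c) < 0.2 for c in result["between_run_correlation"].values())

    def test_needs_two_runs(self, rng):
        run, _ = self.run_records(rng, 0.0)
        with pytest.raises(ValueError, match="two runs"):
            reproducibility([run])


def test_full_report_combines_everything(rng):
    records = make_records({c: rng.uniform(i * 12 + 1, i * 12 + 10, 12) for i, c in enumerate(DAB_CLASSES)})
    for r in records:
        r.pid_score = r.dab_consensus
    report = full_report(records)
    assert 0 <= report.r_squared <= 1
    assert report.table.to_numpy().sum() == len(records)
    assert set(report.adjacent_comparisons) == {"0_vs_1+", "1+_vs_2+", "2+_vs_3+"}
    d = report.to_dict()
    assert "table" in d and "adjacent_comparisons" in d


def test_adjacent_comparisons_detect_separated_classes(rng):
    records = make_records({c: rng.normal(i * 20, 1.0, 15) + 100 for i, c in enumerate(DAB_CLASSES)})
    comps = adjacent_class_comparisons(records)
    assert all(c.significant and c.significant_strict for c in comps.values())
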
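import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tesgroup.cohort import CohortSpec, generate_cohort
from tesgroup.model import Montage
from tesgroup.optimize import OptimizationConfig, ga_optimize
from tesgroup.transfer import (
    Protocol,
    compare_protocols,
    dunn_test,
    evaluate_transfer,
    nerni_vs_mean_en_fit,
)


def _table(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    rows = []
    for cond, per_subject in values.items():
        for sid, v in per_subject.items():
            rows.append(
                {
                    "subject_id": sid,
                    "protocol_id": cond,
                    "protocol_kind": "template",
                    "condition": cond,
                    "nerni": v,
                    "mean_en": v / 10.0,
                }
            )
    return pd.DataFrame(rows)


class TestEvaluateTransfer:
    def test_personalized_row_matches_optimizer_objective(self, subject):
        cfg = OptimizationConfig(ga_population=30, max_electrodes=3, seed=6)
        res = ga_optimize(subject, config=cfg)
        proto = Protocol("pers", "personalized", res.montage, own_subject=subject.subject_id)
        table = evaluate_transfer([proto], [subject])
        assert table.loc[0, "nerni"] == pytest.approx(res.objective, abs=1e-9)

    def test_zero_current_protocol_scores_zero_everywhere(self, cohort6):
        table = evaluate_transfer({"sham": Montage({})}, cohort6)
        assert (table["nerni"] == 0).all()
        assert (table["mean_en"] == 0).all()

    def test_identical_cohort_gives_identical_rows(self):
        cohort = generate_cohort(
            CohortSpec(
                n_subjects=3, seed=8, radius_jitter=0.0,
                surface_subdivisions=2, compute_features=False,
            )
        )
        m = Montage({"F3": 1.0, "Fp2": -1.0})
        table = evaluate_transfer({"m": m}, cohort)
        assert table["nerni"].nunique() == 1

    def test_cohort_order_does_not_matter(self, cohort6):
        m = Montage({"F3": 1.0, "T8": -1.0})
        a = evaluate_transfer({"m": m}, cohort6)
        b = evaluate_transfer({"m": m}, list(reversed(cohort6)))
        pd.testing.assert_frame_equal(a, b)

    def test_own_subject_restriction(self, cohort6):
        proto = Protocol("p0", "personalized", Montage({"F3": 1.0}), own_subject="sub-00")
        table = evaluate_transfer([proto], cohort6)
        assert set(table["subject_id"]) == {"sub-00"}


class TestCompareProtocols:
    def test_identical_conditions_give_t0_p1(self):
        vals = {s: v for s, v in zip("abcdef", [0.1, 0.2, 0.3, 0.25, 0.15, 0.22])}
        report = compare_protocols(_table({"x": vals, "y": dict(vals)}))
        row = report.paired_t.iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12) or np.isnan(row["t"])

    def test_bonferroni_multiplies_by_pair_count(self, rng):
        conds = {
            c: {f"s{i}": float(rng.normal()) for i in range(8)} for c in ("a", "b", "c")
        }
        report = compare_protocols(_table(conds))
        assert len(report.paired_t) == 3
        for _, row in report.paired_t.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p_raw"] * 3))

    def test_paired_t_matches_hand_rolled_oracle(self, rng):
        a = rng.normal(0.2, 0.05, 20)
        b = a + rng.normal(0.02, 0.03, 20)
        conds = {
            "a": {f"s{i}": float(a[i]) for i in range(20)},
            "b": {f"s{i}": float(b[i]) for i in range(20)},
        }
        report = compare_protocols(_table(conds))
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert report.paired_t.iloc[0]["t"] == pytest.approx(t_oracle, abs=1e-10)

    def test_missing_cells_are_an_error(self):
        table = _table({"a": {"s1": 0.1, "s2": 0.2, "s3": 0.15}, "b": {"s1": 0.1, "s2": 0.2}})
        table = table[~((table["condition"] == "b") & (table["subject_id"] == "s3"))]
        with pytest.raises(ValueError, match="missing cells"):
            compare_protocols(table)

    def test_paired_t_power_matches_noncentral_t(self, rng):
        # constant shift delta with gaussian noise at n=54: rejection rate of
        # the paired t should match the analytic noncentral-t power
        n, delta, sigma, reps = 54, 0.02, 0.05, 500
        rejections = 0
        for _ in range(reps):
            d = rng.normal(delta, sigma, n)
            _, p = stats.ttest_rel(d, np.zeros(n))
            rejections += p < 0.05
        power_mc = rejections / reps
        nc = delta / (sigma / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        power_an = 1 - stats.nct.cdf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
        se = np.sqrt(power_an * (1 - power_an) / reps)
        assert abs(power_mc - power_an) < 4 * se + 1e-9


class TestDunn:
    def test_two_groups_z_squared_equals_kruskal_h(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        h, _ = stats.kruskal(a, b)
        p_dunn = dunn_test({"a": a, "b": b}).loc["a", "b"]
        z = np.sqrt(h)
        assert p_dunn == pytest.approx(2 * stats.norm.sf(z), rel=1e-9)

    def test_matrix_shape_and_bounds(self, rng):
        groups = {c: rng.normal(i, 1, 10) for i, c in enumerate("abc")}
        p = dunn_test(groups)
        assert p.shape == (3, 3)
        assert (p.to_numpy() <= 1.0).all() and (p.to_numpy() >= 0.0).all()
        assert np.allclose(p.to_numpy(), p.to_numpy().T)

    def test_shifted_group_detected(self, rng):
        a = rng.normal(0, 0.1, 25)
        b = rng.normal(0, 0.1, 25)
        c = rng.normal(2.0, 0.1, 25)
        p = dunn_test({"a": a, "b": b, "c": c})
        assert p.loc["a", "c"] < 0.001
        assert p.loc["a", "b"] > 0.2


class TestQuadraticFit:
    def test_exact_parabola_recovered(self):
        x = np.linspace(0.01, 0.4, 30)
        y = 0.003 + 8.0 * x - 89.0 * x**2
        table = pd.DataFrame({"mean_en": x, "nerni": y})
        fit = nerni_vs_mean_en_fit(table)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.003, abs=1e-9)
        assert fit.linear == pytest.approx(8.0, abs=1e-9)
        assert fit.quadratic == pytest.approx(-89.0, abs=1e-7)

    def test_pure_noise_has_near_zero_r2(self, rng):
        r2 = []
        for _ in range(500):
            x = rng.uniform(0, 0.4, 200)
            y = rng.normal(0, 1, 200)
            r2.append(nerni_vs_mean_en_fit(pd.DataFrame({"mean_en": x, "nerni": y})).r_squared)
        assert np.median(r2) < 0.05

    def test_noisy_parabola_coefficient_coverage(self, rng):
        # each coefficient falls within 2 s.e. of truth ~95% of the time
        import statsmodels.api as sm

        covered = np.zeros(3)
        reps = 40
        for _ in range(reps):
            x = rng.uniform(0, 0.4, 300)
            y = 0.1 + 5.0 * x - 20.0 * x**2 + rng.normal(0, 0.05, 300)
            fit = nerni_vs_mean_en_fit(pd.DataFrame({"mean_en": x, "nerni": y}))
            X = sm.add_constant(np.column_stack([x, x**2]))
            se = np.sqrt(np.diag(np.linalg.inv(X.T @ X))) * 0.05
            covered += np.abs(
                np.array([fit.intercept, fit.linear, fit.quadratic]) - [0.1, 5.0, -20.0]
            ) < 2 * se
        assert (covered >= 0.8 * reps).all()

    def test_too_few_distinct_values_is_an_error(self):
        table = pd.DataFrame({"mean_en": [0.1, 0.1, 0.2], "nerni": [0.0, 0.1, 0.2]})
        with pytest.raises(ValueError, match="distinct"):
            nerni_vs_mean_en_fit(table)
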
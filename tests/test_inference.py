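import numpy as np
import pandas as pd
import pytest

from delaydetect import (
    ancova_two_covariates,
    correlate,
    homogeneity_test,
    normality_screen,
    oneway_anova_ges,
    tukey_hsd,
)
from delaydetect.errors import (
    CollinearityError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)


def brute_force_ss(values, labels):
    """Independent oracle: one-way sums of squares by direct enumeration."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    ss_effect = 0.0
    ss_error = 0.0
    for g in np.unique(labels):
        sub = values[labels == g]
        ss_effect += sub.size * (sub.mean() - grand) ** 2
    for g in np.unique(labels):
        sub = values[labels == g]
        ss_error += float(np.sum((sub - sub.mean()) ** 2))
    return ss_total, ss_effect, ss_error


def make_table(means, n=10, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in means.items():
        for v in rng.normal(mu, sd, n):
            rows.append({"group": g, "y": v})
    return pd.DataFrame(rows)


class TestNormality:
    def test_symmetric_sample_has_high_W(self):
        res = normality_screen(np.arange(20, dtype=float))
        assert res["W"] > 0.9

    def test_log_transform_restores_normality_of_lognormal(self):
        """Right-skewed log-normal sample fails the screen; its log passes
        in most seeded draws — the rationale for log thresholds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            raw = rng.lognormal(4.5, 0.6, 56)
            if (normality_screen(raw)["p"] < 0.01
                    and normality_screen(np.log(raw))["p"] > 0.05):
                hits += 1
        assert hits >= 15

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            normality_screen([1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            normality_screen([3.0, 3.0, 3.0])


class TestAnova:
    def test_no_group_separation_gives_tiny_effect(self):
        table = make_table({"a": 0.0, "b": 0.0, "c": 0.0}, n=30, seed=1)
        res = oneway_anova_ges(table, "y", "group")
        assert res["p"] > 0.05
        assert res["eta_G_squared"] < 0.1

    def test_matches_brute_force_ss_oracle(self):
        table = make_table({"a": 0.0, "b": 0.0, "c": 1.0}, n=10, seed=2)
        res = oneway_anova_ges(table, "y", "group")
        ss_total, ss_effect, ss_error = brute_force_ss(table.y, table.group)
        k, n = 3, len(table)
        f_oracle = (ss_effect / (k - 1)) / (ss_error / (n - k))
        assert res["F"] == pytest.approx(f_oracle, rel=1e-8)
        assert res["eta_G_squared"] == pytest.approx(
            ss_effect / (ss_effect + ss_error), rel=1e-8)
        assert res["df_effect"] == 2 and res["df_error"] == 27

    def test_ss_identity_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = make_table({"a": rng.normal(), "b": rng.normal(),
                                "c": rng.normal()},
                               n=int(rng.integers(3, 15)),
                               sd=float(rng.uniform(0.5, 3)),
                               seed=int(rng.integers(1e6)))
            res = oneway_anova_ges(table, "y", "group")
            ss_total, ss_effect, ss_error = brute_force_ss(table.y, table.group)
            assert ss_effect + ss_error == pytest.approx(ss_total, abs=1e-8)
            assert res["ss_effect"] == pytest.approx(ss_effect, rel=1e-8)
            assert res["ss_error"] == pytest.approx(ss_error, rel=1e-8)

    def test_single_group_rejected(self):
        table = make_table({"a": 0.0})
        with pytest.raises(InvalidInputError):
            oneway_anova_ges(table, "y", "group")


class TestTukey:
    def test_identical_groups_not_rejected(self):
        table = make_table({"a": 0.0, "b": 0.0}, n=25, seed=4)
        res = tukey_hsd(table, "y", "group")
        assert len(res) == 1
        assert res.p_adj.iloc[0] > 0.5

    def test_three_groups_give_three_pairs(self):
        table = make_table({"a": 0.0, "b": 0.0, "c": 1.0}, n=10, seed=5)
        res = tukey_hsd(table, "y", "group")
        assert len(res) == 3

    def test_shifted_group_flagged_against_both_others(self):
        """One shifted group: its two contrasts significant, the null pair
        not, in most seeds (the published post-hoc pattern)."""
        hits = 0
        for seed in range(20):
            table = make_table({"pianist": 0.0, "brass": 0.0,
                                "nonmusician": 1.2}, n=17, seed=seed)
            res = tukey_hsd(table, "y", "group").set_index(["group1", "group2"])

            def p(g1, g2):
                key = (g1, g2) if (g1, g2) in res.index else (g2, g1)
                return res.loc[key, "p_adj"]

            if (p("nonmusician", "pianist") < 0.05
                    and p("nonmusician", "brass") < 0.05
                    and p("brass", "pianist") > 0.05):
                hits += 1
        assert hits >= 17


class TestLevene:
    def test_equal_variances_usually_pass(self):
        hits = sum(
            homogeneity_test(make_table({"a": 0, "b": 0, "c": 0}, n=18,
                                        seed=s), "y", "group")["p"] > 0.05
            for s in range(20))
        assert hits >= 17

    def test_inflated_variance_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = ([{"group": "a", "y": v} for v in rng.normal(0, 1, 18)]
                    + [{"group": "b", "y": v} for v in rng.normal(0, 5, 18)])
            res = homogeneity_test(pd.DataFrame(rows), "y", "group")
            hits += res["p"] < 0.05
        assert hits >= 18

    def test_constant_groups_rejected(self):
        table = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                              "y": [1.0] * 3 + [2.0] * 3})
        with pytest.raises(DegenerateInputError):
            homogeneity_test(table, "y", "group")


class TestCorrelate:
    def test_adjusted_r2_formula(self):
        """r = .60 at n = 51 gives adjusted R^2 = 0.347 (rounds to .35)."""
        rng = np.random.default_rng(0)
        # construct a sample with exactly r = .6 via Gram-Schmidt
        x = rng.normal(size=51)
        e = rng.normal(size=51)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (e @ x) / (x @ x)
        e /= e.std()
        y = 0.6 * x + np.sqrt(1 - 0.36) * e
        table = pd.DataFrame({"x": x, "y": y})
        res = correlate(table, "x", "y")
        assert res["r"] == pytest.approx(0.6, abs=1e-10)
        assert res["df"] == 49
        assert res["adjusted_R2"] == pytest.approx(0.347, abs=5e-4)

    def test_perfect_correlation(self):
        table = pd.DataFrame({"x": np.arange(10.0)})
        table["y"] = table.x
        res = correlate(table, "x", "y")
        assert res["r"] == pytest.approx(1.0)
        assert res["adjusted_R2"] == pytest.approx(1.0)

    def test_independent_variables_stay_small(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame({"x": rng.normal(size=51),
                                  "y": rng.normal(size=51)})
            hits += abs(correlate(table, "x", "y")["r"]) < 0.28
        assert hits >= 36  # ~95% under the null at n=51

    def test_degenerate_input(self):
        table = pd.DataFrame({"x": [1.0] * 10, "y": np.arange(10.0)})
        with pytest.raises(DegenerateInputError):
            correlate(table, "x", "y")


def make_ancova_table(seed, group_signal=1.0, covariate_signal=0.0, n=17):
    """Group carries `group_signal` directly; covariates optionally carry
    an independent latent with loading `covariate_signal`."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(["pianist", "brass", "nonmusician"]):
        shift = group_signal if g == "nonmusician" else 0.0
        for _ in range(n):
            latent = rng.normal()
            rows.append({
                "group": g,
                "log_delay_threshold": shift + covariate_signal * latent
                + rng.normal(0, 0.5),
                "log_aniso_threshold": covariate_signal * latent
                + rng.normal(0, 0.5),
                "sync_vector_z": -covariate_signal * latent
                + rng.normal(0, 0.5),
            })
    return pd.DataFrame(rows)


class TestAncova:
    def test_group_signal_with_noise_covariates(self):
        """Covariates pure noise, group carries the signal: group main
        effect significant, covariate main effects not, in most seeds."""
        hits = 0
        for seed in range(20):
            table = make_ancova_table(seed, group_signal=1.0,
                                      covariate_signal=0.0)
            res = ancova_two_covariates(table)
            terms = res["terms"]
            if (terms["C(group)"]["p"] < 0.05
                    and terms["log_aniso_threshold"]["p"] > 0.05
                    and terms["sync_vector_z"]["p"] > 0.05):
                hits += 1
        assert hits >= 17

    def test_reports_five_term_tests(self):
        res = ancova_two_covariates(make_ancova_table(0))
        assert set(res["terms"]) == {
            "C(group)", "log_aniso_threshold", "sync_vector_z",
            "C(group):log_aniso_threshold", "C(group):sync_vector_z"}

    def test_duplicate_covariates_raise_collinearity_error(self):
        table = make_ancova_table(1)
        table["sync_vector_z"] = table["log_aniso_threshold"]
        with pytest.raises(CollinearityError):
            ancova_two_covariates(table)

    def test_zero_weight_covariates_reproduce_oneway_group_ss(self):
        """Covariates orthogonalised against the group dummies, the
        response and each other get exactly zero weight, so the Type-II
        group sum of squares equals the one-way ANOVA's SS_effect and the
        group F equals the one-way F after the residual-df adjustment."""
        table = make_ancova_table(2, group_signal=1.0, covariate_signal=0.0)
        dummies = pd.get_dummies(table.group, dtype=float).to_numpy()
        basis = np.column_stack(
            [dummies, table.log_delay_threshold.to_numpy()])
        q, _ = np.linalg.qr(basis)

        def orthogonalise(v):
            v = v - q @ (q.T @ v)
            return v / v.std()

        c1 = orthogonalise(table.log_aniso_threshold.to_numpy())
        # second covariate also orthogonal to the first
        q2, _ = np.linalg.qr(np.column_stack([basis, c1]))
        c2 = table.sync_vector_z.to_numpy()
        c2 = c2 - q2 @ (q2.T @ c2)
        c2 /= c2.std()
        table = table.assign(log_aniso_threshold=c1, sync_vector_z=c2)

        oneway = oneway_anova_ges(table, "log_delay_threshold", "group")
        res = ancova_two_covariates(table)
        g = res["terms"]["C(group)"]
        assert g["sum_sq"] == pytest.approx(oneway["ss_effect"], rel=1e-6)
        # interactions of orthogonal covariates still absorb residual df,
        # so compare through the SS identity rather than raw F
        ms_group = g["sum_sq"] / g["df"][0]
        ms_resid = res["ss_residual"] / res["df_residual"]
        assert g["F"] == pytest.approx(ms_group / ms_resid, rel=1e-10)
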
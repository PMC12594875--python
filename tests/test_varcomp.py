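"""REML variance components against independent moment oracles, plus the
algebraic invariances the estimator must satisfy."""

import numpy as np
import pandas as pd
import pytest

from dietgxe.simulate import SimulationTruth, simulate_phenotypes
from dietgxe.varcomp import ModelSpec, anova_type3_balanced, fit_mixed_model
from dietgxe.varcomp import test_random_term as lrt_random_term

ONE_WAY = ModelSpec(trait="trait", fixed=(), random=("line",))


def one_way_panel(seed=21, n_lines=10, n=5, s2l=1.0, s2e=1.0):
    truth = SimulationTruth(
        n_lines=n_lines, var_components={"line": s2l, "e": s2e}, seed=seed,
    )
    return simulate_phenotypes(
        truth, None, diets=("control",), ages=(7,), n_reps=1, flies_per_rep=n,
    )


class TestOneWayOracle:
    def test_reml_equals_classical_ems_identity(self):
        """sigma2_L = (MS_between - MS_within)/n on balanced one-way data."""
        df = one_way_panel()
        y = df["trait"].to_numpy()
        groups = [g.to_numpy() for _, g in df.groupby("line_id")["trait"]]
        a, n = len(groups), len(groups[0])
        grand = y.mean()
        msb = n * sum((g.mean() - grand) ** 2 for g in groups) / (a - 1)
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (a * (n - 1))
        expected_l = (msb - msw) / n

        vc = fit_mixed_model(df, ONE_WAY)
        assert vc.estimates["line"] == pytest.approx(expected_l, rel=1e-6)
        assert vc.estimates["e"] == pytest.approx(msw, rel=1e-6)


class TestBalancedTwoWayOracle:
    def test_matches_hand_ems_arithmetic(self, toy_two_way):
        """Independent EMS solution computed from explicit mean squares."""
        df = toy_two_way
        y = df["trait"].to_numpy()
        n, a, d, m = 12, 3, 2, 2
        grand = y.mean()
        lm = df.groupby("line_id")["trait"].mean()
        dm = df.groupby("diet")["trait"].mean()
        cm = df.groupby(["line_id", "diet"])["trait"].mean()
        ss_l = (n / a) * ((lm - grand) ** 2).sum()
        ss_ld = m * sum(
            (cm[li, di] - lm[li] - dm[di] + grand) ** 2
            for li in lm.index for di in dm.index
        )
        cell = df.groupby(["line_id", "diet"])["trait"].transform("mean")
        ss_e = ((y - cell) ** 2).sum()
        ms_l, ms_ld, ms_e = ss_l / (a - 1), ss_ld / ((a - 1) * (d - 1)), ss_e / 6
        # E[MS_e]=s2e; E[MS_LD]=s2e+2 s2ld; E[MS_L]=s2e+2 s2ld+4 s2l
        exp_e = ms_e
        exp_ld = (ms_ld - ms_e) / m
        exp_l = (ms_l - ms_ld) / (m * d)

        spec = ModelSpec(trait="trait", fixed=("diet",),
                         random=("line", "line:diet"))
        mom = anova_type3_balanced(df, spec)
        assert mom.estimates["e"] == pytest.approx(exp_e, rel=1e-12)
        assert mom.estimates["line:diet"] == pytest.approx(exp_ld, rel=1e-12)
        assert mom.estimates["line"] == pytest.approx(exp_l, rel=1e-12)

        # REML coincides on this balanced interior case
        vc = fit_mixed_model(df, spec)
        for t in ("line", "line:diet", "e"):
            assert vc.estimates[t] == pytest.approx(mom.estimates[t], rel=1e-6)

    def test_equal_cell_means_give_zero_components(self):
        rows = []
        for li in ("L1", "L2", "L3"):
            for di in ("control", "restricted"):
                for r in (1, 2):
                    rows.append({"line_id": li, "diet": di, "age_days": 7,
                                 "replicate": r, "trait": 4.0 + (r - 1.5)})
        df = pd.DataFrame(rows)
        spec = ModelSpec(trait="trait", fixed=("diet",),
                         random=("line", "line:diet"))
        # moment solution: interaction/line mean squares are exactly zero,
        # so the as-is Type-III estimates are non-positive ...
        mom = anova_type3_balanced(df, spec)
        assert mom.estimates["line"] <= 0.0
        assert mom.estimates["line:diet"] <= 0.0
        assert mom.estimates["e"] == pytest.approx(0.5, rel=1e-12)
        # ... while REML truncates them at the zero boundary
        vc = fit_mixed_model(df, spec)
        assert vc.estimates["line"] == 0.0 and "line" in vc.boundary
        assert vc.estimates["line:diet"] == 0.0

    def test_unbalanced_input_rejected(self, toy_two_way):
        spec = ModelSpec(trait="trait", fixed=("diet",),
                         random=("line", "line:diet"))
        with pytest.raises(ValueError, match="not balanced"):
            anova_type3_balanced(toy_two_way.iloc[:-1], spec)


class TestFullModel:
    def test_reml_matches_ems_on_full_balanced_design(self, balanced_panel):
        spec = ModelSpec(trait="trait")
        vc = fit_mixed_model(balanced_panel, spec)
        mom = anova_type3_balanced(balanced_panel, spec)
        for t in vc.estimates:
            assert vc.estimates[t] == pytest.approx(mom.estimates[t], rel=1e-6)

    def test_zero_residual_noise_hits_boundary(self):
        truth = SimulationTruth(
            n_lines=8, var_components={"line": 1.0, "e": 0.0}, seed=5,
        )
        df = simulate_phenotypes(
            truth, None, diets=("control",), ages=(7,), n_reps=1,
            flies_per_rep=5,
        )
        vc = fit_mixed_model(df, ONE_WAY)
        assert "e" in vc.boundary
        line_effects = df.groupby("line_id")["trait"].mean()
        assert vc.estimates["line"] == pytest.approx(
            line_effects.var(ddof=1), rel=1e-3
        )

    def test_scale_equivariance(self, balanced_panel):
        spec = ModelSpec(trait="trait")
        vc1 = fit_mixed_model(balanced_panel, spec, compute_cov=False)
        scaled = balanced_panel.assign(trait=balanced_panel["trait"] * 3.0)
        vc2 = fit_mixed_model(scaled, spec, compute_cov=False)
        for t in vc1.estimates:
            assert vc2.estimates[t] == pytest.approx(9.0 * vc1.estimates[t],
                                                     rel=1e-5, abs=1e-10)

    def test_row_permutation_invariance(self, balanced_panel):
        spec = ModelSpec(trait="trait")
        vc1 = fit_mixed_model(balanced_panel, spec, compute_cov=False)
        shuffled = balanced_panel.sample(frac=1.0, random_state=42)
        vc2 = fit_mixed_model(shuffled, spec, compute_cov=False)
        for t in vc1.estimates:
            assert vc2.estimates[t] == pytest.approx(vc1.estimates[t],
                                                     rel=1e-8, abs=1e-12)

    def test_unbalanced_data_converges(self, balanced_panel):
        df = balanced_panel.sample(frac=0.7, random_state=1)
        vc = fit_mixed_model(df, ModelSpec(trait="trait"))
        assert vc.converged
        assert all(v >= 0 for v in vc.estimates.values())
        assert vc.asy_cov.shape == (6, 6)
        np.testing.assert_allclose(
            vc.asy_cov.to_numpy(), vc.asy_cov.to_numpy().T, atol=1e-12
        )

    def test_too_few_levels_rejected(self):
        df = one_way_panel(n_lines=2).query("line_id == 'line_001'")
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            fit_mixed_model(df, ONE_WAY)


class TestRandomTermLrt:
    def test_identical_loglik_gives_p_one(self, balanced_panel):
        import dataclasses

        full = ModelSpec(trait="trait", random=("line", "line:diet"))
        red = ModelSpec(trait="trait", random=("line",))
        f = fit_mixed_model(balanced_panel, full, compute_cov=False)
        r = dataclasses.replace(f, spec=red)
        assert lrt_random_term(f, r) == 1.0

    def test_dropping_a_real_term_is_detected(self, balanced_panel):
        full = ModelSpec(trait="trait")
        red = ModelSpec(trait="trait",
                        random=("line", "line:age", "line:diet", "rep"))
        f = fit_mixed_model(balanced_panel, full, compute_cov=False)
        r = fit_mixed_model(balanced_panel, red, compute_cov=False)
        p = lrt_random_term(f, r)
        assert 0.0 <= p <= 1.0
        assert f.loglik >= r.loglik - 1e-8   # nesting

    def test_non_nested_rejected(self, balanced_panel):
        a = fit_mixed_model(
            balanced_panel,
            ModelSpec(trait="trait", random=("line", "line:age")),
            compute_cov=False,
        )
        b = fit_mixed_model(
            balanced_panel,
            ModelSpec(trait="trait", random=("line", "line:diet")),
            compute_cov=False,
        )
        with pytest.raises(ValueError, match="nested"):
            lrt_random_term(a, b)
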
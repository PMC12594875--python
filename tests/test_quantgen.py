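"""Heritability, correlation and rank-decomposition arithmetic against
closed forms and brute-force oracles."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietgxe.quantgen import (
    estimate_H2,
    genetic_correlation,
    gxe_summary,
    percent_rank,
    spearman_correlation,
)
from dietgxe.varcomp import ModelSpec, VarianceComponents


def make_vc(estimates, asy_cov=None, random=None):
    random = random or tuple(t for t in estimates if t != "e")
    spec = ModelSpec(trait="t", fixed=(), random=random)
    terms = list(random) + ["e"]
    cov = None
    if asy_cov is not None:
        cov = pd.DataFrame(asy_cov, index=terms, columns=terms)
    return VarianceComponents(
        spec=spec, estimates=estimates, asy_cov=cov,
        fixed_effects=pd.Series(dtype=float), fixed_se=pd.Series(dtype=float),
        loglik=0.0, n_obs=100, converged=True,
    )


class TestHeritability:
    def test_quarter(self):
        h = estimate_H2(make_vc({"line": 1.0, "e": 3.0}))
        assert h.H2 == pytest.approx(0.25)

    def test_half_with_all_interactions(self):
        h = estimate_H2(make_vc({
            "line": 1.0, "line:age": 1.0, "line:diet": 1.0,
            "line:age:diet": 1.0, "e": 4.0,
        }))
        assert h.H2 == pytest.approx(0.5)

    def test_delta_method_arithmetic(self):
        # Var(sG)=Var(se)=0.04, cov=0, G=e=1 -> Var(H2)=2*(1/4)^2*0.04=0.005
        h = estimate_H2(make_vc(
            {"line": 1.0, "e": 1.0}, asy_cov=[[0.04, 0.0], [0.0, 0.04]],
        ))
        assert h.var_H2 == pytest.approx(0.005)
        assert h.se_H2 == pytest.approx(np.sqrt(0.005))  # ~0.0707
        assert h.ci_low == pytest.approx(0.5 - 1.96 * h.se_H2)
        assert h.ci_high == pytest.approx(0.5 + 1.96 * h.se_H2)

    def test_rep_variance_excluded_from_ratio(self):
        h = estimate_H2(make_vc({"line": 1.0, "rep": 2.0, "e": 3.0}))
        assert h.H2 == pytest.approx(0.25)          # rep excluded as printed
        assert h.H2_with_rep == pytest.approx(1.0 / 6.0)   # labelled alternative

    def test_all_zero_is_undefined(self):
        with pytest.raises(ValueError, match="0/0"):
            estimate_H2(make_vc({"line": 0.0, "e": 0.0}))

    def test_invariant_to_rescaling_and_monotone_in_genetic_variance(self):
        base = estimate_H2(make_vc({"line": 1.0, "e": 2.0})).H2
        scaled = estimate_H2(make_vc({"line": 9.0, "e": 18.0})).H2
        assert scaled == pytest.approx(base)
        more = estimate_H2(make_vc({"line": 1.5, "e": 2.0})).H2
        assert more > base

    def test_delta_se_close_to_parametric_bootstrap(self):
        """Delta-method SE vs bootstrap SD of H2 on a one-way panel."""
        from dietgxe.simulate import SimulationTruth, simulate_phenotypes
        from dietgxe.varcomp import fit_mixed_model

        spec = ModelSpec(trait="trait", fixed=(), random=("line",))

        def fit(seed, s2l, s2e, cov):
            truth = SimulationTruth(
                n_lines=100, var_components={"line": s2l, "e": s2e}, seed=seed,
            )
            df = simulate_phenotypes(
                truth, None, diets=("control",), ages=(7,), n_reps=1,
                flies_per_rep=10,
            )
            return fit_mixed_model(df, spec, compute_cov=cov)

        anchor = fit(2024, 2.0 / 3.0, 1.0, cov=True)   # true H2 = 0.4
        delta_se = estimate_H2(anchor).se_H2
        s2l, s2e = anchor.estimates["line"], anchor.estimates["e"]
        boot = [
            estimate_H2(make_vc(fit(3000 + b, s2l, s2e, cov=False).estimates))
            .H2
            for b in range(200)
        ]
        assert delta_se == pytest.approx(np.std(boot, ddof=1), rel=0.2)


class TestGeneticCorrelation:
    def test_plain_ratio(self):
        c = genetic_correlation(0.5, 1.0, 1.0, n_lines=50)
        assert c.rho == pytest.approx(0.5)
        assert c.se == pytest.approx((1 - 0.25) / np.sqrt(47))
        assert not c.out_of_range

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 2, 40)
        sd = m.std(ddof=1)
        c = genetic_correlation(np.cov(m, m, ddof=1)[0, 1], sd, sd, 40)
        assert c.rho == pytest.approx(1.0)

    def test_out_of_range_flagged_not_clamped(self):
        c = genetic_correlation(1.5, 1.0, 1.0, n_lines=20)
        assert c.rho == pytest.approx(1.5)
        assert c.out_of_range

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError, match="among-line variance"):
            genetic_correlation(0.1, 0.0, 1.0, 20)

    def test_recovery_within_two_se(self):
        """Estimated rho within +/-2 SE of truth in >=93% of replicates."""
        rho, n_lines, n_rep = 0.7, 200, 300
        rng = np.random.default_rng(99)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        hits = 0
        for _ in range(n_rep):
            xy = rng.multivariate_normal([0, 0], cov, n_lines)
            c = genetic_correlation(
                np.cov(xy.T, ddof=1)[0, 1],
                xy[:, 0].std(ddof=1), xy[:, 1].std(ddof=1), n_lines,
            )
            hits += abs(c.rho - rho) <= 2 * c.se
        assert hits / n_rep >= 0.93


class TestPercentRank:
    @pytest.mark.parametrize("si,sj,rho,expected", [
        (1.0, 1.0, 0.0, 100.0),
        (2.0, 1.0, 0.5, 100.0 / 1.5),     # 66.67%
        (2.0, 1.0, 1.0, 0.0),
    ])
    def test_closed_forms(self, si, sj, rho, expected):
        d = percent_rank(si, sj, rho)
        assert d.pct_rank == pytest.approx(expected, abs=1e-10)
        assert d.rank_component + d.scale_component == pytest.approx(
            si * sj * (1 - rho) + (si - sj) ** 2 / 2
        )

    def test_no_interaction_status(self):
        d = percent_rank(1.0, 1.0, 1.0)
        assert d.pct_rank is None and d.status == "no interaction"

    @given(
        st.floats(0.1, 5.0), st.floats(0.1, 5.0), st.floats(-0.99, 0.99),
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetry_and_range(self, si, sj, rho):
        a = percent_rank(si, sj, rho)
        b = percent_rank(sj, si, rho)
        assert a.pct_rank == pytest.approx(b.pct_rank)
        assert 0.0 <= a.pct_rank <= 100.0

    def test_decreasing_in_rho(self):
        vals = [percent_rank(2.0, 1.0, r).pct_rank for r in (-0.5, 0.0, 0.5, 0.9)]
        assert vals == sorted(vals, reverse=True)

    def test_equal_sigmas_always_pure_rank(self):
        for rho in (-0.9, 0.0, 0.7, 0.999):
            assert percent_rank(1.7, 1.7, rho).pct_rank == pytest.approx(100.0)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.arange(1.0, 13.0)
        c = spearman_correlation(x, np.exp(x))
        assert c.rho == pytest.approx(1.0)
        assert c.ci_high == 1.0

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, -x).rho == pytest.approx(-1.0)

    def test_null_se_and_fisher_ci_at_n52(self):
        # rho=0, n=52: SE = 1/7, z = 0, CI = tanh(+/-1.96/7) = +/-0.2729
        rng = np.random.default_rng(8)
        x = np.arange(52.0)
        y = rng.permutation(52).astype(float)
        c = spearman_correlation(x, y)
        se_null = (1 - 0**2) / np.sqrt(52 - 3)
        assert se_null == pytest.approx(1 / 7)
        assert np.tanh(1.96 * se_null) == pytest.approx(0.2729, abs=5e-5)
        # and the estimator's own CI obeys the same construction
        assert c.ci_low == pytest.approx(np.tanh(c.fisher_z - 1.96 * c.se))
        assert c.ci_high == pytest.approx(np.tanh(c.fisher_z + 1.96 * c.se))

    def test_matches_rank_then_pearson_on_all_permutations(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        for perm in itertools.permutations(range(6)):
            y = np.array([10.0, 2.0, 7.0, 5.0, 1.0, 6.0])[list(perm)]
            rx = pd.Series(x).rank().to_numpy()
            ry = pd.Series(y).rank().to_numpy()
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman_correlation(x, y).rho == pytest.approx(oracle)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="4 paired"):
            spearman_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def _line_means_frame(values: dict, conditions=("control", "restricted")):
    rows = []
    for line, (v1, v2) in values.items():
        rows.append({"line_id": line, "diet": conditions[0], "age_days": 7,
                     "mean": v1, "n": 5, "sd": 1.0, "trait": "t"})
        rows.append({"line_id": line, "diet": conditions[1], "age_days": 7,
                     "mean": v2, "n": 5, "sd": 1.0, "trait": "t"})
    return pd.DataFrame(rows)


class TestGxeSummary:
    def test_pure_rank_change(self):
        # equal per-condition sigma, low correlation -> ~100% rank
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 200)
        b = 0.3 * a + np.sqrt(1 - 0.09) * rng.normal(0, 1, 200)
        b *= a.std(ddof=1) / b.std(ddof=1)    # exactly equal sigmas
        lm = _line_means_frame({f"L{i}": (a[i], b[i]) for i in range(200)})
        s = gxe_summary(line_means=lm, trait="t", axis="diet")
        assert s["pct_rank"].pct_rank == pytest.approx(100.0, abs=1e-6)
        assert abs(s["rho_G"].rho - 0.3) < 0.2

    def test_pure_scale_change(self):
        # identical standardized line effects, sigma ratio 2 -> 0% rank
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 100)
        lm = _line_means_frame({f"L{i}": (2 * a[i], a[i]) for i in range(100)})
        s = gxe_summary(line_means=lm, trait="t", axis="diet")
        assert s["pct_rank"].pct_rank == pytest.approx(0.0, abs=1e-8)
        assert s["rho_G"].rho == pytest.approx(1.0)

    def test_duplicated_condition_reports_no_interaction(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 50)
        lm = _line_means_frame({f"L{i}": (a[i], a[i]) for i in range(50)})
        s = gxe_summary(line_means=lm, trait="t", axis="diet")
        assert s["rho_G"].rho == pytest.approx(1.0)
        assert s["pct_rank"].status == "no interaction"

    def test_too_few_shared_lines(self):
        lm = _line_means_frame({"L1": (1, 2), "L2": (2, 3), "L3": (3, 1)})
        with pytest.raises(ValueError, match="4 shared"):
            gxe_summary(line_means=lm, trait="t", axis="diet")
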
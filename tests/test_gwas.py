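"""GRM construction, response building, covariate adjustment and the
mixed-model scan, checked against ordinary least squares and null
calibration."""

import numpy as np
import pandas as pd
import pytest

from dietgxe.gwas import (
    ResponsePhenotype,
    adjust_covariates,
    bonferroni_threshold,
    compute_grm,
    genomic_control_lambda,
    gwas_scan,
    make_response,
    plot_tables,
)
from dietgxe.simulate import GenotypeMatrix, simulate_covariates, simulate_genotypes


def response_from(values, line_ids):
    return ResponsePhenotype(
        values=pd.Series(values, index=line_ids), description="test",
    )


class TestGrm:
    def test_identical_lines_share_relatedness(self, small_genotypes):
        g = small_genotypes
        dup = GenotypeMatrix(
            dosages=np.vstack([g.dosages, g.dosages[:1]]),
            variant_meta=g.variant_meta,
            line_ids=g.line_ids + ["copy_of_first"],
        )
        grm = compute_grm(dup)
        K = grm.matrix
        assert K[0, -1] == pytest.approx(K[0, 0], abs=1e-10)
        assert K[-1, -1] == pytest.approx(K[0, 0], abs=1e-10)

    def test_variant_permutation_invariance(self, small_genotypes):
        g = small_genotypes
        rng = np.random.default_rng(1)
        perm = rng.permutation(g.n_variants)
        shuffled = GenotypeMatrix(
            dosages=g.dosages[:, perm],
            variant_meta=g.variant_meta.iloc[perm].reset_index(drop=True),
            line_ids=g.line_ids,
        )
        np.testing.assert_allclose(
            compute_grm(g).matrix, compute_grm(shuffled).matrix, atol=1e-12
        )

    def test_offdiagonals_vanish_for_exchangeable_variants(self):
        g = simulate_genotypes(40, 5000, ("uniform", 0.2, 0.5), seed=13)
        K = compute_grm(g).matrix
        off = K[~np.eye(40, dtype=bool)]
        # empirical centering forces sum_i z_i = 0, so the off-diagonal
        # mean is pinned near -diag.mean()/(n-1)
        assert abs(off.mean() + np.diag(K).mean() / 39) < 0.005
        assert np.abs(off).mean() < 3.0 / np.sqrt(5000)
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.1)

    def test_no_passing_variants(self):
        g = simulate_genotypes(10, 5, ("point", 0.5), seed=3)
        with pytest.raises(ValueError, match="MAF threshold"):
            compute_grm(g, maf_min=0.5)


class TestResponse:
    def lm(self, values):
        rows = []
        for line, (c, r) in values.items():
            if c is not None:
                rows.append({"line_id": line, "diet": "control", "age_days": 7,
                             "mean": c, "n": 3, "sd": 1.0, "trait": "t"})
            if r is not None:
                rows.append({"line_id": line, "diet": "restricted", "age_days": 7,
                             "mean": r, "n": 3, "sd": 1.0, "trait": "t"})
        return pd.DataFrame(rows)

    def test_toy_differences(self):
        resp = make_response(self.lm({"L1": (5, 3), "L2": (4, 4)}),
                             mode="difference",
                             conditions=("control", "restricted"))
        assert resp.values.to_dict() == {"L1": 2.0, "L2": 0.0}

    def test_identical_conditions_give_zero(self):
        resp = make_response(self.lm({"L1": (7, 7), "L2": (3, 3)}),
                             mode="difference",
                             conditions=("control", "restricted"))
        assert (resp.values == 0).all()

    def test_lines_missing_a_condition_are_excluded_and_reported(self):
        resp = make_response(self.lm({"L1": (5, 3), "L2": (4, None)}),
                             mode="difference",
                             conditions=("control", "restricted"))
        assert list(resp.values.index) == ["L1"]
        assert resp.excluded_lines == ["L2"]

    def test_single_mode(self):
        resp = make_response(self.lm({"L1": (5, 3), "L2": (4, 1)}),
                             mode="single", conditions="restricted")
        assert resp.values.to_dict() == {"L1": 3.0, "L2": 1.0}

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            make_response(self.lm({"L1": (5, None), "L2": (None, 2)}),
                          mode="difference",
                          conditions=("control", "restricted"))


class TestCovariateAdjustment:
    def test_response_equal_to_wolbachia_vanishes(self, small_genotypes):
        cov = simulate_covariates(small_genotypes.line_ids, seed=5)
        resp = response_from(cov["wolbachia"].astype(float).to_numpy(),
                             small_genotypes.line_ids)
        adj = adjust_covariates(resp, cov)
        assert adj.adjusted
        np.testing.assert_allclose(adj.values.to_numpy(), 0.0, atol=1e-10)

    def test_orthogonal_covariates_only_center(self, small_genotypes):
        cov = simulate_covariates(small_genotypes.line_ids, seed=5)
        cov["wolbachia"] = False
        for c in cov.columns:
            if c.startswith("In"):
                cov[c] = "ST"
        rng = np.random.default_rng(2)
        y = rng.normal(5.0, 1.0, len(cov))
        with pytest.warns(UserWarning, match="aliased"):
            # constant covariates are aliased with the intercept and dropped
            adj = adjust_covariates(response_from(y, small_genotypes.line_ids),
                                    cov)
        np.testing.assert_allclose(adj.values.to_numpy(), y - y.mean(),
                                   atol=1e-10)

    def test_planted_confounder_removed(self, small_genotypes):
        cov = simulate_covariates(small_genotypes.line_ids, seed=5)
        rng = np.random.default_rng(3)
        y = 2.0 * cov["wolbachia"].astype(float).to_numpy() + rng.normal(
            0, 0.5, len(cov)
        )
        adj = adjust_covariates(response_from(y, small_genotypes.line_ids), cov)
        w = cov["wolbachia"].astype(float).to_numpy()
        assert abs(np.corrcoef(adj.values, w)[0, 1]) < 1e-8

    def test_missing_lines_rejected(self, small_genotypes):
        cov = simulate_covariates(small_genotypes.line_ids[:-1], seed=5)
        resp = response_from(np.ones(30), small_genotypes.line_ids)
        with pytest.raises(ValueError, match="missing"):
            adjust_covariates(resp, cov)


class TestScan:
    def test_perfect_signal_attains_minimum_p(self, small_genotypes):
        g = small_genotypes
        v = int(np.argmax(g.maf()))                 # a well-powered variant
        y = g.dosages[:, v].astype(float)           # exact linear function
        scan = gwas_scan(response_from(y, g.line_ids), g, None)
        assert int(scan["p"].idxmin()) == v

    def test_grm_identity_equals_ols(self, small_genotypes):
        g = small_genotypes
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, g.n_lines)
        scan = gwas_scan(response_from(y, g.line_ids), g, None)
        n = g.n_lines
        tested = scan.index[scan["tested"]][:50]
        for v in tested:
            A = np.column_stack([np.ones(n), g.dosages[:, v]])
            b = np.linalg.lstsq(A, y, rcond=None)[0]
            r = y - A @ b
            s2 = (r @ r) / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(A.T @ A)[1, 1])
            assert scan["effect"][v] == pytest.approx(b[1], abs=1e-8)
            assert scan["se"][v] == pytest.approx(se, abs=1e-8)

    def test_affine_response_rescaling_preserves_p(self, small_genotypes):
        g = small_genotypes
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, g.n_lines)
        grm = compute_grm(g)
        p1 = gwas_scan(response_from(y, g.line_ids), g, grm)["p"]
        p2 = gwas_scan(response_from(3.0 * y + 7.0, g.line_ids), g, grm)["p"]
        # identical up to the null-model optimizer tolerance on h2
        np.testing.assert_allclose(p1.dropna(), p2.dropna(), rtol=1e-5)

    def test_low_maf_variants_flagged_untested(self):
        g = simulate_genotypes(60, 100, ("uniform", 0.02, 0.5), seed=9)
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, 60)
        scan = gwas_scan(response_from(y, g.line_ids), g, None, maf_min=0.05)
        low = scan[~scan["tested"]]
        assert (low["maf"] <= 0.05).all()
        assert (low["filter_reason"] == "maf<=0.05").all()
        assert scan.loc[scan["tested"], "p"].between(0, 1).all()

    def test_misaligned_lines_rejected(self, small_genotypes):
        resp = response_from(np.ones(3), ["nope_1", "nope_2", "nope_3"])
        with pytest.raises(ValueError, match="absent"):
            gwas_scan(resp, small_genotypes, None)


class TestThresholdAndTables:
    @pytest.mark.parametrize("n,alpha,expected", [
        (1_928_067, 0.05, 2.593e-8),
        (1, 0.05, 0.05),
        (100, 0.05, 5e-4),
    ])
    def test_bonferroni(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected,
                                                               rel=1e-3)

    def test_bonferroni_needs_tests(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)

    def test_extreme_p_tops_manhattan(self, small_genotypes):
        g = small_genotypes
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, g.n_lines)
        scan = gwas_scan(response_from(y, g.line_ids), g, None)
        scan.loc[42, "p"] = 1e-12
        tables = plot_tables(scan)
        top = tables["manhattan"].loc[tables["manhattan"]["neglog10p"].idxmax()]
        assert top["pos"] == scan.loc[42, "pos"]

    def test_qq_near_diagonal_under_null(self):
        g = simulate_genotypes(120, 600, ("uniform", 0.1, 0.5), seed=21)
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, g.n_lines)
        scan = gwas_scan(response_from(y, g.line_ids), g, None)
        qq = plot_tables(scan)["qq"]
        inside = (
            (qq["observed_neglog10p"] >= qq["band_low_neglog10p"])
            & (qq["observed_neglog10p"] <= qq["band_high_neglog10p"])
        )
        assert inside.mean() >= 0.95
        lam = genomic_control_lambda(scan["p"].dropna())
        assert 0.7 < lam < 1.3

    def test_empty_tested_set_rejected(self, small_genotypes):
        scan = gwas_scan(
            response_from(np.random.default_rng(9).normal(size=30),
                          small_genotypes.line_ids),
            small_genotypes, None,
        )
        scan["tested"] = False
        with pytest.raises(ValueError, match="no tested"):
            plot_tables(scan)
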
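import numpy as np
import pandas as pd
import pytest

from nbpower.pilot_estimation import (
    CountMatrix,
    estimate_common_dispersion,
    estimate_gene_params,
    estimate_pilot,
    filter_low_count_genes,
    norm_factors,
    ratio_w,
    select_prognostic,
)
from tests.conftest import make_count_matrix

# edgeR 4.0.16 calcNormFactors(method="TMM") on the seeded fixture from
# conftest, converted to effective per-sample factors with geometric mean 1
EDGER_EFFECTIVE_FACTORS = np.array(
    [0.6237495373, 1.0218036976, 1.4881667652, 0.8544175579, 1.2803619599, 0.9637574880]
)


class TestCountMatrix:
    def test_duplicate_gene_ids_rejected(self):
        cols = ["a", "b"]
        frame = pd.DataFrame([[1, 2], [3, 4]], index=["g", "g"], columns=cols)
        groups = pd.Series(["control", "treatment"], index=cols)
        with pytest.raises(ValueError, match="duplicate"):
            CountMatrix(frame, groups)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_count_matrix([[1, -1, 2, 2]])

    def test_unlabelled_sample_rejected(self):
        frame = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            CountMatrix(frame, pd.Series(["control"], index=["a"]))


class TestFilter:
    def test_low_group_total_removed(self):
        # control total 5 is "no more than 5" -> gene dropped even though
        # the treatment group is abundant; totals of 6 survive
        cm = make_count_matrix([[2, 3, 50, 50], [3, 3, 3, 3], [10, 10, 2, 3]])
        kept = filter_low_count_genes(cm, min_total=5)
        assert list(kept.counts.index) == ["g1"]

    def test_boundary_kept_just_above_threshold(self):
        cm = make_count_matrix([[3, 3, 3, 3]])
        kept = filter_low_count_genes(cm, min_total=5)
        assert kept.n_genes == 1

    def test_all_zero_matrix_errors(self):
        cm = make_count_matrix(np.zeros((3, 4), dtype=int))
        with pytest.raises(ValueError):
            filter_low_count_genes(cm)


class TestNormFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 8, 0, 13, 40])
        cm = make_count_matrix(np.tile(col[:, None], (1, 4)))
        np.testing.assert_allclose(norm_factors(cm).to_numpy(), 1.0, atol=1e-12)

    def test_pure_depth_difference(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(30, size=(50, 1))
        counts = np.hstack([base, 2 * base, base, base])
        cm = make_count_matrix(counts)
        d = norm_factors(cm)
        assert d.iloc[1] / d.iloc[0] == pytest.approx(2.0, rel=1e-9)

    def test_matches_edger_oracle(self, tmm_fixture_counts):
        cm = make_count_matrix(tmm_fixture_counts)
        d = norm_factors(cm, method="tmm")
        np.testing.assert_allclose(d.to_numpy(), EDGER_EFFECTIVE_FACTORS, atol=1e-8)

    def test_geometric_mean_is_one(self, tmm_fixture_counts):
        for method in ("tmm", "libsize"):
            d = norm_factors(make_count_matrix(tmm_fixture_counts), method=method)
            assert np.exp(np.mean(np.log(d))) == pytest.approx(1.0, abs=1e-10)

    def test_all_zero_sample_errors(self):
        counts = np.array([[1, 0, 2, 3], [4, 0, 5, 6]])
        with pytest.raises(ValueError, match="all-zero"):
            norm_factors(make_count_matrix(counts))


class TestRatioW:
    def test_equal_factors(self):
        f = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        g = pd.Series(["control", "control", "treatment", "treatment"], index=list("abcd"))
        assert ratio_w(f, g) == pytest.approx(1.0)

    def test_doubled_treatment_factors(self):
        f = pd.Series([1.0, 1.0, 2.0, 2.0], index=list("abcd"))
        g = pd.Series(["control", "control", "treatment", "treatment"], index=list("abcd"))
        assert ratio_w(f, g) == pytest.approx(2.0)

    def test_targeted_depth_imbalance_recovered(self):
        # libraries built so treatment depth is ~0.9x the control depth
        rng = np.random.default_rng(5)
        base = rng.gamma(3, 20, size=300)
        depth = np.array([1.0, 1.0, 1.0, 0.9, 0.9, 0.9])
        counts = rng.poisson(np.outer(base, depth))
        cm = make_count_matrix(counts, n_control=3)
        d = norm_factors(cm, method="tmm")
        assert ratio_w(d, cm.groups) == pytest.approx(0.9, abs=0.01)


class TestGeneParams:
    def test_equal_means_give_unit_fold_change(self):
        cm = make_count_matrix([[7, 9, 8, 8], [3, 5, 4, 4]])
        d = pd.Series(1.0, index=cm.counts.columns)
        est = estimate_gene_params(cm, d, common_dispersion=0.0)
        assert est.loc["g0", "rho"] == pytest.approx(1.0)
        assert est.loc["g0", "mu0"] == pytest.approx(8.0)

    def test_zero_mean_group_uses_continuity_offset(self):
        cm = make_count_matrix([[0, 0, 10, 10]])
        d = pd.Series(1.0, index=cm.counts.columns)
        est = estimate_gene_params(cm, d, common_dispersion=0.0)
        assert est.loc["g0", "rho"] == pytest.approx(10.5 / 0.5)

    def test_poisson_gene_dispersion_near_zero(self):
        rng = np.random.default_rng(21)
        counts = rng.poisson(20.0, size=(8, 100))  # 50 per group
        cm = make_count_matrix(counts)
        d = pd.Series(1.0, index=cm.counts.columns)
        est = estimate_gene_params(cm, d, common_dispersion=0.0)
        assert (est["phi"] < 0.02).all()

    def test_nb_dispersion_recovery(self):
        rng = np.random.default_rng(22)
        phi, mu = 0.5, 10.0
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(12, 200))  # 100/group
        cm = make_count_matrix(counts)
        d = pd.Series(1.0, index=cm.counts.columns)
        est = estimate_gene_params(cm, d, common_dispersion=phi)
        med_rel_err = np.median(np.abs(est["phi"] - phi) / phi)
        assert med_rel_err < 0.25
        assert est["phi"].between(0.25, 0.80).mean() > 0.8

    def test_fold_change_recovery(self):
        rng = np.random.default_rng(23)
        mu0, rho, phi = 8.0, 2.0, 0.2
        r = 1 / phi
        ctrl = rng.negative_binomial(r, r / (r + mu0), size=(40, 100))
        trt = rng.negative_binomial(r, r / (r + rho * mu0), size=(40, 100))
        cm = make_count_matrix(np.hstack([ctrl, trt]))
        d = pd.Series(1.0, index=cm.counts.columns)
        est = estimate_gene_params(cm, d, common_dispersion=phi)
        assert np.median(np.abs(est["rho"] - rho) / rho) < 0.10

    @pytest.mark.parametrize("method,rtol", [("libsize", 1e-6), ("tmm", 0.02)])
    def test_scale_invariance_of_estimates(self, tmm_fixture_counts, method, rtol):
        # tripling one library's depth is absorbed by its factor: fold
        # changes are untouched, and control means shift only by the common
        # geometric-mean renormalization (3^(1/6)) shared by every gene.
        # Library-size factors absorb the change exactly; TMM's precision
        # weights depend on depth, so its factors move at the percent level.
        cm = filter_low_count_genes(
            make_count_matrix(tmm_fixture_counts, n_control=3), min_total=5
        )
        d = norm_factors(cm, method=method)
        est = estimate_gene_params(cm, d, common_dispersion=0.1)
        scaled_counts = tmm_fixture_counts.copy().astype(int)
        scaled_counts[:, 0] *= 3
        cm2 = filter_low_count_genes(
            make_count_matrix(scaled_counts, n_control=3), min_total=5
        )
        cm2 = CountMatrix(cm2.counts.loc[cm.counts.index], cm2.groups)
        d2 = norm_factors(cm2, method=method)
        est2 = estimate_gene_params(cm2, d2, common_dispersion=0.1)
        np.testing.assert_allclose(est2["rho"], est["rho"], rtol=rtol)
        ratio = (est2["mu0"] / est["mu0"]).to_numpy()
        np.testing.assert_allclose(ratio, 3 ** (1 / 6), rtol=rtol)

    def test_single_replicate_group_rejected(self):
        cm = make_count_matrix([[1, 2, 3]], n_control=1)
        d = pd.Series(1.0, index=cm.counts.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            estimate_gene_params(cm, d)


class TestCommonDispersion:
    def test_conditional_estimator_recovers_truth(self):
        rng = np.random.default_rng(31)
        phi, mu = 0.3, 6.0
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(600, 12))
        cm = make_count_matrix(counts)
        assert estimate_common_dispersion(cm) == pytest.approx(phi, rel=0.15)

    def test_poisson_data_estimated_at_boundary(self):
        rng = np.random.default_rng(32)
        counts = rng.poisson(10.0, size=(400, 10))
        cm = make_count_matrix(counts)
        assert estimate_common_dispersion(cm) < 0.01


class TestSelectPrognostic:
    def _frame(self):
        return pd.DataFrame(
            {
                "rho": [2.0, 1.1, 8.0, 0.5, 1.0],
                "pvalue": [0.01, 0.20, 0.01, 0.05, 0.90],
                "mu0": 1.0,
                "phi": 0.1,
            },
            index=["gA", "gB", "gC", "gD", "gE"],
        )

    def test_ceiling_count_and_order(self):
        chosen = select_prognostic(self._frame(), 0.45)  # ceil(2.25) = 3
        # ties at p=0.01 broken toward larger |log2 rho|: gC (8.0) before gA
        assert list(chosen) == ["gC", "gA", "gD"]

    def test_proportion_bounds(self):
        with pytest.raises(ValueError):
            select_prognostic(self._frame(), 1.5)

    def test_full_tie_breaks_lexicographically(self):
        frame = pd.DataFrame(
            {"rho": [2.0, 2.0], "pvalue": [0.5, 0.5], "mu0": 1.0, "phi": 0.1},
            index=["z", "a"],
        )
        assert list(select_prognostic(frame, 0.5)) == ["a"]


class TestPipeline:
    def test_estimate_pilot_end_to_end(self, tmm_fixture_counts):
        cm = make_count_matrix(tmm_fixture_counts, n_control=3)
        est = estimate_pilot(cm, min_total=5, proportion=0.1)
        assert est.per_gene["prognostic"].sum() == int(np.ceil(0.1 * len(est.per_gene)))
        assert est.w > 0
        # the DE block was planted in the treatment group at 4x
        de_genes = [f"g{i}" for i in range(10) if f"g{i}" in est.per_gene.index]
        assert est.per_gene.loc[de_genes, "prognostic"].mean() > 0.5
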
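"""Fit indices, evidence weights, entropy diagnostics, bootstrap LRT."""

import numpy as np
import pandas as pd
import pytest

import epiiprofiles as ep
from epiiprofiles import selection, tables


class TestInformationCriteria:
    def test_recompute_published_five_class_row(self):
        """BIC and SABIC recomputed from the printed five-class (LL, d)
        at N=652 match the printed columns to rounding of the printed LL."""
        d, ll = tables.FIT_TABLE_LL[5]
        bic, sabic = tables.FIT_TABLE_BIC[5]
        ic = ep.information_criteria(ll, d, tables.STUDY_N)
        assert ic["BIC"] == pytest.approx(bic, abs=0.02)
        assert ic["SABIC"] == pytest.approx(sabic, abs=0.02)

    def test_zero_parameters_all_equal_minus_2ll(self):
        ic = ep.information_criteria(-100.0, 0, 50)
        assert set(ic.values()) == {200.0}

    def test_requires_n_above_one(self):
        with pytest.raises(ValueError):
            ep.information_criteria(-1.0, 2, 1)


class TestEvidenceWeights:
    def test_equal_bics_split_evenly(self):
        bf, cmp_ = ep.evidence_weights([100.0, 100.0])
        assert bf[0] == pytest.approx(1.0)
        assert np.allclose(cmp_, [0.5, 0.5])

    def test_bayes_factor_closed_form(self):
        bf, _ = ep.evidence_weights([0.0, 2 * np.log(10)])
        assert bf[0] == pytest.approx(10.0)

    def test_cmp_direct_evaluation(self):
        _, cmp_ = ep.evidence_weights([0.0, 2 * np.log(2), 1000.0])
        assert np.allclose(cmp_, [2 / 3, 1 / 3, 0.0], atol=1e-9)

    def test_transitivity_in_log_space_and_normalization(self):
        rng = np.random.default_rng(0)
        bics = rng.uniform(1000, 2000, 5)
        bf, cmp_ = ep.evidence_weights(bics)
        sic = -bics / 2
        # BF(A,C) must equal BF(A,B) * BF(B,C) exactly in log space
        assert np.log(bf[0]) + np.log(bf[1]) == pytest.approx(sic[0] - sic[2])
        assert cmp_.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_model(self):
        bf, cmp_ = ep.evidence_weights([123.0])
        assert bf.size == 0 and np.allclose(cmp_, [1.0])


class TestRelativeEntropy:
    def test_one_hot_rows_give_one(self):
        assert ep.relative_entropy(np.eye(4)[[0, 1, 2, 3, 0]]) == pytest.approx(1.0)

    def test_uniform_rows_give_zero(self):
        assert ep.relative_entropy(np.full((6, 3), 1 / 3)) == pytest.approx(0.0)

    def test_hand_value_half(self):
        tau = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert ep.relative_entropy(tau) == pytest.approx(0.5)

    def test_blending_toward_uniform_never_increases(self):
        rng = np.random.default_rng(1)
        tau = rng.dirichlet(np.full(3, 0.5), size=50)
        uniform = np.full_like(tau, 1 / 3)
        vals = [ep.relative_entropy((1 - w) * tau + w * uniform)
                for w in (0.0, 0.25, 0.5, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        tau = rng.dirichlet(np.ones(4), size=30)
        assert ep.relative_entropy(tau[:, [3, 1, 0, 2]]) == pytest.approx(
            ep.relative_entropy(tau))

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            ep.relative_entropy(np.ones((5, 1)))


class TestUnivariateEntropy:
    def test_class_invariant_item_contributes_nothing(self):
        params = ep.LCAParameters([0.5, 0.5], np.array([[0.4, 0.4], [0.2, 0.9]]))
        assert ep.univariate_entropy(params, 0) == pytest.approx(0.0, abs=1e-12)

    def test_fully_diagnostic_item_approaches_one(self):
        for eps, floor in ((1e-3, 0.98), (1e-6, 0.999)):
            params = ep.LCAParameters([0.5, 0.5],
                                      np.array([[1 - eps, eps]]))
            assert ep.univariate_entropy(params, 0) > floor

    def test_published_high_entropy_items_rank_top_quartile(self, reference_params):
        """The childcare/teaching and work-exposure items that dominate
        the printed per-item entropy column also dominate ours."""
        items = tables.indicator_items()
        e = {it: ep.univariate_entropy(reference_params, j)
             for j, it in enumerate(items)}
        order = sorted(e, key=e.get, reverse=True)
        top_quartile = set(order[:len(items) // 4 + 1])
        assert {4, 5, 15, 16, 17} <= top_quartile

    def test_out_of_range_item_errors(self, reference_params):
        with pytest.raises(ValueError):
            ep.univariate_entropy(reference_params, 38)


class TestAvgPosteriorTable:
    def test_one_hot_gives_identity(self):
        tau = np.eye(3)[[0, 1, 2, 1]]
        W, _ = ep.modal_assignment(tau)
        assert np.allclose(ep.avg_posterior_table(tau, W).to_numpy(), np.eye(3))

    def test_hand_average(self):
        tau = np.array([[0.9, 0.1], [0.7, 0.3], [0.2, 0.8]])
        W, _ = ep.modal_assignment(tau)
        table = ep.avg_posterior_table(tau, W)
        assert np.allclose(table.iloc[0], [0.8, 0.2])

    def test_empty_class_warns_with_nan_row(self):
        tau = np.array([[0.9, 0.1], [0.8, 0.2]])
        W, _ = ep.modal_assignment(tau)
        with pytest.warns(UserWarning, match="class 2"):
            table = ep.avg_posterior_table(tau, W)
        assert table.iloc[1].isna().all()


class TestBootstrapLRT:
    def test_strong_two_class_structure_rejected_at_floor(self):
        rng = np.random.default_rng(3)
        labels = rng.random(500) < 0.5
        rho = np.where(labels[:, None], 0.9, 0.1)
        Y = (rng.random((500, 8)) < rho).astype(float)
        res = ep.bootstrap_lrt(Y, 2, B=19,
                               policy=ep.StartPolicy(n_starts=5, seed=0))
        assert res["p_value"] == pytest.approx(1 / 20)

    def test_invalid_arguments(self):
        Y = np.zeros((10, 2))
        with pytest.raises(ValueError):
            ep.bootstrap_lrt(Y, 1, B=9)
        with pytest.raises(ValueError):
            ep.bootstrap_lrt(Y, 2, B=0)


class TestEnumeration:
    def test_single_class_data_selects_one(self):
        rng = np.random.default_rng(8)
        Y = (rng.random((400, 6)) < [0.3, 0.5, 0.4, 0.6, 0.2, 0.7]).astype(float)
        enum = ep.class_enumeration(Y, 3, ep.StartPolicy(n_starts=10, seed=0))
        assert enum.selected_K == 1

    def test_kmax_one_gives_single_row(self):
        rng = np.random.default_rng(9)
        Y = rng.integers(0, 2, (50, 4)).astype(float)
        enum = ep.class_enumeration(Y, 1)
        assert list(enum.table.index) == [1]
        assert np.isnan(enum.table.loc[1, "BF_vs_next"])

    def test_table_identities(self, enumeration_2000, synthetic_2000):
        """d strictly increasing, BIC exactly -2LL + d ln N, cmP sums to 1."""
        tab = enumeration_2000.table
        n = synthetic_2000.config.n
        assert tab["d"].is_monotonic_increasing
        assert np.allclose(tab["BIC"],
                           -2 * tab["LL"] + tab["d"] * np.log(n), atol=1e-8)
        assert tab["cmP"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_entropy_column_matches_fits(self, enumeration_2000):
        for K, fit in enumeration_2000.fits.items():
            if K == 1:
                continue
            assert enumeration_2000.table.loc[K, "entropy"] == pytest.approx(
                ep.relative_entropy(fit.posteriors))
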
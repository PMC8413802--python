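"""Item catalog, dichotomization, domain counts and scale scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epiiprofiles as ep
from epiiprofiles import catalog


def make_raw(codes_by_item: dict[int, list[int]]) -> pd.DataFrame:
    return pd.DataFrame({catalog.epii_column(i): v for i, v in codes_by_item.items()})


class TestCatalog:
    def test_domain_sizes(self):
        cat = ep.ItemCatalog()
        sizes = {d: len(cat.items_in_domain(d)) for d in catalog.DOMAINS}
        assert sizes == {"work": 12, "home": 19, "social": 18, "health": 24,
                         "positive": 19}
        assert sorted(cat.item_ids) == list(range(1, 93))

    def test_household_items_flagged(self):
        cat = ep.ItemCatalog()
        flagged = cat.table.index[cat.table["household_level"]].tolist()
        assert flagged == [42, 43, 65]


class TestDichotomize:
    @pytest.mark.parametrize("code,expected", [
        (catalog.YES_ME, 1), (catalog.YES_OTHER, 1),
        (catalog.NO, 0), (catalog.NOT_APPLICABLE, 0),
        (catalog.NONDISCLOSED, 0),
    ])
    def test_code_mapping(self, code, expected):
        raw = make_raw({1: [code]})
        assert ep.dichotomize_responses(raw).iloc[0, 0] == expected

    def test_all_no_row_is_all_zero(self):
        raw = make_raw({i: [catalog.NO] for i in range(1, 93)})
        assert (ep.dichotomize_responses(raw).to_numpy() == 0).all()

    def test_unknown_code_names_row_and_column(self):
        raw = make_raw({1: [0, 7], 2: [1, 1]})
        with pytest.raises(catalog.CodingError, match="EPII01"):
            ep.dichotomize_responses(raw)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.lists(st.sampled_from([0, 1, 2, 3, 9]), min_size=4,
                             max_size=4), min_size=1, max_size=8))
    def test_total_and_idempotent(self, rows):
        """Every valid table maps to a complete 0/1 matrix; re-applying
        the collapse to its own output changes nothing."""
        raw = pd.DataFrame(rows, columns=[catalog.epii_column(i) for i in range(1, 5)])
        out = ep.dichotomize_responses(raw)
        assert out.isin([0, 1]).all().all() and out.notna().all().all()
        assert ep.dichotomize_responses(out).equals(out)


class TestDomainCounts:
    def test_all_ones_row_gives_domain_sizes(self):
        raw = make_raw({i: [catalog.YES_ME] for i in range(1, 93)})
        counts = ep.domain_counts(ep.dichotomize_responses(raw))
        row = counts.iloc[0]
        assert tuple(row[list(catalog.DOMAINS)]) == (12, 19, 18, 24, 19)
        assert row["adverse_total"] == 12 + 19 + 18 + 24

    def test_all_zero_row(self):
        raw = make_raw({i: [catalog.NO] for i in range(1, 93)})
        assert (ep.domain_counts(ep.dichotomize_responses(raw)).iloc[0] == 0).all()

    def test_single_items_attributed(self):
        codes = {i: [catalog.NO] for i in range(1, 93)}
        codes[1] = [catalog.YES_ME]     # work item
        codes[74] = [catalog.YES_ME]    # positive item
        counts = ep.domain_counts(ep.dichotomize_responses(make_raw(codes)))
        row = counts.iloc[0]
        assert row["work"] == 1 and row["positive"] == 1
        assert row["home"] == row["social"] == row["health"] == 0

    def test_counts_sum_to_row_sum(self):
        rng = np.random.default_rng(3)
        raw = make_raw({i: rng.integers(0, 4, 20).tolist() for i in range(1, 93)})
        binary = ep.dichotomize_responses(raw)
        counts = ep.domain_counts(binary)
        assert (counts[list(catalog.DOMAINS)].sum(axis=1)
                == binary.sum(axis=1)).all()

    def test_unknown_column_errors(self):
        with pytest.raises(KeyError):
            ep.domain_counts(pd.DataFrame({"EPII99": [1]}))


class TestScaleScoring:
    def test_phq9_all_threes_scores_27(self):
        items = pd.DataFrame([[3] * 9])
        assert ep.score_scale(items, 0, 3)["total"].iloc[0] == 27

    def test_pss_all_zero_scores_0(self):
        items = pd.DataFrame([[0] * 10])
        assert ep.score_scale(items, 0, 4)["total"].iloc[0] == 0

    def test_mean_imputation_of_nondisclosed(self):
        # eight items at 2 and one opt-out: imputed value 2, total 18
        items = pd.DataFrame([[2] * 8 + [9]])
        scored = ep.score_scale(items, 0, 3)
        assert scored["total"].iloc[0] == pytest.approx(18)
        assert scored["imputed_fraction"].iloc[0] == pytest.approx(1 / 9)

    def test_all_nondisclosed_is_missing(self):
        scored = ep.score_scale(pd.DataFrame([[9] * 5]), 0, 3)
        assert np.isnan(scored["total"].iloc[0]) and scored["missing"].iloc[0]

    def test_item_order_invariance_and_identity_without_optout(self):
        rng = np.random.default_rng(1)
        items = pd.DataFrame(rng.integers(0, 4, (30, 9)))
        a = ep.score_scale(items, 0, 3)
        b = ep.score_scale(items[list(reversed(items.columns))], 0, 3)
        assert np.allclose(a["total"], b["total"])
        assert np.allclose(a["total"], items.sum(axis=1))
        assert (a["imputed_fraction"] == 0).all()


class TestScreenFlags:
    @pytest.mark.parametrize("scale,total,flag,expected", [
        ("phq9", 15, "phq9_ge15", True),
        ("phq9", 14, "phq9_ge15", False),
        ("gad7", 21, "gad7_ge15", True),
        ("pcptsd", 2, "pcptsd_ge3", False),
        ("pcptsd", 3, "pcptsd_ge3", True),
    ])
    def test_cutoffs(self, scale, total, flag, expected):
        scores = pd.DataFrame({f"{s}_total": [0.0] for s in
                               ("pss", "phq9", "gad7", "pcptsd", "ssq")})
        scores[f"{scale}_total"] = float(total)
        assert ep.screen_flags(scores)[flag].iloc[0] == expected

    def test_missing_total_gives_missing_flag(self):
        scores = pd.DataFrame({f"{s}_total": [np.nan] for s in
                               ("pss", "phq9", "gad7", "pcptsd", "ssq")})
        assert ep.screen_flags(scores)["phq9_ge15"].isna().iloc[0]

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 27), st.integers(0, 27))
    def test_flags_monotone_in_totals(self, t1, t2):
        lo, hi = sorted((t1, t2))
        cols = {f"{s}_total": [0.0, 0.0] for s in ("pss", "phq9", "gad7", "pcptsd", "ssq")}
        scores = pd.DataFrame(cols)
        scores["phq9_total"] = [float(lo), float(hi)]
        flags = ep.screen_flags(scores)["phq9_ge15"]
        assert flags.iloc[1] >= flags.iloc[0]


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        x = np.tile(np.random.default_rng(0).normal(size=(40, 1)), (1, 4))
        assert ep.cronbach_alpha(x) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        x = np.random.default_rng(0).normal(size=(20000, 2))
        assert abs(ep.cronbach_alpha(x)) < 0.05

    def test_hand_value_for_exchangeable_covariance(self):
        # 3 items, unit variances, pairwise covariance 0.5:
        # alpha = (3/2) (1 - 3/6) = 0.75; data constructed so the
        # *sample* covariance is exactly the target.
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 3))
        x -= x.mean(axis=0)
        s = np.linalg.cholesky(np.cov(x, rowvar=False))
        x = x @ np.linalg.inv(s).T  # sample covariance now identity
        target = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        x = x @ np.linalg.cholesky(target).T
        assert ep.cronbach_alpha(x) == pytest.approx(0.75, abs=1e-10)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            ep.cronbach_alpha(np.ones((10, 1)))
        with pytest.raises(ValueError):
            ep.cronbach_alpha(np.ones((10, 3)))  # zero total variance
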
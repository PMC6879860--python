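import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressmet.stats import (
    CohortTable,
    adjust_fdr,
    cohen_d,
    correlation_fold_change,
    correlation_map,
    group_difference,
    group_differences,
    mannwhitney_u,
    preprocess,
)


def brute_force_mw_p(x, y):
    """Independent oracle: enumerate assignments, count pairwise wins."""
    pooled = list(x) + list(y)
    m = len(x)
    center = m * len(y) / 2.0

    def ustat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    obs = abs(ustat(x, y) - center)
    hits = total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, m):
        comb = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        total += 1
        if abs(ustat(xs, ys) - center) >= obs - 1e-9:
            hits += 1
    return hits / total


def make_table(case, ctrl, feature="f"):
    n1, n2 = len(case), len(ctrl)
    return CohortTable(
        data=pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n1 + n2)],
                "group": ["PTSD"] * n1 + ["control"] * n2,
                feature: list(case) + list(ctrl),
            }
        ),
        metabolites=[feature],
    )


class TestPreprocess:
    def test_per_sample_median_centering(self):
        t = make_table([np.e], [np.e**2], feature="a")
        t.data["b"] = [np.e**2, np.e**3]
        t.data["c"] = [np.e**3, np.e**4]
        t2 = CohortTable(data=t.data, metabolites=["a", "b", "c"])
        out = preprocess(t2)
        # log rows [1,2,3] and [2,3,4], medians 2 and 3
        assert np.allclose(out.data[["a", "b", "c"]].iloc[0], [-1, 0, 1])
        assert np.allclose(out.data[["a", "b", "c"]].iloc[1], [-1, 0, 1])

    def test_all_equal_sample_zeroed(self):
        t = make_table([5.0], [5.0], feature="a")
        t.data["b"] = [5.0, 5.0]
        t2 = CohortTable(data=t.data, metabolites=["a", "b"])
        out = preprocess(t2)
        assert np.allclose(out.data[["a", "b"]], 0.0)

    def test_nonpositive_named(self):
        t = make_table([1.0, -2.0], [3.0], feature="a")
        with pytest.raises(ValueError, match="'a'"):
            preprocess(t)

    def test_idempotent_on_centered(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(6, 3))
        df = pd.DataFrame(vals, columns=["a", "b", "c"])
        df.insert(0, "group", ["PTSD"] * 3 + ["control"] * 3)
        df.insert(0, "sample_id", [f"s{i}" for i in range(6)])
        t = CohortTable(data=df, metabolites=["a", "b", "c"])
        once = preprocess(t)
        # exp() the centered values and preprocess again: same result
        redo = once.data.copy()
        redo[["a", "b", "c"]] = np.exp(redo[["a", "b", "c"]])
        twice = preprocess(CohortTable(data=redo, metabolites=["a", "b", "c"]))
        assert np.allclose(once.data[["a", "b", "c"]], twice.data[["a", "b", "c"]])

    def test_missing_preserved(self):
        t = make_table([1.0, np.nan], [2.0], feature="a")
        out = preprocess(t)
        assert out.data["a"].isna().sum() == 1

    def test_provenance_recorded(self):
        t = make_table([1.0], [2.0])
        assert preprocess(t).provenance


class TestMannWhitney:
    def test_spec_example_separated_groups(self):
        u, p = mannwhitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        u, p = mannwhitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            m = int(rng.integers(2, 9))
            n = int(rng.integers(2, 9))
            # mix continuous and tied integer data
            if rng.random() < 0.5:
                x = rng.normal(size=m)
                y = rng.normal(size=n)
            else:
                x = rng.integers(0, 4, m).astype(float)
                y = rng.integers(0, 4, n).astype(float)
            _, p = mannwhitney_u(x, y)
            assert p == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_large_sample_asymptotic(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(loc=1.0, size=30)
        _, p = mannwhitney_u(x, y)
        assert 0 < p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_u([], [1.0])


class TestCohenD:
    def test_closed_form(self):
        assert abs(cohen_d([0.0, 2.0], [1.0, 3.0])) == pytest.approx(1 / np.sqrt(2))

    def test_zero_for_identical(self):
        assert cohen_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_feature_nan(self):
        assert np.isnan(cohen_d([1.0, 1.0], [1.0, 1.0]))


class TestGroupDifference:
    def test_result_fields(self):
        t = make_table([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        r = group_difference(t, "f")
        assert r.u == 0.0
        assert r.direction == -1

    def test_identical_groups_null(self):
        t = make_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        r = group_difference(t, "f")
        assert r.p == pytest.approx(1.0)
        assert r.cohen_d == 0.0

    def test_panel_classification(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(40)],
            "group": ["PTSD"] * 20 + ["control"] * 20,
        })
        df["big"] = np.r_[rng.normal(3, 1, 20), rng.normal(0, 1, 20)]
        df["null"] = rng.normal(0, 1, 40)
        t = CohortTable(data=df, metabolites=["big", "null"])
        panel = group_differences(t, ["big", "null"])
        row = panel.set_index("feature")
        assert row.loc["big", "significance_class"] == "significant"
        assert row.loc["big", "q"] >= row.loc["big", "p"] or row.loc["big", "q"] == pytest.approx(row.loc["big", "p"] * 2, abs=1)


class TestFDR:
    def test_bh_closed_form(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04], pi0=1.0)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert adjust_fdr([0.5], pi0=1.0)[0] == pytest.approx(0.5)

    def test_all_ones(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0], pi0=1.0), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = adjust_fdr(p, pi0=1.0)
        assert (q >= p - 1e-12).all()

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.uniform(size=30))
        q = adjust_fdr(p, pi0=1.0)
        assert (np.diff(q) >= -1e-12).all()

    def test_smoother_pi0_large_null_panel(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=500)  # all null -> pi0 near 1
        q = adjust_fdr(p)
        assert q.min() > 0.1

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_bounded(self, ps):
        q = adjust_fdr(ps, pi0=1.0)
        assert ((q >= 0) & (q <= 1)).all()


class TestCorrelation:
    def _table(self, df, mets):
        df = df.copy()
        df.insert(0, "group", ["PTSD", "control"] * (len(df) // 2))
        df.insert(0, "sample_id", [f"s{i}" for i in range(len(df))])
        return CohortTable(data=df, metabolites=mets)

    def test_perfect_anticorrelation(self):
        t = self._table(pd.DataFrame({"x": [1, 2, 3, 4], "y": [4, 3, 2, 1]}), ["y"])
        cm = correlation_map(t, ["x"], ["y"])
        assert cm["rho"].loc["x", "y"] == pytest.approx(-1.0)

    def test_monotone_invariance(self, rng):
        x = rng.normal(size=20)
        t = self._table(pd.DataFrame({"x": x, "y": np.exp(2 * x)}), ["y"])
        cm = correlation_map(t, ["x"], ["y"])
        assert cm["rho"].loc["x", "y"] == pytest.approx(1.0)

    def test_too_few_pairs_flagged(self):
        df = pd.DataFrame({"x": [1, 2, np.nan, np.nan], "y": [1, 2, 3, 4.0]})
        t = self._table(df, ["y"])
        cm = correlation_map(t, ["x"], ["y"])
        assert cm["missing"].loc["x", "y"]
        assert np.isnan(cm["rho"].loc["x", "y"])

    def test_type_i_rate(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            from scipy.stats import spearmanr

            hits += spearmanr(x, y).pvalue < 0.05
        assert 0.02 < hits / reps < 0.08

    def test_subsets(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=10), "y": rng.normal(size=10)})
        t = self._table(df, ["y"])
        for sub in ("all", "PTSD", "control"):
            cm = correlation_map(t, ["x"], ["y"], subset=sub)
            assert cm["rho"].shape == (1, 1)


class TestFoldChange:
    def _frames(self, case, ctrl):
        return (
            pd.DataFrame([[case]], index=["c"], columns=["m"]),
            pd.DataFrame([[ctrl]], index=["c"], columns=["m"]),
        )

    def test_simple_ratio(self):
        fc = correlation_fold_change(*self._frames(0.6, 0.2))
        assert fc["fold"].iloc[0, 0] == pytest.approx(3.0)

    def test_cap_at_four(self):
        fc = correlation_fold_change(*self._frames(0.9, 0.1))
        assert fc["fold"].iloc[0, 0] == 4.0
        assert fc["capped"].iloc[0, 0]

    def test_sign_flip_flagged_not_ratioed(self):
        fc = correlation_fold_change(*self._frames(-0.3, 0.3))
        assert fc["sign_flip"].iloc[0, 0]
        assert np.isnan(fc["fold"].iloc[0, 0])

    def test_zero_control_capped(self):
        fc = correlation_fold_change(*self._frames(0.5, 0.0))
        assert fc["fold"].iloc[0, 0] == 4.0
        assert fc["capped"].iloc[0, 0]

    def test_nonconformable_rejected(self):
        a = pd.DataFrame(np.zeros((2, 2)))
        b = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            correlation_fold_change(a, b)


class TestCohortTable:
    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"sample_id": ["a", "a"], "group": ["PTSD", "control"], "f": [1, 2]})
        with pytest.raises(ValueError, match="duplicate"):
            CohortTable(data=df, metabolites=["f"])

    def test_bad_group_labels_rejected(self):
        df = pd.DataFrame({"sample_id": ["a", "b"], "group": ["case", "ctl"], "f": [1, 2]})
        with pytest.raises(ValueError):
            CohortTable(data=df, metabolites=["f"])
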
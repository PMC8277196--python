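"""Tests for group-comparison statistics."""

import numpy as np
import pytest

from punctakit import (
    compare_many_groups,
    compare_two_groups,
    normalize_to_reference,
    sem,
    significance_letters,
    significance_marker,
    summarize_dose_response,
)


class TestNormalization:
    def test_ratio_to_reference_mean(self):
        out = normalize_to_reference({"young": [4.0, 4.0], "aged": [2.0, 6.0]}, "young")
        assert np.allclose(out["aged"], [0.5, 1.5])
        assert np.allclose(out["young"], [1.0, 1.0])

    def test_scale_equivariance(self):
        vals = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0]}
        base = normalize_to_reference(vals, "a")
        scaled = normalize_to_reference(
            {g: [7.3 * x for x in v] for g, v in vals.items()}, "a"
        )
        for g in vals:
            assert np.allclose(base[g], scaled[g])

    def test_guards(self):
        with pytest.raises(ValueError):
            normalize_to_reference({"a": [0.0, 0.0], "b": [1.0]}, "a")
        with pytest.raises(ValueError):
            normalize_to_reference({"a": [1.0]}, "missing")


class TestTwoGroups:
    def test_identical_groups_null(self):
        res = compare_two_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_large_shift_tiny_variance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, 8)
        res = compare_two_groups(a, a + 100.0)
        assert res.p_value < 1e-6

    def test_matches_hand_computed_t(self):
        # classical pooled-variance t for n=3 vs 3, worked by hand
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = compare_two_groups(a, b)
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.n == {"control": 3, "treated": 3}
        assert res.sem["control"] == pytest.approx(sem(a))

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            compare_two_groups([1.0], [2.0, 3.0])

    def test_null_type_one_error_rate(self):
        """Empirical rejection rate at alpha=0.05 under the null is
        0.05 +/- 0.01 over 10,000 simulated experiments."""
        rng = np.random.default_rng(12345)
        a = rng.normal(size=(10000, 8))
        b = rng.normal(size=(10000, 8))
        rejections = sum(
            compare_two_groups(a[i], b[i]).p_value < 0.05 for i in range(10000)
        )
        assert abs(rejections / 10000 - 0.05) <= 0.01


class TestManyGroups:
    def test_identical_groups_null(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = compare_many_groups(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_computed_anova(self):
        g = {
            "a": np.array([1.0, 2.0, 3.0]),
            "b": np.array([2.0, 3.0, 4.0]),
            "c": np.array([6.0, 7.0, 8.0]),
        }
        grand = np.mean(np.concatenate(list(g.values())))
        ss_between = sum(3 * (v.mean() - grand) ** 2 for v in g.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in g.values())
        f_hand = (ss_between / 2) / (ss_within / 6)
        res = compare_many_groups(g)
        assert res.statistic == pytest.approx(f_hand, abs=1e-10)

    def test_two_group_anova_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 7)
        f = compare_many_groups({"a": a, "b": b}).statistic
        t = compare_two_groups(a, b).statistic
        assert f == pytest.approx(t**2, abs=1e-9)

    def test_shifted_group_flagged_by_posthoc_and_letters(self):
        rng = np.random.default_rng(2)
        g = {
            "ctrl": rng.normal(0, 1, 10),
            "mid": rng.normal(0.2, 1, 10),
            "far": rng.normal(15, 1, 10),
        }
        res = compare_many_groups(g)
        ph = res.posthoc.set_index(["group1", "group2"])
        assert ph.loc[("ctrl", "far"), "reject"]
        assert ph.loc[("mid", "far"), "reject"]
        assert not ph.loc[("ctrl", "mid"), "reject"]
        # ctrl and mid share a letter; far has its own
        assert set(res.letters["ctrl"]) & set(res.letters["mid"])
        assert not set(res.letters["far"]) & set(res.letters["ctrl"])

    def test_tukey_matches_statsmodels_oracle(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        g = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(1, 1, 8),
            "c": rng.normal(2, 1, 8),
        }
        res = compare_many_groups(g)
        values = np.concatenate([g[k] for k in g])
        labels = sum(([k] * 8 for k in g), [])
        sm = pairwise_tukeyhsd(values, labels)
        sm_p = {
            (r[0], r[1]): float(r[3]) for r in sm.summary().data[1:]
        }
        for _, row in res.posthoc.iterrows():
            assert row["p_adj"] == pytest.approx(
                sm_p[(row["group1"], row["group2"])], abs=1e-4
            )


class TestMarkersAndDose:
    def test_significance_markers(self):
        assert significance_marker(0.005) == "**"
        assert significance_marker(0.01) == "**"
        assert significance_marker(0.03) == "*"
        assert significance_marker(0.2) == "ns"

    def test_letters_all_different(self):
        p = {("a", "b"): 0.001, ("a", "c"): 0.001, ("b", "c"): 0.001}
        letters = significance_letters(["a", "b", "c"], p)
        assert len({letters[g] for g in "abc"}) == 3

    def test_dose_response_excludes_toxic_dose(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        rows = []
        for dose, shift in [(0, 0.0), (25, 0.1), (100, 0.5), (400, 1.0)]:
            for _ in range(5):
                rows.append(
                    {
                        "dose": dose,
                        "mean_area_um2": 0.3 + shift + rng.normal(0, 0.05),
                        "n_puncta": 50 - 10 * shift + rng.normal(0, 3),
                    }
                )
        df = pd.DataFrame(rows)
        viability = {0: 0.95, 25: 0.9, 100: 0.8, 400: 0.2}
        summary = summarize_dose_response(df, viability)
        assert 400 in summary.excluded
        assert "toxicity" in summary.excluded[400]
        assert summary.anova is not None
        assert set(summary.anova.groups) == {"0", "25", "100"}
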
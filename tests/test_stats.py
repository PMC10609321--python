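"""Outlier trimming, ANOVA, pairwise t, Tukey–Kramer, connecting letters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cottonsect import (
    StatsError,
    analyze_table,
    anova_oneway,
    connecting_letters,
    letters_report_text,
    pairwise_t,
    summarize_lines,
    trim_outliers,
    tukey_kramer,
)


class TestTrimOutliers:
    def test_iqr_removes_gross_outlier(self):
        kept, removed = trim_outliers([1, 2, 2, 3, 2, 2, 50], rule="iqr", k=1.5)
        assert 50 in removed
        assert 50 not in kept
        assert set(kept) <= {1, 2, 3}

    def test_clean_sample_identity(self):
        v = [10.0, 11.0, 12.0, 13.0, 11.5]
        kept, removed = trim_outliers(v, rule="iqr")
        assert list(kept) == v and len(removed) == 0

    def test_too_few_values_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept, removed = trim_outliers([1.0, 2.0, 100.0], rule="iqr")
        assert len(kept) == 3 and len(removed) == 0

    def test_zscore_catches_planted_contamination(self):
        """≥ 90% of 8-sd shift outliers removed at k = 3."""
        rng = np.random.default_rng(0)
        clean = rng.normal(100.0, 5.0, 950)
        outliers = rng.normal(140.0, 5.0, 50)
        v = np.concatenate([clean, outliers])
        kept, removed = trim_outliers(v, rule="zscore", k=3.0)
        caught = (removed > 120).sum()
        assert caught / 50 >= 0.90
        assert (np.asarray(kept) > 120).sum() <= 5

    def test_unknown_rule(self):
        with pytest.raises(StatsError):
            trim_outliers([1.0, 2.0, 3.0, 4.0], rule="mad")


class TestAnova:
    def test_identical_groups_f_zero_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = anova_oneway({"a": g, "b": g, "c": g})
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == (2, 9)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = anova_oneway({"a": a, "b": b})
        t = pairwise_t({"a": a, "b": b})["t"].iloc[0]
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_degenerate_zero_variance_errors(self):
        with pytest.raises(StatsError, match="degenerate"):
            anova_oneway({"a": [5.0, 5.0], "b": [5.0, 5.0]})

    def test_group_size_validation(self):
        with pytest.raises(StatsError):
            anova_oneway({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(StatsError):
            anova_oneway({"a": [1.0, 2.0]})


class TestPairwiseT:
    def test_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0]
        tab = pairwise_t({"a": g, "b": g})
        assert tab["p"].iloc[0] == pytest.approx(1.0)

    def test_mean_diff_antisymmetric(self):
        tab = pairwise_t({"a": [1.0, 2.0], "b": [5.0, 6.0]})
        row = tab.iloc[0]
        assert row["mean_diff"] == pytest.approx(-4.0)
        assert row["t"] < 0

    def test_matches_hand_computed_pooled_t(self):
        # 3+3 toy, worked by the pooled-variance formula
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        tab = pairwise_t({"a": a, "b": b})
        assert tab["t"].iloc[0] == pytest.approx(t_hand, rel=1e-12)


class TestTukeyKramer:
    def test_equal_means_no_significance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10, 1, 30)
        rep = tukey_kramer({"a": base, "b": base + 1e-12, "c": base - 1e-12})
        assert not rep.pairs["significant"].any()
        assert set(rep.letters.values()) == {"A"}

    def test_equal_n_reduces_to_classical_tukey(self):
        """Cross-check q and p against the standard equal-n HSD routine."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        groups = {k: rng.normal(mu, 1.0, 20) for k, mu in zip("abcd", [0, 0.3, 1.0, 1.4])}
        rep = tukey_kramer(groups, alpha=0.05)
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 20)
        sm = pairwise_tukeyhsd(data, labels, alpha=0.05)
        summary = pd.DataFrame(sm.summary().data[1:], columns=sm.summary().data[0])
        sm_p = {
            frozenset((g1, g2)): p
            for g1, g2, p in zip(summary["group1"], summary["group2"], sm.pvalues)
        }
        for _, row in rep.pairs.iterrows():
            key = frozenset((row["group_i"], row["group_j"]))
            assert row["p_adj"] == pytest.approx(sm_p[key], abs=1e-6)

    def test_relabeling_and_shift_invariance(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(mu, 1.0, 15) for k, mu in zip("abc", [0, 1, 2])}
        rep = tukey_kramer(groups)
        shifted = {k.upper(): np.asarray(v) + 100.0 for k, v in groups.items()}
        rep2 = tukey_kramer(shifted)
        got = {
            frozenset((r["group_i"].lower(), r["group_j"].lower())): r["q"]
            for _, r in rep2.pairs.iterrows()
        }
        for _, r in rep.pairs.iterrows():
            assert got[frozenset((r["group_i"], r["group_j"]))] == pytest.approx(
                r["q"], rel=1e-10
            )

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            tukey_kramer({"a": [1.0], "b": [1.0, 2.0, 3.0]})

    def test_letters_match_significance(self):
        """Two lines share a letter iff their pair is not significant."""
        rng = np.random.default_rng(5)
        groups = {
            k: rng.normal(mu, 1.0, 25) for k, mu in zip("abcde", [0, 0.2, 1.5, 1.6, 4.0])
        }
        rep = tukey_kramer(groups)
        for _, row in rep.pairs.iterrows():
            shared = set(rep.letters[row["group_i"]]) & set(rep.letters[row["group_j"]])
            assert bool(shared) == (not row["significant"])


def brute_force_cld(names, sig):
    """Oracle: maximal cliques of the non-significance graph by subset scan."""
    def compatible(sub):
        return all(not sig[frozenset((a, b))] for a, b in itertools.combinations(sub, 2))

    cliques = []
    for r in range(1, len(names) + 1):
        for sub in itertools.combinations(names, r):
            if compatible(sub):
                cliques.append(frozenset(sub))
    return {c for c in cliques if not any(c < d for d in cliques)}


class TestConnectingLetters:
    def test_all_nonsignificant_single_letter(self):
        names = ["w", "x", "y"]
        sig = {frozenset(p): False for p in itertools.combinations(names, 2)}
        assert set(connecting_letters(names, sig).values()) == {"A"}

    def test_all_significant_distinct_letters(self):
        names = ["w", "x", "y"]
        sig = {frozenset(p): True for p in itertools.combinations(names, 2)}
        letters = connecting_letters(names, sig)
        assert sorted(letters.values()) == ["A", "B", "C"]
        assert letters["w"] == "A"  # first in presentation order

    def test_missing_pair_rejected(self):
        with pytest.raises(StatsError, match="missing"):
            connecting_letters(["a", "b", "c"], {frozenset(("a", "b")): True})

    def test_matches_clique_oracle_all_patterns_4_groups(self):
        names = ["a", "b", "c", "d"]
        pairs = list(itertools.combinations(names, 2))
        for bits in range(2 ** len(pairs)):
            sig = {frozenset(p): bool(bits >> i & 1) for i, p in enumerate(pairs)}
            letters = connecting_letters(names, sig)
            classes = {}
            for n, ls in letters.items():
                for ch in ls:
                    classes.setdefault(ch, set()).add(n)
            assert set(map(frozenset, classes.values())) == brute_force_cld(names, sig)
            for a, b in pairs:
                shared = set(letters[a]) & set(letters[b])
                assert bool(shared) == (not sig[frozenset((a, b))])


class TestTableLevel:
    def _table(self):
        # L2 is L1 shifted by a negligible 0.1; L3 is far away — the
        # expected letter structure is then robust, not seed-dependent
        rng = np.random.default_rng(7)
        base = rng.normal(100.0, 5.0, 40)
        rows = []
        for line, vals in [("L1", base), ("L2", base + 0.1), ("L3", base + 30.0)]:
            rows += [{"Name": "f", "Outer True Area": v, "Line": line} for v in vals]
        return pd.DataFrame(rows)

    def test_summaries_quantiles_monotone(self):
        s = summarize_lines(self._table(), ["Outer True Area"])
        assert len(s) == 3
        for _, r in s.iterrows():
            assert r["min"] <= r["q25"] <= r["median"] <= r["q75"] <= r["max"]
            assert r["n"] == 40 and r["sd"] > 0

    def test_analyze_table_separates_shifted_line(self):
        summaries, anova, hsd, trimmed = analyze_table(self._table(), ["Outer True Area"])
        rep = hsd["Outer True Area"]
        assert anova["Outer True Area"].p < 1e-6
        # L3 shares no letter with L1/L2; L1 and L2 share one
        assert not set(rep.letters["L3"]) & set(rep.letters["L1"])
        assert set(rep.letters["L1"]) & set(rep.letters["L2"])

    def test_letters_report_shape(self):
        _, _, hsd, _ = analyze_table(self._table(), ["Outer True Area"])
        text = letters_report_text(hsd["Outer True Area"])
        lines = text.strip().splitlines()
        assert len(lines) == 2 + 3  # title + header + one row per line
        assert lines[1].startswith("Line\t")
        # rows sorted by descending mean
        means = [float(l.split("\t")[-1]) for l in lines[2:]]
        assert means == sorted(means, reverse=True)
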
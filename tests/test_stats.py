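from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from kymotility.io_model import ExperimentManifest
from kymotility.stats import (
    aggregate,
    conover_posthoc,
    dagostino_pearson,
    directionality_proportions,
    dunn_posthoc,
    holm_bonferroni,
    kruskal_wallis,
    motility_battery,
)

from conftest import simple_manifest


# ---------------------------------------------------------------------------
# Exact-arithmetic oracles: literal textbook formulas evaluated with Fractions,
# fully independent of the numpy implementations they check.

def exact_ranks(values):
    """Mid-rank assignment computed with exact rational arithmetic."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [Fraction(0)] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        r = Fraction(sum(range(i + 1, j + 1)), j - i)
        for k in range(i, j):
            ranks[order[k]] = r
        i = j
    return ranks


def exact_h(groups):
    """Tie-corrected Kruskal-Wallis H as an exact Fraction."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = exact_ranks(pooled)
    h = Fraction(0)
    i = 0
    for g in groups:
        r = sum(ranks[i : i + len(g)])
        h += Fraction(r * r, len(g))
        i += len(g)
    h = Fraction(12, n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(c**3 - c for c in ties.values())
    return h / (1 - Fraction(tie_sum, n**3 - n))


def exact_conover(groups):
    """Conover-Iman pairwise two-sided p values via exact intermediates."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    k = len(groups)
    ranks = exact_ranks(pooled)
    means, i = [], 0
    for g in groups:
        means.append(sum(ranks[i : i + len(g)]) / len(g))
        i += len(g)
    s2 = (sum(r * r for r in ranks) - Fraction(n * (n + 1) ** 2, 4)) / (n - 1)
    h = exact_h(groups)
    df = n - k
    scale = s2 * (n - 1 - h) / df
    out = {}
    for a, b in combinations(range(k), 2):
        se2 = scale * (Fraction(1, len(groups[a])) + Fraction(1, len(groups[b])))
        t = float(means[a] - means[b]) / float(se2) ** 0.5
        out[(a, b)] = (t, 2 * sps.t.sf(abs(t), df))
    return out


def exact_dunn(groups):
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = exact_ranks(pooled)
    means, i = [], 0
    for g in groups:
        means.append(sum(ranks[i : i + len(g)]) / len(g))
        i += len(g)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(c**3 - c for c in ties.values())
    var = Fraction(n * (n + 1), 12) - Fraction(tie_sum, 12 * (n - 1))
    out = {}
    for a, b in combinations(range(len(groups)), 2):
        se2 = var * (Fraction(1, len(groups[a])) + Fraction(1, len(groups[b])))
        z = float(means[a] - means[b]) / float(se2) ** 0.5
        out[(a, b)] = (z, 2 * sps.norm.sf(abs(z)))
    return out


FIXED_GROUPS = [
    [2.1, 5.3, 1.4, 8.0, 2.1, 3.3, 7.7, 4.4],
    [6.1, 7.2, 8.3, 2.1, 9.9, 10.4],
    [0.5, 1.1, 2.2, 3.3, 3.3, 0.9, 1.7],
]


class TestDagostinoPearson:
    def test_matches_scipy_to_1e10_on_fixed_samples(self):
        rng = np.random.default_rng(42)
        for sample in [rng.normal(size=100), rng.lognormal(size=200), rng.uniform(size=50)]:
            mine = dagostino_pearson(sample)
            ref_stat, ref_p = sps.normaltest(sample)
            assert mine.statistic == pytest.approx(float(ref_stat), abs=1e-10)
            assert mine.p == pytest.approx(float(ref_p), abs=1e-10)

    def test_null_calibration(self):
        """Rejection rate ~5% at alpha=0.05 under the null (1,000 reps)."""
        rng = np.random.default_rng(7)
        rejections = sum(dagostino_pearson(rng.normal(size=10_000)).p < 0.05 for _ in range(1000))
        assert abs(rejections / 1000 - 0.05) < 0.025

    def test_lognormal_strongly_rejected(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            assert dagostino_pearson(rng.lognormal(size=200)).p < 1e-3

    def test_small_sample_refused_by_default(self):
        with pytest.raises(ValueError, match="refused"):
            dagostino_pearson(np.arange(10))
        with pytest.warns(UserWarning):
            dagostino_pearson(np.random.default_rng(0).normal(size=10), force=True)

    def test_constant_sample_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            dagostino_pearson([3.0] * 30)


class TestKruskalWallis:
    def test_identical_groups_give_h0_p1(self):
        res = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.p < 1.0001 and res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_returns_h0_p1(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_rank_formula(self):
        # groups (1,2,3),(4,5,6),(7,8,9): rank sums 6,15,24 -> H = 7.2
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.p == pytest.approx(float(sps.chi2.sf(7.2, 2)))
        assert res.df == 2

    def test_exact_oracle_with_ties(self):
        res = kruskal_wallis(FIXED_GROUPS)
        assert res.statistic == pytest.approx(float(exact_h(FIXED_GROUPS)), abs=1e-10)

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestConover:
    def test_matches_exact_formula_oracle(self):
        res = conover_posthoc(FIXED_GROUPS)
        oracle = exact_conover(FIXED_GROUPS)
        names = list(res.pvalue.index)
        for (i, j), (t, p) in oracle.items():
            assert res.statistic.loc[names[i], names[j]] == pytest.approx(t, abs=1e-8)
            assert res.pvalue.loc[names[i], names[j]] == pytest.approx(p, abs=1e-8)

    def test_identical_groups_p1(self):
        res = conover_posthoc([[4.0, 4.0, 4.0], [4.0, 4.0]])
        assert res.pvalue.iloc[0, 1] == 1.0

    def test_permuting_groups_permutes_matrix(self):
        g = {"a": FIXED_GROUPS[0], "b": FIXED_GROUPS[1], "c": FIXED_GROUPS[2]}
        perm = {"c": g["c"], "a": g["a"], "b": g["b"]}
        r1, r2 = conover_posthoc(g), conover_posthoc(perm)
        for x in "abc":
            for y in "abc":
                assert r1.pvalue.loc[x, y] == pytest.approx(r2.pvalue.loc[x, y], abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            conover_posthoc({"a": [1.0, 2.0], "b": []})


class TestDunn:
    def test_matches_exact_formula_oracle(self):
        res = dunn_posthoc(FIXED_GROUPS)
        oracle = exact_dunn(FIXED_GROUPS)
        names = list(res.pvalue.index)
        for (i, j), (z, p) in oracle.items():
            assert res.statistic.loc[names[i], names[j]] == pytest.approx(z, abs=1e-8)
            assert res.pvalue.loc[names[i], names[j]] == pytest.approx(p, abs=1e-8)

    def test_identical_groups_p1(self):
        res = dunn_posthoc([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.pvalue.iloc[0, 1] == 1.0

    def test_permutation_symmetry(self):
        g = {"a": FIXED_GROUPS[0], "b": FIXED_GROUPS[1], "c": FIXED_GROUPS[2]}
        perm = {"b": g["b"], "c": g["c"], "a": g["a"]}
        r1, r2 = dunn_posthoc(g), dunn_posthoc(perm)
        for x in "abc":
            for y in "abc":
                assert r1.pvalue.loc[x, y] == pytest.approx(r2.pvalue.loc[x, y], abs=1e-12)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_down(self):
        adj = holm_bonferroni([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.04, 0.04])

    def test_adjusted_geq_raw_and_capped(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=20)
        adj = holm_bonferroni(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        # order preserved after sorting
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestRankInvariance:
    def test_monotone_transform_leaves_rank_tests_unchanged(self):
        transformed = [list(np.exp(np.asarray(g) / 3.0)) for g in FIXED_GROUPS]
        assert kruskal_wallis(FIXED_GROUPS).statistic == pytest.approx(
            kruskal_wallis(transformed).statistic
        )
        a = conover_posthoc(FIXED_GROUPS).pvalue.to_numpy()
        b = conover_posthoc(transformed).pvalue.to_numpy()
        assert a == pytest.approx(b)


class TestAggregate:
    def test_single_experiment_mean(self):
        man = simple_manifest(["t1", "t2", "t3"])
        s = aggregate(pd.Series({"t1": 1.0, "t2": 2.0, "t3": 3.0}), man)
        assert s.group_means.tolist() == [2.0]
        assert s.pooled_median == 2.0
        assert s.n_groups == 1 and s.n_values == 3

    def test_identical_values_identical_means(self):
        rows = []
        for e in ("e1", "e2", "e3"):
            for i in range(4):
                rows.append(("c", e, "m", "mt1", f"{e}_t{i}"))
        man = ExperimentManifest(
            pd.DataFrame(rows, columns=["condition", "experiment_id", "movie_id", "context_id", "track_id"])
        )
        vals = pd.Series({r[4]: 7.5 for r in rows})
        s = aggregate(vals, man)
        assert np.allclose(s.group_means, 7.5)

    def test_matches_groupby_recomputation(self, rng):
        rows, vals = [], {}
        for e in range(4):
            for i in range(rng.integers(3, 9)):
                tid = f"e{e}_t{i}"
                rows.append(("c", f"e{e}", f"m{e}", f"mt{e}", tid))
                vals[tid] = float(rng.normal())
        man = ExperimentManifest(
            pd.DataFrame(rows, columns=["condition", "experiment_id", "movie_id", "context_id", "track_id"])
        )
        s = aggregate(pd.Series(vals), man, level="experiment")
        df = pd.DataFrame(rows, columns=["c", "e", "m", "mt", "t"]).assign(v=[vals[r[4]] for r in rows])
        expected = df.groupby("e")["v"].mean()
        assert s.group_means.sort_index().tolist() == pytest.approx(expected.sort_index().tolist())
        assert s.quartile1 <= s.pooled_median <= s.quartile3
        assert s.p10 <= s.quartile1 and s.quartile3 <= s.p90

    def test_orphan_value_raises_naming_id(self):
        man = simple_manifest(["t1"])
        with pytest.raises(KeyError, match="ghost"):
            aggregate(pd.Series({"ghost": 1.0}), man)


class TestDirectionality:
    def test_counts_and_fractions_sum(self):
        labels = ["plus"] * 190 + ["minus"] * 1182 + ["static"] * 22 + ["bidirectional"] * 24
        props = directionality_proportions(labels)
        assert props["count"].sum() == 1418
        assert props["pooled_fraction"].sum() == pytest.approx(1.0)
        assert props.loc["minus", "count"] == 1182

    def test_single_class_single_experiment(self):
        props = directionality_proportions(["minus"] * 10)
        assert props.loc["minus", "experiment_mean_fraction"] == 1.0
        assert props.loc["minus", "experiment_sd_fraction"] == 0.0

    def test_per_experiment_mean_sd_hand_computed(self):
        # three experiments with minus fractions 0.5, 0.75, 1.0
        rows, labels = [], {}
        fracs = {"e1": (2, 2), "e2": (3, 1), "e3": (4, 0)}
        i = 0
        for e, (nm, np_) in fracs.items():
            for lab in ["minus"] * nm + ["plus"] * np_:
                tid = f"t{i}"; i += 1
                rows.append(("c", e, "m", "mt", tid))
                labels[tid] = lab
        man = ExperimentManifest(
            pd.DataFrame(rows, columns=["condition", "experiment_id", "movie_id", "context_id", "track_id"])
        )
        props = directionality_proportions(pd.Series(labels), man)
        assert props.loc["minus", "experiment_mean_fraction"] == pytest.approx(0.75)
        assert props.loc["minus", "experiment_sd_fraction"] == pytest.approx(np.std([0.5, 0.75, 1.0], ddof=1))
        # pooled fraction differs from the per-experiment mean here
        assert props.loc["minus", "pooled_fraction"] == pytest.approx(9 / 12)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            directionality_proportions(["diagonal"])


class TestBattery:
    def test_nonnormal_data_takes_kw_conover_path(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": rng.lognormal(0.0, 1.0, 60),
            "b": rng.lognormal(0.5, 1.0, 60),
            "c": rng.lognormal(0.5, 1.0, 60),
        }
        res = motility_battery(groups)
        assert not res["all_normal"]
        assert res["method"] == "conover_iman"
        assert res["omnibus"] is not None
        for c in res["comparisons"]:
            assert c.p_adjusted >= c.p - 1e-15

    def test_normal_data_takes_t_test_path(self):
        rng = np.random.default_rng(6)
        groups = {"a": rng.normal(0, 1, 80), "b": rng.normal(0.1, 1, 80)}
        res = motility_battery(groups)
        assert res["all_normal"]
        assert res["method"] == "t_test_independent"

    def test_dunn_option(self):
        rng = np.random.default_rng(8)
        groups = {"a": rng.lognormal(size=40), "b": rng.lognormal(size=40)}
        res = motility_battery(groups, posthoc="dunn")
        assert res["method"] == "dunn"

    def test_full_battery_type1_error_bounded(self):
        """KW -> Conover -> Holm falsely rejects at most ~alpha under the null."""
        rng = np.random.default_rng(11)
        alpha, reps = 0.05, 600
        false_hits = 0
        for _ in range(reps):
            groups = [rng.normal(size=20) for _ in range(3)]
            kw = kruskal_wallis(groups)
            if kw.p >= alpha:
                continue
            ph = conover_posthoc(groups)
            adj = holm_bonferroni(ph.flat_pvalues().to_numpy())
            if (adj < alpha).any():
                false_hits += 1
        rate = false_hits / reps
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)
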
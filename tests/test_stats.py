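"""Sample-size computation, normality gate, and nonparametric tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from microleak.stats import (
    GroupStudy,
    dunn_bonferroni,
    full_report,
    kruskal_wallis,
    sample_size_oneway,
    shapiro_gate,
    summarize,
)
from microleak.synthetic import GroupParams, generate_group_study


class TestSampleSizeOneway:
    def test_three_group_medium_effect(self):
        """f = 0.5, alpha = 0.05, power = 0.8, k = 3 needs 42 specimens."""
        assert sample_size_oneway(0.5, 0.05, 0.8, 3) == 42

    def test_monotone_in_effect_size_alpha_power(self):
        base = sample_size_oneway(0.5, 0.05, 0.8, 3)
        assert sample_size_oneway(1.0, 0.05, 0.8, 3) < base
        assert sample_size_oneway(0.5, 0.01, 0.8, 3) >= base
        assert sample_size_oneway(0.5, 0.10, 0.8, 3) <= base
        assert sample_size_oneway(0.5, 0.05, 0.95, 3) > base

    def test_matches_statsmodels_power_solver(self):
        """Independent cross-check against statsmodels' ANOVA power solver."""
        from statsmodels.stats.power import FTestAnovaPower

        for f, k in [(0.25, 3), (0.4, 4), (0.5, 3)]:
            n_float = FTestAnovaPower().solve_power(
                effect_size=f, alpha=0.05, power=0.8, k_groups=k
            )
            ours = sample_size_oneway(f, 0.05, 0.8, k)
            # ours rounds up to the next balanced (divisible-by-k) total
            assert ours == k * math.ceil(n_float / k)

    def test_monte_carlo_power_at_returned_n(self, rng):
        """Simulated one-way ANOVA at N = 42 achieves the 0.8 target power.

        Group means (-d, 0, d) with unit sigma and d = 0.5 * sqrt(3/2)
        realise Cohen's f = 0.5 exactly; 20,000 replicates.
        """
        n_total = sample_size_oneway(0.5, 0.05, 0.8, 3)
        n = n_total // 3
        delta = 0.5 * math.sqrt(1.5)
        means = np.array([-delta, 0.0, delta])
        reps = 20_000
        x = rng.normal(means[None, :, None], 1.0, size=(reps, 3, n))
        gm = x.mean(axis=2)
        grand = gm.mean(axis=1, keepdims=True)
        ssb = n * ((gm - grand) ** 2).sum(axis=1)
        ssw = ((x - gm[:, :, None]) ** 2).sum(axis=(1, 2))
        f_stat = (ssb / 2) / (ssw / (n_total - 3))
        crit = sps.f.isf(0.05, 2, n_total - 3)
        assert (f_stat > crit).mean() >= 0.8 - 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_size_oneway(0.0)
        with pytest.raises(ValueError):
            sample_size_oneway(0.5, alpha=1.5)
        with pytest.raises(ValueError):
            sample_size_oneway(0.5, k=1)


class TestShapiroGate:
    def test_capped_data_flagged_nonnormal(self):
        """Heavy censoring at the cap rejects normality at n = 15.

        Over half the specimens sit exactly at the 7.18 mm cap, the
        situation the normality gate exists for.
        """
        rng = np.random.default_rng(7)
        groups = {
            g: list(np.minimum(rng.normal(7.5, 1.2, 15), 7.18)) for g in "abc"
        }
        p_values, flag = shapiro_gate(GroupStudy(groups))
        assert flag is True

    def test_level_on_normal_data(self):
        """On a genuinely normal sample the gate passes ~95% of the time."""
        passed = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 5000)
            _, flag = shapiro_gate(GroupStudy({"g": list(x)}))
            passed += not flag
        assert passed >= 90

    def test_zero_variance_group_flagged_with_warning(self):
        study = GroupStudy({"a": [7.18] * 5, "b": [1.0, 2.0, 3.0, 2.5, 1.5]})
        with pytest.warns(UserWarning, match="zero variance"):
            p_values, flag = shapiro_gate(study)
        assert p_values["a"] == 0.0 and flag is True

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="n=2"):
            shapiro_gate(GroupStudy({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]}))


class TestKruskalWallis:
    def test_hand_computed_h(self):
        """{1,2,3}/{4,5,6}/{7,8,9}: H = 12/(9*10) * sum(R^2/3) - 3*10 = 7.2."""
        study = GroupStudy({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        h, p = kruskal_wallis(study)
        assert h == pytest.approx(7.2, abs=1e-9)
        assert p == pytest.approx(sps.chi2.sf(7.2, 2), rel=1e-9)

    def test_group_relabelling_invariance(self):
        values = {"a": [1, 5, 2], "b": [9, 3, 7], "c": [4, 8, 6]}
        h0, _ = kruskal_wallis(GroupStudy(values))
        for perm in itertools.permutations("abc"):
            relabelled = {k: values[v] for k, v in zip("abc", perm)}
            h, _ = kruskal_wallis(GroupStudy(relabelled))
            assert h == pytest.approx(h0, abs=1e-12)

    def test_identical_groups_give_null(self):
        study = GroupStudy({"a": [2.0] * 5, "b": [2.0] * 5})
        assert kruskal_wallis(study) == (0.0, 1.0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            kruskal_wallis(GroupStudy({"a": [1, 2, 3]}))
        with pytest.raises(ValueError):
            kruskal_wallis(GroupStudy({"a": [1.0], "b": [2.0]}))


def _dunn_oracle(groups):
    """Direct transcription of the Dunn z formula, written independently."""
    labels = list(groups)
    pooled = [v for g in labels for v in groups[g]]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        for t in range(i, j + 1):
            ranks[order[t]] = (i + j) / 2 + 1
        i = j + 1
    # tie correction
    from collections import Counter

    ties = Counter(pooled)
    tie_sum = sum(t**3 - t for t in ties.values())
    var = n * (n + 1) / 12 - tie_sum / (12 * (n - 1))
    offsets, mean_rank = {}, {}
    pos = 0
    for g in labels:
        size = len(groups[g])
        mean_rank[g] = sum(ranks[pos : pos + size]) / size
        offsets[g] = size
        pos += size
    m = len(labels) * (len(labels) - 1) // 2
    out = {}
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(var * (1 / offsets[a] + 1 / offsets[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        raw = 2 * (1 - sps.norm.cdf(abs(z)))
        out[(a, b)] = min(1.0, raw * m)
    return out


class TestDunnBonferroni:
    FIXTURE = {
        "printed": [1.1, 0.4, 2.0, 7.18],
        "milled": [3.5, 7.18, 4.2, 5.0],
        "molded": [7.18, 7.18, 6.4, 5.9],
    }

    def test_matches_direct_formula_oracle(self):
        ours = dunn_bonferroni(GroupStudy(self.FIXTURE))
        oracle = _dunn_oracle(self.FIXTURE)
        for pair in oracle:
            assert ours[pair] == pytest.approx(oracle[pair], abs=1e-12)

    def test_identical_pair_has_adjusted_p_one(self):
        study = GroupStudy(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [10.0, 11.0, 12.0]}
        )
        adjusted = dunn_bonferroni(study)
        assert adjusted[("a", "b")] == 1.0

    def test_adjustment_never_below_raw(self):
        ours = dunn_bonferroni(GroupStudy(self.FIXTURE))
        oracle = _dunn_oracle(self.FIXTURE)
        m = 3
        for pair, adj in ours.items():
            assert adj >= oracle[pair] / m - 1e-12

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            dunn_bonferroni(GroupStudy({"a": [], "b": [1.0]}))

    def test_familywise_error_under_complete_null(self):
        """FWER of the Bonferroni-adjusted Dunn tests stays at/below ~5%.

        10,000 simulated three-group null studies of n = 15 per group.
        """
        rng = np.random.default_rng(202)
        rejections = 0
        sims = 10_000
        for _ in range(sims):
            study = GroupStudy(
                {g: list(rng.normal(0, 1, 15)) for g in ("a", "b", "c")}
            )
            if any(p < 0.05 for p in dunn_bonferroni(study).values()):
                rejections += 1
        assert rejections / sims <= 0.05 + 0.01


class TestSummarize:
    def test_trivial_groups(self):
        out = summarize(GroupStudy({"a": [7.18, 7.18], "b": [1.0, 2.0, 3.0]}))
        assert out["a"]["mean"] == pytest.approx(7.18)
        assert out["a"]["sd"] == pytest.approx(0.0)
        assert out["b"]["mean"] == pytest.approx(2.0)
        assert out["b"]["sd"] == pytest.approx(1.0)

    def test_counts_passed_through(self):
        study = GroupStudy(
            {"a": [1.0, 2.0]}, {"a": 3}, {"a": 1}
        )
        out = summarize(study)
        assert out["a"]["delaminated"] == 3
        assert out["a"]["complete_penetration"] == 1

    def test_generator_ground_truth_recovered(self):
        """Summaries of a large synthetic study match generator parameters."""
        params = {
            "a": GroupParams(2.2, 0.5, cap_mm=100.0),
            "b": GroupParams(4.7, 0.5, cap_mm=100.0),
        }
        study = generate_group_study(10_000, params, seed=11)
        out = summarize(study)
        for g, p in params.items():
            assert out[g]["mean"] == pytest.approx(p.mean_mm, rel=0.02)
            assert out[g]["sd"] == pytest.approx(p.sd_mm, rel=0.02)


def test_full_report_shape():
    rng = np.random.default_rng(5)
    study = GroupStudy(
        {g: list(np.minimum(rng.normal(m, 1.0, 15), 7.18))
         for g, m in [("printed", 2.2), ("milled", 4.7), ("molded", 6.8)]}
    )
    report = full_report(study)
    assert set(report.shapiro_p) == {"printed", "milled", "molded"}
    assert 0.0 <= report.omnibus_p <= 1.0
    assert len(report.pairwise_adjusted_p) == 3
    assert all(0.0 <= p <= 1.0 for p in report.pairwise_adjusted_p.values())
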
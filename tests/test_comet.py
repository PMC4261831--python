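"""Comet-assay summaries, FPG net damage, and the Kruskal-Wallis workflow."""

import numpy as np
import pandas as pd
import pytest

from sedtriad.comet import (CometCondition, condition_summary,
                            kw_concentration_test, net_oxidative_damage)
from sedtriad.exceptions import PairingError


def make_condition(values, concentration=0.0, fpg=False, site="X", fraction=1,
                   replicates=None, gels=None):
    values = np.asarray(values, dtype=float)
    n = values.size
    reps = replicates if replicates is not None else np.ones(n, dtype=int)
    gel = gels if gels is not None else np.ones(n, dtype=int)
    return CometCondition(site, fraction, concentration, fpg, pd.DataFrame(
        {"replicate": reps, "gel": gel, "tail_pct": values}))


def kruskal_h_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from first principles (rank formula)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    srt = pooled[order]
    while i < n:
        j = i
        while j < n and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank of the tie block
        i = j
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / correction


class TestConditionSummary:
    def test_constant_nucleoids(self):
        s = condition_summary(make_condition([10.0] * 6))
        assert s["mean_tail_pct"] == pytest.approx(10.0)
        assert s["sd_tail_pct"] == pytest.approx(0.0)

    def test_two_value_mean(self):
        s = condition_summary(make_condition([0.0, 20.0]))
        assert s["mean_tail_pct"] == pytest.approx(10.0)

    def test_sampling_mean_within_three_se(self):
        rng = np.random.default_rng(42)
        draws = np.clip(rng.normal(25.0, 8.0, size=300), 0, 100)
        s = condition_summary(make_condition(draws))
        se = 8.0 / np.sqrt(300)
        assert abs(s["mean_tail_pct"] - 25.0) < 3 * se + 0.2  # small clip bias allowance

    def test_invariant_to_ordering_and_gel_grouping(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 40, size=60)
        a = make_condition(vals, gels=np.repeat([1, 2], 30))
        perm = rng.permutation(60)
        b = make_condition(vals[perm], gels=np.tile([1, 2], 30))
        assert condition_summary(a) == pytest.approx(condition_summary(b))

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            condition_summary(make_condition([]))

    def test_out_of_range_tail_rejected(self):
        with pytest.raises(ValueError):
            make_condition([120.0])


class TestNetOxidativeDamage:
    def test_difference(self):
        fpg = make_condition([30.0] * 4, concentration=50.0, fpg=True)
        std = make_condition([18.0] * 4, concentration=50.0)
        assert net_oxidative_damage(fpg, std) == pytest.approx(12.0)

    def test_negative_difference_preserved(self):
        fpg = make_condition([15.0] * 4, concentration=50.0, fpg=True)
        std = make_condition([18.0] * 4, concentration=50.0)
        assert net_oxidative_damage(fpg, std) == pytest.approx(-3.0)

    def test_mismatched_conditions_rejected(self):
        fpg = make_condition([30.0], concentration=50.0, fpg=True)
        std = make_condition([18.0], concentration=100.0)
        with pytest.raises(PairingError):
            net_oxidative_damage(fpg, std)


class TestKruskalWallis:
    def test_identical_groups_give_null_result(self):
        conds = [make_condition([5.0] * 4, concentration=c) for c in (0, 10, 50)]
        res = kw_concentration_test(conds, unit="nucleoid")
        assert res["H"] == 0.0
        assert res["p"] == 1.0
        assert not res["significant"]

    def test_h_matches_first_principles_oracle(self):
        """On a small toy set H equals the rank-formula oracle exactly."""
        groups = [np.array([3.1, 4.2, 5.0, 4.2]),
                  np.array([6.3, 7.1, 5.0, 8.0]),
                  np.array([9.4, 10.0, 8.0, 11.2])]
        conds = [make_condition(g, concentration=float(i * 10))
                 for i, g in enumerate(groups)]
        res = kw_concentration_test(conds, unit="nucleoid")
        assert res["H"] == pytest.approx(kruskal_h_oracle(groups), rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        groups = [rng.uniform(1, 50, 8) for _ in range(3)]
        conds = [make_condition(g, concentration=float(i))
                 for i, g in enumerate(groups)]
        trans = [make_condition(np.sqrt(g) * 3, concentration=float(i))
                 for i, g in enumerate(groups)]
        r1 = kw_concentration_test(conds, unit="nucleoid")
        r2 = kw_concentration_test(trans, unit="nucleoid")
        assert r1["H"] == pytest.approx(r2["H"], rel=1e-12)

    def test_pairwise_flags_shifted_concentration(self):
        rng = np.random.default_rng(3)
        control = make_condition(rng.normal(8, 2, 20).clip(0, 100))
        low = make_condition(rng.normal(8.5, 2, 20).clip(0, 100), concentration=10.0)
        high = make_condition(rng.normal(25, 2, 20).clip(0, 100), concentration=100.0)
        res = kw_concentration_test([control, low, high], unit="nucleoid")
        pw = res["pairwise_vs_control"].set_index("concentration")
        assert res["significant"]
        assert bool(pw.loc[100.0, "significant"])
        assert not bool(pw.loc[10.0, "significant"])

    def test_detection_rate_monotone_in_shift(self):
        rates = []
        for shift in (0.0, 2.0, 8.0):
            hits = 0
            for seed in range(60):
                rng = np.random.default_rng(seed)
                conds = [
                    make_condition(rng.normal(10, 3, 10).clip(0, 100)),
                    make_condition(rng.normal(10 + shift / 2, 3, 10).clip(0, 100),
                                   concentration=10.0),
                    make_condition(rng.normal(10 + shift, 3, 10).clip(0, 100),
                                   concentration=100.0),
                ]
                hits += kw_concentration_test(conds, unit="nucleoid")["significant"]
            rates.append(hits / 60)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.95

    def test_replicate_unit_collapses_nucleoids(self):
        rng = np.random.default_rng(9)
        conds = []
        for c in (0.0, 50.0):
            vals = rng.uniform(0, 30, 60)
            conds.append(make_condition(vals, concentration=c,
                                        replicates=np.repeat([1, 2, 3], 20)))
        res = kw_concentration_test(conds, unit="replicate")
        assert res["unit"] == "replicate"
        # 2 groups x 3 replicate means
        assert len(res["pairwise_vs_control"]) == 1

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kw_concentration_test([make_condition([1.0, 2.0])], unit="nucleoid")
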
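"""Wallenius category enrichment and the probability-weighting function."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biotinpaint.go import _wallenius_pmf_recursive, fit_pwf, go_test, wallenius_p
from biotinpaint.simulate import generate_go


def wallenius_tail_enumeration(m1, m2, n, odds, x):
    """Oracle: sum sequential-draw probabilities over all ordered sequences."""
    total = 0.0
    for seq in itertools.product([1, 0], repeat=n):
        if sum(seq) < x:
            continue
        p, c1, c2 = 1.0, m1, m2
        for draw in seq:
            denom = odds * c1 + c2
            if denom <= 0:
                p = 0.0
                break
            if draw:
                if c1 == 0:
                    p = 0.0
                    break
                p *= odds * c1 / denom
                c1 -= 1
            else:
                if c2 == 0:
                    p = 0.0
                    break
                p *= c2 / denom
                c2 -= 1
        total += p
    return total


class TestWallenius:
    def test_urn_two_white_weight_two(self):
        # 2 white (weight 2) + 2 black, draw 2: P(both white) = (4/6)(2/4) = 1/3
        assert wallenius_p(2, 2, 2, 4, 2.0) == pytest.approx(1 / 3, abs=1e-12)

    def test_odds_one_matches_central_hypergeometric(self):
        for N in (5, 17, 40):
            for m1 in (1, N // 3, N - 1):
                for n in (1, N // 2, N - 1):
                    pmf = _wallenius_pmf_recursive(m1, N - m1, n, 1.0)
                    for x in range(min(m1, n) + 1):
                        assert pmf[x:].sum() == pytest.approx(
                            stats.hypergeom.sf(x - 1, N, m1, n), abs=1e-9
                        )

    @pytest.mark.parametrize("odds", [0.4, 1.0, 2.5])
    def test_matches_ordered_draw_enumeration(self, odds):
        for m1, m2, n in [(3, 4, 5), (5, 5, 6), (2, 8, 4), (6, 2, 7)]:
            for x in range(min(m1, n) + 1):
                expected = wallenius_tail_enumeration(m1, m2, n, odds, x)
                assert wallenius_p(x, m1, n, m1 + m2, odds) == pytest.approx(
                    expected, abs=1e-9
                )

    def test_matches_scipy_distribution(self):
        # independent implementation of the same distribution
        for odds in (0.5, 3.0):
            mine = wallenius_p(7, 20, 30, 100, odds)
            ref = stats.nchypergeom_wallenius.sf(6, 100, 20, 30, odds)
            assert mine == pytest.approx(float(ref), rel=1e-6)

    def test_zero_tail_is_one(self):
        assert wallenius_p(0, 5, 5, 20, 1.7) == 1.0

    def test_impossible_margins_rejected(self):
        with pytest.raises(ValueError, match="impossible margins"):
            wallenius_p(6, 5, 10, 20, 1.0)
        with pytest.raises(ValueError):
            wallenius_p(1, 5, 5, 20, -1.0)

    def test_pmf_sums_to_one(self):
        for odds in (0.3, 1.0, 4.0):
            pmf = _wallenius_pmf_recursive(10, 15, 12, odds)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)


class TestPwf:
    def test_constant_bias_gives_uniform_weights(self):
        member = pd.Series({f"p{i}": i % 3 == 0 for i in range(30)})
        bias = pd.Series({f"p{i}": 2.0 for i in range(30)})
        pwf = fit_pwf(member, bias)
        assert np.allclose(pwf.weights, pwf.weights[0])

    def test_monotone_nondecreasing_in_bias(self, rng):
        bias = pd.Series(rng.lognormal(0, 1, 100), index=[f"p{i}" for i in range(100)])
        prob = 1 / (1 + np.exp(-np.log(bias)))
        member = pd.Series(rng.random(100) < prob, index=bias.index)
        pwf = fit_pwf(member, bias)
        order = np.argsort(pwf.bias)
        assert np.all(np.diff(pwf.weights[order]) >= -1e-12)
        assert np.all(pwf.weights > 0)

    def test_linear_membership_recovered_at_data_points(self):
        # strictly monotone noiseless data: isotonic fit reproduces it
        bias = pd.Series(np.arange(1, 21, dtype=float), index=[f"p{i}" for i in range(20)])
        member = pd.Series(
            [0] * 10 + [1] * 10, index=bias.index, dtype=bool
        )
        pwf = fit_pwf(member, bias)
        assert pwf.weights[-1] > pwf.weights[0]

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError):
            fit_pwf(pd.Series({"a": True}), pd.Series({"a": 1.0}))


class TestGoTest:
    def test_constant_bias_equals_fisher(self, rng):
        accs = [f"p{i}" for i in range(60)]
        ann = {a: {"T1"} if i < 20 else {"T2"} for i, a in enumerate(accs)}
        biotinome = set(rng.choice(accs, 25, replace=False))
        bias = {a: 1.0 for a in accs}
        res = go_test(ann, biotinome, bias, universe=accs)
        for _, row in res.iterrows():
            k = int(row["k"])
            size = int(row["category_size"])
            ref = stats.hypergeom.sf(k - 1, 60, size, len(biotinome))
            assert row["p_value"] == pytest.approx(float(ref), abs=1e-9)

    def test_small_categories_filtered(self):
        accs = [f"p{i}" for i in range(20)]
        ann = {accs[0]: {"tiny"}, accs[1]: {"tiny"}}
        for a in accs[:10]:
            ann.setdefault(a, set()).add("big")
        res = go_test(ann, set(accs[:5]), {a: 1.0 for a in accs}, universe=accs)
        assert "tiny" not in set(res["term"])
        assert "big" in set(res["term"])

    def test_planted_category_usually_ranks_first(self):
        # clean recovery design: the category effect is the only signal
        # (the bias-confounded design has its own dedicated type-I test)
        hits = 0
        for seed in range(10):
            go = generate_go(
                [f"p{i}" for i in range(500)], n_terms=50, category_size=25,
                planted_odds=5.0, bias_strength=0.0, bias_coupling=0.0, seed=seed,
            )
            res = go_test(
                go.annotations, go.biotinome, go.bias,
                universe=[f"p{i}" for i in range(500)],
            )
            hits += res.iloc[0]["term"] == go.planted_term
        assert hits >= 8

    def test_empty_biotinome_rejected(self):
        accs = [f"p{i}" for i in range(12)]
        ann = {a: {"T"} for a in accs}
        with pytest.raises(ValueError, match="empty biotinome"):
            go_test(ann, set(), {a: 1.0 for a in accs})

    def test_fold_enrichment_definition(self):
        accs = [f"p{i}" for i in range(40)]
        ann = {a: {"T"} for a in accs[:10]}
        for a in accs:
            ann.setdefault(a, set()).add("ALL2" if int(a[1:]) % 2 else "ALL1")
        biotinome = set(accs[:8])
        res = go_test(ann, biotinome, {a: 1.0 for a in accs}, universe=accs)
        row = res[res["term"] == "T"].iloc[0]
        assert row["fold"] == pytest.approx((8 / 8) / (10 / 40))
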
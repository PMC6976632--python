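"""Bias-corrected category (GO) enrichment via the Wallenius distribution.

Category enrichment of a protein set (here, a biotinome) is confounded by any
per-protein bias factor that drives both detection and annotation — protein
expression being the canonical example. Following the probability-weighting
approach of bias-aware GO testing, a monotone function of the bias factor is
fitted to set membership (isotonic regression), each protein's fitted
probability becomes its sampling weight, and each category is tested with the
Wallenius noncentral hypergeometric distribution — the law of biased sampling
without replacement — using the ratio of mean weights inside vs outside the
category as the odds. With constant bias the weights are equal and the test
reduces to the central hypergeometric (Fisher's exact one-sided test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

WEIGHT_FLOOR = 1e-6


@dataclass
class Pwf:
    """Fitted probability-weighting function: per-protein sampling weights."""

    accessions: list[str]
    bias: np.ndarray
    weights: np.ndarray  # fitted membership probabilities, floored > 0

    def weight_of(self, accession: str) -> float:
        return float(self.weights[self.accessions.index(accession)])


def fit_pwf(
    membership: Mapping[str, bool] | pd.Series,
    bias: Mapping[str, float] | pd.Series,
) -> Pwf:
    """Isotonic regression of set membership on a per-protein bias factor.

    Fits a monotone non-decreasing probability of membership as a function of
    bias; the fitted values (floored at a small epsilon so weights stay
    strictly positive) are the Wallenius sampling weights. Constant bias
    degenerates to one pooled probability — equal weights — which downstream
    reduces the test to Fisher's exact.
    """
    membership = pd.Series(membership).astype(float)
    bias = pd.Series(bias).astype(float)
    accs = [a for a in membership.index if a in bias.index]
    if len(accs) < 10:
        raise ValueError("need >= 10 proteins to fit the weighting function")
    x = bias.loc[accs].to_numpy()
    y = membership.loc[accs].to_numpy()
    if np.any(x <= 0):
        raise ValueError("bias factors must be strictly positive")
    if np.unique(x).size == 1:
        logger.info("constant bias factor: uniform weights (central hypergeometric)")
        fitted = np.full_like(y, y.mean())
    else:
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        fitted = iso.fit_transform(x, y)
    weights = np.clip(fitted, WEIGHT_FLOOR, None)
    return Pwf(accessions=list(accs), bias=x, weights=weights)


def _wallenius_pmf_recursive(m1: int, m2: int, n: int, odds: float) -> np.ndarray:
    """Exact pmf of the 2-colour Wallenius distribution by draw recursion.

    State after i draws: probability vector over x = number of category items
    drawn. The next draw is a category item with probability
    w*(m1-x) / (w*(m1-x) + (m2-(i-x))). Exact up to float rounding.
    """
    xmax = min(m1, n)
    probs = np.zeros(xmax + 1)
    probs[0] = 1.0
    xs = np.arange(xmax + 1)
    for i in range(n):
        cat_left = np.maximum(m1 - xs, 0).astype(float)
        non_left = np.maximum(m2 - (i - xs), 0).astype(float)
        total = odds * cat_left + non_left
        with np.errstate(invalid="ignore", divide="ignore"):
            p_cat = np.where(total > 0, odds * cat_left / np.where(total > 0, total, 1.0), 0.0)
        new = probs * (1.0 - p_cat)
        new[1:] += (probs * p_cat)[:-1]
        probs = new
    return probs


def wallenius_p(
    category_in: int,
    category_size: int,
    sample_size: int,
    population: int,
    odds: float,
    exact_max_population: int = 2000,
) -> float:
    """Over-representation tail P(X >= category_in) under Wallenius sampling.

    ``odds`` is the weight of a category item relative to a non-category item.
    For populations up to ``exact_max_population`` the pmf is computed by an
    exact draw-by-draw recursion; above that the computation falls back to
    scipy's numerical-integration implementation of the distribution.
    """
    m1, m2 = category_size, population - category_size
    n, x = sample_size, category_in
    if odds <= 0:
        raise ValueError("odds must be > 0")
    if not (0 <= m1 <= population and 0 <= n <= population):
        raise ValueError("impossible margins")
    if x < max(0, n - m2) or x > min(m1, n):
        if x <= max(0, n - m2):
            return 1.0  # whole support is >= x
        raise ValueError(
            f"impossible margins: x={x}, m1={m1}, m2={m2}, n={n}"
        )
    if population <= exact_max_population:
        pmf = _wallenius_pmf_recursive(m1, m2, n, odds)
        return float(min(1.0, pmf[x:].sum()))
    return float(
        min(1.0, stats.nchypergeom_wallenius.sf(x - 1, population, m1, n, odds))
    )


@dataclass(frozen=True)
class CategoryResult:
    term: str
    k: int  # biotinome members in the category
    category_size: int
    fold: float
    p_value: float
    p_adj: float


def go_test(
    annotations: Mapping[str, Iterable[str]],
    biotinome: Iterable[str],
    bias: Mapping[str, float],
    universe: Iterable[str] | None = None,
    min_category: int = 3,
    correct_bias: bool = True,
    alternative: str = "over",
) -> pd.DataFrame:
    """Per-category enrichment of the biotinome with bias correction.

    The population universe defaults to the annotated proteins; pass it
    explicitly to use a different background. For every category of size >=
    ``min_category`` the Wallenius over-representation p-value is computed
    with odds = mean fitted weight inside the category / mean outside, fold
    enrichment = (k/sample)/(category/population), and Benjamini-Hochberg
    adjustment across tested categories. ``correct_bias=False`` forces odds
    1 everywhere (a plain Fisher-style hypergeometric test) for comparison.
    """
    annotations = {a: set(t) for a, t in annotations.items() if t}
    if universe is None:
        universe_l = sorted(annotations)
    else:
        universe_l = sorted(set(universe))
    biotinome = set(biotinome) & set(universe_l)
    if not biotinome:
        raise ValueError("empty biotinome within the universe")
    population = len(universe_l)
    sample_size = len(biotinome)

    membership = pd.Series({a: a in biotinome for a in universe_l})
    if correct_bias:
        pwf = fit_pwf(membership, pd.Series(bias).loc[universe_l])
        w = pd.Series(pwf.weights, index=pwf.accessions)
    else:
        w = pd.Series(1.0, index=universe_l)

    terms: dict[str, set[str]] = {}
    for acc in universe_l:
        for t in annotations.get(acc, ()):  # unannotated proteins stay in the universe
            terms.setdefault(t, set()).add(acc)

    rows = []
    for term in sorted(terms):
        members = terms[term]
        size = len(members)
        if size < min_category or size == population:
            continue
        k = len(members & biotinome)
        mean_in = float(w.loc[sorted(members)].mean())
        out = [a for a in universe_l if a not in members]
        mean_out = float(w.loc[out].mean())
        odds = mean_in / mean_out
        if alternative == "over":
            p = wallenius_p(k, size, sample_size, population, odds)
        elif alternative == "under":
            pmf = _wallenius_pmf_recursive(size, population - size, sample_size, odds)
            p = float(min(1.0, pmf[: k + 1].sum()))
        else:
            raise ValueError("alternative must be 'over' or 'under'")
        expected = sample_size * size / population
        fold = (k / sample_size) / (size / population) if sample_size else np.nan
        rows.append((term, k, size, expected, fold, p))
    df = pd.DataFrame(
        rows, columns=["term", "k", "category_size", "expected", "fold", "p_value"]
    )
    if len(df):
        df["p_adj"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p_adj", "p_value", "term"]).reset_index(drop=True)
    else:
        df["p_adj"] = []
    return df
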
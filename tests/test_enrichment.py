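"""Binomial enrichment of sites within IDRs: oracle checks and pipeline."""

import math

import numpy as np
import pytest
from scipy import stats

from biotinpaint.enrichment import (
    bin_biotin_count,
    binomial_test,
    biotin_disorder_association,
    count_target_residues,
    pooled_null_rate,
    study_enrichment,
    subset_enrichment,
    summarize_biotin_counts,
)
from biotinpaint.idr import idrset_from_intervals
from biotinpaint.io import ProteinRecord, SiteRecord
from biotinpaint.simulate import generate_proteome, plant_sites, target_residue_index


def brute_force_binomial(k, n, p0, alternative):
    """Independent oracle: direct pmf enumeration with exact binomials."""
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    if alternative == "greater":
        return sum(pmf[k:])
    return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-7))


class TestCountTargetResidues:
    def test_lysine_counts_on_kakyk(self, small_proteome):
        idr = idrset_from_intervals("P2", [(1, 2)], 5)
        c = count_target_residues(small_proteome["P2"], idr, {"K"})
        assert (c.n_in_idr, c.n_total) == (1, 3)

    def test_tyrosine_counts_on_kakyk(self, small_proteome):
        idr = idrset_from_intervals("P2", [(1, 2)], 5)
        c = count_target_residues(small_proteome["P2"], idr, {"Y"})
        assert (c.n_in_idr, c.n_total) == (0, 1)

    def test_empty_idr_set_never_in_idr(self, small_proteome):
        idr = idrset_from_intervals("P2", [], 5)
        assert count_target_residues(small_proteome["P2"], idr, {"K"}).n_in_idr == 0

    def test_empty_residue_set_rejected(self, small_proteome):
        idr = idrset_from_intervals("P2", [], 5)
        with pytest.raises(ValueError):
            count_target_residues(small_proteome["P2"], idr, set())


class TestPooledNullRate:
    def test_pooled_arithmetic(self):
        from biotinpaint.enrichment import ResidueCounts

        counts = [
            ResidueCounts("a", frozenset("K"), 2, 10),
            ResidueCounts("b", frozenset("K"), 3, 10),
        ]
        assert pooled_null_rate(counts) == pytest.approx(0.25)

    def test_degenerate_null_rates_flagged_downstream(self):
        from biotinpaint.enrichment import ResidueCounts

        assert pooled_null_rate([ResidueCounts("a", frozenset("K"), 0, 7)]) == 0.0
        assert pooled_null_rate([ResidueCounts("a", frozenset("K"), 10, 10)]) == 1.0
        with pytest.raises(ValueError, match="no target residues"):
            pooled_null_rate([ResidueCounts("a", frozenset("K"), 0, 0)])


class TestBinomialTest:
    def test_all_successes_greater_closed_form(self):
        assert binomial_test(10, 10, 0.5, "greater") == pytest.approx(2**-10)

    def test_two_sided_symmetric_half(self):
        # p0 = 0.5 is symmetric: p = 2 * P(X <= 3) = 2 * 176/1024
        assert binomial_test(3, 10, 0.5, "two-sided") == pytest.approx(0.34375)

    def test_mode_two_sided_is_one(self):
        assert binomial_test(5, 10, 0.5, "two-sided") == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_matches_brute_force_oracle(self, alternative):
        for n in (1, 2, 5, 9, 17, 25):
            for p0 in (0.05, 0.3, 0.5, 0.72, 0.95):
                for k in range(n + 1):
                    expected = brute_force_binomial(k, n, p0, alternative)
                    assert binomial_test(k, n, p0, alternative) == pytest.approx(
                        expected, abs=1e-12
                    )

    def test_matches_scipy_binomtest(self):
        # independent cross-check against the reference implementation
        for k, n, p0 in [(3, 40, 0.2), (30, 40, 0.5), (0, 12, 0.7)]:
            for alt in ("two-sided", "greater"):
                ref = stats.binomtest(k, n, p0, alternative=alt).pvalue
                assert binomial_test(k, n, p0, alt) == pytest.approx(ref, rel=1e-10)

    def test_greater_tail_monotone_in_k(self):
        for n in (8, 15):
            for p0 in (0.2, 0.5, 0.8):
                ps = [binomial_test(k, n, p0, "greater") for k in range(n + 1)]
                assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_test(1, 2, 0.0)
        with pytest.raises(ValueError):
            binomial_test(1, 2, 1.0)
        with pytest.raises(ValueError):
            binomial_test(3, 2, 0.5)


@pytest.fixture(scope="module")
def planted():
    sim = generate_proteome(n_proteins=120, mean_length=800, seed=7)
    idx = target_residue_index(sim.proteome, sim.truth_idrsets, ["K"])
    sites = plant_sites(
        sim.proteome, sim.truth_idrsets, "K", 800, 3.0, seed=8, index=idx
    )
    return sim, idx, sites


@pytest.fixture(scope="module")
def tagged():
    sim = generate_proteome(n_proteins=100, mean_length=300, seed=17)
    sites = plant_sites(sim.proteome, sim.truth_idrsets, "K", 800, 2.0, seed=18)
    return sim, sites


class TestStudyEnrichment:

    def test_fold_tracks_planting_closed_form(self, planted, sim_registry):
        sim, idx, sites = planted
        res, bar = study_enrichment(
            sites, sim.proteome, sim.truth_idrsets, sim_registry
        )
        q = idx.q_r
        expected_rate = 3 * q / (3 * q + 1 - q)
        # planting saturation (dedup) pulls the observed rate slightly down
        assert res.k / res.n == pytest.approx(expected_rate, abs=0.05)
        assert res.fold > 1.3
        assert res.p_value < 1e-10
        assert bar.loc[bar["quantity"] == "expected", "in_idr_rate"].iloc[0] == res.p0

    def test_observed_rate_and_result_consistency(self, planted, sim_registry):
        sim, _, sites = planted
        res, _ = study_enrichment(sites, sim.proteome, sim.truth_idrsets, sim_registry)
        assert res.fold == pytest.approx((res.k / res.n) / res.p0)
        assert res.scope == "SIM"

    def test_all_sites_in_idr_boundary(self, sim_registry):
        proteome = {"P1": ProteinRecord("P1", "KKKKKAAAAA")}
        idrs = {"P1": idrset_from_intervals("P1", [(1, 3)], 10)}
        sites = [SiteRecord("SIM", "P1", i, "K", "biotin") for i in (1, 2, 3)]
        res, _ = study_enrichment(
            sites, proteome, idrs, sim_registry, alternative="greater"
        )
        assert res.k == res.n == 3
        assert res.p0 == pytest.approx(0.6)
        assert res.p_value == pytest.approx(0.6**3)
        assert res.fold == pytest.approx(1 / 0.6)

    def test_empty_biotinome_rejected(self, sim_registry, small_proteome):
        with pytest.raises(ValueError):
            study_enrichment([], small_proteome, {}, sim_registry, study_id="SIM")


class TestSubsetEnrichment:
    def test_predicate_scope_counts(self, tagged, sim_registry):
        sim, sites = tagged
        n_tagged = sum(
            "ribosomal" in p.description for p in sim.proteome.values()
        )
        assert n_tagged == 10  # ribosomal_fraction default 0.10
        res, _ = subset_enrichment(
            sim.proteome and sites, sim.proteome, sim.truth_idrsets, sim_registry,
            name_predicate="ribosomal",
        )
        assert res.n <= len(sites)

    def test_disjoint_subsets_bounded_by_total(self, tagged, sim_registry):
        sim, sites = tagged
        res_all, _ = study_enrichment(
            sites, sim.proteome, sim.truth_idrsets, sim_registry
        )
        res_ribo, _ = subset_enrichment(
            sites, sim.proteome, sim.truth_idrsets, sim_registry, "ribosomal"
        )
        assert res_ribo.k <= res_all.k and res_ribo.n <= res_all.n

    def test_mito_scope_subset_of_ribosomal_scope(self, tagged, sim_registry):
        sim, sites = tagged
        res_mito, _ = subset_enrichment(
            sites, sim.proteome, sim.truth_idrsets, sim_registry,
            "mitochondrial ribosomal",
        )
        res_ribo, _ = subset_enrichment(
            sites, sim.proteome, sim.truth_idrsets, sim_registry, "ribosomal"
        )
        assert res_mito.n <= res_ribo.n

    def test_zero_selection_rejected(self, tagged, sim_registry):
        sim, sites = tagged
        with pytest.raises(ValueError, match="zero proteins"):
            subset_enrichment(
                sites, sim.proteome, sim.truth_idrsets, sim_registry, "no such name"
            )


class TestAssociation:
    def test_binning_rule(self):
        assert [bin_biotin_count(c) for c in (0, 1, 2, 7)] == ["0", "1", "2", "5+"]

    def test_perfect_correlation(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "accession": list("abcde"),
                "biotin_count": [1, 2, 3, 4, 5],
                "disorder_fraction": [0.1, 0.2, 0.3, 0.4, 0.5],
                "bin": ["1", "2", "3", "4", "5+"],
            }
        )
        res = biotin_disorder_association(df)
        assert res.r == pytest.approx(1.0)

    def test_null_association_near_zero(self, sim_registry):
        sim = generate_proteome(n_proteins=300, mean_length=300, seed=27)
        sites = plant_sites(sim.proteome, sim.truth_idrsets, "K", 3000, 1.0, seed=28)
        df = summarize_biotin_counts(sites, sim.proteome, sim.truth_idrsets)
        res = biotin_disorder_association(df)
        assert abs(res.r) < 0.2
        assert set(res.bin_table["bin"]) <= {"0", "1", "2", "3", "4", "5+"}

    def test_zero_variance_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "accession": list("abc"),
                "biotin_count": [2, 2, 2],
                "disorder_fraction": [0.1, 0.2, 0.3],
                "bin": ["2", "2", "2"],
            }
        )
        with pytest.raises(ValueError, match="variance"):
            biotin_disorder_association(df)
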
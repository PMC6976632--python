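"""The synthetic-data generator: determinism, coverage and planting model."""

import numpy as np
import pytest

from biotinpaint.idr import combine_consensus, disorder_fraction
from biotinpaint.simulate import (
    _random_blocks,
    generate_go,
    generate_proteome,
    generate_tmt,
    plant_sites,
    target_residue_index,
)


class TestProteome:
    def test_zero_disorder_means_no_blocks(self):
        sim = generate_proteome(n_proteins=10, disorder_fraction=0.0, seed=1)
        assert all(s.intervals == () for s in sim.truth_idrsets.values())

    def test_full_disorder_saturates(self):
        sim = generate_proteome(n_proteins=10, disorder_fraction=1.0, seed=1)
        assert all(
            disorder_fraction(s).fraction == 1.0 for s in sim.truth_idrsets.values()
        )

    def test_block_mask_hits_target_exactly(self, rng):
        for L, q in [(100, 0.3), (57, 0.5), (200, 0.05)]:
            mask = _random_blocks(rng, L, q, 20.0)
            assert mask.sum() == round(q * L)

    def test_seeded_rerun_is_identical(self):
        a = generate_proteome(n_proteins=15, seed=42)
        b = generate_proteome(n_proteins=15, seed=42)
        assert all(
            a.proteome[k].sequence == b.proteome[k].sequence for k in a.proteome
        )
        assert all(
            a.truth_idrsets[k].intervals == b.truth_idrsets[k].intervals
            for k in a.proteome
        )

    def test_zero_flip_noise_consensus_equals_truth(self):
        sim = generate_proteome(
            n_proteins=10,
            predictors=tuple((f"p{i}", 0.0) for i in range(5)),
            seed=3,
        )
        from biotinpaint.idr import binarize_track

        for acc, tracks in sim.tracks.items():
            cons = combine_consensus([binarize_track(t) for t in tracks])
            assert cons.intervals == sim.truth_idrsets[acc].intervals

    def test_fraction_spread_populates_all_classes(self):
        from biotinpaint.structure import classify_protein

        sim = generate_proteome(
            n_proteins=200, disorder_fraction_spread=2.0, seed=55
        )
        classes = {
            classify_protein(s.n_disordered / s.length)
            for s in sim.truth_idrsets.values()
        }
        assert classes == {"F", "P", "U"}

    def test_spread_creates_count_disorder_association(self):
        from biotinpaint.enrichment import (
            biotin_disorder_association,
            summarize_biotin_counts,
        )

        sim = generate_proteome(
            n_proteins=300, disorder_fraction_spread=2.0, seed=56
        )
        sites = plant_sites(sim.proteome, sim.truth_idrsets, "K", 2000, 3.0, seed=57)
        df = summarize_biotin_counts(sites, sim.proteome, sim.truth_idrsets)
        assoc = biotin_disorder_association(df)
        assert assoc.r > 0.15 and assoc.p_value < 0.01

    def test_ribosomal_tagging_fractions(self):
        sim = generate_proteome(n_proteins=100, seed=4)
        ribo = [p for p in sim.proteome.values() if "ribosomal" in p.description]
        mito = [p for p in ribo if "mitochondrial" in p.description]
        assert len(ribo) == 10 and len(mito) == 2


class TestPlanting:
    def test_null_planting_matches_background(self):
        sim = generate_proteome(n_proteins=300, mean_length=400, seed=5)
        idx = target_residue_index(sim.proteome, sim.truth_idrsets, ["K"])
        sites = plant_sites(
            sim.proteome, sim.truth_idrsets, "K", 3000, 1.0, seed=6, index=idx
        )
        masks = {a: s.to_mask() for a, s in sim.truth_idrsets.items()}
        obs = np.mean([masks[s.accession][s.position - 1] for s in sites])
        se = np.sqrt(idx.q_r * (1 - idx.q_r) / len(sites))
        assert obs == pytest.approx(idx.q_r, abs=4 * se)

    def test_extreme_rho_saturates_idrs(self):
        sim = generate_proteome(n_proteins=30, seed=7)
        sites = plant_sites(sim.proteome, sim.truth_idrsets, "K", 200, 1e9, seed=8)
        masks = {a: s.to_mask() for a, s in sim.truth_idrsets.items()}
        assert all(masks[s.accession][s.position - 1] for s in sites)

    @pytest.mark.parametrize("rho,q_target", [(0.5, 0.3), (3.0, 0.3), (2.0, 0.5)])
    def test_in_idr_fraction_matches_closed_form(self, rho, q_target):
        sim = generate_proteome(
            n_proteins=400, mean_length=2000, disorder_fraction=q_target,
            predictors=(("VSL2b", 0.0),), seed=9,
        )
        idx = target_residue_index(sim.proteome, sim.truth_idrsets, ["K"])
        sites = plant_sites(
            sim.proteome, sim.truth_idrsets, "K", 10_000, rho, seed=10, index=idx
        )
        q = idx.q_r
        expected = rho * q / (rho * q + 1 - q)
        masks = {a: s.to_mask() for a, s in sim.truth_idrsets.items()}
        obs = np.mean([masks[s.accession][s.position - 1] for s in sites])
        se = np.sqrt(expected * (1 - expected) / len(sites))
        # small extra slack for with-replacement dedup saturation
        assert obs == pytest.approx(expected, abs=3 * se + 0.01)

    def test_residue_letters_match_sequences(self):
        sim = generate_proteome(n_proteins=20, seed=11)
        sites = plant_sites(sim.proteome, sim.truth_idrsets, "Y", 100, 2.0, seed=12)
        for s in sites:
            assert sim.proteome[s.accession].sequence[s.position - 1] == "Y" == s.residue

    def test_no_target_residues_rejected(self):
        sim = generate_proteome(
            n_proteins=3, composition={"A": 0.5, "L": 0.5}, seed=13
        )
        with pytest.raises(ValueError, match="no target residues"):
            plant_sites(sim.proteome, sim.truth_idrsets, "K", 10, 1.0, seed=14)


class TestTmtAndGo:
    def test_tmt_seeded_rerun_identical(self):
        a = generate_tmt(seed=20)
        b = generate_tmt(seed=20)
        assert a.equals(b)

    def test_tmt_missingness_and_contamination(self):
        tmt = generate_tmt(
            n_null=200, n_late=0, missing_rate=0.1, nonbiotin_rate=0.2,
            nonribosomal_rate=0.1, seed=21,
        )
        chans = [c for c in tmt.columns if c[0].isdigit() or c.startswith("carrier")]
        assert 0.05 < tmt[chans].isna().to_numpy().mean() < 0.15
        assert 0.1 < (~tmt["is_biotinylated"]).mean() < 0.3

    def test_late_effect_raises_300s_channels(self):
        tmt = generate_tmt(n_null=50, n_late=50, effect=2.0, seed=22)
        log300 = np.log2(tmt[["300s_1", "300s_2", "300s_3"]]).mean(axis=1)
        log10 = np.log2(tmt[["10s_1", "10s_2", "10s_3"]]).mean(axis=1)
        diff = (log300 - log10).groupby(tmt["is_late_truth"]).mean()
        assert diff[True] == pytest.approx(2.0, abs=0.5)
        assert diff[False] == pytest.approx(0.0, abs=0.5)

    def test_go_seeded_rerun_identical(self):
        accs = [f"p{i}" for i in range(100)]
        a = generate_go(accs, seed=23)
        b = generate_go(accs, seed=23)
        assert a.annotations == b.annotations and a.biotinome == b.biotinome

    def test_planted_category_overrepresented(self):
        accs = [f"p{i}" for i in range(500)]
        go = generate_go(accs, planted_odds=5.0, bias_strength=0.0, seed=24)
        planted = {a for a in accs if go.planted_term in go.annotations[a]}
        in_rate = len(planted & go.biotinome) / len(planted)
        bg_rate = len(go.biotinome) / len(accs)
        assert in_rate > bg_rate

    def test_oversized_category_rejected(self):
        with pytest.raises(ValueError):
            generate_go(["a", "b"], category_size=5, seed=25)
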
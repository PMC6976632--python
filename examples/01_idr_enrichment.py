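"""Observed vs expected biotinylation inside IDRs on a simulated study.

Builds a small synthetic proteome with ~30% disorder, plants 800 biotin
sites on lysines with a 3x preference for disordered residues, and runs the
composition-aware binomial enrichment test. The fold should sit near the
planting closed form rho/(rho*q + 1 - q) = 1.87 at q = 0.3.
"""

from biotinpaint.enrichment import study_enrichment
from biotinpaint.io import StudyRegistry, StudyRegistryEntry
from biotinpaint.simulate import generate_proteome, plant_sites, target_residue_index

sim = generate_proteome(n_proteins=300, mean_length=800, disorder_fraction=0.3, seed=1)
idx = target_residue_index(sim.proteome, sim.truth_idrsets, ["K"])
sites = plant_sites(
    sim.proteome, sim.truth_idrsets, "K", n_sites=800, rho=3.0, seed=2,
    study_id="DEMO", index=idx,
)

registry = StudyRegistry([StudyRegistryEntry("DEMO", "K", "NHS-Biotin", 1000.0)])
result, bar_table = study_enrichment(sites, sim.proteome, sim.truth_idrsets, registry)

print(f"target-residue fraction in IDRs (q_r): {idx.q_r:.3f}")
print(f"unique sites (trials) n = {result.n}, in-IDR successes k = {result.k}")
print(f"null rate p0 = {result.p0:.3f}, observed rate = {result.k / result.n:.3f}")
print(f"fold enrichment = {result.fold:.2f}   p = {result.p_value:.3g}")
print(bar_table.to_string(index=False))
# The fold ~1.8 and tiny p say: biotins land inside IDRs almost twice as
# often as the lysine composition of these proteins would predict.
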
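"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of (config, seed): one global seed expands
into per-component child seeds through ``numpy.random.SeedSequence.spawn`` in
a fixed order (proteome, sites, PTMs, TMT, GO), so each component can be
regenerated independently and reruns are byte-identical.

The proteome model: i.i.d. residues from a fixed composition (lysine 6%,
tyrosine 3%, the remaining 18 amino acids uniform — approximate natural
abundances for the two residues that matter to the chemistry); per protein,
a block-structured disorder mask covering exactly ``round(q * length)``
residues, split into geometric-length blocks placed uniformly at random
without overlap. Hitting the target disorder fraction q exactly (instead of
only in expectation) keeps the planting closed form sharp in tests.

Site planting realizes the enrichment alternative: each site picks a target
residue with weight rho inside IDRs and 1 outside, with replacement, then
duplicates collapse (real studies count unique sites). The expected unique
in-IDR fraction is rho*q_r / (rho*q_r + 1 - q_r) with q_r the fraction of
target residues inside IDRs — the quantity the enrichment module should
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .idr import IdrSet, _runs_to_intervals
from .io import DisorderTrack, ProteinRecord, SiteRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def default_composition() -> dict[str, float]:
    """K at 6%, Y at 3%, remaining mass uniform over the other 18 residues."""
    comp = {aa: 0.91 / 18 for aa in AA_ORDER if aa not in "KY"}
    comp["K"] = 0.06
    comp["Y"] = 0.03
    return comp


@dataclass
class SimProteome:
    proteome: dict[str, ProteinRecord]
    truth_idrsets: dict[str, IdrSet]
    tracks: dict[str, list[DisorderTrack]]


def _random_blocks(
    rng: np.random.Generator, length: int, q: float, mean_block: float
) -> np.ndarray:
    """Binary disorder mask with exactly round(q*length) residues in blocks.

    The disordered residues are split into m blocks (m ~ Poisson of the
    expected block count, clipped to feasibility) and the blocks are placed
    by a uniformly random composition of the ordered residues into the m+1
    surrounding gaps (interior gaps >= 1, so blocks never touch).
    """
    n_dis = int(round(q * length))
    mask = np.zeros(length, dtype=bool)
    if n_dis <= 0:
        return mask
    if n_dis >= length:
        return np.ones(length, dtype=bool)
    n_ord = length - n_dis
    m_max = min(n_dis, n_ord + 1)
    m = int(rng.poisson(max(n_dis / mean_block, 1e-9)))
    m = max(1, min(m, m_max))
    # block sizes: uniform composition of n_dis into m parts >= 1
    if m > 1:
        cuts = np.sort(rng.choice(np.arange(1, n_dis), size=m - 1, replace=False))
        sizes = np.diff(np.concatenate(([0], cuts, [n_dis])))
    else:
        sizes = np.array([n_dis])
    # gap sizes: composition of n_ord into m+1 parts, interior parts >= 1
    free = n_ord - (m - 1)
    bars = np.sort(rng.integers(0, free + 1, size=m))
    gaps = np.diff(np.concatenate(([0], bars, [free])))
    gaps[1:-1] += 1  # restore the mandatory interior separators
    pos = 0
    for gap, size in zip(gaps[:-1], sizes):
        pos += int(gap)
        mask[pos : pos + int(size)] = True
        pos += int(size)
    return mask


def generate_proteome(
    n_proteins: int = 200,
    mean_length: float = 450.0,
    length_shape: float = 6.0,
    min_length: int = 50,
    composition: Mapping[str, float] | None = None,
    disorder_fraction: float = 0.3,
    disorder_fraction_spread: float | None = None,
    mean_block_length: float = 30.0,
    predictors: Sequence[tuple[str, float]] = (("VSL2b", 0.0), ("IUPred-L", 0.05)),
    ribosomal_fraction: float = 0.10,
    mito_ribosomal_fraction: float = 0.02,
    seed: int | np.random.SeedSequence = 0,
) -> SimProteome:
    """Simulate a proteome with block-structured IDRs and predictor tracks.

    Lengths are gamma-distributed (shape ``length_shape``) around
    ``mean_length`` with a floor. ``predictors`` lists (name, flip_noise)
    pairs: each track is the true disorder mask with independent per-residue
    flips at the given rate, so a rate of 0 reproduces the truth exactly.
    The first zero-noise predictor doubles as the ground-truth caller.

    The first ``mito_ribosomal_fraction`` of proteins are described as
    mitochondrial ribosomal proteins and the next ones as cytosolic ribosomal
    proteins up to ``ribosomal_fraction`` in total, so name-predicate subset
    analyses have something to select.

    With the default ``disorder_fraction_spread=None`` every protein carries
    exactly the target disorder fraction, which keeps the site-planting
    closed form sharp. Setting a spread draws per-protein fractions from a
    Beta distribution with mean ``disorder_fraction`` and concentration
    ``spread`` (smaller = more variable), populating all three structural
    classes and creating a real count/disorder association under rho > 1.
    """
    if not (0.0 <= disorder_fraction <= 1.0):
        raise ValueError("disorder fraction must be in [0, 1]")
    if mean_block_length > mean_length and disorder_fraction not in (0.0, 1.0):
        raise ValueError("mean block length exceeds mean protein length")
    comp = dict(composition) if composition is not None else default_composition()
    aas = sorted(comp)
    probs = np.array([comp[a] for a in aas], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("composition must be a probability distribution")
    probs = probs / probs.sum()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    aa_arr = np.array(list(aas))
    width = len(str(max(n_proteins, 1)))
    proteome: dict[str, ProteinRecord] = {}
    truth: dict[str, IdrSet] = {}
    tracks: dict[str, list[DisorderTrack]] = {}
    n_mito = int(round(mito_ribosomal_fraction * n_proteins))
    n_ribo = int(round(ribosomal_fraction * n_proteins))
    for i in range(n_proteins):
        acc = f"SIM{i + 1:0{width}d}"
        length = max(
            min_length, int(round(rng.gamma(length_shape, mean_length / length_shape)))
        )
        seq = "".join(aa_arr[rng.choice(len(aas), size=length, p=probs)])
        if disorder_fraction_spread is None:
            q_i = disorder_fraction
        elif disorder_fraction in (0.0, 1.0):
            q_i = disorder_fraction
        else:
            c = disorder_fraction_spread
            q_i = float(
                rng.beta(disorder_fraction * c, (1.0 - disorder_fraction) * c)
            )
        mask = _random_blocks(rng, length, q_i, mean_block_length)
        if i < n_mito:
            desc = f"{acc} synthetic mitochondrial ribosomal protein"
        elif i < n_ribo:
            desc = f"{acc} synthetic ribosomal protein"
        else:
            desc = f"{acc} synthetic protein"
        proteome[acc] = ProteinRecord(accession=acc, sequence=seq, description=desc)
        truth[acc] = IdrSet(
            accession=acc,
            intervals=_runs_to_intervals(mask),
            length=length,
            caller_label="truth",
        )
        tlist = []
        for name, flip in predictors:
            values = mask.copy()
            if flip > 0:
                flips = rng.random(length) < flip
                values = values ^ flips
            tlist.append(
                DisorderTrack(
                    accession=acc, predictor=name, values=values.astype(float)
                )
            )
        tracks[acc] = tlist
    return SimProteome(proteome=proteome, truth_idrsets=truth, tracks=tracks)


@dataclass
class TargetIndex:
    """Flat arrays of every target-residue position in a proteome."""

    accessions: np.ndarray  # object array of accession strings
    positions: np.ndarray  # 1-based
    residues: np.ndarray
    in_idr: np.ndarray  # bool

    @property
    def q_r(self) -> float:
        """Fraction of target residues inside IDRs."""
        return float(self.in_idr.mean())


def target_residue_index(
    proteome: Mapping[str, ProteinRecord],
    idrsets: Mapping[str, IdrSet],
    residues: Sequence[str],
) -> TargetIndex:
    accs, poss, ress, flags = [], [], [], []
    targets = set(residues)
    for acc, prot in proteome.items():
        mask = idrsets[acc].to_mask()
        for i, aa in enumerate(prot.sequence):
            if aa in targets:
                accs.append(acc)
                poss.append(i + 1)
                ress.append(aa)
                flags.append(bool(mask[i]))
    if not accs:
        raise ValueError(f"no target residues {sorted(targets)} in proteome")
    return TargetIndex(
        accessions=np.array(accs, dtype=object),
        positions=np.array(poss, dtype=int),
        residues=np.array(ress, dtype=object),
        in_idr=np.array(flags, dtype=bool),
    )


def plant_sites(
    proteome: Mapping[str, ProteinRecord],
    idrsets: Mapping[str, IdrSet],
    target_residue: str = "K",
    n_sites: int = 1000,
    rho: float = 1.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    study_id: str = "SIM",
    modification: str = "biotin",
    index: TargetIndex | None = None,
) -> list[SiteRecord]:
    """Plant modification sites with in-IDR enrichment factor rho.

    Each of ``n_sites`` draws picks a target-residue position with weight rho
    inside IDRs and 1 outside (with replacement); duplicates then collapse to
    unique sites. A precomputed ``index`` makes repeated simulated studies on
    one proteome cheap.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if index is None:
        index = target_residue_index(proteome, idrsets, [target_residue])
    weights = np.where(index.in_idr, rho, 1.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    chosen = rng.choice(len(weights), size=n_sites, replace=True, p=weights / total)
    unique = np.unique(chosen)
    return [
        SiteRecord(
            study_id=study_id,
            accession=str(index.accessions[i]),
            position=int(index.positions[i]),
            residue=str(index.residues[i]),
            modification=modification,
        )
        for i in unique
    ]


def generate_tmt(
    n_null: int = 100,
    n_late: int = 25,
    effect: float = 1.5,
    noise_sd: float = 1.0,
    effect_at_120s: bool = True,
    baseline_mean: float = 14.0,
    baseline_sd: float = 1.0,
    missing_rate: float = 0.0,
    nonbiotin_rate: float = 0.0,
    nonribosomal_rate: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate a TMT reporter matrix for the labelling time course.

    Log2 intensities are baseline + condition effect + Normal(0, noise_sd)
    noise; "late" peptides gain ``effect`` (in log2 units, i.e. ``effect /
    noise_sd`` noise-standard-deviations) at 300 s and — kinetics accumulate —
    also at 120 s unless ``effect_at_120s=False``. Null peptides are flat. A
    carrier channel and optional missingness/contamination flags exercise the
    filtering rules. Intensities are emitted on the linear scale.
    """
    if n_late > n_null + n_late:
        raise ValueError("n_late exceeds total")
    rng = np.random.default_rng(seed)
    n = n_null + n_late
    is_late = np.zeros(n, dtype=bool)
    is_late[n_null:] = True
    baseline = rng.normal(baseline_mean, baseline_sd, size=n)
    conditions = ["10s"] * 3 + ["120s"] * 3 + ["300s"] * 3 + ["carrier"]
    cols = [f"{c}_{i % 3 + 1}" if c != "carrier" else "carrier_1"
            for i, c in enumerate(conditions)]
    log2 = np.tile(baseline[:, None], (1, len(cols)))
    for j, cond in enumerate(conditions):
        if cond == "300s":
            log2[is_late, j] += effect
        elif cond == "120s" and effect_at_120s:
            log2[is_late, j] += effect
        elif cond == "carrier":
            log2[is_late, j] += effect  # carrier saturates late sites too
    log2 += rng.normal(0.0, noise_sd, size=log2.shape)
    intensities = np.power(2.0, log2)
    if missing_rate > 0:
        miss = rng.random(intensities.shape) < missing_rate
        intensities[miss] = np.nan
    df = pd.DataFrame(intensities, columns=cols)
    width = len(str(n))
    df.insert(0, "peptide_id", [f"PEP{i + 1:0{width}d}" for i in range(n)])
    df.insert(1, "accession", [f"RP{i % 21 + 1:02d}" for i in range(n)])
    df.insert(2, "site", rng.integers(1, 200, size=n))
    df.insert(3, "is_biotinylated", rng.random(n) >= nonbiotin_rate)
    df.insert(4, "is_ribosomal", rng.random(n) >= nonribosomal_rate)
    df["is_late_truth"] = is_late
    return df


@dataclass
class SimGo:
    annotations: dict[str, set[str]]
    bias: dict[str, float]
    biotinome: set[str]
    planted_term: str | None


def generate_go(
    accessions: Sequence[str],
    n_terms: int = 50,
    category_size: int = 15,
    planted_odds: float = 1.0,
    bias_strength: float = 1.0,
    bias_sigma: float = 1.0,
    bias_coupling: float = 1.0,
    base_membership: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
) -> SimGo:
    """Simulate GO annotations, a bias factor and biotinome membership.

    Per protein, the bias factor is log-normal; the probability of biotinome
    membership is logistic in log-bias with slope ``bias_strength``. Category
    members are drawn with weights ``bias**bias_coupling``, so categories are
    themselves abundance-skewed — the confound the Wallenius correction
    exists to remove. If ``planted_odds > 1`` the first category multiplies
    its members' membership odds, creating one genuinely enriched term.
    """
    accs = list(accessions)
    if category_size > len(accs):
        raise ValueError("category size exceeds the proteome")
    rng = np.random.default_rng(seed)
    log_bias = rng.normal(0.0, bias_sigma, size=len(accs))
    bias = np.exp(log_bias)
    weights = np.power(bias, bias_coupling)
    weights = weights / weights.sum()
    width = len(str(n_terms))
    annotations: dict[str, set[str]] = {a: set() for a in accs}
    planted_term = f"GO:SIM{1:0{width}d}" if planted_odds != 1.0 else None
    planted_members: set[str] = set()
    for t in range(n_terms):
        term = f"GO:SIM{t + 1:0{width}d}"
        members = rng.choice(len(accs), size=category_size, replace=False, p=weights)
        for i in members:
            annotations[accs[i]].add(term)
        if t == 0 and planted_term is not None:
            planted_members = {accs[i] for i in members}
    logit0 = np.log(base_membership / (1.0 - base_membership))
    eta = logit0 + bias_strength * log_bias
    if planted_term is not None:
        boost = np.array([a in planted_members for a in accs])
        eta = eta + np.log(planted_odds) * boost
    p_member = 1.0 / (1.0 + np.exp(-eta))
    member = rng.random(len(accs)) < p_member
    return SimGo(
        annotations=annotations,
        bias={a: float(b) for a, b in zip(accs, bias)},
        biotinome={a for a, m in zip(accs, member) if m},
        planted_term=planted_term,
    )


@dataclass
class SimConfig:
    """End-to-end simulation settings; one seed drives every component."""

    seed: int = 0
    n_proteins: int = 200
    mean_length: float = 450.0
    disorder_fraction: float = 0.3
    mean_block_length: float = 30.0
    predictors: tuple = (("VSL2b", 0.0), ("IUPred-L", 0.05))
    n_sites: int = 1000
    rho: float = 3.0
    ptm_rho: float = 2.0
    n_ptm_sites: int = 500
    tmt: dict = field(default_factory=dict)
    go: dict = field(default_factory=dict)


def child_seeds(seed: int, n: int = 5) -> list[np.random.SeedSequence]:
    """Fixed seed derivation: SeedSequence(seed).spawn in component order
    (proteome, biotin sites, PTM sites, TMT, GO)."""
    return np.random.SeedSequence(seed).spawn(n)


def simulate_all(config: SimConfig):
    """Generate every pipeline input from one config; see child_seeds order."""
    from .io import StudyRegistry, load_study_registry

    s_prot, s_sites, s_ptm, s_tmt, s_go = child_seeds(config.seed)
    sim = generate_proteome(
        n_proteins=config.n_proteins,
        mean_length=config.mean_length,
        disorder_fraction=config.disorder_fraction,
        mean_block_length=config.mean_block_length,
        predictors=tuple(config.predictors),
        seed=s_prot,
    )
    registry: StudyRegistry = load_study_registry()
    rng_sites = np.random.default_rng(s_sites)
    sites: list[SiteRecord] = []
    idx_by_target = {
        t: target_residue_index(sim.proteome, sim.truth_idrsets, [t])
        for t in ("K", "Y")
    }
    for entry in registry:
        sites.extend(
            plant_sites(
                sim.proteome,
                sim.truth_idrsets,
                target_residue=entry.target_residue,
                n_sites=config.n_sites,
                rho=config.rho,
                seed=rng_sites,
                study_id=entry.study_id,
                index=idx_by_target[entry.target_residue],
            )
        )
    rng_ptm = np.random.default_rng(s_ptm)
    ptm_sites: list[SiteRecord] = []
    idx_sty = target_residue_index(sim.proteome, sim.truth_idrsets, ["S", "T", "Y"])
    ptm_sites.extend(
        plant_sites(
            sim.proteome,
            sim.truth_idrsets,
            n_sites=config.n_ptm_sites,
            rho=config.ptm_rho,
            seed=rng_ptm,
            study_id="PTMDB",
            modification="phospho",
            index=idx_sty,
        )
    )
    ptm_sites.extend(
        plant_sites(
            sim.proteome,
            sim.truth_idrsets,
            n_sites=config.n_ptm_sites,
            rho=config.ptm_rho,
            seed=rng_ptm,
            study_id="PTMDB",
            modification="ubiquitination",
            index=idx_by_target["K"],
        )
    )
    tmt = generate_tmt(seed=s_tmt, **config.tmt)
    go = generate_go(list(sim.proteome), seed=s_go, **config.go)
    return sim, sites, ptm_sites, tmt, go
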
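"""Observed-vs-expected biotinylation within IDRs.

The core statistic: for one study, every detected biotin site is a Bernoulli
trial whose "success" is landing inside a predicted IDR. The null success
rate is composition-aware — the fraction of the chemistry's target residues
(K for BirA/NHS-biotin, Y for APEX2) that sit inside IDRs, pooled over the
study's biotinome (proteins carrying at least one detected site). An exact
binomial test compares the observed in-IDR count with that null.

Two-sided p-values use the minimum-likelihood definition: the sum of the
probabilities of all outcomes no more likely than the observed one. This is
stated explicitly because exact two-sided binomial definitions differ across
tools; it matches R's binom.test and scipy's binomtest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .idr import IdrSet, disorder_fraction
from .io import ProteinRecord, SiteRecord, StudyRegistry


@dataclass(frozen=True)
class ResidueCounts:
    """Target-residue tallies for one protein (or a pooled scope)."""

    scope: str
    target_residues: frozenset
    n_in_idr: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_in_idr <= self.n_total):
            raise ValueError("require 0 <= n_in_idr <= n_total")


@dataclass(frozen=True)
class EnrichmentResult:
    """One binomial enrichment test: k successes of n trials against p0."""

    scope: str
    k: int
    n: int
    p0: float
    p_value: float
    fold: float
    alternative: str
    testable: bool = True

    @property
    def observed_rate(self) -> float:
        return self.k / self.n if self.n else float("nan")

    def stars(self) -> str:
        """Cosmetic significance annotation (*** for p < 0.0005)."""
        if not self.testable:
            return ""
        if self.p_value < 1e-12:
            return "****"
        if self.p_value < 0.0005:
            return "***"
        return ""


def count_target_residues(
    protein: ProteinRecord, idr: IdrSet, residues: Iterable[str]
) -> ResidueCounts:
    """Count target residues in the whole sequence and inside IDRs."""
    residues = frozenset(residues)
    if not residues:
        raise ValueError("residue set must be non-empty")
    if idr.accession != protein.accession:
        raise ValueError("IdrSet does not belong to this protein")
    if idr.length != protein.length:
        raise ValueError("IdrSet length does not match protein length")
    seq = np.frombuffer(protein.sequence.encode("ascii"), dtype="S1")
    is_target = np.isin(seq, [r.encode("ascii") for r in residues])
    n_total = int(is_target.sum())
    n_in = int((is_target & idr.to_mask()).sum())
    return ResidueCounts(
        scope=protein.accession,
        target_residues=residues,
        n_in_idr=n_in,
        n_total=n_total,
    )


def pooled_null_rate(counts: Sequence[ResidueCounts]) -> float:
    """Null success rate p0 = Σ n_in_idr / Σ n_total over the pooling scope."""
    if not counts:
        raise ValueError("no residue counts to pool")
    targets = counts[0].target_residues
    if any(c.target_residues != targets for c in counts):
        raise ValueError("all counts must share the same target residue set")
    total = sum(c.n_total for c in counts)
    if total == 0:
        raise ValueError("no target residues in scope")
    return sum(c.n_in_idr for c in counts) / total


def binomial_test(
    k: int, n: int, p0: float, alternative: str = "two-sided"
) -> float:
    """Exact binomial p-value by pmf summation in log space.

    ``greater``: P(X >= k). ``two-sided``: sum of P(X = j) over all j with
    pmf(j) <= pmf(k), the minimum-likelihood convention. No normal
    approximation is used at any n.
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if n < 1:
        raise ValueError("require n >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly between 0 and 1 (degenerate null)")
    ks = np.arange(n + 1)
    logpmf = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * np.log(p0)
        + (n - ks) * np.log1p(-p0)
    )
    if alternative == "greater":
        p = np.exp(logsumexp(logpmf[k:]))
    elif alternative == "two-sided":
        # relative tolerance guards against ties broken by rounding
        keep = logpmf <= logpmf[k] + 1e-7
        p = np.exp(logsumexp(logpmf[keep]))
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    return float(min(1.0, p))


def unique_sites(sites: Iterable[SiteRecord]) -> list[SiteRecord]:
    """Deduplicate on (study_id, accession, position, modification)."""
    seen: set[tuple] = set()
    out = []
    for s in sites:
        key = (s.study_id, s.accession, s.position, s.modification)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def sites_enrichment(
    sites: Sequence[SiteRecord],
    proteome: Mapping[str, ProteinRecord],
    idrsets: Mapping[str, IdrSet],
    eligible_residues: Iterable[str],
    scope: str,
    pooling: str = "biotinome",
    alternative: str = "two-sided",
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Generic in-IDR enrichment for any site collection and residue background.

    Trials are the unique sites; successes are sites inside an IDR; p0 pools
    eligible-residue counts over either the ``biotinome`` (proteins with at
    least one site in this collection — the default, so undetected proteins
    do not dilute the null) or the whole ``proteome``.
    """
    eligible = frozenset(eligible_residues)
    sites = unique_sites(sites)
    if not sites:
        raise ValueError(f"no sites in scope {scope!r}")
    detected = sorted({s.accession for s in sites})
    for acc in detected:
        if acc not in idrsets:
            raise ValueError(f"no IDR set for detected protein {acc}")
    if pooling == "biotinome":
        pool = detected
    elif pooling == "proteome":
        pool = [acc for acc in proteome if acc in idrsets]
    else:
        raise ValueError("pooling must be 'biotinome' or 'proteome'")
    counts = [
        count_target_residues(proteome[acc], idrsets[acc], eligible) for acc in pool
    ]
    p0 = pooled_null_rate(counts)
    masks = {acc: idrsets[acc].to_mask() for acc in detected}
    k = sum(1 for s in sites if masks[s.accession][s.position - 1])
    n = len(sites)
    testable = 0.0 < p0 < 1.0
    fold = (k / n) / p0 if (testable and n) else float("nan")
    p_value = binomial_test(k, n, p0, alternative) if testable else float("nan")
    result = EnrichmentResult(
        scope=scope,
        k=k,
        n=n,
        p0=p0,
        p_value=p_value,
        fold=fold,
        alternative=alternative,
        testable=testable,
    )
    bar_table = pd.DataFrame(
        {
            "scope": [scope, scope],
            "quantity": ["expected", "observed"],
            "in_idr_rate": [p0, k / n],
        }
    )
    return result, bar_table


def study_enrichment(
    sites: Sequence[SiteRecord],
    proteome: Mapping[str, ProteinRecord],
    idrsets: Mapping[str, IdrSet],
    registry: StudyRegistry,
    study_id: str | None = None,
    pooling: str = "biotinome",
    alternative: str = "two-sided",
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Expected vs observed in-IDR biotinylation for one study.

    The null counts the study chemistry's target residue (K or Y per the
    registry) over the study biotinome. Returns the test result plus a tidy
    expected/observed rate table for bar plotting.
    """
    if study_id is None:
        ids = {s.study_id for s in sites}
        if len(ids) != 1:
            raise ValueError(f"sites span studies {sorted(ids)}; pass study_id")
        study_id = ids.pop()
    study_sites = [s for s in sites if s.study_id == study_id]
    if not study_sites:
        raise ValueError(f"empty biotinome for study {study_id!r}")
    target = registry.target_residue(study_id)
    return sites_enrichment(
        study_sites,
        proteome,
        idrsets,
        {target},
        scope=study_id,
        pooling=pooling,
        alternative=alternative,
    )


# Default predicates for the ribosomal-protein subset analyses; matched
# against FASTA descriptions, case-insensitively.
RIBOSOMAL_PATTERN = r"ribosomal protein"
MITO_RIBOSOMAL_PATTERN = r"mitochondrial ribosomal protein"


def subset_enrichment(
    sites: Sequence[SiteRecord],
    proteome: Mapping[str, ProteinRecord],
    idrsets: Mapping[str, IdrSet],
    registry: StudyRegistry,
    name_predicate: str | Callable[[ProteinRecord], bool],
    study_id: str | None = None,
    scope_label: str | None = None,
    pooling: str = "biotinome",
    alternative: str = "two-sided",
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Enrichment restricted to proteins selected by name.

    ``name_predicate`` is a regular expression matched (case-insensitively)
    against each protein's description and accession, or a callable on the
    ProteinRecord. The computation is study_enrichment on the selected
    proteins' sites only.
    """
    if callable(name_predicate):
        pred = name_predicate
        label = scope_label or "subset"
    else:
        rx = re.compile(name_predicate, re.IGNORECASE)
        pred = lambda p: bool(rx.search(p.description) or rx.search(p.accession))
        label = scope_label or name_predicate
    selected = {acc for acc, prot in proteome.items() if pred(prot)}
    if not selected:
        raise ValueError("name predicate selects zero proteins")
    sub = [s for s in sites if s.accession in selected]
    if study_id is not None:
        sub = [s for s in sub if s.study_id == study_id]
        label = f"{study_id}:{label}"
    if not sub:
        raise ValueError(f"no sites on proteins selected by {label!r}")
    target_residues = {registry.target_residue(s.study_id) for s in sub}
    if len(target_residues) != 1:
        raise ValueError(
            "subset spans studies with different target residues; pass study_id"
        )
    return sites_enrichment(
        sub,
        proteome,
        idrsets,
        target_residues,
        scope=label,
        pooling=pooling,
        alternative=alternative,
    )


def bin_biotin_count(count: int) -> str:
    """Collapse per-protein biotin counts >= 5 into a single '5+' bin."""
    if count < 0:
        raise ValueError("count must be >= 0")
    return str(count) if count < 5 else "5+"


def summarize_biotin_counts(
    sites: Sequence[SiteRecord],
    proteome: Mapping[str, ProteinRecord],
    idrsets: Mapping[str, IdrSet],
    include_zero: bool = False,
) -> pd.DataFrame:
    """Per-protein unique-site counts, disorder fractions and count bins.

    By default only detected proteins (count >= 1) appear; with
    ``include_zero=True`` every protein with an IDR set is listed.
    """
    sites = unique_sites(sites)
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.accession] = counts.get(s.accession, 0) + 1
    accessions = (
        [a for a in proteome if a in idrsets] if include_zero else sorted(counts)
    )
    rows = []
    for acc in accessions:
        c = counts.get(acc, 0)
        frac = disorder_fraction(idrsets[acc]).fraction
        rows.append((acc, c, frac, bin_biotin_count(c)))
    return pd.DataFrame(
        rows, columns=["accession", "biotin_count", "disorder_fraction", "bin"]
    )


@dataclass(frozen=True)
class AssociationResult:
    r: float
    p_value: float
    n: int
    bin_table: pd.DataFrame


def biotin_disorder_association(summaries: pd.DataFrame) -> AssociationResult:
    """Pearson correlation of per-protein biotin count with disorder fraction.

    Uses the unbinned counts for the correlation; also emits the violin-plot
    style table of disorder-fraction distributions grouped by the binned count
    (0..4, 5+) with per-bin medians.
    """
    x = summaries["biotin_count"].to_numpy(dtype=float)
    y = summaries["disorder_fraction"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 proteins")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in counts or fractions")
    r, p = stats.pearsonr(x, y)
    order = [str(i) for i in range(5)] + ["5+"]
    grp = summaries.groupby("bin")["disorder_fraction"]
    bin_table = pd.DataFrame(
        {
            "bin": [b for b in order if b in grp.groups],
            "n_proteins": [len(grp.get_group(b)) for b in order if b in grp.groups],
            "median_fraction": [
                float(grp.get_group(b).median()) for b in order if b in grp.groups
            ],
        }
    )
    return AssociationResult(r=float(r), p_value=float(p), n=len(x), bin_table=bin_table)


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tidy TSV-ready table of enrichment results with significance stars."""
    rows = [
        (r.scope, r.k, r.n, r.p0, r.fold, r.p_value, r.alternative, r.stars())
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["scope", "k", "n", "p0", "fold", "p_value", "alternative", "stars"],
    )
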
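"""Endogenous-PTM analyses reusing the enrichment machinery.

Each PTM type has a fixed residue background: phosphorylation can occur on
S, T or Y; ubiquitination, acetylation and sumoylation on K. The in-IDR
enrichment null counts those eligible residues instead of a study's biotin
target residue; the test construction is otherwise identical to the biotin
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult, sites_enrichment
from .idr import IdrSet
from .io import ProteinRecord, SiteRecord

logger = logging.getLogger(__name__)

PTM_BACKGROUNDS: dict[str, frozenset] = {
    "phospho": frozenset("STY"),
    "ubiquitination": frozenset("K"),
    "acetylation": frozenset("K"),
    "sumoylation": frozenset("K"),
}


@dataclass(frozen=True)
class PtmBackground:
    ptm_type: str
    eligible_residues: frozenset


def ptm_background(ptm_type: str) -> PtmBackground:
    """The fixed residue background of a PTM type (e.g. phospho -> {S,T,Y})."""
    if ptm_type not in PTM_BACKGROUNDS:
        raise ValueError(
            f"unsupported PTM type {ptm_type!r}; supported: "
            f"{sorted(PTM_BACKGROUNDS)}"
        )
    return PtmBackground(ptm_type=ptm_type, eligible_residues=PTM_BACKGROUNDS[ptm_type])


def ptm_idr_enrichment(
    sites: Sequence[SiteRecord],
    proteome: Mapping[str, ProteinRecord],
    idrsets: Mapping[str, IdrSet],
    ptm_type: str | None = None,
    strict: bool = False,
    pooling: str = "biotinome",
    alternative: str = "two-sided",
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """In-IDR enrichment of one PTM type with its residue-specific null.

    Sites on residues outside the eligible set are dropped with a warning
    (``strict=True`` aborts instead). The null rate pools eligible residues
    over the detected proteins, exactly as the biotin analysis pools the
    study's target residue.
    """
    if ptm_type is None:
        types = {s.modification for s in sites}
        if len(types) != 1:
            raise ValueError(f"sites span PTM types {sorted(types)}; pass ptm_type")
        ptm_type = types.pop()
    bg = ptm_background(ptm_type)
    kept = []
    for s in sites:
        if s.modification != ptm_type:
            raise ValueError(
                f"site with modification {s.modification!r} in a {ptm_type} analysis"
            )
        if s.residue not in bg.eligible_residues:
            msg = (
                f"{ptm_type} site on ineligible residue {s.residue} at "
                f"{s.accession}:{s.position}"
            )
            if strict:
                raise ValueError(msg)
            logger.warning("dropping %s", msg)
            continue
        kept.append(s)
    if not kept:
        raise ValueError(f"no eligible {ptm_type} sites")
    return sites_enrichment(
        kept,
        proteome,
        idrsets,
        bg.eligible_residues,
        scope=ptm_type,
        pooling=pooling,
        alternative=alternative,
    )


@dataclass(frozen=True)
class MeanComparison:
    mean_a: float
    mean_b: float
    mean_diff: float
    statistic: float
    df: float
    p_value: float


def biotinome_vs_proteome_ptm(
    biotinome_counts: Sequence[float],
    proteome_counts: Sequence[float],
    welch: bool = True,
) -> MeanComparison:
    """Two-sample t-test of per-protein PTM burden: biotinome vs reference.

    Both samples are per-protein PTM counts supplied explicitly (this package
    does not define what the reference proteome is). Welch's unequal-variance
    form is the default.
    """
    a = np.asarray(biotinome_counts, dtype=float)
    b = np.asarray(proteome_counts, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return MeanComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_diff=float(a.mean() - b.mean()),
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )
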
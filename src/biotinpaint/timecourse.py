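"""TMT biotin-painting time-course analysis.

A 10-plex TMT experiment quantifies biotinylated ribosomal peptides after
10 s, 120 s and 300 s of NHS-biotin exposure (triplicates each) plus a 1 h
carrier channel. Peptides with any missing required channel, non-biotinylated
peptides and non-ribosomal peptides are removed; the carrier is excluded from
statistics; intensities are deliberately NOT median-normalised, because the
fraction of biotinylated peptide in each channel genuinely differs between
time points and equalising medians would erase the signal of interest.

Each peptide is tested for increased labelling at 120 s and at 300 s relative
to the 10 s reference with an empirical-Bayes moderated t-statistic: the
per-peptide residual variance s²_g (d_g degrees of freedom) is shrunk toward
a prior (d0, s0²) estimated from the ensemble of variances by moment matching
of log variances (digamma/trigamma inversion), giving

    s²_post = (d0·s0² + d_g·s²_g) / (d0 + d_g),
    t_mod   = Δmean / (s_post · sqrt(1/n1 + 1/n2)),   df = d0 + d_g.

Peptides with a Benjamini-Hochberg adjusted p < 0.05 AND a positive increase
in either contrast are "late" biotinylation events; all others are "early".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

META_COLUMNS = ["peptide_id", "accession", "site", "is_biotinylated", "is_ribosomal"]
CONDITIONS = ("10s", "120s", "300s")
CARRIER = "carrier"
D0_CAP = 1e6  # effectively full shrinkage when the trigamma equation has no root

_CHANNEL_RE = re.compile(r"^(\d+s|carrier)_(\d+)$")


def channel_columns(matrix: pd.DataFrame) -> dict[str, list[str]]:
    """Group channel columns (e.g. ``120s_2``) by condition label."""
    out: dict[str, list[str]] = {}
    for col in matrix.columns:
        m = _CHANNEL_RE.match(str(col))
        if m:
            out.setdefault(m.group(1), []).append(col)
    return {cond: sorted(cols) for cond, cols in out.items()}


@dataclass
class FilterReport:
    retained: int
    dropped_missing: int
    dropped_nonbiotin: int
    dropped_nonribosomal: int


def filter_peptides(
    matrix: pd.DataFrame, normalize: bool = False
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the time-course peptide filters.

    Removes rows with any missing required channel (complete-case, no
    imputation), non-biotinylated rows and non-ribosomal rows; drops carrier
    channels from the returned matrix. ``normalize=True`` equalises
    per-channel medians afterwards (off by default, deliberately).
    """
    chans = channel_columns(matrix)
    required = [c for cond in CONDITIONS for c in chans.get(cond, [])]
    if not required:
        raise ValueError("no 10s/120s/300s channel columns found")
    biotin = matrix["is_biotinylated"].astype(bool)
    ribo = matrix["is_ribosomal"].astype(bool)
    complete = matrix[required].notna().all(axis=1)
    n_missing = int((~complete).sum())
    n_nonbiotin = int((complete & ~biotin).sum())
    n_nonribo = int((complete & biotin & ~ribo).sum())
    keep = complete & biotin & ribo
    report = FilterReport(
        retained=int(keep.sum()),
        dropped_missing=n_missing,
        dropped_nonbiotin=n_nonbiotin,
        dropped_nonribosomal=n_nonribo,
    )
    if report.retained == 0:
        raise ValueError(
            "no peptides survive filtering "
            f"(missing={n_missing}, non-biotinylated={n_nonbiotin}, "
            f"non-ribosomal={n_nonribo})"
        )
    meta = [c for c in META_COLUMNS if c in matrix.columns]
    out = matrix.loc[keep, meta + required].copy()
    if normalize:
        grand = np.nanmedian(out[required].to_numpy())
        for c in required:
            out[c] = out[c] - out[c].median() + grand
    return out.reset_index(drop=True), report


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(60):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the variance prior (d0, s0²) from per-peptide variances.

    Under the scaled-F model, z = log s²_g has variance trigamma(d_g/2) +
    trigamma(d0/2); solving the trigamma equation gives d0, and the mean of z
    gives s0². If the observed variance of z is no larger than the sampling
    term, the equation has no positive root: d0 is capped (full shrinkage)
    and the event logged.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.clip(s2, 1e-12, None)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    if n < 2:
        raise ValueError("need >= 2 variances to estimate the prior")
    var_e = float(np.sum((e - e.mean()) ** 2) / (n - 1))
    excess = var_e - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        logger.info("no positive trigamma root; capping d0 at %g", D0_CAP)
        d0 = D0_CAP
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_test(
    matrix: pd.DataFrame,
    contrast: tuple[str, str] = ("120s", "10s"),
    log2_transform: bool = True,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample test of one contrast.

    ``contrast = (numerator, reference)`` names two conditions; the statistic
    is the mean log2 difference divided by the moderated standard error.
    ``d0_override=0`` recovers the ordinary pooled two-sample t-test; a very
    large override forces every posterior variance to s0². Returns one row
    per peptide with logFC, t_mod, df, p and BH-adjusted p.
    """
    chans = channel_columns(matrix)
    num_cols = chans.get(contrast[0], [])
    ref_cols = chans.get(contrast[1], [])
    if len(num_cols) < 2 or len(ref_cols) < 2:
        raise ValueError(f"contrast {contrast} needs >= 2 replicates per condition")
    if len(matrix) < 2:
        raise ValueError("need >= 2 peptides")
    num = matrix[num_cols].to_numpy(dtype=float)
    ref = matrix[ref_cols].to_numpy(dtype=float)
    if log2_transform:
        if np.any(num <= 0) or np.any(ref <= 0):
            raise ValueError("intensities must be > 0 for log2 transformation")
        num, ref = np.log2(num), np.log2(ref)
    n1, n2 = num.shape[1], ref.shape[1]
    diff = num.mean(axis=1) - ref.mean(axis=1)
    ss = ((num - num.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ref - ref.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    dg = float(n1 + n2 - 2)
    s2 = ss / dg
    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_2 = estimate_prior(s2, dg)
    else:
        d0, s0_2 = estimate_prior(s2, dg)
    if d0 > 0:
        s2_post = (d0 * s0_2 + dg * s2) / (d0 + dg)
    else:
        s2_post = s2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_mod = diff / se
    df_total = min(d0 + dg, D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "peptide_id": matrix["peptide_id"].to_numpy()
            if "peptide_id" in matrix
            else np.arange(len(matrix)),
            "logFC": diff,
            "t_mod": t_mod,
            "df": df_total,
            "p": p,
            "p_adj": p_adj,
        }
    )


def classify_kinetics(
    stats_by_contrast: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Label each peptide early or late from the per-contrast statistics.

    Late iff some contrast shows adjusted p strictly below ``alpha`` together
    with a positive log fold change (a significant *increase*); early
    otherwise. The triggering contrasts are reported.
    """
    if not stats_by_contrast:
        raise ValueError("no contrast statistics supplied")
    frames = []
    for name, df in stats_by_contrast.items():
        d = df[["peptide_id", "logFC", "p_adj"]].copy()
        d["contrast"] = name
        frames.append(d)
    longf = pd.concat(frames, ignore_index=True)
    rows = []
    for pid, grp in longf.groupby("peptide_id", sort=False):
        hits = grp[(grp["p_adj"] < alpha) & (grp["logFC"] > 0)]
        rows.append(
            (
                pid,
                "late" if len(hits) else "early",
                ";".join(sorted(hits["contrast"])) if len(hits) else "",
            )
        )
    return pd.DataFrame(rows, columns=["peptide_id", "label", "triggered_by"])


def run_timecourse(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    normalize: bool = False,
    log2_transform: bool = True,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, FilterReport]:
    """Filter, test both contrasts against the 10 s reference, classify."""
    filtered, report = filter_peptides(matrix, normalize=normalize)
    contrasts = {
        "120s_vs_10s": ("120s", "10s"),
        "300s_vs_10s": ("300s", "10s"),
    }
    results = {
        name: moderated_test(filtered, contrast=c, log2_transform=log2_transform)
        for name, c in contrasts.items()
    }
    calls = classify_kinetics(results, alpha=alpha)
    return results, calls, report
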
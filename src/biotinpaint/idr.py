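"""IDR interval calling: binarize disorder tracks, combine predictors, score.

An IDR set is a normalized list of 1-based inclusive residue intervals on one
protein: sorted, non-overlapping, with adjacent intervals merged. No minimum
interval length is imposed anywhere — a single residue can be an IDR. This
favours sensitivity of disorder calling over specificity.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import DisorderTrack


@dataclass(frozen=True)
class IdrSet:
    """Normalized disorder intervals for one protein.

    ``intervals`` are (start, end) pairs, 1-based, inclusive on both ends,
    sorted, non-overlapping and non-adjacent. ``length`` is the protein
    length, carried so masks and fractions need no external lookup.
    """

    accession: str
    intervals: tuple[tuple[int, int], ...]
    length: int
    caller_label: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("protein length must be >= 1")
        prev_end = -1  # so an interval starting at residue 1 is never "adjacent"
        for start, end in self.intervals:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"interval ({start},{end}) outside 1..{self.length} "
                    f"on {self.accession}"
                )
            if start <= prev_end + 1:
                raise ValueError(
                    f"intervals not normalized at ({start},{end}) on {self.accession}"
                )
            prev_end = end

    @property
    def n_disordered(self) -> int:
        return sum(end - start + 1 for start, end in self.intervals)

    def to_mask(self) -> np.ndarray:
        """Binary per-residue mask; index i holds residue i+1."""
        mask = np.zeros(self.length, dtype=bool)
        for start, end in self.intervals:
            mask[start - 1 : end] = True
        return mask


@dataclass(frozen=True)
class DisorderFraction:
    accession: str
    fraction: float
    caller_label: str = ""


def _runs_to_intervals(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Maximal runs of True in a binary mask, as 1-based inclusive intervals."""
    padded = np.concatenate(([False], mask.astype(bool), [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2] + 1, edges[1::2]
    return tuple(zip(starts.tolist(), ends.tolist()))


def normalize_intervals(
    intervals: Iterable[tuple[int, int]], length: int
) -> tuple[tuple[int, int], ...]:
    """Sort, merge overlapping and adjacent intervals, clip nothing."""
    ivals = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for start, end in ivals:
        if not (1 <= start <= end <= length):
            raise ValueError(f"interval ({start},{end}) outside 1..{length}")
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def idrset_from_intervals(
    accession: str,
    intervals: Iterable[tuple[int, int]],
    length: int,
    caller_label: str = "",
) -> IdrSet:
    return IdrSet(
        accession=accession,
        intervals=normalize_intervals(intervals, length),
        length=length,
        caller_label=caller_label,
    )


def binarize_track(track: DisorderTrack, threshold: float = 0.5) -> IdrSet:
    """Call IDR intervals from a dense disorder track.

    Residue i is disordered iff ``value_i >= threshold``; maximal runs of
    disordered residues become intervals. Binary tracks pass through unchanged
    at the default threshold. No minimum-length filter is applied, so
    single-residue IDRs are kept.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    mask = track.values >= threshold
    return IdrSet(
        accession=track.accession,
        intervals=_runs_to_intervals(mask),
        length=track.length,
        caller_label=track.predictor,
    )


def combine_union(a: IdrSet, b: IdrSet) -> IdrSet:
    """Residue-level union of two predictors' IDR sets for one protein.

    This is the "called by one or both predictors" combination; labels join
    with an underscore (e.g. ``VSL2b_IUPred-L``).
    """
    if a.accession != b.accession:
        raise ValueError(f"accession mismatch: {a.accession} vs {b.accession}")
    if a.length != b.length:
        raise ValueError("protein length mismatch")
    label = f"{a.caller_label}_{b.caller_label}" if a.caller_label or b.caller_label else ""
    return idrset_from_intervals(
        a.accession, list(a.intervals) + list(b.intervals), a.length, label
    )


def combine_consensus(
    idrsets: Sequence[IdrSet], quorum: float = 0.75, caller_label: str | None = None
) -> IdrSet:
    """Quorum consensus across predictors for one protein.

    Residue i is consensus-disordered iff the fraction of predictors calling
    it disordered is ``>= quorum``. The denominator is the number of
    predictors supplied for this protein. The default quorum of 0.75 over nine
    predictors requires at least 7 callers (inclusive comparison: 7/9 ≈ 0.778
    passes, 6/9 ≈ 0.667 does not).
    """
    if len(idrsets) == 0:
        raise ValueError("consensus requires at least one predictor IdrSet")
    if not (0.0 < quorum <= 1.0):
        raise ValueError("quorum must be in (0, 1]")
    acc, length = idrsets[0].accession, idrsets[0].length
    for s in idrsets[1:]:
        if s.accession != acc or s.length != length:
            raise ValueError("all IdrSets must describe the same protein")
    votes = np.zeros(length, dtype=int)
    for s in idrsets:
        votes += s.to_mask()
    # float division is exact enough here: n_called/n_predictors vs quorum
    mask = votes / len(idrsets) >= quorum - 1e-12
    if caller_label is None:
        caller_label = f"consensus{int(round(quorum * 100))}"
    return IdrSet(
        accession=acc,
        intervals=_runs_to_intervals(mask),
        length=length,
        caller_label=caller_label,
    )


def disorder_fraction(idr: IdrSet, length: int | None = None) -> DisorderFraction:
    """Fraction of the protein covered by IDR intervals."""
    if length is None:
        length = idr.length
    if length != idr.length:
        raise ValueError(f"length {length} != IdrSet length {idr.length}")
    return DisorderFraction(
        accession=idr.accession,
        fraction=idr.n_disordered / length,
        caller_label=idr.caller_label,
    )


def in_idr(idr: IdrSet, position: int) -> bool:
    """True iff the 1-based position falls inside some interval (inclusive)."""
    if not (1 <= position <= idr.length):
        raise ValueError(f"position {position} outside 1..{idr.length}")
    starts = [s for s, _ in idr.intervals]
    i = bisect_right(starts, position) - 1
    return i >= 0 and idr.intervals[i][0] <= position <= idr.intervals[i][1]


def export_idrsets(idrsets: Iterable[IdrSet]) -> pd.DataFrame:
    rows = [
        (s.accession, s.caller_label, start, end)
        for s in idrsets
        for start, end in s.intervals
    ]
    return pd.DataFrame(rows, columns=["accession", "caller", "start", "end"])


def export_fractions(idrsets: Iterable[IdrSet]) -> pd.DataFrame:
    rows = [
        (s.accession, s.caller_label, disorder_fraction(s).fraction) for s in idrsets
    ]
    return pd.DataFrame(rows, columns=["accession", "caller", "fraction"])


def call_idrs(
    tracks: dict[str, list[DisorderTrack]],
    caller: str = "union",
    threshold: float = 0.5,
    quorum: float = 0.75,
    union_pair: tuple[str, str] = ("VSL2b", "IUPred-L"),
) -> dict[str, IdrSet]:
    """Per-protein IDR sets from prediction tracks under one caller policy.

    ``caller`` is a single predictor name, ``"union"`` (the two predictors in
    ``union_pair``, falling back to the residue-level union of all available
    tracks when the pair is absent) or ``"consensus"`` (quorum vote over all
    tracks for each protein).
    """
    out: dict[str, IdrSet] = {}
    for acc, tlist in tracks.items():
        sets = [binarize_track(t, threshold) for t in tlist]
        by_name = {s.caller_label: s for s in sets}
        if caller == "consensus":
            out[acc] = combine_consensus(sets, quorum=quorum)
        elif caller == "union":
            if union_pair[0] in by_name and union_pair[1] in by_name:
                chosen = [by_name[union_pair[0]], by_name[union_pair[1]]]
            else:
                chosen = sets
            combined = chosen[0]
            for s in chosen[1:]:
                combined = combine_union(combined, s)
            out[acc] = combined
        else:
            if caller not in by_name:
                raise ValueError(
                    f"no track from predictor {caller!r} for {acc}; "
                    f"available: {sorted(by_name)}"
                )
            out[acc] = by_name[caller]
    return out
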
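"""Readers and writers for the file formats the pipeline touches.

Coordinate convention, used everywhere in this package: residue positions are
1-based and intervals are inclusive on both ends, matching UniProt/PDB usage
and the site tables of proximity-labelling studies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

MODIFICATIONS = frozenset(
    {"biotin", "phospho", "ubiquitination", "acetylation", "sumoylation"}
)

SITE_TABLE_COLUMNS = ["study_id", "accession", "position", "residue", "modification"]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: an accession, its sequence and an optional description."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """One modification event (a biotin or a named PTM) at a residue."""

    study_id: str
    accession: str
    position: int  # 1-based
    residue: str
    modification: str


@dataclass(frozen=True)
class StudyRegistryEntry:
    """One proximity-labelling study and the chemistry of its target residue."""

    study_id: str
    target_residue: str  # "K" or "Y"
    chemistry: str
    activated_biotin_conc_uM: float  # upper bound where the source says "<x"

    def __post_init__(self) -> None:
        if self.target_residue not in ("K", "Y"):
            raise ValueError(
                f"target_residue must be K or Y, got {self.target_residue!r}"
            )


@dataclass
class DisorderTrack:
    """Dense per-residue disorder values (scores in [0,1] or binary calls)."""

    accession: str
    predictor: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("track values must be a non-empty 1-D array")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("track values must lie in [0, 1]")

    @property
    def length(self) -> int:
        return int(self.values.size)


@dataclass
class ValidationReport:
    """Bookkeeping for site-table ingestion: what was kept, what was dropped."""

    retained: int = 0
    dropped: dict = field(default_factory=dict)

    def count(self, reason: str, k: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + k

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())


# Table of the four re-analysed in vivo biotinylation studies: which residue
# each chemistry targets and the activated-biotin concentration (µM; an upper
# bound where the source reports "<x").
DEFAULT_STUDIES = (
    StudyRegistryEntry("BioSITe", "Y", "APEX2", 50.0),
    StudyRegistryEntry("Ab-APEX", "Y", "APEX2", 500.0),
    StudyRegistryEntry("DiDBiT", "K", "NHS-Biotin", 1000.0),
    StudyRegistryEntry("SpotBioID", "K", "BirA", 50.0),
)


class StudyRegistry:
    """Validated mapping of study_id -> StudyRegistryEntry."""

    def __init__(self, entries: Iterable[StudyRegistryEntry]):
        self._entries: dict[str, StudyRegistryEntry] = {}
        for e in entries:
            if e.study_id in self._entries:
                raise ValueError(f"duplicate study_id {e.study_id}")
            self._entries[e.study_id] = e
        if not self._entries:
            raise ValueError("registry must contain at least one study")

    def __getitem__(self, study_id: str) -> StudyRegistryEntry:
        return self._entries[study_id]

    def __contains__(self, study_id: str) -> bool:
        return study_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def target_residue(self, study_id: str) -> str:
        return self._entries[study_id].target_residue


def load_study_registry(config: Mapping | None = None) -> StudyRegistry:
    """Build a study registry from a config mapping, or the built-in default.

    The config maps ``study_id -> {target_residue, chemistry,
    activated_biotin_conc_uM}``. With ``config=None`` the registry of the four
    published studies (BioSITe, Ab-APEX, DiDBiT, SpotBioID) is returned.
    """
    if config is None:
        return StudyRegistry(DEFAULT_STUDIES)
    entries = []
    for study_id, spec in config.items():
        entries.append(
            StudyRegistryEntry(
                study_id=str(study_id),
                target_residue=str(spec["target_residue"]),
                chemistry=str(spec.get("chemistry", "")),
                activated_biotin_conc_uM=float(
                    spec.get("activated_biotin_conc_uM", float("nan"))
                ),
            )
        )
    return StudyRegistry(entries)


def read_fasta(path, uniprot_ids: bool = False) -> dict[str, ProteinRecord]:
    """Read a FASTA file into an accession-keyed dict of ProteinRecord.

    The accession is the first whitespace-delimited header token; with
    ``uniprot_ids=True`` the second pipe-delimited field of that token is used
    instead (UniProt ``sp|ACC|NAME`` convention). Sequences are upper-cased and
    must be over the 20-letter amino-acid alphabet. Duplicate accessions and
    empty files are errors.
    """
    proteome: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        token = rec.id
        if uniprot_ids and "|" in token:
            parts = token.split("|")
            if len(parts) < 2 or not parts[1]:
                raise ValueError(f"cannot extract UniProt accession from {token!r}")
            accession = parts[1]
        else:
            accession = token
        seq = str(rec.seq).upper()
        for i, aa in enumerate(seq, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"non-amino-acid character {aa!r} at position {i} of {accession}"
                )
        if accession in proteome:
            raise ValueError(f"duplicate accession {accession}")
        proteome[accession] = ProteinRecord(
            accession=accession, sequence=seq, description=rec.description
        )
    if not proteome:
        raise ValueError(f"no FASTA records found in {path}")
    return proteome


def write_fasta(proteome: Mapping[str, ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in proteome.values():
            header = rec.description if rec.description else rec.accession
            fh.write(f">{header}\n{rec.sequence}\n")


def read_site_table(
    path,
    registry: StudyRegistry | None,
    proteome: Mapping[str, ProteinRecord],
    strict: bool = False,
) -> tuple[list[SiteRecord], ValidationReport]:
    """Read and validate a TSV site table against a proteome and registry.

    ``registry=None`` skips the study-membership check (PTM tables carry a
    database label, not a proximity-labelling study id).

    Retained records satisfy all SiteRecord invariants. Records whose residue
    letter does not match the sequence, whose position is out of range, or
    whose accession/study is unknown are dropped with a logged warning (or
    abort the run when ``strict=True``). Duplicates on
    (study_id, accession, position, modification) count once; the validation
    report tallies every drop reason.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing required column(s): {missing}")

    report = ValidationReport()
    sites: list[SiteRecord] = []
    seen: set[tuple] = set()

    def reject(line_no: int, reason: str, detail: str) -> None:
        msg = f"line {line_no}: {detail}"
        if strict:
            raise ValueError(f"site table validation failed ({reason}): {msg}")
        logger.warning("dropping site (%s): %s", reason, msg)
        report.count(reason)

    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            position = int(row.position)
        except (TypeError, ValueError):
            raise ValueError(f"non-integer position {row.position!r} at line {idx}")
        if position < 1:
            raise ValueError(f"position {position} < 1 at line {idx}")
        modification = str(row.modification)
        if modification not in MODIFICATIONS:
            reject(idx, "unknown_modification", f"{modification!r}")
            continue
        if registry is not None and str(row.study_id) not in registry:
            reject(idx, "unknown_study", f"{row.study_id!r} not in registry")
            continue
        prot = proteome.get(str(row.accession))
        if prot is None:
            reject(idx, "unknown_accession", f"{row.accession!r} not in proteome")
            continue
        if position > prot.length:
            reject(
                idx,
                "position_out_of_range",
                f"{row.accession} position {position} > length {prot.length}",
            )
            continue
        residue = str(row.residue).upper()
        if prot.sequence[position - 1] != residue:
            reject(
                idx,
                "residue_mismatch",
                f"{row.accession} position {position} is "
                f"{prot.sequence[position - 1]}, table says {residue}",
            )
            continue
        key = (str(row.study_id), str(row.accession), position, modification)
        if key in seen:
            report.count("duplicate")
            continue
        seen.add(key)
        sites.append(
            SiteRecord(
                study_id=str(row.study_id),
                accession=str(row.accession),
                position=position,
                residue=residue,
                modification=modification,
            )
        )
    report.retained = len(sites)
    return sites, report


def write_site_table(sites: Iterable[SiteRecord], path) -> None:
    """Write sites as canonical TSV (fixed column order, no float formatting)."""
    df = pd.DataFrame(
        [
            (s.study_id, s.accession, s.position, s.residue, s.modification)
            for s in sites
        ],
        columns=SITE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def _tracks_from_tsv(path, proteome) -> dict[str, list[DisorderTrack]]:
    df = pd.read_csv(path, sep="\t")
    required = ["accession", "predictor", "position", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"track TSV missing required column(s): {missing}")
    out: dict[str, list[DisorderTrack]] = {}
    for (acc, predictor), grp in df.groupby(["accession", "predictor"], sort=True):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy(dtype=int)
        length = int(positions.max())
        if proteome is not None:
            if acc not in proteome:
                raise ValueError(f"track accession {acc!r} not in proteome")
            plen = proteome[acc].length
            if length > plen:
                raise ValueError(
                    f"{acc}/{predictor}: position {length} beyond protein length {plen}"
                )
            length = plen
        expected = np.arange(1, length + 1)
        present = np.zeros(length, dtype=bool)
        present[positions - 1] = True
        if not present.all():
            first_missing = int(expected[~present][0])
            raise ValueError(
                f"{acc}/{predictor}: track not dense, missing residue {first_missing}"
            )
        values = np.zeros(length, dtype=float)
        values[positions - 1] = grp["value"].to_numpy(dtype=float)
        out.setdefault(str(acc), []).append(
            DisorderTrack(accession=str(acc), predictor=str(predictor), values=values)
        )
    return out


def _tracks_from_d2p2_json(path, proteome) -> dict[str, list[DisorderTrack]]:
    with open(path) as fh:
        data = json.load(fh)
    out: dict[str, list[DisorderTrack]] = {}
    for acc, predictors in data.items():
        if "length" in predictors:
            length = int(predictors["length"])
        elif proteome is not None and acc in proteome:
            length = proteome[acc].length
        else:
            raise ValueError(f"{acc}: no 'length' key and accession not in proteome")
        if proteome is not None and acc in proteome and length != proteome[acc].length:
            raise ValueError(
                f"{acc}: declared length {length} != protein length "
                f"{proteome[acc].length}"
            )
        for predictor, intervals in predictors.items():
            if predictor == "length":
                continue
            values = np.zeros(length, dtype=float)
            for start, end in intervals:
                if not (1 <= start <= end <= length):
                    raise ValueError(
                        f"{acc}/{predictor}: interval ({start},{end}) beyond "
                        f"protein length {length}"
                    )
                values[start - 1 : end] = 1.0
            out.setdefault(acc, []).append(
                DisorderTrack(accession=acc, predictor=predictor, values=values)
            )
    return out


def read_disorder_tracks(
    path,
    dialect: str = "tsv",
    proteome: Mapping[str, ProteinRecord] | None = None,
) -> dict[str, list[DisorderTrack]]:
    """Read per-residue disorder predictions.

    Two dialects: ``tsv`` with columns accession/predictor/position/value
    (dense, one value per residue), and ``d2p2-json`` with per-protein
    ``{predictor: [[start, end], ...], "length": L}`` interval lists that are
    expanded to binary per-residue calls (residues outside any interval = 0).
    Passing the proteome enables length validation against the sequences.
    """
    path = Path(path)
    if dialect == "tsv":
        return _tracks_from_tsv(path, proteome)
    if dialect == "d2p2-json":
        return _tracks_from_d2p2_json(path, proteome)
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'd2p2-json'")
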
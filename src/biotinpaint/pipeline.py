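"""End-to-end orchestration: load inputs, run every stage, write reports.

All tables are written as TSV with a fixed column order and 6-significant-
digit float formatting so reruns diff cleanly; a manifest records the
configuration, seed and package version (and nothing time-dependent, so an
output tree hashes identically across reruns).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import (
    biotin_disorder_association,
    enrichment_table,
    study_enrichment,
    summarize_biotin_counts,
)
from .go import go_test
from .idr import call_idrs, export_fractions, export_idrsets
from .io import load_study_registry, read_disorder_tracks, read_fasta, read_site_table
from .ptm import PTM_BACKGROUNDS, ptm_idr_enrichment
from .structure import class_values, classify_proteins, compare_classes
from .timecourse import run_timecourse

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Paths to every input plus the analysis options of a pipeline run."""

    fasta: str = ""
    sites: str = ""
    tracks: str = ""
    tracks_dialect: str = "tsv"
    ptm_sites: str = ""
    tmt: str = ""
    go_annotations: str = ""
    go_bias: str = ""
    outdir: str = "results"
    caller: str = "VSL2b"
    threshold: float = 0.5
    quorum: float = 0.75
    alternative: str = "two-sided"
    alpha: float = 0.05
    pseudo_count: float = 0.5
    pooling: str = "biotinome"
    seed: int = 0
    uniprot_ids: bool = False
    stages: tuple = ("enrich", "classify", "ptm", "go", "timecourse")


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Run the stages in dependency order and write all reports.

    Stage order: io -> idr calling -> {enrichment, classes, ptm, go} with the
    time course independent of the sequence stages. Every input path is
    checked before any computation starts; any stage error is re-raised with
    the stage name attached.
    """
    required = [("fasta", config.fasta), ("sites", config.sites),
                ("tracks", config.tracks)]
    optional = [("ptm_sites", config.ptm_sites), ("tmt", config.tmt),
                ("go_annotations", config.go_annotations),
                ("go_bias", config.go_bias)]
    for name, p in required:
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {p!r}")
    for name, p in optional:
        if p and not Path(p).exists():
            raise FileNotFoundError(f"configured input {name!r} does not exist: {p!r}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, object] = {}

    current = ["setup"]

    def stage(name):
        current[0] = name
        logger.info("stage: %s", name)

    try:
        stage("io")
        registry = load_study_registry()
        proteome = read_fasta(config.fasta, uniprot_ids=config.uniprot_ids)
        sites, report = read_site_table(config.sites, registry, proteome)
        tracks = read_disorder_tracks(
            config.tracks, dialect=config.tracks_dialect, proteome=proteome
        )
        stage("idr")
        idrsets = call_idrs(
            tracks,
            caller=config.caller,
            threshold=config.threshold,
            quorum=config.quorum,
        )
        write_tsv(export_idrsets(idrsets.values()), outdir / "idr_intervals.tsv")
        write_tsv(export_fractions(idrsets.values()), outdir / "idr_fractions.tsv")
        fractions = {
            acc: s.n_disordered / s.length for acc, s in idrsets.items()
        }
        write_tsv(classify_proteins(fractions), outdir / "structure_classes.tsv")

        study_ids = sorted({s.study_id for s in sites})
        if "enrich" in config.stages:
            stage("enrich")
            results, bars = [], []
            for sid in study_ids:
                res, bar = study_enrichment(
                    sites, proteome, idrsets, registry, study_id=sid,
                    pooling=config.pooling, alternative=config.alternative,
                )
                results.append(res)
                bars.append(bar)
            write_tsv(enrichment_table(results), outdir / "enrichment.tsv")
            write_tsv(pd.concat(bars, ignore_index=True),
                      outdir / "enrichment_bars.tsv")
            assoc_rows = []
            for sid in study_ids:
                summaries = summarize_biotin_counts(
                    [s for s in sites if s.study_id == sid], proteome, idrsets
                )
                outputs[f"summaries_{sid}"] = summaries
                try:
                    assoc = biotin_disorder_association(summaries)
                    assoc_rows.append((sid, assoc.r, assoc.p_value, assoc.n))
                except ValueError as exc:
                    logger.warning("association skipped for %s: %s", sid, exc)
            write_tsv(
                pd.DataFrame(assoc_rows, columns=["study", "pearson_r", "p_value", "n"]),
                outdir / "biotin_disorder_association.tsv",
            )
            outputs["enrichment"] = results

        if "classify" in config.stages:
            stage("classify")
            frames = []
            for sid in study_ids:
                summaries = outputs.get(f"summaries_{sid}")
                if summaries is None:
                    summaries = summarize_biotin_counts(
                        [s for s in sites if s.study_id == sid], proteome, idrsets
                    )
                values = class_values(summaries, pseudo=config.pseudo_count)
                long = pd.concat(
                    [pd.DataFrame({"study": sid, "class": c, "log2_biotins": v})
                     for c, v in values.items()],
                    ignore_index=True,
                )
                frames.append(long)
                try:
                    comparison = compare_classes(values, alpha=config.alpha)
                    cmp_df = comparison.to_frame()
                    cmp_df.insert(0, "study", sid)
                    outputs.setdefault("class_comparisons", []).append(cmp_df)
                except ValueError as exc:
                    logger.warning("class comparison skipped for %s: %s", sid, exc)
            write_tsv(pd.concat(frames, ignore_index=True),
                      outdir / "class_log2_biotins.tsv")
            if "class_comparisons" in outputs:
                write_tsv(
                    pd.concat(outputs["class_comparisons"], ignore_index=True),
                    outdir / "class_comparisons.tsv",
                )

        if "ptm" in config.stages and config.ptm_sites:
            stage("ptm")
            ptm_sites, _ = read_site_table(config.ptm_sites, None, proteome)
            ptm_results = []
            for ptm_type in sorted(PTM_BACKGROUNDS):
                subset = [s for s in ptm_sites if s.modification == ptm_type]
                if not subset:
                    continue
                res, _ = ptm_idr_enrichment(
                    subset, proteome, idrsets, ptm_type=ptm_type,
                    pooling=config.pooling, alternative=config.alternative,
                )
                ptm_results.append(res)
            write_tsv(enrichment_table(ptm_results), outdir / "ptm_enrichment.tsv")

        if "go" in config.stages and config.go_annotations:
            stage("go")
            ann_df = pd.read_csv(config.go_annotations, sep="\t")
            annotations: dict[str, set] = {}
            for acc, term in zip(ann_df["accession"], ann_df["term"]):
                annotations.setdefault(acc, set()).add(term)
            bias_df = pd.read_csv(config.go_bias, sep="\t")
            bias = dict(zip(bias_df["accession"], bias_df["bias"]))
            biotinome = {s.accession for s in sites}
            go_df = go_test(annotations, biotinome, bias, universe=list(proteome))
            write_tsv(go_df, outdir / "go_enrichment.tsv")

        if "timecourse" in config.stages and config.tmt:
            stage("timecourse")
            tmt = pd.read_csv(config.tmt, sep="\t")
            contrast_stats, calls, tc_report = run_timecourse(tmt, alpha=config.alpha)
            for name, df in contrast_stats.items():
                merged = df.merge(calls, on="peptide_id")
                write_tsv(merged, outdir / f"timecourse_{name}.tsv")
            write_tsv(calls, outdir / "timecourse_labels.tsv")
            outputs["timecourse_report"] = tc_report

        manifest = {
            "package": "biotinpaint",
            "version": __version__,
            # outdir is excluded: it is where the manifest lives, and keeping
            # it out makes output trees byte-identical across target paths
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
                if k != "outdir"
            },
            "site_validation": {
                "retained": report.retained,
                "dropped": report.dropped,
            },
            "studies": study_ids,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        outputs["manifest"] = manifest
        return outputs
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current[0]!r}: {exc}") from exc
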
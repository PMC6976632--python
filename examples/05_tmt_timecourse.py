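"""TMT biotin-painting time course: moderated tests and early/late calls.

Simulates a 10-plex labelling time course (10 s / 120 s / 300 s triplicates
plus a carrier), filters to complete biotinylated ribosomal peptides, runs
empirical-Bayes moderated t-tests of each later time point against the 10 s
reference, and labels peptides early or late. A strong 3-sigma effect is
used so most late peptides are recovered.
"""

from biotinpaint.simulate import generate_tmt
from biotinpaint.timecourse import run_timecourse

tmt = generate_tmt(
    n_null=100, n_late=25, effect=3.0, noise_sd=1.0,
    missing_rate=0.02, nonbiotin_rate=0.05, seed=6,
)
contrast_stats, calls, report = run_timecourse(tmt)

print(f"filtered: kept {report.retained}, "
      f"dropped {report.dropped_missing} missing / "
      f"{report.dropped_nonbiotin} non-biotinylated / "
      f"{report.dropped_nonribosomal} non-ribosomal")
print(calls["label"].value_counts().to_string())

truth = tmt.set_index("peptide_id")["is_late_truth"]
labels = calls.set_index("peptide_id")["label"]
shared = labels.index.intersection(truth.index)
late_ids = truth[shared][truth[shared]].index
recovery = (labels[late_ids] == "late").mean()
print(f"late-peptide recovery at adjusted p < 0.05: {recovery:.0%}")
print(contrast_stats["300s_vs_10s"].head(3).to_string(index=False))
# "late" = significantly increased labelling after 10 s in either contrast;
# early peptides are the surface sites the first seconds already saturate.
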
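"""IDR calling: binarizing tracks, predictor union, and quorum consensus.

Shows the interval algebra on one toy protein: two predictors with partly
overlapping calls combine either as a union (called by one or both) or as a
75% quorum vote across many predictors.
"""

import numpy as np

from biotinpaint.idr import binarize_track, combine_consensus, combine_union, disorder_fraction
from biotinpaint.io import DisorderTrack

L = 30
vsl2b = DisorderTrack("P1", "VSL2b", np.array([1] * 8 + [0] * 14 + [1] * 8, float))
iupred = DisorderTrack("P1", "IUPred-L", np.array([0] * 5 + [1] * 10 + [0] * 15, float))

a, b = binarize_track(vsl2b), binarize_track(iupred)
union = combine_union(a, b)
print("VSL2b intervals:   ", a.intervals)
print("IUPred-L intervals:", b.intervals)
print("union:             ", union.intervals, f"({union.caller_label})")
print(f"disorder fraction under union: {disorder_fraction(union).fraction:.2f}")

# quorum consensus over nine noisy pseudo-predictors: a residue is called
# disordered only when >= 75% of predictors agree (7 of 9)
rng = np.random.default_rng(0)
truth = a.to_mask()
nine = [
    binarize_track(
        DisorderTrack("P1", f"pred{i}", (truth ^ (rng.random(L) < 0.15)).astype(float))
    )
    for i in range(9)
]
cons = combine_consensus(nine, quorum=0.75)
print("consensus75:       ", cons.intervals)
# The consensus suppresses single-predictor noise but keeps regions most
# predictors agree on, including single-residue IDRs when supported.
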
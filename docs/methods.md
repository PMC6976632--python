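# Methods

## Coordinates and interval calling

All residue positions are 1-based and all intervals are inclusive on both
ends (UniProt/PDB convention); this is enforced in every type, reader and
writer. An IDR set is a normalized interval list: sorted, non-overlapping,
adjacent intervals merged. Normalization makes interval counts
deterministic; it never changes residue-level content.

Disorder tracks binarize at a threshold of 0.5 by default (residue
disordered iff score ≥ 0.5). The threshold only matters for user-supplied
continuous score tracks; interval-dialect inputs (the D2P2-style JSON) are
already binary. **No minimum IDR length is applied anywhere**: a length-1
IDR is legal and kept. This deliberately favours sensitivity over
specificity of disorder calling — short flexible linkers are exactly the
segments accessible to labelling chemistry — at the cost of false-positive
single-residue calls from noisy predictors.

Predictor combination:

- *Union* — residue disordered if called by either predictor; caller labels
  join with `_` (e.g. `VSL2b_IUPred-L`).
- *Quorum consensus* — disordered iff (callers voting) / (callers with a
  track for this protein) ≥ quorum, inclusive. At the default quorum 0.75
  over nine predictors this means ≥ 7 voters (7/9 ≈ 0.778 passes, 6/9 does
  not). The denominator is the number of predictors *available for that
  protein*, not a fixed nine, so proteins missing a predictor are still
  callable; the caller label records the quorum (`consensus75`).

## The enrichment model

For a study whose chemistry targets residue r ∈ {K, Y}, with unique sites
(deduplicated on study, accession, position, modification — unique sites
are the counting unit because replicate spectra of one site are not
independent observations):

- trials n = number of unique sites in the study,
- successes k = sites whose position lies in an IDR,
- null rate p0 = Σ n_in_idr / Σ n_total of target residues, pooled over the
  **biotinome** (proteins with ≥ 1 site in this study).

Pooling over the biotinome rather than the whole proteome avoids diluting
the null with proteins the study could never have sampled; whole-proteome
pooling is available via `pooling="proteome"` for sensitivity analysis. A
p0 of exactly 0 or 1 marks the scope untestable rather than producing a
p-value.

The exact binomial p-value is computed by pmf summation in log space
(`gammaln`-based, no normal approximation at any n). Two-sided p-values use
the minimum-likelihood convention — the sum of probabilities of all
outcomes no more likely than the observed one (with a 1e-7 relative
tolerance for ties) — matching R's `binom.test` and scipy's `binomtest`;
this is stated because exact two-sided definitions differ between tools.
The default alternative is two-sided, with direction read from the fold;
`greater` is available by flag.

PTM analyses reuse the identical machinery with the residue background
swapped in: phosphorylation S/T/Y; ubiquitination, acetylation, sumoylation
K. Sites on ineligible residues are dropped with a warning (strict mode
aborts). Running biotin sites through the PTM path with the study's target
residue reproduces the study analysis bit-for-bit — asserted in tests.

## Structural classes

Class boundaries honour the printed ranges "<10%", "10–30%", ">30%"
literally: F = [0, 0.10), P = [0.10, 0.30], U = (0.30, 1]. Both boundary
values land in P; a convention had to be chosen and this one keeps every
stated range true.

Biotin counts are compared on log2(count + pseudo) with pseudo-count 0.5,
so zero-count proteins sit strictly below the zero line and one-site
proteins just above it. Pairwise t-tests default to Welch (class variances
are plainly unequal in practice); pooled-variance tests are a flag away.
One-way ANOVA is fixed-effects; Tukey's HSD uses the studentized-range
distribution (scipy's implementation, numerical quadrature of the CDF) with
the Tukey–Kramer standard error √(MSE/2·(1/nᵢ+1/nⱼ)) for unbalanced
classes. With exactly two groups the q = √2·|t| identity makes the Tukey
adjusted p equal the pooled t-test p, which the tests assert; the
implementation is also cross-checked against `scipy.stats.tukey_hsd`.

## Bias-corrected category enrichment

The probability-weighting function is an isotonic (monotone non-decreasing)
regression of biotinome membership on the per-protein bias factor
(expression or similar). Isotonic regression was chosen over a monotone
spline: parameter-free, order-preserving, and exactly flat under constant
bias, where the whole test degenerates to Fisher's exact (asserted to
1e-9). Fitted probabilities are floored at 1e-6 so weights stay positive.

Category tests use the two-colour Wallenius noncentral hypergeometric with
odds = (mean fitted weight inside the category) / (mean outside). The pmf
is computed by exact draw-by-draw recursion — state (draws, category draws),
next-draw probability w·m₁′/(w·m₁′+m₂′) — for populations up to 2000, and
by scipy's numerical-integration implementation above that; the two agree
to ~1e-6 relative in the tested range. Only over-representation is reported
by default (under-representation by flag); categories smaller than
`min_category = 3` are skipped; BH adjustment is applied across tested
categories (the multiplicity rule is a package decision, recorded in the
output).

The population universe is taken explicitly (defaulting to the annotated
proteins) because the right universe — detected proteome vs annotated
proteome — is a study-design question, not something the package should
decide silently. Unannotated proteins stay in the universe and simply
belong to no category.

## TMT time course

Filtering is row-wise complete-case over the 10 s/120 s/300 s triplicates
(no imputation), keeps only biotinylated ribosomal peptides, and drops the
1 h carrier channels from all statistics. Intensities are **not**
median-normalised by default: the biotinylated fraction of the peptide pool
genuinely grows between 10 s and 300 s, and equalising channel medians
would erase exactly that signal. An optional normalization flag exists for
sensitivity analysis.

Testing is on log2 intensities (reporter noise is multiplicative; the
variance model needs a roughly variance-stabilised scale; a linear-scale
mode exists for sensitivity analysis). Each contrast (120 s vs 10 s, 300 s
vs 10 s) is fitted separately: per peptide, the pooled two-sample variance
s²_g with d_g = 4 df is shrunk toward a prior (d₀, s₀²) estimated across
peptides by moment matching of log variances — var(log s²) =
ψ′(d_g/2) + ψ′(d₀/2), solved by Newton inversion of the trigamma; when the
equation has no positive root (observed variances less dispersed than
sampling alone predicts) d₀ is capped at 10⁶, i.e. full shrinkage, and
logged. Moderated t = Δmean/(s_post·√(2/3)) with d₀+d_g df and BH
adjustment per contrast. Setting d₀ = 0 recovers the ordinary pooled
t-test exactly; the implementation was verified numerically identical
(≈1e-15) to limma's `eBayes` on shared data during development.

Classification: "late" requires adjusted p strictly below 0.05 **and** a
positive log fold change (the biological claim is a labelling *increase*;
the p-value itself stays two-sided and conventional); everything else is
"early". p_adj = 0.05 exactly is early.

## Synthetic-data generator

The generator is a pure function of (config, seed); one global seed expands
to per-component child seeds via `SeedSequence.spawn` in a fixed order
(proteome, biotin sites, PTM sites, TMT, GO), so components regenerate
independently and byte-identically.

- *Proteome*: residues i.i.d. with K at 6% and Y at 3% (approximate natural
  abundances of the two chemistry-relevant residues), the remaining mass
  uniform; gamma-distributed lengths (mean 450, shape 6, floor 50). Per
  protein the disorder mask covers exactly round(q·L) residues, split into
  geometric-length blocks (mean 30) placed uniformly with ≥ 1 ordered
  residue between blocks. Exact coverage keeps the planting closed form
  sharp. With `disorder_fraction_spread` set, per-protein fractions are
  Beta(qc, (1−q)c) with concentration c, which populates all three
  structural classes and creates a genuine count/disorder correlation —
  used by the class and association analyses.
- *Sites*: each draw picks a target residue with weight ρ inside IDRs, 1
  outside, with replacement; duplicates collapse (real studies report
  unique sites). Expected unique in-IDR fraction ρq_r/(ρq_r+1−q_r) with
  q_r the in-IDR fraction of target residues. Heavy sampling relative to
  the number of target residues saturates IDR positions first and pulls the
  observed fraction slightly below the closed form; simulations sized for
  closed-form checks keep draws ≪ target residues (the checks use ~10⁴
  sites on a ~9-Mresidue proteome, where the deficit is ≈ 0.003).
- *TMT*: log2 intensities = N(14, 1) baseline + condition effect + N(0, σ)
  noise, σ = 1 by default; late peptides gain the effect (default 1.5·σ)
  at 120 s and 300 s; carrier saturates. **Power note**: with triplicates
  the standard error of a contrast is σ√(2/3), so a 1.5·σ effect has
  noncentrality ≈ 1.84 — the moderated test recovers only a minority of
  late peptides at BH 0.05 at that effect size (the acceptance script
  reports the realized rate), while a 3·σ effect yields ≥ 80% recovery
  (asserted in tests). Detecting subtle kinetic differences needs either
  larger effects or more replicates; the defaults describe the design, not
  a guarantee of power.
- *GO*: per-protein bias log-normal; membership probability logistic in
  log-bias (slope = bias strength); category members drawn with weights
  bias^coupling, so annotations are abundance-skewed — the confound the
  Wallenius correction removes; an optional planted category multiplies its
  members' membership odds.

What the generator does **not** emulate: real sequence statistics (no
homology, no domain architecture), real predictor error structure
(pseudo-predictors use independent per-residue flips; real predictors err
in correlated blocks), isoform/version drift between site tables and
sequence databases (the validation report exists to surface this in real
data), missing-not-at-random TMT patterns, and the GO DAG (terms are flat
labels). Passing tests therefore demonstrate correctness of the statistics
under the stated models, not robustness to every artefact of real data.

## Degenerate inputs and numerical choices

Untestable scopes (p0 ∈ {0,1}) are flagged, never silently tested. Classes
with < 2 observations are skipped with a warning; comparisons need ≥ 2
usable classes. ANOVA on identical values returns F = 0, p = 1. Binomial
two-sided ties use a 1e-7 relative tolerance. Wallenius margins where the
whole support satisfies the tail give p = 1. Isotonic weights are floored
at 1e-6. All report tables use fixed column order and 6-significant-digit
floats; manifests contain no timestamps, so output trees hash identically
across reruns.
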
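# Methods

`plexquant` implements the quantitative analysis chain of an isobaric
(TMT 10-plex) SPS-MS3 proteomics experiment, from MS3 reporter peaks to
differential-abundance and pathway-level results, together with a
photoconversion pulse-chase decay analysis and a synthetic-data generator
that provides planted ground truth for every stage.  This note records the
models, the parameters that matter, and the design choices made where the
protocol the package follows leaves the implementation open.

## Reporter-ion quantification

The ten TMT reporter cations share the C8H16N+ skeleton and differ by
combinations of 13C/15N substitutions.  Their theoretical m/z values are
computed from elemental isotope compositions (monoisotopic masses via
pyteomics, minus one electron), not copied from a table; the N/C
isotopologue pairs are ~6.32 mDa apart, which is why extraction uses a
narrow ±0.003 Da window around each theoretical m/z.  Within the window the
most intense peak is taken (robust to small calibration jitter; the
convention matters only when several peaks fall inside 6 mDa).  Per-channel
signal-to-noise is the selected peak's intensity over its instrument noise
estimate.

PSM-level quality filters: a PSM is excluded from quantification when its
summed S/N across the 10 channels is below 100 or its precursor isolation
specificity is below 0.7.  Both bounds are treated as strict inequalities —
values exactly at 100 or 0.70 are kept.  The isolation specificity is
consumed as a given PSM field; it is not recomputed from MS1 data.

## PSM confidence

PSMs are scored with a Fisher linear discriminant over standardized search
features (XCorr, deltaCn, |mass error|, missed cleavages, peptide length,
charge): `w ∝ (S_W + εI)^(-1)(μ_target − μ_decoy)` with ridge ε = 1e-6,
sign fixed so targets score higher.  The feature list is a package decision
(exposed in the API); any numeric column can be supplied.

Target-decoy FDR at threshold t is estimated as
`#decoys(score ≥ t) / max(1, #targets(score ≥ t))` (a +1 correction on the
decoy count is available behind a flag); q-values are the monotonized
minima and the kept set is every target at or above the smallest score with
q ≤ level (default 1%).  Confident PSMs are collapsed to proteins by the
maximum peptide score and the same estimator is applied at the protein
level — max is the simplest collapse whose protein score is monotone in
every peptide score.  When no threshold achieves the level the kept set is
empty with a warning rather than an error.

Calibration: with half decoys and 10% entrapment false targets drawn from
the decoy distributions, the decoy count over-counts the false targets
roughly tenfold, so the realized false-discovery proportion at nominal 1%
sits near 0.1% — conservative, as expected when the decoy population is
larger than the false-target population it models.

## Protein inference

Parsimony is formalized as minimum set cover, which is NP-hard; the solver
is the classical greedy (pick the protein explaining the most unexplained
peptides; ties by total peptide count, then lexicographic accession),
followed by a pruning pass that enforces irredundancy.  The greedy loop
uses a lazily invalidated heap, so proteome-scale maps with mostly unique
peptides run in near-linear time.  Proteins with identical peptide sets
form one group.  An exact brute-force solver is available for maps of ≤ 15
proteins and backs the property tests (greedy cover ≤ exact minimum + 1 on
random instances).  Shared peptides are assigned to the selected group
with the most peptides; paralog-specific ("unique peptides only")
quantification is available per accession.

## Quantification and normalization

Peptide reproducibility: within each replicate group of ≥ 2 channels, the
coefficient of variation (sample sd / mean) must be strictly below 20% in
*every* evaluable group — the stricter of the two possible readings of a
per-group rule.  Zero-mean peptides are dropped with reason `zero-signal`.

Protein channel values are the sum of kept peptide intensities (reporter
ion signal is additive).  Two normalizations are implemented: label-check
mixing factors (mean of pooled channel totals over each total, which
equalizes the totals exactly and is idempotent) and equal-loading
normalization of the final matrix (each column scaled by the mean column
total over its own; conserves the grand total to ≤ 1e-9 relative).

A consequence worth knowing: planting 5% of the proteome up twofold shifts
the channel totals by ~5%, so after equal-loading normalization the
recovered log2 fold change of a planted unit effect is ≈ 1 − log2(1.05) ≈
0.93, not 1.0.  This compositional compression is inherent to
total-signal normalization, not an estimator bias.

## Differential statistics

Per protein: log2 ratio of group means (zeros replaced by half the smallest
positive matrix value before the ratio), delta-method standard error
`se = (1/ln2)·sqrt(sd_A²/(n_A·m_A²) + sd_B²/(n_B·m_B²))`, and an
equal-variance two-sample Student's t test (Welch behind a flag).  Raw
p-values are reported for the volcano tables (significance at p < 0.05);
Benjamini-Hochberg adjustment is applied only where the workflow calls for
adjusted p-values (enrichment, proximity-labeling selection).  Degenerate
zero-variance data give p = 1 for equal means and p = 0 otherwise.

Clustering is agglomerative with Euclidean distance and average (UPGMA)
linkage on per-protein z-scored rows — z-scoring keeps high-abundance
proteins from dominating the distance; both choices are exposed.  PCA
centers proteins and fixes each component's sign so its largest-|loading|
entry is positive, making scores reproducible.

## Over-representation analysis

The statistic is the hypergeometric upper tail P(X ≥ k) for an overlap of k
between a query of n and a term of K proteins in a background of N — the
background being all proteins quantified in the plex, not the genome.
Terms are filtered to 5 ≤ K ≤ 500 within the background (common ORA
defaults; configurable), BH is applied within each GO namespace (a global
flag exists), and up-/down-regulated queries are analyzed separately.
Annotations are consumed as a flat protein→term table; no ontology-graph
propagation is performed.

## Cross-model meta-analysis

Integration across tissues/models is set logic.  "Altered at least 20%,
allowing for standard error" is operationalized on the log scale as
`(|log2FC| − m·se) ≥ log2(1.20)` with m = 1 by default (0 and 1.96
available) — the central interpretive decision of this module, since no
formula accompanies the phrase.  Tissue counts track direction and flag
discordant proteins.  Young/old overlap uses strict >25% fold change with
p < 0.05 in each cohort; proximity-labeling (APEX2-style) selection uses
fold ≥ 1.5 (inclusive, "or greater") with BH-adjusted p < 0.05 (strict).

## Decay fitting

The pulse-chase readout is the per-event RFP/CFP ratio of the gated
RFP-positive population, averaged per timepoint (mean of ratios, matching
the per-population computation; not ratio of means).  The decay model is

    R(t) = a_f·exp(−k_f t) + a_s·exp(−k_s t) + c,   k_f > k_s ≥ 0

with nonnegative spans and optional plateau c (fitted by default, pinnable
to 0).  Fitting is bounded trust-region least squares, weighted by inverse
SE when available, multi-started over a log-spaced rate grid covering
0.05–50 characteristic decays per observation window.  If the best
two-phase fit has k_f/k_s < 3 or a span under 2% of R(0), the curve is
refit as a single exponential and reported as `monophasic`; constant data
short-circuit to a plateau-only fit with rates 0.  Half-lives are ln2/k.
Non-convergence from every start returns best-effort parameters with
`converged=False` rather than raising.

## Synthetic data: what it emulates, and what it does not

The generator draws random-sequence proteomes (uniform over the 20-letter
alphabet) with reversed-sequence decoys (`rev_` prefix; the decoy method is
an assumption — reversal, not shuffling), digests them with the standard
trypsin rule (cleave after K/R, suppressed before P), lays experimental
arms out on 10-plex channels, and plants fold changes on a chosen fraction
of proteins, applied consistently across every non-reference condition, as
expected of a genuine client protein visible in multiple tissues.

For a correctly matched PSM the true channel signal is
`base · fc(condition) · ionization factor · loading factor · lognormal
noise` (all lognormal factors have mean 1, so noiseless means are exact),
and the measured signal blends a channel-uniform co-isolation term with
weight (1 − isolation specificity), scaled by an `interference_level`
representing the fraction of co-isolated signal that survives the SPS-MS3
stage (default 0.1 — MS3 acquisition exists precisely because it removes
most of this).  Decoy PSMs score lower by a configurable XCorr shift
(default 1.5) and carry flat reporter patterns; a configurable fraction of
target PSMs are "entrapment" mismatches with decoy-like scores and
interference-like quantification — the known false positives against which
realized FDR is measured.

Default desk-scale study conditions: 2,000 proteins, one 10-plex with a
3 vs 3 wild-type/knockout brain design, ~15 PSMs per protein (~30,000+
PSMs), 10% measurement CV, 5% of proteins planted at log2FC 1.0, 5%
entrapment, 25% decoy PSM fraction.  These sizes exercise every filter
meaningfully while keeping a full run under a minute.

Not modeled: fragment spectra, retention time, fractionation, isotope
impurity between channels (hence no impurity-correction matrix),
peptide-level biological variance beyond measurement noise, and shared
peptides between random-sequence proteins (vanishingly rare by
construction — protein inference is therefore exercised by dedicated
constructed and randomized maps, not by the proteome-scale simulation).
Passing tests consequently demonstrate correctness of the computations and
calibration under the stated noise model, not robustness to every
real-instrument artifact.

## Numerical choices

Lognormal noise uses σ² = ln(1 + CV²) with mean-one correction.  LDA
standardization guards zero-variance features (sd floored at 1, so a
constant feature gets weight from its zero between-class gap, i.e. none).
FDR q-values cap at 1.  The hypergeometric tail uses SciPy's survival
function (exact to ≤ 1e-12 against binomial-coefficient enumeration for
N ≤ 15).  Decay fits use xtol = ftol = gtol = 1e-15 so noiseless round
trips recover parameters to ~1e-9 relative.  All stochastic code takes an
explicit seed (default 17) through `numpy.random.default_rng`; fixed seeds
give byte-identical outputs.

## Reported benchmark sizes

The reproduction script (`scripts/acceptance.py`) uses: 20 × 20,000 PSMs
for FDR calibration; one full default-design run for fold-change recovery;
10,000 null t tests; 1,000 uniform ORA query draws over a background of
2,000 with 300-protein terms (sizes chosen analytically so the discrete
test's attainable level, 0.0495, sits next to the nominal 0.05); 200
random parsimony instances of ≤ 10 proteins; and 50 seeded decay
replicates at 1,000 events × 7 timepoints with 5% event CV.
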
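# Methods

This note documents the models, conventions and parameter choices behind
each stage of the pipeline, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Hi3 label-free quantification (`prsascreen.hi3`)

The pipeline consumes a long-format peptide table (protein accession,
peptide sequence, modification flag, strain, biological replicate, raw
intensity) — the information content of a search engine's peptide export.
Processing order, which matters, is:

1. **Modified-peptide filter.** Rows flagged modified are discarded before
   anything else; modified forms split a peptide's signal and would bias a
   top-3 estimator.
2. **Median normalization.** Each biological replicate's reported
   intensities are divided by their median, taken over *all* unmodified
   reported peptides of the replicate — normalization precedes any
   protein-level filtering. The even-count median is the mean of the two
   middle values. Zero and missing intensities are both treated as "not
   reported": search-engine tables conventionally write 0 for
   non-detection, and a zero cannot carry abundance information.
3. **Hi3.** A protein's value in a replicate is the sum of its three
   largest normalized peptide intensities, and is absent when fewer than
   three peptides are reported there. Ties at the third rank are
   interchangeable — the sum of the three largest *values* is unaffected —
   so the result does not depend on row order.
4. **Replicate filter.** A protein is quantifiable in a strain when a Hi3
   value exists in at least 2 of 3 replicates; for n replicates the
   threshold generalizes to ceil(2n/3), preserving the same proportion,
   and is overridable.
5. **Relative abundance.** Per replicate, fraction = Hi3 / Σ Hi3 over the
   quantifiable proteins reported in that replicate, so fractions sum to 1
   within each replicate; the denominator includes the target itself. The
   default summary averages per-replicate fractions; dividing mean target
   Hi3 by mean total (ratio of means) is available as a mode switch since
   both orders are defensible. Fold changes between strains are ratios of
   mean fractions with the standard first-order error propagation
   sd = ratio·√((sd_a/μ_a)² + (sd_b/μ_b)²).

Consequences worth knowing: the whole stage is invariant to rescaling any
one replicate (normalization absorbs it), and relative abundances carry a
composition effect — spiking one protein dilutes everyone else's fraction,
so a true k-fold spike is recovered slightly below k. The brute-force
oracle in the test suite computes the same quantity independently, which
quantifies that effect exactly in the noiseless case.

Out of scope by design: FDR re-estimation, match-between-runs, protein
inference. The import shim takes the leading accession of a shared-peptide
group as given.

## Mature-sequence identity and trees (`prsascreen.identity`)

Secreted proteins are compared on the mature sequence: signal-peptide
boundaries are user-supplied (name → 0-based mature start), never
predicted, and trimming happens before alignment.

Pairwise comparison is Smith–Waterman local alignment with affine gaps
(Gotoh recurrences), written in-package so the traceback convention is
fully specified: ties resolve diagonal > up (gap in the second sequence)
> left, and the highest-scoring cell with the smallest (row, column) wins.
Defaults are BLOSUM62 with gap open 10 and gap extend 0.5 — the classic
local-alignment parameterization — and are configurable; the first residue
of a gap costs the open penalty and each further residue the extend
penalty. Percent identity is 100 × identical columns / alignment length
(gap columns included); dividing by the shorter sequence length instead is
a switch, because conventions differ between tools and published tables
rarely state theirs. Each unordered pair is aligned once, making the
matrix symmetric by construction.

Identity converts to distance as d = 1 − identity/100, and the tree is
standard neighbor joining (via scikit-bio) with negative branch-length
estimates clamped to zero and logged. NJ is exact on additive matrices —
the test suite verifies tip-to-tip distances to 1e-9 on random 5–8-taxon
trees — but distances derived from percent identity are not additive, so
real trees are descriptive, not model-based phylogenies. No bootstrap, no
multiple alignment.

The alignment implementation is cross-checked two independent ways: an
exhaustive enumeration over alignment skeletons (every strictly increasing
matching of residue positions, with affine gap costs between consecutive
matches) on short sequences, and Biopython's PairwiseAligner under the
same scoring on longer ones.

## Motif scanning (`prsascreen.motifs`)

Scanning is exact-count, not probabilistic: a window scores the number of
positions identical to the canonical motif (case-insensitive; `N` never
matches), and every window at or above the threshold is reported — no
position-weight matrices, no enrichment statistics. Coordinates are
0-based, half-open, always on the forward strand; a minus-strand hit is
the reverse complement of the forward slice it occupies. Overlapping hits
are all reported, because real regulatory sites overlap (an operator can
sit on a −35 box).

The two-box σ^A model pairs every −35 (`TTGACA`) and −10 (`TATAAT`)
candidate meeting the per-box threshold (default 5 of 6) whose spacer —
the gap between the end of the −35 and the start of the −10 — lies in
16–18 nt. A promoter's reported center is the midpoint of the full
−35-through-−10 span by default ("centered N bp upstream" is read as that
midpoint N bases 5′ of the anchor); the midpoint of the −10 box alone is
the alternative convention, and every hit echoes which was used.

## Assay units (`prsascreen.assays`)

Amylase activity is the least-squares slope of A405 vs time over the full
trace (default 7 readings, minutes 0–6): one unit = one absorbance unit
per minute, so the slope *is* the activity. Fitting all timepoints rather
than differencing endpoints uses every reading and makes the value
invariant to a constant baseline. Calibration is an ordinary least-squares
line of response vs standard concentration (R² reported); unknowns are
inverse-predicted as (slope − intercept)/gain with extrapolation outside
the standard range flagged (a 1e-9-relative tolerance keeps boundary
standards from flagging spuriously).

β-galactosidase activity uses the classical Miller formula
1000·(A420 − 1.75·A550)/(t·v·OD600) with t in minutes, v in mL, matching
the unit's dimensions (nmol·OD⁻¹·min⁻¹); the 1.75 scatter-correction
factor is the field convention and configurable. Technical duplicates are
averaged on the reading scale before unit conversion; biological
replicates are summarized after.

## Yield statistics (`prsascreen.relyield`)

Within one amylase row, every cell's replicate activities are divided by
the mean of the no-chaperone reference cell, so the reference maps to
exactly 1 and all numbers read as fold improvements. Each non-reference
cell is compared to the reference with a two-sided t-test on the
normalized replicate values (equivalent to raw values up to the common
scale); Welch's unequal-variance form is the default, pooled variance a
switch. The Bonferroni family is the number of non-reference cells in that
row — the comparisons actually made against the shared reference — not the
whole matrix. Classes: significant p < 0.05, marginal 0.05 ≤ p < 0.10,
else ns, with both boundaries tested explicitly.

Degenerate inputs are guarded rather than crashed on: two zero-variance
samples give p = 1 at equal means and p = 0 (flagged degenerate) at
unequal means, which noiseless synthetic data would otherwise trigger.
Replicates are treated as independent observations; no mixed-effects
structure is modelled.

## Synthetic data (`prsascreen.synthetic`)

All generators draw from `numpy.random.default_rng(seed)`; one seed
determines the entire output byte-for-byte.

**Peptide tables.** A peptide's intensity is base abundance × strain fold
change × peptide response factor × lognormal noise. Response factors are
drawn once per peptide (lognormal, σ = 0.5 by default) because real
ionization efficiencies span orders of magnitude — this makes the top-3
selection nontrivial. Measurement noise is mean-one lognormal with
coefficient of variation `intensity_cv` (default 0.1, a conventional
choice for replicate-level label-free data; dispersion estimates for this
kind of experiment are rarely published). Missingness is
intensity-independent (MCAR, default 5%) — the simplest model that
exercises the replicate filter; real non-detection is intensity-dependent,
so the generator does not probe abundance-correlated dropout. Modified
peptides (default 5%) are flagged per peptide species. Defaults emulate
biological triplicates.

**Sequence families.** A pairwise divergence matrix is not freely
realizable by independent mutation from one ancestor (triangle
constraints), so a star model is used: member 0 realizes the ancestor and
member i is the ancestor mutated at exactly round(f₀ᵢ·L) positions, with
substitutions never restoring the original letter. Divergence from member
0 is therefore exact by construction; divergence between two mutated
members follows from the independent overlap of their mutation sets. The
realized position-count identity matrix is returned and is the ground
truth tests use — no expectation needs to be trusted.

**Promoter regions** are uniform-random backgrounds with motif copies
implanted at stated positions/strands with exactly n randomized mismatch
positions; implants must not overlap. **Plate-reader tables** are linear
traces and calibration lines with optional Gaussian noise, and
β-galactosidase readings back-computed from true Miller units so the
noiseless round trip is exact.

What passing tests on these data show: the *processing rules* —
filters, normalization, top-3 arithmetic, alignment scoring, scanning,
unit conversion, test statistics — are implemented correctly. What they do
not show: robustness to the structure of real instrument data
(intensity-dependent missingness, shared peptides, chromatographic
artifacts, non-linear assay saturation), which the generators deliberately
do not model.

## Problem sizes used in verification

The test suite and acceptance script use: 200 random peptide tables
(≤ 10 proteins × ≤ 6 peptides × 3 replicates) against the brute-force
pipeline oracle at 1e-9; spike recovery at folds 0.5/1/2 with 50-protein
proteomes, cv = 0.1, 3 replicates, median over 20 simulations (15%
acceptance band, after which the noiseless run is compared to the oracle
exactly); 100 random pairs of length ≤ 8 against the exhaustive alignment
enumeration plus 100 self-identity checks; 50 random 5–8-taxon additive
trees at 1e-9; 100 random 1-kb regions × 3 mismatch thresholds against the
naive scanner plus 20 implant-recovery regions. These sizes make each
oracle comparison exhaustive or statistically stable while keeping the
whole verification run to well under a minute per stage.

## Known limitations

- The Hi3 stage quantifies relative abundance only; absolute
  quantification (spiked standards) is not implemented.
- Identity-derived distances are not evolutionary distances; the NJ tree
  has no support values.
- Motif scanning has no statistical background model; on long sequences
  low thresholds (5/6, 7/8 ≈ expected by chance every few hundred bp)
  produce background hits by design, and interpretation is the user's.
- The proprietary strains of a typical screen have unpublished sequences;
  family-structure conclusions are exercised here on synthetic stand-in
  families with divergences in the published ranges.
- Yield statistics assume independent replicates and use only Bonferroni
  correction.
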
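# Methods

## Search model

The engine treats peptide-spectrum matching as an intersection problem
between two discretized fragment-ion sets. Experimental MS2 peaks are
reduced to their K most intense fragments and binned on a uniform m/z
grid, `bin = floor((mz − offset)/w)` with half-open intervals
`[b·w, (b+1)·w)`; the run is then represented as an inverted index from
bin to postings `(spectrum id, summed selected intensity)`. Candidate
peptides come from in-silico digestion of the target database plus
reversed-sequence decoys, expanded over variable-modification site
subsets; their theoretical b/y ladders (charge 1+ and, for precursors of
charge ≥ 2, 2+) are generated at query time, binned on the same grid, and
looked up. Per (candidate, spectrum) pair the engine accumulates matched
b/y counts and intensities, applies a minimum matched-ion floor, scores
survivors, and keeps the best match per spectrum under a total order
(hyperscore, then xcorr, then lexicographic peptide key, then target over
decoy), which makes the reduction independent of candidate order and
batch size.

Assumptions: centroided spectra; monoisotopic masses; tryptic specificity
(C-terminal of K/R, not before P) unless reconfigured; b/y ions only, no
neutral losses or isotope-error expansion; fragment-bin collisions within
a spectrum merge by intensity summation (preserving total matched
intensity); every peptide is scored against every spectrum — precursor
mass is reported as Δm but only gated by the configured window (full
mode −6000..+4500 Da; open −150..+500 Da; narrow, a ppm tolerance).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `top_k` | 150 | peaks | beyond this, additional fragment peaks add little identification signal while inflating the index |
| `bin_width` | 0.02 | Da | near the optimum the calibration curve finds for ~5 mDa fragment error (see below) |
| `min_matched_ions` | 4 | ions | candidate floor; bounds accumulator noise and removes unscorable matches |
| modification cap | 20 sites | — | full 2^n enumeration up to the cap; above it, subsets of ≤ 3 sites |
| peptide length window | 7–50 | residues | standard detectable tryptic range |
| missed cleavages | ≤ 2 | — | standard tryptic incompleteness allowance |
| fragment charges | 1+, 2+ | — | 2+ fragments only counted for precursors of charge ≥ 2 |
| FDR threshold | 0.01 | — | reporting level at PSM/peptide/protein |

Proton 1.007276466 Da, water 18.0105646 Da, residue masses from
pyteomics.

## Scores

Hyperscore `H = ln(Nb!·Ny!·max(ΣIb,1)·max(ΣIy,1))`; the `max(·,1)` guard
keeps H ≥ 0 for sub-unit intensity sums and leaves H = 0 with no matches.
The fast cross-correlation first square-roots intensities and normalizes
the maximum to 50 within 10 equal m/z windows spanning the selection,
then evaluates `y'[b] = y[b] − mean(y[b−75..b+75])` lazily from prefix
sums over the sparse nonzero bins, so no dense vector is materialized;
`X` is the sum of `y'` over the candidate's ion bins, rounded to 4
decimals. During the search X is computed only for hyperscore ties and
for each spectrum's final best match — the tie order consults X strictly
after H, so lazy evaluation cannot change any outcome. Matched-intensity
accumulation follows one canonical ion order (b series over ascending
charges, then y series, sequential floating-point addition) in both the
index path and the all-pairs reference matcher, so the two agree
bit-for-bit, which the tests assert on seeded instances.

## Bin-width calibration

`optimal_bin_width` scans a width grid and measures, per peak, a
matched-reconstruction error against a reference m/z (in practice the
theoretical fragment m/z of identified peptides; in the tests, the
generator's ground truth): if observed and reference fall in the same
bin, the residual after snapping to the bin center,
`(ref − bin_center)²`; if binning separates them, the raw measurement
error `(ref − obs)²`, since binning at that width failed to link the
observation to its ion. Too-narrow bins split observation from reference
and pin the error at the instrument level; too-wide bins quantize
coarsely; the total falls and then rises with a single interior minimum
at roughly twice the m/z error σ. The default grid is log-spaced
(0.005–0.1 Da, 20 points): on a fine linear grid the sampling noise of
the curve between adjacent widths exceeds the drift and produces spurious
local minima, while log spacing keeps successive steps large relative to
that noise. Without a reference the function falls back to the plain
quantization error `Σ(obs − bin_center)²`, which grows ~w²/12 per peak
and is minimized by the smallest width on the grid — useful as a bound,
not as a calibration.

## Learned validation

Training data are assembled per run from the run itself: positives are
target precursors (best PSM per peptide+charge) at q ≤ 1% by
hyperscore-ranked target-decoy competition; negatives are all decoy PSMs.
If either side is empty — on small or very clean runs no decoy may ever
reach the matched-ion floor — validation falls back to hyperscore ranking
with a warning and reports are still produced.

The retention-time model maps a 63-dimensional composition encoding
(20 whole-sequence residue counts, 20 over the first two residues, 20
over the last two, C-terminal residue index, length, modified neutral
mass) to RT in seconds. With ≥ 200 confident peptides it is a multilayer
perceptron (two 64-unit ReLU layers) trained with full-batch L-BFGS on
standardized features and min-max-scaled RT — at these training-set sizes
(hundreds to a few thousand peptides) L-BFGS converges far more reliably
than stochastic optimizers; with 20–199 peptides a ridge regression on
the same features; below 20 the model is disabled and the RT-error
feature zeroed. Composition counts ignore modification state; only the
mass feature reflects it.

The discriminant is a 32-16-1 ReLU network over 16 match features
(H, X, ln(1+Nb), ln(1+Ny), matched-intensity fraction, length, ln M,
charge one-hot 1..4+, Δm, |Δm|, variable-modification count, missed
cleavages, RT error = observed − predicted). Class imbalance is handled
by seeded resampling of the minority class to the majority size,
equivalent in expectation to loss re-weighting (the sklearn classifier
exposes no per-sample weights). The score d is the pre-sigmoid logit.
All training is per run, from scratch, deterministic given the run seed.

q-values sort by d descending; `FDR(i) = #decoys(≤i)/max(1, #targets(≤i))`
and `q(i) = min_{j≥i} FDR(j)`, with score ties sharing the q of the
lowest-ranked member. Peptide level collapses to the best d per modified
peptide, protein level to the best d per accession with no parsimony
(proteins supported only by shared peptides are kept and flagged
`shared_only`). Decoys are excluded from reports, retained in the q
tables. The estimator uses the plain decoy/target ratio without the +1
correction.

## Synthetic data

The generator emulates what the search engine consumes: uniform-composition
proteins (default 200, 100–400 residues); MS2 spectra (default 1000, 80%
signal) whose signal peaks are the full b/y ladders (1+, and 2+ for
charge ≥ 2) of a randomly drawn tryptic peptide with Gaussian m/z error
(σ 0.005 Da), log-normal intensities (μ 0, σ 0.5), Poisson(30) uniform
noise peaks, precursor neutral-mass error σ 0.002 Da; retention times
follow an additive per-residue model (coefficients ~N(120, 40) s drawn
once per run) with σ 30 s scatter; charges 2+/3+ at 0.7/0.3. Every
spectrum carries a ground-truth label.

It does **not** emulate chromatographic peak shape, isotope envelopes,
co-fragmentation chimeras, missing fragments, or intensity structure
along the ladder. Consequently, passing the recovery and FDR checks shows
the machinery is correct and calibrated under its stated noise model —
not that real-data identification rates would match. Two regimes of the
generator matter for interpretation: under the clean defaults no decoy
reaches the matched-ion floor, so the end-to-end path exercises the
hyperscore fallback; raising the noise-peak density (e.g. to hundreds per
spectrum) produces decoy matches and exercises the full learned
validation path, which the unit tests do explicitly.

## Numerical and degenerate-input choices

Half-open floor binning (boundary value belongs to the upper bin);
intensity ties in top-K selection break toward lower m/z; empty peak
lists produce empty selections and score nothing; spectra missing a
charge are assumed 2+; FASTA records with non-canonical residues are
kept, but peptides spanning them are skipped; a peptide found in both
target and decoy proteins (palindromic cases) is kept as a target and
never used as a negative example. Index serialization is a documented
little-endian flat layout and is byte-stable across save/load cycles.
The mzML reader is a small lxml-based parser of the PSI 1.1 schema
(MS2 scans, 32/64-bit float arrays, optional zlib), sufficient for
centroided DDA input; MGF is the primary text format.

## Known limitations

Single-threaded reference implementation (the per-spectrum reduction is
already order-independent, so parallelization would not change results);
no semi- or non-specific digestion, a/c/x/z ions, neutral losses, or
PTM-site localization scores; no expectation-value calibration (by
design — the discriminant replaces it); protein inference is accession-level
best-peptide with no parsimony grouping; open-modification Δm values are
reported but not annotated against a modification database.
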
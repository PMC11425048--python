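# pepsearch

Full-database peptide-spectrum matching for DDA (data-dependent
acquisition) shotgun proteomics, with an inverted index over the
*experimental* spectra and learned target-decoy validation.

## The problem

A bottom-up proteomics experiment digests proteins into peptides and
fragments selected precursor ions, producing tens to hundreds of thousands
of MS2 spectra. A search engine must decide, for each spectrum, which
peptide (possibly carrying post-translational modifications) produced it.
Conventional engines keep this tractable by restricting the precursor mass
error — to tens of ppm (narrow search) or a few hundred Da (open search) —
and by capping variable modifications per peptide at about three. Both
restrictions limit what the data can be made to say: modified or unusual
peptides whose precursor mass falls outside the window are never even
considered.

`pepsearch` removes the precursor-mass gate entirely. Every in-silico
peptide of the FASTA database, with up to 20 variable-modification sites
enumerated in full (2^n forms; beyond 20 sites, all forms with at most 3
modifications), is scored against **all** spectra of the run. This is
affordable because the engine inverts the usual indexing direction:
instead of indexing the astronomically large theoretical fragment space,
it builds an inverted index over the run's fragment peaks,

```
bin(fragment m/z)  ->  [(spectrum id, peak intensity), ...]
```

whose memory footprint depends only on the number of spectra — never on
the database or the modification load. Theoretical b/y ions are generated
on the fly per candidate and exist only long enough to be looked up.

## Scoring and validation

For a candidate peptide with matched fragment counts `Nb, Ny` and matched
intensity sums `ΣIb, ΣIy` in a spectrum:

* **hyperscore** (X!Tandem lineage):
  `H = ln(Nb! · Ny! · max(ΣIb,1) · max(ΣIy,1))`
* **xcorr** (SEQUEST/Comet fast form, on the same bin grid): the dot
  product of the theoretical ion bins with the background-subtracted
  spectrum `y'[b] = y[b] − (1/151) Σ_{τ=−75..75} y[b+τ]`, after
  square-root intensity scaling normalized to 50 within 10 m/z windows.

Spectra with fewer than 4 matched ions are dropped; the best match per
spectrum is kept (max H, ties by xcorr). Because precursor mass never
gated the search, the reported mass difference Δm spans the full window
(default −6000 to +4500 Da) and is itself informative.

Validation is learned per run, never transferred: target precursors
passing a 1% hyperscore-ranked FDR become positives, all decoy matches
(reversed-protein peptides) become negatives; a 63-dimensional
composition encoding feeds a retention-time regressor, and match features
plus the RT prediction error feed a small discriminant network. Records
are ranked by the discriminant score and q-values are computed by
target-decoy competition at the PSM, peptide, and protein levels
(`q(i) = min_{j≥i} #decoys/#targets` down the ranked list).

## Worked example

Everything is runnable without external data via the built-in DDA
simulator, which emits a FASTA database, an MGF run with known
ground-truth peptides, noise peaks, m/z error, and an additive
retention-time model:

```sh
pepsearch simulate --out-dir demo --seed 7 --n-proteins 50 --n-spectra 300
pepsearch search   --spectra demo/run.mgf --fasta demo/proteome.fasta \
                   --out-dir demo --seed 7
pepsearch validate --out-dir demo --seed 7
```

prints

```
wrote 50 proteins, 300 spectra (228 with signal) to demo
wrote 228 PSMs to demo/psm.tsv
reported 217 peptides, 49 proteins at q <= 0.01 (hyperscore fallback)
```

Of the 300 simulated spectra, 228 carry true peptide signal and exactly
those 228 receive a best match (the 4-matched-ion floor discards the pure
noise spectra); 217 unique peptides and 49 of the 50 proteins pass the 1%
FDR threshold. "hyperscore fallback" reports that on this small, clean run
no decoy peptide ever reached 4 matched ions, so there were no negative
examples to train the discriminant on and ranking fell back to the raw
hyperscore — the designed behavior when the decoy side is empty. A first
row of `demo/psm.tsv`:

```
spectrum_id  retention_time  charge  peptide                           ...  hyperscore  xcorr      delta_mass
1            3623.3569       3       HTFNINGMGRFHALALVQMFVAECIEEVMRMR  ...  287.128497  3060.0663  -0.002008
```

reads: spectrum 1 is matched to the carbamidomethylated peptide shown,
with a mass difference of −2 mDa between observed precursor and candidate
— a correct identification of the simulated ground truth.

The same stages are available as library calls (`pepsearch.run_search`,
`pepsearch.run_validation`, `pepsearch.search_all`, ...) for use from
Python.

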
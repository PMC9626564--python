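# Methods

## In-silico digestion

Recognition sites are IUPAC-degenerate patterns with a blunt-cut offset
(`GAANN^NNTTC` → offset 5). Coordinates are 0-based, half-open, on the top
strand; a cut coordinate is the position immediately before which both
strands are cleaved. Circular genomes are scanned with the first
pattern-length−1 bases appended so windows spanning the sequence origin are
seen, and coordinates are reduced modulo the genome length; the fragment
spanning the origin is stored with `end > genome_length`. Both strands are
scanned (the built-in AleI, PshAI, XmnI and PvuII patterns are their own
degenerate reverse complements, so the second scan is a consistency check,
not a source of new sites); overlapping windows that imply the same
coordinate are counted once, overlapping windows with different coordinates
separately. Genome `N` bases never match any pattern position — phantom
sites from ambiguity are considered worse than missed sites in an
assembly gap. Only blunt cutters are supported; overhang chemistry is an
extension point, not a parameter.

Duplicate fragments — identical canonical sequence, where canonical means
the lexicographic minimum of a sequence and its reverse complement — are
collapsed to one reference entry with a `copy_count`, because an aligner
cannot distinguish them; in a real bacterial genome these arise in the
ribosomal repeat regions. 3'-terminal classes are unordered: the left end's
3' base lies on the bottom strand (complement of the fragment's first base),
the right end's on the top strand (last base); 10 unordered single-base
pairs exist, 136 dinucleotide pairs.

## Counting and normalization

Read→fragment assignment is the aligner's reference name — the reference is
built with one entry per predicted fragment, so no positional re-assignment
is needed or attempted. A read with ≥ 1 supplementary alignment is the
signature of an incompletely digested, chimeric molecule and is dropped with
all its records; secondary and unmapped records are never counted; each
surviving read contributes its single primary record (two primaries for one
read id is treated as malformed input, not silently resolved). Zero-count
fragments stay in every table: the full inventory is the denominator for
threshold summaries.

`freq_pct` (sums to 100), `rpm` (sums to 1e6) and `rpkm = rpm/(L/1000)` are
computed per library. "Observed length" is the query read length; the
aligned span is recorded separately (for intact single-molecule reads they
coincide). A fragment whose median observed length falls below 0.9·L is
flagged shear-suspect; the 0.9 is a reporting convention, configurable, not
an estimate. Coverage profiles use equal-width bins over [0, L) normalized
to the maximum depth over all fragments of the genome source (a per-fragment
option exists; the per-source choice makes profiles of different fragments
of one DNA comparable).

## Bias quantification

CV-by-length uses sample SD / mean of `freq_pct` in 500 bp bins (≥ 2
members). End-bias cells are (end class × length bin) with mean raw count
and CV; default bins are 401–1000 bp then 1000-wide to 10 kb, and cells with
≤ 5 fragments are suppressed as unstable. Raw counts are the primary
response (frequency available by flag); class orderings are invariant to
uniform library rescaling either way. The class-level summary weights each
bin by its fragment count.

## Replication gradients

Per-fragment ratio = `freq_pct(A)/freq_pct(B)` after within-sample
normalization, which cancels sequencing depth exactly. Fragments with zero
frequency in either condition are excluded and counted. Tracks: unweighted
mean per fixed genomic bin (default 100 kb, circular tiling, fragments
assigned by midpoint), or a fragment-length-weighted rolling window of k
adjacent fragments (default 50) — length weighting because long fragments
average the copy-number profile over more of the genome and carry more
reads. Extremum positions are reported both as bin starts and as the
midpoint of the strongest member fragment, since either convention is
defensible.

Significance of an origin-vs-terminus difference uses a two-sided
permutation test on the difference of mean ratios over two disjoint windows
(fixed genomic distance or fixed fragment count around each position), with
the add-one estimator p = (1 + #{|d*| ≥ |d|})/(n_perm + 1). A permutation
test is the default because per-fragment ratios are neither normal nor
homoskedastic across lengths; Mann–Whitney U is available as an alternative
statistic. Under an exchangeable null the permutation p is uniform, and the
suite verifies the 5 % type-I error rate empirically over 1000 null
replicates (Monte Carlo SE ≈ 0.7 %).

## Spline calibration

The spike-in response is per-molecule frequency, `freq_pct/copy_count` —
duplicate-collapsed fragments receive the reads of every copy, and
equimolarity holds per molecule. Duplicate lengths are aggregated by mean
response before fitting (smoothing splines need distinct abscissae).

The cubic smoothing spline minimizes p·Σ(y−g)² + (1−p)·∫g″², implemented on
the equivalent objective Σ(y−g)² + λ∫g″² with λ = (1−p)/p; p = 1 (λ = 0)
interpolates, p = 0 is fitted directly as the least-squares line. The
natural-spline system needs ≥ 5 distinct abscissae; fewer is refused.

Two numerical choices matter and are worth stating plainly:

* **Log response by default (spike-in fitting).** Counts carry
  multiplicative noise (Poisson, CV ∝ 1/√count) over a ~20-fold dynamic
  range. Linear-space least squares is dominated by the mid-length peak and
  systematically misfits the steep short-fragment flank — in simulation the
  misfit failed to shrink with read depth. Fitting log frequency
  variance-stabilizes the problem; predictions are back-transformed. The
  bare estimator (`SplineCalibration`) defaults to a linear response so the
  p = 0 / p = 1 limits hold verbatim; the spike-in wrapper
  (`fit_calibration`, CLI) defaults to log with `--linear-y` available.
* **Interior-only leave-one-out selection.** When a boundary point is left
  out, predicting it is cubic *extrapolation*, whose variance at small λ is
  enormous; scoring boundary points drives the selection toward drastic
  over-smoothing (observed: 15 % rms truth misfit at 2×10⁵ reads).
  Scoring only interior points restores sensible selection (1.9 % rms at
  the same depth). The λ grid spans 10⁻⁴–10¹⁰ in 43 log steps.

Prediction clamps: below the training minimum, e(L_min) (splines
extrapolate poorly and the method's claims stop at ~200 bp); above
min(10 kb, training maximum), a constant plateau (read counts of longer
DNA are fairly flat, so modeling there adds nothing). Corrected abundances
are renormalized to sum to exactly 100; non-positive predicted efficiency
anywhere in the clamped range is a fatal model-quality error, never silently
floored. Models serialize to JSON with hex-encoded floats, so a reloaded
model predicts bit-identically.

## The synthetic-data generator

The simulator is the package's ground-truth instrument; its defaults are
the study conditions the analyses are tested under.

* **Length efficiency**: log-normal-shaped unimodal curves with floor 0.05,
  peaking at 4 kb (`short_prep`) or 10 kb (`long_prep`), width 0.75 in log
  space — a smooth stand-in for the SPRI-plus-sequencing length response;
  `flat` for null fixtures; any callable accepted.
* **End efficiency**: per-3'-base ligation multipliers, default A 0.41,
  T 0.8, G 0.9, C 1.0 (ordering A < T < G < C), composed multiplicatively
  over a fragment's two ends; the AA-vs-CC dinucleotide-pair deficit this
  induces, 1/0.41² ≈ 5.9-fold, matches the magnitude reported for
  ligation-based nanopore libraries.
* **Shearing**: molecule-level break count ~ Poisson(rate·L), breaks
  uniform, pieces tiling the molecule exactly; default rate when enabled
  1e-4/bp, which puts the mean-read-length plateau near 10 kb.
* **Incomplete digestion**: with probability 0.01 (0.07 is the AleI-like
  setting; both reflect reported digest-completion rates) a molecule spans
  two genomically adjacent fragments and is emitted as a primary plus a
  supplementary alignment — exactly the signature the filter removes.
* **Replication gradient**: copy number interpolating linearly (in circular
  distance, along both arcs) from `fold` at an origin to 1 at a terminus.
* **Transposase mode**: read count ∝ L (every internal position is an
  insertion opportunity); each read runs from a uniform internal start to a
  uniform end beyond it, so original length information is destroyed —
  RPM then grows with L while RPKM is length-flat.

Sampling is two-stage when shearing is on: molecules are drawn by molecular
abundance (copy number × duplicate copies), sheared, and each piece is then
retained with probability ∝ length-efficiency(piece length) × end
efficiency — library preparation sees the sheared piece, not the original
molecule. This reproduces the mid-fragment coverage dip of long fragments
(interior positions sit in size-biased longer pieces, which a peaked
efficiency curve disfavors) and reduces *exactly* to per-fragment weights
abundance × e(L) × end efficiencies when shearing is off. Consequence: with
shearing enabled, `n_reads` is the molecule budget and emitted reads are
fewer; the truth table records both.

All randomness flows from one integer seed; regenerating a library with the
same seed reproduces every output file bit-exactly. SAM output is minimal
but valid (one @SQ per fragment, CIGAR `<len>M`, no sequences or qualities —
base-level realism is out of scope).

### What the generator does not emulate

Base-calling errors, mappability, adapter artifacts, CCS pass-number
effects, methylation-blocked sites, cosN concatemerization, or
condition-dependent shear rates. Passing tests therefore demonstrate that
the *computations* are correct and that the method recovers known inputs
under its stated bias mechanisms — not that real libraries obey those
mechanisms quantitatively.

## Problem sizes

Test fixtures use random genomes of 80 kb–1 Mb (tens to ~250 XmnI
fragments), libraries of 2×10⁴–4×10⁵ reads, 1000-replicate null studies for
the type-I check, and 200 random genomes up to 50 kb for the
digestion-oracle property; these sizes give per-fragment counts in the
hundreds-to-thousands, the same counting regime as a real run, while the
whole suite stays fast. The digestion checks against the published
four-enzyme inventory of the real 4.64 Mb MG1655 genome run only when the
reference FASTAs are present under `data/` (see README); everything else is
generated at run time.

## Known limitations

* The calibration corrects length bias only; end-base and pass-number
  biases are quantified but not corrected (a length-only model is what a
  spike-in of different sequence composition can support).
* Efficiency below the training minimum and above 10 kb is clamped, not
  modeled; abundance estimates there are flagged and only indicative.
* `collapse_unique` groups exact canonical-sequence duplicates only;
  near-identical fragments that confuse an aligner in practice are not
  detected.
* The permutation test treats fragments as exchangeable units; spatial
  autocorrelation of copy number within a window is not modeled (windows
  are compared, not single fragments, which blunts but does not remove
  this).
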
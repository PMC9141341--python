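# Methods

## The statistic

`hexaw` measures how unevenly 6-base words (hexamers) occur in a set of coding
sequences (CDS).  For one CDS set it computes two indices, W1 and W2, built
from three ranked hexamer spectra:

1. **Counting.**  Every CDS is scanned with 6-base windows starting at 1-based
   in-frame positions 1, 4, 7, …, l−5 (3-base step, so consecutive windows
   overlap by one codon and both codon phases of every hexamer are sampled).
   Each window increments one cell of a 4096-cell array; counts accumulate
   over all CDS of the set, never across record boundaries.  A window maps to
   its cell by reading the hexamer as a little-endian base-4 number with
   a=1, t=2, c=3, g=4.
2. **Normalisation and ranking.**  The array is scaled to a fixed total of
   10⁶ (removing set size from the comparison) and sorted ascending.  The
   ranked observed spectrum is Q1.  Ranking is the same device used in
   Gini-coefficient curves: cell identity is deliberately discarded, so only
   the shape of the frequency distribution matters and local unevenness at
   particular words cannot dominate the index.
3. **Null models.**  Two Monte Carlo baselines are built by re-shuffling each
   CDS `replicates` times (default 100), accumulating window counts over
   replicates, dividing by the replicate count, then normalising and ranking
   (averaging strictly precedes ranking):
   * **R1** — each replicate permutes the bases of the CDS uniformly at
     random, subject to the constraint that no stop codon (default
     taa/tag/tga, configurable for other genetic codes) appears at an
     in-frame codon position.  Base composition is conserved exactly.
   * **T1** — each replicate permutes the codons of the CDS.  Codon usage is
     conserved exactly.
4. **Divergence.**  Q1 and a null are stacked into a 2×4096 table M and
   compared with the mutual-information statistic (natural logs, 0 ln 0 = 0)

       I = Σ m ln m − Σ x ln x − Σ y ln y + L ln L,

   where x, y are row/column sums and L = 2×10⁶ the grand total.  2I is the
   G statistic of the table, approximately χ² under row–column independence.
   Fisher's square-root normal approximation maps it to the reported scale:

       W = √(4I) − √(2·df − 1).

   W1 = W(Q1 vs R1) and W2 = W(Q1 vs T1).  W1 responds to triplet
   periodicity plus all longer correlations; W2 only to correlations spanning
   six bases or more, because codon shuffling already reproduces everything
   attributable to codon usage.

A per-word z statistic, z = (N − Sum·p)/√(Sum·p(1−p)), is provided for the
small pedagogical cases where a single word's count is compared against a
binomial expectation; p = 1 (a certain word) returns 0 by convention.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| word length / step | 6 / 3 | the published method; both configurable (word length must be a multiple of the step) but 6/3 is the tested configuration |
| `replicates` | 100 | null-model replicates per CDS; averaging before ranking suppresses Monte Carlo fluctuation in R1/T1 |
| `df` | 4095 | degrees of freedom in the W transform, the standard (rows−1)(cols−1) of a 2×4096 table; shifts W by a constant-like offset only |
| `stop_codons` | taa, tag, tga | the codons the base shuffle must not create in frame; configurable for alternative genetic codes |
| `threshold` | 475 | two-group boundary on W1 (boundary value assigned to group 2); 425 is a defensible alternative given the bimodal bacterial W1 distribution, and is settable by flag |
| `seed` | 1 | root of all randomness; replicate streams are derived per (seed, null mode, CDS index, replicate index), so results are bit-reproducible and independent of iteration order |

At df = 4095 the floor of W (identical spectra, I = 0) is −√8189 ≈ −90.49.
Historical presentations of this index quote a floor of −89.7 and a
theoretical maximum near 7400 together with "4095 × 15" degrees of freedom;
those numbers are mutually inconsistent with the transform above (a −89.7
floor would imply df ≈ 4024) and are not reproduced here.  The df choice
moves W by under one unit against a working range of hundreds.

## Numerical and procedural choices

* Normalised and averaged spectra are kept real-valued; the statistic needs
  no integrality and the χ² interpretation is approximate either way.
* Ranking uses a stable sort; ties cannot affect I, which is invariant to
  permutations of equal values.
* I is clipped to 0 when rounding residue makes it negative by less than
  10⁻⁹·L; a larger negative value raises.
* The stop-avoiding shuffle draws a full Fisher–Yates permutation and then
  repairs: each remaining in-frame stop has one of its three bases swapped
  with a uniformly chosen position, rescanning until clean or until the
  budget (default 10× sequence length) is exhausted.  The output is
  approximately, not exactly, uniform over stop-free permutations; the
  residual bias is negligible for rank statistics.  A CDS whose composition
  (nearly) forces stops is excluded from Q1, R1 and T1 alike and reported,
  so the three spectra always describe the same material.
* The constraint is enforced in reading frame 1 only — the only frame the
  counting method uses.
* Shuffling is a permutation (composition-preserving), not an i.i.d. redraw
  from base frequencies; for long sequences the two agree closely.
* Preprocessing: case-fold, U→T, trim 1–2 trailing bases restoring a
  multiple-of-3 length, then strip trailing stop codons repeatedly until none
  remains.  Repeated stripping makes preprocessing idempotent; for biological
  CDS (one terminal stop) it is identical to a single strip.  Records with
  ambiguity codes are dropped by default; an opt-in policy masks them and
  skips only the affected windows.  Internal in-frame stops are *not*
  filtered (selenoproteins, pseudogenes); they simply contribute their words.
* Degenerate inputs: zero-total spectra, empty sets, p = 0 with a positive
  observed count, and mismatched spectrum shapes are hard errors.

## The synthetic-data generator

`generate_cds_set` draws codons i.i.d. from a weight table over the 61 sense
codons (stop codons are required to have weight 0); `hexamer_coupling` makes
each codon copy its predecessor with the given probability, a deliberately
transparent Markov device that injects correlations of six bases and longer —
exactly the structure that survives codon shuffling and therefore drives W2.
`skewed_codon_weights(strength)` exponentiates a fixed standard-normal draw
per codon, so one dial sharpens a single usage pattern monotonically.
Deterministic constructors reproduce the pedagogical sequences: the
atc-triplet repeat (pure triplet periodicity), the tttccc repeat (triplet plus
6-base periodicity), and the 900-nt gene with all 90 t bases in one
frame-aligned run (29 tttttt windows out of 299, asserted at construction).

What the generator does **not** emulate: amino-acid-level selection, GC
gradients along genes, length distributions of real genomes, horizontal
transfer mosaicism.  Passing tests therefore demonstrate the statistic's
internal laws (conservation, determinism, monotone response to bias and
coupling), not any claim about particular organisms.

## Sample-size behaviour and scaled-down test regime

Because both rows of M are rescaled to 10⁶, the statistic's noise floor
depends on the real window count Sum: a single observed realisation differs
from the replicate-averaged null by sampling noise whose contribution to I
grows like 10⁶/Sum.  Real genomes (Sum ~ 10⁶ windows) resolve the floor;
small synthetic sets do not.  The test suite uses sets of 30 CDS × 900 nt
(~9×10³ windows) for the monotonicity checks, 20–50 null replicates, and one
larger 300 CDS × 1800 nt run (~1.8×10⁵ windows) to show W2 of an
uncorrelated codon stream decaying toward the floor and below the lower edge
(~170) of the range seen for real genomes.  These sizes were chosen so the
whole suite runs in well under a minute of statistics time while every
qualitative law is resolved far beyond its seed-to-seed noise.

## Known limitations

* The χ²/normal reading of W is approximate: entries of M are real-valued,
  rows are not independent multinomials, and ranking induces correlation
  between cells.  W is used as an index, not as a calibrated p-value.
* The repair-based stop-free shuffle is not an exact uniform sampler of the
  constrained permutation polytope.
* W values from scaled-down CDS sets are not comparable with genome-scale
  values without accounting for the 10⁶/Sum noise term above.
* The two-group boundary on W1 is descriptive, not a fitted classifier; both
  475 and 425 are defensible and the package only applies whichever it is
  given.
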
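# Methods

This note documents the models, conventions and numerical choices
implemented in `tmhflank`, and their limitations. Everything stated about
behaviour here is implemented and tested; no empirical claims are made
about biological datasets that the package has not computed.

## Coordinates and orientation

Internally all coordinates are 0-based half-open; both supported file
formats use 1-based inclusive coordinates on disk and are converted at the
I/O boundary.

A helix's orientation is resolved from its nearest flanking topology
domains: if the nearest *preceding* domain label contains the substring
"cytoplasmic" (case-insensitive), the helix is kept as annotated; if the
nearest *following* domain does, the helix (and its flanks) is reversed so
that every stored segment reads inside → outside; if neither does, the
helix is omitted. Both adjacent domains claiming the cytoplasmic side is a
record-level inconsistency and is reported as such. Omissions and
inconsistencies are counted in the extraction ledger, never silently
dropped.

Limitation: with a zero-length loop between consecutive helices the
nearest labelled domain lies beyond the neighbouring helix, and the literal
nearest-domain rule can assign both helices the same orientation even
though membrane topology must alternate. The extractor emits a warning
when consecutive kept helices share an orientation; resolving the conflict
is left to the annotation source.

## Length filter and flank regimes

Helix cores of 16–38 residues (inclusive) are analysed; the filter is
applied before orientation so that ledger categories are well defined.

* `db_no_overlap` — flanks extend up to `max_flank` (default 10) residues
  beyond the annotated helix boundary. A loop of length L shared with a
  neighbouring membrane feature (TRANSMEM or INTRAMEM) contributes
  ⌊L/2⌋ residues to each adjoining flank; the middle residue of an odd
  loop belongs to neither flank.
* `db_overlap` — flanks extend to `max_flank` regardless of the
  neighbouring helix's flank, but never into a membrane core.
* `db_viable` — as `db_no_overlap`, keeping only helices whose flanks on
  *both* sides reach ⌈`viable_fraction` · `max_flank`⌉ residues
  (default 5 of 10).
* `central` — helices are aligned on the central residue of the core
  (position 0); the segment is the window ±`central_half_width`, clipped
  at protein termini and at the no-overlap flank limits. For even-length
  cores the earlier (cytoplasmic-side) of the two middle residues is the
  centre by default (`even_center="lower"`).

Leaflet splits divide the core into equal inner and outer halves; the
central residue of an odd-length core belongs to neither half by default.

## Profile normalizations

With `a[i, r]` the count of residue type i at aligned position r:

1. **Absolute relative occurrence** `p[i, r] = a[i, r] / max_r(a_r)`,
   where the denominator is the largest alignment-column total (the depth
   at full coverage). Positions with zero coverage are reported as
   missing, not zero.
2. **Relative percentage** `q[i, r] = 100 · a[i, r] / a_i`, with `a_i`
   the total abundance of type i over the whole region; sums to 100 over
   positions. For a type that never occurs the curve is *undefined* and
   raising is preferred over fabricating zeros.
3. **Net charge** `c_r = ((a_K + a_R) − (a_D + a_E)) / N` per helix, all
   other residues neutral.
4. **Background** is the unweighted mean of a profile over positions
   −30…−25 and +25…+30; flank averages use −20…−10 and +10…+20
   (inclusive, 11 positions each).

Nonstandard residue letters (B, Z, X, U, O) count toward column coverage
but belong to no residue-type row; in strict mode they raise.

## Hydrophobicity

Four published scales ship with the package (Kyte-Doolittle;
White-Wimley octanol; Hessa biological; Eisenberg consensus), cited in the
data file. Windowed hydropathy uses an unweighted window (default 3)
clipped at segment ends — partial windows average over the residues
available — and the window runs end to end over flanks + core, so flank
residues inform core-edge windows. Curves are stratified by TMH-count
class (1, 2, …, 14, 15+). Per-position group comparisons use the
two-group rank test or Welch's t test; positions with fewer than two
values in either group are skipped.

## Statistics

* **Two-group Kruskal-Wallis** with the standard tie correction. Below 9
  observations per group the p value is computed by exhaustive permutation
  (all label assignments) instead of the χ²₁ approximation; all-identical
  data yield (H = 0, p = 1). For inside/outside comparisons the reported
  statistic carries a sign: positive for an outside excess (mean outside >
  mean inside), negative for an inside excess.
* **χ² homogeneity** on 2 × R position-count tables. Adjacent columns are
  pooled left to right until every expected count is ≥ 1 (a trailing
  remainder is merged into the last pooled column); a table that collapses
  below two columns is reported as degenerate rather than tested.
* **Kolmogorov-Smirnov** via scipy on per-occurrence position samples.
* **N conventions**: for occurrence-level tests N is the total number of
  residue-class occurrences in both groups; for per-helix count tests N is
  the number of helices (or proteins, when aggregated per protein).
* **Bahadur slope** `B = |ln p| / N`, zero at p = 1, reported with every
  test; underflowed p (= 0) yields an infinite slope flag rather than a
  fabricated number. Benjamini-Hochberg q values are available as an
  optional extra column; raw p values are the primary report.
* Degenerate inputs (an empty group, a single helix) raise a typed error;
  the pipeline converts these into skip rows carrying the reason.

## Synthetic cohort generator

Residues are drawn independently from per-region propensity vectors over
seven region classes on the inside → outside axis (distal inside, inside
flank, inner leaflet, centre, outer leaflet, outside flank, distal
outside), plus interfacial "belt" variants of the three core classes at
the outermost `belt_width` (default 3) core positions. Flank classes
cover loop residues within `flank_width` (default 10) of a membrane
boundary. Loops and tails use a globular-like background composition;
cores use a hydrophobic composition — both are modelling choices, not
measurements.

Multiplicative knobs bias the vectors before renormalization:
`k_pos_in` (K/R in the inside flank), `k_neg_in` / `k_neg_out` (D/E in
the inside / outside flank), `k_leu_core` (L in the core) with
`s_leu` as the inner/outer leaflet weight ratio (applied as ×√s and ÷√s),
and `k_aromatic_belt` (W/Y at belt positions). With every knob at 1 the
inside and outside flank distributions are *identical*, which is the null
construction used for calibration. `orientation_noise` is the probability
that a record's topology labels omit the "cytoplasmic" keyword, making the
record unusable for orientation.

The documented `preset_paperlike` sets knob magnitudes in the ranges
reported for real proteomes (2–3× positive-inside enrichment, 2–3× acidic
suppression inside with mild outside enrichment, an inner-leaflet leucine
ratio around 1.45, strong interfacial W/Y hotspots). These defaults are
study conditions, fixed in code; they were not adjusted against test
outcomes.

Scope and limitations of the generator: residues are i.i.d. within a
region class (no positional autocorrelation, no helical periodicity, no
sequence motifs); TMH counts, lengths, loop and tail lengths are drawn
from categorical distributions; topology alternates deterministically.
This is sufficient to exercise the counting, extraction and statistical
machinery with known ground truth, and is not a model of real membrane
protein evolution. The complexity classifier below is likewise a
pluggable approximation.

## Complexity classification

Single-pass helix cores are scored in the (mean hydrophobicity, Shannon
entropy) plane: score = meanH − 0.5 · (entropy − 2 bits), called
"simple" at score ≥ 1, "complex" at ≤ 0, "twilight" between. Both
features are order-free, so calls are invariant under core reversal. The
boundary is a documented, configurable approximation — externally produced
three-way calls can be imported from TSV instead.

## Determinism and reporting

Cohort generation uses `numpy.random.default_rng(seed)`; identical config
and seed give identical records and byte-identical serialized output.
Report bundles are long-format TSVs written with a fixed float format;
identical inputs give byte-identical bundles, and every row carries the
dataset label and a 16-hex-digit hash of the run configuration.
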
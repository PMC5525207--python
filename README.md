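# tmhflank

Genome-scale positional composition analysis of transmembrane helices
(TMHs) and their flanking loops.

## The science

Membrane proteins thread their helices through the lipid bilayer with a
strong, measurable asymmetry between the cytoplasmic ("inside") and the
non-cytoplasmic ("outside") face. The best-known signal is the
**positive-inside rule**: lysine and arginine pile up on the cytoplasmic
flank. Its acidic counterpart is subtler — aspartate and glutamate are
**depleted** from the cytoplasmic flank and mildly enriched outside — and
there are further layers: tryptophan/tyrosine hotspots at the
membrane-water interfaces, a leucine excess in the inner (cytoplasmic-side)
leaflet of the helix core, and higher overall hydrophobicity in single-pass
than multi-pass helices.

Detecting these signals at genome scale is mostly a problem of careful
bookkeeping, which is what this package implements:

* **Orientation normalization.** Every annotated helix is placed on a
  common inside → outside axis using the topology annotation of its
  flanking domains; helices whose cytoplasmic side follows them in the
  sequence are reversed, and helices without a resolvable orientation are
  omitted — with every decision recorded in an extraction ledger.
* **Flank regimes.** Loops shared between neighbouring helices can be
  split evenly (no-overlap), used fully by both helices (overlap), or
  required to reach a minimum length on both sides (viable). A fourth
  regime aligns helices on their central residue for profile work.
* **Two normalizations.** Per-position counts `a[i, r]` become either the
  *absolute relative occurrence* `a[i, r] / max_r(a_r)` (how common is the
  residue here?) or the *relative percentage* `100 · a[i, r] / a_i` (given
  that the residue occurs, where?). The second sums to 100 over positions
  and makes rare residues visible.
* **Statistics.** Two-group rank tests (exact permutation p below 9
  observations per group), Kolmogorov-Smirnov, and χ² homogeneity with
  low-count column pooling — each reported with the **Bahadur slope**
  `|ln p| / N`, a sample-size-independent strength of evidence.
* **Synthetic cohorts.** A generator with explicit bias knobs (positive
  inside, acidic in/out, leucine leaflet skew, aromatic belt) produces
  annotated cohorts with known ground truth, used to calibrate the tests
  under the null and to check that the pipeline recovers injected skews.

## Worked example

The classic normalization example — 1705 aligned helices, 91 glutamates at
position +12, 22 at −12, 615 glutamates in total
(`examples/01_worked_normalization.py`):

```
aligned segments : 1705
glutamates total : 615
position +12: absolute relative occurrence = 0.053, relative percentage (fraction) = 0.148
position -12: absolute relative occurrence = 0.013, relative percentage (fraction) = 0.036
sum of q over positions: 100.0
```

Testing the charge skews on a synthetic cohort with known biases
(`examples/03_charge_skew.py`):

```
945 oriented helices

 class  inside  outside   signed H          p   Bahadur direction
    KR    2396     1054     -490.6  1.03e-108    0.1316 inside_excess
    DE     431     1301      404.0   7.52e-90    0.1086 outside_excess
     K    1197      543     -238.8   7.23e-54    0.0647 inside_excess
     R    1199      511     -255.8   1.40e-57    0.0693 inside_excess
     D     198      598      188.8   5.69e-43    0.0515 outside_excess
     E     233      703      206.2   9.22e-47    0.0561 outside_excess
```

The signed H statistic is negative for a cytoplasmic (inside) excess. Both
canonical skews — K/R inside, D/E outside — come out with the expected
directions, matching the biases injected by the generator preset.

More narrative scripts live in `examples/`: cohort simulation and
extraction (`02`), hydrophobicity profiles stratified by TMH count (`04`),
and the full report bundle (`05`).

## Command line

A thin CLI wraps the library:

```
tmhflank simulate --preset paperlike --n-proteins 500 --seed 7 --out cohort.txt
tmhflank extract cohort.txt --regime db_no_overlap --fasta segments.fasta
tmhflank run cohort.txt --outdir report/
tmhflank compare cohort.txt --grouping simple_vs_complex_vs_multi --out cmp.tsv
```

`run` writes a bundle of long-format TSV tables (extraction ledger, flank
skews under all regimes, leaflet asymmetry, positional profiles, net
charge, hydrophobicity curves with per-position p values), each row tagged
with the run's config hash. Identical inputs give byte-identical bundles.

## Data formats

* A **minimal UniProt-text-like flat file** (`ID`/`CC`/`FT`/`SQ`/`//`
  lines; `TRANSMEM`, `INTRAMEM` and `TOPO_DOM` features; coordinates
  1-based inclusive on disk). Unknown line types and feature kinds are
  ignored, so genuine UniProt text largely parses.
* A **TSV segment table** (`accession`, `sequence`, `tmh_spans`,
  `orientations` with per-helix `in_before`/`in_after`/`unknown` flags).
* FASTA export of oriented segments (flanks lowercase, core uppercase).

Malformed records are collected as per-record errors, never silently
dropped.

## Reproduction

```
pip install --no-build-isolation -e .
python -m pytest tests/                      # full suite incl. acceptance (~1 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion,
including a 500-replicate null-calibration study and a 20-seed recovery
study on the documented generator preset. `scripts/acceptance.py`
recomputes the worked-example target values at runtime and writes them as
JSON.

Methodological details, modelling choices and limitations are documented in
[docs/methods.md](docs/methods.md).
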
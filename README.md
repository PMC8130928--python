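# bovidzooms

A toolkit for Zooarchaeology by Mass Spectrometry (ZooMS) of African
bovids: peptide mass fingerprinting of bone collagen for taxonomic
identification of fragmentary skeletal remains.

Sub-Saharan Africa hosts the richest bovid fauna on Earth, and highly
fragmented archaeofaunal assemblages there are often identifiable only as
"large mammal" or "medium bovid" by morphology. ZooMS identifies such
fragments from the masses of tryptic collagen (I) peptides measured by
MALDI-TOF-MS: a handful of marker peptides, named P1, P2, A-G (with
`A/A'`-style +16 Da hydroxylation pairs) plus two markers named by chain
coordinates (COL1α2 375 and COL1α2 889-906), differ in sequence between
bovid groups and act as a fingerprint. This package bundles a complete
reference marker panel for all African bovid tribes (20 taxon groups, 12
marker loci) and implements everything needed to use, audit and extend
it:

* **`chem`** — monoisotopic `[M+H]+` arithmetic with hydroxylation
  (+15.9949 Da on P/K) and deamidation (+0.98402 Da on N/Q) counts, the
  floor-based nominal-m/z convention, and a Poisson isotope-envelope
  model.
* **`digestion`** — in-silico tryptic digestion with missed cleavages
  and the dual-form behaviour at K/R-P sites (both the cleaved and the
  read-through peptide are emitted, e.g. COL1α2 375-386 *and* 375-396).
* **`panel`** — the taxa × loci table of expected nominal masses with
  per-value reliability flags, validation, and ambiguity-class
  computation (which groups are indistinguishable by fingerprint alone).
* **`discovery`** — mapping marker loci through sequence alignments,
  novel-marker search at variant columns, collision/uniqueness checks,
  and the empirical promotion rules for new markers (present in >= 2
  individuals per species and > 75% of reference spectra).
* **`spectra`** — MALDI profile processing: baseline correction,
  Savitzky-Golay smoothing, S/N-based peak picking, deisotoping, and a
  collagen quality screen.
* **`synthetic`** — a seeded simulator of MALDI fingerprints (isotope
  envelopes, baseline, noise, calibration jitter, mass-dependent marker
  dropout) plus synthetic reference chains for testing the mapping
  machinery.
* **`classify`** — the identification engine: match a peak list against
  the panel and return a `full` / `partial` / `unknown_collagen` /
  `fail` call with the lowest unambiguous taxonomic label, optionally
  narrowed by the specimen's body-size class.

## Worked example

Simulate a water-buffalo-group (Bubalina) fingerprint, process it to a
peak list, and identify it:

```sh
$ bovidzooms simulate --taxon Bubalina --seed 7 -o bubalina.txt
wrote simulated Bubalina spectrum (29063 samples) to bubalina.txt
$ bovidzooms process-spectrum bubalina.txt -o bubalina_peaks.tsv
wrote 102 peaks to bubalina_peaks.tsv
$ bovidzooms classify bubalina_peaks.tsv -o results.tsv
counts: full=1 partial=0 unknown=0 fail=0
```

`results.tsv` then contains one row per sample:

```
sample              status  label     candidates  matched_loci  ...
bubalina_peaks.tsv  full    Bubalina  Bubalina    Bubalina:10   ...
```

The call is `full` because exactly one ambiguity class — Bubalina, i.e.
*Bubalus*/*Syncerus* — is consistent with every confidently observed
marker: among much else the B marker at m/z 1455 (vs 1427 in all other
bovids) and the G/G' pair at 3059/3075 separate African buffalo from
cattle. Ten marker loci were matched; the `conflicts` column records why
every other taxon was rejected.

The same library calls are available from Python:

```python
import bovidzooms as bz

panel = bz.load_panel()
bz.monoisotopic_mh("GIPGEFGLPGPAGAR", n_hydroxylations=2)  # 1427.7277 -> m/z 1427
classes = bz.ambiguity_classes(panel)  # 18 distinguishable groups of 20 taxa
```

Checking the panel against its own sequences (every printed marker mass
must regenerate from its peptide sequence and hydroxylation count):

```sh
$ bovidzooms validate-panel
panel ok: 20 taxa, 12 loci, 38 masses verified
```

## Data files

All reference data ship as editable TSVs under `src/bovidzooms/data/`:
the marker panel (`panel.tsv`, cells are integer m/z with `?` marking
caution values shared across bovids and `!` the unusable m/z 3017
collision), marker locus coordinates (`loci.tsv`), sequence-bearing
variants with hydroxylation counts (`variants.tsv`), shared
non-diagnostic peptides, common MALDI contaminants, and the body-size
class table used to narrow ambiguous calls.

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
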
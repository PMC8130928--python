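# Methods

## Mass arithmetic and the nominal-m/z convention

All masses are monoisotopic. A peptide's `[M+H]+` is the sum of its
residue masses (20-entry table in `data/residue_masses.tsv`, 5-decimal
standard values) plus water (18.0105647 Da) and a proton (1.0072765 Da).
Collagen PTMs are carried as counts, not sites: hydroxylation of proline
or lysine adds 15.9949 Da per site, deamidation of asparagine or
glutamine 0.98402 Da. Site assignment is irrelevant to a fingerprint
mass and is not modelled.

Marker masses are quoted as integer *nominal* m/z, defined as
`floor([M+H]+)`. This convention reproduces every integer mass in the
bundled panel from its sequence and stored hydroxylation count;
rounding half-up would not (e.g. 1150.63 would print as 1151). A
marker's `Mass'` form is the same peptide with one additional
hydroxylation, so `Mass' - Mass` is 15.9949 and the floors differ by 15
or 16.

Hydroxylation counts for the bundled variants were derived as the
smallest non-negative k for which `floor(base + 15.9949 k)` equals the
printed mass; because each oxidation moves the floor by 15-16, k is
unique, and a test asserts this for every variant.

## Isotope envelopes

Envelope peaks sit at `mh + k * 1.0033548` (the 13C-12C spacing), charge
1 only. Relative intensities follow a Poisson model with rate
`lambda = 5.2e-4 * mh`: an averagine-style closed form for the expected
number of heavy isotopes, dominated by 13C (~4.94 carbons per 111.13 Da
at 1.07% abundance) with a small 15N correction. The distribution is
unimodal; above ~1900 Da the first isotopologue overtakes the
monoisotopic peak, which the deisotoper must (and does) tolerate.

## Tryptic digestion

Cleavage is C-terminal of K/R, fully specific, with a configurable
missed-cleavage budget (default 2, the usual database-search setting).
K/R sites followed by proline are treated as *optional* cleavages: both
the cleaved and the read-through product are emitted, and the
read-through does not count against the missed-cleavage budget (it is
flagged `follows_proline_site` instead). This models the observed
behaviour at the COL1α2 375 marker, where both the 375-386 and the
375-396 peptide appear in real digests; the alternative (Keil-rule
suppression, never cleaving before P) would lose the short form.
Digestion is validated against a brute-force substring oracle on
hundreds of random sequences.

PTM enumeration per peptide runs hydroxylations from 0 to
`min(count(P) + count(K), 6)`; the cap bounds combinatorics on long
collagen peptides and is configurable. Deamidation enumeration is off by
default. The fingerprint mass window is 800-3500 Da.

## The marker panel

The panel is data, not code: one TSV row per taxon group (20 rows
covering all African bovid tribes, sheep, goat, and the Tibetan
antelope), one column per marker value (16 columns over 12 loci; paired
`Mass/Mass'` columns belong to one locus). Cells are integer nominal
masses with two per-value flags:

* `?` (caution) — the peak at this mass also contains a non-diagnostic
  peptide present in essentially all bovids, so its presence carries no
  taxonomic information. Applies to m/z 1560 at the 889-906 locus, and
  to 1182/2056/2072 at the 375 locus.
* `!` (unusable) — m/z 3017: two co-occurring peptides (a diagnostic
  COL1α2 757-789 variant at 4 hydroxylations and a conserved COL1α2
  89-130 peptide at 5) floor to the same nominal mass, so the peak can
  never be attributed. The collision is machine-checked from the two
  sequences. The +16 partner at 3033 contains only the diagnostic
  peptide and remains usable.

Four loci (P1, P2, D, E) are shared by every bovid with invariant masses
1105/1648/2131/2792; the loader enforces this. These loci are
nominal-only in this release (no bundled sequences); where an exact mass
is needed (simulation), a synthetic fractional mass of +0.61 — the
typical mass defect of collagen peptides in this window — stands in and
is matched by a floor-based rule, so the convention is internally
consistent.

Sequence-backed cells carry exact masses derived from their variant
sequence and hydroxylation count, and `regenerate_panel_masses` recomputes
every one of them (38 Mass/Mass' values) plus the coverage of every cell,
failing loudly on any drift between the table and the sequences.

### Ambiguity classes

Two taxa are indistinguishable when their profiles, restricted to usable
(unflagged) values, are identical; `ambiguity_classes` partitions the
panel accordingly (18 classes among the 20 rows; the impala, the
gazelle group and the oribi/steenbok group merge into one class).
Caution values never separate taxa: a group whose only distinctive mass
is the unreliable 1560 still forms its own class only if some *usable*
value distinguishes it (presence of 1532 in the sibling group does).

## Spectrum processing

* **Baseline**: the m/z range is split into `precision` segments
  (default 52); each contributes an anchor at
  `min + (offset/100) * (median - min)` (default offset 39); anchors are
  linearly interpolated and subtracted. This is a percentile-based
  piecewise approximation whose two parameters play the roles of the
  "precision" and "relative offset" knobs of common MALDI software; no
  bit-for-bit agreement with any particular implementation is implied
  and nothing downstream depends on one.
* **Smoothing**: Savitzky-Golay, window specified in m/z (default 0.3)
  and converted to points from the median sample spacing, polynomial
  order 2. The corrected trace is kept signed through smoothing and
  clipped at zero only afterwards — clipping first would rectify the
  noise and inflate the false-peak rate.
* **Noise**: estimated *before* smoothing as 1.4826 x MAD of the
  high-frequency residual (corrected minus smoothed) over a sliding
  window of 501 points, interpolated to the full axis.
* **Peak picking**: local maxima of the smoothed trace, scored by height
  above the local background (sliding median), with an S/N threshold
  (default 3) and a relative-intensity threshold (default 1% of the base
  peak); apex m/z refined by 3-point parabolic interpolation.
* **Deisotoping**: chains of peaks spaced 1.0034 +- 0.1 m/z whose
  successive intensity ratios agree with the Poisson envelope model
  within 50% (relative) collapse to their first (monoisotopic) peak;
  charge 1 only.
* **Collagen screen**: a spectrum "has collagen" when at least 2 of the
  four shared markers (1105/1648/2131/2792) are present.

## Identification

Matching uses a 0.5 Da tolerance — the same window used when markers
are cross-confirmed between MALDI and LC-MS/MS data — against exact
masses where a sequence backs the value and the floor-based nominal rule
otherwise. The engine then applies, per taxon:

* **Evidence**: a locus is observed when one of the taxon's own usable
  values matches a peak (either member of a Mass/Mass' pair suffices).
  Caution and unusable values never score, in either direction.
* **Conflict (hard veto)**: a peak that matches another taxon's usable
  value at some locus, reaches S/N >= 6 (the reference-screening
  confidence threshold; near-threshold noise must never veto), and
  cannot be explained by *any* mass in the taxon's own fingerprint,
  removes the taxon.
* **Candidacy**: at least `min_loci` observed loci (default 3 — chosen
  so that shared-markers-only spectra yield a family-level partial call,
  never a positive identification) and zero conflicts.
* **Full-observation preference**: among candidates, those whose entire
  usable profile is present outrank those that would require additional,
  absent peaks. On clean spectra this separates groups that differ only
  by one group's extra usable marker (e.g. the two Tragelaphini groups);
  on degraded spectra, where no candidate is fully observed, the whole
  compatible set is kept.
* **Size constraint**: an optional body-size class (Brain's classes
  1-4, editable table) filters the candidate set; it is never evidence.
  Example: cattle and the common duiker share every marker below
  3000 Da, so a spectrum missing the G/G' region yields the
  Bovina/Sylvicapra pair — recording the specimen as size class >= 3
  resolves it to cattle.

Statuses: `full` iff the final candidate set equals one ambiguity class;
`partial` when several classes remain; `unknown_collagen` when the
collagen screen passes but no profile is consistent; `fail` when it does
not. A `full` call can thus legitimately name a multi-taxon class
(reported as a slash-joined label); ties are never broken arbitrarily.

## The simulator

`simulate_spectrum` renders a taxon's complete expected fingerprint —
panel masses including caution/unusable values plus the shared
non-diagnostic peptides, because all of these are real peaks in real
spectra — as Gaussian peaks (resolution m/FWHM = 8000, so 0.25 Da FWHM
at 2000), 4-peak Poisson isotope envelopes, an exponentially decaying
chemical baseline, additive Gaussian noise, per-envelope calibration
jitter (sigma 0.02 Da), a few random non-marker peaks (kept >= 3 Da from
every panel mass so simulation truth stays unambiguous), and
mass-dependent marker dropout: by default the drop probability ramps
linearly from 0 at the low-mass end to the configured maximum at the
high-mass end, reflecting that large collagen peptides are the first
casualties of diagenesis (a uniform profile is available). The grid
spans 795-3120 m/z at 0.08 Da; a seed fully determines the output, and
every generated envelope is listed in a truth record.

What the simulator does *not* emulate: matrix clusters and real
contaminant chemistry, deamidation-driven mass shifts in aged samples,
detector saturation, and mass-calibration drift beyond a per-peak
jitter. Passing round-trip tests therefore demonstrate internal
consistency of the pipeline under controlled degradation, not
performance on real archaeological spectra.

In round-trip testing (200 seeded draws across all 20 taxa at minimum
peak S/N 10 and dropout up to 0.1) a run counts as recovered when the
generating taxon is contained in a positive (`full` or `partial`) call:
with markers missing, the scientifically correct answer is a coarser
candidate set that still contains the truth, exactly as partial
identifications are used in practice. When dropout removes the single
peak that distinguishes two groups, the degraded spectrum is genuinely
identical to the sibling group's and no classifier could recover the
distinction; the mass-dependent dropout shape makes this rare for the
low-mass distinguishing markers.

## Numerical choices and degenerate inputs

Deisotoping never removes the first peak of an envelope and never grows
a peak list. Empty spectra pick to empty peak lists (not an error);
empty peak lists fail the collagen screen and classify as `fail`.
Tolerance boundaries are inclusive (`<= tol`). Peptides shorter than the
mass window, chains without K/R (single-peptide digest), all-gap locus
regions (reported missing, never fabricated) and candidate markers with
no background (trivially unique) are all covered by tests.

## Known limitations

* P1/P2/D/E are nominal-only; adding their sequences would tighten
  matching at these loci from the floor rule to exact masses.
* The reference chains bundled for mapping/discovery tests are
  synthetic scaffolds (marker peptides at their published coordinates
  joined by Gly-Ala-Arg filler), not real COL1 sequences; mapping
  behaviour on real alignments with indels is exercised only on toy
  examples.
* The panel covers the taxa studied to date; unstudied Cephalophinae
  and Antilopinae species may carry different marker masses, and calls
  should be read as "consistent with the panel", not as proof of
  species identity.
* Triplicate-spot merging is not modelled; each peak list is treated as
  one sample.
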
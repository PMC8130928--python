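"""Marker mapping and novel-marker discovery across aligned collagen chains.

The alignment itself is an input (pre-aligned protein FASTA, one row per
species); this module maps marker loci through the alignment, enumerates
variant-bearing tryptic peptides in the fingerprint mass window, checks
candidate masses for collisions against digest backgrounds and common
contaminants, and screens reference peak lists for the empirical presence
rules used when promoting a candidate to a diagnostic marker (found in at
least 2 individuals per species; present in more than 75% of reference
spectra overall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO

from .chem import PeptideVariant
from .digestion import CollagenChain, TrypticPeptide, digest
from .spectra import PeakList

__all__ = [
    "SiteMap",
    "CandidateMarker",
    "map_marker_loci",
    "find_variant_peptides",
    "check_uniqueness",
    "screen_reference_spectra",
    "load_contaminants",
    "filter_psm_table",
    "read_alignment_fasta",
]

GAP = "-"


@dataclass
class SiteMap:
    """Aligned chains (equal-length rows) with gap-aware position maps.

    Positions follow the reference species' chain numbering; columns are
    0-based alignment columns.
    """

    aligned: dict[str, str]
    reference: str
    chain_id: str = "COL1A2"
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.aligned.values()}
        if len(lengths) != 1:
            raise ValueError("aligned rows differ in length")
        if self.reference not in self.aligned:
            raise ValueError(f"reference species {self.reference!r} not in alignment")
        ref = self.aligned[self.reference]
        self._col_of_pos: dict[int, int] = {}
        pos = self.numbering_offset
        for col, aa in enumerate(ref):
            if aa != GAP:
                self._col_of_pos[pos] = col
                pos += 1

    def species(self) -> list[str]:
        return list(self.aligned)

    def column_of(self, position: int) -> int:
        return self._col_of_pos[position]

    def ungapped(self, species: str) -> str:
        return self.aligned[species].replace(GAP, "")

    def chain(self, species: str) -> CollagenChain:
        return CollagenChain(self.chain_id, species, self.ungapped(species), self.numbering_offset)

    def species_index_of_column(self, species: str, col: int) -> int | None:
        """0-based index into the ungapped species sequence, None on a gap."""
        row = self.aligned[species]
        if row[col] == GAP:
            return None
        return len(row[:col]) - row[:col].count(GAP)


@dataclass
class CandidateMarker:
    locus: tuple[int, int]  # reference coordinates, inclusive
    per_species: dict[str, TrypticPeptide]
    groups: dict[float, frozenset[str]] = field(default_factory=dict)  # base mass -> species
    unique: bool = True
    collisions: list[tuple[str, float]] = field(default_factory=list)
    warnings: list[tuple[str, float]] = field(default_factory=list)
    presence_fraction: float | None = None

    def masses_at(self, n_hydroxylations: int) -> dict[str, int]:
        """Nominal m/z per species at a fixed hydroxylation count."""
        return {
            sp: PeptideVariant(pep.sequence, n_hydroxylations).nominal_mz
            for sp, pep in self.per_species.items()
        }

    def all_masses(self) -> set[float]:
        out = set()
        for pep in self.per_species.values():
            n_oh = min(pep.sequence.count("P") + pep.sequence.count("K"), 6)
            for k in range(n_oh + 1):
                out.add(PeptideVariant(pep.sequence, k).mh_mass)
        return out


def _covering_peptides(chain: CollagenChain, lo: int, hi: int) -> list[TrypticPeptide]:
    """Tryptic peptides covering chain positions [lo, hi], preferring fewer
    missed cleavages, then shorter length (read-through forms included; up
    to 2 missed cleavages, matching the digest search settings)."""
    peps = [
        p
        for p in digest(chain, max_missed=2)
        if p.start <= lo and p.end >= hi
    ]
    return sorted(peps, key=lambda p: (p.missed_cleavages, len(p.sequence), p.start))


def map_marker_loci(
    site_map: SiteMap,
    loci: list[tuple[int, int]],
) -> dict[str, dict[tuple[int, int], TrypticPeptide | None]]:
    """Extract, per species, the homologous tryptic peptide spanning each locus.

    Peptide boundaries are recomputed from each species' own K/R sites.  A
    locus that falls in an all-gap region for a species is reported as
    None (missing), never fabricated.
    """
    results: dict[str, dict[tuple[int, int], TrypticPeptide | None]] = {}
    for sp in site_map.species():
        chain = site_map.chain(sp)
        per_locus: dict[tuple[int, int], TrypticPeptide | None] = {}
        for lo, hi in loci:
            cols = [site_map.column_of(p) for p in (lo, hi)]
            idx_lo = site_map.species_index_of_column(sp, cols[0])
            idx_hi = site_map.species_index_of_column(sp, cols[1])
            if idx_lo is None and idx_hi is None:
                per_locus[(lo, hi)] = None
                continue
            # map to this species' own coordinates, then find the tryptic
            # peptide of the species covering the region
            if idx_lo is None or idx_hi is None:
                per_locus[(lo, hi)] = None
                continue
            sp_lo = idx_lo + site_map.numbering_offset
            sp_hi = idx_hi + site_map.numbering_offset
            covering = _covering_peptides(chain, sp_lo, sp_hi)
            per_locus[(lo, hi)] = covering[0] if covering else None
        results[sp] = per_locus
    return results


def find_variant_peptides(
    site_map: SiteMap,
    min_mass: float = 800.0,
    max_mass: float = 3500.0,
) -> list[CandidateMarker]:
    """Candidate markers at every alignment position where species differ.

    For each variant column the containing tryptic peptides are collected
    per species (their own cleavage boundaries), peptides are merged into
    one candidate per distinct reference span, filtered to the mass
    window, and annotated with the species groups that each peptide
    sequence (hence mass) separates.  Ordering is by reference coordinate.
    """
    species = site_map.species()
    if len(species) < 2:
        raise ValueError("need at least 2 species to search for variants")
    ncol = len(site_map.aligned[species[0]])
    variant_cols = [
        c
        for c in range(ncol)
        if len({site_map.aligned[sp][c] for sp in species}) > 1
    ]
    chains = {sp: site_map.chain(sp) for sp in species}
    digests = {sp: digest(chains[sp], max_missed=0) for sp in species}

    candidates: dict[tuple[int, int], dict[str, TrypticPeptide]] = {}
    for col in variant_cols:
        for sp in species:
            idx = site_map.species_index_of_column(sp, col)
            if idx is None:
                continue
            pos = idx + site_map.numbering_offset
            covering = sorted(
                (p for p in digests[sp] if p.start <= pos <= p.end),
                key=lambda p: (len(p.sequence), p.start),
            )
            if not covering:
                continue
            pep = covering[0]
            key = (pep.start, pep.end)
            candidates.setdefault(key, {})[sp] = pep

    out: list[CandidateMarker] = []
    for (lo, hi) in sorted(candidates):
        per_species = candidates[(lo, hi)]
        # make the candidate total: species whose covering peptide has the
        # same span but no variant column inside still belong to the group
        for sp in species:
            if sp in per_species:
                continue
            idx = site_map.species_index_of_column(sp, site_map.column_of(lo))
            if idx is None:
                continue
            pos = idx + site_map.numbering_offset
            covering = sorted(
                (p for p in digests[sp] if p.start <= pos <= p.end and (p.start, p.end) == (lo, hi)),
                key=lambda p: len(p.sequence),
            )
            if covering:
                per_species[sp] = covering[0]
        base_masses = {sp: PeptideVariant(p.sequence).mh_mass for sp, p in per_species.items()}
        in_window = {
            sp: p
            for sp, p in per_species.items()
            if min_mass <= base_masses[sp] <= max_mass
        }
        if len(in_window) < 2:
            continue
        if len({p.sequence for p in in_window.values()}) < 2:
            continue
        groups: dict[float, set[str]] = {}
        for sp in in_window:
            groups.setdefault(round(base_masses[sp], 4), set()).add(sp)
        out.append(
            CandidateMarker(
                locus=(lo, hi),
                per_species=in_window,
                groups={m: frozenset(s) for m, s in groups.items()},
            )
        )
    return out


def load_contaminants(path=None) -> list[tuple[str, float]]:
    if path is None:
        text = resources.files("bovidzooms.data").joinpath("contaminants.tsv").read_text()
    else:
        text = Path(path).read_text()
    out = []
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    for ln in lines[1:]:
        label, mz = ln.split("\t")
        out.append((label, float(mz)))
    return out


def check_uniqueness(
    candidate: CandidateMarker,
    background: list[tuple[str, float]],
    tolerance: float = 0.5,
    warn_tolerance: float | None = 2.5,
) -> CandidateMarker:
    """Flag a candidate non-unique when any background mass falls within
    ``tolerance`` of any of its masses; nearby masses within
    ``warn_tolerance`` yield proximity warnings only."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    masses = candidate.all_masses()
    collisions: list[tuple[str, float]] = []
    warnings: list[tuple[str, float]] = []
    for label, bg in background:
        for m in masses:
            d = abs(bg - m)
            if d <= tolerance:
                collisions.append((label, bg))
                break
            if warn_tolerance is not None and d <= warn_tolerance:
                warnings.append((label, bg))
                break
    candidate.unique = not collisions
    candidate.collisions = collisions
    candidate.warnings = warnings
    return candidate


@dataclass
class ScreenEntry:
    species: str
    n_matched: int
    n_total: int
    present: bool
    insufficient_replication: bool


@dataclass
class ScreenReport:
    entries: dict[tuple[int, int], list[ScreenEntry]]
    presence_fraction: dict[tuple[int, int], float]
    promoted: list[tuple[int, int]]


def screen_reference_spectra(
    candidates: list[CandidateMarker],
    peaklists_by_individual: dict[str, tuple[str, PeakList]],
    sn_min: float = 6.0,
    min_individuals: int = 2,
    presence_min: float = 0.75,
    tolerance: float = 0.5,
) -> ScreenReport:
    """Empirical confirmation of candidates against reference peak lists.

    ``peaklists_by_individual`` maps an individual id to (species, peak
    list).  A candidate is present for a species when a peak with S/N >=
    ``sn_min`` matches one of its masses in at least ``min_individuals``
    individuals; it is promoted to diagnostic when its overall presence
    fraction (matched spectra / all spectra) exceeds ``presence_min``.
    """
    entries: dict[tuple[int, int], list[ScreenEntry]] = {}
    fractions: dict[tuple[int, int], float] = {}
    promoted: list[tuple[int, int]] = []
    by_species: dict[str, list[PeakList]] = {}
    for _, (species, pl) in sorted(peaklists_by_individual.items()):
        by_species.setdefault(species, []).append(pl)

    for cand in candidates:
        cand_entries = []
        n_matched_total = 0
        n_total = 0
        for species, lists in sorted(by_species.items()):
            pep = cand.per_species.get(species)
            if pep is None:
                continue
            masses = [
                PeptideVariant(pep.sequence, k).mh_mass
                for k in range(min(pep.sequence.count("P") + pep.sequence.count("K"), 6) + 1)
            ]
            n_hit = 0
            for pl in lists:
                hit = any(
                    p.sn >= sn_min and any(abs(p.mz - m) <= tolerance for m in masses)
                    for p in pl
                )
                if hit:
                    n_hit += 1
            n_matched_total += n_hit
            n_total += len(lists)
            cand_entries.append(
                ScreenEntry(
                    species=species,
                    n_matched=n_hit,
                    n_total=len(lists),
                    present=n_hit >= min_individuals,
                    insufficient_replication=len(lists) < min_individuals,
                )
            )
        frac = n_matched_total / n_total if n_total else 0.0
        entries[cand.locus] = cand_entries
        fractions[cand.locus] = frac
        cand.presence_fraction = frac
        if frac > presence_min:
            promoted.append(cand.locus)
    return ScreenReport(entries=entries, presence_fraction=fractions, promoted=promoted)


def filter_psm_table(
    records: list[dict],
    target_mz: float,
    min_psms: int = 3,
    max_qvalue: float = 0.01,
    max_pep2d: float = 0.001,
    mass_tolerance: float = 0.5,
) -> tuple[bool, list[dict]]:
    """Confirmation filter over an external PSM table.

    Keeps records with q-value and PEP 2D below threshold and precursor
    m/z within ``mass_tolerance`` of the target; the marker is confirmed
    when at least ``min_psms`` such records remain.  (Only the threshold
    filters of the upstream search are mirrored here; the scoring engine
    itself is out of scope.)
    """
    kept = [
        r
        for r in records
        if float(r.get("q_value", 1.0)) < max_qvalue
        and float(r.get("pep2d", 1.0)) < max_pep2d
        and abs(float(r["precursor_mz"]) - target_mz) <= mass_tolerance
    ]
    return len(kept) >= min_psms, kept


def read_alignment_fasta(path, reference: str | None = None, chain_id: str = "COL1A2") -> SiteMap:
    """Read a pre-aligned protein FASTA into a SiteMap.

    Records may follow the ``species|chain`` header convention or plain
    species ids; the first record is the reference unless one is named.
    """
    aligned: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        species = rec.id.split("|", 1)[0]
        aligned[species] = str(rec.seq).upper()
    if not aligned:
        raise ValueError(f"no FASTA records found in {path}")
    ref = reference if reference is not None else next(iter(aligned))
    return SiteMap(aligned=aligned, reference=ref, chain_id=chain_id)
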
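"""In-silico tryptic digestion of collagen chains.

Trypsin cleaves C-terminal of K and R.  Collagen digests routinely show
*both* the cleaved and the read-through product when the cleavage site is
followed by a proline, so K/R-P sites are treated as optional cleavages:
both forms are emitted and the read-through does not count against the
missed-cleavage budget (it is flagged via ``follows_proline_site``
instead).  Internal K/R sites *not* followed by P count as missed
cleavages in the usual way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO

from .chem import PeptideVariant

__all__ = [
    "CollagenChain",
    "TrypticPeptide",
    "digest",
    "peptides_in_window",
    "read_chain_fasta",
]

CHAIN_IDS = ("COL1A1", "COL1A2")

#: default cap on enumerated hydroxylations per peptide (bounds combinatorics)
DEFAULT_MAX_HYDROXYLATIONS = 6


@dataclass(frozen=True)
class CollagenChain:
    """One collagen (I) chain of one species.

    ``numbering_offset`` maps string index to the marker-position
    convention: residue at string index ``i`` has position
    ``i + numbering_offset``.  The default of 1 gives 1-based positions
    from the start of the stored sequence.
    """

    chain_id: str
    species_label: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if self.chain_id not in CHAIN_IDS:
            raise ValueError(f"chain_id must be one of {CHAIN_IDS}, got {self.chain_id!r}")
        if not self.sequence:
            raise ValueError("empty chain sequence")

    def position(self, index: int) -> int:
        return index + self.numbering_offset

    def index(self, position: int) -> int:
        return position - self.numbering_offset


@dataclass(frozen=True)
class TrypticPeptide:
    """A fully tryptic peptide with chain coordinates (inclusive)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    follows_proline_site: bool = False


def _cut_points(seq: str) -> tuple[list[int], set[int]]:
    """All cut points (index *after* which the chain may be cut).

    Returns (all cut indices, subset that precede a proline).  The chain
    terminus is not included.
    """
    cuts: list[int] = []
    proline: set[int] = set()
    for i, aa in enumerate(seq[:-1]):
        if aa in "KR":
            cuts.append(i)
            if seq[i + 1] == "P":
                proline.add(i)
    return cuts, proline


def digest(chain: CollagenChain, max_missed: int = 2) -> set[TrypticPeptide]:
    """All fully tryptic peptides with at most ``max_missed`` missed cleavages.

    Peptides spanning a K/R-P site are emitted both cleaved and read
    through; the read-through site is flagged, not counted as missed.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = chain.sequence
    cuts, proline_cuts = _cut_points(seq)
    starts = [0] + [c + 1 for c in cuts]
    ends = [c for c in cuts] + [len(seq) - 1]
    # prefix counts: number of cut sites (all / followed-by-proline) at index < i
    n = len(seq) + 1
    all_prefix = [0] * n
    prol_prefix = [0] * n
    cut_set = set(cuts)
    for i in range(1, n):
        c = i - 1
        all_prefix[i] = all_prefix[i - 1] + (1 if c in cut_set else 0)
        prol_prefix[i] = prol_prefix[i - 1] + (1 if c in proline_cuts else 0)
    mand_prefix = [a - p for a, p in zip(all_prefix, prol_prefix)]
    peptides: set[TrypticPeptide] = set()
    for a in starts:
        for b in ends:
            if b < a:
                continue
            missed = mand_prefix[b] - mand_prefix[a]
            if missed > max_missed:
                break
            has_readthrough = (prol_prefix[b] - prol_prefix[a]) > 0
            peptides.add(
                TrypticPeptide(
                    sequence=seq[a : b + 1],
                    start=chain.position(a),
                    end=chain.position(b),
                    missed_cleavages=missed,
                    follows_proline_site=has_readthrough,
                )
            )
    return peptides


def peptides_in_window(
    peptides: Iterable[TrypticPeptide],
    min_mass: float = 800.0,
    max_mass: float = 3500.0,
    max_hydroxylations: int = DEFAULT_MAX_HYDROXYLATIONS,
    include_deamidation: bool = False,
) -> set[PeptideVariant]:
    """Enumerate PTM states and keep variants whose [M+H]+ lies in the window.

    Hydroxylation counts run from 0 to ``min(count(P) + count(K),
    max_hydroxylations)``; deamidation states (0..count(N,Q)) are included
    only on request.
    """
    if not min_mass < max_mass:
        raise ValueError("min_mass must be < max_mass")
    out: set[PeptideVariant] = set()
    for pep in peptides:
        seq = pep.sequence
        n_oh = min(seq.count("P") + seq.count("K"), max_hydroxylations)
        n_deam = seq.count("N") + seq.count("Q") if include_deamidation else 0
        for k in range(n_oh + 1):
            for d in range(n_deam + 1):
                var = PeptideVariant(seq, k, d)
                if min_mass <= var.mh_mass <= max_mass:
                    out.add(var)
    return out


def read_chain_fasta(path) -> list[CollagenChain]:
    """Read collagen chains from protein FASTA.

    Header convention: ``>species|chain [offset=N]``, e.g.
    ``>Bos_taurus|COL1A2 offset=1``.  The offset is optional and defaults
    to 1.
    """
    chains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"FASTA header {rec.id!r} does not follow the 'species|chain' convention"
            )
        species, chain_id = rec.id.split("|", 1)
        offset = 1
        for token in rec.description.split():
            if token.startswith("offset="):
                offset = int(token.split("=", 1)[1])
        chains.append(
            CollagenChain(
                chain_id=chain_id,
                species_label=species,
                sequence=str(rec.seq).upper(),
                numbering_offset=offset,
            )
        )
    if not chains:
        raise ValueError(f"no FASTA records found in {path}")
    return chains
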
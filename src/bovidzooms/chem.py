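"""Peptide mass arithmetic for collagen peptide mass fingerprinting.

All masses are monoisotopic.  The quantity of interest throughout the
package is the singly protonated ion [M+H]+, the species observed in
linear-mode MALDI-TOF of tryptic collagen digests.  Markers are quoted by
their *nominal* m/z, defined here as ``floor([M+H]+)``; this convention
reproduces every published integer marker mass in the bundled panel
(rounding half-up would not, e.g. 1150.63 -> 1151).

Collagen is heavily hydroxylated on proline and lysine (+15.9949 Da per
site); deamidation of N/Q (+0.98402 Da) accumulates in aged samples.  PTMs
are modelled as counts only -- site assignment does not change the
fingerprint mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "WATER_MASS",
    "PROTON_MASS",
    "HYDROXYLATION_MASS",
    "DEAMIDATION_MASS",
    "ISOTOPE_SPACING",
    "RESIDUE_MASSES",
    "PeptideVariant",
    "monoisotopic_mh",
    "nominal_mz",
    "isotope_envelope",
]

WATER_MASS = 18.0105646863
PROTON_MASS = 1.00727646688
#: mass shift of one hydroxylation (oxidation) on P or K
HYDROXYLATION_MASS = 15.9949
#: mass shift of one deamidation on N or Q
DEAMIDATION_MASS = 0.98402
#: 13C - 12C, the spacing of a singly charged isotope envelope
ISOTOPE_SPACING = 1.0033548378

# Averagine-style heavy-isotope rate per Da: 13C dominates (4.9384 C per
# 111.1254 Da at 1.07%), 15N adds a small correction.  Used for the
# Poisson envelope model below.
_LAMBDA_PER_DA = 5.2e-4


def _load_residue_masses() -> dict[str, float]:
    table = {}
    text = resources.files("bovidzooms.data").joinpath("residue_masses.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        aa, mass = line.split("\t")
        table[aa] = float(mass)
    return table


#: monoisotopic residue (amino-acid minus water) masses, 20 canonical letters
RESIDUE_MASSES: dict[str, float] = _load_residue_masses()


def monoisotopic_mh(sequence: str, n_hydroxylations: int = 0, n_deamidations: int = 0) -> float:
    """Monoisotopic [M+H]+ of a peptide carrying the given PTM counts.

    Parameters
    ----------
    sequence:
        Uppercase amino-acid string (20 canonical letters).
    n_hydroxylations:
        Number of +15.9949 Da hydroxylations; must not exceed the number
        of P and K residues.
    n_deamidations:
        Number of +0.98402 Da deamidations; must not exceed the number of
        N and Q residues.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER_MASS + PROTON_MASS
    for aa in sequence:
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue letter {aa!r} in sequence {sequence!r}") from None
    if n_hydroxylations < 0 or n_deamidations < 0:
        raise ValueError("PTM counts must be non-negative")
    n_oh_sites = sequence.count("P") + sequence.count("K")
    if n_hydroxylations > n_oh_sites:
        raise ValueError(
            f"{n_hydroxylations} hydroxylations requested but only "
            f"{n_oh_sites} P/K sites in {sequence!r}"
        )
    n_deam_sites = sequence.count("N") + sequence.count("Q")
    if n_deamidations > n_deam_sites:
        raise ValueError(
            f"{n_deamidations} deamidations requested but only "
            f"{n_deam_sites} N/Q sites in {sequence!r}"
        )
    return total + HYDROXYLATION_MASS * n_hydroxylations + DEAMIDATION_MASS * n_deamidations


def nominal_mz(mh_mass: float) -> int:
    """Integer nominal marker mass: ``floor([M+H]+)``."""
    if mh_mass <= 0:
        raise ValueError(f"non-positive mass {mh_mass!r}")
    return math.floor(mh_mass)


def isotope_envelope(mh_mass: float, n_peaks: int) -> list[tuple[float, float]]:
    """Model isotope envelope of a singly charged ion.

    Peaks sit at ``mh_mass + k * ISOTOPE_SPACING`` for ``k = 0..n_peaks-1``.
    Relative intensities follow a Poisson model with rate
    ``lambda = 5.2e-4 * mh_mass`` (an averagine-style closed form: the
    expected number of heavy isotopes grows linearly with mass), normalised
    so the tallest peak is 1.  The distribution is unimodal, so intensities
    decay monotonically after the modal peak.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    lam = _LAMBDA_PER_DA * mh_mass
    weights = []
    w = math.exp(-lam)
    for k in range(n_peaks):
        weights.append(w)
        w = w * lam / (k + 1)
    top = max(weights)
    return [
        (mh_mass + k * ISOTOPE_SPACING, weights[k] / top)
        for k in range(n_peaks)
    ]


@dataclass(frozen=True)
class PeptideVariant:
    """A tryptic peptide in a definite PTM state, with its marker masses."""

    sequence: str
    n_hydroxylations: int = 0
    n_deamidations: int = 0
    mh_mass: float = field(init=False)
    nominal_mz: int = field(init=False)

    def __post_init__(self) -> None:
        mass = monoisotopic_mh(self.sequence, self.n_hydroxylations, self.n_deamidations)
        object.__setattr__(self, "mh_mass", mass)
        object.__setattr__(self, "nominal_mz", nominal_mz(mass))

    def with_extra_hydroxylation(self) -> "PeptideVariant":
        """The +16 counterpart (Mass' form) carrying one more hydroxylation."""
        return PeptideVariant(self.sequence, self.n_hydroxylations + 1, self.n_deamidations)
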
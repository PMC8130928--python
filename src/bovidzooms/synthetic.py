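"""Synthetic MALDI fingerprints and synthetic reference collagen chains.

Two fixture generators live here:

``simulate_spectrum``
    Renders a profile spectrum for any panel taxon: Gaussian peaks with a
    resolution-scaled width, Poisson-model isotope envelopes, an
    exponentially decaying chemical baseline, additive Gaussian noise,
    small calibration jitter, mass-dependent marker dropout and a few
    random non-marker peaks.  The accompanying truth record lists every
    generated envelope.  A seed fully determines the output.

``build_reference_chains``
    SYNTHETIC stand-in collagen (I) chains, one pair per panel taxon,
    assembled from the sequence-confirmed marker peptides placed at their
    published chain coordinates and joined by neutral Gly-Ala-Arg filler.
    They are *not* real COL1A1/COL1A2 sequences -- real chains are only
    partially printed in the sources this package encodes -- but they
    digest to the correct marker peptides at the correct positions, which
    is exactly what the mapping and discovery machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import ISOTOPE_SPACING, isotope_envelope
from .digestion import CollagenChain
from .panel import MarkerPanel
from .spectra import Peak, PeakList, RawSpectrum

__all__ = [
    "SimulationConfig",
    "simulate_spectrum",
    "degrade_peaklist",
    "build_reference_chains",
]


@dataclass
class SimulationConfig:
    """Knobs for one simulated acquisition.

    ``peak_sn`` is the *minimum* apex signal-to-noise of a generated
    marker peak (per-peak heights vary uniformly up to 3x above it).
    ``dropout`` is a probability in [0, 1]; with ``dropout_profile``
    ``"uniform"`` every marker is dropped with that probability, with
    ``"linear"`` the probability ramps from 0 at the low-mass end to
    ``dropout`` at the high-mass end (heavy peptides survive burial
    worst).
    """

    taxon: str
    seed: int = 0
    peak_sn: float = 20.0
    noise_sigma: float = 1.0
    baseline_amplitude: float = 5.0
    dropout: float = 0.0
    dropout_profile: str = "linear"
    calibration_jitter: float = 0.02
    extra_peaks: int = 5
    resolution: float = 8000.0  # m / FWHM
    mz_min: float = 795.0
    mz_max: float = 3120.0
    grid_step: float = 0.08
    n_isotopes: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.dropout_profile not in ("uniform", "linear"):
            raise ValueError("dropout_profile must be 'uniform' or 'linear'")


@dataclass
class TruthPeak:
    label: str
    mz: float
    scale: float
    dropped: bool


@dataclass
class TruthRecord:
    taxon: str
    seed: int
    peaks: list[TruthPeak] = field(default_factory=list)

    @property
    def present_mzs(self) -> list[float]:
        return [p.mz for p in self.peaks if not p.dropped]


def _dropout_probability(config: SimulationConfig, mz: float) -> float:
    if config.dropout_profile == "uniform":
        return config.dropout
    ramp = (mz - config.mz_min) / (config.mz_max - config.mz_min)
    return config.dropout * float(np.clip(ramp, 0.0, 1.0))


def simulate_spectrum(config: SimulationConfig, panel: MarkerPanel) -> tuple[RawSpectrum, TruthRecord]:
    """Render a profile spectrum for ``config.taxon`` plus its truth record."""
    if config.taxon not in panel.taxon_names():
        raise KeyError(f"unknown taxon {config.taxon!r}")
    rng = np.random.default_rng(config.seed)
    grid = np.arange(config.mz_min, config.mz_max, config.grid_step)
    signal = np.zeros_like(grid)
    truth = TruthRecord(taxon=config.taxon, seed=config.seed)

    marker_mzs = panel.clean_peaklist(config.taxon, include_shared=True)

    def render(mono_mz: float, scale: float) -> None:
        sigma = (mono_mz / config.resolution) / 2.3548
        for iso_mz, rel in isotope_envelope(mono_mz, config.n_isotopes):
            lo = np.searchsorted(grid, iso_mz - 5 * sigma)
            hi = np.searchsorted(grid, iso_mz + 5 * sigma)
            signal[lo:hi] += scale * rel * np.exp(-0.5 * ((grid[lo:hi] - iso_mz) / sigma) ** 2)

    for mono in marker_mzs:
        dropped = bool(rng.random() < _dropout_probability(config, mono))
        jitter = float(rng.normal(0.0, config.calibration_jitter)) if config.calibration_jitter else 0.0
        # envelope maximum may be an isotopologue, not the monoisotopic peak:
        # scale so the *monoisotopic* apex reaches >= peak_sn * noise_sigma
        envelope = isotope_envelope(mono, config.n_isotopes)
        mono_rel = envelope[0][1]
        height = config.peak_sn * config.noise_sigma * float(rng.uniform(1.0, 3.0)) / mono_rel
        truth.peaks.append(TruthPeak(label="marker", mz=mono + jitter, scale=height, dropped=dropped))
        if not dropped:
            render(mono + jitter, height)

    # random non-marker peaks, kept away from every panel mass so the truth
    # of a simulated spectrum stays unambiguous
    all_panel = np.array(
        sorted(
            {v.mass for t in panel.taxa for v in panel.row_values(t.name)}
            | {sp.mass for sp in panel.shared_peptides}
        )
    )
    n_extra = 0
    attempts = 0
    while n_extra < config.extra_peaks and attempts < 100 * max(config.extra_peaks, 1):
        attempts += 1
        mz = float(rng.uniform(config.mz_min + 30, config.mz_max - 30))
        if np.min(np.abs(all_panel - mz)) < 3.0:
            continue
        height = config.peak_sn * config.noise_sigma * float(rng.uniform(0.5, 1.5))
        truth.peaks.append(TruthPeak(label="background", mz=mz, scale=height, dropped=False))
        render(mz, height)
        n_extra += 1

    baseline = config.baseline_amplitude * config.noise_sigma * np.exp(-(grid - config.mz_min) / 800.0)
    noise = rng.normal(0.0, config.noise_sigma, size=grid.shape)
    intensity = np.maximum(signal + baseline + noise, 0.0)
    spectrum = RawSpectrum(
        mz=grid,
        intensity=intensity,
        metadata={"sample": f"sim-{config.taxon}-{config.seed}", "taxon": config.taxon},
    )
    return spectrum, truth


def degrade_peaklist(
    peaklist: PeakList,
    drop_above: float | None = None,
    drop_set: list[float] | None = None,
    tolerance: float = 0.75,
) -> PeakList:
    """Deterministically remove peaks: everything above ``drop_above`` and/or
    everything within ``tolerance`` of a mass in ``drop_set``."""
    kept: list[Peak] = []
    for p in peaklist:
        if drop_above is not None and p.mz > drop_above:
            continue
        if drop_set and any(abs(p.mz - d) <= tolerance for d in drop_set):
            continue
        kept.append(p)
    return PeakList(kept, provenance=dict(peaklist.provenance, degraded=True))


# ---------------------------------------------------------------------------
# synthetic reference chains


def _filler(n: int) -> str:
    if n % 3 == 0:
        return "GAR" * (n // 3)
    if n % 3 == 1:
        return "R" + "GAR" * ((n - 1) // 3)
    return "GR" + "GAR" * ((n - 2) // 3)


_CONSERVED_89_130 = "GPPGASGAPGPQGFQGPPGEPGEPGQTGPAGAR"

# layout of the synthetic chains: (start, end, locus_id or None for filler)
_A2_LAYOUT = [
    (89, 121, "conserved"),
    (375, 396, "COL1a2 375-396"),
    (484, 498, "COL1a2 484-498"),
    (502, 519, "COL1a2 502-519"),
    (757, 789, "COL1a2 757-789"),
    (889, 906, "COL1a2 889-906"),
    (978, 990, "COL1a2 978-990"),
]
_A2_LENGTH = 999
_A1_LAYOUT = [(586, 618, "COL1a1 586-618")]
_A1_LENGTH = 627


def _variant_sequence(panel: MarkerPanel, taxon: str, locus_id: str) -> str:
    cell = panel.cell(taxon, locus_id)
    nominal = cell[0].nominal
    for v in panel.variants_for(locus_id):
        if v.nominal == nominal:
            return v.sequence
    raise KeyError(f"no sequence-bearing variant for {taxon} at {locus_id} (nominal {nominal})")


def _assemble(length: int, layout: list[tuple[int, int, str]], pick) -> str:
    chunks: list[str] = []
    cursor = 1  # 1-based position of the next residue to emit
    for start, end, locus_id in layout:
        if start > cursor:
            chunks.append(_filler(start - cursor))
        seq = pick(locus_id)
        assert len(seq) == end - start + 1, (locus_id, len(seq), start, end)
        chunks.append(seq)
        cursor = end + 1
    if cursor <= length:
        chunks.append(_filler(length - cursor + 1))
    chain = "".join(chunks)
    assert len(chain) == length
    return chain


def build_reference_chains(panel: MarkerPanel) -> dict[str, dict[str, CollagenChain]]:
    """Synthetic COL1A1/COL1A2 stand-in chains for every panel taxon.

    Marker peptides sit at their published coordinates (e.g. the A marker
    at COL1A2 978-990); the conserved COL1a2 89-130 peptide is present in
    every chain; everything else is Gly-Ala-Arg filler.  Loci known only
    by nominal mass (P1, P2, D, E) are filler in these chains.
    """
    out: dict[str, dict[str, CollagenChain]] = {}
    for taxon in panel.taxon_names():

        def pick_a2(locus_id: str, _taxon=taxon) -> str:
            if locus_id == "conserved":
                return _CONSERVED_89_130
            return _variant_sequence(panel, _taxon, locus_id)

        a2 = _assemble(_A2_LENGTH, _A2_LAYOUT, pick_a2)
        a1 = _assemble(_A1_LENGTH, _A1_LAYOUT, lambda lid, _taxon=taxon: _variant_sequence(panel, _taxon, lid))
        out[taxon] = {
            "COL1A2": CollagenChain("COL1A2", taxon, a2, numbering_offset=1),
            "COL1A1": CollagenChain("COL1A1", taxon, a1, numbering_offset=1),
        }
    return out
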
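"""Marker mapping through alignments, variant discovery, uniqueness
checking and reference-spectrum screening."""

import pytest

from bovidzooms.chem import PeptideVariant, monoisotopic_mh
from bovidzooms.digestion import CollagenChain, digest
from bovidzooms.discovery import (
    CandidateMarker,
    SiteMap,
    check_uniqueness,
    filter_psm_table,
    find_variant_peptides,
    map_marker_loci,
    screen_reference_spectra,
)
from bovidzooms.spectra import Peak, PeakList


def test_b_marker_substitution_predicts_1427_vs_1455():
    """An A->V substitution at the B locus separates buffalo from cattle."""
    a = "GAKGIPGEFGLPGPAGARGDR"
    b = "GAKGIPGEFGLPGPAGVRGDR"
    sm = SiteMap({"cattle": a, "buffalo": b}, reference="cattle")
    table = map_marker_loci(sm, [(4, 18)])
    masses = {
        sp: PeptideVariant(pep.sequence, 2).nominal_mz
        for sp, pep in ((s, t[(4, 18)]) for s, t in table.items())
    }
    assert masses == {"cattle": 1427, "buffalo": 1455}


def test_identity_alignment_identical_predictions(panel, reference_chains):
    chains = {t: reference_chains[t]["COL1A2"].sequence for t in ("Bovina",)}
    sm = SiteMap({"a": chains["Bovina"], "b": chains["Bovina"]}, reference="a")
    loci = [(l.start, l.end) for l in panel.loci if l.chain == "COL1A2" and l.n_hydroxylations is not None]
    table = map_marker_loci(sm, loci)
    for span in table["a"]:
        assert table["a"][span].sequence == table["b"][span].sequence


def test_engineered_cleavage_site_recomputes_boundaries():
    """A K->R substitution inside a locus changes the peptide boundaries;
    the mapped peptide equals a brute-force digest of the species."""
    ref = "GAKAGQPGAVGPAGIRGDR"
    alt = "GAKAGQPGRVGPAGIRGDR"  # new cleavage site inside the locus
    sm = SiteMap({"ref": ref, "alt": alt}, reference="ref")
    table = map_marker_loci(sm, [(4, 16)])
    assert table["ref"][(4, 16)].sequence == "AGQPGAVGPAGIR"
    alt_chain = CollagenChain("COL1A2", "alt", alt)
    oracle = {
        (p.sequence, p.start, p.end)
        for p in digest(alt_chain, max_missed=2)
        if p.start <= 4 and p.end >= 16
    }
    mapped = table["alt"][(4, 16)]
    assert (mapped.sequence, mapped.start, mapped.end) in oracle
    assert mapped.missed_cleavages >= 1  # must read through the engineered site


def test_gap_region_reported_missing():
    sm = SiteMap(
        {"ref": "GAKAGQPGAVGPAGIRGDR", "gappy": "GAK-------------GDR"},
        reference="ref",
    )
    table = map_marker_loci(sm, [(4, 16)])
    assert table["gappy"][(4, 16)] is None
    assert table["ref"][(4, 16)] is not None


def test_889_locus_reproduces_published_mass_classes(panel, reference_chains):
    aligned = {t: reference_chains[t]["COL1A2"].sequence for t in panel.taxon_names()}
    sm = SiteMap(aligned, reference="Bovina")
    candidates = find_variant_peptides(sm)
    c889 = next(c for c in candidates if c.locus == (889, 906))
    assert sorted(set(c889.masses_at(1).values())) == [1532, 1560, 1574, 1588, 1590]
    # the two composition-identical 1560 sequences merge into one group
    groups_with_1560 = [
        g for m, g in c889.groups.items() if PeptideVariant("GEPGPVGAVGPAGAVGPR", 1).mh_mass == pytest.approx(m + 15.9949, abs=1e-3)
    ]
    assert len(groups_with_1560) == 1


def test_identical_sequences_yield_no_candidates():
    seq = "GAKAGQPGAVGPAGIRGDR"
    sm = SiteMap({"a": seq, "b": seq}, reference="a")
    assert find_variant_peptides(sm) == []


def test_candidates_match_set_difference_oracle():
    """Candidates at variant columns equal an oracle that digests each
    species independently and diffs the in-window peptide sets."""
    base = list("GAK" + "AGQPGAVGPAGIR" + "GDR" + "GEPGPAGAVGPAGAVGPR" + "GVR")
    alt = base.copy()
    alt[7] = "S"   # inside the first marker
    alt[26] = "V"  # inside the second marker (the A->V composition shift)
    seq_a, seq_b = "".join(base), "".join(alt)
    sm = SiteMap({"a": seq_a, "b": seq_b}, reference="a")
    candidates = find_variant_peptides(sm, min_mass=800, max_mass=3500)

    def window_peptides(seq):
        return {
            p.sequence
            for p in digest(CollagenChain("COL1A2", "x", seq), max_missed=0)
            if 800 <= monoisotopic_mh(p.sequence) <= 3500
        }

    differing = window_peptides(seq_a) ^ window_peptides(seq_b)
    found = {pep.sequence for c in candidates for pep in c.per_species.values()}
    assert found == differing
    assert len(candidates) == 2


class TestUniqueness:
    def test_3017_collision_flagged(self, panel):
        g = next(v for v in panel.variants_for("COL1a2 757-789") if v.nominal == 3017)
        pep_mass = monoisotopic_mh(g.sequence, g.n_hydroxylations)
        conserved = next(sp for sp in panel.shared_peptides if sp.label == "COL1a2 89-130")
        cand = CandidateMarker(locus=(757, 789), per_species={"Bovina": _pep(g.sequence)})
        checked = check_uniqueness(cand, [("COL1a2 89-130", conserved.mass)], tolerance=0.5)
        assert not checked.unique
        assert checked.collisions[0][0] == "COL1a2 89-130"
        assert abs(conserved.mass - pep_mass) < 0.5

    def test_1588_proximity_warning(self):
        cand = CandidateMarker(
            locus=(889, 906), per_species={"Hippotraginae": _pep("GEPGPVGAVGPVGAVGPR")}
        )
        checked = check_uniqueness(cand, [("shared-1586", 1586.61)], tolerance=0.5)
        assert checked.unique
        assert checked.warnings  # within 2.5 Da of the shared 1586 peak

    def test_empty_background_is_unique(self):
        cand = CandidateMarker(locus=(1, 10), per_species={"x": _pep("AGQPGAVGPAGIR")})
        assert check_uniqueness(cand, [], tolerance=0.5).unique


def _pep(seq):
    from bovidzooms.digestion import TrypticPeptide

    return TrypticPeptide(sequence=seq, start=1, end=len(seq), missed_cleavages=0)


class TestReferenceScreening:
    @staticmethod
    def _candidate():
        return CandidateMarker(locus=(889, 906), per_species={"sp1": _pep("GEPGPAGAVGPAGAVGPR")})

    @staticmethod
    def _peaklist(present: bool, sn: float = 10.0):
        mass = monoisotopic_mh("GEPGPAGAVGPAGAVGPR", 1)
        peaks = [Peak(mass, 50.0, sn)] if present else [Peak(900.0, 50.0, sn)]
        return PeakList(peaks)

    def test_present_in_two_of_three_individuals(self):
        cand = self._candidate()
        lists = {
            "i1": ("sp1", self._peaklist(True)),
            "i2": ("sp1", self._peaklist(True)),
            "i3": ("sp1", self._peaklist(False)),
        }
        report = screen_reference_spectra([cand], lists)
        (entry,) = report.entries[cand.locus]
        assert entry.present and entry.n_matched == 2

    def test_low_sn_peaks_do_not_count(self):
        cand = self._candidate()
        lists = {
            "i1": ("sp1", self._peaklist(True, sn=4.0)),
            "i2": ("sp1", self._peaklist(True, sn=4.0)),
        }
        report = screen_reference_spectra([cand], lists, sn_min=6)
        (entry,) = report.entries[cand.locus]
        assert not entry.present

    @pytest.mark.parametrize("n_present,n_total,promoted", [(74, 100, False), (76, 100, True)])
    def test_presence_fraction_threshold_is_strict(self, n_present, n_total, promoted):
        """0.74 is not promoted, 0.76 is: the rule is 'over 75%'."""
        cand = self._candidate()
        lists = {
            f"i{k}": ("sp1", self._peaklist(k < n_present))
            for k in range(n_total)
        }
        report = screen_reference_spectra([cand], lists)
        assert (cand.locus in report.promoted) is promoted
        assert report.presence_fraction[cand.locus] == pytest.approx(n_present / n_total)

    def test_no_peaklists_means_absent(self):
        cand = self._candidate()
        report = screen_reference_spectra([cand], {})
        assert report.presence_fraction[cand.locus] == 0.0
        assert report.promoted == []

    def test_single_individual_reports_insufficient_replication(self):
        cand = self._candidate()
        report = screen_reference_spectra([cand], {"i1": ("sp1", self._peaklist(True))})
        (entry,) = report.entries[cand.locus]
        assert entry.insufficient_replication
        assert not entry.present  # 1 < min_individuals, not auto-failed as error


def test_psm_confirmation_filter():
    records = [
        {"q_value": 0.001, "pep2d": 1e-5, "precursor_mz": 1532.78},
        {"q_value": 0.001, "pep2d": 1e-5, "precursor_mz": 1532.79},
        {"q_value": 0.001, "pep2d": 1e-5, "precursor_mz": 1532.60},
        {"q_value": 0.5, "pep2d": 1e-5, "precursor_mz": 1532.78},  # fails FDR
        {"q_value": 0.001, "pep2d": 0.01, "precursor_mz": 1532.78},  # fails PEP
        {"q_value": 0.001, "pep2d": 1e-5, "precursor_mz": 1540.0},  # off-mass
    ]
    confirmed, kept = filter_psm_table(records, target_mz=1532.78)
    assert confirmed and len(kept) == 3
    confirmed2, _ = filter_psm_table(records[:2], target_mz=1532.78)
    assert not confirmed2  # only 2 PSMs, need >= 3
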
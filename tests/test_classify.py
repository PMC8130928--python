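"""The identification engine: matching, conflicts, statuses, size
constraints and the panel-wide consistency invariants."""

import pytest

from bovidzooms.classify import (
    ClassifyParams,
    classify_batch,
    identify,
    match_markers,
)
from bovidzooms.panel import ambiguity_classes
from bovidzooms.spectra import Peak, PeakList, collagen_screen
from bovidzooms.synthetic import SimulationConfig, simulate_spectrum
from bovidzooms.spectra import deisotope, pick_peaks, preprocess


def _call(panel, peaklist, **kw):
    return identify(match_markers(peaklist, panel), panel, **kw)


class TestMatchMarkers:
    def test_bubalina_list_conflicts_bovina_b_locus(self, panel, clean_peaklist):
        states = match_markers(clean_peaklist("Bubalina"), panel)
        b_state = states["Bovina"].loci["COL1a2 484-498"]
        assert b_state.conflicts  # 1455 observed where 1427 expected
        assert b_state.conflicts[0][0] == 1455

    def test_empty_list_all_absent(self, panel):
        states = match_markers(PeakList([]), panel)
        for name, st in states.items():
            assert st.observed_locus_count == 0
            assert st.conflict_count == 0

    def test_tolerance_boundary(self, panel):
        b_exact = 1427.7277  # B marker, sequence-backed cell
        for delta, expect in ((0.49, True), (0.51, False)):
            pl = PeakList([Peak(b_exact + delta, 10.0, 20.0)])
            states = match_markers(pl, panel, tolerance=0.5)
            got = states["Bovina"].loci["COL1a2 484-498"].state == "observed"
            assert got is expect

    def test_low_sn_peak_never_vetoes(self, panel, clean_peaklist):
        """A near-threshold peak at another taxon's variant mass is not
        treated as conflicting evidence."""
        peaks = list(clean_peaklist("Bovina").peaks)
        peaks.append(Peak(1455.759, 2.0, 3.5))  # weak spurious buffalo B
        states = match_markers(PeakList(peaks), panel)
        assert states["Bovina"].conflict_count == 0
        strong = list(clean_peaklist("Bovina").peaks)
        strong.append(Peak(1455.759, 50.0, 20.0))
        states2 = match_markers(PeakList(strong), panel)
        assert states2["Bovina"].conflict_count > 0


class TestIdentify:
    def test_all_20_clean_profiles_give_full_class_calls(self, panel, clean_peaklist):
        classes = ambiguity_classes(panel)
        for taxon in panel.taxon_names():
            res = _call(panel, clean_peaklist(taxon))
            assert res.status == "full", (taxon, res.candidate_taxa)
            assert taxon in res.candidate_taxa
            assert frozenset(res.candidate_taxa) in classes

    def test_reduncinae_full_without_g_markers(self, panel, clean_peaklist):
        pl = clean_peaklist("Reduncinae", predicate=lambda m: not 3010 < m < 3040)
        res = _call(panel, pl)
        assert res.status == "full"
        assert res.candidate_taxa == ("Reduncinae",)

    def test_bovina_without_g_prime_partial_then_size_resolves(self, panel, clean_peaklist):
        pl = clean_peaklist("Bovina", predicate=lambda m: m < 3000)
        res = _call(panel, pl)
        assert res.status == "partial"
        assert set(res.candidate_taxa) == {"Bovina", "Sylvicapra"}
        res_sized = _call(panel, pl, size_class=3)
        assert res_sized.status == "full"
        assert res_sized.candidate_taxa == ("Bovina",)
        assert "Bovina" in res_sized.label

    def test_all_absent_is_fail_after_negative_screen(self, panel):
        pl = PeakList([])
        ok = collagen_screen(pl)
        res = identify(match_markers(pl, panel), panel, collagen_ok=ok)
        assert res.status == "fail"
        assert res.candidate_taxa == ()

    def test_shared_markers_only_gives_family_level_partial(self, panel):
        pl = PeakList([Peak(m + 0.6, 10.0, 20.0) for m in (1105, 1648, 2131, 2792)])
        res = _call(panel, pl)
        assert res.status == "partial"
        assert set(res.candidate_taxa) == set(panel.taxon_names())
        assert res.label == "Bovidae"

    def test_caution_masses_alone_never_full(self, panel):
        pl = PeakList(
            [Peak(1560.81, 50.0, 30.0), Peak(1182.61, 50.0, 30.0)]
            + [Peak(m + 0.6, 10.0, 20.0) for m in (1105, 1648, 2131, 2792)]
        )
        res = _call(panel, pl)
        assert res.status != "full"

    def test_min_loci_validation(self, panel, clean_peaklist):
        with pytest.raises(ValueError):
            _call(panel, clean_peaklist("Bovina"), min_loci=0)


class TestExclusionInvariant:
    def test_removing_3017_changes_no_identification(self, panel, clean_peaklist):
        for taxon in panel.taxon_names():
            full = clean_peaklist(taxon)
            trimmed = PeakList([p for p in full if not 3016.5 <= p.mz < 3018.5])
            r1 = _call(panel, full)
            r2 = _call(panel, trimmed)
            assert r1.status == r2.status
            assert r1.candidate_taxa == r2.candidate_taxa


class TestMonotonicity:
    def test_adding_matching_peak_never_shrinks_observed(self, panel, clean_peaklist):
        partial = clean_peaklist("Hippotraginae", predicate=lambda m: m < 2000)
        before = match_markers(partial, panel)["Hippotraginae"].observed_locus_count
        extended = PeakList(list(partial.peaks) + [Peak(2883.4231, 50.0, 30.0)])
        after = match_markers(extended, panel)["Hippotraginae"].observed_locus_count
        assert after >= before

    def test_conflicting_peak_never_adds_candidates(self, panel, clean_peaklist):
        pl = clean_peaklist("Bovina", predicate=lambda m: m < 3000)
        base = set(_call(panel, pl).candidate_taxa)
        poisoned = PeakList(list(pl.peaks) + [Peak(3077.4962, 50.0, 30.0)])  # Capra G
        after = set(_call(panel, poisoned).candidate_taxa)
        assert after <= base


class TestBatch:
    def test_three_full_quality_samples(self, panel):
        lists = {}
        for taxon in ("Bubalina", "Reduncinae", "Hippotraginae"):
            spec, _ = simulate_spectrum(SimulationConfig(taxon=taxon, seed=2), panel)
            lists[taxon] = deisotope(pick_peaks(preprocess(spec)))
        results, counts = classify_batch(lists, panel)
        assert counts == {"full": 3, "partial": 0, "unknown_collagen": 0, "fail": 0}
        by_sample = {r.sample: r for r in results}
        assert by_sample["Bubalina"].candidate_taxa == ("Bubalina",)
        assert by_sample["Reduncinae"].candidate_taxa == ("Reduncinae",)
        assert by_sample["Hippotraginae"].candidate_taxa == ("Hippotraginae",)

    def test_empty_plus_clean_counts(self, panel, clean_peaklist):
        lists = {"clean": clean_peaklist("Bovina"), "empty": PeakList([])}
        _, counts = classify_batch(lists, panel)
        assert counts["full"] == 1
        assert counts["fail"] == 1

    def test_non_panel_fingerprint_is_unknown_collagen(self, panel):
        """Shared collagen peaks plus strong peaks at off-panel variant
        masses: collagen present but no profile is consistent."""
        peaks = [Peak(m + 0.6, 20.0, 20.0) for m in (1105, 1648, 2131, 2792)]
        # strong peaks matching mutually exclusive variants of one locus
        peaks += [Peak(1150.633, 50.0, 20.0), Peak(1180.643, 50.0, 20.0), Peak(1192.680, 50.0, 20.0)]
        res = _call(panel, PeakList(peaks), min_loci=5)
        assert res.status == "unknown_collagen"
        assert res.candidate_taxa == ()

    def test_deterministic_ordering(self, panel, clean_peaklist):
        lists = {"b": clean_peaklist("Bovina"), "a": clean_peaklist("Ovis")}
        results, _ = classify_batch(lists, panel)
        assert [r.sample for r in results] == ["a", "b"]
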
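"""Taxonomic identification of peak lists against the marker panel.

Matching and scoring rules
--------------------------
* A peak matches a marker value within ``tolerance`` (0.5 Da by default,
  the concordance window used when markers are cross-confirmed between
  MALDI and LC-MS/MS).  Values backed by a sequence are matched on their
  exact mass; nominal-only values on the integer window
  ``[n - tol, n + 1 + tol)``.
* Only *usable* values score.  Caution values (peaks shared across all
  bovids, e.g. m/z 1560) and the unusable m/z 3017 collision never count
  as evidence for or against any taxon.
* Conflict (hard veto): a peak that matches another taxon's usable value
  at some locus, and that cannot be explained by *any* mass in the
  candidate's own fingerprint, removes the candidate.
* A candidate needs at least ``min_loci`` loci observed through usable
  values and zero conflicts.
* Among surviving candidates, those whose complete usable profile is
  observed are preferred: a clean spectrum showing every expected marker
  of one group outranks a group that would require additional, absent
  peaks.  (Degraded spectra, where nobody is fully observed, keep the
  whole compatible set -- a partial identification.)
* An optional body-size class acts as a constraint filter only.

Call statuses follow field practice: ``full`` when the candidate set
equals one ambiguity class of the panel, ``partial`` when several classes
remain, ``unknown_collagen`` when collagen is present but no profile
fits, ``fail`` when the collagen screen is negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .panel import MarkerPanel, MarkerValue, ambiguity_classes
from .spectra import PeakList, collagen_screen, nominal_match

__all__ = [
    "ObservedMarkerState",
    "IdentificationResult",
    "ClassifyParams",
    "match_markers",
    "identify",
    "classify_batch",
    "load_size_classes",
]

OBSERVED = "observed"
ABSENT = "absent"
IGNORED = "unusable-ignored"


def _value_matches(value: MarkerValue, mz: float, tolerance: float) -> bool:
    if value.exact is not None:
        return abs(mz - value.exact) <= tolerance
    return nominal_match(mz, value.nominal, tolerance)


@dataclass
class LocusState:
    state: str  # observed | absent | unusable-ignored
    matched_values: list[int] = field(default_factory=list)  # nominal m/z
    matched_peaks: list[float] = field(default_factory=list)
    conflicts: list[tuple[int, float]] = field(default_factory=list)  # (other nominal, peak)


@dataclass
class ObservedMarkerState:
    """Per-taxon match summary across all loci."""

    taxon: str
    loci: dict[str, LocusState]

    @property
    def observed_locus_count(self) -> int:
        return sum(1 for s in self.loci.values() if s.state == OBSERVED)

    @property
    def conflict_count(self) -> int:
        return sum(len(s.conflicts) for s in self.loci.values())


def match_markers(
    peaklist: PeakList,
    panel: MarkerPanel,
    tolerance: float = 0.5,
    conflict_sn_min: float = 6.0,
) -> dict[str, ObservedMarkerState]:
    """Match a peak list against every taxon profile in the panel.

    Evidence (a taxon's own marker observed) accepts any peak in the list;
    a *conflict* -- a peak that positively supports a different variant at
    the same locus -- must additionally reach ``conflict_sn_min`` S/N, so
    that near-threshold noise never vetoes a taxon.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    mzs = [p.mz for p in peaklist]

    # distinct usable values per locus across the whole panel
    usable_by_locus: dict[str, list[MarkerValue]] = {}
    for loc in panel.loci:
        seen: dict[int, MarkerValue] = {}
        for t in panel.taxa:
            for v in panel.cells[(t.name, loc.locus_id)]:
                if v.usable and v.nominal not in seen:
                    seen[v.nominal] = v
        usable_by_locus[loc.locus_id] = list(seen.values())

    # which confident peaks match each usable value (conflict candidates)
    peaks_for_value: dict[tuple[str, int], list[float]] = {}
    for lid, values in usable_by_locus.items():
        for v in values:
            hits = [
                p.mz
                for p in peaklist
                if p.sn >= conflict_sn_min and _value_matches(v, p.mz, tolerance)
            ]
            if hits:
                peaks_for_value[(lid, v.nominal)] = hits

    states: dict[str, ObservedMarkerState] = {}
    for t in panel.taxa:
        row = panel.row_values(t.name)

        def explained(mz: float, _row=row) -> bool:
            return any(_value_matches(v, mz, tolerance) for v in _row)

        loci_states: dict[str, LocusState] = {}
        for loc in panel.loci:
            cell = panel.cells[(t.name, loc.locus_id)]
            own_usable = [v for v in cell if v.usable]
            matched_vals: list[int] = []
            matched_peaks: list[float] = []
            for v in own_usable:
                hits = [mz for mz in mzs if _value_matches(v, mz, tolerance)]
                if hits:
                    matched_vals.append(v.nominal)
                    matched_peaks.extend(hits)
            conflicts: list[tuple[int, float]] = []
            own_nominals = {v.nominal for v in cell}
            for v in usable_by_locus[loc.locus_id]:
                if v.nominal in own_nominals:
                    continue
                if any(abs(v.mass - own.mass) <= tolerance for own in cell):
                    continue
                for mz in peaks_for_value.get((loc.locus_id, v.nominal), []):
                    if not explained(mz):
                        conflicts.append((v.nominal, mz))
            if not own_usable:
                state = IGNORED
            elif matched_vals:
                state = OBSERVED
            else:
                state = ABSENT
            loci_states[loc.locus_id] = LocusState(
                state=state,
                matched_values=matched_vals,
                matched_peaks=matched_peaks,
                conflicts=conflicts,
            )
        states[t.name] = ObservedMarkerState(taxon=t.name, loci=loci_states)
    return states


def _fully_observed(state: ObservedMarkerState, panel: MarkerPanel) -> bool:
    """True when every usable value of the taxon's profile was matched."""
    for loc in panel.loci:
        cell = panel.cells[(state.taxon, loc.locus_id)]
        expected = {v.nominal for v in cell if v.usable}
        if not expected:
            continue
        if not expected <= set(state.loci[loc.locus_id].matched_values):
            return False
    return True


@dataclass
class IdentificationResult:
    sample: str
    status: str  # full | partial | unknown_collagen | fail
    candidate_taxa: tuple[str, ...]
    label: str
    matched_loci: dict[str, int]
    conflicts: dict[str, int]
    applied_constraints: dict
    evidence: dict

    def to_row(self) -> dict:
        return {
            "sample": self.sample,
            "status": self.status,
            "label": self.label,
            "candidates": "/".join(self.candidate_taxa),
            "matched_loci": ";".join(f"{t}:{n}" for t, n in self.matched_loci.items()),
            "conflicts": ";".join(f"{t}:{n}" for t, n in self.conflicts.items() if n),
            "evidence_json": json.dumps(self.evidence, sort_keys=True),
        }


def load_size_classes(path=None) -> dict[str, tuple[int, int]]:
    """Body-size class range per panel taxon (editable TSV)."""
    if path is None:
        text = resources.files("bovidzooms.data").joinpath("size_classes.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, tuple[int, int]] = {}
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    for ln in lines[1:]:
        name, lo, hi = ln.split("\t")
        table[name] = (int(lo), int(hi))
    return table


def _label_for(candidates: list[str], panel: MarkerPanel) -> str:
    if not candidates:
        return ""
    if len(candidates) == 1:
        return candidates[0]
    paths = [panel.taxon(name).path for name in candidates]
    # deepest rank on which all candidates agree (path[0] is the family)
    common = ""
    for depth in range(4):
        parts = {p[depth] for p in paths}
        if len(parts) == 1 and parts != {"-"}:
            common = parts.pop()
        else:
            break
    if common and common != "Bovidae":
        return common
    if common == "Bovidae" and len(candidates) == len(panel.taxa):
        return "Bovidae"
    return "/".join(candidates)


def identify(
    states: dict[str, ObservedMarkerState],
    panel: MarkerPanel,
    min_loci: int = 3,
    size_class: int | None = None,
    collagen_ok: bool = True,
    size_table: dict[str, tuple[int, int]] | None = None,
    sample: str = "",
) -> IdentificationResult:
    """Reduce per-taxon marker states to one identification call.

    ``size_class`` is the specimen's minimum body-size class (Brain's
    classes 1-4); taxa whose size range tops out below it are filtered
    out.  Size never adds evidence, it only narrows the candidate set.
    """
    if min_loci < 1:
        raise ValueError("min_loci must be >= 1")
    order = panel.taxon_names()
    compatible = [
        name
        for name in order
        if states[name].conflict_count == 0 and states[name].observed_locus_count >= min_loci
    ]
    constraints: dict = {}
    if size_class is not None:
        table = size_table if size_table is not None else load_size_classes()
        compatible = [n for n in compatible if table.get(n, (1, 4))[1] >= size_class]
        constraints["size_class_min"] = size_class
    full_obs = [n for n in compatible if _fully_observed(states[n], panel)]
    final = full_obs if full_obs else compatible

    if not collagen_ok:
        status = "fail"
        final = []
    elif not final:
        status = "unknown_collagen"
    else:
        classes = ambiguity_classes(panel)
        status = "full" if frozenset(final) in classes else "partial"

    return IdentificationResult(
        sample=sample,
        status=status,
        candidate_taxa=tuple(final),
        label=_label_for(final, panel),
        matched_loci={n: states[n].observed_locus_count for n in final},
        conflicts={n: states[n].conflict_count for n in order},
        applied_constraints=constraints,
        evidence={
            n: {
                lid: {
                    "state": s.state,
                    "matched": s.matched_values,
                }
                for lid, s in states[n].loci.items()
                if s.state == OBSERVED or s.conflicts
            }
            for n in final
        },
    )


@dataclass
class ClassifyParams:
    tolerance: float = 0.5
    min_loci: int = 3
    size_class: int | None = None
    screen_k_min: int = 2


def classify_batch(
    peaklists: dict[str, PeakList],
    panel: MarkerPanel,
    params: ClassifyParams | None = None,
) -> tuple[list[IdentificationResult], dict[str, int]]:
    """Identify every sample; return per-sample results plus summary counts."""
    params = params or ClassifyParams()
    results = []
    counts = {"full": 0, "partial": 0, "unknown_collagen": 0, "fail": 0}
    for name in sorted(peaklists):
        pl = peaklists[name]
        ok = collagen_screen(pl, k_min=params.screen_k_min, tolerance=params.tolerance)
        if ok:
            states = match_markers(pl, panel, tolerance=params.tolerance)
            res = identify(
                states,
                panel,
                min_loci=params.min_loci,
                size_class=params.size_class,
                collagen_ok=True,
                sample=name,
            )
        else:
            res = IdentificationResult(
                sample=name,
                status="fail",
                candidate_taxa=(),
                label="",
                matched_loci={},
                conflicts={},
                applied_constraints={},
                evidence={},
            )
        counts[res.status] += 1
        results.append(res)
    return results, counts
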
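"""The reference marker panel: taxa x marker-locus matrix of nominal m/z.

The bundled panel covers 20 African bovid groups (plus sheep, goat and the
Tibetan antelope) scored at 12 marker loci on the two collagen (I) chains.
Several loci come as Mass/Mass' pairs -- the same peptide with one
additional hydroxylation, 16 Da apart -- stored as separate columns.

Value-level reliability flags
-----------------------------
``?`` (caution)  the peak at this mass also contains a non-diagnostic
                 peptide shared across bovids, so its *presence* carries no
                 taxonomic information.  Caution values are never used as
                 evidence for or against a taxon.
``!`` (unusable) the mass is a known collision of a diagnostic and a
                 conserved peptide (m/z 3017); it is excluded from
                 identification entirely.

Cells are written as the integer nominal mass plus an optional flag
character, e.g. ``3017!`` or ``1560?``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .chem import HYDROXYLATION_MASS, monoisotopic_mh, nominal_mz

__all__ = [
    "MarkerValue",
    "MarkerLocus",
    "Taxon",
    "MarkerPanel",
    "PanelError",
    "load_panel",
    "save_panel",
    "ambiguity_classes",
    "regenerate_panel_masses",
]

#: loci shared by all bovids, with their invariant nominal masses
SHARED_LOCI = {"P1": 1105, "P2": 1648, "D": 2131, "E": 2792}

#: fractional mass used to synthesise an exact mass for nominal-only cells
#: (typical mass defect of collagen peptides in the fingerprint window)
SYNTHETIC_MASS_DEFECT = 0.61

_META_COLUMNS = ["name", "subfamily", "tribe", "group", "evidence", "members"]


class PanelError(ValueError):
    """Schema or consistency error in a panel file."""


@dataclass(frozen=True)
class MarkerValue:
    nominal: int
    flag: str = ""  # '', '?' (caution) or '!' (unusable)
    exact: float | None = None
    is_prime: bool = False

    @property
    def usable(self) -> bool:
        return self.flag == ""

    @property
    def mass(self) -> float:
        """Best available mass: exact if a sequence backs it, else synthetic."""
        return self.exact if self.exact is not None else self.nominal + SYNTHETIC_MASS_DEFECT

    def cell_text(self) -> str:
        return f"{self.nominal}{self.flag}"


@dataclass(frozen=True)
class MarkerLocus:
    locus_id: str
    letter: str
    tryptic_name: str
    chain: str
    start: int
    end: int
    n_hydroxylations: int | None  # None when only nominal masses are known
    mass_column: str
    prime_column: str | None = None

    @property
    def columns(self) -> tuple[str, ...]:
        if self.prime_column:
            return (self.mass_column, self.prime_column)
        return (self.mass_column,)


@dataclass(frozen=True)
class Taxon:
    name: str
    path: tuple[str, ...]  # (family, subfamily, tribe, subtribe-or-genus-group)
    member_species: tuple[str, ...]
    evidence: str  # MALDI+LCMSMS | MALDI | predicted

    @property
    def display(self) -> str:
        return self.name


@dataclass(frozen=True)
class VariantRecord:
    locus_id: str
    sequence: str
    n_hydroxylations: int
    nominal: int
    prime_nominal: int | None


@dataclass(frozen=True)
class SharedPeptide:
    """A non-diagnostic peptide present in (essentially) all bovid spectra."""

    label: str
    sequence: str | None
    n_hydroxylations: int | None
    nominal: int

    @property
    def mass(self) -> float:
        if self.sequence is not None and self.n_hydroxylations is not None:
            return monoisotopic_mh(self.sequence, self.n_hydroxylations)
        return self.nominal + SYNTHETIC_MASS_DEFECT


@dataclass
class MarkerPanel:
    loci: list[MarkerLocus]
    taxa: list[Taxon]
    cells: dict[tuple[str, str], tuple[MarkerValue, ...]]  # (taxon, locus) -> values
    variants: list[VariantRecord]
    shared_peptides: list[SharedPeptide]
    column_order: list[str] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------
    def locus(self, locus_id: str) -> MarkerLocus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)

    def locus_by_letter(self, letter: str) -> MarkerLocus:
        for loc in self.loci:
            if loc.letter == letter:
                return loc
        raise KeyError(letter)

    def taxon(self, name: str) -> Taxon:
        for t in self.taxa:
            if t.name == name:
                return t
        raise KeyError(name)

    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    def cell(self, taxon: str, locus_id: str) -> tuple[MarkerValue, ...]:
        return self.cells[(taxon, locus_id)]

    def row_values(self, taxon: str) -> list[MarkerValue]:
        out = []
        for loc in self.loci:
            out.extend(self.cells[(taxon, loc.locus_id)])
        return out

    def usable_profile(self, taxon: str, loci: list[str] | None = None) -> tuple:
        """Per-locus frozensets of usable nominal values (class fingerprint)."""
        ids = loci if loci is not None else [l.locus_id for l in self.loci]
        return tuple(
            frozenset(v.nominal for v in self.cells[(taxon, lid)] if v.usable)
            for lid in ids
        )

    def variants_for(self, locus_id: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.locus_id == locus_id]

    def clean_peaklist(self, taxon: str, include_shared: bool = True) -> list[float]:
        """The complete expected fingerprint of a taxon, as exact m/z values.

        Includes caution and unusable masses (they are real peptides and do
        appear in spectra) and, optionally, the shared non-diagnostic
        peptides seen in every bovid digest.
        """
        masses = [v.mass for v in self.row_values(taxon)]
        if include_shared:
            masses.extend(sp.mass for sp in self.shared_peptides)
        return sorted(set(masses))

    # -- validation ------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of consistency problems (empty when the panel is sound)."""
        problems: list[str] = []
        seen_paths = set()
        for t in self.taxa:
            if t.path in seen_paths:
                problems.append(f"duplicate taxon path {'/'.join(t.path)}")
            seen_paths.add(t.path)
        letters = [l.letter for l in self.loci if l.letter != "-"]
        for letter in set(letters):
            if letters.count(letter) > 1:
                problems.append(f"marker letter {letter!r} appears more than once")
        for t in self.taxa:
            for letter, nominal in SHARED_LOCI.items():
                try:
                    loc = self.locus_by_letter(letter)
                except KeyError:
                    problems.append(f"shared locus {letter} missing from panel")
                    continue
                vals = self.cells.get((t.name, loc.locus_id), ())
                if [v.nominal for v in vals] != [nominal]:
                    problems.append(
                        f"shared locus {letter} must be {nominal} for every "
                        f"taxon; row {t.name!r} has {[v.nominal for v in vals]}"
                    )
        return problems


# ---------------------------------------------------------------------------
# parsing


def _data_path(name: str):
    return resources.files("bovidzooms.data").joinpath(name)


def _parse_cell(text: str, row: str, column: str) -> MarkerValue:
    text = text.strip()
    flag = ""
    if text.endswith(("?", "!")):
        flag = text[-1]
        text = text[:-1]
    try:
        nominal = int(text)
    except ValueError:
        raise PanelError(
            f"cell {text!r} (row {row!r}, column {column!r}) is not an integer m/z"
        ) from None
    return MarkerValue(nominal=nominal, flag=flag)


def _read_tsv(source) -> list[dict[str, str]]:
    if hasattr(source, "read_text"):
        text = source.read_text()
    else:
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    if not lines:
        raise PanelError("empty table: missing header row")
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise PanelError(f"row has {len(parts)} fields, header has {len(header)}: {ln!r}")
        rows.append(dict(zip(header, parts)))
    return rows, header


def _load_loci(path=None) -> list[MarkerLocus]:
    rows, _ = _read_tsv(path or _data_path("loci.tsv"))
    loci = []
    for r in rows:
        loci.append(
            MarkerLocus(
                locus_id=r["locus_id"],
                letter=r["letter"],
                tryptic_name=r["tryptic_name"],
                chain=r["chain"],
                start=int(r["start"]),
                end=int(r["end"]),
                n_hydroxylations=None if r["oh"] == "-" else int(r["oh"]),
                mass_column=r["mass_column"],
                prime_column=None if r["prime_column"] == "-" else r["prime_column"],
            )
        )
    return loci


def _load_variants(path=None) -> list[VariantRecord]:
    rows, _ = _read_tsv(path or _data_path("variants.tsv"))
    return [
        VariantRecord(
            locus_id=r["locus_id"],
            sequence=r["sequence"],
            n_hydroxylations=int(r["oh"]),
            nominal=int(r["nominal"]),
            prime_nominal=None if r["prime_nominal"] == "-" else int(r["prime_nominal"]),
        )
        for r in rows
    ]


def _load_shared(path=None) -> list[SharedPeptide]:
    rows, _ = _read_tsv(path or _data_path("shared_peptides.tsv"))
    return [
        SharedPeptide(
            label=r["label"],
            sequence=None if r["sequence"] == "-" else r["sequence"],
            n_hydroxylations=None if r["oh"] == "-" else int(r["oh"]),
            nominal=int(r["nominal"]),
        )
        for r in rows
    ]


def load_panel(path=None, loci_path=None, variants_path=None, shared_path=None) -> MarkerPanel:
    """Load a marker panel (the bundled reference panel by default).

    Raises :class:`PanelError` on schema violations: missing headers,
    non-integer cells, duplicate taxon paths, or a broken shared-locus
    invariant.
    """
    loci = _load_loci(loci_path)
    variants = _load_variants(variants_path)
    shared = _load_shared(shared_path)
    rows, header = _read_tsv(path or _data_path("panel.tsv"))

    for col in _META_COLUMNS:
        if col not in header:
            raise PanelError(f"panel file is missing required header column {col!r}")
    marker_columns = [c for c in header if c not in _META_COLUMNS]
    known_columns = {c for loc in loci for c in loc.columns}
    for col in marker_columns:
        if col not in known_columns:
            raise PanelError(f"unknown marker column {col!r} (no locus declares it)")
    for loc in loci:
        for col in loc.columns:
            if col not in marker_columns:
                raise PanelError(f"panel file is missing required header column {col!r}")

    # exact masses from sequence-bearing variants: (locus, nominal) -> exact
    exact: dict[tuple[str, int], float] = {}
    prime_of: dict[tuple[str, int], bool] = {}
    for v in variants:
        base = monoisotopic_mh(v.sequence, v.n_hydroxylations)
        exact.setdefault((v.locus_id, v.nominal), base)
        prime_of.setdefault((v.locus_id, v.nominal), False)
        if v.prime_nominal is not None:
            exact.setdefault((v.locus_id, v.prime_nominal), base + HYDROXYLATION_MASS)
            prime_of.setdefault((v.locus_id, v.prime_nominal), True)

    taxa: list[Taxon] = []
    cells: dict[tuple[str, str], tuple[MarkerValue, ...]] = {}
    for r in rows:
        name = r["name"]
        path_tuple = ("Bovidae", r["subfamily"], r["tribe"], r["group"])
        taxa.append(
            Taxon(
                name=name,
                path=path_tuple,
                member_species=tuple(s for s in r["members"].split(",") if s),
                evidence=r["evidence"],
            )
        )
        for loc in loci:
            values = []
            for col in loc.columns:
                mv = _parse_cell(r[col], name, col)
                key = (loc.locus_id, mv.nominal)
                values.append(
                    MarkerValue(
                        nominal=mv.nominal,
                        flag=mv.flag,
                        exact=exact.get(key),
                        is_prime=prime_of.get(key, col == loc.prime_column),
                    )
                )
            cells[(name, loc.locus_id)] = tuple(values)

    panel = MarkerPanel(
        loci=loci,
        taxa=taxa,
        cells=cells,
        variants=variants,
        shared_peptides=shared,
        column_order=list(header),
    )
    problems = panel.validate()
    if problems:
        raise PanelError("; ".join(problems))
    return panel


def save_panel(panel: MarkerPanel, path) -> None:
    """Write the panel in canonical TSV form (round-trips byte-identically)."""
    lines = ["\t".join(panel.column_order)]
    col_to_locus = {}
    for loc in panel.loci:
        for i, col in enumerate(loc.columns):
            col_to_locus[col] = (loc.locus_id, i)
    for t in panel.taxa:
        fields = {
            "name": t.name,
            "subfamily": t.path[1],
            "tribe": t.path[2],
            "group": t.path[3],
            "evidence": t.evidence,
            "members": ",".join(t.member_species),
        }
        row = []
        for col in panel.column_order:
            if col in fields:
                row.append(fields[col])
            else:
                lid, i = col_to_locus[col]
                row.append(panel.cells[(t.name, lid)][i].cell_text())
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# operations


def ambiguity_classes(panel: MarkerPanel, usable_loci: list[str] | None = None) -> list[frozenset[str]]:
    """Partition taxa into indistinguishability classes.

    Two taxa fall in the same class iff their profiles, restricted to the
    given loci and to usable (unflagged) values, are identical.  Caution
    and unusable masses carry no information, so they do not separate taxa.
    """
    groups: dict[tuple, list[str]] = {}
    for t in panel.taxa:
        key = panel.usable_profile(t.name, usable_loci)
        groups.setdefault(key, []).append(t.name)
    order = {name: i for i, name in enumerate(panel.taxon_names())}
    classes = [frozenset(names) for names in groups.values()]
    classes.sort(key=lambda c: min(order[n] for n in c))
    return classes


@dataclass
class MassCheck:
    locus_id: str
    sequence: str
    n_hydroxylations: int
    stored: int
    recomputed: int
    is_prime: bool

    @property
    def ok(self) -> bool:
        return self.stored == self.recomputed


@dataclass
class PanelReport:
    checks: list[MassCheck]
    uncovered_cells: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def mismatches(self) -> list[MassCheck]:
        return [c for c in self.checks if not c.ok]

    @property
    def ok(self) -> bool:
        return not self.mismatches and not self.uncovered_cells


def regenerate_panel_masses(panel: MarkerPanel) -> PanelReport:
    """Recompute the nominal m/z of every sequence-bearing variant.

    For each variant the stored hydroxylation count is applied and the
    floored [M+H]+ compared against the stored nominal mass (and, for
    Mass' columns, the stored value plus one extra hydroxylation).
    Additionally, every panel cell at a sequence-bearing locus must carry
    a value some variant reproduces; cells no variant can explain are
    reported, not silently accepted.
    """
    checks = []
    for v in panel.variants:
        base = monoisotopic_mh(v.sequence, v.n_hydroxylations)
        checks.append(
            MassCheck(v.locus_id, v.sequence, v.n_hydroxylations, v.nominal, nominal_mz(base), False)
        )
        if v.prime_nominal is not None:
            checks.append(
                MassCheck(
                    v.locus_id,
                    v.sequence,
                    v.n_hydroxylations + 1,
                    v.prime_nominal,
                    nominal_mz(base + HYDROXYLATION_MASS),
                    True,
                )
            )
    covered: dict[str, set[int]] = {}
    for v in panel.variants:
        base = monoisotopic_mh(v.sequence, v.n_hydroxylations)
        covered.setdefault(v.locus_id, set()).add(nominal_mz(base))
        if v.prime_nominal is not None:
            covered[v.locus_id].add(nominal_mz(base + HYDROXYLATION_MASS))
    uncovered = []
    for t in panel.taxa:
        for loc in panel.loci:
            if loc.locus_id not in covered:
                continue  # nominal-only locus, nothing to regenerate against
            for val in panel.cells[(t.name, loc.locus_id)]:
                if val.nominal not in covered[loc.locus_id]:
                    uncovered.append((t.name, loc.locus_id, val.nominal))
    return PanelReport(checks, uncovered_cells=uncovered)
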
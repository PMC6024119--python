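"""Core data types and delimited-text I/O for the representation pipeline.

The pipeline consumes three tables, all plain delimited text (comma or
tab, UTF-8, header row):

* long-format species presence records, one ``(species_id, unit_id)``
  pair per row;
* a planning-unit attribute table with stratum, land area, protected-area
  (PA) coverage and optionally per-year coverage columns;
* a species attribute table with taxon group, priority flags
  (threatened / nationally protected / endemic) and a region assignment.

Presence data is kept sparse: :class:`IncidenceMatrix` stores the binary
species x unit relation as two mirrored set indexes, which is how county
occurrence lists are published and how the greedy selection consumes
them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("comprep")

__all__ = [
    "ValidationError",
    "ConfigError",
    "IncidenceMatrix",
    "SpeciesRecord",
    "SpeciesTable",
    "UnitRecord",
    "UnitTable",
    "PaRecord",
    "read_presence_records",
    "write_presence_records",
    "read_species_table",
    "write_species_table",
    "read_unit_table",
    "write_unit_table",
    "allocate_pa_area",
    "pa_coverage_from_allocation",
    "cross_validate",
]


class ValidationError(ValueError):
    """Input data violates a structural contract."""


class ConfigError(ValueError):
    """A configuration value is out of range or inconsistent."""


_YEAR_COL = re.compile(r"^(?:coverage_)?(\d{4})$")
_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no", "", "nan"}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


# ---------------------------------------------------------------------------
# incidence matrix


class IncidenceMatrix:
    """Binary species x planning-unit presence relation.

    A record either exists or it does not; duplicated input pairs are
    collapsed (the count is kept in :attr:`n_duplicates` and logged by the
    readers). Every species occurs in at least one unit by construction.

    Parameters
    ----------
    records
        Iterable of ``(species_id, unit_id)`` pairs.
    """

    __slots__ = ("_species_of", "_units_of", "_units", "_species", "n_duplicates")

    def __init__(self, records: Iterable[tuple[str, str]]):
        species_of: dict[str, set[str]] = {}
        units_of: dict[str, set[str]] = {}
        total = 0
        n_pairs = 0
        for sp, unit in records:
            sp, unit = str(sp), str(unit)
            total += 1
            bucket = species_of.setdefault(unit, set())
            if sp not in bucket:
                bucket.add(sp)
                units_of.setdefault(sp, set()).add(unit)
                n_pairs += 1
        if not n_pairs:
            raise ValidationError("no presence records supplied")
        self.n_duplicates = total - n_pairs
        self._species_of = {u: frozenset(s) for u, s in species_of.items()}
        self._units_of = {s: frozenset(u) for s, u in units_of.items()}
        self._units = tuple(sorted(self._species_of))
        self._species = tuple(sorted(self._units_of))

    # -- basic accessors ---------------------------------------------------

    @property
    def units(self) -> tuple[str, ...]:
        """Sorted unit identifiers with at least one record."""
        return self._units

    @property
    def species(self) -> tuple[str, ...]:
        """Sorted species identifiers (each occurs in >= 1 unit)."""
        return self._species

    @property
    def n_units(self) -> int:
        return len(self._units)

    @property
    def n_species(self) -> int:
        return len(self._species)

    @property
    def n_records(self) -> int:
        return sum(len(s) for s in self._species_of.values())

    def species_of(self, unit: str) -> frozenset[str]:
        """Species set of *unit* (S_j as a set); empty for unknown units."""
        return self._species_of.get(unit, frozenset())

    def units_of(self, species: str) -> frozenset[str]:
        """Units where *species* occurs; empty for unknown species."""
        return self._units_of.get(species, frozenset())

    def richness(self, unit: str) -> int:
        """Species count S_j of *unit*."""
        return len(self.species_of(unit))

    def records(self) -> Iterator[tuple[str, str]]:
        """All (species_id, unit_id) pairs in sorted order."""
        for sp in self._species:
            for unit in sorted(self._units_of[sp]):
                yield (sp, unit)

    # -- derived matrices --------------------------------------------------

    def restrict_units(self, units: Iterable[str]) -> "IncidenceMatrix":
        """Sub-matrix on a unit subset; species losing all occurrences drop.

        Raises :class:`ValidationError` when the restriction is empty.
        """
        keep = set(units)
        recs = [
            (sp, u)
            for u in self._units
            if u in keep
            for sp in sorted(self._species_of[u])
        ]
        return IncidenceMatrix(recs)

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        species_col: str = "species_id",
        unit_col: str = "unit_id",
    ) -> "IncidenceMatrix":
        missing = [c for c in (species_col, unit_col) if c not in frame.columns]
        if missing:
            raise ValidationError(f"presence table lacks column(s) {missing}")
        return cls(zip(frame[species_col].astype(str), frame[unit_col].astype(str)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records(), columns=["species_id", "unit_id"])

    def __eq__(self, other) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return self._species_of == other._species_of

    def __hash__(self):  # pragma: no cover - identity hashing is enough
        return id(self)

    def __repr__(self) -> str:
        return (
            f"IncidenceMatrix({self.n_species} species x {self.n_units} units, "
            f"{self.n_records} records)"
        )


# ---------------------------------------------------------------------------
# species table


@dataclass(frozen=True)
class SpeciesRecord:
    """Per-species attributes used for prioritisation and reporting."""

    species_id: str
    taxon_group: str = "unknown"
    threatened: bool = False
    nationally_protected: bool = False
    endemic: bool = False
    region: str | None = None


class SpeciesTable:
    """Collection of :class:`SpeciesRecord`, unique by ``species_id``."""

    def __init__(self, records: Iterable[SpeciesRecord]):
        by_id: dict[str, SpeciesRecord] = {}
        dupes = []
        for rec in records:
            if rec.species_id in by_id:
                dupes.append(rec.species_id)
            by_id[rec.species_id] = rec
        if dupes:
            raise ValidationError(f"duplicate species_id(s): {sorted(set(dupes))}")
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self._by_id.values())

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._by_id

    def __getitem__(self, species_id: str) -> SpeciesRecord:
        return self._by_id[species_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._by_id)

    def record(self, species_id: str) -> SpeciesRecord:
        """Record for *species_id*; a default (all-flags-false) record when absent."""
        rec = self._by_id.get(species_id)
        return rec if rec is not None else SpeciesRecord(species_id)

    def ids_where(self, predicate: Callable[[SpeciesRecord], bool]) -> set[str]:
        return {r.species_id for r in self if predicate(r)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": [r.species_id for r in self],
                "taxon_group": [r.taxon_group for r in self],
                "threatened": [int(r.threatened) for r in self],
                "nationally_protected": [int(r.nationally_protected) for r in self],
                "endemic": [int(r.endemic) for r in self],
                "region": [r.region if r.region is not None else "" for r in self],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpeciesTable":
        if "species_id" not in frame.columns:
            raise ValidationError("species table lacks a species_id column")
        flags = ("threatened", "nationally_protected", "endemic")
        absent = [c for c in flags if c not in frame.columns]
        if absent:
            logger.info("species table lacks column(s) %s; defaulting to false", absent)
        records = []
        for row in frame.itertuples(index=False):
            d = row._asdict()
            region = d.get("region")
            if region is not None:
                region = str(region).strip() or None
                if region and region.lower() == "nan":
                    region = None
            records.append(
                SpeciesRecord(
                    species_id=str(d["species_id"]),
                    taxon_group=str(d.get("taxon_group", "unknown")),
                    threatened=_parse_bool(d.get("threatened", False)),
                    nationally_protected=_parse_bool(d.get("nationally_protected", False)),
                    endemic=_parse_bool(d.get("endemic", False)),
                    region=region,
                )
            )
        return cls(records)


# ---------------------------------------------------------------------------
# unit table


@dataclass(frozen=True)
class UnitRecord:
    """Per-planning-unit attributes.

    ``pa_present`` defaults to ``pa_coverage > 0`` but can be overridden
    explicitly, e.g. for units whose only PAs are recorded as points with
    no mapped area.
    """

    unit_id: str
    stratum: str
    area: float
    pa_coverage: float = 0.0
    pa_present: bool | None = None
    coverage_by_year: Mapping[int, float] | None = None

    def __post_init__(self):
        if not self.area > 0:
            raise ValidationError(f"unit {self.unit_id}: area must be > 0")
        if not 0.0 <= self.pa_coverage <= 1.0:
            raise ValidationError(
                f"unit {self.unit_id}: pa_coverage {self.pa_coverage} outside [0, 1]"
            )
        if self.pa_present is None:
            object.__setattr__(self, "pa_present", self.pa_coverage > 0)
        if self.coverage_by_year is not None:
            bad = {y: c for y, c in self.coverage_by_year.items() if not 0 <= c <= 1}
            if bad:
                raise ValidationError(
                    f"unit {self.unit_id}: yearly coverage outside [0, 1]: {bad}"
                )
            object.__setattr__(
                self,
                "coverage_by_year",
                {int(y): float(c) for y, c in sorted(self.coverage_by_year.items())},
            )


class UnitTable:
    """Collection of :class:`UnitRecord`, unique by ``unit_id``."""

    def __init__(self, records: Iterable[UnitRecord]):
        by_id: dict[str, UnitRecord] = {}
        dupes = []
        for rec in records:
            if rec.unit_id in by_id:
                dupes.append(rec.unit_id)
            by_id[rec.unit_id] = rec
        if dupes:
            raise ValidationError(f"duplicate unit_id(s): {sorted(set(dupes))}")
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[UnitRecord]:
        return iter(self._by_id.values())

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self._by_id

    def __getitem__(self, unit_id: str) -> UnitRecord:
        return self._by_id[unit_id]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._by_id)

    def strata(self) -> dict[str, str]:
        return {r.unit_id: r.stratum for r in self}

    def areas(self) -> dict[str, float]:
        return {r.unit_id: r.area for r in self}

    def years(self) -> tuple[int, ...]:
        """Years present in every unit's coverage_by_year (empty if none)."""
        sets = [
            set(r.coverage_by_year) for r in self if r.coverage_by_year is not None
        ]
        if len(sets) < len(self._by_id) or not sets:
            return ()
        common = set.intersection(*sets)
        return tuple(sorted(common))

    def to_frame(self) -> pd.DataFrame:
        years = sorted({y for r in self if r.coverage_by_year for y in r.coverage_by_year})
        data = {
            "unit_id": [r.unit_id for r in self],
            "stratum": [r.stratum for r in self],
            "area": [r.area for r in self],
            "pa_coverage": [r.pa_coverage for r in self],
            "pa_present": [int(bool(r.pa_present)) for r in self],
        }
        for y in years:
            data[f"coverage_{y}"] = [
                (r.coverage_by_year or {}).get(y, float("nan")) for r in self
            ]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "UnitTable":
        required = ["unit_id", "stratum", "area", "pa_coverage"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"unit table lacks column(s) {missing}")
        frame = frame.copy()
        frame["unit_id"] = frame["unit_id"].astype(str)
        cov = pd.to_numeric(frame["pa_coverage"], errors="coerce")
        bad = frame.loc[(cov < 0) | (cov > 1) | cov.isna(), "unit_id"].tolist()
        if bad:
            raise ValidationError(f"pa_coverage outside [0, 1] for unit(s): {bad}")
        area = pd.to_numeric(frame["area"], errors="coerce")
        bad = frame.loc[(area <= 0) | area.isna(), "unit_id"].tolist()
        if bad:
            raise ValidationError(f"non-positive area for unit(s): {bad}")
        year_cols = {
            c: int(m.group(1))
            for c in frame.columns
            if (m := _YEAR_COL.match(str(c))) is not None
        }
        records = []
        for row in frame.itertuples(index=False):
            d = row._asdict()
            present = d.get("pa_present")
            if present is not None and not (isinstance(present, float) and pd.isna(present)):
                present = _parse_bool(present)
            else:
                present = None
            cby = {
                year: float(d[col])
                for col, year in year_cols.items()
                if not pd.isna(d[col])
            } or None
            records.append(
                UnitRecord(
                    unit_id=str(d["unit_id"]),
                    stratum=str(d["stratum"]),
                    area=float(d["area"]),
                    pa_coverage=float(d["pa_coverage"]),
                    pa_present=present,
                    coverage_by_year=cby,
                )
            )
        return cls(records)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    import csv as _csv

    try:
        if sep is None:
            return pd.read_csv(path, sep=None, engine="python", dtype=str)
        return pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty input file") from exc
    except _csv.Error as exc:  # sniffer cannot see a delimiter (e.g. blank file)
        raise ValidationError(f"{path}: cannot parse delimited text ({exc})") from exc


def read_presence_records(
    path: str | Path,
    sep: str | None = None,
    species_col: str = "species_id",
    unit_col: str = "unit_id",
) -> IncidenceMatrix:
    """Read long-format presence records into an :class:`IncidenceMatrix`.

    The delimiter is sniffed when *sep* is None. Duplicated pairs are
    collapsed with a warning carrying the duplicate count.
    """
    frame = _read_table(path, sep)
    if frame.empty:
        raise ValidationError(f"{path}: no presence records")
    matrix = IncidenceMatrix.from_frame(frame, species_col, unit_col)
    if matrix.n_duplicates:
        logger.warning(
            "%s: collapsed %d duplicated presence record(s)", path, matrix.n_duplicates
        )
    return matrix


def write_presence_records(
    matrix: IncidenceMatrix, path: str | Path, sep: str = ","
) -> None:
    matrix.to_frame().to_csv(path, sep=sep, index=False)


def read_species_table(path: str | Path, sep: str | None = None) -> SpeciesTable:
    return SpeciesTable.from_frame(_read_table(path, sep))


def write_species_table(table: SpeciesTable, path: str | Path, sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)


def read_unit_table(path: str | Path, sep: str | None = None) -> UnitTable:
    return UnitTable.from_frame(_read_table(path, sep))


def write_unit_table(table: UnitTable, path: str | Path, sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False, float_format="%.10g")


def cross_validate(matrix: IncidenceMatrix, species: SpeciesTable) -> dict:
    """Cross-check the presence relation against the species table.

    Species present in the table but absent from the incidence matrix are
    retained (they simply never enter a selection universe); both
    directions are reported so callers can log them.
    """
    in_matrix = set(matrix.species)
    in_table = set(species.ids)
    report = {
        "absent_from_incidence": sorted(in_table - in_matrix),
        "missing_from_table": sorted(in_matrix - in_table),
    }
    if report["absent_from_incidence"]:
        logger.info(
            "%d species in the attribute table have no presence records",
            len(report["absent_from_incidence"]),
        )
    if report["missing_from_table"]:
        logger.info(
            "%d species in the presence records lack attribute rows (defaults used)",
            len(report["missing_from_table"]),
        )
    return report


# ---------------------------------------------------------------------------
# protected-area area allocation


@dataclass(frozen=True)
class PaRecord:
    """One protected area with the planning units it intersects.

    When ``unit_areas`` is None the PA's total area is split evenly across
    its units, the convention for PAs whose per-unit breakdown is not
    published.
    """

    pa_id: str
    total_area: float
    unit_ids: tuple[str, ...]
    unit_areas: tuple[float, ...] | None = None


def allocate_pa_area(pa_records: Iterable[PaRecord | tuple]) -> pd.DataFrame:
    """Allocate each PA's area to its planning units.

    Returns a frame with columns ``pa_id, unit_id, area``; per PA the
    allocated areas sum to the PA total when no breakdown is given, and
    are taken verbatim when one is.
    """
    rows = []
    for rec in pa_records:
        if not isinstance(rec, PaRecord):
            rec = PaRecord(*rec)
        if not rec.unit_ids:
            raise ValidationError(f"PA {rec.pa_id}: names zero planning units")
        if rec.unit_areas is None:
            share = rec.total_area / len(rec.unit_ids)
            areas = [share] * len(rec.unit_ids)
        else:
            if len(rec.unit_areas) != len(rec.unit_ids):
                raise ValidationError(
                    f"PA {rec.pa_id}: {len(rec.unit_areas)} areas for "
                    f"{len(rec.unit_ids)} units"
                )
            if any(a < 0 for a in rec.unit_areas):
                raise ValidationError(f"PA {rec.pa_id}: negative per-unit area")
            areas = list(rec.unit_areas)
        rows.extend(
            {"pa_id": rec.pa_id, "unit_id": u, "area": float(a)}
            for u, a in zip(rec.unit_ids, areas)
        )
    return pd.DataFrame(rows, columns=["pa_id", "unit_id", "area"])


def pa_coverage_from_allocation(
    allocation: pd.DataFrame, units: UnitTable
) -> dict[str, float]:
    """Sum per-unit PA contributions and convert to coverage fractions.

    Overlapping PAs add; the summed area is capped at the unit's land area
    (coverage 1.0) with a logged warning.
    """
    unknown = sorted(set(allocation["unit_id"].astype(str)) - set(units.ids))
    if unknown:
        raise ValidationError(f"allocation names unknown unit(s): {unknown}")
    sums = allocation.groupby("unit_id")["area"].sum()
    coverage: dict[str, float] = {}
    n_capped = 0
    for rec in units:
        pa_area = float(sums.get(rec.unit_id, 0.0))
        if pa_area > rec.area:
            n_capped += 1
            pa_area = rec.area
        coverage[rec.unit_id] = pa_area / rec.area
    if n_capped:
        logger.warning("PA coverage capped at 1.0 for %d unit(s)", n_capped)
    return coverage
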
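"""Scoring a protected-area layer against a complementary set.

Ecological representation of a PA network with respect to a CS is

    I_E = a / (a + b) x 100%,

where a counts CS units meeting the protection criterion (PA presence, or
PA coverage >= a threshold) and b the CS units that do not; a + b = |CS|.
CS units failing the criterion are the conservation gaps. Around that
single statistic this module provides gap species listings, the
congruence of the CS with the PA-holding units, the distribution of CS
area over PA-coverage classes, per-region species-capture effectiveness,
and the representation time series over a yearly coverage history.

Percentages are computed on exact rational counts and rounded half-up
only for presentation, so values printed at one decimal are reproducible
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import percentage
from .data import ConfigError, IncidenceMatrix, SpeciesTable, UnitTable, ValidationError
from .complementarity import ComplementarySet

__all__ = [
    "RepresentationResult",
    "GapReport",
    "CongruenceSummary",
    "RegionalEffectiveness",
    "select_protected_units",
    "representation_index",
    "identify_gaps",
    "congruence_summary",
    "coverage_class_areas",
    "regional_effectiveness",
    "representation_time_series",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_CLASS_EDGES",
]

#: coverage thresholds conventionally reported alongside the presence criterion
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40)

#: default coverage-class edges for the CS area distribution
DEFAULT_CLASS_EDGES: tuple[float, ...] = (0.0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60)


@dataclass(frozen=True)
class RepresentationResult:
    """Eq.-style representation of a CS under one protection criterion."""

    threshold: float | str  # coverage fraction, or the token "presence"
    a: int  # CS units meeting the criterion
    b: int  # CS units not meeting it (the gaps)
    i_e: float  # a/(a+b) x 100, rounded half-up to one decimal
    i_e_exact: float  # unrounded value
    s_p: frozenset[str]  # the qualifying-unit set the CS was scored against


@dataclass(frozen=True)
class GapReport:
    """CS units and species left unprotected under a criterion."""

    gap_units: frozenset[str]
    uncovered_species: frozenset[str]
    threatened_uncovered: frozenset[str]
    endemic_uncovered: frozenset[str]
    definition: str


@dataclass(frozen=True)
class CongruenceSummary:
    """Overlap between a CS and the PA-holding units, by count and by area."""

    n_union: int
    n_common: int
    pct_common: float  # one decimal
    pct_common_int: float  # integer presentation
    area_union: float
    area_common: float
    area_pct_common: float  # one decimal


@dataclass(frozen=True)
class RegionalEffectiveness:
    """Per-region (x taxon group) species capture of a CS, with summary."""

    per_region: pd.DataFrame  # columns: region[, taxon_group], n_species, n_captured, pct
    mean: float
    sd: float


def select_protected_units(
    units: UnitTable | Iterable, criterion: float | str = "presence"
) -> frozenset[str]:
    """Units meeting the protection criterion (the set S_P).

    ``criterion="presence"`` selects units where a PA exists regardless of
    coverage; a float t selects units with ``pa_coverage >= t``
    (inclusive).
    """
    if criterion == "presence":
        return frozenset(r.unit_id for r in units if r.pa_present)
    t = float(criterion)
    if not 0.0 <= t <= 1.0:
        raise ConfigError(f"coverage threshold {t} outside [0, 1]")
    return frozenset(r.unit_id for r in units if r.pa_coverage >= t)


def representation_index(
    cs: ComplementarySet,
    s_p: Iterable[str],
    threshold: float | str = "presence",
) -> RepresentationResult:
    """I_E = a/(a+b) x 100 for one protection criterion."""
    if not cs.members:
        raise ValidationError("representation index of an empty CS is undefined")
    s_p = frozenset(s_p)
    a = len(cs.members & s_p)
    b = len(cs.members) - a
    return RepresentationResult(
        threshold=threshold,
        a=a,
        b=b,
        i_e=percentage(a, a + b, 1),
        i_e_exact=100.0 * a / (a + b),
        s_p=s_p,
    )


def identify_gaps(
    cs: ComplementarySet,
    s_p: Iterable[str],
    incidence: IncidenceMatrix,
    universe: Iterable[str],
    species_table: SpeciesTable | None = None,
    definition: str = "rangewide",
) -> GapReport:
    """Gap units (CS members outside S_P) and the species they leave exposed.

    Two uncovered-species definitions are supported:

    * ``rangewide`` — universe species with zero occurrences in any
      protected unit nationwide (a species is unprotected outright);
    * ``cs_only`` — universe species whose occurrences within the CS lie
      entirely in gap units (species the CS intended to represent but
      whose selected sites are unprotected).
    """
    if definition not in ("rangewide", "cs_only"):
        raise ConfigError(f"unknown gap definition {definition!r}")
    s_p = frozenset(s_p)
    universe = frozenset(universe)
    gap_units = cs.members - s_p
    if definition == "rangewide":
        uncovered = frozenset(
            sp for sp in universe if not (incidence.units_of(sp) & s_p)
        )
    else:
        uncovered = frozenset(
            sp
            for sp in universe
            if (occ := incidence.units_of(sp) & cs.members) and occ <= gap_units
        )
    table = species_table if species_table is not None else SpeciesTable([])
    return GapReport(
        gap_units=frozenset(gap_units),
        uncovered_species=uncovered,
        threatened_uncovered=frozenset(
            sp for sp in uncovered if table.record(sp).threatened
        ),
        endemic_uncovered=frozenset(sp for sp in uncovered if table.record(sp).endemic),
        definition=definition,
    )


def congruence_summary(
    cs: ComplementarySet, pa_units: Iterable[str], units: UnitTable
) -> CongruenceSummary:
    """Count and area overlap of the CS with the PA-holding unit set.

    Percentages are taken over the union of the two sets; the integer
    presentation mirrors how count panels are conventionally printed.
    """
    pa_units = frozenset(pa_units)
    union = cs.members | pa_units
    common = cs.members & pa_units
    areas = units.areas()
    missing = sorted(u for u in union if u not in areas)
    if missing:
        raise ValidationError(f"unit table lacks area for unit(s): {missing[:10]}")
    area_union = sum(areas[u] for u in union)
    area_common = sum(areas[u] for u in common)
    return CongruenceSummary(
        n_union=len(union),
        n_common=len(common),
        pct_common=percentage(len(common), len(union), 1),
        pct_common_int=percentage(len(common), len(union), 0),
        area_union=area_union,
        area_common=area_common,
        area_pct_common=float(round(100.0 * area_common / area_union, 1)),
    )


def coverage_class_areas(
    cs: ComplementarySet,
    units: UnitTable,
    class_edges: Sequence[float] = DEFAULT_CLASS_EDGES,
) -> pd.DataFrame:
    """Distribute CS units and area over PA-coverage classes.

    A distinguished zero class holds units with coverage exactly 0 (no
    PA); positive coverage falls into half-open classes ``[lo, hi)``
    between consecutive edges, the last class extending to 1 inclusive.
    Counts sum to |CS| and area percentages to 100.
    """
    edges = [float(e) for e in class_edges]
    if edges != sorted(set(edges)) or edges[0] != 0.0 or edges[-1] > 1.0:
        raise ConfigError(f"class edges must be strictly increasing within [0, 1]: {edges}")
    bounds = list(zip(edges, edges[1:] + [1.0 + 1e-12]))
    labels = ["0"] + [
        f"({lo:g},{hi:g})" if lo == 0.0 else f"[{lo:g},{hi:g})"
        for lo, hi in zip(edges, edges[1:])
    ] + [f"[{edges[-1]:g},1]"]
    # classes: exact zero; (0, e1); [e1, e2); ...; [e_last, 1]
    rows = {label: {"n_units": 0, "area": 0.0} for label in labels}
    total_area = 0.0
    for unit in sorted(cs.members):
        rec = units[unit]
        total_area += rec.area
        if rec.pa_coverage == 0.0:
            label = labels[0]
        else:
            idx = max(
                i for i, (lo, hi) in enumerate(bounds) if rec.pa_coverage >= lo
            )
            label = labels[idx + 1]
        rows[label]["n_units"] += 1
        rows[label]["area"] += rec.area
    frame = pd.DataFrame(
        [
            {
                "coverage_class": label,
                "n_units": rows[label]["n_units"],
                "area": rows[label]["area"],
                "area_pct": 100.0 * rows[label]["area"] / total_area,
            }
            for label in labels
        ]
    )
    return frame


def regional_effectiveness(
    cs: ComplementarySet,
    incidence: IncidenceMatrix,
    species_regions: Mapping[str, str],
    unit_regions: Mapping[str, str],
    species_groups: Mapping[str, str] | None = None,
) -> RegionalEffectiveness:
    """Per-region capture proportion of the CS.

    For region r the proportion is the share of r's species that occur in
    at least one CS unit located in r, x 100. With *species_groups* the
    rows split by taxon group; the mean and sample standard deviation are
    taken across all emitted rows (regions, or region x group cells).
    """
    missing_sp = sorted(sp for sp in incidence.species if sp not in species_regions)
    missing_u = sorted(u for u in cs.members if u not in unit_regions)
    if missing_sp or missing_u:
        raise ValidationError(
            f"missing region assignments — species: {missing_sp[:10]}, "
            f"units: {missing_u[:10]}"
        )
    cs_units_in_region: dict[str, set[str]] = {}
    for u in cs.members:
        cs_units_in_region.setdefault(unit_regions[u], set()).add(u)

    def captured(sp: str, region: str) -> bool:
        return bool(incidence.units_of(sp) & cs_units_in_region.get(region, set()))

    rows = []
    regions = sorted(set(species_regions[sp] for sp in incidence.species))
    for region in regions:
        sp_here = [sp for sp in incidence.species if species_regions[sp] == region]
        if species_groups is None:
            cells = {None: sp_here}
        else:
            cells = {}
            for sp in sp_here:
                cells.setdefault(species_groups.get(sp, "unknown"), []).append(sp)
        for group in sorted(cells, key=str):
            members = cells[group]
            n_cap = sum(captured(sp, region) for sp in members)
            row = {
                "region": region,
                "n_species": len(members),
                "n_captured": n_cap,
                "pct": 100.0 * n_cap / len(members),
            }
            if group is not None:
                row["taxon_group"] = group
            rows.append(row)
    frame = pd.DataFrame(rows)
    mean = float(frame["pct"].mean())
    sd = float(frame["pct"].std(ddof=1)) if len(frame) > 1 else 0.0
    return RegionalEffectiveness(per_region=frame, mean=mean, sd=sd)


def representation_time_series(
    cs: ComplementarySet,
    units: UnitTable,
    criterion: float | str = "presence",
    years: Sequence[int] | None = None,
) -> dict[int, RepresentationResult]:
    """I_E per year from the units' yearly coverage history.

    Each year's protected-unit set is derived from ``coverage_by_year``
    (presence meaning coverage > 0 that year) and scored by the
    single-year path. No monotonicity is enforced: protected areas can be
    downsized or degazetted.
    """
    if years is None:
        years = units.years()
        if not years:
            raise ValidationError("no common coverage years across units")
    results: dict[int, RepresentationResult] = {}
    for year in years:
        year = int(year)
        cov: dict[str, float] = {}
        for rec in units:
            if rec.coverage_by_year is None or year not in rec.coverage_by_year:
                raise ValidationError(f"unit {rec.unit_id}: no coverage for year {year}")
            cov[rec.unit_id] = rec.coverage_by_year[year]
        if criterion == "presence":
            s_p = frozenset(u for u, c in cov.items() if c > 0)
        else:
            t = float(criterion)
            if not 0.0 <= t <= 1.0:
                raise ConfigError(f"coverage threshold {t} outside [0, 1]")
            s_p = frozenset(u for u, c in cov.items() if c >= t)
        results[year] = representation_index(cs, s_p, threshold=criterion)
    return results
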
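"""Pairwise complementarity and greedy complementary-set construction.

The complementarity score between two sites j and k with species sets of
size S_j and S_k sharing V_jk species is

    C_jk = 1 - V_jk / S_jk,        S_jk = S_j + S_k - V_jk,

i.e. one minus the Jaccard similarity of the two sets: 0 for identical
sets, 1 for disjoint ones.

A complementary set (CS) is assembled by staged greedy selection:

1. seed with the unit of greatest species richness within the target
   universe;
2. for the priority species class (nationally protected or threatened
   species), repeatedly add the unit with the greatest complementarity
   score against the pooled species of the current CS until the class is
   fully covered;
3. repeat for the remaining species.

Ties on the selection criterion are broken by total species richness,
then lexicographically by unit identifier, so a run is a deterministic
function of its inputs. Two selection modes are offered: maximising the
complementarity score against the pooled CS (the default), or the classic
richness-gain greedy that maximises the count of not-yet-covered species.
Candidates contributing no uncovered species are never selected — without
that restriction a small fully-covered unit could outscore units that
still add species and the loop would stall short of full coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .data import (
    ConfigError,
    IncidenceMatrix,
    SpeciesRecord,
    SpeciesTable,
    ValidationError,
)

__all__ = [
    "PairOverlap",
    "SelectionStep",
    "ComplementarySet",
    "SelectionConfig",
    "complementarity_score",
    "pooled_species",
    "greedy_step",
    "build_complementary_set",
    "write_trace",
    "read_trace",
]

Predicate = Callable[[SpeciesRecord], bool]


@dataclass(frozen=True)
class PairOverlap:
    """Species overlap of a site pair and its complementarity score C_jk."""

    s_j: int
    s_k: int
    v_jk: int
    s_jk: int
    c_jk: float


def complementarity_score(
    species_j: Iterable[str], species_k: Iterable[str]
) -> PairOverlap:
    """Score two species sets; symmetric, in [0, 1].

    Raises :class:`ValidationError` when both sets are empty (the score is
    a 0/0 form there).
    """
    a, b = set(species_j), set(species_k)
    v = len(a & b)
    s_union = len(a) + len(b) - v
    if s_union == 0:
        raise ValidationError("complementarity score undefined for two empty sets")
    return PairOverlap(s_j=len(a), s_k=len(b), v_jk=v, s_jk=s_union, c_jk=1 - v / s_union)


@dataclass(frozen=True)
class SelectionStep:
    """One selection event in a CS trace."""

    unit_id: str
    score: float
    n_new_species: int
    stage: str


@dataclass(frozen=True)
class ComplementarySet:
    """Ordered selection trace plus the covered-species ledger.

    ``steps`` is empty for externally supplied unit sets (e.g. a published
    site list being assessed rather than one built here).
    """

    steps: tuple[SelectionStep, ...]
    members: frozenset[str]
    covered_species: frozenset[str]
    universe_label: str = "all"

    def __post_init__(self):
        if self.steps:
            traced = {s.unit_id for s in self.steps}
            if traced != set(self.members):
                raise ValidationError("trace unit_ids do not match CS members")

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_members(
        cls,
        members: Iterable[str],
        incidence: IncidenceMatrix | None = None,
        universe: Iterable[str] | None = None,
        universe_label: str = "external",
    ) -> "ComplementarySet":
        """Wrap an externally supplied unit set for assessment.

        When an incidence matrix is given the covered-species ledger is
        filled in (optionally intersected with *universe*).
        """
        members = frozenset(str(m) for m in members)
        if not members:
            raise ValidationError("a complementary set cannot be empty")
        covered: frozenset[str] = frozenset()
        if incidence is not None:
            covered = frozenset().union(*(incidence.species_of(u) for u in members))
            if universe is not None:
                covered &= frozenset(universe)
        return cls(
            steps=(),
            members=members,
            covered_species=covered,
            universe_label=universe_label,
        )


def _universe_predicate(universe) -> tuple[Predicate, str]:
    if callable(universe):
        return universe, "custom"
    if universe == "all":
        return (lambda r: True), "all"
    if universe == "threatened":
        return (lambda r: r.threatened), "threatened"
    raise ConfigError(f"unknown universe {universe!r}")


def default_stages() -> tuple[tuple[str, Predicate], ...]:
    """Priority species (nationally protected or threatened) first, rest after."""
    return (
        ("priority", lambda r: r.nationally_protected or r.threatened),
        ("remainder", lambda r: True),
    )


@dataclass
class SelectionConfig:
    """Configuration of the staged greedy selection.

    Parameters
    ----------
    universe
        ``"all"``, ``"threatened"``, or a predicate over
        :class:`SpeciesRecord` defining the target species universe.
    stages
        Ordered ``(label, predicate)`` pairs; classes are made disjoint by
        sequential subtraction and must jointly cover the universe.
    mode
        ``"complementarity_score"`` (default) or ``"new_species_count"``.
    tie_breakers
        Order of the secondary tie-breaks after the selection criterion;
        must end with ``"unit_id"`` so selection is a total order.
    """

    universe: str | Predicate = "all"
    stages: Sequence[tuple[str, Predicate]] | None = None
    mode: str = "complementarity_score"
    tie_breakers: tuple[str, ...] = ("richness", "unit_id")

    def __post_init__(self):
        if self.mode not in ("complementarity_score", "new_species_count"):
            raise ConfigError(f"unknown selection mode {self.mode!r}")
        if not self.tie_breakers or self.tie_breakers[-1] != "unit_id":
            raise ConfigError("tie_breakers must end with 'unit_id'")
        if any(t not in ("richness", "unit_id") for t in self.tie_breakers):
            raise ConfigError(f"unknown tie-breaker in {self.tie_breakers}")


def pooled_species(
    cs: ComplementarySet, incidence: IncidenceMatrix, universe: Iterable[str]
) -> frozenset[str]:
    """Union of the members' species sets intersected with *universe*.

    The CS is treated as one composite site; this is the set the candidate
    score is computed against.
    """
    universe = frozenset(universe)
    pooled: set[str] = set()
    for unit in cs.members:
        pooled |= incidence.species_of(unit) & universe
    return frozenset(pooled)


def _candidate_key(score, richness, unit_id, tie_breakers):
    key = [-score]
    for tb in tie_breakers:
        key.append(-richness if tb == "richness" else unit_id)
    return tuple(key)


def greedy_step(
    incidence: IncidenceMatrix,
    cs: ComplementarySet,
    universe: Iterable[str],
    config: SelectionConfig | None = None,
) -> tuple[str, PairOverlap, int] | None:
    """One greedy selection against *universe*, or None when exhausted.

    Only units contributing at least one uncovered universe species are
    candidates; among them the configured criterion is maximised (scores
    and overlaps are computed on species restricted to *universe*).
    """
    config = config or SelectionConfig()
    universe = frozenset(universe)
    covered = cs.covered_species & universe
    best_key = None
    best: tuple[str, PairOverlap, int] | None = None
    for unit in incidence.units:
        if unit in cs.members:
            continue
        cand = incidence.species_of(unit) & universe
        gain = len(cand - covered)
        if gain == 0:
            continue
        overlap = complementarity_score(cand, covered)
        score = overlap.c_jk if config.mode == "complementarity_score" else float(gain)
        key = _candidate_key(score, incidence.richness(unit), unit, config.tie_breakers)
        if best_key is None or key < best_key:
            best_key = key
            best = (unit, overlap, gain)
    return best


def build_complementary_set(
    incidence: IncidenceMatrix,
    species_table: SpeciesTable | None = None,
    config: SelectionConfig | None = None,
) -> ComplementarySet:
    """Build a complementary set covering the configured species universe.

    The seed is the unit of greatest richness within the universe; each
    stage then iterates :func:`greedy_step` on its species class until the
    class is covered. The returned trace records, per step, the stage
    label, the selection score (universe richness for the seed) and the
    number of universe species newly covered.
    """
    config = config or SelectionConfig()
    table = species_table if species_table is not None else SpeciesTable([])
    universe_pred, default_label = _universe_predicate(config.universe)
    universe = frozenset(
        sp for sp in incidence.species if universe_pred(table.record(sp))
    )
    if not universe:
        raise ValidationError("selection universe is empty")

    # disjoint stage universes by sequential subtraction
    stage_defs = tuple(config.stages) if config.stages is not None else default_stages()
    assigned: set[str] = set()
    stage_universes: list[tuple[str, frozenset[str]]] = []
    for label, pred in stage_defs:
        su = frozenset(
            sp for sp in universe if sp not in assigned and pred(table.record(sp))
        )
        assigned |= su
        stage_universes.append((label, su))
    if assigned != set(universe):
        raise ConfigError(
            f"priority classes leave {len(universe - assigned)} species unassigned"
        )

    def univ_richness(u: str) -> int:
        return len(incidence.species_of(u) & universe)

    seed = min(
        incidence.units,
        key=lambda u: _candidate_key(
            float(univ_richness(u)), incidence.richness(u), u, config.tie_breakers
        ),
    )
    covered = set(incidence.species_of(seed) & universe)
    members = {seed}
    steps = [
        SelectionStep(
            unit_id=seed,
            score=float(univ_richness(seed)),
            n_new_species=len(covered),
            stage="seed",
        )
    ]

    for label, stage_universe in stage_universes:
        while stage_universe - covered:
            state = ComplementarySet(
                steps=tuple(steps),
                members=frozenset(members),
                covered_species=frozenset(covered),
                universe_label=default_label,
            )
            picked = greedy_step(incidence, state, stage_universe, config)
            if picked is None:  # cannot occur on a valid matrix; guard anyway
                break
            unit, overlap, _ = picked
            newly = (incidence.species_of(unit) & universe) - covered
            covered |= newly
            members.add(unit)
            score = (
                overlap.c_jk
                if config.mode == "complementarity_score"
                else float(len(newly & stage_universe))
            )
            steps.append(
                SelectionStep(
                    unit_id=unit,
                    score=score,
                    n_new_species=len(newly),
                    stage=label,
                )
            )

    return ComplementarySet(
        steps=tuple(steps),
        members=frozenset(members),
        covered_species=frozenset(covered),
        universe_label=default_label,
    )


# ---------------------------------------------------------------------------
# trace I/O


def write_trace(
    cs: ComplementarySet,
    path: str | Path,
    manifest_path: str | Path | None = None,
    manifest_extra: Mapping | None = None,
    sep: str = ",",
) -> None:
    """Write the selection trace as delimited text (+ optional JSON manifest)."""
    rows = []
    cumulative = 0
    for i, step in enumerate(cs.steps, start=1):
        cumulative += step.n_new_species
        rows.append(
            {
                "step": i,
                "stage": step.stage,
                "unit_id": step.unit_id,
                "score": step.score,
                "n_new_species": step.n_new_species,
                "cumulative_covered": cumulative,
            }
        )
    if not rows:  # externally supplied set: members only
        rows = [
            {
                "step": i,
                "stage": "external",
                "unit_id": u,
                "score": float("nan"),
                "n_new_species": 0,
                "cumulative_covered": 0,
            }
            for i, u in enumerate(sorted(cs.members), start=1)
        ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.6g")
    if manifest_path is not None:
        manifest = {
            "universe_label": cs.universe_label,
            "n_members": len(cs.members),
            "n_covered_species": len(cs.covered_species),
            "seed_unit": cs.steps[0].unit_id if cs.steps else None,
        }
        if manifest_extra:
            manifest.update(manifest_extra)
        Path(manifest_path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_trace(
    path: str | Path,
    incidence: IncidenceMatrix | None = None,
    sep: str | None = None,
) -> ComplementarySet:
    """Read a trace written by :func:`write_trace` back into a CS.

    With an incidence matrix the covered-species ledger is recomputed;
    without one it is left empty (member-only operations still work).
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = {"step", "stage", "unit_id", "score", "n_new_species"}
    if not required <= set(frame.columns):
        raise ValidationError(f"{path}: not a CS trace (columns {list(frame.columns)})")
    frame = frame.sort_values("step")
    if (frame["stage"] == "external").all():
        return ComplementarySet.from_members(
            frame["unit_id"].astype(str), incidence=incidence
        )
    steps = tuple(
        SelectionStep(
            unit_id=str(r.unit_id),
            score=float(r.score),
            n_new_species=int(r.n_new_species),
            stage=str(r.stage),
        )
        for r in frame.itertuples(index=False)
    )
    members = frozenset(s.unit_id for s in steps)
    covered: frozenset[str] = frozenset()
    if incidence is not None:
        covered = frozenset().union(*(incidence.species_of(u) for u in members))
    return ComplementarySet(steps=steps, members=members, covered_species=covered)
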
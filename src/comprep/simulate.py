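"""Synthetic species-occurrence and protected-area data.

The generator emulates the statistical shape of a national county-level
occurrence database without any spatial geometry: several taxon groups of
very different sizes; a heavy-tailed occupancy distribution (many
narrow-range species, a few widespread ones) drawn from a truncated
log-series by default; species ranges clustered within a home
biogeographic stratum; threatened/protected/endemic flags at configured
per-group fractions with threatened species biased toward narrow ranges;
and a zero-inflated, right-skewed PA-coverage layer in which most units
have little or no protection and a minority are well covered.

Strata double as the bootstrap stratification and as the region
assignment for regional effectiveness, mirroring how biogeographic
regionalisations are used for both purposes.

Also provided: planted known-answer fixtures whose unique minimal cover
is recorded in a manifest (for exercising the greedy selector), and a
yearly PA-coverage timeline generator (for the representation time
series), with an optional degazettement regime in which coverage can
occasionally decrease.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import (
    ConfigError,
    IncidenceMatrix,
    SpeciesRecord,
    SpeciesTable,
    UnitRecord,
    UnitTable,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "PlantedFixture",
    "simulate_dataset",
    "simulate_planted_cover",
    "simulate_pa_timeline",
    "DEFAULT_SPECIES_PER_GROUP",
    "DEFAULT_THREATENED_FRACTION",
]

# Desk-scale emulation of a national six-taxon database: group sizes at
# roughly 1/25 of a realistic national flora/fauna, units at ~1/10.
DEFAULT_SPECIES_PER_GROUP: dict[str, int] = {
    "woody_plant": 416,
    "fern": 92,
    "amphibian": 16,
    "reptile": 18,
    "bird": 55,
    "mammal": 24,
}

# Threatened shares per group, patterned on national red-list ratios
# (amphibians and reptiles far more threatened than birds or ferns).
DEFAULT_THREATENED_FRACTION: dict[str, float] = {
    "woody_plant": 0.143,
    "fern": 0.064,
    "amphibian": 0.433,
    "reptile": 0.300,
    "bird": 0.107,
    "mammal": 0.264,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset generator.

    ``occupancy_distribution`` is ``("logseries", {"p": ...})`` (default;
    heavy-tailed, most species narrow-ranged) or ``("lognormal",
    {"mean": ..., "sigma": ...})`` on per-species unit counts; draws are
    truncated to ``[1, n_units]``. ``range_cohesion`` is the probability
    mass of a species' occurrences placed in its home stratum.
    ``threat_range_bias`` > 0 biases threatened (and endemic) flags toward
    narrow-ranged species, rank-correlating threat with small range.
    """

    n_units: int = 240
    n_strata: int = 8
    species_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_PER_GROUP)
    )
    occupancy_distribution: tuple[str, Mapping[str, float]] = (
        "logseries",
        {"p": 0.98},
    )
    range_cohesion: float = 0.8
    threatened_fraction: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THREATENED_FRACTION)
    )
    protected_fraction: float | Mapping[str, float] = 0.10
    endemic_fraction: float | Mapping[str, float] = 0.35
    threat_range_bias: float = 1.0
    pa_zero_fraction: float = 0.30
    pa_coverage_distribution: tuple[str, Mapping[str, float]] = (
        "beta",
        {"a": 1.1, "b": 8.0},
    )
    area_lognormal: tuple[float, float] = (12.6, 0.6)  # ln-hectares mean/sd
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 1 or self.n_strata < 1 or self.n_strata > self.n_units:
            raise ConfigError("need 1 <= n_strata <= n_units")
        if not self.species_per_group or any(
            n < 1 for n in self.species_per_group.values()
        ):
            raise ConfigError("species_per_group entries must be >= 1")
        if not 0.5 <= self.range_cohesion <= 1.0:
            raise ConfigError("range_cohesion must lie in [0.5, 1]")
        if not 0.0 <= self.pa_zero_fraction <= 1.0:
            raise ConfigError("pa_zero_fraction must lie in [0, 1]")
        for name in ("threatened_fraction", "protected_fraction", "endemic_fraction"):
            value = getattr(self, name)
            values = value.values() if isinstance(value, Mapping) else [value]
            if any(not 0.0 <= v <= 1.0 for v in values):
                raise ConfigError(f"{name} must lie in [0, 1]")

    def fraction_for(self, name: str, group: str) -> float:
        value = getattr(self, name)
        if isinstance(value, Mapping):
            return float(value.get(group, 0.0))
        return float(value)


@dataclass(frozen=True)
class SimulatedDataset:
    incidence: IncidenceMatrix
    species: SpeciesTable
    units: UnitTable
    config: SimulationConfig


def _draw_occupancy(
    kind: str, params: Mapping[str, float], size: int, n_units: int, rng
) -> np.ndarray:
    if kind == "logseries":
        p = float(params.get("p", 0.98))
        if not 0 < p < 1:
            raise ConfigError(f"log-series parameter p must lie in (0, 1): {p}")
        draws = stats.logser.rvs(p, size=size, random_state=rng)
    elif kind == "lognormal":
        mean = float(params.get("mean", 1.5))
        sigma = float(params.get("sigma", 1.2))
        draws = np.rint(rng.lognormal(mean, sigma, size=size))
    else:
        raise ConfigError(f"unknown occupancy distribution {kind!r}")
    return np.clip(draws, 1, n_units).astype(int)


def truncated_occupancy_mean(
    kind: str, params: Mapping[str, float], n_units: int
) -> float:
    """Mean of the occupancy distribution after truncation to [1, n_units].

    Computed by direct summation of the probability mass (log-series) or
    numerically over a fine grid (lognormal); used to check that realised
    occupancies match the configured distribution.
    """
    if kind == "logseries":
        p = float(params.get("p", 0.98))
        k = np.arange(1, 200_000)
        pmf = stats.logser.pmf(k, p)
        clipped = np.minimum(k, n_units)
        return float(np.sum(pmf * clipped) / np.sum(pmf))
    if kind == "lognormal":
        mean = float(params.get("mean", 1.5))
        sigma = float(params.get("sigma", 1.2))
        # distribution of rint(X) clipped to [1, n_units]
        k = np.arange(0, 200_000)
        upper = stats.lognorm.cdf(k + 0.5, s=sigma, scale=np.exp(mean))
        lower = stats.lognorm.cdf(np.maximum(k - 0.5, 0), s=sigma, scale=np.exp(mean))
        pmf = upper - lower
        pmf[-1] += 1 - upper[-1]
        clipped = np.clip(k, 1, n_units)
        return float(np.sum(pmf * clipped))
    raise ConfigError(f"unknown occupancy distribution {kind!r}")


def _flag_sample(rng, ids: list[str], occupancy: np.ndarray, frac: float, bias: float):
    """Choose round(frac*n) ids without replacement, weighted toward narrow ranges."""
    k = int(round(frac * len(ids)))
    if k == 0:
        return set()
    weights = occupancy.astype(float) ** (-bias)
    weights = weights / weights.sum()
    return set(rng.choice(ids, size=k, replace=False, p=weights).tolist())


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate an incidence matrix plus species and unit tables.

    Fully reproducible from ``config.seed``; every species occurs in at
    least one unit by construction.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_units))
    unit_ids = [f"u{i:0{width}d}" for i in range(1, cfg.n_units + 1)]
    strata = [f"str{(i % cfg.n_strata) + 1}" for i in range(cfg.n_units)]
    stratum_of = dict(zip(unit_ids, strata))
    units_by_stratum: dict[str, list[str]] = {}
    for u, s in stratum_of.items():
        units_by_stratum.setdefault(s, []).append(u)
    stratum_names = sorted(units_by_stratum)

    kind, params = cfg.occupancy_distribution
    records: list[tuple[str, str]] = []
    species_records: list[SpeciesRecord] = []
    others_by_stratum = {
        s: [u for u in unit_ids if stratum_of[u] != s] for s in stratum_names
    }

    for group in sorted(cfg.species_per_group):
        n_sp = int(cfg.species_per_group[group])
        ids = [f"{group}_{i:04d}" for i in range(1, n_sp + 1)]
        homes = rng.choice(stratum_names, size=n_sp)
        occ = _draw_occupancy(kind, params, n_sp, cfg.n_units, rng)
        for sp, home, n in zip(ids, homes, occ):
            home_units = units_by_stratum[home]
            other_units = others_by_stratum[home]
            n = int(n)
            # ~range_cohesion of the range in the home stratum, always >= 1
            # occurrence there, saturating gracefully for widespread species
            n_home = min(len(home_units), max(1, round(cfg.range_cohesion * n)))
            n_home = max(n_home, n - len(other_units))
            n_other = n - n_home
            chosen = list(rng.choice(home_units, size=n_home, replace=False))
            if n_other > 0:
                chosen += list(rng.choice(other_units, size=n_other, replace=False))
            records.extend((sp, str(u)) for u in chosen)
        threatened = _flag_sample(
            rng, ids, occ, cfg.fraction_for("threatened_fraction", group),
            cfg.threat_range_bias,
        )
        protected = _flag_sample(
            rng, ids, occ, cfg.fraction_for("protected_fraction", group),
            cfg.threat_range_bias / 2,
        )
        endemic = _flag_sample(
            rng, ids, occ, cfg.fraction_for("endemic_fraction", group),
            cfg.threat_range_bias,
        )
        species_records.extend(
            SpeciesRecord(
                species_id=sp,
                taxon_group=group,
                threatened=sp in threatened,
                nationally_protected=sp in protected,
                endemic=sp in endemic,
                region=home,
            )
            for sp, home in zip(ids, homes)
        )

    ckind, cparams = cfg.pa_coverage_distribution
    if ckind != "beta":
        raise ConfigError(f"unknown pa_coverage distribution {ckind!r}")
    coverage = rng.beta(cparams["a"], cparams["b"], size=cfg.n_units)
    zero = rng.random(cfg.n_units) < cfg.pa_zero_fraction
    coverage[zero] = 0.0
    areas = rng.lognormal(*cfg.area_lognormal, size=cfg.n_units)
    unit_records = [
        UnitRecord(
            unit_id=u,
            stratum=stratum_of[u],
            area=float(a),
            pa_coverage=float(min(c, 1.0)),
        )
        for u, a, c in zip(unit_ids, areas, coverage)
    ]

    return SimulatedDataset(
        incidence=IncidenceMatrix(records),
        species=SpeciesTable(species_records),
        units=UnitTable(unit_records),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# planted known-answer fixture


@dataclass(frozen=True)
class PlantedFixture:
    """Synthetic dataset with a known unique minimal cover (in the manifest)."""

    incidence: IncidenceMatrix
    species: SpeciesTable
    units: UnitTable
    manifest: dict


def simulate_planted_cover(
    k_blocks: int,
    extra_units: int = 0,
    decoys_per_block: int = 2,
    seed: int = 0,
    species_per_block: int = 3,
) -> PlantedFixture:
    """Block structure whose unique minimal cover is k designated units.

    Each designated unit is the sole holder of one single-site endemic
    species (hence irreplaceable) plus ``species_per_block - 1`` species
    shared with its decoys; decoy and extra units carry only species
    already held by designated units, so they can never enter a correct
    CS. The manifest records the planted units, decoys and the minimal
    cover for consumption by tests.
    """
    if k_blocks < 1:
        raise ConfigError("k_blocks must be >= 1")
    if species_per_block < 1:
        raise ConfigError("species_per_block must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    species_records: list[SpeciesRecord] = []
    planted, decoys, extras = [], [], []
    shared_pool: list[str] = []
    for b in range(1, k_blocks + 1):
        unit = f"P{b:02d}"
        planted.append(unit)
        unique_sp = f"b{b:02d}_endemic"
        species_records.append(
            SpeciesRecord(
                species_id=unique_sp,
                taxon_group="planted",
                threatened=True,
                endemic=True,
                region=f"str{(b - 1) % min(k_blocks, 4) + 1}",
            )
        )
        records.append((unique_sp, unit))
        block_shared = []
        for s in range(1, species_per_block):
            sp = f"b{b:02d}_s{s}"
            block_shared.append(sp)
            shared_pool.append(sp)
            species_records.append(
                SpeciesRecord(
                    species_id=sp,
                    taxon_group="planted",
                    region=f"str{(b - 1) % min(k_blocks, 4) + 1}",
                )
            )
            records.append((sp, unit))
        for d in range(1, decoys_per_block + 1):
            decoy = f"D{b:02d}_{d}"
            decoys.append(decoy)
            if block_shared:
                take = 1 + int(rng.integers(0, len(block_shared)))
                for sp in rng.choice(block_shared, size=take, replace=False):
                    records.append((str(sp), decoy))
            else:  # no shared species in block: decoy duplicates nothing new
                pass
    for e in range(1, extra_units + 1):
        unit = f"E{e:02d}"
        extras.append(unit)
        if shared_pool:
            take = 1 + int(rng.integers(0, min(2, len(shared_pool))))
            for sp in rng.choice(shared_pool, size=take, replace=False):
                records.append((str(sp), unit))
    # decoy/extra units that ended up with no species are dropped implicitly
    matrix = IncidenceMatrix(records)
    n_strata = min(k_blocks, 4)

    def stratum_of_unit(u: str) -> str:
        if u[0] in ("P", "D"):  # P<block> / D<block>_<i>: stratum of the block
            block = int(u[1:3])
            return f"str{(block - 1) % n_strata + 1}"
        return f"str{int(u[1:]) % n_strata + 1}"

    unit_records = [
        UnitRecord(unit_id=u, stratum=stratum_of_unit(u), area=1000.0, pa_coverage=0.0)
        for u in matrix.units
    ]
    manifest = {
        "planted_units": planted,
        "decoy_units": [d for d in decoys if d in matrix.units],
        "extra_units": [e for e in extras if e in matrix.units],
        "minimal_cover": planted,
        "k_blocks": k_blocks,
        "seed": seed,
    }
    return PlantedFixture(
        incidence=matrix,
        species=SpeciesTable(species_records),
        units=UnitTable(unit_records),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# yearly PA-coverage timeline


def simulate_pa_timeline(
    units: UnitTable,
    years: Sequence[int],
    growth_rule: str = "monotone",
    rate: float = 0.1,
    seed: int = 0,
) -> UnitTable:
    """Attach a per-unit yearly coverage path ending at today's coverage.

    ``monotone``: zero until a random establishment year, then a
    non-decreasing ramp up to the unit's current coverage. ``constant``:
    every year equals the current coverage. ``with_degazettement``: a random walk from the current
    coverage in which each yearly transition decreases with probability
    *rate* (protected areas being downsized or degazetted).
    """
    years = [int(y) for y in years]
    if years != sorted(years):
        raise ConfigError("years must be ordered")
    if growth_rule not in ("monotone", "constant", "with_degazettement"):
        raise ConfigError(f"unknown growth rule {growth_rule!r}")
    rng = np.random.default_rng(seed)
    out = []
    for rec in units:
        n = len(years)
        if growth_rule == "constant":
            path = np.full(n, rec.pa_coverage)
        elif growth_rule == "monotone":
            # zero before a random establishment year, then a rising ramp
            path = np.zeros(n)
            if n and rec.pa_coverage > 0:
                start = int(rng.integers(0, n))
                ramp = np.sort(rng.uniform(0.0, 1.0, size=n - start))
                ramp[-1] = 1.0
                path[start:] = rec.pa_coverage * ramp
        else:
            path = np.empty(n)
            path[0] = rec.pa_coverage
            for t in range(1, n):
                delta = rng.uniform(0.0, 0.05)
                sign = -1.0 if rng.random() < rate else 1.0
                path[t] = float(np.clip(path[t - 1] + sign * delta, 0.0, 1.0))
        out.append(
            dataclasses.replace(
                rec, coverage_by_year=dict(zip(years, (float(c) for c in path)))
            )
        )
    return UnitTable(out)
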
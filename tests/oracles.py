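"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and written against plain dicts of
sets, independent of the package's own data structures and selection
code paths.
"""

from __future__ import annotations

from itertools import combinations


def random_instance(rng, max_units=12, max_species=20):
    """Random unit->species-set instance; every species occurs somewhere."""
    n_units = int(rng.integers(2, max_units + 1))
    n_species = int(rng.integers(2, max_species + 1))
    species = [f"s{i}" for i in range(n_species)]
    units = {f"u{j:02d}": set() for j in range(n_units)}
    unit_ids = list(units)
    for sp in species:
        k = int(rng.integers(1, n_units + 1))
        k = min(k, 1 + int(rng.geometric(0.5)))  # skew toward narrow ranges
        for u in rng.choice(unit_ids, size=min(k, n_units), replace=False):
            units[str(u)].add(sp)
    # guarantee occurrence
    for sp in species:
        if not any(sp in s for s in units.values()):
            units[str(rng.choice(unit_ids))].add(sp)
    return {u: s for u, s in units.items() if s}


def exact_min_cover_size(units: dict[str, set], universe: set) -> int:
    """Size of a minimum set cover, by exhaustive search over subset sizes."""
    ids = sorted(units)
    for size in range(1, len(ids) + 1):
        for combo in combinations(ids, size):
            if set().union(*(units[u] for u in combo)) >= universe:
                return size
    raise AssertionError("universe not coverable")


def naive_staged_greedy(
    units: dict[str, set],
    universe: set,
    priority: set = frozenset(),
    mode: str = "complementarity_score",
) -> list[str]:
    """Straight-line simulation of the staged greedy selection.

    Seed on richness within the universe, then cover the priority class,
    then the remainder; candidate scores restricted to the stage's
    species; ties broken by total richness then unit id.
    """
    universe = set(universe)

    def total_rich(u):
        return len(units[u])

    seed = sorted(
        units, key=lambda u: (-len(units[u] & universe), -total_rich(u), u)
    )[0]
    chosen = [seed]
    covered = units[seed] & universe
    for stage_universe in (priority & universe, universe - priority):
        while stage_universe - covered:
            best, best_key = None, None
            for u in sorted(units):
                if u in chosen:
                    continue
                cand = units[u] & stage_universe
                stage_covered = covered & stage_universe
                gain = len(cand - stage_covered)
                if gain == 0:
                    continue
                union = len(cand | stage_covered)
                shared = len(cand & stage_covered)
                score = 1 - shared / union if mode == "complementarity_score" else gain
                key = (-score, -total_rich(u), u)
                if best_key is None or key < best_key:
                    best, best_key = u, key
            if best is None:
                break
            chosen.append(best)
            covered |= units[best] & universe
    return chosen
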
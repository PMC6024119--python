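"""Stratified bootstrap of complementary-set construction.

Occurrence databases carry geographical sampling bias, and greedy site
selection is sensitive to it through rare species. To quantify that
sensitivity, planning units are resampled within biogeographic strata
(so every environmental region stays represented), a CS is rebuilt on
each subset, and the proportional overlap

    overlap = N_c / N_s

is recorded, where N_s is the size of the subset-derived CS and N_c the
number of its units shared with the full-data CS. High mean overlaps
across sampling fractions indicate the selection is robust to which
units happened to be sampled.

Reproducibility: one master seed spawns an independent RNG substream per
(fraction, replicate) cell via ``SeedSequence(seed, spawn_key=...)``, so
the replicate table is a pure function of the configuration and the
first 200 replicates of a 1000-replicate run match a 200-replicate run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ConfigError, IncidenceMatrix, SpeciesTable, UnitTable, ValidationError
from .complementarity import ComplementarySet, SelectionConfig, build_complementary_set

logger = logging.getLogger("comprep")

__all__ = [
    "OverlapResult",
    "BootstrapConfig",
    "BootstrapResult",
    "stratified_sample",
    "proportional_overlap",
    "bootstrap_robustness",
]


@dataclass(frozen=True)
class OverlapResult:
    """Proportional overlap of one subset-derived CS with the original."""

    fraction: float
    replicate: int
    n_s: int
    n_c: int
    overlap: float
    failed: bool = False


@dataclass
class BootstrapConfig:
    """Bootstrap settings.

    ``fractions`` are the per-stratum sampling proportions; ``replicates``
    can be reduced for large universes where a CS build is expensive.
    """

    fractions: Sequence[float] = (0.60, 0.70, 0.80, 0.90)
    replicates: int = 1000
    seed: int = 0
    stratum_field: str = "stratum"

    def __post_init__(self):
        if not self.fractions or any(not 0 < f <= 1 for f in self.fractions):
            raise ConfigError(f"fractions must lie in (0, 1]: {self.fractions}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.stratum_field != "stratum":
            raise ConfigError("only the 'stratum' unit attribute is available as a stratum")


def stratified_sample(
    units: UnitTable, fraction: float, rng: np.random.Generator
) -> frozenset[str]:
    """Sample units independently within each stratum, without replacement.

    Per stratum of size n, round-half-up(fraction x n) units are drawn
    (at least 1), so every stratum stays represented in the subset.
    """
    if not 0 < fraction <= 1:
        raise ConfigError(f"fraction {fraction} outside (0, 1]")
    by_stratum: dict[str, list[str]] = {}
    for rec in units:
        by_stratum.setdefault(rec.stratum, []).append(rec.unit_id)
    chosen: set[str] = set()
    for stratum in sorted(by_stratum):
        ids = sorted(by_stratum[stratum])
        k = max(1, int(math.floor(fraction * len(ids) + 0.5)))
        k = min(k, len(ids))
        chosen.update(rng.choice(ids, size=k, replace=False).tolist())
    return frozenset(chosen)


def proportional_overlap(
    cs_subset: ComplementarySet, cs_original: ComplementarySet
) -> OverlapResult:
    """N_c / N_s between a subset-derived CS and the original CS."""
    if not cs_subset.members or not cs_original.members:
        raise ValidationError("proportional overlap of an empty CS is undefined")
    n_s = len(cs_subset.members)
    n_c = len(cs_subset.members & cs_original.members)
    return OverlapResult(
        fraction=float("nan"), replicate=-1, n_s=n_s, n_c=n_c, overlap=n_c / n_s
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate-level overlaps plus per-fraction summaries."""

    replicates: pd.DataFrame  # fraction, replicate, n_s, n_c, overlap, failed
    summary: pd.DataFrame  # fraction, n_ok, n_failed, mean_overlap, sd_overlap
    full_cs: ComplementarySet


def _substream(seed: int, fraction_index: int, replicate_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(fraction_index, replicate_index))
    return np.random.default_rng(ss)


def bootstrap_robustness(
    incidence: IncidenceMatrix,
    species_table: SpeciesTable | None,
    units: UnitTable,
    selection_config: SelectionConfig | None = None,
    bootstrap_config: BootstrapConfig | None = None,
) -> BootstrapResult:
    """Run the stratified bootstrap of CS construction.

    For each fraction and replicate: draw a stratified unit subset,
    restrict the incidence matrix to it (species losing all their
    occurrences drop out of that replicate's universe), rebuild the CS
    with the same selection configuration, and record the proportional
    overlap against the full-data CS. Replicates whose restricted
    universe is empty are recorded as failed and excluded from the means.
    """
    sel = selection_config or SelectionConfig()
    cfg = bootstrap_config or BootstrapConfig()
    full_cs = build_complementary_set(incidence, species_table, sel)
    rows = []
    for fi, fraction in enumerate(cfg.fractions):
        for ri in range(cfg.replicates):
            rng = _substream(cfg.seed, fi, ri)
            subset = stratified_sample(units, fraction, rng)
            try:
                sub_matrix = incidence.restrict_units(subset)
                cs = build_complementary_set(sub_matrix, species_table, sel)
                ov = proportional_overlap(cs, full_cs)
                rows.append(
                    {
                        "fraction": fraction,
                        "replicate": ri,
                        "n_s": ov.n_s,
                        "n_c": ov.n_c,
                        "overlap": ov.overlap,
                        "failed": False,
                    }
                )
            except ValidationError:
                rows.append(
                    {
                        "fraction": fraction,
                        "replicate": ri,
                        "n_s": 0,
                        "n_c": 0,
                        "overlap": float("nan"),
                        "failed": True,
                    }
                )
    replicates = pd.DataFrame(rows)
    ok = replicates[~replicates["failed"]]
    summary = (
        ok.groupby("fraction")["overlap"]
        .agg(mean_overlap="mean", sd_overlap="std", n_ok="count")
        .reset_index()
    )
    n_failed = (
        replicates.groupby("fraction")["failed"].sum().rename("n_failed").reset_index()
    )
    summary = n_failed.merge(summary, on="fraction", how="left").loc[
        :, ["fraction", "n_ok", "n_failed", "mean_overlap", "sd_overlap"]
    ]
    summary["n_ok"] = summary["n_ok"].fillna(0).astype(int)
    summary["n_failed"] = summary["n_failed"].astype(int)
    total_failed = int(replicates["failed"].sum())
    if total_failed:
        logger.warning("%d bootstrap replicate(s) failed (empty universe)", total_failed)
    return BootstrapResult(replicates=replicates, summary=summary, full_cs=full_cs)
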
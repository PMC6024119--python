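import numpy as np
import pandas as pd
import pytest

import comprep as cp


def make_units(coverages, stratum="strA", area=1000.0):
    return cp.UnitTable(
        [
            cp.UnitRecord(f"u{i}", stratum, area, c)
            for i, c in enumerate(coverages, start=1)
        ]
    )


class TestSelectProtectedUnits:
    def test_threshold_is_inclusive(self):
        units = make_units([0.0, 0.05, 0.10, 0.4])
        assert cp.select_protected_units(units, 0.10) == {"u3", "u4"}

    def test_presence_criterion(self):
        units = make_units([0.0, 0.05, 0.10, 0.4])
        assert cp.select_protected_units(units, "presence") == {"u2", "u3", "u4"}

    def test_zero_threshold_selects_all(self):
        units = make_units([0.0, 0.05, 0.10, 0.4])
        assert cp.select_protected_units(units, 0.0) == {"u1", "u2", "u3", "u4"}

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(cp.ConfigError):
            cp.select_protected_units(make_units([0.1]), 1.5)


class TestRepresentationIndex:
    def test_simple_half(self):
        cs = cp.ComplementarySet.from_members(["u1", "u2"])
        res = cp.representation_index(cs, {"u1"})
        assert (res.a, res.b, res.i_e) == (1, 1, 50.0)

    def test_fully_protected_cs_scores_100(self):
        cs = cp.ComplementarySet.from_members(["u1", "u2"])
        assert cp.representation_index(cs, {"u1", "u2", "u9"}).i_e == 100.0

    def test_empty_cs_is_error(self):
        with pytest.raises(cp.ValidationError):
            cp.ComplementarySet.from_members([])

    def test_identity_a_plus_b_is_cs_size(self, rng):
        for _ in range(20):
            members = {f"u{i}" for i in rng.choice(50, size=rng.integers(1, 30), replace=False)}
            s_p = {f"u{i}" for i in rng.choice(50, size=20, replace=False)}
            res = cp.representation_index(cp.ComplementarySet.from_members(members), s_p)
            assert res.a + res.b == len(members)
            assert res.i_e_exact == pytest.approx(100 * res.a / len(members))

    def test_threshold_monotonicity_on_random_layers(self, rng):
        grid = [0.0, 0.05, 0.10, 0.20, 0.30, 0.40]
        for _ in range(30):
            n = int(rng.integers(5, 40))
            coverages = np.where(rng.random(n) < 0.3, 0.0, rng.beta(1.2, 6, n))
            units = make_units(coverages.tolist())
            members = [f"u{i}" for i in range(1, n + 1) if rng.random() < 0.6] or ["u1"]
            cs = cp.ComplementarySet.from_members(members)
            values = [
                cp.representation_index(cs, cp.select_protected_units(units, t)).i_e_exact
                for t in grid
            ]
            assert all(x >= y for x, y in zip(values, values[1:]))
            presence = cp.representation_index(
                cs, cp.select_protected_units(units, "presence")
            ).i_e_exact
            assert all(presence >= v for v in values[1:])  # bounds positive thresholds


class TestIdentifyGaps:
    @pytest.fixture
    def toy(self):
        # 5 units; species x occurs in gap CS unit u1 and in protected non-CS u4
        m = cp.IncidenceMatrix(
            [("x", "u1"), ("y", "u1"), ("z", "u2"), ("x", "u4"), ("w", "u3")]
        )
        cs = cp.ComplementarySet.from_members(["u1", "u2", "u3"], m)
        s_p = {"u2", "u3", "u4"}  # u1 is the gap unit
        return m, cs, s_p

    def test_protected_cs_has_no_gaps(self, toy):
        m, cs, _ = toy
        report = cp.identify_gaps(cs, cs.members | {"u9"}, m, set(m.species))
        assert report.gap_units == frozenset() and report.uncovered_species == frozenset()

    def test_single_occurrence_in_gap_unit_uncovered_under_both(self, toy):
        m, cs, s_p = toy
        for definition in ("rangewide", "cs_only"):
            rep = cp.identify_gaps(cs, s_p, m, set(m.species), definition=definition)
            assert "y" in rep.uncovered_species  # y occurs only in gap unit u1

    def test_definitions_disagree_on_rescued_species(self, toy):
        m, cs, s_p = toy
        rangewide = cp.identify_gaps(cs, s_p, m, set(m.species), definition="rangewide")
        cs_only = cp.identify_gaps(cs, s_p, m, set(m.species), definition="cs_only")
        assert "x" not in rangewide.uncovered_species  # protected at u4, outside the CS
        assert "x" in cs_only.uncovered_species  # its CS occurrences are all gaps
        assert rangewide.gap_units == cs_only.gap_units == {"u1"}

    def test_unknown_definition_rejected(self, toy):
        m, cs, s_p = toy
        with pytest.raises(cp.ConfigError):
            cp.identify_gaps(cs, s_p, m, set(m.species), definition="fuzzy")

    def test_each_definition_matches_brute_force(self, rng):
        for _ in range(20):
            n_u, n_s = 8, 15
            recs = {
                (f"s{rng.integers(n_s)}", f"u{rng.integers(n_u)}") for _ in range(40)
            }
            m = cp.IncidenceMatrix(recs)
            members = set(np.random.default_rng(rng.integers(1 << 30)).choice(
                m.units, size=max(1, len(m.units) // 2), replace=False
            ).tolist())
            cs = cp.ComplementarySet.from_members(members, m)
            s_p = {u for u in m.units if rng.random() < 0.5}
            universe = set(m.species)
            gaps = members - s_p
            expect_rw = {s for s in universe if not (set(m.units_of(s)) & s_p)}
            expect_cs = {
                s
                for s in universe
                if (occ := set(m.units_of(s)) & members) and occ <= gaps
            }
            got_rw = cp.identify_gaps(cs, s_p, m, universe, definition="rangewide")
            got_cs = cp.identify_gaps(cs, s_p, m, universe, definition="cs_only")
            assert got_rw.uncovered_species == expect_rw
            assert got_cs.uncovered_species == expect_cs

    def test_flagged_subsets_use_species_table(self, toy):
        m, cs, s_p = toy
        table = cp.SpeciesTable(
            [cp.SpeciesRecord("y", threatened=True, endemic=True)]
        )
        rep = cp.identify_gaps(cs, s_p, m, set(m.species), table)
        assert rep.threatened_uncovered == {"y"} and rep.endemic_uncovered == {"y"}


class TestCongruence:
    def test_disjoint_sets(self):
        units = make_units([0.0] * 6)
        cs = cp.ComplementarySet.from_members(["u1", "u2"])
        summary = cp.congruence_summary(cs, {"u3", "u4"}, units)
        assert summary.n_common == 0 and summary.pct_common == 0.0

    def test_identical_sets(self):
        units = make_units([0.0] * 3)
        cs = cp.ComplementarySet.from_members(["u1", "u2", "u3"])
        summary = cp.congruence_summary(cs, {"u1", "u2", "u3"}, units)
        assert summary.pct_common == 100.0 and summary.area_pct_common == 100.0

    def test_area_percentage_uses_unit_areas(self):
        units = cp.UnitTable(
            [
                cp.UnitRecord("u1", "strA", 300.0, 0.0),
                cp.UnitRecord("u2", "strA", 100.0, 0.0),
                cp.UnitRecord("u3", "strA", 600.0, 0.0),
            ]
        )
        cs = cp.ComplementarySet.from_members(["u1", "u2"])
        summary = cp.congruence_summary(cs, {"u2", "u3"}, units)
        # union area 1000, common area 100
        assert summary.area_pct_common == pytest.approx(10.0)


class TestCoverageClasses:
    def test_all_zero_coverage(self):
        units = make_units([0.0, 0.0, 0.0])
        cs = cp.ComplementarySet.from_members(units.ids)
        classes = cp.coverage_class_areas(cs, units)
        zero = classes.loc[classes["coverage_class"] == "0"].iloc[0]
        assert zero["area_pct"] == pytest.approx(100.0)
        assert zero["n_units"] == 3

    def test_two_equal_area_units(self):
        units = make_units([0.07, 0.25])
        cs = cp.ComplementarySet.from_members(units.ids)
        classes = cp.coverage_class_areas(cs, units).set_index("coverage_class")
        assert classes.loc["[0.05,0.1)", "area_pct"] == pytest.approx(50.0)
        assert classes.loc["[0.2,0.3)", "area_pct"] == pytest.approx(50.0)

    def test_matches_naive_tally_and_conserves(self, rng):
        coverages = np.where(rng.random(30) < 0.2, 0.0, rng.random(30))
        areas = rng.uniform(10, 1000, size=30)
        units = cp.UnitTable(
            [
                cp.UnitRecord(f"u{i}", "strA", float(a), float(c))
                for i, (a, c) in enumerate(zip(areas, coverages), start=1)
            ]
        )
        cs = cp.ComplementarySet.from_members(units.ids)
        classes = cp.coverage_class_areas(cs, units)
        assert classes["n_units"].sum() == len(cs.members)
        assert classes["area_pct"].sum() == pytest.approx(100.0, abs=1e-9)
        edges = list(cp.DEFAULT_CLASS_EDGES) + [1.0000001]
        for _, row in classes.iterrows():
            naive = 0.0
            for rec in units:
                c = rec.pa_coverage
                if row["coverage_class"] == "0":
                    hit = c == 0.0
                elif row["coverage_class"].startswith("("):
                    hit = 0.0 < c < edges[1]
                else:
                    lo, hi = row["coverage_class"].strip("[)]").split(",")
                    hi = 1.0000001 if row["coverage_class"].endswith("]") else float(hi)
                    hit = float(lo) <= c < hi
                if hit:
                    naive += rec.area
            assert row["area"] == pytest.approx(naive)

    def test_non_monotone_edges_rejected(self):
        units = make_units([0.1])
        cs = cp.ComplementarySet.from_members(["u1"])
        with pytest.raises(cp.ConfigError):
            cp.coverage_class_areas(cs, units, class_edges=[0.0, 0.3, 0.2])


class TestRegionalEffectiveness:
    def test_cs_of_all_units_captures_everything(self, sim_dataset, sim_cs):
        ds = sim_dataset
        all_cs = cp.ComplementarySet.from_members(ds.incidence.units, ds.incidence)
        sp_regions = {r.species_id: r.region for r in ds.species}
        eff = cp.regional_effectiveness(
            all_cs, ds.incidence, sp_regions, ds.units.strata()
        )
        assert (eff.per_region["pct"] == 100.0).all() and eff.mean == 100.0

    def test_matches_brute_force(self, sim_dataset, sim_cs):
        ds = sim_dataset
        sp_regions = {r.species_id: r.region for r in ds.species}
        unit_regions = ds.units.strata()
        eff = cp.regional_effectiveness(sim_cs, ds.incidence, sp_regions, unit_regions)
        for _, row in eff.per_region.iterrows():
            region = row["region"]
            sp_here = [s for s in ds.incidence.species if sp_regions[s] == region]
            cs_here = {u for u in sim_cs.members if unit_regions[u] == region}
            captured = sum(
                1 for s in sp_here if set(ds.incidence.units_of(s)) & cs_here
            )
            assert row["n_captured"] == captured
            assert row["pct"] == pytest.approx(100 * captured / len(sp_here))

    def test_missing_region_assignment_is_error(self, tiny_matrix):
        cs = cp.ComplementarySet.from_members(["u1"], tiny_matrix)
        with pytest.raises(cp.ValidationError, match="region"):
            cp.regional_effectiveness(cs, tiny_matrix, {}, {"u1": "r1"})


class TestTimeSeries:
    def make_units(self, paths):
        return cp.UnitTable(
            [
                cp.UnitRecord(
                    f"u{i}", "strA", 100.0, max(path.values()), coverage_by_year=path
                )
                for i, path in enumerate(paths, start=1)
            ]
        )

    def test_constant_coverage_gives_constant_series(self):
        units = self.make_units(
            [{2000: 0.2, 2001: 0.2}, {2000: 0.0, 2001: 0.0}]
        )
        cs = cp.ComplementarySet.from_members(["u1", "u2"])
        series = cp.representation_time_series(cs, units)
        assert {r.i_e for r in series.values()} == {50.0}

    def test_nondecreasing_coverage_gives_nondecreasing_series(self):
        units = self.make_units(
            [
                {2000: 0.0, 2001: 0.1, 2002: 0.2},
                {2000: 0.0, 2001: 0.0, 2002: 0.3},
                {2000: 0.1, 2001: 0.2, 2002: 0.2},
            ]
        )
        cs = cp.ComplementarySet.from_members(["u1", "u2", "u3"])
        series = cp.representation_time_series(cs, units, criterion=0.1)
        values = [series[y].i_e_exact for y in sorted(series)]
        assert values == sorted(values)

    def test_yearly_values_equal_single_year_path(self, rng):
        years = [2000, 2005, 2010]
        paths = [
            {y: float(c) for y, c in zip(years, rng.random(3))} for _ in range(10)
        ]
        units = self.make_units(paths)
        cs = cp.ComplementarySet.from_members(["u1", "u3", "u7"])
        series = cp.representation_time_series(cs, units, criterion=0.3)
        for year in years:
            s_p = {u.unit_id for u in units if u.coverage_by_year[year] >= 0.3}
            assert series[year].i_e == cp.representation_index(cs, s_p).i_e

    def test_missing_year_names_the_year(self):
        units = self.make_units([{2000: 0.1}])
        cs = cp.ComplementarySet.from_members(["u1"])
        with pytest.raises(cp.ValidationError, match="2004"):
            cp.representation_time_series(cs, units, years=[2004])
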
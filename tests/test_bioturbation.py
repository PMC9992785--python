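"""Bioturbation fluxes, the excavation-work integral, table I/O and the
synthetic generator."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seafloor_energy import (
    BurrowerPopulation,
    FluidConstants,
    GroupSpec,
    crack_flux,
    excavation_flux,
    flux_distributions,
    read_reworking_table,
    synthesize_reworking_table,
)
from seafloor_energy.bioturbation import (
    excavation_work,
    excavation_work_closed_form,
    population_fluxes,
    write_reworking_table,
)


class TestExcavationFlux:
    def test_zero_reworking(self, burrower, fluid):
        p = BurrowerPopulation("x", "g", R=0.0, b=0.005, d=0.05)
        assert excavation_flux(p, fluid).value == 0.0

    def test_hand_value(self, burrower, fluid):
        # 0.5 * 0.6 * 1825 * 0.1 * 9.81 * 0.05
        assert excavation_flux(burrower, fluid).value == pytest.approx(26.855, rel=1e-4)

    @given(factor=st.floats(min_value=0.01, max_value=100))
    def test_linear_in_R_and_d(self, burrower, fluid, factor):
        base = excavation_flux(burrower, fluid).value
        scaled_R = BurrowerPopulation("x", "g", R=burrower.R * factor, b=burrower.b, d=burrower.d)
        scaled_d = BurrowerPopulation("x", "g", R=burrower.R, b=burrower.b, d=burrower.d * factor)
        assert excavation_flux(scaled_R, fluid).value == pytest.approx(factor * base, rel=1e-9)
        assert excavation_flux(scaled_d, fluid).value == pytest.approx(factor * base, rel=1e-9)

    def test_buoyant_sediment_rejected(self, fluid):
        p = BurrowerPopulation("x", "g", R=0.1, b=0.005, d=0.05, rho_s=1000.0)
        with pytest.raises(ValueError):
            excavation_flux(p, fluid)


class TestCrackFlux:
    def test_zero_reworking(self):
        p = BurrowerPopulation("x", "g", R=0.0, b=0.005, d=0.05, mode="crack_propagation")
        assert crack_flux(p).value == 0.0

    def test_hand_value(self, burrower):
        # 2 * 1 * 0.1 / (pi * 0.005)
        assert crack_flux(burrower).value == pytest.approx(12.732, rel=1e-4)

    @given(st.floats(min_value=1e-4, max_value=0.1))
    def test_inverse_in_radius(self, b):
        p1 = BurrowerPopulation("x", "g", R=0.1, b=b, d=0.05, mode="both")
        p2 = BurrowerPopulation("x", "g", R=0.1, b=b / 2, d=0.05, mode="both")
        assert crack_flux(p2).value == pytest.approx(2 * crack_flux(p1).value, rel=1e-12)

    @given(factor=st.floats(min_value=0.01, max_value=100))
    def test_linear_in_R(self, burrower, factor):
        scaled = BurrowerPopulation("x", "g", R=burrower.R * factor, b=burrower.b, d=burrower.d,
                                    mode="both")
        assert crack_flux(scaled).value == pytest.approx(
            factor * crack_flux(burrower).value, rel=1e-9
        )


class TestExcavationWorkIntegral:
    """The discrete lift-n-slabs sum against the closed form
    ½(1−φ)(ρ_s−ρ_w)πb²gd²."""

    def test_midpoint_rule_is_exact(self, fluid):
        # the integrand is linear in depth, so one midpoint slab suffices
        w1 = excavation_work(0.005, 0.3, n_segments=1, rule="midpoint", fluid=fluid)
        assert w1 == pytest.approx(excavation_work_closed_form(0.005, 0.3, fluid=fluid), rel=1e-12)

    def test_left_sum_convergence_order(self, fluid):
        exact = excavation_work_closed_form(0.005, 0.3, fluid=fluid)
        errs = []
        for n in (10, 100, 1000):
            approx = excavation_work(0.005, 0.3, n_segments=n, rule="left", fluid=fluid)
            errs.append(abs(approx - exact) / exact)
        # first-order convergence: the left sum underestimates by exactly 1/n
        assert errs[0] == pytest.approx(0.1, rel=1e-6)
        assert errs[1] == pytest.approx(0.01, rel=1e-6)
        assert errs[2] == pytest.approx(0.001, rel=1e-6)

    def test_shallow_limit(self, fluid):
        assert excavation_work(0.005, 1e-9, 100, fluid=fluid) < 1e-12

    def test_invalid_segments(self):
        with pytest.raises(ValueError):
            excavation_work(0.005, 0.3, n_segments=0)


class TestSyntheticGenerator:
    def test_deterministic(self):
        a = synthesize_reworking_table(seed=3)
        b = synthesize_reworking_table(seed=3)
        assert [(p.taxon, p.R, p.b, p.d) for p in a] == [(p.taxon, p.R, p.b, p.d) for p in b]

    def test_different_seeds_differ(self):
        a = synthesize_reworking_table(seed=3)
        b = synthesize_reworking_table(seed=4)
        assert [p.R for p in a] != [p.R for p in b]

    def test_empty(self):
        assert synthesize_reworking_table(seed=0, n_taxa_per_group=0) == []
        with pytest.raises(ValueError):
            synthesize_reworking_table(seed=0, group_specs=[])

    def test_nine_decade_flux_span(self, default_pops, fluid):
        exc = population_fluxes(default_pops, "excavation", fluid)
        crk = population_fluxes(default_pops, "crack_propagation", fluid)
        allv = np.concatenate([exc, crk])
        assert math.log10(allv.max() / allv.min()) >= 9.0

    def test_median_burrow_depth(self, default_pops):
        """The pooled median burrow depth tracks the 0.05 m vertical
        observation window used by the chemical flux."""
        med = np.median([p.d for p in default_pops])
        assert 0.03 <= med <= 0.08

    def test_rates_within_declared_ranges(self, default_pops):
        assert min(p.R for p in default_pops) >= 1e-6 * (1 - 1e-12)
        assert max(p.R for p in default_pops) <= 1e3 * (1 + 1e-12)

    def test_custom_group_spec(self):
        spec = GroupSpec("one", (-1.0, 1.0), (0.01, 0.02), (0.05, 0.1), "both")
        pops = synthesize_reworking_table(seed=0, n_taxa_per_group=5, group_specs=[spec])
        assert len(pops) == 5
        assert {p.group for p in pops} == {"one"}


class TestTableIO:
    def test_round_trip(self, tmp_path, default_pops):
        path = tmp_path / "table.csv"
        write_reworking_table(default_pops, path)
        back = read_reworking_table(path)
        assert len(back) == len(default_pops)
        for p, q in zip(default_pops, back):
            assert p.taxon == q.taxon
            assert p.R == pytest.approx(q.R, rel=1e-12)
            assert p.mode == q.mode

    def test_missing_column_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("taxon,group,reworking_rate\nworm,poly,0.1\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_reworking_table(path)

    def test_negative_rate_names_row(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text(
            "taxon,group,reworking_rate,burrow_radius,burrow_depth\n"
            "worm,poly,0.1,0.005,0.05\n"
            "bad,poly,-2.0,0.005,0.05\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            read_reworking_table(path)

    def test_permissive_skips_bad_rows(self, tmp_path):
        path = tmp_path / "mixed.csv"
        path.write_text(
            "taxon,group,reworking_rate,burrow_radius,burrow_depth\n"
            "worm,poly,0.1,0.005,0.05\n"
            "bad,poly,0.2,0.0,0.05\n"
        )
        with pytest.warns(UserWarning, match="row 1"):
            pops = read_reworking_table(path, permissive=True)
        assert [p.taxon for p in pops] == ["worm"]

    def test_units_row_accepted_and_stripped(self, tmp_path):
        path = tmp_path / "units.csv"
        path.write_text(
            "taxon,group,reworking_rate,burrow_radius,burrow_depth\n"
            "-,-,m3/m2/yr,m,m\n"
            "worm,poly,0.1,0.005,0.05\n"
        )
        pops = read_reworking_table(path)
        assert len(pops) == 1 and pops[0].R == 0.1

    def test_unknown_units_rejected(self, tmp_path):
        path = tmp_path / "badunits.csv"
        path.write_text(
            "taxon,group,reworking_rate,burrow_radius,burrow_depth\n"
            "-,-,furlongs,m,m\n"
            "worm,poly,0.1,0.005,0.05\n"
        )
        with pytest.raises(ValueError, match="unsupported unit"):
            read_reworking_table(path)

    def test_empty_table_warns(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("taxon,group,reworking_rate,burrow_radius,burrow_depth\n")
        with pytest.warns(UserWarning, match="no valid records"):
            assert read_reworking_table(path) == []

    def test_xlsx_round_trip(self, tmp_path, default_pops):
        import pandas as pd

        path = tmp_path / "table.xlsx"
        sub = default_pops[:4]
        pd.DataFrame(
            {
                "taxon": [p.taxon for p in sub],
                "group": [p.group for p in sub],
                "reworking_rate": [p.R for p in sub],
                "burrow_radius": [p.b for p in sub],
                "burrow_depth": [p.d for p in sub],
            }
        ).to_excel(path, index=False)
        back = read_reworking_table(path)
        assert [p.taxon for p in back] == [p.taxon for p in sub]


class TestFluxDistributions:
    def test_single_record(self, fluid):
        p = BurrowerPopulation("x", "g", R=0.1, b=0.005, d=0.05, mode="both")
        dists = flux_distributions([p], "excavation", fluid)
        solo = [d for d in dists if d.group == "g"][0]
        assert solo.min == solo.q25 == solo.median == solo.q75 == solo.max

    def test_known_five_value_quartiles(self, fluid):
        """Linear-interpolation quartiles of {10,20,30,40,50} are 20/30/40."""
        pops = []
        for i, d in enumerate((0.01, 0.02, 0.03, 0.04, 0.05)):
            # R chosen so fluxes are exactly 10..50
            R = 10 * (i + 1) / (0.5 * 0.6 * 1825 * 9.81 * d)
            pops.append(BurrowerPopulation(f"t{i}", "g", R=R, b=0.005, d=d))
        dist = [d for d in flux_distributions(pops, "excavation", fluid) if d.group == "all"][0]
        assert dist.q25 == pytest.approx(20.0, rel=1e-9)
        assert dist.median == pytest.approx(30.0, rel=1e-9)
        assert dist.q75 == pytest.approx(40.0, rel=1e-9)

    def test_crack_median_exceeds_excavation_median(self, default_pops, fluid):
        """Upper-endmember check: over the taxa that admit both mechanical
        models, the crack-propagation median exceeds the excavation median."""
        both = [p for p in default_pops if p.mode == "both"]
        exc = np.median(population_fluxes(both, "excavation", fluid))
        crk = np.median(population_fluxes(both, "crack_propagation", fluid))
        assert crk > exc

    def test_mode_filtering(self, default_pops, fluid):
        crack_groups = {p.group for p in default_pops if p.supports("crack_propagation")}
        with pytest.warns(UserWarning, match="no taxa supporting"):
            dists = flux_distributions(default_pops, "crack_propagation", fluid)
        assert {d.group for d in dists} == crack_groups | {"all"}

    def test_empty_rejected(self, fluid):
        with pytest.raises(ValueError):
            flux_distributions([], "excavation", fluid)
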
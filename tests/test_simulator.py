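import numpy as np
import pytest

from toricity.ratio import ExtractionInput, extract_toricity
from toricity.simulator import (
    LensCatalog,
    LensModel,
    ToricityModel,
    simulate_calculator,
    tau_for_case,
)
from toricity.srkt import BiometryCase
from toricity.vectors import CylinderVector


def case_with(al=24.0, mean_k=43.0, cyl=4.0, steep_axis=90.0):
    return BiometryCase(
        axial_length=al, k_flat=mean_k - cyl / 2, k_steep=mean_k + cyl / 2,
        steep_axis=steep_axis,
    )


class TestToricityModel:
    def test_constant_requires_positive_value(self):
        with pytest.raises(ValueError):
            ToricityModel.constant(-1.0)

    def test_table_values_must_be_physiological(self):
        with pytest.raises(ValueError, match=r"\(1, 3\)"):
            ToricityModel.from_table([21, 27], [39, 47], [[0.9, 1.4], [1.5, 1.6]])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ToricityModel(kind="table")

    def test_vergence_needs_exactly_one_elp_source(self):
        with pytest.raises(ValueError):
            ToricityModel.vergence()
        with pytest.raises(ValueError):
            ToricityModel.vergence(elp_mm=5.0, elp_a_constant=118.8)


class TestTauForCase:
    def test_constant(self):
        assert tau_for_case(ToricityModel.constant(1.46), case_with()) == 1.46

    def test_table_nodes_exact(self):
        model = ToricityModel.from_table(
            [21.0, 24.0, 27.0], [39.0, 43.0, 47.0],
            [[1.33, 1.38, 1.42], [1.40, 1.52, 1.56], [1.47, 1.63, 1.75]],
        )
        assert tau_for_case(model, case_with(al=21.0, mean_k=39.0)) == pytest.approx(1.33)
        assert tau_for_case(model, case_with(al=27.0, mean_k=47.0)) == pytest.approx(1.75)

    def test_table_bilinear_midpoint(self):
        model = ToricityModel.from_table(
            [21.0, 27.0], [39.0, 47.0], [[1.30, 1.40], [1.50, 1.80]]
        )
        got = tau_for_case(model, case_with(al=24.0, mean_k=43.0))
        assert got == pytest.approx((1.30 + 1.40 + 1.50 + 1.80) / 4)

    def test_table_clamped_at_edges(self):
        model = ToricityModel.from_table(
            [21.0, 27.0], [39.0, 47.0], [[1.30, 1.40], [1.50, 1.80]]
        )
        assert tau_for_case(model, case_with(al=19.0, mean_k=38.0)) == pytest.approx(1.30)

    def test_vergence_tends_to_one_as_elp_vanishes(self):
        model = ToricityModel.vergence(elp_mm=1e-9)
        assert tau_for_case(model, case_with()) == pytest.approx(1.0, abs=1e-6)

    def test_vergence_hand_computed_value(self):
        # independent longhand arithmetic for K 41/45, ELP 5 mm, n = 1.336:
        #   steep: 1.336/45 = 0.0296889 m; -0.005 -> 0.0246889; 1.336/x = 54.1134
        #   flat:  1.336/41 = 0.0325854 m; -0.005 -> 0.0275854; 1.336/x = 48.4313
        #   tau = (54.1134 - 48.4313) / 4 = 1.42048
        model = ToricityModel.vergence(elp_mm=5.0)
        got = tau_for_case(model, case_with(al=24.0, mean_k=43.0, cyl=4.0))
        n = 1.336
        steep = n / (n / 45.0 - 0.005)
        flat = n / (n / 41.0 - 0.005)
        assert got == pytest.approx((steep - flat) / 4.0, rel=1e-12)
        assert got == pytest.approx(1.42048, abs=1e-5)

    def test_vergence_monotone_in_elp(self):
        taus = [
            tau_for_case(ToricityModel.vergence(elp_mm=e), case_with())
            for e in (3.0, 4.0, 5.0, 6.0, 7.0)
        ]
        assert all(a < b for a, b in zip(taus, taus[1:]))

    def test_vergence_monotone_in_mean_k(self):
        model = ToricityModel.vergence(elp_mm=5.0)
        taus = [tau_for_case(model, case_with(mean_k=k)) for k in (39.0, 43.0, 47.0)]
        assert all(a < b for a, b in zip(taus, taus[1:]))

    def test_vergence_srkt_elp_monotone_in_axial_length(self):
        # with the SRK/T-derived ELP, longer eyes sit the lens deeper,
        # raising the ratio at fixed K
        model = ToricityModel.vergence(elp_a_constant=118.8)
        taus = [tau_for_case(model, case_with(al=al)) for al in (21.0, 24.0, 27.0)]
        assert all(a < b for a, b in zip(taus, taus[1:]))


class TestSimulateCalculator:
    def test_alcon_worked_example(self, alcon_catalog):
        # the published run recommends SN6AT8 with +0.40 D even though SN6AT9
        # would leave a smaller (but axis-flipping) residual: avoid_flip policy
        case = case_with(al=21.0, mean_k=39.0)
        result = simulate_calculator(
            case, alcon_catalog, ToricityModel.constant(1.46), policy="avoid_flip"
        )
        assert result.sphere_power == pytest.approx(34.0)
        top = result.selected
        assert top.lens.name == "SN6AT8"
        printed = top.printed()
        assert printed["residual_D"] == pytest.approx(0.40)
        assert printed["residual_axis_deg"] == pytest.approx(90.0)

    def test_min_residual_policy_prefers_smallest_magnitude(self, alcon_catalog):
        case = case_with(al=21.0, mean_k=39.0)
        result = simulate_calculator(case, alcon_catalog, ToricityModel.constant(1.46))
        # at tau 1.46 the ideal cylinder is 5.84 D: SN6AT9 over-corrects by 0.11
        assert result.selected.lens.name == "SN6AT9"
        assert result.selected.signed_residual_exact == pytest.approx(
            4.0 - 6.0 / 1.46
        )

    def test_unknown_policy_rejected(self, alcon_catalog):
        with pytest.raises(ValueError, match="policy"):
            simulate_calculator(case_with(), alcon_catalog,
                                ToricityModel.constant(1.46), policy="bogus")

    def test_abbott_residual_ladder_at_constant_tau(self, abbott_catalog):
        # frozen direct arithmetic at tau = 1.33: r = 4 - L/1.33
        case = case_with(al=21.0, mean_k=39.0)
        result = simulate_calculator(case, abbott_catalog, ToricityModel.constant(1.33))
        by_name = {rec.lens.name: rec for rec in result.recommended}
        assert round(by_name["ZCT450"].signed_residual_exact, 2) == pytest.approx(0.62)
        assert round(by_name["ZCT525"].signed_residual_exact, 2) == pytest.approx(0.05)
        assert round(by_name["ZCT600"].signed_residual_exact, 2) == pytest.approx(-0.51)
        assert by_name["ZCT600"].residual.axis == pytest.approx(0.0)

    def test_spherical_cornea_selects_lowest_cylinder(self, alcon_catalog):
        case = BiometryCase(axial_length=24.0, k_flat=43.0, k_steep=43.0)
        tau = 1.46
        result = simulate_calculator(case, alcon_catalog, ToricityModel.constant(tau))
        top = result.selected
        assert top.lens.cylinder_iol_plane == min(
            lens.cylinder_iol_plane for lens in alcon_catalog
        )
        assert top.signed_residual_exact == pytest.approx(-top.lens.cylinder_iol_plane / tau)

    def test_closure_with_extractor_full_precision(self, alcon_catalog):
        # the repository's central correctness property: extraction from the
        # simulator's exact outputs recovers the configured ratio
        model = ToricityModel.constant(1.5713)
        case = case_with(al=24.0, mean_k=43.0)
        result = simulate_calculator(case, alcon_catalog, model)
        for rec in result.recommended:
            got = extract_toricity(
                ExtractionInput(
                    lens_cylinder_iol_plane=rec.lens.cylinder_iol_plane,
                    cross_cylinder=result.cross_cylinder,
                    residual_magnitude=rec.residual.magnitude,
                    residual_axis=rec.residual.axis,
                )
            )
            assert got.value == pytest.approx(1.5713, abs=1e-9)

    def test_ranking_invariant_under_catalog_permutation(self, alcon_catalog):
        case = case_with()
        model = ToricityModel.constant(1.46)
        baseline = simulate_calculator(case, alcon_catalog, model).selected.lens.name
        rng = np.random.default_rng(3)
        lenses = list(alcon_catalog.lenses)
        for _ in range(5):
            rng.shuffle(lenses)
            shuffled = LensCatalog(lenses=tuple(lenses))
            assert simulate_calculator(case, shuffled, model).selected.lens.name == baseline

    def test_tie_break_prefers_lower_cylinder(self):
        # two lenses equidistant from the ideal cylinder: under-correct
        catalog = LensCatalog(
            lenses=(
                LensModel("LO", 4.0, 5.0, 34.0, 118.8),
                LensModel("HI", 6.0, 5.0, 34.0, 118.8),
            )
        )
        # at tau = 1 the ideal cylinder is 5.0 -> both residuals have magnitude 1.0
        case = BiometryCase(axial_length=24.0, k_flat=41.0, k_steep=46.0,
                            steep_axis=90.0)
        result = simulate_calculator(case, catalog, ToricityModel.constant(1.0))
        assert result.selected.lens.name == "LO"

    def test_no_sphere_coverage_warns_and_returns_empty(self):
        catalog = LensCatalog(
            lenses=(LensModel("NARROW", 4.0, 20.0, 21.0, 118.8),)
        )
        case = case_with(al=27.0, mean_k=47.0)
        with pytest.warns(RuntimeWarning, match="no lens"):
            result = simulate_calculator(case, catalog, ToricityModel.constant(1.46))
        assert result.recommended == ()
        assert result.selected is None

    def test_empty_catalog_rejected(self, alcon_catalog):
        with pytest.raises(ValueError, match="empty"):
            simulate_calculator(case_with(), LensCatalog(lenses=()),
                                ToricityModel.constant(1.46))
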
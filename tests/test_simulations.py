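"""Simulation protocols: yields, fumarase deficiency, proton leak,
acetyl-CoA attribution."""

import warnings

import pytest

from mitoflux import (
    ATP_OBJECTIVE,
    YieldProtocol,
    atp_yield,
    attribute_acetyl_coa,
    default_cardiomyocyte_bounds,
    default_cardiomyocyte_model,
    default_leak_values,
    fba,
    proton_leak_scan,
    simulate_fumarase_deficiency,
)
from mitoflux.simulations import apply_yield_protocol


def test_yield_protocol_closes_other_fuels(bundled):
    prepared = apply_yield_protocol(bundled, YieldProtocol(fuel_id="glc_D"))
    assert prepared.reactions["EX_glc_D"].lower_bound == -1.0
    assert prepared.reactions["EX_hdca"].lower_bound == 0.0
    assert prepared.reactions["EX_o2"].lower_bound == -50.0
    # non-degradable boundary steps stay untouched
    assert prepared.reactions["EX_pi"].lower_bound == -1000.0


def test_zero_uptake_gives_zero_yield(bundled):
    value = atp_yield(
        bundled, YieldProtocol(fuel_id="glc_D", fuel_uptake=0.0, method="fba")
    )
    assert value == pytest.approx(0.0, abs=1e-9)


def test_yield_scales_linearly_while_oxygen_spare(bundled):
    one = atp_yield(bundled, YieldProtocol(fuel_id="glc_D", method="fba"))
    two = atp_yield(
        bundled, YieldProtocol(fuel_id="glc_D", fuel_uptake=2.0, method="fba")
    )
    assert two == pytest.approx(2.0 * one, rel=1e-6)


def test_yield_warns_on_undegradable_fuel(bundled):
    """A fuel whose degradation route is silenced yields zero, with a
    warning rather than an error."""
    crippled = bundled.copy()
    crippled.reactions["BDHm"].lower_bound = 0.0
    crippled.reactions["BDHm"].upper_bound = 0.0
    crippled.reactions["BHBtm_MitoCore"].upper_bound = 0.0
    with pytest.warns(UserWarning, match="no degradation route"):
        value = atp_yield(crippled, YieldProtocol(fuel_id="bhb", method="fba"))
    assert value == pytest.approx(0.0, abs=1e-9)


def test_geometric_and_plain_fba_agree_on_yield_value(bundled):
    plain = atp_yield(bundled, YieldProtocol(fuel_id="lac_L", method="fba"))
    geometric = atp_yield(bundled, YieldProtocol(fuel_id="lac_L"))
    assert geometric == pytest.approx(plain, abs=1e-6)


def test_fuel_ordering_matches_energy_density(bundled):
    """Hexadecanoate is the richest fuel, then glucose, then lactate."""
    yields = {
        fuel: atp_yield(bundled, YieldProtocol(fuel_id=fuel, method="fba"))
        for fuel in ("hdca", "glc_D", "lac_L")
    }
    assert yields["hdca"] > yields["glc_D"] > yields["lac_L"]


def test_default_bounds_leave_oxygen_limiting(bundled):
    """Fuels are supplied in slight excess, so oxygen caps the optimum."""
    model = default_cardiomyocyte_model(bundled)
    result = fba(model, ATP_OBJECTIVE)
    assert result.ok
    bound = default_cardiomyocyte_bounds()["EX_o2"]["lower"]
    assert result.fluxes["EX_o2"] == pytest.approx(bound, abs=1e-6)
    assert result.objective_value > 90.0


def test_fumarase_deficiency_bundled_bounds(bundled):
    outcome = simulate_fumarase_deficiency(bundled, method="fba")
    assert outcome.wild_type.ok and outcome.knockout.ok
    # both isoforms silenced through the single shared gene
    assert outcome.knockout.fluxes["FUMm"] == 0.0
    assert outcome.knockout.fluxes["FUM"] == 0.0
    assert outcome.fumarate_efflux > 0.0
    assert outcome.percent_atp_reduction > 50.0
    assert outcome.knockout.objective_value <= outcome.wild_type.objective_value


def test_fumarase_knockout_uses_plausible_compensation(bundled):
    """With the cycle broken at fumarate, oxaloacetate is replenished by
    pyruvate carboxylase and the malate-aspartate shuttle keeps running."""
    outcome = simulate_fumarase_deficiency(bundled)  # geometric flux map
    ko = outcome.knockout.fluxes
    assert ko["PCm"] > 1e-6
    assert ko["ASPGLUm_MitoCore"] > 1e-6
    assert ko["EX_fum"] > 0.0


def test_proton_leak_scan_monotone_and_reversing(bundled):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = default_leak_values(bundled, n_points=6)
        result = proton_leak_scan(bundled, values, method="fba")
    points = result.feasible_points
    assert len(points) >= 4
    atp = [p.max_atp for p in points]
    synthase = [p.atp_synthase_flux for p in points]
    assert all(a >= b - 1e-6 for a, b in zip(atp, atp[1:]))
    assert all(a >= b - 1e-6 for a, b in zip(synthase, synthase[1:]))
    top = points[-1]
    assert top.atp_synthase_flux < 0
    assert top.ant_flux < 0
    assert top.pi_carrier_flux < 0


def test_leak_zero_reproduces_baseline(bundled):
    base = fba(default_cardiomyocyte_model(bundled), ATP_OBJECTIVE)
    scan = proton_leak_scan(bundled, [0.0], method="fba")
    assert scan.points[0].max_atp == pytest.approx(
        base.objective_value, abs=1e-6
    )


def test_acetyl_coa_attribution_single_fuel(bundled):
    prepared = apply_yield_protocol(bundled, YieldProtocol(fuel_id="glc_D"))
    result = fba(prepared, ATP_OBJECTIVE)
    attribution = attribute_acetyl_coa(result, bundled)
    assert attribution.fractions["glucose"] == pytest.approx(1.0, abs=1e-6)
    assert sum(attribution.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_acetyl_coa_attribution_amino_acid_routes(bundled):
    prepared = apply_yield_protocol(bundled, YieldProtocol(fuel_id="asp_L"))
    result = fba(prepared, ATP_OBJECTIVE)
    attribution = attribute_acetyl_coa(result, bundled)
    assert attribution.fractions["amino_acid"] == pytest.approx(1.0, abs=1e-6)


def test_acetyl_coa_attribution_mixed_default(bundled):
    """Under the default cardiomyocyte mix, fatty-acid oxidation is the
    dominant acetyl-CoA source, as in well-perfused heart."""
    result = fba(default_cardiomyocyte_model(bundled), ATP_OBJECTIVE)
    attribution = attribute_acetyl_coa(result, bundled)
    fractions = attribution.fractions
    assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert fractions["fatty_acid"] == max(fractions.values())
    assert fractions["fatty_acid"] > 0.4


def test_acetyl_coa_attribution_empty_without_flux(bundled):
    closed = bundled.copy()  # all fuel uptakes are zero by default
    result = fba(closed, ATP_OBJECTIVE)
    attribution = attribute_acetyl_coa(result, bundled)
    assert attribution.fractions == {}
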
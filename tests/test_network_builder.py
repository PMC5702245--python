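"""PMF bookkeeping, transport construction and the bundled network."""

import pytest

from mitoflux import (
    PMFParameters,
    TransportCategory,
    build_oxphos_micromodel,
    build_reduced_model,
    fba,
    make_pseudo_reactions,
    make_respiratory_chain,
    make_transport_step,
    pmf_coefficient,
)
from mitoflux.model_core import ModelStructureError, validate_balance
from mitoflux.network_builder import (
    ALTERNATIVE_COMPLEX_SPLIT,
    ANT_ID,
    ANT_REVERSE_ID,
    ATP_OBJECTIVE,
    ATP_SYNTHASE_ID,
    PROTON_LEAK_ID,
    _metabolites,
)
from mitoflux.simulations import YieldProtocol, apply_yield_protocol


@pytest.mark.parametrize(
    "charge,protons,expected",
    [
        (1, 0, 0.82),  # ATP4-/ADP3- exchange affects only the potential
        (0, 1, 0.18),  # electroneutral phosphate/H+ symport affects only pH
        (1, 1, 1.00),  # a fully vectorial pumped proton
        (-1, 0, 0.82),  # magnitude of the charge matters, not its sign
        (2, 0, 1.64),
    ],
)
def test_pmf_coefficient(charge, protons, expected):
    assert pmf_coefficient(charge, protons) == pytest.approx(expected)


def test_pmf_coefficient_rejects_negative_protons():
    with pytest.raises(ValueError):
        pmf_coefficient(1, -1)


def test_pmf_parameters_invariants():
    with pytest.raises(ValueError):
        PMFParameters(delta_psi_fraction=0.8, delta_ph_fraction=0.18)
    with pytest.raises(ValueError):
        PMFParameters(complex_split=(("CI", 5.0), ("CIII", 2.0), ("CIV", 4.0)))
    alt = PMFParameters(complex_split=ALTERNATIVE_COMPLEX_SPLIT)
    assert alt.split == {"CI": 4.0, "CIII": 4.0, "CIV": 2.0}


def test_ant_transport_step_matches_printed_equation(params):
    mets = {m.id: m for m in _metabolites()}
    forward, reverse = make_transport_step(
        ANT_ID, TransportCategory.CARRIER, imported=["adp"], exported=["atp"],
        metabolites=mets, params=params, split_reverse=True,
    )
    assert forward.stoichiometry == {
        "atp_m": -1.0, "adp_c": -1.0, "pmf_c": -0.82,
        "atp_c": 1.0, "adp_m": 1.0, "pmf_m": 0.82,
    }
    # the reverse leg carries neither proton nor PMF: the pair cannot pump
    assert reverse.stoichiometry == {
        "atp_c": -1.0, "adp_m": -1.0, "atp_m": 1.0, "adp_c": 1.0,
    }
    assert forward.lower_bound == 0 and reverse.lower_bound == 0


def test_diffusion_step_is_reversible_and_pmf_free(params):
    (step,) = make_transport_step(
        "O2tm", TransportCategory.DIFFUSION, imported=["o2"], params=params
    )
    assert step.reversible
    assert "pmf_c" not in step.stoichiometry
    with pytest.raises(ModelStructureError):
        make_transport_step(
            "BAD", TransportCategory.DIFFUSION, imported=["pyr"], params=params
        )


def test_unknown_uniport_charges_delta_psi(params):
    """A charged metabolite entering by an unidentified uniporter co-moves
    0.82 PMF inward."""
    (step,) = make_transport_step(
        "ASPt_test", TransportCategory.UNIPORT_UNKNOWN, imported=["asp_L"],
        params=params,
    )
    assert step.stoichiometry["pmf_c"] == pytest.approx(-0.82)


def test_flippase_couples_atp_hydrolysis(params):
    (step,) = make_transport_step(
        "FLIP_test", TransportCategory.FLIPPASE, imported=["pmtcoa"],
        params=params,
    )
    assert step.stoichiometry["atp_c"] == -1.0
    assert step.stoichiometry["adp_c"] == 1.0


def test_respiratory_chain_stoichiometry(params):
    chain = make_respiratory_chain(params)
    f = params.ros_fraction
    synthase = chain["atp_synthase"]
    assert synthase.stoichiometry["pmf_c"] == -2.7
    assert synthase.stoichiometry["atp_m"] == 1.0
    assert synthase.reversible
    ci = chain["complex_i"]
    assert ci.stoichiometry["pmf_c"] == pytest.approx(4 * (1 - f))
    assert ci.stoichiometry["o2s_m"] == pytest.approx(2 * f)
    # PMF delivered per matrix NADH: CI + CIII + CIV(/2, written per O2)
    per_nadh = (
        ci.stoichiometry["pmf_c"]
        + chain["complex_iii"].stoichiometry["pmf_c"] * (1 - f)
        + chain["complex_iv"].stoichiometry["pmf_c"] * (1 - f) / 2.0
    )
    assert per_nadh == pytest.approx(10 * (1 - f), abs=1e-9)
    # complex II reduces ubiquinone directly in a single reaction
    cii = chain["complex_ii"]
    assert cii.stoichiometry["q10_m"] == -1.0
    assert cii.stoichiometry["succ_m"] == -1.0


def test_no_free_fad_species_anywhere(bundled):
    for met_id in bundled.metabolites:
        assert not met_id.startswith(("fad", "fadh")), met_id


def test_pseudo_reactions_are_four_and_exempt(bundled):
    pseudo = make_pseudo_reactions()
    assert len(pseudo) == 4
    ids = {r.id for r in pseudo}
    assert ATP_OBJECTIVE in ids
    for rxn in pseudo:
        assert validate_balance(rxn, bundled.metabolites).exemption == "pseudo"
    atp = next(r for r in pseudo if r.id == ATP_OBJECTIVE)
    assert atp.stoichiometry["atp_c"] == -1.0
    assert atp.stoichiometry["adp_c"] == 1.0


def test_bundled_model_has_required_components(bundled):
    for rid in (PROTON_LEAK_ID, ANT_ID, ANT_REVERSE_ID, ATP_SYNTHASE_ID,
                "PDHm", "CSm", "FUMm", "FUM", "CPT1", "FAOXC160_MitoCore",
                "BDHm", "OCOAT1m", "LDH_L", "GLUDm", "PEPCK", "ME2m",
                "ASPGLUm_MitoCore", "AKGMALtm", "EX_fum", "EX_o2"):
        assert rid in bundled.reactions, rid
    assert bundled.objective_id == ATP_OBJECTIVE
    assert len(bundled.pseudo_reactions()) == 4
    bundled.validate()


def test_yields_invariant_to_complex_split(bundled):
    """Only the pumping totals per NADH/QH2 matter for ATP yields, so the
    alternative per-complex split leaves the glucose yield unchanged."""
    alt = build_reduced_model(
        PMFParameters(complex_split=ALTERNATIVE_COMPLEX_SPLIT), qc=False
    )
    protocol = YieldProtocol(fuel_id="glc_D", method="fba")
    y_default = fba(apply_yield_protocol(bundled, protocol), ATP_OBJECTIVE)
    y_alt = fba(apply_yield_protocol(alt, protocol), ATP_OBJECTIVE)
    assert y_alt.objective_value == pytest.approx(
        y_default.objective_value, abs=1e-6
    )


def test_micromodel_atp_per_nadh(params, micro):
    """OxPhos plus export delivers 10(1-ros)/3.7 ATP per matrix NADH: 2.7 PMF
    at the synthase plus 0.82 + 0.18 for nucleotide and phosphate transport."""
    result = fba(micro, ATP_OBJECTIVE)
    expected = params.pmf_per_nadh * (1 - params.ros_fraction) / (
        params.protons_per_atp + 1.0
    )
    assert result.objective_value == pytest.approx(expected, abs=1e-9)
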
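"""LP machinery: FBA against an exact oracle, FVA, geometric FBA, knockouts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoflux import (
    FBAError,
    GeometricFBASettings,
    fba,
    fva,
    geometric_fba,
    knockout,
    scan,
)
from mitoflux.model_core import (
    BOUNDARY_EXCHANGE,
    CYTOSOLIC,
    Metabolite,
    ModelNetwork,
    Reaction,
    assemble_stoichiometric_matrix,
)
from mitoflux.network_builder import ATP_OBJECTIVE

from conftest import toy_chain, toy_parallel
from _oracles import brute_force_lp_max


def _oracle_value(model, objective_id):
    sm = assemble_stoichiometric_matrix(model)
    lb = [model.reactions[r].lower_bound for r in sm.reaction_ids]
    ub = [model.reactions[r].upper_bound for r in sm.reaction_ids]
    c = [1.0 if r == objective_id else 0.0 for r in sm.reaction_ids]
    return brute_force_lp_max(sm.matrix.tolist(), lb, ub, c)


def test_fba_toy_chain_hits_uptake_cap():
    model = toy_chain()
    result = fba(model)
    assert result.ok
    assert result.objective_value == pytest.approx(5.0)
    assert result.residual <= 1e-9


def test_fba_matches_exact_oracle_on_toys():
    for model in (toy_chain(), toy_parallel()):
        expected = _oracle_value(model, model.objective_id)
        got = fba(model).objective_value
        assert got == pytest.approx(float(expected), abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=st.data())
def test_fba_matches_exact_oracle_on_random_networks(data):
    """On arbitrary small networks the HiGHS optimum equals exhaustive
    exact-arithmetic vertex enumeration of the flux polytope."""
    n_mets = data.draw(st.integers(1, 3))
    n_rxns = data.draw(st.integers(2, 6))
    model = ModelNetwork()
    met_ids = [f"x{i}_c" for i in range(n_mets)]
    for mid in met_ids:
        model.add_metabolite(Metabolite(mid, mid, CYTOSOLIC))
    coeff = st.integers(-2, 2)
    for j in range(n_rxns):
        stoich = {}
        for mid in met_ids:
            value = data.draw(coeff)
            if value:
                stoich[mid] = float(value)
        if not stoich:
            stoich = {met_ids[0]: 1.0}
        reversible = data.draw(st.booleans())
        ub = float(data.draw(st.integers(0, 10)))
        lb = -float(data.draw(st.integers(0, 10))) if reversible else 0.0
        model.add_reaction(
            Reaction(f"r{j}", stoich, lb, max(lb, ub),
                     category=BOUNDARY_EXCHANGE)
        )
    objective = "r0"
    expected = _oracle_value(model, objective)
    result = fba(model, objective)
    if expected is None:
        assert result.status != "optimal" or abs(result.objective_value) < 1e-9
    else:
        assert result.ok
        assert result.objective_value == pytest.approx(float(expected), abs=1e-8)


def test_fba_reports_infeasible_status():
    model = toy_chain()
    model.reactions["A_in"].lower_bound = 6.0
    model.reactions["A_in"].upper_bound = 6.0
    model.reactions["A_to_B"].upper_bound = 1.0
    assert fba(model).status == "infeasible"


def test_fba_requires_an_objective():
    model = toy_chain()
    model.objective_id = None
    with pytest.raises(FBAError):
        fba(model)
    with pytest.raises(FBAError):
        fba(model, "nonexistent")


def test_closed_bundled_model_steady_state_residual(bundled):
    result = fba(bundled, ATP_OBJECTIVE)
    assert result.ok
    norm = max(1.0, max(abs(v) for v in result.fluxes.values()))
    assert result.residual <= 1e-9 * norm


def test_fva_single_path_ranges_are_points():
    model = toy_chain()
    ranges = fva(model, fraction=1.0).ranges
    for rid, (lo, hi) in ranges.items():
        assert hi - lo == pytest.approx(0.0, abs=1e-8), rid
        assert lo == pytest.approx(5.0, abs=1e-8)


def test_fva_isoenzyme_pair_wide_but_sum_fixed():
    model = toy_parallel()
    ranges = fva(model, fraction=1.0).ranges
    assert ranges["P1"] == pytest.approx((0.0, 10.0), abs=1e-6)
    assert ranges["P2"] == pytest.approx((0.0, 10.0), abs=1e-6)
    assert ranges["B_out"] == pytest.approx((10.0, 10.0), abs=1e-6)


def test_fva_relaxed_fraction_contains_strict_ranges(bundled):
    model = bundled.copy()
    model.reactions["EX_glc_D"].lower_bound = -1.0
    model.reactions["EX_o2"].lower_bound = -50.0
    strict = fva(model, ATP_OBJECTIVE, fraction=1.0)
    relaxed = fva(model, ATP_OBJECTIVE, fraction=0.98)
    for rid, (lo, hi) in strict.ranges.items():
        rlo, rhi = relaxed.ranges[rid]
        assert rlo <= lo + 1e-6 and rhi >= hi - 1e-6, rid


def test_geometric_fba_equals_fba_on_single_path():
    model = toy_chain()
    geo = geometric_fba(model)
    plain = fba(model)
    assert geo.objective_value == pytest.approx(plain.objective_value, abs=1e-6)
    for rid in model.reactions:
        assert geo.fluxes[rid] == pytest.approx(plain.fluxes[rid], abs=1e-6)


def test_geometric_fba_centres_parallel_paths():
    """Two identical routes of total capacity 10 each carry 5 at the
    well-centred optimum (the symmetric minimax point)."""
    geo = geometric_fba(toy_parallel())
    assert geo.fluxes["P1"] == pytest.approx(5.0, abs=1e-6)
    assert geo.fluxes["P2"] == pytest.approx(5.0, abs=1e-6)
    assert geo.objective_value == pytest.approx(10.0, abs=1e-9)


def test_geometric_fba_deterministic_and_idempotent(bundled):
    model = bundled.copy()
    model.reactions["EX_glc_D"].lower_bound = -1.0
    model.reactions["EX_o2"].lower_bound = -50.0
    first = geometric_fba(model, ATP_OBJECTIVE)
    second = geometric_fba(model, ATP_OBJECTIVE)
    for rid in model.reactions:
        assert first.fluxes[rid] == second.fluxes[rid], rid


def test_geometric_result_lies_inside_fva_box(bundled):
    model = bundled.copy()
    model.reactions["EX_glc_D"].lower_bound = -1.0
    model.reactions["EX_o2"].lower_bound = -50.0
    geo = geometric_fba(model, ATP_OBJECTIVE)
    plain = fba(model, ATP_OBJECTIVE)
    box = fva(model, ATP_OBJECTIVE, fraction=1.0)
    assert box.brackets(geo.fluxes, tol=1e-5)
    assert box.brackets(plain.fluxes, tol=1e-5)


def test_knockout_unknown_gene_lists_known_genes(bundled):
    with pytest.raises(FBAError, match="FH"):
        knockout(bundled, ["NOT_A_GENE"], ATP_OBJECTIVE)


def test_knockout_never_beats_wild_type(bundled):
    model = bundled.copy()
    model.reactions["EX_glc_D"].lower_bound = -1.0
    model.reactions["EX_o2"].lower_bound = -50.0
    wild_type = fba(model, ATP_OBJECTIVE).objective_value
    for target in ("LDHA", "BDH1", "CPT1"):
        ko = knockout(model, [target], ATP_OBJECTIVE)
        assert ko.objective_value <= wild_type + 1e-9


def test_knockout_of_inactive_reaction_changes_nothing(bundled):
    """Silencing a pathway that carries no flux on glucose leaves the optimum
    untouched."""
    model = bundled.copy()
    model.reactions["EX_glc_D"].lower_bound = -1.0
    model.reactions["EX_o2"].lower_bound = -50.0
    wild_type = fba(model, ATP_OBJECTIVE).objective_value
    ko = knockout(model, ["BDH1"], ATP_OBJECTIVE)
    assert ko.objective_value == pytest.approx(wild_type, abs=1e-9)


def test_scan_reports_infeasible_points_and_continues():
    model = toy_chain()
    results = scan(model, "A_to_B", "lower", [0.0, 3.0, 7.0])
    assert [r.status for r in results] == ["optimal", "optimal", "infeasible"]
    assert results[1].objective_value == pytest.approx(5.0)


def test_fba_agrees_with_cobrapy_on_bundled_model(bundled, tmp_path):
    """Independent cross-check: the bundled model exported to SBML, read by
    cobrapy and solved with its own LP stack gives the same optimum as our
    engine under the glucose protocol."""
    cobra = pytest.importorskip("cobra")
    from mitoflux.sbml_io import write_sbml

    model = bundled.copy()
    model.reactions["EX_glc_D"].lower_bound = -1.0
    model.reactions["EX_o2"].lower_bound = -50.0
    path = tmp_path / "model.xml"
    write_sbml(model, str(path))
    ours = fba(model, ATP_OBJECTIVE).objective_value

    cobra_model = cobra.io.read_sbml_model(str(path))
    cobra_model.objective = ATP_OBJECTIVE
    theirs = cobra_model.optimize().objective_value
    assert theirs == pytest.approx(ours, abs=1e-5)
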
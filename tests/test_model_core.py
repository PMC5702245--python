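"""Domain types, matrix assembly and balance checking."""

import numpy as np
import pytest

from mitoflux.model_core import (
    BOUNDARY_EXCHANGE,
    CYTOSOLIC,
    MITO_TRANSPORT,
    Metabolite,
    ModelNetwork,
    ModelStructureError,
    PSEUDO,
    Reaction,
    assemble_stoichiometric_matrix,
    parse_formula,
    validate_balance,
)
from mitoflux.network_builder import ANT_ID, ATP_OBJECTIVE, PI_CARRIER_ID


def test_parse_formula():
    assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
    assert parse_formula("HO4P") == {"H": 1, "O": 4, "P": 1}
    assert parse_formula("C21H32N7O16P3S") == {
        "C": 21, "H": 32, "N": 7, "O": 16, "P": 3, "S": 1,
    }
    with pytest.raises(ValueError):
        parse_formula("C6H12O6!")


def test_metabolite_suffix_enforced():
    with pytest.raises(ModelStructureError):
        Metabolite("atp_x", "ATP", CYTOSOLIC)
    with pytest.raises(ModelStructureError):
        Metabolite("atp_c", "ATP", "nucleus")


def test_reaction_invariants():
    with pytest.raises(ModelStructureError):
        Reaction("r", {"a_c": -1.0}, lower_bound=2.0, upper_bound=1.0)
    with pytest.raises(ModelStructureError):
        Reaction("r", {}, 0.0, 1.0)
    with pytest.raises(ModelStructureError):
        Reaction("r", {"a_c": -1.0}, 0.0, 1.0, category="weird")


def test_matrix_toy_transcription():
    """{R1: A->B, R2: B->} assembles to [[-1,0],[1,-1]] over rows (A,B)."""
    model = ModelNetwork()
    model.add_metabolite(Metabolite("a_c", "A", CYTOSOLIC))
    model.add_metabolite(Metabolite("b_c", "B", CYTOSOLIC))
    model.add_reaction(Reaction("R1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1.0))
    model.add_reaction(
        Reaction("R2", {"b_c": -1.0}, 0.0, 1.0, category=BOUNDARY_EXCHANGE)
    )
    sm = assemble_stoichiometric_matrix(model)
    assert sm.metabolite_ids == ("a_c", "b_c")
    assert sm.reaction_ids == ("R1", "R2")
    assert np.array_equal(sm.matrix, np.array([[-1.0, 0.0], [1.0, -1.0]]))


def test_matrix_empty_model():
    sm = assemble_stoichiometric_matrix(ModelNetwork())
    assert sm.matrix.shape == (0, 0)


def test_matrix_ant_column_matches_printed_carrier_equation(bundled):
    """The ATP/ADP carrier column carries the 0.82 PMF coefficients."""
    sm = assemble_stoichiometric_matrix(bundled)
    j = sm.reaction_ids.index(ANT_ID)
    col = {
        sm.metabolite_ids[i]: sm.matrix[i, j]
        for i in np.nonzero(sm.matrix[:, j])[0]
    }
    assert col == {
        "atp_m": -1.0,
        "adp_c": -1.0,
        "pmf_c": -0.82,
        "atp_c": 1.0,
        "adp_m": 1.0,
        "pmf_m": 0.82,
    }


def test_matrix_assembly_is_bijective(bundled):
    """Rebuilding stoichiometries from the matrix reproduces every reaction."""
    sm = assemble_stoichiometric_matrix(bundled)
    rebuilt = sm.to_reactions(bundled)
    for rid, rxn in bundled.reactions.items():
        assert rebuilt[rid] == rxn.stoichiometry


def test_matrix_unknown_metabolite_names_reaction():
    model = ModelNetwork()
    model.add_metabolite(Metabolite("a_c", "A", CYTOSOLIC))
    model.add_reaction(Reaction("R1", {"a_c": -1.0}, 0.0, 1.0,
                                category=BOUNDARY_EXCHANGE))
    model.reactions["R1"].stoichiometry["ghost_c"] = 1.0
    with pytest.raises(ModelStructureError, match="R1"):
        assemble_stoichiometric_matrix(model)


def test_transport_pmf_antisymmetry(bundled):
    """PMF is moved, never created, by transport: cytosolic and matrix
    coefficients are exact negatives on every inner-membrane step."""
    for rxn in bundled.reactions.values():
        if rxn.category != MITO_TRANSPORT:
            continue
        pmf_c = rxn.stoichiometry.get("pmf_c", 0.0)
        pmf_m = rxn.stoichiometry.get("pmf_m", 0.0)
        assert pmf_c == -pmf_m, rxn.id


def test_balance_phosphate_carrier_excludes_pmf(bundled):
    report = validate_balance(
        bundled.reactions[PI_CARRIER_ID], bundled.metabolites
    )
    assert report.balanced
    assert report.charge_delta == 0
    assert set(report.excluded_species) == {"pmf_c", "pmf_m"}


def test_balance_reports_charge_delta():
    mets = {
        "a_c": Metabolite("a_c", "A", CYTOSOLIC, charge=-1),
        "b_c": Metabolite("b_c", "B", CYTOSOLIC, charge=0),
    }
    report = validate_balance(
        Reaction("r", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1.0), mets
    )
    assert report.charge_delta == pytest.approx(1.0)
    assert not report.balanced


def test_balance_pseudo_reactions_exempt(bundled):
    report = validate_balance(
        bundled.reactions[ATP_OBJECTIVE], bundled.metabolites
    )
    assert report.exemption == "pseudo"
    assert report.balanced


def test_balance_missing_formula_reports_not_raises():
    mets = {
        "a_c": Metabolite("a_c", "A", CYTOSOLIC, charge=0, formula=None),
        "b_c": Metabolite("b_c", "B", CYTOSOLIC, charge=0, formula="CH4"),
    }
    report = validate_balance(
        Reaction("r", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1.0), mets
    )
    assert report.element_deltas is None
    assert report.missing_formulas == ["a_c"]


def test_bundled_model_is_charge_and_element_clean(bundled):
    for rxn in bundled.reactions.values():
        assert validate_balance(rxn, bundled.metabolites).balanced, rxn.id


def test_model_validate_catches_category_violations(bundled):
    broken = bundled.copy()
    # a "metabolic" reaction spanning both compartments is a curation error
    broken.reactions["PDHm"].stoichiometry["pyr_c"] = -1.0
    with pytest.raises(ModelStructureError, match="PDHm"):
        broken.validate()


def test_pmf_species_exist_in_both_compartments(bundled):
    pmf = [m for m in bundled.metabolites.values() if m.is_pmf]
    assert sorted(m.compartment for m in pmf) == ["cytosolic", "mitochondrial"]
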
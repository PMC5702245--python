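"""Shared fixtures: the bundled network, micro-model and broken variants."""

import pytest

from mitoflux import (
    PMFParameters,
    build_oxphos_micromodel,
    build_reduced_model,
)
from mitoflux.model_core import (
    CYTOSOLIC,
    METABOLIC,
    BOUNDARY_EXCHANGE,
    Metabolite,
    ModelNetwork,
    Reaction,
)
from mitoflux.network_builder import ANT_ID, PI_CARRIER_ID, PROTON_LEAK_ID


@pytest.fixture(scope="session")
def params():
    return PMFParameters()


@pytest.fixture(scope="session")
def bundled():
    """The bundled reduced network (QC is exercised separately)."""
    return build_reduced_model(qc=False)


@pytest.fixture(scope="session")
def micro():
    return build_oxphos_micromodel()


@pytest.fixture()
def energy_cycle_model(bundled):
    """Deliberately broken: PMF terms stripped from the ANT and phosphate
    carriers plus a reversible proton leak, so carriers running in reverse
    recycle the synthase's PMF and mint ATP in a closed system."""
    broken = bundled.copy()
    for rid in (ANT_ID, PI_CARRIER_ID):
        rxn = broken.reactions[rid]
        rxn.stoichiometry = {
            m: c for m, c in rxn.stoichiometry.items() if not m.startswith("pmf_")
        }
    broken.reactions[PROTON_LEAK_ID].lower_bound = -1000.0
    return broken


@pytest.fixture()
def dead_end_model(bundled):
    """Deliberately broken: a metabolite produced but never consumed."""
    broken = bundled.copy()
    broken.add_metabolite(Metabolite("xenobiotic_c", "orphan product", CYTOSOLIC))
    broken.add_reaction(
        Reaction(
            "PYR_TO_X",
            {"pyr_c": -1.0, "xenobiotic_c": 1.0},
            0.0,
            1000.0,
            category=METABOLIC,
        )
    )
    return broken


@pytest.fixture()
def blocked_model(bundled):
    """Deliberately broken: an orphan two-metabolite reaction that can never
    carry flux."""
    broken = bundled.copy()
    broken.add_metabolite(Metabolite("orphan_a_c", "orphan A", CYTOSOLIC))
    broken.add_metabolite(Metabolite("orphan_b_c", "orphan B", CYTOSOLIC))
    broken.add_reaction(
        Reaction(
            "ORPHAN",
            {"orphan_a_c": -1.0, "orphan_b_c": 1.0},
            0.0,
            1000.0,
            category=METABOLIC,
        )
    )
    return broken


def toy_chain():
    """A_in -> A -> B -> B_out with A_in capped at 5."""
    m = ModelNetwork()
    for mid in ("a_c", "b_c"):
        m.add_metabolite(Metabolite(mid, mid, CYTOSOLIC))
    m.add_reaction(Reaction("A_in", {"a_c": 1.0}, 0.0, 5.0,
                            category=BOUNDARY_EXCHANGE))
    m.add_reaction(Reaction("A_to_B", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("B_out", {"b_c": -1.0}, 0.0, 1000.0,
                            category=BOUNDARY_EXCHANGE))
    m.objective_id = "B_out"
    return m


def toy_parallel():
    """Two identical parallel routes sharing a capacity-10 supply."""
    m = ModelNetwork()
    for mid in ("a_c", "b_c"):
        m.add_metabolite(Metabolite(mid, mid, CYTOSOLIC))
    m.add_reaction(Reaction("A_in", {"a_c": 1.0}, 0.0, 10.0,
                            category=BOUNDARY_EXCHANGE))
    m.add_reaction(Reaction("P1", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("P2", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0))
    m.add_reaction(Reaction("B_out", {"b_c": -1.0}, 0.0, 1000.0,
                            category=BOUNDARY_EXCHANGE))
    m.objective_id = "B_out"
    return m
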
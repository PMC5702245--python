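"""Domain types for compartmentalised metabolic models.

The model is a two-compartment abstraction of a human cell: ``cytosolic``
(cytosol, outer mitochondrial membrane, intermembrane space and the cytosolic
face of the inner membrane) and ``mitochondrial`` (matrix and the matrix face
of the inner membrane).  The proton motive force across the inner membrane is
carried by a bookkeeping pseudo-metabolite (one species per compartment,
``is_pmf=True``) that electrogenic and proton-coupled steps co-transport.

Flux unit throughout: umol/min/gDW.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

CYTOSOLIC = "cytosolic"
MITOCHONDRIAL = "mitochondrial"
BOUNDARY = "boundary"
COMPARTMENTS = (CYTOSOLIC, MITOCHONDRIAL, BOUNDARY)

#: compartment id -> metabolite id suffix
COMPARTMENT_SUFFIX = {CYTOSOLIC: "_c", MITOCHONDRIAL: "_m"}

# reaction categories
METABOLIC = "metabolic"
MITO_TRANSPORT = "mito_transport"
BOUNDARY_EXCHANGE = "boundary_exchange"
PSEUDO = "pseudo"
CATEGORIES = (METABOLIC, MITO_TRANSPORT, BOUNDARY_EXCHANGE, PSEUDO)

DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelStructureError(ValueError):
    """A reaction or model violates a structural invariant."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula such as ``C6H12O6`` into element counts."""
    pos = 0
    counts: Dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in a specific compartment.

    ``charge`` is the signed elementary charge of the predominant species at
    physiological pH.  ``is_pmf`` marks the proton-motive-force bookkeeping
    species, which is exempt from charge and elemental balance checks.
    """

    id: str
    name: str
    compartment: str
    charge: int = 0
    formula: Optional[str] = None
    is_pmf: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelStructureError(
                f"metabolite {self.id}: unknown compartment {self.compartment!r}"
            )
        suffix = COMPARTMENT_SUFFIX.get(self.compartment)
        if suffix is not None and not self.id.endswith(suffix):
            raise ModelStructureError(
                f"metabolite {self.id}: id must end with {suffix!r} "
                f"for compartment {self.compartment}"
            )
        if self.formula is not None:
            parse_formula(self.formula)  # fail fast on malformed formulas

    @property
    def elements(self) -> Optional[Dict[str, int]]:
        return parse_formula(self.formula) if self.formula is not None else None


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and provenance annotation.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  Ids carry the suffix ``_MitoCore`` when the reaction departs
    from its reference-database form.  ``genes`` is a list of
    ``(symbol, stable_id)`` pairs; complexes are single reactions, so a single
    subunit gene disables the whole step in knockouts.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    genes: List[Tuple[str, str]] = field(default_factory=list)
    subsystem: str = ""
    category: str = METABOLIC
    annotation: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ModelStructureError(
                f"reaction {self.id}: unknown category {self.category!r}"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            genes=list(self.genes),
            subsystem=self.subsystem,
            category=self.category,
            annotation=dict(self.annotation),
        )

    def compartments(self, metabolites: Mapping[str, Metabolite]) -> set:
        return {metabolites[m].compartment for m in self.stoichiometry}

    def gene_symbols(self) -> List[str]:
        return [symbol for symbol, _ in self.genes]


@dataclass
class ModelNetwork:
    """An assembled two-compartment metabolic network with an objective."""

    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    objective_id: Optional[str] = None
    notes: str = ""

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelStructureError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelStructureError(f"duplicate reaction id {rxn.id}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelStructureError(
                    f"reaction {rxn.id}: unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "ModelNetwork":
        clone = ModelNetwork(
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            objective_id=self.objective_id,
            notes=self.notes,
        )
        return clone

    # -- queries -----------------------------------------------------------

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.category == BOUNDARY_EXCHANGE]

    def pseudo_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.category == PSEUDO]

    def reactions_for_gene(self, symbol: str) -> List[Reaction]:
        return [r for r in self.reactions.values() if symbol in r.gene_symbols()]

    def known_genes(self) -> List[str]:
        seen = sorted({g for r in self.reactions.values() for g in r.gene_symbols()})
        return seen

    # -- validation --------------------------------------------------------

    def validate(self, allow_orphans: bool = False) -> None:
        """Enforce structural invariants.

        * every metabolite id referenced by a reaction exists;
        * category/compartment consistency (a mito_transport reaction touches
          both compartments, a metabolic reaction exactly one, a
          boundary_exchange only cytosolic species);
        * the objective, if set, exists;
        * unless ``allow_orphans``, every metabolite takes part in at least
          two reactions (a single-use metabolite is a certain dead end).
        """
        for rxn in self.reactions.values():
            missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
            if missing:
                raise ModelStructureError(
                    f"reaction {rxn.id}: unknown metabolites {missing}"
                )
            comps = rxn.compartments(self.metabolites)
            real = comps - {BOUNDARY}
            if rxn.category == MITO_TRANSPORT and real != {CYTOSOLIC, MITOCHONDRIAL}:
                raise ModelStructureError(
                    f"transport reaction {rxn.id} must touch both compartments"
                )
            if rxn.category == METABOLIC and len(real) != 1:
                raise ModelStructureError(
                    f"metabolic reaction {rxn.id} must sit in exactly one "
                    f"compartment, touches {sorted(real)}"
                )
            if rxn.category == BOUNDARY_EXCHANGE and not real <= {CYTOSOLIC}:
                raise ModelStructureError(
                    f"boundary exchange {rxn.id} may only touch cytosolic species"
                )
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ModelStructureError(f"objective {self.objective_id!r} not in model")
        if not allow_orphans:
            use: Dict[str, int] = {m: 0 for m in self.metabolites}
            for rxn in self.reactions.values():
                for met_id in rxn.stoichiometry:
                    use[met_id] += 1
            orphans = [m for m, n in use.items() if n < 2]
            if orphans:
                raise ModelStructureError(
                    f"metabolites used by fewer than two reactions: {orphans}"
                )


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Dense stoichiometric matrix with row/column id bookkeeping."""

    matrix: np.ndarray  # rows = metabolites, columns = reactions
    metabolite_ids: Tuple[str, ...]
    reaction_ids: Tuple[str, ...]

    def to_reactions(self, model: ModelNetwork) -> Dict[str, Dict[str, float]]:
        """Rebuild stoichiometry maps from the matrix (inverse of assembly)."""
        out: Dict[str, Dict[str, float]] = {}
        for j, rid in enumerate(self.reaction_ids):
            col = self.matrix[:, j]
            out[rid] = {
                self.metabolite_ids[i]: float(col[i])
                for i in np.nonzero(col)[0]
            }
        return out


def assemble_stoichiometric_matrix(model: ModelNetwork) -> StoichiometricMatrix:
    """Assemble S with rows over non-boundary metabolites, columns over reactions.

    Entry (i, j) is the coefficient of metabolite i in reaction j.  Boundary
    sinks and sources appear only as one-sided boundary_exchange columns.
    """
    met_ids = tuple(
        m for m in model.metabolites if model.metabolites[m].compartment != BOUNDARY
    )
    rxn_ids = tuple(model.reactions)
    index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for met_id, coeff in model.reactions[rid].stoichiometry.items():
            if met_id not in model.metabolites:
                raise ModelStructureError(
                    f"reaction {rid}: unknown metabolite {met_id!r}"
                )
            if model.metabolites[met_id].compartment == BOUNDARY:
                continue
            S[index[met_id], j] = coeff
    return StoichiometricMatrix(S, met_ids, rxn_ids)


@dataclass
class BalanceReport:
    """Outcome of a mass/charge balance check for one reaction.

    ``charge_delta`` is net product charge minus net substrate charge over the
    non-exempt participants.  ``element_deltas`` is None when any participant
    lacks a formula (the elemental tally is then not computable).  PMF species
    are always excluded from the tallies; pseudo and boundary-exchange
    reactions are exempt wholesale.
    """

    reaction_id: str
    charge_delta: float = 0.0
    element_deltas: Optional[Dict[str, float]] = None
    exemption: Optional[str] = None
    excluded_species: List[str] = field(default_factory=list)
    missing_formulas: List[str] = field(default_factory=list)

    @property
    def balanced(self) -> bool:
        if self.exemption is not None:
            return True
        if abs(self.charge_delta) > 1e-9:
            return False
        if self.element_deltas is not None and any(
            abs(d) > 1e-9 for d in self.element_deltas.values()
        ):
            return False
        return True


def validate_balance(
    reaction: Reaction, metabolites: Mapping[str, Metabolite]
) -> BalanceReport:
    """Report net charge and elemental imbalances for one reaction.

    Never raises for missing formulas: the elemental tally is simply reported
    as unavailable.  Pseudo reactions and one-sided boundary exchanges are
    exempt (flagged as such), and PMF species never enter the tallies.
    """
    report = BalanceReport(reaction_id=reaction.id)
    if reaction.category == PSEUDO:
        report.exemption = "pseudo"
        return report
    if reaction.category == BOUNDARY_EXCHANGE:
        report.exemption = "boundary"
        return report

    charge = 0.0
    elements: Dict[str, float] = {}
    have_all_formulas = True
    for met_id, coeff in reaction.stoichiometry.items():
        met = metabolites[met_id]
        if met.is_pmf:
            report.excluded_species.append(met_id)
            continue
        charge += coeff * met.charge
        if met.formula is None:
            have_all_formulas = False
            report.missing_formulas.append(met_id)
            continue
        for element, count in parse_formula(met.formula).items():
            elements[element] = elements.get(element, 0.0) + coeff * count
    report.charge_delta = charge
    if have_all_formulas:
        report.element_deltas = {
            el: d for el, d in elements.items() if abs(d) > 1e-9
        } or {}
    return report
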
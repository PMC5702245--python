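"""Reproducible simulation protocols.

Three protocols drive the bundled network: single-fuel ATP yields, fumarase
deficiency (a TCA-cycle disease with fumarate efflux as diagnostic marker)
and an uncoupling-protein proton-leak scan.  A fourth routine partitions
acetyl-CoA production by fuel source, mirroring how cardiac fuel selection
is usually summarised.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

from .model_core import BOUNDARY_EXCHANGE, ModelNetwork
from .fba_engine import (
    FluxResult,
    GeometricFBAError,
    GeometricFBASettings,
    fba,
    geometric_fba,
    knockout_model,
)
from .network_builder import (
    ANT_ID,
    ANT_REVERSE_ID,
    ATP_OBJECTIVE,
    ATP_SYNTHASE_ID,
    FUMARASE_GENE,
    PI_CARRIER_ID,
    PI_CARRIER_REVERSE_ID,
    PROTON_LEAK_ID,
    _FUEL_EXCHANGES,
)

#: exchange reactions of metabolites degradable to ATP (closed during yields)
DEGRADABLE_FUEL_EXCHANGES = tuple(f"EX_{base}" for base in _FUEL_EXCHANGES)


@dataclass
class YieldProtocol:
    """Single-fuel maximum-ATP protocol.

    All degradable-fuel uptakes are closed, oxygen is opened to 50
    umol/min/gDW so it cannot limit the result, the fuel of interest enters
    at 1 umol/min/gDW and ATP hydrolysis is maximised with geometric FBA.
    At unit uptake the objective equals mol ATP per mol fuel.
    """

    fuel_id: str = "EX_glc_D"
    fuel_uptake: float = 1.0
    o2_uptake: float = 50.0
    objective: str = ATP_OBJECTIVE
    method: str = "geometric"


def apply_yield_protocol(model: ModelNetwork, protocol: YieldProtocol) -> ModelNetwork:
    prepared = model.copy()
    for ex_id in DEGRADABLE_FUEL_EXCHANGES:
        if ex_id in prepared.reactions:
            prepared.reactions[ex_id].lower_bound = 0.0
    prepared.reactions["EX_o2"].lower_bound = -abs(protocol.o2_uptake)
    fuel = protocol.fuel_id if protocol.fuel_id.startswith("EX_") else "EX_" + protocol.fuel_id
    if fuel not in prepared.reactions:
        raise KeyError(f"fuel exchange {fuel!r} not in model")
    prepared.reactions[fuel].lower_bound = -abs(protocol.fuel_uptake)
    return prepared


def _solve(model: ModelNetwork, objective: str, method: str,
           settings: Optional[GeometricFBASettings] = None) -> FluxResult:
    if method == "geometric":
        try:
            return geometric_fba(model, objective, settings)
        except GeometricFBAError as err:
            return err.last_iterate
    return fba(model, objective)


def atp_yield(
    model: ModelNetwork,
    protocol: YieldProtocol,
    settings: Optional[GeometricFBASettings] = None,
) -> float:
    """Maximum ATP per unit fuel under the yield protocol.

    Asserts that oxygen is non-binding at the optimum; a fuel the network
    cannot degrade yields 0 with a warning rather than an error.
    """
    prepared = apply_yield_protocol(model, protocol)
    result = _solve(prepared, protocol.objective, protocol.method, settings)
    if not result.ok:
        raise RuntimeError(f"yield protocol did not solve: {result.status}")
    o2_flux = result.fluxes.get("EX_o2", 0.0)
    if o2_flux <= -abs(protocol.o2_uptake) + 1e-6:
        raise AssertionError(
            "oxygen bound is binding at the optimum; raise o2_uptake"
        )
    value = float(result.objective_value)
    if protocol.fuel_uptake > 0 and abs(value) < 1e-9:
        warnings.warn(
            f"{protocol.fuel_id}: no degradation route carries flux; yield 0",
            stacklevel=2,
        )
    return value


# ---------------------------------------------------------------------------
# default cardiomyocyte bounds
# ---------------------------------------------------------------------------


def default_cardiomyocyte_bounds() -> Dict[str, Dict[str, float]]:
    """Bundled approximate cardiomyocyte boundary-uptake configuration.

    Fuels are provided in slight excess of what the oxygen bound supports, so
    oxygen availability limits the overall flux, as in well-perfused heart.
    The values are editable approximations, not transcriptions.
    """
    text = resources.files("mitoflux.data").joinpath(
        "cardiomyocyte_uptakes.json"
    ).read_text()
    raw = json.loads(text)
    return {k: v for k, v in raw.items() if not k.startswith("_")}


def apply_uptake_bounds(
    model: ModelNetwork, bounds: Dict[str, Dict[str, float]]
) -> ModelNetwork:
    configured = model.copy()
    for ex_id, spec in bounds.items():
        rxn = configured.reactions[ex_id]
        if rxn.category != BOUNDARY_EXCHANGE:
            raise ValueError(f"{ex_id} is not a boundary exchange")
        if "lower" in spec:
            rxn.lower_bound = spec["lower"]
        if "upper" in spec:
            rxn.upper_bound = spec["upper"]
    return configured


def default_cardiomyocyte_model(model: ModelNetwork) -> ModelNetwork:
    return apply_uptake_bounds(model, default_cardiomyocyte_bounds())


# ---------------------------------------------------------------------------
# fumarase deficiency
# ---------------------------------------------------------------------------


@dataclass
class FumaraseDeficiencyResult:
    wild_type: FluxResult
    knockout: FluxResult
    percent_atp_reduction: Optional[float]
    fumarate_efflux: Optional[float]
    infeasible: bool = False


def simulate_fumarase_deficiency(
    model: ModelNetwork,
    uptake_bounds: Optional[Dict[str, Dict[str, float]]] = None,
    method: str = "geometric",
    settings: Optional[GeometricFBASettings] = None,
) -> FumaraseDeficiencyResult:
    """Inactivate both fumarate hydratase isoforms and compare to wild type.

    Both the cytosolic and the mitochondrial reaction map to the single FH
    gene, so a gene knockout silences the pair.  Uptake bounds stay at the
    (default cardiomyocyte) values.  Reports the percent ATP reduction and
    the fumarate boundary efflux; an infeasible knockout is reported, not
    raised.
    """
    configured = apply_uptake_bounds(
        model, uptake_bounds or default_cardiomyocyte_bounds()
    )
    wild_type = _solve(configured, ATP_OBJECTIVE, method, settings)
    ko_model = knockout_model(configured, [FUMARASE_GENE])
    ko = _solve(ko_model, ATP_OBJECTIVE, method, settings)
    if not (wild_type.ok and ko.ok):
        return FumaraseDeficiencyResult(wild_type, ko, None, None, True)
    wt_atp = wild_type.objective_value or 0.0
    reduction = 100.0 * (1.0 - ko.objective_value / wt_atp) if wt_atp else None
    return FumaraseDeficiencyResult(
        wild_type, ko, reduction, ko.fluxes.get("EX_fum", 0.0)
    )


# ---------------------------------------------------------------------------
# proton leak
# ---------------------------------------------------------------------------


@dataclass
class LeakScanPoint:
    leak: float
    status: str
    max_atp: Optional[float] = None
    atp_synthase_flux: Optional[float] = None
    ant_flux: Optional[float] = None
    pi_carrier_flux: Optional[float] = None


@dataclass
class LeakScanResult:
    points: List[LeakScanPoint] = field(default_factory=list)
    truncated_at: Optional[float] = None

    @property
    def feasible_points(self) -> List[LeakScanPoint]:
        return [p for p in self.points if p.status == "optimal"]


def max_feasible_leak(
    model: ModelNetwork,
    uptake_bounds: Optional[Dict[str, Dict[str, float]]] = None,
) -> float:
    """Largest proton leak the fuel supply can sustain (max leak-step flux)."""
    configured = apply_uptake_bounds(
        model, uptake_bounds or default_cardiomyocyte_bounds()
    )
    result = fba(configured, PROTON_LEAK_ID)
    if not result.ok:
        raise RuntimeError(f"leak maximisation failed: {result.status}")
    return float(result.objective_value)


def default_leak_values(
    model: ModelNetwork,
    n_points: int = 9,
    uptake_bounds: Optional[Dict[str, Dict[str, float]]] = None,
) -> List[float]:
    """Evenly spaced leak values from zero up to the feasibility edge."""
    top = max_feasible_leak(model, uptake_bounds)
    step = top / (n_points - 1)
    values = [round(i * step, 6) for i in range(n_points - 1)]
    values.append(round(top - 1e-6 * max(1.0, top), 6))
    return values


def proton_leak_scan(
    model: ModelNetwork,
    leak_values: Sequence[float],
    uptake_bounds: Optional[Dict[str, Dict[str, float]]] = None,
    method: str = "geometric",
    settings: Optional[GeometricFBASettings] = None,
) -> LeakScanResult:
    """Force increasing proton leak through UCP2 and track OxPhos fluxes.

    The lower bound of the leak step (cytosol->matrix proton re-entry,
    dissipating one PMF each) is raised over the series; for every value the
    maximal ATP production and the ATP synthase, adenine-nucleotide-carrier
    and phosphate-carrier net fluxes are recorded.  The series truncates at
    the first infeasible leak with a notice.
    """
    configured = apply_uptake_bounds(
        model, uptake_bounds or default_cardiomyocyte_bounds()
    )
    result = LeakScanResult()
    for leak in leak_values:
        m = configured.copy()
        rxn = m.reactions[PROTON_LEAK_ID]
        rxn.lower_bound = leak
        rxn.upper_bound = max(rxn.upper_bound, leak)
        solved = _solve(m, ATP_OBJECTIVE, method, settings)
        if not solved.ok:
            result.points.append(LeakScanPoint(leak, solved.status))
            result.truncated_at = leak
            warnings.warn(
                f"leak scan truncated: infeasible at leak {leak}", stacklevel=2
            )
            break
        ant = solved.fluxes.get(ANT_ID, 0.0) - solved.fluxes.get(ANT_REVERSE_ID, 0.0)
        pic = solved.fluxes.get(PI_CARRIER_ID, 0.0) - solved.fluxes.get(
            PI_CARRIER_REVERSE_ID, 0.0
        )
        result.points.append(
            LeakScanPoint(
                leak,
                solved.status,
                solved.objective_value,
                solved.fluxes.get(ATP_SYNTHASE_ID, 0.0),
                ant,
                pic,
            )
        )
    return result


# ---------------------------------------------------------------------------
# acetyl-CoA attribution
# ---------------------------------------------------------------------------

#: producing reactions of each traced pool: reaction -> (weight, source)
#: where source is either a fuel tag or another pool (prefixed "pool:")
_POOL_GRAPH: Dict[str, Dict[str, Tuple[float, str]]] = {
    "accoa_m": {
        "FAOXC160_MitoCore": (8.0, "fatty_acid"),
        "ACACT1rm": (2.0, "ketone"),
        "PDHm": (1.0, "pool:pyr_m"),
    },
    "pyr_m": {
        "PYRt2m_MitoCore": (1.0, "pool:pyr_c"),
        "ALATA_Lm": (1.0, "amino_acid"),
        "ME2m": (1.0, "amino_acid"),
    },
    "pyr_c": {
        "PYK": (1.0, "pool:pep_c"),
        "LDH_L": (1.0, "lactate"),
    },
    "pep_c": {
        "ENO": (1.0, "glucose"),
        "PEPCK": (1.0, "amino_acid"),
    },
}

SOURCE_TAGS = ("fatty_acid", "glucose", "lactate", "ketone", "amino_acid", "glycerol")


@dataclass
class AcetylCoAAttribution:
    """Fractions of matrix acetyl-CoA production by fuel source.

    Empty when no acetyl-CoA is produced; otherwise fractions sum to 1.
    Mixed pools (pyruvate) are split pro rata over their producing fluxes,
    since FBA carries no tracer information.
    """

    fractions: Dict[str, float] = field(default_factory=dict)
    total_flux: float = 0.0


def _pool_sources(
    pool: str, fluxes: Dict[str, float], seen: Tuple[str, ...] = ()
) -> Tuple[Dict[str, float], float]:
    """Fractional fuel-source composition of a metabolite pool."""
    composition: Dict[str, float] = {}
    total = 0.0
    for rid, (weight, source) in _POOL_GRAPH.get(pool, {}).items():
        flux = max(fluxes.get(rid, 0.0), 0.0) * weight
        if flux <= 1e-9:
            continue
        total += flux
        if source.startswith("pool:"):
            child = source[5:]
            if child in seen:  # defensive: no cycles in the pool graph
                continue
            child_comp, _ = _pool_sources(child, fluxes, seen + (pool,))
            for tag, frac in child_comp.items():
                composition[tag] = composition.get(tag, 0.0) + flux * frac
        else:
            composition[source] = composition.get(source, 0.0) + flux
    if total > 0:
        composition = {tag: v / total for tag, v in composition.items()}
    return composition, total


def attribute_acetyl_coa(
    flux_result: FluxResult, model: ModelNetwork
) -> AcetylCoAAttribution:
    """Partition matrix acetyl-CoA production by upstream fuel pathway."""
    composition, total = _pool_sources("accoa_m", flux_result.fluxes)
    if total <= 1e-9:
        return AcetylCoAAttribution()
    fractions = {tag: composition.get(tag, 0.0) for tag in SOURCE_TAGS}
    return AcetylCoAAttribution(fractions, total)
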
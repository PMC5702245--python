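"""Automated model quality control.

Three network-level checks mirror the curation tests applied to carefully
built core models: every reaction must be able to carry flux when the
cytosolic boundary is open, no metabolite may be a dead end, and a fully
closed system must not be able to generate ATP (or any other energy
currency) from nothing.  A mass/charge balance sweep over all non-exempt
reactions completes the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .model_core import (
    BOUNDARY_EXCHANGE,
    DEFAULT_BOUND,
    PSEUDO,
    ModelNetwork,
    Reaction,
    validate_balance,
)
from .fba_engine import _LP, _STATUS

_FLUX_TOL = 1e-6
#: fuel-free currency sinks screened for energy-generating cycles
_CURRENCY_SINKS = {
    "ATP_c": {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
    "PMF_c": {"pmf_c": -1.0, "pmf_m": 1.0},
    "NADH_c": {"nadh_c": -1.0, "nad_c": 1.0, "h_c": 1.0},
    "NADH_m": {"nadh_m": -1.0, "nad_m": 1.0, "h_m": 1.0},
    "NADPH_m": {"nadph_m": -1.0, "nadp_m": 1.0, "h_m": 1.0},
}


@dataclass
class QCReport:
    """Aggregated QC outcome; ``passed`` iff every check is clean."""

    blocked_reactions: List[str] = field(default_factory=list)
    dead_end_metabolites: List[str] = field(default_factory=list)
    energy_cycle_atp: float = 0.0
    energy_cycle_detail: Dict[str, float] = field(default_factory=dict)
    balance_issues: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return (
            not self.blocked_reactions
            and not self.dead_end_metabolites
            and not self.balance_issues
            and abs(self.energy_cycle_atp) <= _FLUX_TOL
            and all(abs(v) <= _FLUX_TOL for v in self.energy_cycle_detail.values())
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "blocked_reactions": self.blocked_reactions,
                "dead_end_metabolites": self.dead_end_metabolites,
                "energy_cycle_atp": self.energy_cycle_atp,
                "energy_cycle_detail": self.energy_cycle_detail,
                "balance_issues": self.balance_issues,
            },
            indent=2,
        )


def _open_boundaries(model: ModelNetwork, bound: float) -> ModelNetwork:
    opened = model.copy()
    for rxn in opened.reactions.values():
        if rxn.category == BOUNDARY_EXCHANGE:
            rxn.lower_bound = -abs(bound)
            rxn.upper_bound = abs(bound)
    return opened


def check_flux_capability(
    model: ModelNetwork, bound: float = DEFAULT_BOUND
) -> List[str]:
    """Reactions unable to carry any flux with all boundary exchanges open.

    Each reaction flux is maximised and minimised in turn; a reaction is
    blocked when both optima are zero.
    """
    opened = _open_boundaries(model, bound)
    lp = _LP(opened)
    blocked: List[str] = []
    e = np.zeros(len(lp.rxn_ids))
    for j, rid in enumerate(lp.rxn_ids):
        e[j] = 1.0
        hi = lp.solve(e, "max")
        lo = lp.solve(e, "min")
        e[j] = 0.0
        vmax = -hi.fun if hi.status == 0 else 0.0
        vmin = lo.fun if lo.status == 0 else 0.0
        if abs(vmax) <= _FLUX_TOL and abs(vmin) <= _FLUX_TOL:
            blocked.append(rid)
    return blocked


def check_energy_generating_cycles(
    model: ModelNetwork, detail: Optional[Dict[str, float]] = None
) -> float:
    """Maximal ATP-hydrolysis flux with every boundary exchange closed.

    A positive value exposes a thermodynamically impossible internal loop
    that mints ATP from nothing.  The test is repeated with fuel-free
    currency sinks (PMF, NADH, NADPH) as objectives; per-objective optima are
    written into ``detail`` when a dict is supplied.  Returns the ATP value.
    """
    closed = model.copy()
    for rxn in closed.reactions.values():
        if rxn.category == BOUNDARY_EXCHANGE:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    atp_value = 0.0
    for name, stoich in _CURRENCY_SINKS.items():
        if any(m not in closed.metabolites for m in stoich):
            continue  # currency species absent from this model
        probe = closed.copy()
        sink_id = f"_QC_SINK_{name}"
        probe.add_reaction(
            Reaction(sink_id, dict(stoich), 0.0, DEFAULT_BOUND, category=PSEUDO,
                     subsystem="qc_probe")
        )
        lp = _LP(probe)
        c = np.zeros(len(lp.rxn_ids))
        c[lp.index[sink_id]] = 1.0
        res = lp.solve(c, "max")
        value = float(-res.fun) if res.status == 0 else 0.0
        if detail is not None:
            detail[name] = value
        if name == "ATP_c":
            atp_value = value
    return atp_value


def check_dead_ends(model: ModelNetwork) -> List[str]:
    """Metabolites only ever produced or only ever consumed.

    Reversible reactions count their participants on both sides; boundary
    exchanges count like any other reaction, so an exchanged metabolite is
    never a dead end.
    """
    produced: Dict[str, bool] = {m: False for m in model.metabolites}
    consumed: Dict[str, bool] = {m: False for m in model.metabolites}
    for rxn in model.reactions.values():
        if rxn.category == BOUNDARY_EXCHANGE:
            # structural check: an exchange supports both uptake and export
            forward = backward = True
        else:
            forward = rxn.upper_bound > 0
            backward = rxn.lower_bound < 0
        for met, coeff in rxn.stoichiometry.items():
            if coeff > 0:
                produced[met] |= forward
                consumed[met] |= backward
            elif coeff < 0:
                consumed[met] |= forward
                produced[met] |= backward
    return sorted(
        m for m in model.metabolites if produced[m] != consumed[m]
    )


def check_balance(model: ModelNetwork) -> List[str]:
    issues: List[str] = []
    for rxn in model.reactions.values():
        report = validate_balance(rxn, model.metabolites)
        if not report.balanced:
            issues.append(
                f"{rxn.id}: charge {report.charge_delta:+g}"
                + (
                    f", elements {report.element_deltas}"
                    if report.element_deltas
                    else ""
                )
            )
    return issues


def run_qc(model: ModelNetwork) -> QCReport:
    """Run all checks and aggregate the report."""
    report = QCReport()
    report.blocked_reactions = check_flux_capability(model)
    report.dead_end_metabolites = check_dead_ends(model)
    report.energy_cycle_atp = check_energy_generating_cycles(
        model, report.energy_cycle_detail
    )
    report.balance_issues = check_balance(model)
    return report
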
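"""Flux balance analysis, flux variability analysis and geometric FBA.

All solves go through scipy's HiGHS interface with tight (1e-9) feasibility
tolerances and deterministic settings; there is no randomisation anywhere.
Optimisation is of a single reaction flux subject to steady state
(``S v = 0``) and box bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_core import ModelNetwork, assemble_stoichiometric_matrix

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 1: "iteration_limit", 2: INFEASIBLE, 3: UNBOUNDED}
_SOLVER_OPTIONS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}


class FBAError(ValueError):
    """Misconfigured FBA problem (missing or degenerate objective)."""


class GeometricFBAError(RuntimeError):
    """Geometric FBA failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: "FluxResult"):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class FluxResult:
    """Solver outcome: status, objective value and the full flux vector.

    ``residual`` is the steady-state violation ``max |S v|`` of the returned
    vector (populated for optimal results).
    """

    status: str
    objective_value: Optional[float] = None
    fluxes: Dict[str, float] = field(default_factory=dict)
    residual: Optional[float] = None

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL

    def to_json(self) -> str:
        return json.dumps(
            {
                "status": self.status,
                "objective_value": self.objective_value,
                "fluxes": self.fluxes,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a fraction of the optimal objective."""

    fraction: float
    ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    failures: Dict[str, str] = field(default_factory=dict)

    def brackets(self, fluxes: Dict[str, float], tol: float = 1e-6) -> bool:
        return all(
            lo - tol <= fluxes[rid] <= hi + tol
            for rid, (lo, hi) in self.ranges.items()
        )


@dataclass
class GeometricFBASettings:
    """Convergence controls for geometric FBA.

    ``epsilon`` is the box width below which a flux is considered pinned;
    ``flex_rel`` relaxes the objective constraint to ``(1-flex_rel)*opt``;
    both can be loosened when convergence is difficult.
    """

    epsilon: float = 1e-6
    flex_rel: float = 0.0
    max_iter: int = 60


class _LP:
    """Cached arrays for repeated solves on one model."""

    def __init__(self, model: ModelNetwork):
        sm = assemble_stoichiometric_matrix(model)
        self.S = sm.matrix
        self.rxn_ids: Tuple[str, ...] = sm.reaction_ids
        self.index = {rid: j for j, rid in enumerate(self.rxn_ids)}
        self.lb = np.array([model.reactions[r].lower_bound for r in self.rxn_ids])
        self.ub = np.array([model.reactions[r].upper_bound for r in self.rxn_ids])
        self.b = np.zeros(self.S.shape[0])

    def solve(
        self,
        c: np.ndarray,
        sense: str,
        extra_lb: Optional[np.ndarray] = None,
        extra_ub: Optional[np.ndarray] = None,
        a_ub: Optional[np.ndarray] = None,
        b_ub: Optional[np.ndarray] = None,
    ):
        lb = self.lb if extra_lb is None else np.maximum(self.lb, extra_lb)
        ub = self.ub if extra_ub is None else np.minimum(self.ub, extra_ub)
        n_cols = len(c) if a_ub is None else a_ub.shape[1]
        n_extra = n_cols - len(self.rxn_ids)
        cost = np.concatenate([c, np.zeros(n_cols - len(c))]) if n_cols > len(c) else c
        if sense == "max":
            cost = -cost
        elif sense != "min":
            raise FBAError(f"unknown sense {sense!r}")
        S = self.S
        if n_extra:
            S = np.hstack([S, np.zeros((S.shape[0], n_extra))])
            lb = np.concatenate([lb, np.full(n_extra, -np.inf)])
            ub = np.concatenate([ub, np.full(n_extra, np.inf)])
        res = linprog(
            cost,
            A_ub=a_ub,
            b_ub=b_ub,
            A_eq=S,
            b_eq=np.zeros(S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options=_SOLVER_OPTIONS,
        )
        return res


def _objective_vector(lp: _LP, objective_id: Optional[str], model: ModelNetwork):
    rid = objective_id or model.objective_id
    if rid is None:
        raise FBAError("no objective reaction configured")
    if rid not in lp.index:
        raise FBAError(f"objective reaction {rid!r} not in model")
    c = np.zeros(len(lp.rxn_ids))
    c[lp.index[rid]] = 1.0
    return c, rid


def _result(lp: _LP, res) -> FluxResult:
    status = _STATUS.get(res.status, f"solver_error({res.status})")
    if status != OPTIMAL:
        return FluxResult(status=status)
    v = res.x[: len(lp.rxn_ids)]
    residual = float(np.max(np.abs(lp.S @ v))) if len(v) else 0.0
    fluxes = {rid: float(v[j]) for j, rid in enumerate(lp.rxn_ids)}
    return FluxResult(OPTIMAL, None, fluxes, residual)


def fba(
    model: ModelNetwork,
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> FluxResult:
    """Maximise (or minimise) one reaction flux at steady state.

    Solver failures are reported through ``FluxResult.status``, never
    silently.
    """
    lp = _LP(model)
    c, rid = _objective_vector(lp, objective_id, model)
    res = lp.solve(c, sense)
    out = _result(lp, res)
    if out.ok:
        out.objective_value = out.fluxes[rid]
    return out


def fva(
    model: ModelNetwork,
    objective_id: Optional[str] = None,
    fraction: float = 1.0,
    reactions: Optional[Sequence[str]] = None,
) -> FVAResult:
    """Per-reaction flux ranges subject to near-optimal objective.

    ``fraction`` scales the required objective (1.0 = at the optimum,
    0.98 = within 2% of it).
    """
    if not 0 < fraction <= 1.0:
        raise FBAError("fraction must lie in (0, 1]")
    lp = _LP(model)
    c, rid = _objective_vector(lp, objective_id, model)
    base = lp.solve(c, "max")
    if _STATUS.get(base.status) != OPTIMAL:
        raise FBAError(f"FBA not optimal ({_STATUS.get(base.status)}), no FVA")
    opt = -base.fun
    # keep c.v >= fraction*opt (small slack guards round-off at fraction 1.0)
    a_ub = -c[None, :]
    b_ub = np.array([-(fraction * opt) + 1e-9 * max(1.0, abs(opt))])
    result = FVAResult(fraction=fraction)
    targets = reactions if reactions is not None else lp.rxn_ids
    e = np.zeros(len(lp.rxn_ids))
    for target in targets:
        j = lp.index[target]
        e[j] = 1.0
        lo_res = lp.solve(e, "min", a_ub=a_ub, b_ub=b_ub)
        hi_res = lp.solve(e, "max", a_ub=a_ub, b_ub=b_ub)
        e[j] = 0.0
        if lo_res.status != 0 or hi_res.status != 0:
            result.failures[target] = _STATUS.get(
                lo_res.status if lo_res.status != 0 else hi_res.status, "error"
            )
            continue
        lo, hi = float(lo_res.fun), float(-hi_res.fun)
        if lo > hi:  # numerical round-off on a pinned flux
            lo = hi = 0.5 * (lo + hi)
        result.ranges[target] = (lo, hi)
    return result


def geometric_fba(
    model: ModelNetwork,
    objective_id: Optional[str] = None,
    settings: Optional[GeometricFBASettings] = None,
) -> FluxResult:
    """Deterministic, well-centred optimal flux distribution.

    Iteratively computes the flux-variability box at the optimum and moves to
    the point minimising the maximum deviation from the box midpoints,
    shrinking the box until every width falls below ``epsilon``.  With
    ``flex_rel > 0`` the objective constraint is relaxed to
    ``(1 - flex_rel) * opt``.  Alternate optima (e.g. isoenzyme pairs) are
    resolved to their midpoint, so the result is reproducible and idempotent.
    """
    settings = settings or GeometricFBASettings()
    lp = _LP(model)
    c, rid = _objective_vector(lp, objective_id, model)
    base = lp.solve(c, "max")
    if _STATUS.get(base.status) != OPTIMAL:
        return _result(lp, base)
    opt = float(-base.fun)
    target = (1.0 - settings.flex_rel) * opt
    a_obj = -c[None, :]
    b_obj = np.array([-target + 1e-9 * max(1.0, abs(opt))])

    n = len(lp.rxn_ids)
    box_lo = lp.lb.astype(float).copy()
    box_hi = lp.ub.astype(float).copy()
    spread = fva(model, objective_id=rid, fraction=1.0 - settings.flex_rel)
    for r, (lo, hi) in spread.ranges.items():
        j = lp.index[r]
        box_lo[j], box_hi[j] = lo, hi

    # pad the working box: per-reaction FVA bounds are each exact only to
    # solver tolerance, and stacking ~100 of them unpadded can make the box
    # jointly infeasible
    pad = max(1e-7, 0.01 * settings.epsilon)

    last = None
    for _ in range(settings.max_iter):
        active = np.nonzero(box_hi - box_lo > settings.epsilon)[0]
        mid = 0.5 * (box_lo + box_hi)
        if len(active) == 0:
            res = lp.solve(
                np.zeros(n), "min", extra_lb=box_lo - pad, extra_ub=box_hi + pad,
                a_ub=a_obj, b_ub=b_obj,
            )
            out = _result(lp, res)
            if out.ok:
                out.objective_value = out.fluxes[rid]
                return out
            break
        # minimise t with |v_i - mid_i| <= t over the active set
        k = len(active)
        rows_pos = np.zeros((k, n + 1))
        rows_neg = np.zeros((k, n + 1))
        for row, j in enumerate(active):
            rows_pos[row, j] = 1.0
            rows_pos[row, n] = -1.0
            rows_neg[row, j] = -1.0
            rows_neg[row, n] = -1.0
        a_ub = np.vstack([np.hstack([a_obj, np.zeros((1, 1))]), rows_pos, rows_neg])
        b_ub = np.concatenate([b_obj, mid[active], -mid[active]])
        t_cost = np.zeros(n + 1)
        t_cost[n] = 1.0  # minimise the maximum deviation t
        res = lp.solve(
            t_cost, "min", extra_lb=box_lo - pad, extra_ub=box_hi + pad,
            a_ub=a_ub, b_ub=b_ub,
        )
        if res.status != 0:
            break
        v = res.x[:n]
        t_star = float(res.x[n])
        last = v
        if t_star <= settings.epsilon:
            out = FluxResult(
                OPTIMAL,
                float(v[lp.index[rid]]),
                {r: float(v[lp.index[r]]) for r in lp.rxn_ids},
                float(np.max(np.abs(lp.S @ v))),
            )
            return out
        # shrink: pull the box toward the centre, then re-tighten with FVA
        new_lo = np.maximum(box_lo, mid - t_star)
        new_hi = np.minimum(box_hi, mid + t_star)
        box_lo, box_hi = new_lo, new_hi
        narrow = fva_within(lp, a_obj, b_obj, box_lo - pad, box_hi + pad,
                            [lp.rxn_ids[j] for j in active])
        for r, (lo, hi) in narrow.items():
            j = lp.index[r]
            box_lo[j], box_hi[j] = lo, hi

    iterate = FluxResult(
        "not_converged",
        None if last is None else float(last[lp.index[rid]]),
        {} if last is None else {r: float(last[lp.index[r]]) for r in lp.rxn_ids},
    )
    raise GeometricFBAError(
        f"geometric FBA did not converge in {settings.max_iter} iterations",
        iterate,
    )


def fva_within(
    lp: _LP,
    a_obj: np.ndarray,
    b_obj: np.ndarray,
    box_lo: np.ndarray,
    box_hi: np.ndarray,
    targets: Sequence[str],
) -> Dict[str, Tuple[float, float]]:
    """FVA restricted to a box; internal helper for geometric FBA."""
    out: Dict[str, Tuple[float, float]] = {}
    n = len(lp.rxn_ids)
    e = np.zeros(n)
    for target in targets:
        j = lp.index[target]
        e[j] = 1.0
        lo_res = lp.solve(e, "min", extra_lb=box_lo, extra_ub=box_hi,
                          a_ub=a_obj, b_ub=b_obj)
        hi_res = lp.solve(e, "max", extra_lb=box_lo, extra_ub=box_hi,
                          a_ub=a_obj, b_ub=b_obj)
        e[j] = 0.0
        if lo_res.status == 0 and hi_res.status == 0:
            lo, hi = float(lo_res.fun), float(-hi_res.fun)
            if lo > hi:
                lo = hi = 0.5 * (lo + hi)
            out[target] = (lo, hi)
    return out


def _resolve_targets(model: ModelNetwork, targets: Sequence[str]) -> List[str]:
    rxn_ids: List[str] = []
    for target in targets:
        if target in model.reactions:
            rxn_ids.append(target)
            continue
        hits = model.reactions_for_gene(target)
        if not hits:
            raise FBAError(
                f"unknown knockout target {target!r}; known genes: "
                f"{', '.join(model.known_genes())}"
            )
        rxn_ids.extend(r.id for r in hits)
    return rxn_ids


def knockout_model(model: ModelNetwork, targets: Sequence[str]) -> ModelNetwork:
    """Copy of the model with all reactions of the targets closed to [0, 0].

    Targets may be reaction ids or gene symbols; protein complexes are single
    reactions, so one subunit gene silences the whole step (and a gene
    encoding two compartmental isoforms silences both).
    """
    ko = model.copy()
    for rid in _resolve_targets(model, targets):
        ko.reactions[rid].lower_bound = 0.0
        ko.reactions[rid].upper_bound = 0.0
    return ko


def knockout(
    model: ModelNetwork,
    targets: Sequence[str],
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> FluxResult:
    """FBA after silencing every reaction mapped to the target genes/reactions."""
    return fba(knockout_model(model, targets), objective_id, sense)


def scan(
    model: ModelNetwork,
    reaction_id: str,
    bound_side: str,
    values: Sequence[float],
    objective_id: Optional[str] = None,
    method: str = "fba",
    settings: Optional[GeometricFBASettings] = None,
) -> List[FluxResult]:
    """One FBA (or geometric FBA) per bound value, in input order.

    Infeasible points are reported in place and the scan continues.
    """
    if bound_side not in ("lower", "upper"):
        raise FBAError("bound_side must be 'lower' or 'upper'")
    if reaction_id not in model.reactions:
        raise FBAError(f"unknown reaction {reaction_id!r}")
    results: List[FluxResult] = []
    for value in values:
        m = model.copy()
        rxn = m.reactions[reaction_id]
        if bound_side == "lower":
            rxn.lower_bound = value
            rxn.upper_bound = max(rxn.upper_bound, value)
        else:
            rxn.upper_bound = value
            rxn.lower_bound = min(rxn.lower_bound, value)
        if method == "geometric":
            try:
                results.append(geometric_fba(m, objective_id, settings))
            except GeometricFBAError as err:
                results.append(err.last_iterate)
        else:
            results.append(fba(m, objective_id))
    return results


def results_table(
    model: ModelNetwork,
    flux: FluxResult,
    variability: Optional[FVAResult] = None,
) -> pd.DataFrame:
    """Reaction/flux table (with FVA ranges when given), TSV/JSON friendly."""
    rows = []
    for rid in model.reactions:
        row = {"reaction": rid, "flux": flux.fluxes.get(rid)}
        if variability is not None and rid in variability.ranges:
            row["min"], row["max"] = variability.ranges[rid]
        rows.append(row)
    return pd.DataFrame(rows)
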
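"""Linear-programming engine: FBA, FVA, weighted flux minimization and
metabolic-task feasibility.

All solves are linear programs over the steady-state constraint
``S v = 0`` with box bounds on fluxes, dispatched to the HiGHS solver
through :func:`scipy.optimize.linprog`.  Objective values are the
contract of this module; flux vectors are one optimal vertex and may
differ between runs under degeneracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .network import (
    EXCHANGE,
    IrreversibleNetwork,
    MetabolicNetwork,
    classify_reaction_kind,
    make_irreversible,
)

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

FEASIBILITY_TOL = 1e-9
ASSERT_TOL = 1e-6


class EngineError(RuntimeError):
    pass


@dataclass
class MediaConstraints:
    """Bounds overriding model defaults for listed exchange reactions."""

    bounds: dict[str, tuple[float, float]]
    label: str = "custom"

    def validate(self, network: MetabolicNetwork) -> None:
        kinds = classify_reaction_kind(network)
        bad = [
            rid for rid in self.bounds
            if rid not in network.reactions or kinds[rid] != EXCHANGE
        ]
        if bad:
            raise EngineError(f"media lists non-exchange reactions: {bad}")
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise EngineError(f"media bound lb > ub for {rid}")


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


@dataclass
class TaskDefinition:
    """One metabolic-task feasibility test.

    ``inputs``/``outputs`` list ``(metabolite_key, lb, ub)`` with bounds
    as non-negative uptake/secretion rates; ``should_fail`` marks tasks
    asserting a known incapability (the task passes when infeasible).
    """

    id: str
    description: str = ""
    inputs: list[tuple[str, float, float]] = field(default_factory=list)
    outputs: list[tuple[str, float, float]] = field(default_factory=list)
    should_fail: bool = False


@dataclass(frozen=True)
class TaskResult:
    task_id: str
    feasible: bool
    should_fail: bool
    error: str | None = None

    @property
    def passed(self) -> bool:
        if self.error is not None:
            return False
        return (not self.feasible) if self.should_fail else self.feasible


@dataclass
class FBAResult:
    status: str
    objective_value: float | None
    fluxes: dict[str, float] | None


def _network_arrays(network: MetabolicNetwork,
                    media: MediaConstraints | None):
    S = network.stoichiometric_matrix()
    lb, ub = network.bounds()
    if media is not None:
        media.validate(network)
        ridx = network.reaction_index
        for rid, (lo, hi) in media.bounds.items():
            j = ridx[rid]
            lb[j], ub[j] = lo, hi
    return S, lb, ub


def _solve(c: np.ndarray, S: sparse.spmatrix, lb: np.ndarray, ub: np.ndarray,
           A_ub: sparse.spmatrix | None = None,
           b_ub: np.ndarray | None = None):
    res = linprog(
        c,
        A_ub=A_ub, b_ub=b_ub,
        A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if res.status == 0:
        return OPTIMAL, res
    if res.status == 2:
        return INFEASIBLE, res
    if res.status == 3:
        return UNBOUNDED, res
    raise EngineError(f"LP solver failure: {res.message}")


def fba(network: MetabolicNetwork, objective_reaction: str | None = None,
        media: MediaConstraints | None = None,
        maximize: bool = True) -> FBAResult:
    """Flux balance analysis: optimize one reaction flux subject to
    ``S v = 0`` and bounds.  Infeasible and unbounded models are
    reported distinctly via ``status``."""
    objective_reaction = objective_reaction or network.objective_id
    if objective_reaction not in network.reactions:
        raise EngineError(f"unknown objective reaction {objective_reaction!r}")
    S, lb, ub = _network_arrays(network, media)
    ridx = network.reaction_index
    c = np.zeros(len(ridx))
    c[ridx[objective_reaction]] = -1.0 if maximize else 1.0
    status, res = _solve(c, S, lb, ub)
    if status != OPTIMAL:
        return FBAResult(status, None, None)
    value = float(res.x[ridx[objective_reaction]])
    fluxes = {rid: float(res.x[j]) for rid, j in ridx.items()}
    return FBAResult(OPTIMAL, value, fluxes)


def doubling_time(growth_rate: float) -> float:
    """Doubling time in hours, ln(2)/mu, for a growth rate mu in 1/h."""
    if growth_rate <= 0:
        raise ValueError(f"growth rate must be positive, got {growth_rate}")
    return math.log(2.0) / growth_rate


def fva(network: MetabolicNetwork,
        reaction_ids: Sequence[str] | None = None,
        media: MediaConstraints | None = None,
        objective_fraction: float = 0.0) -> dict[str, FluxRange]:
    """Flux variability analysis: per-reaction min/max feasible flux.

    With ``objective_fraction`` > 0 the model objective is optimized
    first and its flux floored at that fraction of the optimum.  Blocked
    reactions report ``(0, 0)``.
    """
    S, lb, ub = _network_arrays(network, media)
    ridx = network.reaction_index
    if reaction_ids is None:
        reaction_ids = list(network.reactions)
    if objective_fraction > 0.0:
        if network.objective_id is None:
            raise EngineError("objective_fraction set but no model objective")
        base = fba(network, media=media)
        if base.status != OPTIMAL:
            raise EngineError(f"base model {base.status} during FVA")
        j = ridx[network.objective_id]
        lb = lb.copy()
        lb[j] = max(lb[j], objective_fraction * base.objective_value)
    else:
        # fail fast on an infeasible base model
        status, _ = _solve(np.zeros(len(ridx)), S, lb, ub)
        if status != OPTIMAL:
            raise EngineError(f"base model {status} during FVA")
    out: dict[str, FluxRange] = {}
    for rid in reaction_ids:
        j = ridx[rid]
        c = np.zeros(len(ridx))
        c[j] = 1.0
        status, res_min = _solve(c, S, lb, ub)
        vmin = float(res_min.x[j]) if status == OPTIMAL else -np.inf
        c[j] = -1.0
        status, res_max = _solve(c, S, lb, ub)
        vmax = float(res_max.x[j]) if status == OPTIMAL else np.inf
        if abs(vmin) < ASSERT_TOL:
            vmin = 0.0
        if abs(vmax) < ASSERT_TOL:
            vmax = 0.0
        out[rid] = FluxRange(rid, vmin, vmax)
    return out


@dataclass
class WeightedFluxResult:
    status: str
    demand: float | None
    fluxes: np.ndarray | None


def min_weighted_flux(irrev: IrreversibleNetwork,
                      weights: np.ndarray,
                      forced_column: int | None = None,
                      min_rate: float = 0.0,
                      extra_bounds: dict[int, tuple[float, float]] | None = None,
                      ) -> WeightedFluxResult:
    """Minimize the total weighted flux of an irreversible network.

    Solves ``min w.v  s.t.  S v = 0, v_lb <= v <= v_ub`` after raising
    the lower bound of ``forced_column`` to ``min_rate`` (forcing, e.g.,
    secretion of one metabolite).  The optimal objective (the global
    network demand) is the contract; the flux vector is one optimum.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (irrev.n_columns,):
        raise ValueError("weights must have one entry per irreversible column")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    lb = irrev.lb.copy()
    ub = irrev.ub.copy()
    if forced_column is not None:
        lb[forced_column] = max(lb[forced_column], min_rate)
        if lb[forced_column] > ub[forced_column]:
            return WeightedFluxResult(INFEASIBLE, None, None)
    if extra_bounds:
        for j, (lo, hi) in extra_bounds.items():
            lb[j], ub[j] = lo, hi
    status, res = _solve(weights, irrev.S, lb, ub)
    if status != OPTIMAL:
        return WeightedFluxResult(status, None, None)
    return WeightedFluxResult(OPTIMAL, float(res.fun), res.x)


# --------------------------------------------------------------------
# metabolic tasks

def check_task(network: MetabolicNetwork, task: TaskDefinition) -> TaskResult:
    """Feasibility of one metabolic task.

    All model exchange reactions are closed; each task input opens a
    boundary inflow for its metabolite (uptake between lb and ub) and
    each output a boundary outflow (secretion between lb and ub).
    Unlisted metabolites get no boundary flux at all.  ``passed``
    follows ``should_fail``: a should-fail task passes when infeasible.
    """
    kinds = classify_reaction_kind(network)
    S = network.stoichiometric_matrix().tolil()
    lb, ub = network.bounds()
    for rid, j in network.reaction_index.items():
        if kinds[rid] == EXCHANGE:
            lb[j] = 0.0
            ub[j] = 0.0
    midx = network.metabolite_index
    extra_cols = []
    extra_lb, extra_ub = [], []
    for met, lo, hi in task.inputs:
        if met not in midx:
            return TaskResult(task.id, False, task.should_fail,
                              error=f"unknown metabolite {met}")
        extra_cols.append((midx[met], +1.0))  # inflow produces the metabolite
        extra_lb.append(lo)
        extra_ub.append(hi)
    for met, lo, hi in task.outputs:
        if met not in midx:
            return TaskResult(task.id, False, task.should_fail,
                              error=f"unknown metabolite {met}")
        extra_cols.append((midx[met], -1.0))  # outflow consumes it
        extra_lb.append(lo)
        extra_ub.append(hi)
    n_extra = len(extra_cols)
    if n_extra:
        cols = sparse.lil_matrix((S.shape[0], n_extra))
        for k, (row, sign) in enumerate(extra_cols):
            cols[row, k] = sign
        S_full = sparse.hstack([S.tocsr(), cols.tocsr()], format="csr")
        lb = np.concatenate([lb, extra_lb])
        ub = np.concatenate([ub, extra_ub])
    else:
        S_full = S.tocsr()
    status, _ = _solve(np.zeros(S_full.shape[1]), S_full, lb, ub)
    return TaskResult(task.id, status == OPTIMAL, task.should_fail)


@dataclass
class TaskSummary:
    n_tasks: int
    n_passed: int
    n_failed: int
    failures: list[TaskResult]
    results: list[TaskResult]


def run_tasks(network: MetabolicNetwork,
              tasks: Iterable[TaskDefinition]) -> TaskSummary:
    results = [check_task(network, t) for t in tasks]
    failures = [r for r in results if not r.passed]
    return TaskSummary(
        n_tasks=len(results),
        n_passed=len(results) - len(failures),
        n_failed=len(failures),
        failures=failures,
        results=results,
    )


# --------------------------------------------------------------------
# media builders

def open_exchange_media(network: MetabolicNetwork,
                        ion_ids: Sequence[str]) -> MediaConstraints:
    """Open-exchange condition: unconstrained uptake for the listed
    inorganic-ion exchanges, uptake limited to 1 arbitrary unit for all
    other exchange reactions, secretion unconstrained everywhere.

    ``ion_ids`` may name exchange reactions or exchanged metabolite keys.
    """
    exchanges = network.exchange_reactions()
    met_to_ex = {met: rid for rid, met in exchanges.items()}
    ion_exchanges = set()
    for ion in ion_ids:
        if ion in exchanges:
            ion_exchanges.add(ion)
        elif ion in met_to_ex:
            ion_exchanges.add(met_to_ex[ion])
        else:
            raise EngineError(f"ion {ion!r} is not exchangeable in the network")
    bounds = {}
    for rid in exchanges:
        lb = -np.inf if rid in ion_exchanges else -1.0
        bounds[rid] = (lb, np.inf)
    return MediaConstraints(bounds=bounds, label="open_exchange")
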
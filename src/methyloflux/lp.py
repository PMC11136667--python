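"""Flux balance analysis and parsimonious FBA as linear programs.

FBA maximizes (or minimizes) the flux of an objective reaction subject to
steady state, S·v = 0, and flux bounds lb ≤ v ≤ ub. Parsimonious FBA (pFBA)
is the two-stage variant: the optimal objective flux is fixed, then the
total absolute flux Σ|v| is minimized via the standard non-negative
splitting v = v⁺ − v⁻. The second stage selects enzymatically efficient
distributions and, in particular, drives stoichiometrically balanced futile
cycles to zero.

The linear programs are assembled here and handed to a small solver
contract (:class:`LPBackend`); the default backend is SciPy's HiGHS
interface. Analyses built on top are single/multiple-reaction knockouts,
fixed-flux scans with a linear fit (used for the 6-phosphogluconate
dehydrogenase sensitivity analysis), metabolite consumption fractions, and
flux-variability bounds at the pFBA optimum (used to certify zero-flux
claims independently of solver vertex choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxSolution",
    "ScanResult",
    "KnockoutResult",
    "LPBackend",
    "ScipyHighsBackend",
    "solve_fba",
    "solve_pfba",
    "knockout_growth",
    "flux_scan",
    "consumption_fraction",
    "flux_range_at_pfba",
    "steady_state_residual",
    "FEASIBILITY_TOL",
    "OPTIMALITY_TOL",
    "ZERO_FLUX_TOL",
]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-6
ZERO_FLUX_TOL = 1e-6


class LPBackend(Protocol):
    """Minimal LP contract: minimize c·x s.t. A_eq x = b_eq, A_ub x ≤ b_ub."""

    def solve(self, c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
        """Return (status, x, objective) with status optimal|infeasible|unbounded."""


class ScipyHighsBackend:
    """scipy.optimize.linprog with the HiGHS dual simplex."""

    _STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}

    def __init__(self, feasibility_tol: float = 1e-10):
        self.options = {
            "primal_feasibility_tolerance": feasibility_tol,
            "dual_feasibility_tolerance": 1e-9,
        }

    def solve(self, c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
        res = linprog(
            c,
            A_eq=A_eq,
            b_eq=b_eq,
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=bounds,
            method="highs-ds",
            options=self.options,
        )
        status = self._STATUS.get(res.status, "numerical")
        return status, res.x, res.fun


_DEFAULT_BACKEND = ScipyHighsBackend()


@dataclass
class FluxSolution:
    """Result of one FBA/pFBA solve."""

    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)
    total_abs_flux: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ScanResult:
    """Objective response to fixing one reaction's flux on a grid."""

    reaction_id: str
    grid: list[float]
    growth: list[float]  # NaN where infeasible
    fit_slope: float
    fit_intercept: float
    fit_r2: float

    @property
    def feasible_mask(self) -> list[bool]:
        return [not np.isnan(g) for g in self.growth]


@dataclass
class KnockoutResult:
    wild_type_growth: float
    knockout_growth: float
    ratio: float
    infeasible: bool = False


def _assemble(model: MetabolicModel):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_ids
    ]
    return S, met_ids, rxn_ids, bounds


def solve_fba(
    model: MetabolicModel,
    objective: str | None = None,
    sense: str | None = None,
    backend: LPBackend = _DEFAULT_BACKEND,
) -> FluxSolution:
    """Maximize (or minimize) the objective reaction flux at steady state."""
    objective = objective or model.objective_reaction
    sense = sense or model.objective_sense
    if objective is None or objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    S, _met_ids, rxn_ids, bounds = _assemble(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective)] = -1.0 if sense == "maximize" else 1.0
    status, x, fun = backend.solve(c, S, np.zeros(S.shape[0]), bounds)
    if status != "optimal":
        return FluxSolution(status=status)
    fluxes = dict(zip(rxn_ids, x))
    return FluxSolution(
        status="optimal",
        objective_value=float(fluxes[objective]),
        fluxes=fluxes,
        total_abs_flux=float(np.abs(x).sum()),
    )


def _split_bounds(bounds: Sequence[tuple[float, float]]):
    """Bounds for the v = v⁺ − v⁻ splitting (v⁺, v⁻ ≥ 0)."""
    pos, neg = [], []
    for lb, ub in bounds:
        if lb >= 0:
            pos.append((lb, ub))
            neg.append((0.0, 0.0))
        elif ub <= 0:
            pos.append((0.0, 0.0))
            neg.append((-ub, -lb))
        else:
            pos.append((0.0, ub))
            neg.append((0.0, -lb))
    return pos + neg


def solve_pfba(
    model: MetabolicModel,
    optimality_fraction: float = 1.0,
    objective: str | None = None,
    backend: LPBackend = _DEFAULT_BACKEND,
) -> FluxSolution:
    """Two-stage parsimonious FBA.

    Stage one is :func:`solve_fba`; stage two constrains the objective flux
    to at least ``optimality_fraction`` times the optimum and minimizes
    Σ|v|. The reported ``objective_value`` is the stage-two flux of the
    objective reaction (equal to the FBA optimum for fraction 1).
    """
    objective = objective or model.objective_reaction
    fba = solve_fba(model, objective=objective, backend=backend)
    if not fba.optimal:
        return fba
    opt = fba.objective_value
    S, _met_ids, rxn_ids, bounds = _assemble(model)
    n = len(rxn_ids)
    j = rxn_ids.index(objective)
    # fix the objective (small slack keeps the constraint numerically feasible)
    slack = 1e-9 * max(1.0, abs(opt))
    lb, ub = bounds[j]
    if model.objective_sense == "maximize":
        bounds = list(bounds)
        bounds[j] = (max(lb, optimality_fraction * opt - slack), ub)
    else:
        bounds = list(bounds)
        bounds[j] = (lb, min(ub, optimality_fraction * opt + slack))
    S_split = np.hstack([S, -S])
    c = np.ones(2 * n)
    status, x, _fun = backend.solve(
        c, S_split, np.zeros(S.shape[0]), _split_bounds(bounds)
    )
    if status != "optimal":
        return FluxSolution(status=status)
    v = x[:n] - x[n:]
    fluxes = dict(zip(rxn_ids, v))
    return FluxSolution(
        status="optimal",
        objective_value=float(fluxes[objective]),
        fluxes=fluxes,
        total_abs_flux=float(x.sum()),
    )


def knockout_growth(
    model: MetabolicModel,
    reaction_ids: Iterable[str],
    backend: LPBackend = _DEFAULT_BACKEND,
) -> KnockoutResult:
    """Growth with and without a set of reactions, and their ratio.

    A knockout that leaves no feasible steady state is scored as zero
    growth (lethal) and flagged.
    """
    reaction_ids = list(reaction_ids)
    for rid in reaction_ids:
        if rid not in model.reactions:
            raise KeyError(f"knockout target {rid!r} not in model")
    wt = solve_fba(model, backend=backend)
    if not wt.optimal:
        raise RuntimeError(f"wild-type model does not solve: {wt.status}")
    ko_model = model.copy()
    for rid in reaction_ids:
        ko_model.reactions[rid].lower_bound = 0.0
        ko_model.reactions[rid].upper_bound = 0.0
    ko = solve_fba(ko_model, backend=backend)
    if not ko.optimal:
        return KnockoutResult(wt.objective_value, 0.0, 0.0, infeasible=True)
    ratio = ko.objective_value / wt.objective_value
    return KnockoutResult(wt.objective_value, ko.objective_value, ratio)


def flux_scan(
    model: MetabolicModel,
    reaction_id: str,
    grid: Sequence[float],
    backend: LPBackend = _DEFAULT_BACKEND,
) -> ScanResult:
    """Fix one reaction's flux at each grid value and re-optimize growth.

    A least-squares line is fitted over the feasible grid points; r² of the
    fit quantifies how linear the growth response is. Infeasible points are
    recorded as NaN and excluded from the fit.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty scan grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("scan grid must be strictly increasing")
    if reaction_id not in model.reactions:
        raise KeyError(f"scan target {reaction_id!r} not in model")
    growth: list[float] = []
    for g in grid:
        m = model.copy()
        m.reactions[reaction_id].lower_bound = g
        m.reactions[reaction_id].upper_bound = g
        sol = solve_fba(m, backend=backend)
        growth.append(sol.objective_value if sol.optimal else np.nan)
    xs = np.array([g for g, y in zip(grid, growth) if not np.isnan(y)])
    ys = np.array([y for y in growth if not np.isnan(y)])
    if xs.size == 0:
        raise ValueError(f"no feasible point in scan of {reaction_id!r}")
    if xs.size == 1:
        slope, intercept, r2 = 0.0, float(ys[0]), 1.0
    else:
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = slope * xs + intercept
        ss_res = float(((ys - pred) ** 2).sum())
        ss_tot = float(((ys - ys.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ScanResult(reaction_id, grid, growth, float(slope), float(intercept), float(r2))


def consumption_fraction(
    solution: FluxSolution,
    model: MetabolicModel,
    metabolite_id: str,
    reaction_id: str,
) -> float:
    """Fraction of a metabolite's total consumption carried by one reaction.

    A reaction consumes the metabolite when coefficient × flux < 0. The
    denominator is the summed consumption over all reactions in the same
    solution; at steady state it equals total production.
    """
    if not solution.optimal:
        raise ValueError("consumption fraction requires an optimal solution")
    if metabolite_id not in model.metabolites:
        raise KeyError(f"metabolite {metabolite_id!r} not in model")
    if reaction_id not in model.reactions:
        raise KeyError(f"reaction {reaction_id!r} not in model")
    total = 0.0
    target = 0.0
    for rxn in model.reactions.values():
        coef = rxn.stoichiometry.get(metabolite_id)
        if coef is None:
            continue
        turnover = coef * solution.fluxes[rxn.id]
        if turnover < 0:
            total += -turnover
            if rxn.id == reaction_id:
                target = -turnover
    if total < FEASIBILITY_TOL:
        raise ValueError(
            f"metabolite {metabolite_id!r} is not consumed at this optimum"
        )
    return target / total


def flux_range_at_pfba(
    model: MetabolicModel,
    reaction_id: str,
    optimality_fraction: float = 1.0,
    backend: LPBackend = _DEFAULT_BACKEND,
) -> tuple[float, float]:
    """Min/max flux of one reaction over all pFBA-optimal distributions.

    Both the objective flux and the minimal total absolute flux are held
    fixed (to small numerical slack), then the target flux is minimized and
    maximized. A (0, 0) interval certifies that the reaction cannot carry
    flux in any alternate pFBA optimum.
    """
    if reaction_id not in model.reactions:
        raise KeyError(f"reaction {reaction_id!r} not in model")
    pfba = solve_pfba(model, optimality_fraction, backend=backend)
    if not pfba.optimal:
        raise RuntimeError(f"pFBA failed: {pfba.status}")
    opt = pfba.objective_value
    total = pfba.total_abs_flux
    S, _met_ids, rxn_ids, bounds = _assemble(model)
    n = len(rxn_ids)
    j = rxn_ids.index(model.objective_reaction)
    slack = 1e-9 * max(1.0, abs(opt))
    bounds = list(bounds)
    lb, ub = bounds[j]
    if model.objective_sense == "maximize":
        bounds[j] = (max(lb, optimality_fraction * opt - slack), ub)
    else:
        bounds[j] = (lb, min(ub, optimality_fraction * opt + slack))
    S_split = np.hstack([S, -S])
    # Σ(v⁺+v⁻) ≤ minimal total (plus slack) pins the parsimony constraint
    A_ub = np.ones((1, 2 * n))
    b_ub = np.array([total + 1e-8 * max(1.0, total)])
    k = rxn_ids.index(reaction_id)
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(2 * n)
        c[k] = sign
        c[n + k] = -sign
        status, x, _ = backend.solve(
            c, S_split, np.zeros(S.shape[0]), _split_bounds(bounds), A_ub, b_ub
        )
        if status != "optimal":
            raise RuntimeError(f"variability solve failed: {status}")
        out.append(float(x[k] - x[n + k]))
    return out[0], out[1]


def steady_state_residual(model: MetabolicModel, solution: FluxSolution) -> float:
    """max |S·v| over metabolites — the steady-state defect of a solution."""
    S, _met_ids, rxn_ids, _bounds = _assemble(model)
    v = np.array([solution.fluxes[r] for r in rxn_ids])
    return float(np.abs(S @ v).max())
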
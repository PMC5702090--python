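"""Linear/quadratic programming layer.

Flux balance analysis (FBA), the unique minimum-L2-norm reference flux used
to anchor MOMA, the two-step estimation of photoautotrophic input fluxes
(carbon fixation, then photon use) from measured output fluxes, and the
growth-vs-production solution space (production envelope).

LPs are solved with scipy's HiGHS interface; the strictly convex QPs are
solved with OSQP and then polished by an exact KKT refinement on the
detected active set, which makes the results deterministic and insensitive
to reaction ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import (
    FLUX_ZERO_CLIP,
    FluxState,
    MetabolicModel,
    flux_state_from_vector,
    stoichiometric_matrix,
)

#: LP/QP feasibility and optimality tolerances.
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9


class InfeasibleProblemError(RuntimeError):
    """Raised where infeasibility is a caller error (not a screen outcome)."""


class UnknownReactionError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Constraint handling
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Extra constraints layered over a model's structural bounds.

    ``fixed_fluxes`` pins reactions to exact values (e.g. the carbon-fixation
    flux held constant across all deletion simulations); ``extra_bounds``
    intersects additional (lb, ub) intervals (e.g. a photon-uptake cap);
    ``production_lower_bound`` enforces a minimum flux through a product
    exchange, mirroring the use of the measured 1,3-PDO production rate as a
    screen-wide lower limit.
    """

    fixed_fluxes: dict = field(default_factory=dict)
    extra_bounds: dict = field(default_factory=dict)
    production_lower_bound: Optional[tuple] = None

    def bounds_arrays(self, model: MetabolicModel) -> tuple:
        """Effective (lb, ub) arrays over model.reactions; validates ids and
        that fixed values sit inside the structural bounds."""
        n = len(model.reactions)
        lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        for rid, (blo, bhi) in self.extra_bounds.items():
            j = _rxn_index(model, rid)
            if blo > bhi:
                raise ValueError(f"extra bound for {rid}: lb {blo} > ub {bhi}")
            lb[j] = max(lb[j], blo)
            ub[j] = min(ub[j], bhi)
        if self.production_lower_bound is not None:
            rid, val = self.production_lower_bound
            j = _rxn_index(model, rid)
            lb[j] = max(lb[j], val)
        for rid, val in self.fixed_fluxes.items():
            j = _rxn_index(model, rid)
            r = model.reactions[j]
            if not (r.lower_bound - FEASIBILITY_TOL <= val
                    <= r.upper_bound + FEASIBILITY_TOL):
                raise ValueError(
                    f"fixed flux {val} for {rid} outside structural bounds "
                    f"[{r.lower_bound}, {r.upper_bound}]"
                )
            lb[j] = val
            ub[j] = val
        bad = np.where(lb > ub + FEASIBILITY_TOL)[0]
        if bad.size:
            ids = [model.reactions[j].id for j in bad]
            raise InfeasibleProblemError(
                f"conflicting bounds (lb > ub) on reactions {ids}"
            )
        # collapse tiny inversions from combining constraints
        ub = np.maximum(ub, lb)
        assert lb.shape == (n,)
        return lb, ub

    def with_fixed(self, **fluxes) -> "ConstraintSet":
        merged = dict(self.fixed_fluxes)
        merged.update(fluxes)
        return ConstraintSet(
            fixed_fluxes=merged,
            extra_bounds=dict(self.extra_bounds),
            production_lower_bound=self.production_lower_bound,
        )


def _rxn_index(model: MetabolicModel, rid: str) -> int:
    try:
        return model.reaction_index(rid)
    except KeyError:
        raise UnknownReactionError(f"unknown reaction id {rid!r}") from None


# ---------------------------------------------------------------------------
# FBA (LP)
# ---------------------------------------------------------------------------

@dataclass
class FbaSolution:
    state: Optional[FluxState]
    objective_value: Optional[float]
    status: str  # optimal | infeasible | unbounded


def _solve_lp(model, c, lb, ub):
    S = stoichiometric_matrix(model)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": OPTIMALITY_TOL},
    )
    return res


def solve_fba(model: MetabolicModel, objective_reaction: str,
              sense: str = "max",
              constraints: Optional[ConstraintSet] = None) -> FbaSolution:
    """Maximize/minimize one reaction flux subject to S.v = 0 and bounds.

    Infeasibility and unboundedness are reported in ``status``, never as
    silent zeros.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    constraints = constraints or ConstraintSet()
    j = _rxn_index(model, objective_reaction)
    lb, ub = constraints.bounds_arrays(model)
    c = np.zeros(len(model.reactions))
    c[j] = -1.0 if sense == "max" else 1.0
    res = _solve_lp(model, c, lb, ub)
    if res.status == 2:
        return FbaSolution(None, None, "infeasible")
    if res.status == 3:
        return FbaSolution(None, None, "unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    v = res.x
    obj = float(v[j])
    state = flux_state_from_vector(model, v, residual_norm=_residual(model, v))
    return FbaSolution(state, obj, "optimal")


def _residual(model, v):
    S = stoichiometric_matrix(model)
    r = S.dot(v)
    return float(np.max(np.abs(r))) if r.size else 0.0


# ---------------------------------------------------------------------------
# Strictly convex QP: min ||v - w||^2 s.t. S v = 0, lb <= v <= ub
# ---------------------------------------------------------------------------

def solve_box_eq_qp(model: MetabolicModel, w: np.ndarray,
                    lb: np.ndarray, ub: np.ndarray) -> Optional[np.ndarray]:
    """Project ``w`` onto {v : S v = 0, lb <= v <= ub}.

    Returns None if the polytope is empty.  OSQP provides the solution,
    which is then refined by solving the KKT system of the detected active
    set exactly; the refined point is kept only if it is feasible and not
    worse, so precision never degrades.
    """
    import osqp

    n = len(w)
    S = stoichiometric_matrix(model).tocsc()
    m = S.shape[0]
    # feasibility gate via LP so infeasibility is detected crisply
    res = _solve_lp(model, np.zeros(n), lb, ub)
    if res.status == 2:
        return None
    if res.status != 0:
        raise RuntimeError(f"feasibility LP failure: {res.message}")

    P = sp.identity(n, format="csc")
    q = -np.asarray(w, dtype=float)
    A = sp.vstack([S, sp.identity(n, format="csc")], format="csc")
    l = np.concatenate([np.zeros(m), lb])
    u = np.concatenate([np.zeros(m), ub])
    prob = osqp.OSQP()
    prob.setup(P=P, q=q, A=A, l=l, u=u,
               eps_abs=1e-10, eps_rel=1e-10, max_iter=200000,
               polishing=True, verbose=False)
    sol = prob.solve(raise_error=False)
    status = sol.info.status.lower()
    if "solved" not in status:
        # OSQP struggled; fall back to the LP point refined toward w
        v0 = res.x
    else:
        v0 = np.asarray(sol.x, dtype=float)
    v0 = np.clip(v0, lb, ub)
    v = _refine_qp(S, w, lb, ub, v0)
    return v


def _qp_obj(v, w):
    d = v - w
    return float(d @ d)


def _refine_qp(S, w, lb, ub, v0, active_tol=1e-7):
    """Exact equality-constrained solve on the active set detected at v0."""
    n = len(w)
    at_lb = np.abs(v0 - lb) <= active_tol
    at_ub = np.abs(v0 - ub) <= active_tol
    fixed = at_lb | at_ub
    vfix = np.where(at_ub & ~at_lb, ub, lb)
    free = ~fixed
    v = v0.copy()
    if free.any():
        Sf = S[:, free].toarray()
        b = -S[:, fixed].dot(vfix[fixed]) if fixed.any() else np.zeros(S.shape[0])
        wf = w[free]
        # projection of wf onto {Sf x = b}: x = wf + Sf^T y, (Sf Sf^T) y = b - Sf wf
        y, *_ = np.linalg.lstsq(Sf @ Sf.T, b - Sf @ wf, rcond=None)
        xf = wf + Sf.T @ y
        cand = np.empty(n)
        cand[fixed] = vfix[fixed]
        cand[free] = xf
    else:
        cand = np.where(at_ub, ub, lb)
    feas = (
        np.all(cand >= lb - FEASIBILITY_TOL)
        and np.all(cand <= ub + FEASIBILITY_TOL)
        and (np.max(np.abs(S.dot(cand))) if S.shape[0] else 0.0) <= 1e-8
    )
    if feas and _qp_obj(cand, w) <= _qp_obj(v, w) + 1e-9:
        v = np.clip(cand, lb, ub)
    return v


# ---------------------------------------------------------------------------
# Minimal-norm reference flux
# ---------------------------------------------------------------------------

def minimal_norm_reference(model: MetabolicModel,
                           constraints: Optional[ConstraintSet] = None,
                           objective_reaction: Optional[str] = None) -> FluxState:
    """Unique minimum-L2-norm flux among constraint-satisfying states that
    attain the constrained FBA optimum of ``objective_reaction``.

    FBA optima are typically degenerate; MOMA needs a unique, reproducible
    wild-type reference, which the two-stage scheme (fix objective at its
    optimum, then minimize ||v||^2) provides.  When the constraint set
    already pins the objective (measured-rate anchoring, the default in the
    screen pipeline), stage 1 is a no-op.
    """
    constraints = constraints or ConstraintSet()
    objective_reaction = objective_reaction or model.biomass_reaction_id
    fba = solve_fba(model, objective_reaction, "max", constraints)
    if fba.status != "optimal":
        raise InfeasibleProblemError(
            f"reference constraints are {fba.status}; check fixed fluxes and "
            f"bounds for mutually exclusive requirements"
        )
    staged = constraints.with_fixed(**{objective_reaction: fba.objective_value})
    lb, ub = staged.bounds_arrays(model)
    v = solve_box_eq_qp(model, np.zeros(len(model.reactions)), lb, ub)
    if v is None:  # pragma: no cover - stage 1 proved feasibility
        raise InfeasibleProblemError("stage-2 QP infeasible")
    return flux_state_from_vector(model, v, residual_norm=_residual(model, v))


# ---------------------------------------------------------------------------
# Two-step input-flux estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentalRates:
    """Measured output fluxes: growth 1/h, products mmol/(g DCW)/h."""

    mu: float
    q_pdo: float = 0.0
    q_glycerol: float = 0.0

    def __post_init__(self):
        for name in ("mu", "q_pdo", "q_glycerol"):
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val}")


@dataclass(frozen=True)
class InputFluxes:
    """Uptake magnitudes (positive) of carbon fixation and photon use."""

    carbon_fixation: float
    photon: float


def _anchor_constraints(model, rates, base):
    anchors = {}
    pairs = [
        (model.biomass_reaction_id, rates.mu, "biomass"),
        (model.pdo_exchange_id, rates.q_pdo, "1,3-PDO exchange"),
        (model.glycerol_exchange_id, rates.q_glycerol, "glycerol exchange"),
    ]
    for rid, val, what in pairs:
        if rid is None:
            if val != 0:
                raise ValueError(f"model has no {what} reaction but its "
                                 f"measured rate is {val}")
            continue
        anchors[rid] = val
    return base.with_fixed(**anchors)


def estimate_input_fluxes(model: MetabolicModel, rates: ExperimentalRates,
                          constraints: Optional[ConstraintSet] = None,
                          order: str = "carbon-first") -> InputFluxes:
    """Two-step estimate of the photoautotrophic input fluxes.

    With the measured growth and production rates fixed as equalities, step
    1 minimizes the carbon-fixation uptake magnitude; step 2 fixes carbon at
    that minimum and minimizes the photon uptake magnitude.  ``order`` may
    be "photon-first" to swap the two minimizations.  Uptake is a negative
    exchange flux internally; the returned values are magnitudes.
    """
    if order not in ("carbon-first", "photon-first"):
        raise ValueError(f"unknown order {order!r}")
    if model.carbon_exchange_id is None or model.photon_exchange_id is None:
        raise ValueError("model must declare carbon and photon exchange ids")
    anchored = _anchor_constraints(model, rates, constraints or ConstraintSet())
    first, second = (model.carbon_exchange_id, model.photon_exchange_id)
    if order == "photon-first":
        first, second = second, first

    def _min_uptake(cs, rid):
        # uptake magnitude = -flux; minimal magnitude = maximal flux with flux <= 0
        cs2 = ConstraintSet(
            fixed_fluxes=dict(cs.fixed_fluxes),
            extra_bounds={**cs.extra_bounds, rid: (-np.inf, 0.0)},
            production_lower_bound=cs.production_lower_bound,
        )
        sol = solve_fba(model, rid, "max", cs2)
        if sol.status != "optimal":
            raise InfeasibleProblemError(
                f"measured rates are {sol.status} while minimizing uptake "
                f"through {rid}"
            )
        return -sol.objective_value

    u1 = _min_uptake(anchored, first)
    anchored = anchored.with_fixed(**{first: -u1})
    u2 = _min_uptake(anchored, second)
    if order == "carbon-first":
        carbon, photon = u1, u2
    else:
        photon, carbon = u1, u2
    return InputFluxes(carbon_fixation=max(carbon, 0.0), photon=max(photon, 0.0))


# ---------------------------------------------------------------------------
# Production envelope (solution space)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvelopePoint:
    mu: float
    q_min: float
    q_max: float


def production_envelope(model: MetabolicModel,
                        constraints: Optional[ConstraintSet],
                        target_reaction: str,
                        n_points: int = 20) -> list:
    """Min/max target flux on a uniform growth grid [0, mu_max].

    This is the two-dimensional growth-vs-production solution space: for
    each biomass flux on the grid, the attainable production range is the
    vertical slice of the feasible region.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    constraints = constraints or ConstraintSet()
    _rxn_index(model, target_reaction)
    top = solve_fba(model, model.biomass_reaction_id, "max", constraints)
    if top.status != "optimal":
        raise InfeasibleProblemError(f"base constraints are {top.status}")
    mu_max = top.objective_value
    points = []
    for mu in np.linspace(0.0, mu_max, n_points):
        cs = constraints.with_fixed(**{model.biomass_reaction_id: float(mu)})
        qmin = solve_fba(model, target_reaction, "min", cs)
        qmax = solve_fba(model, target_reaction, "max", cs)
        if qmin.status != "optimal" or qmax.status != "optimal":
            # numerical edge at the apex: retreat by one part in 1e9
            cs = constraints.with_fixed(
                **{model.biomass_reaction_id: float(mu) * (1 - 1e-9)})
            qmin = solve_fba(model, target_reaction, "min", cs)
            qmax = solve_fba(model, target_reaction, "max", cs)
        points.append(EnvelopePoint(
            mu=float(mu) + 0.0,
            q_min=float(qmin.objective_value) + 0.0,  # normalizes -0.0
            q_max=float(qmax.objective_value) + 0.0,
        ))
    return points


# ---------------------------------------------------------------------------
# Desk arithmetic: 3-PG production from carbon fixation
# ---------------------------------------------------------------------------

def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant digits (0 stays 0)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def pg_production_flux(carbon_fixation: float, pg_yield: float = 1.97) -> float:
    """3-PG production flux implied by a carbon-fixation flux.

    The RubisCO reaction lumped with photorespiration yields ``pg_yield``
    (default 1.97) molecules of 3-phosphoglycerate per fixed CO2, so the
    3-PG flux is simply the product; the result is rounded to 3 significant
    digits for display.
    """
    if carbon_fixation < 0 or pg_yield < 0:
        raise ValueError("carbon_fixation and pg_yield must be non-negative")
    return round_sig(carbon_fixation * pg_yield, 3)
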
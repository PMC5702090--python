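"""LP layer: FBA vs a vertex-enumeration oracle, min-norm reference,
input-flux estimation, production envelope, desk arithmetic."""

import itertools

import numpy as np
import pytest

import pdoflux as p
from pdoflux.fba import InfeasibleProblemError, round_sig
from pdoflux.model import stoichiometric_matrix

from conftest import make_chain_model, make_yield_model, random_small_model


# ---------------------------------------------------------------------------
# Brute-force LP oracle: enumerate candidate basic points of
# {S v = 0, lb <= v <= ub} by fixing variable subsets at their bounds.
# ---------------------------------------------------------------------------

def lp_oracle(model, c):
    S = stoichiometric_matrix(model).toarray()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    n = S.shape[1]
    best = None
    for k in range(n + 1):
        for fixed in itertools.combinations(range(n), k):
            free = [j for j in range(n) if j not in fixed]
            if free and np.linalg.matrix_rank(S[:, free]) < len(free):
                continue  # not a basic point; covered by a larger fixed set
            for vals in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
                v = np.zeros(n)
                for j, val in zip(fixed, vals):
                    v[j] = val
                if free:
                    rhs = -S[:, fixed] @ np.array(vals) if fixed \
                        else np.zeros(S.shape[0])
                    sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                    v[free] = sol
                if np.max(np.abs(S @ v), initial=0.0) > 1e-8:
                    continue
                if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                    continue
                obj = float(c @ v)
                if best is None or obj > best:
                    best = obj
    return best


@pytest.mark.parametrize("seed", range(12))
def test_fba_matches_vertex_enumeration(seed):
    rng = np.random.default_rng(seed)
    model = random_small_model(rng)
    j = int(rng.integers(len(model.reactions)))
    target = model.reactions[j].id
    c = np.zeros(len(model.reactions))
    c[j] = 1.0
    want = lp_oracle(model, c)
    sol = p.solve_fba(model, target, "max")
    if want is None:
        assert sol.status == "infeasible"
    else:
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(want, abs=1e-7)


def test_bound_limited_chain():
    sol = p.solve_fba(make_chain_model(cap=10.0), "EX_out", "max")
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(10.0)


def test_unknown_objective_raises(toy):
    model, _ = toy
    with pytest.raises(KeyError):
        p.solve_fba(model, "NOPE", "max")


def test_infeasible_reported_as_status_not_zero(toy):
    model, _ = toy
    cs = p.ConstraintSet(fixed_fluxes={"EX_co2": -1.0, "RBC": 0.0})
    sol = p.solve_fba(model, "BIOMASS", "max", cs)
    assert sol.status == "infeasible"
    assert sol.objective_value is None


def test_optimum_stable_under_reaction_reordering(toy_augmented):
    """Solver-independence proxy: permuting reactions does not move the
    optimum (1e-6 relative)."""
    model = toy_augmented
    base = p.solve_fba(model, "BIOMASS", "max").objective_value
    perm = model.copy()
    perm.reactions = list(reversed(perm.reactions))
    perm.__post_init__()
    again = p.solve_fba(perm, "BIOMASS", "max").objective_value
    assert again == pytest.approx(base, rel=1e-6)


# ---------------------------------------------------------------------------
# Minimum-norm reference
# ---------------------------------------------------------------------------

def test_min_norm_on_single_path_equals_unique_flux():
    model = make_chain_model(cap=4.0)
    cs = p.ConstraintSet(fixed_fluxes={"EX_out": 4.0})
    ref = p.minimal_norm_reference(model, cs, objective_reaction="EX_out")
    for rid, want in (("EX_in", -4.0), ("CONV", 4.0), ("EX_out", 4.0)):
        assert ref.flux[rid] == pytest.approx(want, abs=1e-7)


def test_min_norm_splits_parallel_routes_evenly():
    mets = [p.Metabolite("A"), p.Metabolite("B")]
    rxns = [
        p.Reaction("EX_in", {"A": -1.0}, lower_bound=-6.0, upper_bound=0.0,
                   is_exchange=True),
        p.Reaction("P1", {"A": -1.0, "B": 1.0}, lower_bound=0.0,
                   upper_bound=1000.0),
        p.Reaction("P2", {"A": -1.0, "B": 1.0}, lower_bound=0.0,
                   upper_bound=1000.0),
        p.Reaction("EX_out", {"B": -1.0}, lower_bound=0.0, upper_bound=1000.0,
                   is_exchange=True),
    ]
    model = p.MetabolicModel(id="par", metabolites=mets, reactions=rxns,
                             genes=set(), biomass_reaction_id="EX_out")
    cs = p.ConstraintSet(fixed_fluxes={"EX_out": 6.0})
    ref = p.minimal_norm_reference(model, cs, objective_reaction="EX_out")
    assert ref.flux["P1"] == pytest.approx(3.0, abs=1e-7)
    assert ref.flux["P2"] == pytest.approx(3.0, abs=1e-7)


def test_min_norm_stable_under_reaction_reordering(screen_setup):
    model = screen_setup["model"]
    rates = screen_setup["rates"]
    perm = model.copy()
    perm.reactions = list(reversed(perm.reactions))
    perm.__post_init__()
    kwargs = {model.biomass_reaction_id: rates.mu,
              model.pdo_exchange_id: rates.q_pdo,
              model.glycerol_exchange_id: rates.q_glycerol}
    cs = p.ConstraintSet(fixed_fluxes=dict(screen_setup["input_cs"].fixed_fluxes),
                         extra_bounds=dict(screen_setup["input_cs"].extra_bounds))
    cs = cs.with_fixed(**kwargs)
    a = screen_setup["reference"]
    b = p.minimal_norm_reference(perm, cs)
    va = np.array([a.flux[r] for r in sorted(a.flux)])
    vb = np.array([b.flux[r] for r in sorted(b.flux)])
    assert abs(np.linalg.norm(va) - np.linalg.norm(vb)) <= 1e-8
    np.testing.assert_allclose(va, vb, atol=1e-7)


def test_min_norm_infeasible_constraints_raise(toy):
    model, _ = toy
    cs = p.ConstraintSet(fixed_fluxes={"EX_co2": -1.0, "RBC": 0.0})
    with pytest.raises(InfeasibleProblemError):
        p.minimal_norm_reference(model, cs)


# ---------------------------------------------------------------------------
# Input-flux estimation
# ---------------------------------------------------------------------------

def test_zero_rates_need_zero_inputs(toy_augmented):
    res = p.estimate_input_fluxes(toy_augmented, p.ExperimentalRates(0.0))
    assert res.carbon_fixation == pytest.approx(0.0, abs=1e-9)
    assert res.photon == pytest.approx(0.0, abs=1e-9)


def test_hand_set_yield_arithmetic():
    """1 biomass = 10 C + 48 hv; 1 PDO = 3 C + 14 hv; at mu=0.1, q_pdo=0.2
    the two-step estimate is carbon 1.6 then photons 7.6."""
    model = make_yield_model()
    rates = p.ExperimentalRates(mu=0.1, q_pdo=0.2, q_glycerol=0.0)
    res = p.estimate_input_fluxes(model, rates)
    assert res.carbon_fixation == pytest.approx(1.6, abs=1e-8)
    assert res.photon == pytest.approx(7.6, abs=1e-8)
    swapped = p.estimate_input_fluxes(model, rates, order="photon-first")
    assert swapped.photon == pytest.approx(7.6, abs=1e-8)
    assert swapped.carbon_fixation == pytest.approx(1.6, abs=1e-8)


def test_input_estimation_is_monotone(toy_augmented):
    """Raising any measured rate never lowers either input flux."""
    base = p.estimate_input_fluxes(toy_augmented, p.default_toy_rates())
    r0 = p.default_toy_rates()
    for bumped in (p.ExperimentalRates(r0.mu + 0.02, r0.q_pdo, r0.q_glycerol),
                   p.ExperimentalRates(r0.mu, r0.q_pdo + 0.02, r0.q_glycerol),
                   p.ExperimentalRates(r0.mu, r0.q_pdo, r0.q_glycerol + 0.02)):
        res = p.estimate_input_fluxes(toy_augmented, bumped)
        assert res.carbon_fixation >= base.carbon_fixation - 1e-9
        assert res.photon >= base.photon - 1e-9


def test_infeasible_rates_raise(toy_augmented):
    with pytest.raises(InfeasibleProblemError):
        p.estimate_input_fluxes(toy_augmented, p.ExperimentalRates(mu=50.0))


# ---------------------------------------------------------------------------
# Production envelope
# ---------------------------------------------------------------------------

def test_competing_resource_envelope_is_affine_decreasing():
    model = make_yield_model()
    cs = p.ConstraintSet(extra_bounds={"EX_c": (-1.0, 0.0),
                                       "EX_hv": (-1000.0, 0.0)})
    pts = p.production_envelope(model, cs, "EX_pdo", n_points=6)
    mu_max = pts[-1].mu
    assert mu_max == pytest.approx(0.1, abs=1e-8)  # 1 C / 10 per biomass
    assert pts[-1].q_max == pytest.approx(0.0, abs=1e-8)
    # q_max(mu) = (1 - 10 mu)/3 : affine, decreasing
    for pt in pts:
        assert pt.q_max == pytest.approx((1 - 10 * pt.mu) / 3.0, abs=1e-7)
        assert pt.q_min >= -1e-9  # irreversible export


def test_envelope_endpoints_and_concavity(toy_augmented, screen_setup):
    pts = p.production_envelope(toy_augmented, screen_setup["input_cs"],
                                toy_augmented.pdo_exchange_id, n_points=9)
    mus = [pt.mu for pt in pts]
    assert mus == sorted(mus)
    qmax = np.array([pt.q_max for pt in pts])
    qmin = np.array([pt.q_min for pt in pts])
    # LP value function: q_max concave, q_min convex along the mu grid
    assert np.all(np.diff(qmax, 2) <= 1e-7)
    assert np.all(np.diff(qmin, 2) >= -1e-7)
    two = p.production_envelope(toy_augmented, screen_setup["input_cs"],
                                toy_augmented.pdo_exchange_id, n_points=2)
    assert two[0].mu == pytest.approx(0.0)
    assert two[1].mu == pytest.approx(pts[-1].mu)


def test_envelope_rejects_bad_inputs(toy_augmented):
    with pytest.raises(ValueError):
        p.production_envelope(toy_augmented, None,
                              toy_augmented.pdo_exchange_id, n_points=1)


# ---------------------------------------------------------------------------
# 3-PG production arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("carbon, pg_yield, want", [
    (1.35, 1.97, 2.66),
    (0.0, 1.97, 0.0),
    (2.0, 1.5, 3.0),
])
def test_pg_production_flux(carbon, pg_yield, want):
    assert p.pg_production_flux(carbon, pg_yield) == pytest.approx(want)


def test_pg_production_flux_rejects_negative():
    with pytest.raises(ValueError):
        p.pg_production_flux(-1.0, 1.97)


def test_round_sig():
    assert round_sig(2.6595, 3) == 2.66
    assert round_sig(0.0) == 0.0
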
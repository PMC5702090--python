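"""MOMA knockouts, the deletion screen, classification, patterns, ranking."""

import numpy as np
import pytest
from scipy.optimize import minimize

import pdoflux as p
from pdoflux.model import stoichiometric_matrix
from pdoflux.moma import PhenotypeRecord


def scipy_qp_oracle(model, w, lb, ub):
    """Independent QP route: SLSQP on the same projection problem."""
    S = stoichiometric_matrix(model).toarray()
    res = minimize(
        lambda v: 0.5 * np.sum((v - w) ** 2), np.clip(w, lb, ub),
        jac=lambda v: v - w, method="SLSQP",
        constraints=[{"type": "eq", "fun": lambda v: S @ v,
                      "jac": lambda v: S}],
        bounds=list(zip(lb, ub)), options={"maxiter": 800, "ftol": 1e-14})
    assert res.success, res.message
    return res.x


def test_empty_deletion_returns_reference(screen_setup):
    s = screen_setup
    sol = p.solve_moma(s["model"], s["reference"], set(), s["screen_cs"])
    assert sol.status == "optimal"
    assert sol.distance == pytest.approx(0.0, abs=1e-7)
    for rid, v in s["reference"].flux.items():
        assert sol.state.flux[rid] == pytest.approx(v, abs=1e-6)


def test_zero_flux_gene_deletion_costs_nothing(screen_setup):
    """glgC only carries the glycogen-synthesis reaction, which is silent in
    the reference, so its deletion leaves the flux state untouched."""
    s = screen_setup
    assert abs(s["reference"].flux["GLGS"]) < 1e-9
    sol = p.solve_moma(s["model"], s["reference"], {"glgC"}, s["screen_cs"])
    assert sol.distance == pytest.approx(0.0, abs=1e-7)


@pytest.mark.parametrize("seed", range(10))
def test_moma_matches_independent_qp_solver(screen_setup, seed):
    s = screen_setup
    model = s["model"]
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes - model.pathway_genes)
    gene = genes[int(rng.integers(len(genes)))]
    sol = p.solve_moma(model, s["reference"], {gene}, s["screen_cs"])
    if sol.status != "optimal":
        return
    disabled = p.reactions_disabled_by(model, {gene})
    cs = s["screen_cs"].with_fixed(**{r: 0.0 for r in disabled})
    lb, ub = cs.bounds_arrays(model)
    v_oracle = scipy_qp_oracle(model, s["reference"].vector(model), lb, ub)
    v = sol.state.vector(model)
    assert np.max(np.abs(v - v_oracle)) <= 1e-6 * max(1.0, np.max(np.abs(v)))


def test_distance_matches_recomputed_objective(screen_setup):
    s = screen_setup
    sol = p.solve_moma(s["model"], s["reference"], {"ndh1_01"}, s["screen_cs"])
    v = sol.state.vector(s["model"])
    w = s["reference"].vector(s["model"])
    assert sol.distance == pytest.approx(float(np.linalg.norm(v - w)),
                                         rel=1e-8)


def test_distance_nondecreasing_in_deleted_set(screen_setup):
    """More deletions mean more constraints, so the projection distance can
    only grow."""
    s = screen_setup
    nested = [set(), {"glgC"}, {"glgC", "tpiA"}, {"glgC", "tpiA", "ndh1_01"}]
    dists = []
    for deleted in nested:
        sol = p.solve_moma(s["model"], s["reference"], deleted, s["screen_cs"])
        assert sol.status == "optimal"
        dists.append(sol.distance)
    for a, b in zip(dists, dists[1:]):
        assert b >= a - 1e-9


def test_linear_moma_variant(screen_setup):
    """The L1 variant returns a feasible state whose reported distance is
    the recomputed L1 norm; the empty deletion still costs nothing."""
    s = screen_setup
    empty = p.solve_moma(s["model"], s["reference"], set(), s["screen_cs"],
                         variant="linear")
    assert empty.distance == pytest.approx(0.0, abs=1e-7)
    sol = p.solve_moma(s["model"], s["reference"], {"ndh1_01"},
                       s["screen_cs"], variant="linear")
    assert sol.status == "optimal"
    v = sol.state.vector(s["model"])
    w = s["reference"].vector(s["model"])
    assert sol.distance == pytest.approx(float(np.sum(np.abs(v - w))),
                                         rel=1e-8)
    assert p.check_steady_state(s["model"], sol.state).ok
    assert sol.state.flux[s["model"].pdo_exchange_id] >= 0.03 - 1e-9
    with pytest.raises(ValueError):
        p.solve_moma(s["model"], s["reference"], set(), s["screen_cs"],
                     variant="cubic")


def test_infeasible_is_an_outcome_not_an_exception(screen_setup):
    s = screen_setup
    sol = p.solve_moma(s["model"], s["reference"], {"rbcL"}, s["screen_cs"])
    assert sol.status == "infeasible"
    assert sol.state is None


# ---------------------------------------------------------------------------
# Screen bookkeeping and classification
# ---------------------------------------------------------------------------

def test_screen_covers_every_nonexcluded_gene(toy_screen, screen_setup):
    result, _ = toy_screen
    model = screen_setup["model"]
    want = sorted(model.genes - model.pathway_genes)
    assert [r.gene for r in result.records] == want
    counts = p.group_counts(result.records)
    assert sum(counts.values()) == len(want)
    assert all(r.group in (1, 2, 3, 4) for r in result.records)


def test_group_definitions_hold(toy_screen):
    result, _ = toy_screen
    for rec in result.records:
        assert (rec.group == 1) == (rec.status == "infeasible")
        if rec.group == 2:
            assert rec.mu <= 1e-6


def test_biomass_essential_gene_lands_in_group_2(toy_screen):
    """pyk carries the only route from DHAP to the biomass precursor, so its
    deletion zeroes growth while fixed carbon still reaches the pathway."""
    result, _ = toy_screen
    rec = next(r for r in result.records if r.gene == "pyk")
    assert rec.status == "optimal"
    assert rec.group == 2
    assert rec.q_pdo >= 0.03 - 1e-9


def test_production_blocking_gene_lands_in_group_1(toy_screen):
    """Deleting GAPDH makes the fixed carbon-fixation flux and the 1,3-PDO
    lower limit unsatisfiable."""
    result, _ = toy_screen
    rec = next(r for r in result.records if r.gene == "gap2")
    assert rec.group == 1


def test_ndh_complex_subunits_share_group_4_and_pattern(toy_screen):
    """The cyclic-electron-flow complex knockout reroutes carbon toward the
    DHAP branch; all subunits co-classify with one collapsed pattern and
    the top product score."""
    result, patterns = toy_screen
    ndh = [r for r in result.records if r.gene.startswith("ndh1_")]
    assert len(ndh) == 3
    assert all(r.group == 4 for r in ndh)
    assert len({r.pattern_id for r in ndh}) == 1
    assert all(r.q_pdo > 0.03 for r in ndh)
    ref_score = 0.1 * 0.03
    assert all(r.product_score > ref_score for r in ndh)
    # identical records across subunits
    first = ndh[0]
    for other in ndh[1:]:
        assert other.mu == pytest.approx(first.mu, abs=1e-9)
        assert other.q_pdo == pytest.approx(first.q_pdo, abs=1e-9)


def test_group_1_empty_without_production_demand(screen_setup):
    """With the production lower bound at 0 and no input constraints every
    deletion admits the zero flux vector."""
    model = screen_setup["model"]
    zero_ref = p.FluxState(flux={r.id: 0.0 for r in model.reactions})
    result = p.run_gene_deletion_screen(model, zero_ref, p.ConstraintSet(),
                                        excluded_genes=model.pathway_genes)
    assert all(rec.status == "optimal" for rec in result.records)
    p.classify_records(result.records)
    assert p.group_counts(result.records)[1] == 0


def test_serial_unbranched_genes_collapse_to_one_pattern(screen_setup):
    """PGK and GAPDH catalyze consecutive steps of an unbranched path:
    under relaxed constraints their deletions force identical flux states
    even though their disabled-reaction sets differ."""
    model = screen_setup["model"]
    zero_ref = p.FluxState(flux={r.id: 0.0 for r in model.reactions})
    cs = p.ConstraintSet()
    result = p.run_gene_deletion_screen(model, zero_ref, cs,
                                        excluded_genes=model.pathway_genes)
    p.classify_records(result.records)
    p.collapse_flux_patterns(result.records, result.states)
    by_gene = {r.gene: r for r in result.records}
    assert by_gene["pgk"].pattern_id == by_gene["gap2"].pattern_id


def test_excluded_genes_validated(screen_setup):
    s = screen_setup
    with pytest.raises(KeyError):
        p.run_gene_deletion_screen(s["model"], s["reference"], s["screen_cs"],
                                   excluded_genes={"ghost"})


# ---------------------------------------------------------------------------
# classify_records / collapse / rank unit behavior
# ---------------------------------------------------------------------------

def _rec(gene, score, mu=0.1, status="optimal"):
    return PhenotypeRecord(gene=gene, status=status, mu=mu, q_pdo=score / mu,
                           q_glycerol=0.0, product_score=score)


def test_all_infeasible_is_all_group_1():
    recs = [PhenotypeRecord(gene=f"g{i}", status="infeasible")
            for i in range(3)]
    p.classify_records(recs)
    assert all(r.group == 1 for r in recs)


def test_top_pattern_rule_selects_max_score():
    recs = [_rec("a", 1.0), _rec("b", 2.0)]
    p.classify_records(recs, group4_rule="top-pattern")
    assert [r.group for r in recs] == [3, 4]


def test_threshold_and_quantile_rules():
    recs = [_rec(f"g{i}", s) for i, s in enumerate((0.1, 0.2, 0.3, 0.4))]
    p.classify_records(recs, group4_rule="threshold:0.25")
    assert [r.group for r in recs] == [3, 3, 4, 4]
    p.classify_records(recs, group4_rule="quantile:0.75")
    assert [r.group for r in recs] == [3, 3, 3, 4]


def test_unknown_rule_raises():
    with pytest.raises(ValueError):
        p.classify_records([_rec("a", 1.0)], group4_rule="magic")


def test_pattern_threshold_behavior(screen_setup):
    """A state perturbed by 10x the tolerance splits into its own pattern."""
    model = screen_setup["model"]
    base = {r.id: 0.5 for r in model.reactions}
    tol = 1e-6
    recs = [_rec("a", 1.0), _rec("b", 1.0), _rec("c", 1.0)]
    near = dict(base)
    near["RBC"] += 0.1 * tol
    far = dict(base)
    far["RBC"] += 10 * tol
    states = {"a": p.FluxState(base), "b": p.FluxState(near),
              "c": p.FluxState(far)}
    patterns = p.collapse_flux_patterns(recs, states, tol=tol)
    by_gene = {r.gene: r.pattern_id for r in recs}
    assert by_gene["a"] == by_gene["b"] != by_gene["c"]
    assert len(patterns) == 2


def test_rank_candidates_tie_break():
    recs = [_rec("c", 0.3), _rec("b", 0.5), _rec("a", 0.5)]
    for r in recs:
        r.group = 4
    ranked = p.rank_candidates(recs)
    assert [r.gene for r in ranked] == ["a", "b", "c"]
    assert p.rank_candidates([recs[0]]) == [recs[0]]


def test_top_ranked_pattern_is_the_complex(toy_screen):
    """The screen's best candidate pattern is the cyclic-flow complex whose
    removal pushes fixed carbon into the DHAP branch."""
    result, patterns = toy_screen
    ranked = p.rank_candidates(result.records)
    assert ranked[0].gene.startswith("ndh1_")
    assert set(patterns[0]) == {"ndh1_01", "ndh1_02", "ndh1_03"}
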
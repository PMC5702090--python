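"""Shared fixtures: toy models, the screen pipeline setup, tiny LP fixtures."""

import numpy as np
import pytest

import pdoflux as p


@pytest.fixture(scope="session")
def toy():
    """Default toy photoautotroph and its closed-form manifest."""
    model, manifest = p.generate_toy_photoautotroph()
    return model, manifest


@pytest.fixture(scope="session")
def toy_augmented(toy):
    """Toy grafted with the default 1,3-PDO pathway (cofactors -> NADPH)."""
    model, _ = toy
    spec = p.default_pdo_pathway_spec(gpd_cofactor_id="nadph",
                                      reductase_cofactor_id="nadph")
    return p.augment_model(model, spec)


@pytest.fixture(scope="session")
def screen_setup(toy_augmented):
    """Rates, estimated inputs, constraint sets and min-norm reference for
    the toy screen: carbon fixed, photons capped at their estimated value,
    measured 1,3-PDO rate as the production lower limit."""
    model = toy_augmented
    rates = p.default_toy_rates()
    inputs = p.estimate_input_fluxes(model, rates)
    input_cs = p.ConstraintSet(
        fixed_fluxes={model.carbon_exchange_id: -inputs.carbon_fixation},
        extra_bounds={model.photon_exchange_id: (-inputs.photon, 0.0)},
    )
    ref_cs = input_cs.with_fixed(**{
        model.biomass_reaction_id: rates.mu,
        model.pdo_exchange_id: rates.q_pdo,
        model.glycerol_exchange_id: rates.q_glycerol,
    })
    reference = p.minimal_norm_reference(model, ref_cs)
    screen_cs = p.ConstraintSet(
        fixed_fluxes=dict(input_cs.fixed_fluxes),
        extra_bounds=dict(input_cs.extra_bounds),
        production_lower_bound=(model.pdo_exchange_id, rates.q_pdo),
    )
    return {"model": model, "rates": rates, "inputs": inputs,
            "input_cs": input_cs, "reference": reference,
            "screen_cs": screen_cs}


@pytest.fixture(scope="session")
def toy_screen(screen_setup):
    """Full toy screen result with classification and patterns assigned."""
    s = screen_setup
    result = p.run_gene_deletion_screen(
        s["model"], s["reference"], s["screen_cs"],
        excluded_genes=s["model"].pathway_genes)
    p.classify_records(result.records, group4_rule="top-pattern")
    patterns = p.collapse_flux_patterns(result.records, result.states)
    return result, patterns


def make_chain_model(cap=10.0):
    """uptake(<=cap) -> A -> B -> export, for bound-limited FBA checks."""
    mets = [p.Metabolite("A"), p.Metabolite("B")]
    rxns = [
        p.Reaction("EX_in", {"A": -1.0}, lower_bound=-cap, upper_bound=0.0,
                   is_exchange=True),
        p.Reaction("CONV", {"A": -1.0, "B": 1.0}, lower_bound=0.0,
                   upper_bound=1000.0),
        p.Reaction("EX_out", {"B": -1.0}, lower_bound=0.0, upper_bound=1000.0,
                   is_exchange=True),
    ]
    model = p.MetabolicModel(id="chain", metabolites=mets, reactions=rxns,
                             genes=set(), biomass_reaction_id="CONV")
    model.validate()
    return model


def make_yield_model():
    """Direct-yield photoautotroph: 1 biomass = 10 C + 48 photons,
    1 PDO = 3 C + 14 photons, 1 glycerol = 2 C + 5 photons."""
    mets = [p.Metabolite("c"), p.Metabolite("hv"),
            p.Metabolite("pdo"), p.Metabolite("glyc")]
    rxns = [
        p.Reaction("EX_c", {"c": -1.0}, lower_bound=-1000.0, upper_bound=0.0,
                   is_exchange=True),
        p.Reaction("EX_hv", {"hv": -1.0}, lower_bound=-1000.0,
                   upper_bound=0.0, is_exchange=True),
        p.Reaction("BIO", {"c": -10.0, "hv": -48.0}, lower_bound=0.0,
                   upper_bound=1000.0),
        p.Reaction("PDOSYN", {"c": -3.0, "hv": -14.0, "pdo": 1.0},
                   lower_bound=0.0, upper_bound=1000.0),
        p.Reaction("GLYSYN", {"c": -2.0, "hv": -5.0, "glyc": 1.0},
                   lower_bound=0.0, upper_bound=1000.0),
        p.Reaction("EX_pdo", {"pdo": -1.0}, lower_bound=0.0,
                   upper_bound=1000.0, is_exchange=True),
        p.Reaction("EX_glyc", {"glyc": -1.0}, lower_bound=0.0,
                   upper_bound=1000.0, is_exchange=True),
    ]
    model = p.MetabolicModel(
        id="yield_toy", metabolites=mets, reactions=rxns, genes=set(),
        biomass_reaction_id="BIO", photon_exchange_id="EX_hv",
        carbon_exchange_id="EX_c", pdo_exchange_id="EX_pdo",
        glycerol_exchange_id="EX_glyc")
    model.validate()
    return model


def random_small_model(rng, n_mets=None, n_rxns=None):
    """Random dense-ish toy network with finite bounds for oracle LP tests."""
    n_mets = n_mets or int(rng.integers(2, 4))
    n_rxns = n_rxns or int(rng.integers(4, 8))
    S = rng.integers(-2, 3, size=(n_mets, n_rxns)).astype(float)
    for j in range(n_rxns):  # no empty reactions
        if not S[:, j].any():
            S[int(rng.integers(n_mets)), j] = 1.0
    mets = [p.Metabolite(f"m{i}") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        lo = float(rng.integers(-5, 1))
        hi = float(rng.integers(0, 6))
        stoich = {f"m{i}": S[i, j] for i in range(n_mets) if S[i, j]}
        rxns.append(p.Reaction(f"r{j}", stoich, lower_bound=lo,
                               upper_bound=hi))
    model = p.MetabolicModel(id="rand", metabolites=mets, reactions=rxns,
                             genes=set(), biomass_reaction_id="r0")
    model.validate()
    return model
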
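"""Synthetic fixture models.

``generate_toy_photoautotroph`` builds a small photoautotrophic network
whose FBA optima are known in closed form from its yield parameters, so
every pipeline stage (input-flux estimation, envelope, MOMA screen) is
testable without any external genome-scale model.  ``generate_count_stub``
builds a structurally trivial but valid model with arbitrary prescribed
gene/reaction/metabolite counts for augmentation bookkeeping tests.

Toy network sketch (one compartment, lumped cofactors):

    photon --LEF (psaA and psbA)--> a ATP + n NADPH
    photon --CEF (ndh1_* AND complex)--> c ATP          [cyclic electron flow]
    CO2 + RuBP --RubisCO--> pg_yield 3-PG               [photorespiration lumped]
    3-PG -PGK-> BPG -GAPDH-> GAP <-TPI-> DHAP           [PGK/GAPDH serial pair,
                                                         TPI isozymes tpiA/tpiB]
    5 GAP + 3 ATP --regeneration--> 3 RuBP
    DHAP --lower glycolysis/TCA lump (pyk)--> pyruvate
    b_c pyruvate + b_atp ATP + 2 NADPH --biomass-->
    NADPH --Mehler-like valve-->   ATP --maintenance valve-->
    2 DHAP + ATP --glgC--> glycogen --> exchange        [optional sink]

Net triose per fixed CO2 is ``pg_yield - 5/3``; with the default 1.97 yield
this is ~0.303 DHAP per CO2, close to the 1/3 of an unlumped Calvin cycle.
A glycerol-3-phosphate species is carried as the anchor for the default
1,3-PDO pathway's phosphatase step.
"""

from __future__ import annotations

import random
from dataclasses import asdict, dataclass
from typing import Optional

from .fba import ExperimentalRates
from .model import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_gpr,
)

#: triose (GAP) units regenerated into one RuBP
_REGEN_GAP_PER_RUBP = 5.0 / 3.0
_REGEN_ATP_PER_RUBP = 1.0
#: NADPH stoichiometry of the biomass reaction (fixed; ATP cost is the knob)
_BIOMASS_NADPH = 2.0
#: NADPH demands of the default grafted PDO pathway (Gpd1 + YqhD steps) and
#: of glycerol alone (Gpd1 step), with both cofactors mapped to NADPH
_PDO_NADPH = 2.0
_GLYCEROL_NADPH = 1.0


@dataclass(frozen=True)
class ToyParams:
    """Yield/cost parameters of the toy photoautotroph.

    Defaults are loosely scaled to oxygenic photosynthesis: linear electron
    flow yields ~3 ATP + 2 NADPH per 8 photons, cyclic flow tops up ATP at
    0.5 per photon, and RubisCO carries the photorespiration-lumped 1.97
    3-PG yield.  Uptake limits (photon 20, CO2 1.35 mmol/(g DCW)/h) bound
    the exchange reactions.
    """

    photon_yield_atp: float = 0.375
    photon_yield_nadph: float = 0.25
    cyclic_atp_yield: float = 0.5
    cyclic_flow_enabled: bool = True
    ndh_complex_size: int = 3
    pg_yield: float = 1.97
    biomass_carbon_cost: float = 2.0
    biomass_energy_cost: float = 6.0
    include_glycogen_sink: bool = True
    photon_uptake_limit: float = 20.0
    co2_uptake_limit: float = 1.35
    seed: int = 0

    def __post_init__(self):
        for name in ("photon_yield_atp", "photon_yield_nadph",
                     "cyclic_atp_yield", "pg_yield", "biomass_carbon_cost",
                     "biomass_energy_cost", "photon_uptake_limit",
                     "co2_uptake_limit"):
            if getattr(self, name) <= 0:
                raise ModelValidationError(f"{name} must be positive")
        if self.ndh_complex_size < 2:
            raise ModelValidationError("ndh_complex_size must be >= 2")
        if self.pg_yield <= _REGEN_GAP_PER_RUBP:
            raise ModelValidationError(
                "pg_yield must exceed 5/3 or no net triose can be made and "
                "the biomass cost is unreachable"
            )


def _photons_for(params: ToyParams, atp: float, nadph: float,
                 cyclic: bool) -> float:
    """Minimal photons meeting an (ATP, NADPH) demand, surplus dumped."""
    a, n = params.photon_yield_atp, params.photon_yield_nadph
    base = nadph / n
    extra_atp = atp - a * base
    if extra_atp <= 0:
        return base
    top_yield = max(params.cyclic_atp_yield, a) if cyclic else a
    return base + extra_atp / top_yield


def _demands(params: ToyParams):
    """Per-unit (carbon, ATP, NADPH) demands of biomass, PDO and glycerol."""
    y_t = params.pg_yield - _REGEN_GAP_PER_RUBP
    r_per_dhap = 1.0 / y_t            # CO2 fixed per DHAP delivered
    atp_up = params.pg_yield * r_per_dhap + _REGEN_ATP_PER_RUBP * r_per_dhap
    nadph_up = params.pg_yield * r_per_dhap
    b_c = params.biomass_carbon_cost
    demands = {
        "biomass": (b_c * r_per_dhap,
                    b_c * atp_up + params.biomass_energy_cost,
                    b_c * nadph_up + _BIOMASS_NADPH),
        "pdo": (r_per_dhap, atp_up, nadph_up + _PDO_NADPH),
        "glycerol": (r_per_dhap, atp_up, nadph_up + _GLYCEROL_NADPH),
    }
    return demands


def closed_form_optima(params: ToyParams) -> dict:
    """Closed-form FBA optima implied by the toy yields.

    ``mu_max`` is the maximal growth under the uptake limits with zero
    production; ``q_pdo_max``/``q_glycerol_max`` are the maximal production
    rates at zero growth after grafting the default 1,3-PDO pathway (both
    pathway cofactors mapped onto the toy NADPH pool).  Each optimum is the
    minimum of the carbon-limited and photon-limited values.
    """
    C, P = params.co2_uptake_limit, params.photon_uptake_limit
    out = {}
    for key, (carbon, atp, nadph) in _demands(params).items():
        per_photon = _photons_for(params, atp, nadph,
                                  params.cyclic_flow_enabled)
        out[key] = min(C / carbon, P / per_photon)
    return {
        "mu_max": out["biomass"],
        "q_pdo_max": out["pdo"],
        "q_glycerol_max": out["glycerol"],
    }


def ndh_complex_genes(params: ToyParams) -> list:
    return [f"ndh1_{i + 1:02d}" for i in range(params.ndh_complex_size)]


def generate_toy_photoautotroph(params: Optional[ToyParams] = None):
    """Build the toy model; returns ``(model, manifest)``.

    The manifest echoes the parameters and carries the closed-form optima
    of :func:`closed_form_optima`.  The seed only shuffles metabolite and
    reaction list order (exercising order-robustness downstream); the
    stoichiometry itself is seed-independent.
    """
    params = params or ToyParams()
    p = params
    mets = [
        Metabolite("photon", "photon"),
        Metabolite("co2", "carbon dioxide"),
        Metabolite("atp", "ATP (lumped phosphorylation potential)"),
        Metabolite("nadph", "NADPH (lumped reductant)"),
        Metabolite("pg3", "3-phosphoglycerate"),
        Metabolite("bpg", "1,3-bisphosphoglycerate"),
        Metabolite("gap", "glyceraldehyde 3-phosphate"),
        Metabolite("dhap", "dihydroxyacetone phosphate"),
        Metabolite("rubp", "ribulose-1,5-bisphosphate"),
        Metabolite("g3p", "glycerol-3-phosphate (pathway graft anchor)"),
        Metabolite("pyr", "pyruvate (biomass precursor lump)"),
    ]
    rxns = [
        Reaction("EX_photon", {"photon": -1.0},
                 lower_bound=-p.photon_uptake_limit, upper_bound=0.0,
                 name="photon exchange", is_exchange=True),
        Reaction("EX_co2", {"co2": -1.0},
                 lower_bound=-p.co2_uptake_limit, upper_bound=1000.0,
                 name="CO2 exchange", is_exchange=True),
        Reaction("LEF", {"photon": -1.0, "atp": p.photon_yield_atp,
                         "nadph": p.photon_yield_nadph},
                 lower_bound=0.0, upper_bound=1000.0,
                 gpr=parse_gpr("psaA and psbA"),
                 name="linear electron flow"),
        Reaction("RBC", {"rubp": -1.0, "co2": -1.0, "pg3": p.pg_yield},
                 lower_bound=0.0, upper_bound=1000.0,
                 gpr=parse_gpr("rbcL"),
                 name="RubisCO (photorespiration lumped)"),
        Reaction("PGK", {"pg3": -1.0, "atp": -1.0, "bpg": 1.0},
                 lower_bound=0.0, upper_bound=1000.0,
                 gpr=parse_gpr("pgk"), name="phosphoglycerate kinase"),
        Reaction("GAPDH", {"bpg": -1.0, "nadph": -1.0, "gap": 1.0},
                 lower_bound=0.0, upper_bound=1000.0,
                 gpr=parse_gpr("gap2"), name="GAP dehydrogenase"),
        Reaction("TPI", {"gap": -1.0, "dhap": 1.0},
                 lower_bound=-1000.0, upper_bound=1000.0,
                 gpr=parse_gpr("tpiA or tpiB"),
                 name="triose-phosphate isomerase (isozymes)"),
        Reaction("REGEN", {"gap": -5.0, "atp": -3.0, "rubp": 3.0},
                 lower_bound=0.0, upper_bound=1000.0,
                 gpr=parse_gpr("prk"),
                 name="condensed Calvin regeneration"),
        Reaction("LOWER_GLYC", {"dhap": -1.0, "pyr": 1.0},
                 lower_bound=0.0, upper_bound=1000.0,
                 gpr=parse_gpr("pyk"),
                 name="lower glycolysis / TCA lump toward biomass"),
        Reaction("BIOMASS",
                 {"pyr": -p.biomass_carbon_cost,
                  "atp": -p.biomass_energy_cost,
                  "nadph": -_BIOMASS_NADPH},
                 lower_bound=0.0, upper_bound=1000.0, name="biomass sink"),
        Reaction("MEHLER", {"nadph": -1.0},
                 lower_bound=0.0, upper_bound=1000.0,
                 name="Mehler-like reductant valve"),
        Reaction("ATPM", {"atp": -1.0},
                 lower_bound=0.0, upper_bound=1000.0,
                 name="ATP maintenance valve (not forced)"),
    ]
    genes = {"psaA", "psbA", "rbcL", "pgk", "gap2", "tpiA", "tpiB", "prk",
             "pyk"}
    if p.cyclic_flow_enabled:
        ndh = ndh_complex_genes(p)
        rxns.append(Reaction(
            "CEF", {"photon": -1.0, "atp": p.cyclic_atp_yield},
            lower_bound=0.0, upper_bound=1000.0,
            gpr=parse_gpr(" and ".join(ndh)),
            name="NDH-1-analog cyclic electron flow"))
        genes.update(ndh)
    if p.include_glycogen_sink:
        mets.append(Metabolite("glycogen", "glycogen (storage unit)"))
        rxns.append(Reaction(
            "GLGS", {"dhap": -2.0, "atp": -1.0, "glycogen": 1.0},
            lower_bound=0.0, upper_bound=1000.0,
            gpr=parse_gpr("glgC"), name="glycogen synthesis (lumped)"))
        rxns.append(Reaction(
            "EX_glycogen", {"glycogen": -1.0},
            lower_bound=0.0, upper_bound=1000.0,
            name="glycogen sink exchange", is_exchange=True))
        genes.add("glgC")

    rng = random.Random(p.seed)
    rng.shuffle(mets)
    rng.shuffle(rxns)
    model = MetabolicModel(
        id="toy_photoautotroph",
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        biomass_reaction_id="BIOMASS",
        photon_exchange_id="EX_photon",
        carbon_exchange_id="EX_co2",
    )
    model.validate()
    manifest = {
        "model_id": model.id,
        "params": asdict(p),
        "closed_form": closed_form_optima(p),
        "notes": (
            "q_pdo_max/q_glycerol_max refer to the toy grafted with the "
            "default 1,3-PDO pathway, both cofactors mapped to nadph"
        ),
    }
    return model, manifest


def default_toy_rates() -> ExperimentalRates:
    """Measured-rate stand-in used by the toy end-to-end pipeline."""
    return ExperimentalRates(mu=0.1, q_pdo=0.03, q_glycerol=0.05)


def generate_count_stub(n_genes: int, n_reactions: int,
                        n_metabolites: int) -> MetabolicModel:
    """A structurally trivial model with exactly the requested counts.

    Reaction 0 is a biomass-like sink on the first metabolite; every other
    reaction is an exchange.  All genes hang off reaction 0 in a no-op OR
    association so deletions never disable anything.
    """
    if n_reactions < 1 or n_metabolites < 1:
        raise ModelValidationError(
            "count stub needs at least 1 reaction and 1 metabolite"
        )
    if n_genes < 0:
        raise ModelValidationError("n_genes must be >= 0")
    mets = [Metabolite(f"M{i:04d}", f"stub metabolite {i}")
            for i in range(n_metabolites)]
    genes = [f"g{i:04d}" for i in range(n_genes)]
    gpr = parse_gpr(" or ".join(genes)) if genes else parse_gpr("")
    rxns = [Reaction("R0000", {mets[0].id: -1.0},
                     lower_bound=0.0, upper_bound=1000.0,
                     gpr=gpr, name="stub biomass sink")]
    for i in range(1, n_reactions):
        met = mets[i % n_metabolites]
        rxns.append(Reaction(f"R{i:04d}", {met.id: -1.0},
                             lower_bound=-1000.0, upper_bound=1000.0,
                             name=f"stub exchange {i}", is_exchange=True))
    model = MetabolicModel(
        id=f"stub_{n_genes}g_{n_reactions}r_{n_metabolites}m",
        metabolites=mets,
        reactions=rxns,
        genes=set(genes),
        biomass_reaction_id="R0000",
    )
    model.validate()
    return model
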
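"""Grafting a synthetic pathway onto a base model.

The default spec is the heterologous 1,3-propanediol route: four enzymatic
steps DHAP -> glycerol-3-P -> glycerol -> 3-hydroxypropionaldehyde ->
1,3-PDO plus glycerol and 1,3-PDO exchanges, carried by 8 genes.  The
glycerol-dehydratase step (with its reactivase) is a multi-subunit complex
and carries an AND-type GPR, so knocking out any one subunit abolishes
1,3-PDO synthesis while glycerol export remains possible.

A PathwaySpec is plain data (serializable in the native JSON dialect): a
user holding the real genome-scale model can override every id, cofactor
and coefficient to match its exact composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import (
    GprExpression,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_gpr,
)


@dataclass
class PathwaySpec:
    """Metabolites, reactions and genes to graft onto a base model."""

    tag: str
    new_metabolites: list = field(default_factory=list)
    new_reactions: list = field(default_factory=list)
    new_genes: set = field(default_factory=set)
    #: role ids the augmented model should expose, e.g.
    #: {"pdo_exchange_id": "EX_pdo13"}
    role_ids: dict = field(default_factory=dict)

    def validate_against(self, base: MetabolicModel) -> None:
        base_mets = set(base.metabolite_ids)
        base_rxns = set(base.reaction_ids)
        collisions = sorted(
            {m.id for m in self.new_metabolites} & base_mets
            | {r.id for r in self.new_reactions} & base_rxns
            | (self.new_genes & base.genes)
        )
        if collisions:
            raise ModelValidationError(
                f"pathway {self.tag!r} collides with base model ids: {collisions}"
            )
        known = base_mets | {m.id for m in self.new_metabolites}
        allowed_genes = self.new_genes | base.genes
        for r in self.new_reactions:
            dangling = set(r.stoichiometry) - known
            if dangling:
                raise ModelValidationError(
                    f"pathway reaction {r.id} references unknown metabolites "
                    f"{sorted(dangling)}"
                )
            orphan = r.gpr.genes() - allowed_genes
            if orphan:
                raise ModelValidationError(
                    f"pathway reaction {r.id} GPR references unknown genes "
                    f"{sorted(orphan)}"
                )

    def sizes(self) -> tuple:
        """(n_genes, n_reactions, n_metabolites) added by this spec."""
        return (len(self.new_genes), len(self.new_reactions),
                len(self.new_metabolites))


def augment_model(base: MetabolicModel, spec: PathwaySpec) -> MetabolicModel:
    """Return a new model with the pathway grafted on; the base is untouched.

    Counts increase by exactly the spec sizes, every base-feasible flux
    state remains feasible with zero flux on the new reactions, and the
    pathway genes are recorded in ``pathway_genes`` so the gene-deletion
    screen can exclude them.
    """
    spec.validate_against(base)
    out = base.copy()
    out.id = f"{base.id}_{spec.tag}" if spec.tag else base.id
    out.metabolites = list(out.metabolites) + list(spec.new_metabolites)
    out.reactions = list(out.reactions) + [r.copy() for r in spec.new_reactions]
    out.genes = set(out.genes) | set(spec.new_genes)
    out.pathway_genes = set(out.pathway_genes) | set(spec.new_genes)
    for attr, rid in spec.role_ids.items():
        setattr(out, attr, rid)
    out.__post_init__()  # rebuild indices
    out.validate()
    return out


#: the 8 genes of the default 1,3-PDO pathway
PDO_PATHWAY_GENES = (
    "gpd1", "hor2", "dhaB1", "dhaB2", "dhaB3", "gdrA", "gdrB", "yqhD",
)
#: AND-type GPR of the glycerol dehydratase + reactivase complex
DEHYDRATASE_GPR = "dhaB1 and dhaB2 and dhaB3 and gdrA and gdrB"


def default_pdo_pathway_spec(dhap_id: str = "dhap",
                             g3p_id: str = "g3p",
                             gpd_cofactor_id: Optional[str] = None,
                             reductase_cofactor_id: Optional[str] = None,
                             tag: str = "pdo") -> PathwaySpec:
    """The default 8-gene / 6-reaction / 3-metabolite 1,3-PDO pathway.

    ``dhap_id`` and ``g3p_id`` name the base model's dihydroxyacetone
    phosphate and glycerol-3-phosphate species (the graft anchors; both must
    exist in the base, which is validated at augmentation time).  The three
    genuinely new metabolites are glycerol, 3-HPA and 1,3-PDO.  Cofactor ids
    (reductant for the G3P-dehydrogenase and YqhD-reductase steps) are
    optional: when None, those steps are modeled cofactor-free, which keeps
    count-stub augmentation valid; the toy photoautotroph maps both onto its
    lumped NADPH pool.
    """
    if not dhap_id:
        raise ModelValidationError("default PDO pathway needs a DHAP mapping")
    if not g3p_id:
        raise ModelValidationError("default PDO pathway needs a glycerol-3-P mapping")

    glycerol = Metabolite("glyc__pdo", "glycerol", "c")
    hpa = Metabolite("3hpa__pdo", "3-hydroxypropionaldehyde", "c")
    pdo = Metabolite("pdo13__pdo", "1,3-propanediol", "c")

    def _stoich(base_stoich, cofactor):
        s = dict(base_stoich)
        if cofactor:
            s[cofactor] = s.get(cofactor, 0.0) - 1.0
        return s

    reactions = [
        Reaction(
            id="PDO_GPD",
            name="glycerol-3-phosphate dehydrogenase (Gpd1)",
            stoichiometry=_stoich({dhap_id: -1.0, g3p_id: 1.0}, gpd_cofactor_id),
            lower_bound=0.0, upper_bound=1000.0,
            gpr=parse_gpr("gpd1"),
        ),
        Reaction(
            id="PDO_G3PP",
            name="glycerol-3-phosphatase (Hor2)",
            stoichiometry={g3p_id: -1.0, glycerol.id: 1.0},
            lower_bound=0.0, upper_bound=1000.0,
            gpr=parse_gpr("hor2"),
        ),
        Reaction(
            id="PDO_DHAT",
            name="glycerol dehydratase complex (DhaB123 + GdrAB)",
            stoichiometry={glycerol.id: -1.0, hpa.id: 1.0},
            lower_bound=0.0, upper_bound=1000.0,
            gpr=parse_gpr(DEHYDRATASE_GPR),
        ),
        Reaction(
            id="PDO_YQHD",
            name="1,3-propanediol oxidoreductase (YqhD)",
            stoichiometry=_stoich({hpa.id: -1.0, pdo.id: 1.0},
                                  reductase_cofactor_id),
            lower_bound=0.0, upper_bound=1000.0,
            gpr=parse_gpr("yqhD"),
        ),
        Reaction(
            id="EX_glyc__pdo",
            name="glycerol exchange",
            stoichiometry={glycerol.id: -1.0},
            lower_bound=0.0, upper_bound=1000.0,
            is_exchange=True,
        ),
        Reaction(
            id="EX_pdo13__pdo",
            name="1,3-propanediol exchange",
            stoichiometry={pdo.id: -1.0},
            lower_bound=0.0, upper_bound=1000.0,
            is_exchange=True,
        ),
    ]
    return PathwaySpec(
        tag=tag,
        new_metabolites=[glycerol, hpa, pdo],
        new_reactions=reactions,
        new_genes=set(PDO_PATHWAY_GENES),
        role_ids={
            "pdo_exchange_id": "EX_pdo13__pdo",
            "glycerol_exchange_id": "EX_glyc__pdo",
        },
    )
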
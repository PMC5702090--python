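"""Core data model for stoichiometric metabolic networks.

Metabolites, bounded reactions, gene-protein-reaction (GPR) boolean
associations, the sparse stoichiometric matrix, and steady-state checks.
Flux units are mmol/(g DCW)/h throughout; the biomass flux is 1/h.

Sign conventions
----------------
Exchange reactions are written ``metabolite -> (nothing)`` so that uptake is
a *negative* exchange flux and secretion is positive.  Functions that report
"input fluxes" (carbon fixation, photon use) return uptake magnitudes, i.e.
positive numbers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

#: Default steady-state tolerance (max-norm of S.v).
STEADY_STATE_TOL = 1e-6
#: Fluxes below this magnitude are clipped to zero for pattern comparison.
FLUX_ZERO_CLIP = 1e-9
#: Default bound magnitude when a model file omits bounds.
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A model (or model fragment) violates a structural invariant."""


class GprParseError(ValueError):
    """Raised on malformed GPR strings; message names the offending position."""


# ---------------------------------------------------------------------------
# GPR boolean algebra
# ---------------------------------------------------------------------------

class GprExpression:
    """Base class for GPR trees: leaf gene, AND over subunits, OR over isozymes.

    The empty expression (:class:`GprEmpty`) denotes "no gene requirement";
    such reactions can never be disabled by gene deletion.
    """

    def evaluate(self, deleted: frozenset | set) -> bool:
        raise NotImplementedError

    def genes(self) -> frozenset:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def is_empty(self) -> bool:
        return isinstance(self, GprEmpty)

    def __eq__(self, other):
        return type(self) is type(other) and self._key() == other._key()

    def __hash__(self):
        return hash((type(self).__name__, self._key()))

    def _key(self):
        raise NotImplementedError

    def __repr__(self):
        return f"{type(self).__name__}({self.to_string()!r})"


class GprEmpty(GprExpression):
    """No gene association: the reaction is always active."""

    def evaluate(self, deleted):
        return True

    def genes(self):
        return frozenset()

    def to_string(self):
        return ""

    def _key(self):
        return ()


class GprLeaf(GprExpression):
    def __init__(self, gene: str):
        if not gene:
            raise GprParseError("empty gene id in GPR leaf")
        self.gene = gene

    def evaluate(self, deleted):
        return self.gene not in deleted

    def genes(self):
        return frozenset({self.gene})

    def to_string(self):
        return self.gene

    def _key(self):
        return self.gene


class _GprNode(GprExpression):
    _op = ""

    def __init__(self, children: Sequence[GprExpression]):
        children = tuple(children)
        if len(children) < 2:
            raise GprParseError(f"{self._op.upper()} node needs >= 2 children")
        self.children = children

    def genes(self):
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self):
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, _GprNode):
                s = f"({s})"
            parts.append(s)
        return f" {self._op} ".join(parts)

    def _key(self):
        return self.children


class GprAnd(_GprNode):
    """Protein complex: every subunit gene must be present."""

    _op = "and"

    def evaluate(self, deleted):
        return all(c.evaluate(deleted) for c in self.children)


class GprOr(_GprNode):
    """Isozymes: any one branch suffices."""

    _op = "or"

    def evaluate(self, deleted):
        return any(c.evaluate(deleted) for c in self.children)


_GPR_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(text: str):
    pos = 0
    tokens = []
    while pos < len(text):
        m = _GPR_TOKEN.match(text, pos)
        if m is None:
            break
        tok = m.group(1)
        tokens.append((tok, m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: Optional[str]) -> GprExpression:
    """Parse a GPR string ("(g1 and g2) or g3") into a normalized tree.

    Keywords ``and``/``or`` are case-insensitive; gene ids are any other
    non-parenthesis tokens.  Blank or ``None`` input yields the empty
    expression.  Nested nodes of the same operator are flattened so the
    result is a canonical two-level-per-operator tree.
    """
    if text is None or not text.strip():
        return GprEmpty()
    tokens = _tokenize_gpr(text)
    expr, idx = _parse_or(tokens, 0, text)
    if idx != len(tokens):
        tok, pos = tokens[idx]
        raise GprParseError(f"unexpected token {tok!r} at position {pos}")
    return expr


def _parse_or(tokens, idx, text):
    expr, idx = _parse_and(tokens, idx, text)
    parts = [expr]
    while idx < len(tokens) and tokens[idx][0].lower() == "or":
        idx += 1
        nxt, idx = _parse_and(tokens, idx, text)
        parts.append(nxt)
    return _flatten(GprOr, parts), idx


def _parse_and(tokens, idx, text):
    expr, idx = _parse_primary(tokens, idx, text)
    parts = [expr]
    while idx < len(tokens) and tokens[idx][0].lower() == "and":
        idx += 1
        nxt, idx = _parse_primary(tokens, idx, text)
        parts.append(nxt)
    return _flatten(GprAnd, parts), idx


def _parse_primary(tokens, idx, text):
    if idx >= len(tokens):
        raise GprParseError(f"dangling operator at end of {text!r}")
    tok, pos = tokens[idx]
    if tok == "(":
        expr, idx = _parse_or(tokens, idx + 1, text)
        if idx >= len(tokens) or tokens[idx][0] != ")":
            raise GprParseError(f"unbalanced parenthesis opened at position {pos}")
        return expr, idx + 1
    if tok == ")":
        raise GprParseError(f"unmatched ')' at position {pos}")
    if tok.lower() in ("and", "or"):
        raise GprParseError(f"dangling operator {tok!r} at position {pos}")
    return GprLeaf(tok), idx + 1


def _flatten(cls, parts):
    if len(parts) == 1:
        return parts[0]
    flat = []
    for p in parts:
        if isinstance(p, cls):
            flat.extend(p.children)
        else:
            flat.append(p)
    return cls(flat)


def evaluate_gpr(expr: GprExpression, deleted: Iterable[str]) -> bool:
    """True iff the reaction remains catalyzed when ``deleted`` genes are gone.

    A leaf is active iff its gene is not deleted; AND is conjunction (one
    missing subunit disables the whole complex), OR is disjunction (an
    isozyme rescues); the empty expression is always active.
    """
    return expr.evaluate(frozenset(deleted))


# ---------------------------------------------------------------------------
# Metabolites / reactions / model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and a GPR association.

    Stoichiometric coefficients are negative for consumed metabolites and
    positive for produced ones.  Non-integer coefficients (e.g. a RubisCO
    lumped with photorespiration yielding 1.97 3-PG per RuBP) are stored as
    plain floats.
    """

    id: str
    stoichiometry: dict
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GprExpression = field(default_factory=GprEmpty)
    name: str = ""
    is_exchange: bool = False

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"exchange reaction {self.id} must touch exactly one metabolite"
            )

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            name=self.name,
            is_exchange=self.is_exchange,
        )


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) stoichiometric model.

    ``biomass_reaction_id`` must resolve to a reaction; the optional role
    ids (photon/carbon/product exchanges) may be absent before pathway
    augmentation.  ``pathway_genes`` records genes grafted by
    :func:`pdoflux.pathway.augment_model` so the deletion screen can exclude
    them.
    """

    id: str
    metabolites: list
    reactions: list
    genes: set
    biomass_reaction_id: str = ""
    photon_exchange_id: Optional[str] = None
    carbon_exchange_id: Optional[str] = None
    pdo_exchange_id: Optional[str] = None
    glycerol_exchange_id: Optional[str] = None
    pathway_genes: set = field(default_factory=set)

    def __post_init__(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookup helpers -----------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def reaction_ids(self):
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self):
        return [m.id for m in self.metabolites]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=set(self.genes),
            biomass_reaction_id=self.biomass_reaction_id,
            photon_exchange_id=self.photon_exchange_id,
            carbon_exchange_id=self.carbon_exchange_id,
            pdo_exchange_id=self.pdo_exchange_id,
            glycerol_exchange_id=self.glycerol_exchange_id,
            pathway_genes=set(self.pathway_genes),
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise ModelValidationError."""
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id} references unknown metabolites {sorted(missing)}"
                )
            orphan = r.gpr.genes() - self.genes
            if orphan:
                raise ModelValidationError(
                    f"reaction {r.id} GPR references undeclared genes {sorted(orphan)}"
                )
        if self.biomass_reaction_id and self.biomass_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"biomass_reaction_id {self.biomass_reaction_id!r} does not resolve"
            )
        for attr in ("photon_exchange_id", "carbon_exchange_id",
                     "pdo_exchange_id", "glycerol_exchange_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self._rxn_index:
                raise ModelValidationError(f"{attr} {rid!r} does not resolve")

    def counts(self) -> tuple:
        """(n_genes, n_reactions, n_metabolites)."""
        return (len(self.genes), len(self.reactions), len(self.metabolites))


# ---------------------------------------------------------------------------
# Gene deletion -> reaction disabling
# ---------------------------------------------------------------------------

def reactions_disabled_by(model: MetabolicModel, deleted: Iterable[str]) -> frozenset:
    """Reaction ids whose GPR evaluates False once ``deleted`` genes are gone.

    Two subunit genes of the same AND complex yield identical disabled sets,
    which is the precondition for collapsing deletion simulations into flux
    patterns.
    """
    deleted = frozenset(deleted)
    unknown = deleted - model.genes
    if unknown:
        raise KeyError(f"unknown gene ids: {sorted(unknown)}")
    if not deleted:
        return frozenset()
    return frozenset(
        r.id for r in model.reactions if not r.gpr.evaluate(deleted)
    )


# ---------------------------------------------------------------------------
# Stoichiometric matrix and steady state
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> sp.csr_matrix:
    """Sparse S (metabolites x reactions); S[i, j] = coefficient of
    metabolite i in reaction j."""
    rows, cols, data = [], [], []
    for j, r in enumerate(model.reactions):
        for met_id, coef in r.stoichiometry.items():
            rows.append(model._met_index[met_id])
            cols.append(j)
            data.append(float(coef))
    return sp.csr_matrix(
        (data, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )


@dataclass
class FluxState:
    """A flux vector over all reactions of a model.

    ``residual_norm`` is the max-norm of S.v recorded when the state was
    produced; states straight from the LP/QP layer satisfy it to solver
    tolerance.
    """

    flux: dict
    residual_norm: float = 0.0

    def vector(self, model: MetabolicModel) -> np.ndarray:
        missing = [r.id for r in model.reactions if r.id not in self.flux]
        if missing:
            raise KeyError(f"flux state missing reactions: {missing}")
        return np.array([self.flux[r.id] for r in model.reactions], dtype=float)

    def clipped(self, tol: float = FLUX_ZERO_CLIP) -> "FluxState":
        """Copy with |v| < tol set to exactly 0 (for pattern comparison)."""
        return FluxState(
            flux={k: (0.0 if abs(v) < tol else v) for k, v in self.flux.items()},
            residual_norm=self.residual_norm,
        )


@dataclass(frozen=True)
class SteadyStateReport:
    max_residual: float
    ok: bool
    worst_metabolite: Optional[str]
    tol: float


def flux_state_from_vector(model: MetabolicModel, v: np.ndarray,
                           residual_norm: float = 0.0) -> FluxState:
    return FluxState(
        flux={r.id: float(v[j]) for j, r in enumerate(model.reactions)},
        residual_norm=residual_norm,
    )


def check_steady_state(model: MetabolicModel, state: FluxState,
                       tol: float = STEADY_STATE_TOL) -> SteadyStateReport:
    """Max-norm of S.v with pass/fail against ``tol``.

    Steady state (zero net accumulation for every internal metabolite) is
    the central FBA constraint; exchange reactions provide the open system
    boundary so a balanced model can still run net fluxes.
    """
    v = state.vector(model)
    S = stoichiometric_matrix(model)
    residual = S.dot(v)
    if residual.size == 0:
        return SteadyStateReport(0.0, True, None, tol)
    worst = int(np.argmax(np.abs(residual)))
    max_res = float(np.abs(residual[worst]))
    return SteadyStateReport(
        max_residual=max_res,
        ok=max_res <= tol,
        worst_metabolite=model.metabolites[worst].id,
        tol=tol,
    )
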
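"""Metabolic model input/output, validation and harmonisation.

Models are genome-scale (or toy) stoichiometric networks with flux bounds, a
biomass objective and a set of exchange reactions.  The in-memory
representation is a lightweight :class:`MetabolicModel` that mirrors the
standard constraint-based structure (stoichiometric matrix ``A`` of size
m x n, objective weights ``c``, bounds ``v_l``/``v_u``) and converts to and
from :class:`cobra.Model` for SBML/JSON serialisation and LP solving.

Sign convention throughout the package: for an exchange reaction with
stoichiometry ``{met_e: -1}``, negative flux is uptake from the shared
extracellular pool and positive flux is secretion into it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import cobra
from cobra.util.solver import OptimizationError

from .environments import Medium

__all__ = [
    "GrowthResult",
    "MetabolicModel",
    "Metabolite",
    "ModelValidationError",
    "NamespaceMap",
    "Reaction",
    "check_model_growth",
    "from_cobra",
    "harmonize_extracellular",
    "read_model",
    "to_cobra",
    "write_model",
]

logger = logging.getLogger(__name__)

#: Suffix identifying extracellular metabolites (BiGG convention).
EXTRACELLULAR_SUFFIX = "_e"

#: Oxygen requirement flags consulted by the screening layer.
FACULTATIVE = "facultative"
OBLIGATE_AEROBE = "obligate_aerobe"
OBLIGATE_ANAEROBE = "obligate_anaerobe"
OXYGEN_REQUIREMENTS = (FACULTATIVE, OBLIGATE_AEROBE, OBLIGATE_ANAEROBE)


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class NoBiomassObjectiveError(ModelValidationError):
    """Raised when a model declares no biomass objective."""


@dataclass
class Metabolite:
    id: str
    compartment: str
    formula: str = ""
    name: str = ""

    @property
    def molar_mass(self) -> float | None:
        """Molar mass in g/mmol-compatible g/mol units, from the formula."""
        if not self.formula:
            return None
        met = cobra.Metabolite(self.id, formula=self.formula)
        weight = met.formula_weight
        if weight is None or (isinstance(weight, float) and math.isnan(weight)):
            return None
        return float(weight)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    name: str = ""

    @property
    def is_boundary(self) -> bool:
        """Structurally boundary-shaped: one metabolite with coefficient -1.

        Whether it is an *exchange* additionally requires the metabolite to
        be extracellular (see :meth:`MetabolicModel.exchange_ids`); demand
        or maintenance reactions on intracellular metabolites share this
        shape but are not exchanges.
        """
        if len(self.stoichiometry) != 1:
            return False
        (coeff,) = self.stoichiometry.values()
        return coeff == -1


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds and a biomass objective."""

    model_id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_reaction_id: str = ""
    oxygen_requirement: str = FACULTATIVE

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_ids(self) -> set[str]:
        """Reactions moving exactly one extracellular metabolite across the
        pool boundary with coefficient -1 (negative flux = uptake)."""
        compartments = {m.id: m.compartment for m in self.metabolites}
        out = set()
        for rxn in self.reactions:
            if not rxn.is_boundary:
                continue
            (met_id,) = rxn.stoichiometry
            if _is_extracellular(met_id, compartments.get(met_id, "")):
                out.add(rxn.id)
        return out

    def metabolite(self, met_id: str) -> Metabolite:
        for met in self.metabolites:
            if met.id == met_id:
                return met
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)

    def exchange_metabolite(self, rxn_id: str) -> str:
        """Pool-facing metabolite id of an exchange reaction."""
        rxn = self.reaction(rxn_id)
        if not rxn.is_boundary:
            raise ModelValidationError(f"{rxn_id} is not an exchange reaction")
        (met_id,) = rxn.stoichiometry
        return met_id

    def extracellular_ids(self, suffix: str = EXTRACELLULAR_SUFFIX) -> set[str]:
        return {
            self.exchange_metabolite(rxn_id)
            for rxn_id in self.exchange_ids
            if self.exchange_metabolite(rxn_id).endswith(suffix)
        }

    def molar_masses(self) -> dict[str, float]:
        """Molar masses (g/mol) for all metabolites with parseable formulas."""
        out: dict[str, float] = {}
        for met in self.metabolites:
            mass = met.molar_mass
            if mass is not None:
                out[met.id] = mass
        return out

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.oxygen_requirement not in OXYGEN_REQUIREMENTS:
            raise ModelValidationError(
                f"{self.model_id}: unknown oxygen requirement "
                f"{self.oxygen_requirement!r}"
            )
        declared = self.metabolite_ids
        if len(declared) != len(self.metabolites):
            raise ModelValidationError(f"{self.model_id}: duplicate metabolite ids")
        seen: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelValidationError(
                    f"{self.model_id}: duplicate reaction id {rxn.id}"
                )
            seen.add(rxn.id)
            missing = set(rxn.stoichiometry) - declared
            if missing:
                raise ModelValidationError(
                    f"{self.model_id}: reaction {rxn.id} references undeclared "
                    f"metabolites {sorted(missing)}"
                )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"{self.model_id}: reaction {rxn.id} has lower_bound > upper_bound"
                )
        if not self.objective_reaction_id:
            raise NoBiomassObjectiveError(
                f"model {self.model_id} has no biomass objective"
            )
        if self.objective_reaction_id not in seen:
            raise NoBiomassObjectiveError(
                f"model {self.model_id}: objective reaction "
                f"{self.objective_reaction_id!r} not found (no biomass objective)"
            )


# ---------------------------------------------------------------------------
# cobra conversion and serialisation
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel) -> cobra.Model:
    cm = cobra.Model(model.model_id)
    mets = {
        m.id: cobra.Metabolite(
            m.id, formula=m.formula or None, name=m.name or m.id,
            compartment=m.compartment,
        )
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        rxn = cobra.Reaction(r.id, name=r.name or r.id,
                             lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(rxn)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[met_id]: coeff for met_id, coeff in r.stoichiometry.items()}
        )
    cm.objective = model.objective_reaction_id
    return cm


def from_cobra(cm: cobra.Model,
               oxygen_requirement: str = FACULTATIVE) -> MetabolicModel:
    objective_id = ""
    for rxn in cm.reactions:
        if rxn.objective_coefficient:
            if objective_id:
                raise ModelValidationError(
                    f"model {cm.id}: multiple objective reactions"
                )
            objective_id = rxn.id
    metabolites = [
        Metabolite(m.id, compartment=m.compartment or _infer_compartment(m.id),
                   formula=m.formula or "", name=m.name or "")
        for m in cm.metabolites
    ]
    reactions = [
        Reaction(
            r.id,
            {m.id: coeff for m, coeff in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            name=r.name or "",
        )
        for r in cm.reactions
    ]
    return MetabolicModel(
        model_id=cm.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=objective_id,
        oxygen_requirement=oxygen_requirement,
    )


def _infer_compartment(met_id: str) -> str:
    return met_id.rsplit("_", 1)[-1] if "_" in met_id else ""


def _is_extracellular(met_id: str, compartment: str) -> bool:
    return (
        met_id.endswith(EXTRACELLULAR_SUFFIX)
        or compartment.removeprefix("C_") == "e"
        or compartment == "extracellular"
    )


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        if fmt not in ("sbml", "json"):
            raise ValueError(f"unknown model format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def read_model(path: str | Path, format: str | None = None,
               oxygen_requirement: str = FACULTATIVE) -> MetabolicModel:
    """Read an SBML (Level 3 FBC) or BiGG-style JSON model.

    Exchange reactions are auto-detected as reactions touching exactly one
    metabolite.  Raises :class:`NoBiomassObjectiveError` if the model
    declares no objective, and a format error naming the file on parse
    failure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    try:
        if fmt == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            cm = cobra.io.load_json_model(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ModelValidationError(f"failed to parse {fmt} model {path}: {exc}") from exc
    return from_cobra(cm, oxygen_requirement=oxygen_requirement)


def write_model(model: MetabolicModel, path: str | Path,
                format: str | None = None) -> None:
    path = Path(path)
    fmt = _detect_format(path, format)
    cm = to_cobra(model)
    if fmt == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        cobra.io.save_json_model(cm, str(path), sort=True)


# ---------------------------------------------------------------------------
# Namespace harmonisation
# ---------------------------------------------------------------------------

class NamespaceMap:
    """Per-model mapping from local extracellular metabolite ids to pool ids.

    The shared pool uses BiGG-style identifiers (e.g. ``glc__D_e``).  Each
    model's mapping must be injective; unmappable ids are carried through
    under their local id with a logged warning.
    """

    def __init__(self, per_model: Mapping[str, Mapping[str, str]]):
        self.per_model: dict[str, dict[str, str]] = {
            model_id: dict(mapping) for model_id, mapping in per_model.items()
        }
        for model_id, mapping in self.per_model.items():
            pool_ids = list(mapping.values())
            if len(set(pool_ids)) != len(pool_ids):
                dupes = sorted(
                    {p for p in pool_ids if pool_ids.count(p) > 1}
                )
                raise ModelValidationError(
                    f"model {model_id}: multiple metabolites map to pool ids {dupes}"
                )

    @property
    def pool_ids(self) -> set[str]:
        out: set[str] = set()
        for mapping in self.per_model.values():
            out.update(mapping.values())
        return out

    def to_pool(self, model_id: str, local_id: str) -> str:
        return self.per_model[model_id].get(local_id, local_id)


def harmonize_extracellular(
    models: Sequence[MetabolicModel],
    suffix: str = EXTRACELLULAR_SUFFIX,
    aliases: Mapping[str, str] | None = None,
) -> NamespaceMap:
    """Map every model's extracellular metabolites onto a shared pool.

    With BiGG-style identifiers the mapping is the identity; ``aliases`` can
    rename model-local ids (e.g. legacy namespaces) onto pool ids.  A model
    whose extracellular metabolites collide on one pool id is rejected.
    """
    if not models:
        raise ValueError("need at least one model to harmonise")
    aliases = dict(aliases or {})
    per_model: dict[str, dict[str, str]] = {}
    for model in models:
        ext = model.extracellular_ids(suffix=suffix)
        if not ext:
            logger.warning(
                "model %s has no extracellular metabolites with suffix %r; "
                "carrying exchange metabolites through under local ids",
                model.model_id, suffix,
            )
            ext = {
                model.exchange_metabolite(rxn_id) for rxn_id in model.exchange_ids
            }
        mapping = {}
        for met_id in sorted(ext):
            pool_id = aliases.get(met_id, met_id)
            if pool_id != met_id:
                logger.info("model %s: %s -> pool %s", model.model_id, met_id, pool_id)
            mapping[met_id] = pool_id
        per_model[model.model_id] = mapping
    return NamespaceMap(per_model)


# ---------------------------------------------------------------------------
# Growth QC gate
# ---------------------------------------------------------------------------

class GrowthResult(NamedTuple):
    growth_rate: float
    feasible: bool


def medium_uptake_bounds(
    model: MetabolicModel,
    medium: Medium,
    v_max: float = 20.0,
    k_m: float = 0.05,
) -> dict[str, float]:
    """Static per-exchange uptake limits implied by a medium (mmol/gDW/h).

    Saturable transport at the medium's initial concentrations; metabolites
    absent from the medium get a zero uptake bound.
    """
    bounds: dict[str, float] = {}
    for rxn_id in model.exchange_ids:
        met_id = model.exchange_metabolite(rxn_id)
        s = medium.get(met_id)
        bounds[rxn_id] = v_max * s / (k_m + s) if s > 0 else 0.0
    return bounds


def check_model_growth(model: MetabolicModel, medium: Medium,
                       v_max: float = 20.0, k_m: float = 0.05) -> GrowthResult:
    """Optimal biomass flux of the static FBA LP under medium-implied bounds.

    Returns ``GrowthResult(0.0, feasible=False)`` when the LP is infeasible
    (e.g. an unsatisfiable maintenance demand), which is distinct from a
    feasible optimum of zero growth.
    """
    cm = to_cobra(model)
    bounds = medium_uptake_bounds(model, medium, v_max=v_max, k_m=k_m)
    for rxn_id, bound in bounds.items():
        rxn = cm.reactions.get_by_id(rxn_id)
        rxn.lower_bound = -bound
    try:
        mu = cm.slim_optimize(error_value=None)
    except OptimizationError:
        mu = None
    if mu is None or math.isnan(mu):
        status = cm.solver.status
        if status == "infeasible":
            return GrowthResult(0.0, feasible=False)
        raise RuntimeError(
            f"solver failure for model {model.model_id}: status {status}"
        )
    return GrowthResult(max(float(mu), 0.0), feasible=True)


def eligible_for_regime(model: MetabolicModel, oxygen_regime: str) -> bool:
    """Whether a model may be simulated under the given oxygen regime.

    Obligate anaerobes are excluded from aerobic simulations and obligate
    aerobes from anaerobic ones; the flag is model metadata, not inferred
    from the network.
    """
    if oxygen_regime == "aerobic":
        return model.oxygen_requirement != OBLIGATE_ANAEROBE
    return model.oxygen_requirement != OBLIGATE_AEROBE
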
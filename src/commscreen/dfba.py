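"""Dynamic FBA engine for N species sharing an extracellular metabolite pool.

The batch is simulated with the static-optimisation approach: time is
discretised into steps of length ``dt`` and, at every step, each species
independently solves a parsimonious FBA problem (maximise its own biomass
flux, then minimise total absolute flux at that optimum) under uptake bounds
derived from the current pool concentrations.  No collective community
objective exists; interactions emerge from competition for, and secretion
into, the shared pool.

Per-step substrate uptake bounds combine nutrient availability with
saturable (Michaelis-Menten) transport::

    v_s = min( S_j / (X_i * dt),  V_max * S_j / (K_m + S_j) )

with ``S_j`` the pool concentration (mmol/L), ``X_i`` the species biomass
(g/L), ``V_max`` in mmol/gDW/h and ``K_m`` in mmol/L.

State updates are forward Euler: ``X_i <- X_i * (1 + mu_i*dt)`` and
``S_j <- S_j + sum_i v_ij * X_i * dt`` (uptake negative, secretion
positive).  Because each species sizes its availability term by its own
biomass, aggregate demand can oversubscribe a pool metabolite; when that
happens the offending uptake bounds are tightened proportionally to each
species' realised share and the affected LPs are re-solved once, after which
residual negatives (within solver tolerance) are clipped to zero and logged.

Product formation is tracked on two ledgers.  The pool ledger evolves from
the parsimonious solutions' actual secretion fluxes.  The production
*potential* ledger ``P`` accrues, per species and product, the maximum
product-exchange flux found by a per-step flux variability analysis with the
biomass flux held at a fraction (default 0.999) of the step optimum::

    P_k_i <- P_k_i + v_p_k * X_i * dt
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import cobra
import pandas as pd
from cobra.util.solver import OptimizationError

from .environments import Medium
from .model_io import (
    MetabolicModel,
    NamespaceMap,
    _is_extracellular,
    harmonize_extracellular,
    to_cobra,
)

__all__ = [
    "CommunityState",
    "CommunityTrajectory",
    "FeedEvent",
    "FeedSpec",
    "SimulationConfig",
    "SimulationError",
    "StepSolution",
    "UptakeKinetics",
    "abundances_from_biomass",
    "advance",
    "growth_step",
    "product_fva",
    "simulate",
    "simulate_fed_batch",
    "uptake_bound",
]

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    """Raised when a simulation cannot produce a usable trajectory."""


@dataclass(frozen=True)
class UptakeKinetics:
    """Saturable transport parameters, uniform unless overridden per metabolite."""

    v_max: float = 20.0  # mmol/gDW/h
    k_m: float = 0.05    # mmol/L
    overrides: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(self.v_max, self.k_m), *self.overrides.values()]
        for v_max, k_m in pairs:
            if v_max <= 0 or k_m <= 0:
                raise ValueError("V_max and K_m must be positive")

    def params_for(self, met_id: str | None) -> tuple[float, float]:
        if met_id is not None and met_id in self.overrides:
            return self.overrides[met_id]
        return self.v_max, self.k_m


@dataclass(frozen=True)
class SimulationConfig:
    """Time stepping, inoculation and solver settings for one simulation."""

    dt: float = 0.1                 # h
    horizon: float = 12.0           # h
    initial_biomass: float = 0.01   # g/L per species
    kinetics: UptakeKinetics = field(default_factory=UptakeKinetics)
    fva_growth_fraction: float = 0.999
    averaging_window: int = 5       # feasible time points averaged at the end
    lp_tolerance: float = 1e-9
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon < self.dt:
            raise ValueError("horizon must be at least one step")
        if self.initial_biomass <= 0:
            raise ValueError("initial biomass must be positive")
        if not 0 < self.fva_growth_fraction <= 1:
            raise ValueError("fva_growth_fraction must be in (0, 1]")
        if self.averaging_window < 1:
            raise ValueError("averaging_window must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon / self.dt))


@dataclass(frozen=True)
class FeedSpec:
    """Fed-batch rule: when watch_id falls below trigger, top up to target (g/L)."""

    watch_id: str
    trigger_g_per_l: float
    target_g_per_l: float
    molar_mass: float | None = None  # g/mol; taken from model formulas if None

    def __post_init__(self) -> None:
        if self.trigger_g_per_l >= self.target_g_per_l:
            raise ValueError("feed trigger must be below the feed target")


class FeedEvent(NamedTuple):
    t: float
    metabolite: str
    added_mmol_per_l: float


class ClipEvent(NamedTuple):
    t: float
    metabolite: str
    magnitude_mmol_per_l: float


@dataclass
class CommunityState:
    """Snapshot of the community at one time point."""

    t: float
    X: dict[str, float]
    S: dict[str, float]
    P: dict[tuple[str, str], float]  # (product exchange id, species) -> mmol/L
    mu: dict[str, float]
    feasible: dict[str, bool]

    @property
    def any_feasible(self) -> bool:
        return any(self.feasible.values())

    @property
    def total_biomass(self) -> float:
        return sum(self.X.values())


class StepSolution(NamedTuple):
    mu: float
    fluxes: dict[str, float]
    feasible: bool


@dataclass
class CommunityTrajectory:
    """Time series of a community simulation plus terminal summaries."""

    species: list[str]
    states: list[CommunityState]          # states[0] is the initial condition
    terminal_state: CommunityState        # averaged over the last feasible points
    abundances: dict[str, float]
    inoculum: dict[str, float]
    config: SimulationConfig
    products: tuple[str, ...]
    medium_name: str
    exchange_records: list[tuple[float, str, str, float]]  # t, species, pool id, flux
    feed_events: list[FeedEvent] = field(default_factory=list)
    clip_events: list[ClipEvent] = field(default_factory=list)

    @property
    def exchange_fluxes(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.exchange_records,
            columns=["t", "species", "metabolite", "flux_mmol_per_gdw_h"],
        )

    def terminal_biomass(self, species: str) -> float:
        return self.terminal_state.X[species]

    def growth_fold(self, species: str) -> float:
        """Relative biomass increase over the inoculum, (X_T - X_0)/X_0."""
        x0 = self.inoculum[species]
        return (self.terminal_state.X[species] - x0) / x0

    def terminal_growth_rate(self, species: str) -> float:
        return self.terminal_state.mu[species]

    def product_amount(self, product_id: str, species: str | None = None) -> float:
        """Terminal averaged cumulative production potential (mmol/L)."""
        if product_id not in self.products:
            raise KeyError(f"product {product_id!r} was not tracked")
        return sum(
            amount
            for (prod, sp), amount in self.terminal_state.P.items()
            if prod == product_id and (species is None or sp == species)
        )

    def net_exchange(self, species: str, metabolite: str) -> float:
        """Net integrated exchange of a pool metabolite by one species (mmol/L).

        Positive values are net secretion into the pool, negative net
        consumption, integrated with the biomass at the time of each flux.
        """
        dt = self.config.dt
        total = 0.0
        x_at = {round(s.t, 9): s.X for s in self.states}
        for t, sp, met, flux in self.exchange_records:
            if sp != species or met != metabolite:
                continue
            x = x_at[round(t, 9)][species]
            total += flux * x * dt
        return total

    def tidy(self) -> pd.DataFrame:
        """Long-format time series: time, species, variable, value."""
        rows: list[tuple[float, str, str, float]] = []
        for state in self.states:
            for sp in self.species:
                rows.append((state.t, sp, "biomass_g_per_L", state.X[sp]))
                rows.append((state.t, sp, "growth_rate_per_h", state.mu[sp]))
            for met, conc in state.S.items():
                rows.append((state.t, "pool", f"conc_{met}", conc))
            for (prod, sp), amount in state.P.items():
                rows.append((state.t, sp, f"product_{prod}", amount))
        return pd.DataFrame(rows, columns=["t", "species", "variable", "value"])


# ---------------------------------------------------------------------------
# Per-step primitives
# ---------------------------------------------------------------------------

def abundances_from_biomass(biomass: Mapping[str, float]) -> dict[str, float]:
    """Relative abundance of each species: X_i over the community total."""
    total = sum(biomass.values())
    if total <= 0:
        raise ValueError("total biomass must be positive")
    return {sp: x / total for sp, x in biomass.items()}


def uptake_bound(s_j: float, x_i: float, dt: float,
                 kinetics: UptakeKinetics, met_id: str | None = None) -> float:
    """Substrate uptake limit (mmol/gDW/h): min of availability and transport."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if s_j <= 0 or x_i <= 0:
        return 0.0
    v_max, k_m = kinetics.params_for(met_id)
    availability = s_j / (x_i * dt)
    transport = v_max * s_j / (k_m + s_j)
    return min(availability, transport)


def _solve_parsimonious(cm: cobra.Model, objective_id: str) -> StepSolution:
    """Maximise biomass, then minimise total |flux| at the fixed optimum."""
    try:
        solution = cobra.flux_analysis.pfba(cm, fraction_of_optimum=1.0)
    except OptimizationError:
        return StepSolution(0.0, {}, False)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise SimulationError(
            f"solver failure on {cm.id}: {cm.solver.status}"
        ) from exc
    fluxes = solution.fluxes.to_dict()
    mu = max(float(fluxes.get(objective_id, 0.0)), 0.0)
    return StepSolution(mu, fluxes, True)


def growth_step(model: MetabolicModel | cobra.Model,
                medium_bounds: Mapping[str, float]) -> StepSolution:
    """One parsimonious FBA solve under per-exchange uptake limits.

    ``medium_bounds`` maps exchange reaction ids to non-negative uptake
    limits; they are applied as negative lower bounds.  Exchange reactions
    not listed are closed for uptake.  An infeasible LP yields
    ``StepSolution(0.0, {}, False)``.
    """
    cm, objective_id, exchange_ids = _as_cobra(model)
    for rxn_id in exchange_ids:
        bound = float(medium_bounds.get(rxn_id, 0.0))
        if bound < 0:
            raise ValueError(f"uptake bound for {rxn_id} must be non-negative")
        cm.reactions.get_by_id(rxn_id).lower_bound = -bound
    return _solve_parsimonious(cm, objective_id)


def _as_cobra(model: MetabolicModel | cobra.Model,
              ) -> tuple[cobra.Model, str, set[str]]:
    if isinstance(model, MetabolicModel):
        return to_cobra(model), model.objective_reaction_id, model.exchange_ids
    cm = model
    exchange_ids = {
        r.id for r in cm.reactions
        if len(r.metabolites) == 1
        and next(iter(r.metabolites.values())) == -1
        and _is_extracellular(next(iter(r.metabolites)).id,
                              next(iter(r.metabolites)).compartment or "")
    }
    return cm, _cobra_objective_id(cm), exchange_ids


def _cobra_objective_id(cm: cobra.Model) -> str:
    for rxn in cm.reactions:
        if rxn.objective_coefficient:
            return rxn.id
    raise SimulationError(f"model {cm.id} has no objective reaction")


def product_fva(model: MetabolicModel | cobra.Model,
                medium_bounds: Mapping[str, float],
                mu: float,
                product_id: str,
                growth_fraction: float = 0.999) -> float:
    """Maximum product exchange flux with biomass held near its optimum.

    Returns 0.0 if the product exchange is absent from the model or the
    growth-constrained LP is infeasible.
    """
    cm, objective_id, exchange_ids = _as_cobra(model)
    if product_id not in {r.id for r in cm.reactions}:
        return 0.0
    for rxn_id in exchange_ids:
        cm.reactions.get_by_id(rxn_id).lower_bound = -float(
            medium_bounds.get(rxn_id, 0.0)
        )
    return _product_fva_on(cm, objective_id, mu, product_id, growth_fraction)


def _product_fva_on(cm: cobra.Model, objective_id: str, mu: float,
                    product_id: str, growth_fraction: float) -> float:
    with cm:
        cm.reactions.get_by_id(objective_id).lower_bound = growth_fraction * mu
        cm.objective = product_id
        value = cm.slim_optimize(error_value=None)
    if value is None or math.isnan(value):
        return 0.0
    return float(value)


def advance(state: CommunityState,
            step_solutions: Mapping[str, StepSolution],
            fva_fluxes: Mapping[tuple[str, str], float],
            exchange_pool: Mapping[str, Mapping[str, str]],
            dt: float) -> tuple[CommunityState, list[ClipEvent]]:
    """Forward-Euler update of biomasses, pool concentrations and products.

    ``exchange_pool`` maps species -> exchange reaction id -> pool id.
    ``fva_fluxes`` maps (product exchange id, species) -> FVA flux.  Pool
    updates use the parsimonious solutions' exchange fluxes; the ``P``
    ledger accrues the FVA production potential.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    new_x = dict(state.X)
    new_s = dict(state.S)
    new_p = dict(state.P)
    new_mu = {}
    feasible = {}
    for species, sol in step_solutions.items():
        new_mu[species] = sol.mu
        feasible[species] = sol.feasible
        new_x[species] = state.X[species] * (1.0 + sol.mu * dt)
        for rxn_id, pool_id in exchange_pool[species].items():
            flux = sol.fluxes.get(rxn_id, 0.0)
            if flux:
                new_s[pool_id] = new_s.get(pool_id, 0.0) + flux * state.X[species] * dt
    for (product_id, species), flux in fva_fluxes.items():
        key = (product_id, species)
        new_p[key] = new_p.get(key, 0.0) + max(flux, 0.0) * state.X[species] * dt
    clips: list[ClipEvent] = []
    t_next = state.t + dt
    for met, conc in new_s.items():
        if conc < 0:
            clips.append(ClipEvent(t_next, met, -conc))
            new_s[met] = 0.0
    return (
        CommunityState(t=t_next, X=new_x, S=new_s, P=new_p,
                       mu=new_mu, feasible=feasible),
        clips,
    )


# ---------------------------------------------------------------------------
# Simulation loop
# ---------------------------------------------------------------------------

class _SpeciesLP:
    """Persistent per-species LP with pool-facing exchange bookkeeping."""

    def __init__(self, model: MetabolicModel, namespace: NamespaceMap):
        self.model = model
        self.id = model.model_id
        self.cm = to_cobra(model)
        self.objective_id = model.objective_reaction_id
        # exchange reaction id -> shared pool metabolite id
        self.exchange_pool: dict[str, str] = {
            rxn_id: namespace.to_pool(model.model_id, model.exchange_metabolite(rxn_id))
            for rxn_id in sorted(model.exchange_ids)
        }

    def set_bounds(self, bounds: Mapping[str, float]) -> None:
        for rxn_id in self.exchange_pool:
            self.cm.reactions.get_by_id(rxn_id).lower_bound = -float(
                bounds.get(rxn_id, 0.0)
            )

    def solve(self) -> StepSolution:
        return _solve_parsimonious(self.cm, self.objective_id)

    def fva(self, mu: float, product_id: str, growth_fraction: float) -> float:
        if product_id not in self.exchange_pool:
            return 0.0
        return _product_fva_on(self.cm, self.objective_id, mu, product_id,
                               growth_fraction)


def _step_bounds(lp: _SpeciesLP, s: Mapping[str, float], x_i: float,
                 config: SimulationConfig) -> dict[str, float]:
    bounds: dict[str, float] = {}
    for rxn_id, pool_id in lp.exchange_pool.items():
        conc = s.get(pool_id, 0.0)
        if conc <= config.lp_tolerance:
            bounds[rxn_id] = 0.0
        else:
            bounds[rxn_id] = uptake_bound(conc, x_i, config.dt,
                                          config.kinetics, pool_id)
    return bounds


def simulate(models: Sequence[MetabolicModel],
             medium: Medium,
             config: SimulationConfig | None = None,
             products: Sequence[str] = (),
             inoculum: Mapping[str, float] | None = None,
             feed: FeedSpec | None = None) -> CommunityTrajectory:
    """Run a community (or monoculture) batch simulation.

    A community of one is, by construction, identical to a monoculture run.
    ``products`` lists product exchange reaction ids whose production
    potential is tracked by per-step FVA.  ``inoculum`` overrides the
    uniform ``config.initial_biomass`` per species.  ``feed`` enables the
    fed-batch substrate top-up rule.
    """
    if not models:
        raise ValueError("need at least one model")
    config = config or SimulationConfig()
    namespace = harmonize_extracellular(list(models))
    lps = [_SpeciesLP(m, namespace) for m in models]
    species = [lp.id for lp in lps]
    if len(set(species)) != len(species):
        raise ValueError("duplicate model ids in community")

    inoculum = dict(inoculum or {})
    x0 = {sp: float(inoculum.get(sp, config.initial_biomass)) for sp in species}
    if any(v <= 0 for v in x0.values()):
        raise ValueError("all inocula must be positive")

    feed_mass = _feed_molar_mass(feed, models) if feed else None

    s = {met: float(conc) for met, conc in medium.concentrations.items()}
    products = tuple(products)
    state = CommunityState(
        t=0.0,
        X=dict(x0),
        S=dict(s),
        P={(prod, sp): 0.0 for prod in products for sp in species},
        mu={sp: 0.0 for sp in species},
        feasible={sp: True for sp in species},
    )
    states = [state]
    exchange_records: list[tuple[float, str, str, float]] = []
    feed_events: list[FeedEvent] = []
    clip_events: list[ClipEvent] = []
    exchange_pool = {lp.id: lp.exchange_pool for lp in lps}

    for _ in range(config.n_steps):
        bounds = {lp.id: _step_bounds(lp, state.S, state.X[lp.id], config)
                  for lp in lps}
        solutions: dict[str, StepSolution] = {}
        for lp in lps:
            lp.set_bounds(bounds[lp.id])
            solutions[lp.id] = lp.solve()

        solutions = _correct_oversubscription(
            lps, state, bounds, solutions, config, exchange_records
        )

        fva_fluxes: dict[tuple[str, str], float] = {}
        for lp in lps:
            sol = solutions[lp.id]
            if not sol.feasible:
                for product_id in products:
                    fva_fluxes[(product_id, lp.id)] = 0.0
                continue
            for product_id in products:
                fva_fluxes[(product_id, lp.id)] = lp.fva(
                    sol.mu, product_id, config.fva_growth_fraction
                )

        for lp in lps:
            sol = solutions[lp.id]
            for rxn_id, pool_id in lp.exchange_pool.items():
                flux = sol.fluxes.get(rxn_id, 0.0)
                if abs(flux) > config.lp_tolerance:
                    exchange_records.append((state.t, lp.id, pool_id, float(flux)))

        state, clips = advance(state, solutions, fva_fluxes, exchange_pool,
                               config.dt)
        clip_events.extend(clips)

        if feed is not None:
            conc_g_per_l = state.S.get(feed.watch_id, 0.0) * feed_mass / 1000.0
            if conc_g_per_l < feed.trigger_g_per_l:
                target_mmol = feed.target_g_per_l * 1000.0 / feed_mass
                added = target_mmol - state.S.get(feed.watch_id, 0.0)
                state.S[feed.watch_id] = target_mmol
                feed_events.append(FeedEvent(state.t, feed.watch_id, added))
                logger.info("feed event at t=%.2f h: +%.3f mmol/L %s",
                            state.t, added, feed.watch_id)
        states.append(state)

    feasible_states = [st for st in states[1:] if st.any_feasible]
    if not feasible_states:
        raise SimulationError(
            "no feasible time points: every species' LP failed at every step"
        )
    window = feasible_states[-config.averaging_window:]
    terminal = _average_states(window)
    if terminal.total_biomass > 0:
        abundances = abundances_from_biomass(terminal.X)
    else:  # pragma: no cover - inocula are positive, so the total stays > 0
        abundances = {sp: math.nan for sp in species}
    return CommunityTrajectory(
        species=species,
        states=states,
        terminal_state=terminal,
        abundances=abundances,
        inoculum=x0,
        config=config,
        products=products,
        medium_name=medium.name,
        exchange_records=exchange_records,
        feed_events=feed_events,
        clip_events=clip_events,
    )


def _correct_oversubscription(
    lps: list[_SpeciesLP],
    state: CommunityState,
    bounds: dict[str, dict[str, float]],
    solutions: dict[str, StepSolution],
    config: SimulationConfig,
    exchange_records: list,
) -> dict[str, StepSolution]:
    """Tighten uptake bounds proportionally where aggregate demand exceeds
    the pool, and re-solve the affected species once."""
    dt = config.dt
    demand: dict[str, float] = {}
    for lp in lps:
        sol = solutions[lp.id]
        for rxn_id, pool_id in lp.exchange_pool.items():
            flux = sol.fluxes.get(rxn_id, 0.0)
            if flux < 0:
                demand[pool_id] = demand.get(pool_id, 0.0) \
                    - flux * state.X[lp.id] * dt
    oversubscribed = {
        pool_id: state.S.get(pool_id, 0.0) / amount
        for pool_id, amount in demand.items()
        if amount > state.S.get(pool_id, 0.0) * (1.0 + 1e-9) + config.lp_tolerance
    }
    if not oversubscribed:
        return solutions
    to_resolve: set[str] = set()
    for lp in lps:
        sol = solutions[lp.id]
        changed = False
        for rxn_id, pool_id in lp.exchange_pool.items():
            if pool_id not in oversubscribed:
                continue
            flux = sol.fluxes.get(rxn_id, 0.0)
            if flux < 0:
                bounds[lp.id][rxn_id] = -flux * oversubscribed[pool_id]
                changed = True
        if changed:
            to_resolve.add(lp.id)
    logger.debug("oversubscription at t=%.2f h for %s; re-solving %s",
                 state.t, sorted(oversubscribed), sorted(to_resolve))
    new_solutions = dict(solutions)
    for lp in lps:
        if lp.id in to_resolve:
            lp.set_bounds(bounds[lp.id])
            new_solutions[lp.id] = lp.solve()
    return new_solutions


def _average_states(window: Sequence[CommunityState]) -> CommunityState:
    n = len(window)
    species = list(window[-1].X)
    mets = set()
    for st in window:
        mets.update(st.S)
    return CommunityState(
        t=sum(st.t for st in window) / n,
        X={sp: sum(st.X[sp] for st in window) / n for sp in species},
        S={met: sum(st.S.get(met, 0.0) for st in window) / n for met in mets},
        P={key: sum(st.P.get(key, 0.0) for st in window) / n
           for key in window[-1].P},
        mu={sp: sum(st.mu[sp] for st in window) / n for sp in species},
        feasible=dict(window[-1].feasible),
    )


def _feed_molar_mass(feed: FeedSpec, models: Sequence[MetabolicModel]) -> float:
    if feed.molar_mass is not None:
        return float(feed.molar_mass)
    for model in models:
        masses = model.molar_masses()
        if feed.watch_id in masses:
            return masses[feed.watch_id]
    raise ValueError(
        f"no molar mass known for feed metabolite {feed.watch_id!r}; "
        "add a formula to a model or set FeedSpec.molar_mass"
    )


def simulate_fed_batch(models: Sequence[MetabolicModel],
                       medium: Medium,
                       feed: FeedSpec,
                       config: SimulationConfig | None = None,
                       products: Sequence[str] = (),
                       inoculum: Mapping[str, float] | None = None,
                       ) -> CommunityTrajectory:
    """Batch simulation with substrate top-ups.

    After each step, if the watched metabolite's concentration (g/L) has
    fallen below ``feed.trigger_g_per_l`` it is reset to
    ``feed.target_g_per_l``; every feed event is time-stamped on the
    trajectory.  With a trigger that is never reached this is identical to
    :func:`simulate`.
    """
    return simulate(models, medium, config=config, products=products,
                    inoculum=inoculum, feed=feed)


def _replace_config(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Convenience for derived configs (used by scans)."""
    return replace(config, **kwargs)
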
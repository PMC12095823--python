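"""Screening analytics: metrics, interaction calls, viability and scans.

This layer turns community trajectories into bioprocess decisions.  For a
pair of organisms A and B simulated in the same environment:

* *Productivity* of a system for a product is its terminal averaged
  cumulative product concentration divided by the batch horizon (mmol/L/h).

* The *productivity gain* of the co-culture is benchmarked against the best
  constituent monoculture::

      delta = P(Comm_AB) - max(P(Mono_A), P(Mono_B))
      ratio = delta / |max(P(Mono_A), P(Mono_B))|

  When the best monoculture produces essentially nothing while the
  co-culture produces, the ratio is reported as the sentinel category
  ``"high"`` instead of a number.

* The *interaction type* compares each member's growth in co-culture
  against half its monoculture growth with a +/-10 % band: positive if
  ``Comm > (1+thr) * Mono/2``, negative if ``Comm < (1-thr) * Mono/2``,
  otherwise no change.  The unordered sign pair maps onto six categories:
  (-,-) competition, (-,0) amensalism, (+,-) parasitism, (0,0) neutralism,
  (+,0) commensalism, (+,+) mutualism.

* A community is *viable* when every member keeps a terminal abundance of
  at least 0.1 and grows by at least 10 % over its inoculum.

* *Cross-feeding roles* integrate each species' net exchange of every pool
  metabolite over the run: net secretion marks a Producer, net consumption
  a Consumer; a metabolite is cross-fed when both roles coexist.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import qmc

from .environments import Medium, swap_carbon_source
from .dfba import (
    CommunityTrajectory,
    SimulationConfig,
    UptakeKinetics,
    simulate,
)
from .model_io import MetabolicModel, eligible_for_regime

__all__ = [
    "InteractionCall",
    "ProductivityComparison",
    "ScreenRecord",
    "SensitivityResult",
    "ViabilityResult",
    "check_viability",
    "classify_interaction",
    "classify_pair",
    "cross_feeding_roles",
    "growth_measure",
    "lhs_sensitivity",
    "productivity",
    "productivity_ratio",
    "rank_systems",
    "scan_carbon_sources",
    "scan_inoculum",
    "screen_pairs",
    "yield_per_substrate",
]

logger = logging.getLogger(__name__)

#: Sign-pair -> interaction label (unordered).
INTERACTION_LABELS: dict[frozenset | tuple, str] = {
    ("-", "-"): "competition",
    ("-", "0"): "amensalism",
    ("+", "-"): "parasitism",
    ("0", "0"): "neutralism",
    ("+", "0"): "commensalism",
    ("+", "+"): "mutualism",
}

#: Productivity floor below which a monoculture counts as a non-producer
#: for the "high"-ratio sentinel.
HIGH_RATIO_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def productivity(traj: CommunityTrajectory, product_id: str) -> float:
    """Terminal averaged product concentration / horizon, in mmol/L/h."""
    return traj.product_amount(product_id) / traj.config.horizon


@dataclass(frozen=True)
class ProductivityComparison:
    delta: float                 # mmol/L/h
    ratio: float                 # unitless; inf for the "high" category
    category: str                # "ratio" | "high" | "no_production"


def productivity_ratio(comm: float, mono_a: float, mono_b: float,
                       ) -> ProductivityComparison:
    """Productivity gain of the co-culture over the best monoculture."""
    if min(comm, mono_a, mono_b) < 0:
        raise ValueError("productivities must be non-negative")
    best_mono = max(mono_a, mono_b)
    if best_mono < HIGH_RATIO_FLOOR:
        if comm > 10 * HIGH_RATIO_FLOOR:
            return ProductivityComparison(comm - best_mono, math.inf, "high")
        return ProductivityComparison(0.0, math.nan, "no_production")
    delta = comm - best_mono
    return ProductivityComparison(delta, delta / abs(best_mono), "ratio")


def growth_measure(traj: CommunityTrajectory, species: str,
                   measure: str = "biomass") -> float:
    """Growth measure of one species for interaction classification.

    ``"biomass"`` uses the terminal averaged biomass (g/L); ``"growth_rate"``
    uses the terminal averaged specific growth rate (1/h).
    """
    if measure == "biomass":
        return traj.terminal_biomass(species)
    if measure == "growth_rate":
        return traj.terminal_growth_rate(species)
    raise ValueError(f"unknown growth measure {measure!r}")


@dataclass(frozen=True)
class InteractionCall:
    pair: tuple[str, str]
    signs: tuple[str, str]
    label: str
    threshold: float = 0.1


def _sign(comm: float, mono: float, threshold: float) -> str:
    half = mono / 2.0
    if comm > (1.0 + threshold) * half:
        return "+"
    if comm < (1.0 - threshold) * half:
        return "-"
    return "0"


def classify_interaction(comm_a: float, comm_b: float,
                         mono_a: float, mono_b: float,
                         threshold: float = 0.1,
                         pair: tuple[str, str] = ("A", "B")) -> InteractionCall:
    """Six-way interaction call from co-culture vs monoculture growth.

    Each member's growth in co-culture is compared against half its
    monoculture growth with a ``threshold`` band (default 10 %).  A species
    whose monoculture growth measure is zero cannot be placed on that scale;
    its side is reported as ``"?"`` and the label as ``"undefined"``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    signs = []
    for comm, mono in ((comm_a, mono_a), (comm_b, mono_b)):
        if mono <= 0:
            signs.append("?")
        else:
            signs.append(_sign(comm, mono, threshold))
    if "?" in signs:
        logger.warning("interaction undefined for %s: monoculture growth is "
                       "zero on one side", pair)
        return InteractionCall(pair, tuple(signs), "undefined", threshold)
    # '+' < '-' < '0' in ASCII, matching the key order of INTERACTION_LABELS
    label = INTERACTION_LABELS[tuple(sorted(signs))]
    return InteractionCall(pair, tuple(signs), label, threshold)


def classify_pair(comm: CommunityTrajectory,
                  mono_a: CommunityTrajectory,
                  mono_b: CommunityTrajectory,
                  threshold: float = 0.1,
                  measure: str = "biomass") -> InteractionCall:
    """Interaction call for a simulated pair and its monoculture baselines."""
    sp_a, sp_b = comm.species
    return classify_interaction(
        growth_measure(comm, sp_a, measure),
        growth_measure(comm, sp_b, measure),
        growth_measure(mono_a, sp_a, measure),
        growth_measure(mono_b, sp_b, measure),
        threshold=threshold,
        pair=(sp_a, sp_b),
    )


@dataclass(frozen=True)
class ViabilityResult:
    viable: bool
    abundances: dict[str, float]
    growth_fold: dict[str, float]
    failed: tuple[str, ...]


def check_viability(traj: CommunityTrajectory,
                    min_abundance: float = 0.1,
                    min_growth: float = 0.10,
                    per_member_growth: bool = True) -> ViabilityResult:
    """Viability: every member keeps abundance >= 0.1 and grows >= 10 %.

    With ``per_member_growth=False`` the growth criterion is applied to the
    community's total biomass instead of each member.
    """
    abundances = dict(traj.abundances)
    folds = {sp: traj.growth_fold(sp) for sp in traj.species}
    failed: list[str] = []
    for sp in traj.species:
        if abundances[sp] < min_abundance:
            failed.append(f"abundance[{sp}]={abundances[sp]:.3f}<{min_abundance}")
    if per_member_growth:
        for sp, fold in folds.items():
            if fold < min_growth:
                failed.append(f"growth[{sp}]={fold:.3f}<{min_growth}")
    else:
        total0 = sum(traj.inoculum.values())
        total_fold = (traj.terminal_state.total_biomass - total0) / total0
        if total_fold < min_growth:
            failed.append(f"growth[total]={total_fold:.3f}<{min_growth}")
    return ViabilityResult(not failed, abundances, folds, tuple(failed))


def cross_feeding_roles(traj: CommunityTrajectory,
                        tolerance: float = 1e-6) -> pd.DataFrame:
    """Producer/Consumer roles from net integrated exchange per species.

    Returns a table with columns ``metabolite``, ``species``, ``role``
    (Producer/Consumer/none), ``net_exchange_mmol_per_L`` and
    ``cross_feeding`` (True where the metabolite has at least one Producer
    and one Consumer in this trajectory).
    """
    mets = sorted({met for _, _, met, _ in traj.exchange_records})
    rows = []
    for met in mets:
        for sp in traj.species:
            net = traj.net_exchange(sp, met)
            if net > tolerance:
                role = "Producer"
            elif net < -tolerance:
                role = "Consumer"
            else:
                role = "none"
            rows.append((met, sp, role, net))
    table = pd.DataFrame(
        rows, columns=["metabolite", "species", "role", "net_exchange_mmol_per_L"]
    )
    cross = {
        met: {"Producer", "Consumer"}.issubset(set(sub.role))
        for met, sub in table.groupby("metabolite")
    }
    table["cross_feeding"] = table.metabolite.map(cross).astype(bool)
    return table


def yield_per_substrate(traj: CommunityTrajectory, product_id: str,
                        substrate_id: str,
                        molar_masses: Mapping[str, float]) -> float:
    """Yield in g product per g substrate consumed.

    Consumption is initial minus terminal pool substrate plus any fed
    amounts.  Returns NaN (undefined) when no substrate was consumed.
    """
    product_met = product_id.removeprefix("EX_")
    try:
        mass_p = molar_masses[product_met]
        mass_s = molar_masses[substrate_id]
    except KeyError as exc:
        raise ValueError(f"no molar mass for {exc.args[0]!r}") from None
    produced = traj.product_amount(product_id)
    s0 = traj.states[0].S.get(substrate_id, 0.0)
    s_end = traj.terminal_state.S.get(substrate_id, 0.0)
    fed = sum(ev.added_mmol_per_l for ev in traj.feed_events
              if ev.metabolite == substrate_id)
    consumed = s0 - s_end + fed
    if consumed <= 0:
        logger.warning("yield undefined: no %s consumed", substrate_id)
        return math.nan
    if produced <= 0:
        return 0.0
    return (produced * mass_p) / (consumed * mass_s)


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenRecord:
    system: tuple[str, ...]
    environment: str
    product_id: str
    productivity: float                    # mmol/L/h
    abundances: dict[str, float]
    terminal_biomass: dict[str, float]
    delta: float | None = None             # vs best monoculture (pairs only)
    ratio: float | None = None
    ratio_category: str | None = None
    interaction: str | None = None
    interaction_signs: tuple[str, str] | None = None
    viable: bool | None = None
    carbon_source: str | None = None

    @property
    def system_name(self) -> str:
        return " - ".join(self.system)


def records_frame(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "system": r.system_name,
            "n_species": len(r.system),
            "environment": r.environment,
            "carbon_source": r.carbon_source,
            "product": r.product_id,
            "productivity_mmol_per_L_h": r.productivity,
            "delta_productivity": r.delta,
            "productivity_ratio": r.ratio,
            "ratio_category": r.ratio_category,
            "interaction": r.interaction,
            "viable": r.viable,
            "abundances": ", ".join(f"{v:.2f}" for v in r.abundances.values()),
            "total_biomass_g_per_L": sum(r.terminal_biomass.values()),
        })
    return pd.DataFrame(rows)


def screen_pairs(models: Sequence[MetabolicModel],
                 media: Sequence[Medium],
                 products: Sequence[str],
                 config: SimulationConfig | None = None,
                 threshold: float = 0.1,
                 measure: str = "biomass",
                 carbon_source: str | None = None,
                 ) -> list[ScreenRecord]:
    """Simulate every monoculture and unordered pair in every environment.

    Models whose oxygen-requirement flag excludes them from a medium's
    regime are skipped with a log line.  Monoculture baselines are plain
    :func:`simulate` runs of one model under the identical configuration.
    """
    if not models:
        raise ValueError("need at least one model")
    config = config or SimulationConfig()
    products = list(products)
    records: list[ScreenRecord] = []
    for medium in media:
        eligible = []
        for model in models:
            if eligible_for_regime(model, medium.oxygen_regime):
                eligible.append(model)
            else:
                logger.info("excluding %s from %s (%s regime)",
                            model.model_id, medium.name, medium.oxygen_regime)
        monos: dict[str, CommunityTrajectory] = {}
        for model in eligible:
            traj = simulate([model], medium, config, products=products)
            monos[model.model_id] = traj
            for product_id in products:
                records.append(ScreenRecord(
                    system=(model.model_id,),
                    environment=medium.name,
                    product_id=product_id,
                    productivity=productivity(traj, product_id),
                    abundances=dict(traj.abundances),
                    terminal_biomass=dict(traj.terminal_state.X),
                    carbon_source=carbon_source,
                ))
        for model_a, model_b in itertools.combinations(eligible, 2):
            comm = simulate([model_a, model_b], medium, config,
                            products=products)
            mono_a = monos[model_a.model_id]
            mono_b = monos[model_b.model_id]
            call = classify_pair(comm, mono_a, mono_b,
                                 threshold=threshold, measure=measure)
            viability = check_viability(comm)
            for product_id in products:
                comparison = productivity_ratio(
                    productivity(comm, product_id),
                    productivity(mono_a, product_id),
                    productivity(mono_b, product_id),
                )
                records.append(ScreenRecord(
                    system=(model_a.model_id, model_b.model_id),
                    environment=medium.name,
                    product_id=product_id,
                    productivity=productivity(comm, product_id),
                    abundances=dict(comm.abundances),
                    terminal_biomass=dict(comm.terminal_state.X),
                    delta=comparison.delta,
                    ratio=comparison.ratio,
                    ratio_category=comparison.category,
                    interaction=call.label,
                    interaction_signs=call.signs,
                    viable=viability.viable,
                    carbon_source=carbon_source,
                ))
    return records


def rank_systems(records: Sequence[ScreenRecord], product_id: str,
                 environment: str, top: int = 5) -> list[ScreenRecord]:
    """Top systems for one product in one environment, by productivity."""
    pool = [r for r in records
            if r.product_id == product_id and r.environment == environment]
    return sorted(pool, key=lambda r: r.productivity, reverse=True)[:top]


def scan_carbon_sources(models: Sequence[MetabolicModel],
                        media: Sequence[Medium],
                        carbon_sources: Sequence[str],
                        products: Sequence[str],
                        config: SimulationConfig | None = None,
                        primary_carbon_id: str = "glc__D_e",
                        ) -> list[ScreenRecord]:
    """Repeat the pairwise screen with the primary carbon source swapped.

    Each candidate carbon source replaces the primary one at 10 mmol/L in
    every medium; all other components are untouched.
    """
    records: list[ScreenRecord] = []
    for carbon in carbon_sources:
        swapped = [swap_carbon_source(m, carbon, primary_carbon_id)
                   for m in media]
        records.extend(screen_pairs(models, swapped, products, config,
                                    carbon_source=carbon))
    return records


def scan_inoculum(pair: Sequence[MetabolicModel],
                  ratios: Sequence[tuple[float, float]],
                  total_inoculum: float,
                  medium: Medium,
                  config: SimulationConfig | None = None,
                  product_id: str | None = None) -> pd.DataFrame:
    """Sweep the inoculum split of a pair at fixed total inoculum (g/L)."""
    if len(pair) != 2:
        raise ValueError("inoculum scan is defined for a pair of models")
    if total_inoculum <= 0:
        raise ValueError("total inoculum must be positive")
    config = config or SimulationConfig()
    products = [product_id] if product_id else []
    sp_a, sp_b = (m.model_id for m in pair)
    rows = []
    for f_a, f_b in ratios:
        if abs(f_a + f_b - 1.0) > 1e-9:
            raise ValueError(f"inoculum ratio {(f_a, f_b)} does not sum to 1")
        inoculum = {sp_a: f_a * total_inoculum, sp_b: f_b * total_inoculum}
        traj = simulate(list(pair), medium, config, products=products,
                        inoculum=inoculum)
        row = {
            "ratio_a": f_a,
            "ratio_b": f_b,
            "biomass_a_g_per_L": traj.terminal_biomass(sp_a),
            "biomass_b_g_per_L": traj.terminal_biomass(sp_b),
            "total_biomass_g_per_L": traj.terminal_state.total_biomass,
            "abundance_a": traj.abundances[sp_a],
            "abundance_b": traj.abundances[sp_b],
        }
        if product_id:
            row["product_mmol_per_L"] = traj.product_amount(product_id)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kinetic-parameter sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityResult:
    draws: pd.DataFrame                      # columns v_max, k_m
    response: np.ndarray                     # terminal community biomass (g/L)
    coefficients: dict[str, float]           # raw OLS coefficients
    coefficients_std_inputs: dict[str, float]  # on z-scored predictors
    r_squared: float

    def same_draws(self, other: "SensitivityResult") -> bool:
        return self.draws.equals(other.draws)


def lhs_sensitivity(models: Sequence[MetabolicModel],
                    medium: Medium,
                    config: SimulationConfig | None = None,
                    v_max_range: tuple[float, float] = (1.0, 50.0),
                    k_m_range: tuple[float, float] = (0.01, 1.0),
                    n: int = 10,
                    seed: int | None = None) -> SensitivityResult:
    """Latin hypercube sensitivity of terminal community biomass to V_max, K_m.

    Draws ``n`` stratified (one per equal-probability stratum per parameter)
    samples, runs one simulation per draw with uniform kinetics, and fits an
    ordinary least squares regression of terminal total biomass on the raw
    parameters.  Coefficients are also reported on z-scored predictors for
    scale-free comparison.  R^2 is defined as 0 when the response does not
    vary.
    """
    if n < 3:
        raise ValueError("need at least 3 draws for a regression")
    config = config or SimulationConfig()
    sampler = qmc.LatinHypercube(d=2, seed=seed)
    unit = sampler.random(n)
    lows = [v_max_range[0], k_m_range[0]]
    highs = [v_max_range[1], k_m_range[1]]
    samples = qmc.scale(unit, lows, highs)
    draws = pd.DataFrame(samples, columns=["v_max", "k_m"])
    if float(draws.v_max.std()) == 0.0 or float(draws.k_m.std()) == 0.0:
        raise ValueError("degenerate LHS design: all draws identical")
    response = np.empty(n)
    for i, (v_max, k_m) in enumerate(zip(draws.v_max, draws.k_m)):
        cfg = replace(config, kinetics=UptakeKinetics(v_max=v_max, k_m=k_m))
        traj = simulate(list(models), medium, cfg)
        response[i] = traj.terminal_state.total_biomass
    design = sm.add_constant(draws[["v_max", "k_m"]].to_numpy())
    fit = sm.OLS(response, design).fit()
    intercept, beta_v, beta_k = fit.params
    tss = float(np.sum((response - response.mean()) ** 2))
    r_squared = float(fit.rsquared) if tss > 1e-12 else 0.0
    std_inputs = {
        "v_max": beta_v * float(draws.v_max.std(ddof=1)),
        "k_m": beta_k * float(draws.k_m.std(ddof=1)),
    }
    return SensitivityResult(
        draws=draws,
        response=response,
        coefficients={"intercept": float(intercept),
                      "v_max": float(beta_v), "k_m": float(beta_k)},
        coefficients_std_inputs=std_inputs,
        r_squared=r_squared,
    )
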
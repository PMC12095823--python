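"""Independent brute-force LP oracles for the FBA primitives.

These solve the same optimisation problems as the engine but through a
completely separate code path: the stoichiometric matrix is assembled
directly from the model dataclasses and solved with scipy's HiGHS-based
``linprog`` (the engine goes through cobra/optlang/GLPK).  Used only to
cross-check ``growth_step``, parsimonious flux selection and ``product_fva``
on the small fixture networks.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from commscreen.model_io import MetabolicModel


def _assemble(model: MetabolicModel, uptake_bounds: Mapping[str, float]):
    mets = [m.id for m in model.metabolites]
    met_index = {m: i for i, m in enumerate(mets)}
    rxns = model.reactions
    n = len(rxns)
    a_eq = np.zeros((len(mets), n))
    lb = np.empty(n)
    ub = np.empty(n)
    exchange_ids = model.exchange_ids
    for j, rxn in enumerate(rxns):
        for met_id, coeff in rxn.stoichiometry.items():
            a_eq[met_index[met_id], j] = coeff
        if rxn.id in exchange_ids:
            lb[j] = -float(uptake_bounds.get(rxn.id, 0.0))
        else:
            lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
    return a_eq, lb, ub


def brute_fba(model: MetabolicModel,
              uptake_bounds: Mapping[str, float]) -> float | None:
    """Max biomass flux; None if infeasible."""
    a_eq, lb, ub = _assemble(model, uptake_bounds)
    n = a_eq.shape[1]
    c = np.zeros(n)
    c[model.reaction_ids.index(model.objective_reaction_id)] = -1.0
    res = linprog(c, A_eq=a_eq, b_eq=np.zeros(a_eq.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return None
    return -res.fun


def brute_pfba_total_flux(model: MetabolicModel,
                          uptake_bounds: Mapping[str, float],
                          mu: float) -> float | None:
    """Minimum total |flux| with the biomass flux fixed at ``mu``.

    Split-variable formulation: v = p - q with p, q >= 0; minimise
    sum(p + q) subject to A(p - q) = 0 and the original bounds on p - q.
    """
    a_eq, lb, ub = _assemble(model, uptake_bounds)
    m, n = a_eq.shape
    # variables: [p (n), q (n)]
    a_stoich = np.hstack([a_eq, -a_eq])
    b_stoich = np.zeros(m)
    bio = model.reaction_ids.index(model.objective_reaction_id)
    a_mu = np.zeros((1, 2 * n))
    a_mu[0, bio] = 1.0
    a_mu[0, n + bio] = -1.0
    # bounds on v = p - q enforced as inequalities lb <= p - q <= ub
    a_ub = np.vstack([
        np.hstack([np.eye(n), -np.eye(n)]),    # v <= ub
        np.hstack([-np.eye(n), np.eye(n)]),    # -v <= -lb
    ])
    b_ub = np.concatenate([ub, -lb])
    res = linprog(
        np.ones(2 * n),
        A_eq=np.vstack([a_stoich, a_mu]),
        b_eq=np.concatenate([b_stoich, [mu]]),
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[(0, None)] * (2 * n),
        method="highs",
    )
    if not res.success:
        return None
    return res.fun


def brute_fva_max(model: MetabolicModel,
                  uptake_bounds: Mapping[str, float],
                  mu: float,
                  product_id: str,
                  growth_fraction: float = 0.999) -> float | None:
    """Max product exchange flux with biomass >= growth_fraction * mu."""
    if product_id not in model.reaction_ids:
        return 0.0
    a_eq, lb, ub = _assemble(model, uptake_bounds)
    n = a_eq.shape[1]
    bio = model.reaction_ids.index(model.objective_reaction_id)
    lb = lb.copy()
    lb[bio] = max(lb[bio], growth_fraction * mu)
    c = np.zeros(n)
    c[model.reaction_ids.index(product_id)] = -1.0
    res = linprog(c, A_eq=a_eq, b_eq=np.zeros(a_eq.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return None
    return -res.fun
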
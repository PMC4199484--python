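"""Flux balance analysis, flux variability analysis, and media handling.

All linear programs are solved with the HiGHS backend shipped in SciPy,
through a single :func:`_solve_lp` entry point so the solver can be swapped
without touching callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .exceptions import InfeasibleError, UnboundedError
from .model_core import Media, MetabolicModel

logger = logging.getLogger(__name__)

DEFAULT_UPTAKE = 100.0
INACTIVITY_TOL = 1e-9


@dataclass
class FluxResult:
    status: str                      # "optimal" | "infeasible"
    objective_value: float
    fluxes: dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaResult:
    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


# ---------------------------------------------------------------------------
# LP plumbing
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(model: MetabolicModel):
    """Sparse S (metabolites x reactions) plus index maps, in model order."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(coef)
    S = csr_matrix((data, (rows, cols)),
                   shape=(len(model.metabolites), len(model.reactions)))
    return S, met_index


def _solve_lp(c: np.ndarray, S, bounds: Sequence[tuple[float, float]]):
    """min c.v  s.t.  S.v = 0, bounds. Returns the raw linprog result."""
    rhs = np.zeros(S.shape[0])
    return linprog(c, A_eq=S, b_eq=rhs, bounds=bounds, method="highs")


def _model_bounds(model: MetabolicModel) -> list[tuple[float, float]]:
    return [(r.lower_bound, r.upper_bound) for r in model.reactions]


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

def apply_media(model: MetabolicModel, media: Media,
                default_uptake: float = DEFAULT_UPTAKE) -> MetabolicModel:
    """Return a copy with exchange uptake bounds set from the media.

    Exchanges are written with coefficient -1 on the extracellular compound,
    so uptake is negative flux: the lower bound becomes ``-limit``. Secretion
    (upper) bounds are left untouched. Compounds named by the media with no
    exchange reaction are logged and ignored.
    """
    out = model.copy()
    exchange_compound = {}
    for rxn in out.reactions:
        if out.is_exchange(rxn.id):
            (met_id,) = rxn.stoichiometry
            exchange_compound[met_id] = rxn
    for compound in media.uptake_limits:
        if compound not in exchange_compound:
            logger.warning("media %s names %s but model %s has no exchange "
                           "for it; ignored", media.name, compound, model.id)
    for met_id, rxn in exchange_compound.items():
        if media.complete_flag:
            rxn.lower_bound = -default_uptake
        else:
            rxn.lower_bound = -media.uptake_limits.get(met_id, 0.0)
        if rxn.upper_bound < rxn.lower_bound:
            rxn.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------

def run_fba(model: MetabolicModel, objective_reaction: Optional[str] = None,
            direction: str = "max") -> FluxResult:
    """Maximize (or minimize) a reaction flux at steady state."""
    if objective_reaction is None:
        objective_reaction = model.biomass_reaction_id
    rxn_ids = model.reaction_ids
    if objective_reaction not in set(rxn_ids):
        raise InfeasibleError(f"objective reaction {objective_reaction!r} "
                              f"not in model {model.id}")
    S, _ = build_stoichiometric_matrix(model)
    c = np.zeros(len(rxn_ids))
    j = rxn_ids.index(objective_reaction)
    c[j] = -1.0 if direction == "max" else 1.0
    res = _solve_lp(c, S, _model_bounds(model))
    if res.status == 2:
        return FluxResult(status="infeasible", objective_value=float("nan"),
                          fluxes={})
    if res.status == 3:
        raise UnboundedError(
            f"objective on {objective_reaction} is unbounded; check for an "
            f"open cycle through {objective_reaction}")
    if res.status != 0:
        raise InfeasibleError(f"LP solver failure (status {res.status}): "
                              f"{res.message}")
    fluxes = dict(zip(rxn_ids, res.x.tolist()))
    objective = fluxes[objective_reaction]
    return FluxResult(status="optimal", objective_value=objective,
                      fluxes=fluxes)


def run_fva(model: MetabolicModel,
            reaction_ids: Optional[Iterable[str]] = None,
            fraction_of_optimum: float = 0.0) -> FvaResult:
    """Per-reaction min/max feasible flux, optionally at a biomass fraction.

    ``fraction_of_optimum=0`` imposes no growth requirement; otherwise the
    biomass flux is constrained to at least that fraction of the FBA optimum.
    """
    rxn_ids = list(reaction_ids) if reaction_ids is not None \
        else model.reaction_ids
    all_ids = model.reaction_ids
    index = {rid: j for j, rid in enumerate(all_ids)}
    for rid in rxn_ids:
        if rid not in index:
            raise InfeasibleError(f"FVA reaction {rid!r} not in model")

    bounds = _model_bounds(model)
    if fraction_of_optimum > 0.0:
        base = run_fba(model)
        if not base.ok:
            raise InfeasibleError(
                f"model {model.id} infeasible; cannot constrain growth")
        j_bio = index[model.biomass_reaction_id]
        lo, hi = bounds[j_bio]
        bounds[j_bio] = (max(lo, fraction_of_optimum * base.objective_value), hi)

    S, _ = build_stoichiometric_matrix(model)
    n = len(all_ids)
    ranges: dict[str, tuple[float, float]] = {}
    for rid in rxn_ids:
        j = index[rid]
        lohi = []
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res = _solve_lp(c, S, bounds)
            if res.status == 2:
                raise InfeasibleError(
                    f"model {model.id} infeasible during FVA")
            if res.status == 3:
                # direction unbounded; report the variable bound
                lohi.append(bounds[j][0] if sign > 0 else bounds[j][1])
                continue
            if res.status != 0:
                raise InfeasibleError(
                    f"FVA LP failure on {rid} (status {res.status})")
            lohi.append(float(res.x[j]))
        vmin, vmax = lohi
        ranges[rid] = (min(vmin, vmax), max(vmin, vmax))
    return FvaResult(ranges=ranges)


def find_inactive_reactions(model: MetabolicModel, media: Media,
                            tol: float = INACTIVITY_TOL,
                            gene_associated_only: bool = False) -> list[str]:
    """Reactions whose FVA range on the media lies within [-tol, +tol].

    A reversible reaction counts as inactive only if BOTH directions are
    within tolerance. Returns ids in model order (deterministic).
    """
    constrained = apply_media(model, media)
    if gene_associated_only:
        candidates = constrained.gene_associated_reaction_ids()
    else:
        candidates = constrained.reaction_ids
    fva = run_fva(constrained, candidates, fraction_of_optimum=0.0)
    inactive = []
    for rid in candidates:
        vmin, vmax = fva[rid]
        if abs(vmin) <= tol and abs(vmax) <= tol:
            inactive.append(rid)
    return inactive
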
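"""Targeted gap filling as a mixed-integer linear program.

Candidate modifications are (a) adding a universal-database reaction in its
forward or reverse direction and (b) relaxing the reversibility of an
existing irreversible, non-exchange model reaction. Each candidate carries a
nonnegative cost; the MILP minimizes total cost subject to steady state on
the merged network, media uptake limits, and a minimum flux through the
target reaction.

Cost model (additive; the likelihood mode rescales only the base term)::

    base(x)   = 1 + P_transporter*[transporter] + P_lowdb*[low-confidence]
    U(x, dir) = (12 + 2*max(g, 0)) / 10     g = deltaG opposing `dir`
                (U = 12/10 when deltaG is unknown)

    parsimony:  lambda(x, dir) = base(x)            + U(x,dir)*[dir unfavorable]
    likelihood: lambda(x, dir) = (1 - p(x))*base(x) + U(x,dir)*[dir unfavorable]

    reversibility change: P_reversibility * U(x, new dir) / (12/10)
                          (identical in both modes)

The direction surcharge is deliberately NOT likelihood-scaled, and neither
are reversibility-change costs. The exact weighting equation was
reconstructed from prose constraints (see the repository README); the
calibration anchors are U = 1.2 at low/unknown deltaG and U = 3.2 at
deltaG = 10 kcal/mol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import lil_matrix

from .exceptions import (GapfillTimeoutError, InfeasibleError, LikfillError,
                         ValidationError)
from .fba import DEFAULT_UPTAKE, apply_media, run_fva
from .likelihood import ReactionLikelihoods
from .model_core import Media, MetabolicModel, Reaction

logger = logging.getLogger(__name__)

BIG_M = 1000.0
TARGET_EPSILON = 1e-5
FLUX_TOL = 1e-9
DEFAULT_T_MAX = 86400.0

FORWARD = "forward"
REVERSE = "reverse"


@dataclass
class Penalties:
    """Cost weights; the defaults are the likelihood-optimal values that are
    also used for parsimony runs."""

    transporter: float = 25.0
    unfavorable_reversibility: float = 12.0
    low_confidence_db: float = 5.0
    direction_intercept: float = 12.0
    direction_slope: float = 2.0
    direction_divisor: float = 10.0

    def __post_init__(self) -> None:
        for name in ("transporter", "unfavorable_reversibility",
                     "low_confidence_db", "direction_intercept",
                     "direction_slope"):
            if getattr(self, name) < 0:
                raise ValidationError(f"penalty {name} must be >= 0")

    def direction_surcharge(self, opposing_delta_g: Optional[float]) -> float:
        g = 0.0 if opposing_delta_g is None else max(opposing_delta_g, 0.0)
        return (self.direction_intercept + self.direction_slope * g) \
            / self.direction_divisor

    @property
    def base_surcharge(self) -> float:
        return self.direction_intercept / self.direction_divisor


def direction_is_unfavorable(rxn: Reaction, direction: str) -> bool:
    """Forward is unfavorable iff deltaG > 0; reverse iff deltaG < 0.
    Unknown deltaG makes both directions favorable."""
    if rxn.delta_g is None:
        return False
    if direction == FORWARD:
        return rxn.delta_g > 0
    return rxn.delta_g < 0


def _opposing_delta_g(rxn: Reaction, direction: str) -> Optional[float]:
    if rxn.delta_g is None:
        return None
    return rxn.delta_g if direction == FORWARD else -rxn.delta_g


@dataclass
class GapfillCosts:
    """Per-candidate objective weights for one (universal, draft) pair."""

    mode: str                                     # "parsimony" | "likelihood"
    penalties: Penalties
    likelihoods: Optional[ReactionLikelihoods] = None
    addition: dict[tuple[str, str], float] = field(default_factory=dict)

    def addition_cost(self, rxn: Reaction, direction: str) -> float:
        base = 1.0
        if rxn.is_transporter:
            base += self.penalties.transporter
        if rxn.source_confidence == "low":
            base += self.penalties.low_confidence_db
        if self.mode == "likelihood":
            base *= 1.0 - self.p(rxn.id)
        if direction_is_unfavorable(rxn, direction):
            base += self.penalties.direction_surcharge(
                _opposing_delta_g(rxn, direction))
        return base

    def reversal_cost(self, rxn: Reaction, new_direction: str) -> float:
        surcharge = self.penalties.direction_surcharge(
            _opposing_delta_g(rxn, new_direction))
        return (self.penalties.unfavorable_reversibility
                * surcharge / self.penalties.base_surcharge)

    def p(self, rxn_id: str) -> float:
        if self.likelihoods is None:
            return 0.0
        return self.likelihoods.p(rxn_id)


def compute_costs(universal: MetabolicModel, draft: MetabolicModel,
                  rxn_lik: Optional[ReactionLikelihoods],
                  pen: Optional[Penalties] = None,
                  mode: str = "likelihood") -> GapfillCosts:
    """Precompute addition costs for every universal reaction direction."""
    if mode not in ("parsimony", "likelihood"):
        raise ValidationError(f"unknown cost mode {mode!r}")
    if mode == "likelihood" and rxn_lik is None:
        raise ValidationError("likelihood mode requires reaction likelihoods")
    costs = GapfillCosts(mode=mode, penalties=pen or Penalties(),
                         likelihoods=rxn_lik if mode == "likelihood" else None)
    for rxn in universal.reactions:
        for direction in (FORWARD, REVERSE):
            costs.addition[(rxn.id, direction)] = costs.addition_cost(
                rxn, direction)
    return costs


# ---------------------------------------------------------------------------
# Solutions
# ---------------------------------------------------------------------------

@dataclass
class AddedReaction:
    reaction: Reaction        # copy of the universal entry
    direction: str
    cost: float
    likelihood: float
    gpr: str                  # candidate rule string ("" if none)


@dataclass
class ReversedReaction:
    reaction_id: str
    new_direction: str
    cost: float


@dataclass
class GapfillSolution:
    target: str
    media_name: str
    mode: str
    added: list[AddedReaction] = field(default_factory=list)
    reversibility_changes: list[ReversedReaction] = field(default_factory=list)
    objective_value: float = 0.0
    solver_status: str = "optimal"
    media: Optional[Media] = None

    def is_empty(self) -> bool:
        return not self.added and not self.reversibility_changes

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "media": self.media_name,
            "mode": self.mode,
            "objective": self.objective_value,
            "status": self.solver_status,
            "added": [
                {"reaction_id": a.reaction.id, "direction": a.direction,
                 "cost": a.cost, "likelihood": a.likelihood, "gpr": a.gpr}
                for a in self.added
            ],
            "reversed": [
                {"reaction_id": r.reaction_id, "direction": r.new_direction,
                 "cost": r.cost}
                for r in self.reversibility_changes
            ],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Media helpers
# ---------------------------------------------------------------------------

def complete_media(draft: MetabolicModel,
                   default_uptake: float = DEFAULT_UPTAKE) -> Media:
    """Medium of every extracellular compound touched by a model transporter."""
    compounds: set[str] = set()
    comp_of = {m.id: m.compartment for m in draft.metabolites}
    for rxn in draft.reactions:
        if not rxn.is_transporter:
            continue
        for met_id in rxn.stoichiometry:
            if comp_of[met_id] == "e":
                compounds.add(met_id)
    return Media(name=f"complete-{draft.id}",
                 uptake_limits={c: default_uptake for c in sorted(compounds)})


# ---------------------------------------------------------------------------
# MILP construction and solution
# ---------------------------------------------------------------------------

def _merge_network(draft: MetabolicModel, universal: MetabolicModel,
                   media: Media) -> tuple[MetabolicModel, list[Reaction]]:
    """Media-constrained draft plus the list of candidate universal reactions
    (those whose id is not already in the draft). Candidate exchange
    reactions get their uptake bound from the media too."""
    merged = apply_media(draft, media)
    candidates: list[Reaction] = []
    for rxn in universal.reactions:
        if merged.has_reaction(rxn.id):
            continue
        cand = rxn.copy()
        if universal.is_exchange(rxn.id):
            (met_id,) = cand.stoichiometry
            if media.complete_flag:
                cand.lower_bound = -DEFAULT_UPTAKE
            else:
                cand.lower_bound = -media.uptake_limits.get(met_id, 0.0)
        candidates.append(cand)
    return merged, candidates


def merged_is_exchange(rxn: Reaction, universal: MetabolicModel) -> bool:
    if len(rxn.stoichiometry) != 1:
        return False
    (met_id,) = rxn.stoichiometry
    return universal.has_metabolite(met_id) \
        and universal.metabolite(met_id).compartment == "e"


def reversal_candidates(model: MetabolicModel, target: str) -> list[tuple[str, str]]:
    """(reaction id, new direction) pairs eligible for reversibility changes:
    irreversible, non-exchange reactions other than the target."""
    out = []
    for rxn in model.reactions:
        if rxn.id == target or model.is_exchange(rxn.id):
            continue
        if rxn.lower_bound >= 0 and rxn.upper_bound > 0:
            out.append((rxn.id, REVERSE))
        elif rxn.upper_bound <= 0 and rxn.lower_bound < 0:
            out.append((rxn.id, FORWARD))
    return out


def _solve_milp_with_escalation(args, time_limit: float, t_max: float):
    """Run scipy.optimize.milp, doubling the time limit until success."""
    limit = max(time_limit, 1.0)
    while True:
        res = milp(**args, options={"time_limit": limit,
                                    "mip_rel_gap": 0.0})
        # status 0 = optimal, 1 = iteration/time limit, 2 = infeasible
        if res.status == 0:
            return res
        if res.status == 2:
            raise InfeasibleError("gap filling MILP is infeasible: no "
                                  "combination of candidates activates the "
                                  "target on this media")
        if res.status == 1:
            if limit >= t_max:
                raise GapfillTimeoutError(
                    f"MILP unsolved within t_max={t_max}s")
            limit = min(limit * 2, t_max)
            logger.info("MILP timed out; retrying with limit %.0fs", limit)
            continue
        raise LikfillError(f"MILP solver failure (status {res.status}): "
                           f"{res.message}")


def gapfill_target(draft: MetabolicModel, universal: MetabolicModel,
                   costs: GapfillCosts, target: str, media: Media,
                   time_limit: float = 600.0,
                   t_max: float = DEFAULT_T_MAX,
                   epsilon: float = TARGET_EPSILON,
                   big_m: float = BIG_M) -> GapfillSolution:
    """Minimum-cost set of additions/reversals giving the target a flux of at
    least ``epsilon`` on the media."""
    if not draft.has_reaction(target):
        raise ValidationError(f"target {target!r} not in draft model")

    merged, candidates = _merge_network(draft, universal, media)
    solution = GapfillSolution(target=target, media_name=media.name,
                               mode=costs.mode, media=media)

    # Already active? No MILP needed.
    fva = run_fva(merged, [target])
    vmin, vmax = fva[target]
    if vmax >= epsilon:
        return solution

    reversals = reversal_candidates(merged, target)

    # Variable layout:
    #   [draft fluxes | cand fwd | cand rev | reversal fluxes |
    #    z cand fwd | z cand rev | z reversal | y companions]
    #
    # Each gated flux v has a binary z and an INTEGER companion y with
    # v <= y <= M*z. Without y, a binary within the solver's integrality
    # tolerance (z ~ 1e-6) leaks up to M*1e-6 = 1e-3 flux through an
    # unselected candidate — enough to fake target activation at
    # epsilon = 1e-5. The integer y caps that leak at ~1e-6.
    n_draft = len(merged.reactions)
    n_cand = len(candidates)
    n_rev = len(reversals)
    n_cont = n_draft + 2 * n_cand + n_rev
    n_bin = 2 * n_cand + n_rev
    n = n_cont + 2 * n_bin

    met_ids = {m.id: i for i, m in enumerate(merged.metabolites)}
    next_row = len(met_ids)
    for cand in candidates:
        for met_id in cand.stoichiometry:
            if met_id not in met_ids:
                met_ids[met_id] = next_row
                next_row += 1
    n_mets = next_row

    A_eq = lil_matrix((n_mets, n))
    lower = np.zeros(n)
    upper = np.zeros(n)
    cost_vec = np.zeros(n)

    draft_index = {}
    for j, rxn in enumerate(merged.reactions):
        draft_index[rxn.id] = j
        lower[j], upper[j] = rxn.lower_bound, rxn.upper_bound
        for met_id, coef in rxn.stoichiometry.items():
            A_eq[met_ids[met_id], j] += coef

    j_target = draft_index[target]
    if upper[j_target] < epsilon:
        raise InfeasibleError(
            f"target {target} upper bound {upper[j_target]} below the "
            f"required minimum flux {epsilon}")
    lower[j_target] = max(lower[j_target], epsilon)

    cand_cols = {}
    for i, cand in enumerate(candidates):
        jf = n_draft + i
        jr = n_draft + n_cand + i
        cand_cols[cand.id] = (jf, jr)
        # Candidates may be added in either direction (the wrong direction
        # pays the thermodynamic surcharge); exchanges keep the media's
        # uptake limit on the uptake (reverse) side.
        if merged_is_exchange(cand, universal):
            fwd_cap = big_m
            rev_cap = max(-cand.lower_bound, 0.0)
        else:
            fwd_cap = big_m
            rev_cap = big_m
        lower[jf], upper[jf] = 0.0, fwd_cap
        lower[jr], upper[jr] = 0.0, rev_cap
        for met_id, coef in cand.stoichiometry.items():
            row = met_ids[met_id]
            A_eq[row, jf] += coef
            A_eq[row, jr] -= coef

    rev_cols = {}
    for i, (rxn_id, new_dir) in enumerate(reversals):
        j = n_draft + 2 * n_cand + i
        rev_cols[(rxn_id, new_dir)] = j
        lower[j], upper[j] = 0.0, big_m
        sign = 1.0 if new_dir == FORWARD else -1.0
        for met_id, coef in merged.reaction(rxn_id).stoichiometry.items():
            A_eq[met_ids[met_id], j] += sign * coef

    # Binaries, integer companions, and costs.
    zf0 = n_cont
    zr0 = n_cont + n_cand
    zv0 = n_cont + 2 * n_cand
    y0 = n_cont + n_bin
    lower[n_cont:n_cont + n_bin] = 0.0
    upper[n_cont:n_cont + n_bin] = 1.0
    lower[y0:] = 0.0
    upper[y0:] = big_m
    for i, cand in enumerate(candidates):
        cost_vec[zf0 + i] = costs.addition.get(
            (cand.id, FORWARD), costs.addition_cost(cand, FORWARD))
        cost_vec[zr0 + i] = costs.addition.get(
            (cand.id, REVERSE), costs.addition_cost(cand, REVERSE))
    for i, (rxn_id, new_dir) in enumerate(reversals):
        cost_vec[zv0 + i] = costs.reversal_cost(
            merged.reaction(rxn_id), new_dir)

    # Gated flux columns in the same order as their z columns.
    gated_cols = ([n_draft + i for i in range(n_cand)]
                  + [n_draft + n_cand + i for i in range(n_cand)]
                  + [n_draft + 2 * n_cand + i for i in range(n_rev)])

    # Gating: v - y <= 0, y - M*z <= 0; and z_f + z_r <= 1 per candidate.
    A_ub = lil_matrix((2 * n_bin + n_cand, n))
    b_ub = np.zeros(2 * n_bin + n_cand)
    row = 0
    for k, vcol in enumerate(gated_cols):
        A_ub[row, vcol] = 1.0
        A_ub[row, y0 + k] = -1.0
        row += 1
        A_ub[row, y0 + k] = 1.0
        A_ub[row, n_cont + k] = -big_m
        row += 1
    for i in range(n_cand):
        A_ub[row, zf0 + i] = 1.0
        A_ub[row, zr0 + i] = 1.0
        b_ub[row] = 1.0
        row += 1

    integrality = np.zeros(n)
    integrality[n_cont:] = 1

    constraints = [
        LinearConstraint(A_eq.tocsr(), np.zeros(n_mets), np.zeros(n_mets)),
        LinearConstraint(A_ub.tocsr(), -np.inf, b_ub),
    ]
    args = {
        "c": cost_vec,
        "constraints": constraints,
        "integrality": integrality,
        "bounds": Bounds(lower, upper),
    }
    res = _solve_milp_with_escalation(args, time_limit, t_max)

    x = res.x
    for i, cand in enumerate(candidates):
        for direction, zcol, vcol in ((FORWARD, zf0 + i, n_draft + i),
                                      (REVERSE, zr0 + i, n_draft + n_cand + i)):
            if x[zcol] > 0.5 and abs(x[vcol]) > FLUX_TOL:
                gpr = costs.likelihoods.gpr(cand.id).to_string() \
                    if costs.likelihoods is not None else ""
                solution.added.append(AddedReaction(
                    reaction=cand.copy(),
                    direction=direction,
                    cost=cost_vec[zcol],
                    likelihood=costs.p(cand.id),
                    gpr=gpr,
                ))
    for i, (rxn_id, new_dir) in enumerate(reversals):
        if x[zv0 + i] > 0.5 and abs(x[n_draft + 2 * n_cand + i]) > FLUX_TOL:
            solution.reversibility_changes.append(ReversedReaction(
                reaction_id=rxn_id, new_direction=new_dir,
                cost=cost_vec[zv0 + i]))

    solution.objective_value = (
        sum(a.cost for a in solution.added)
        + sum(r.cost for r in solution.reversibility_changes))
    if abs(solution.objective_value - res.fun) > 1e-6:
        logger.warning("objective accounting drift: items %.9f vs MILP %.9f",
                       solution.objective_value, res.fun)
    solution.solver_status = "optimal"
    return solution


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate_solution(draft: MetabolicModel, sol: GapfillSolution,
                       rxn_lik: Optional[ReactionLikelihoods] = None,
                       universal: Optional[MetabolicModel] = None,
                       epsilon: float = TARGET_EPSILON,
                       big_m: float = BIG_M,
                       verify: bool = True) -> MetabolicModel:
    """Apply a solution to the draft: insert added reactions with the chosen
    direction opened (and candidate rules attached when likelihoods are
    available), apply reversibility changes, and verify target activation."""
    model = draft.copy()
    from .model_core import GprExpression, Metabolite

    for item in sol.added:
        rxn = item.reaction.copy()
        if item.direction == FORWARD:
            rxn.lower_bound = 0.0
            rxn.upper_bound = max(rxn.upper_bound, big_m)
        else:
            rxn.upper_bound = 0.0
            rxn.lower_bound = min(rxn.lower_bound, -big_m)
        if rxn_lik is not None:
            rxn.gpr = rxn_lik.gpr(rxn.id)
        elif item.gpr:
            rxn.gpr = GprExpression.parse(item.gpr)
        new_mets = []
        for met_id in rxn.stoichiometry:
            if not model.has_metabolite(met_id):
                source = universal.metabolite(met_id) if universal is not None \
                    and universal.has_metabolite(met_id) else None
                new_mets.append(Metabolite(
                    id=met_id,
                    name=source.name if source else met_id,
                    compartment=source.compartment if source
                    else ("e" if met_id.endswith("_e") else "c")))
        if model.has_reaction(rxn.id):
            continue
        model.add_reaction(rxn, metabolites=new_mets)

    for change in sol.reversibility_changes:
        rxn = model.reaction(change.reaction_id)
        if change.new_direction == REVERSE:
            rxn.lower_bound = -big_m
        else:
            rxn.upper_bound = big_m

    if verify and sol.media is not None:
        constrained = apply_media(model, sol.media)
        fva = run_fva(constrained, [sol.target])
        _, vmax = fva[sol.target]
        if vmax < epsilon - 1e-9:
            raise LikfillError(
                f"internal consistency error: target {sol.target} still "
                f"inactive (max flux {vmax:.3e}) after integration")
    return model


def attach_candidate_gprs(model: MetabolicModel,
                          rxn_lik: ReactionLikelihoods,
                          only_ids: Optional[set[str]] = None
                          ) -> MetabolicModel:
    """Post-processing for parsimony runs: attach candidate gene rules to
    reactions with positive likelihood (optionally restricted to a subset)."""
    out = model.copy()
    for rxn in out.reactions:
        if only_ids is not None and rxn.id not in only_ids:
            continue
        if rxn.gpr.is_empty() and rxn_lik.p(rxn.id) > 0:
            rxn.gpr = rxn_lik.gpr(rxn.id)
    return out
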
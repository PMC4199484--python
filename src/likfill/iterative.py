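"""Iterative gap filling over inactive gene-associated reactions, followed by
reaction-sensitivity analysis and pruning of non-contributing additions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import GapfillTimeoutError, InfeasibleError
from .fba import (INACTIVITY_TOL, apply_media, find_inactive_reactions,
                  run_fba, run_fva)
from .gapfill import (DEFAULT_T_MAX, TARGET_EPSILON, GapfillCosts,
                      GapfillSolution, gapfill_target, integrate_solution)
from .model_core import Media, MetabolicModel

logger = logging.getLogger(__name__)

GROWTH_THRESHOLD = 1e-9

_CLASS_ORDER = {"central": 0, "biosynthesis": 1, "peripheral": 2, "other": 3}


def order_targets(model: MetabolicModel, inactive: set[str] | list[str]
                  ) -> list[str]:
    """Priority ordering: central, then biosynthesis, then peripheral, then
    other; ties broken by reaction id."""
    def key(rxn_id: str) -> tuple[int, str]:
        return (_CLASS_ORDER[model.reaction(rxn_id).priority_class], rxn_id)

    return sorted(inactive, key=key)


@dataclass
class TargetOutcome:
    target: str
    status: str                        # "filled" | "already_active" | "failed"
    solution: Optional[GapfillSolution] = None
    detail: str = ""


def iterative_gapfill(draft: MetabolicModel, universal: MetabolicModel,
                      costs: GapfillCosts, media: Media,
                      time_limit: float = 600.0,
                      t_max: float = DEFAULT_T_MAX,
                      tol: float = INACTIVITY_TOL
                      ) -> tuple[MetabolicModel, list[TargetOutcome]]:
    """Gap fill every inactive gene-associated reaction, one at a time.

    Targets are processed in priority order; each is re-checked for activity
    immediately before its turn (earlier integrations may have activated it).
    Per-target infeasibility or timeout is recorded and the loop continues.
    """
    model = draft.copy()
    inactive = find_inactive_reactions(model, media, tol=tol,
                                       gene_associated_only=True)
    outcomes: list[TargetOutcome] = []
    for target in order_targets(model, inactive):
        constrained = apply_media(model, media)
        fva = run_fva(constrained, [target])
        vmin, vmax = fva[target]
        if abs(vmin) > tol or abs(vmax) > tol:
            outcomes.append(TargetOutcome(target=target,
                                          status="already_active"))
            continue
        try:
            solution = gapfill_target(model, universal, costs, target, media,
                                      time_limit=time_limit, t_max=t_max)
        except InfeasibleError as exc:
            logger.info("target %s infeasible: %s", target, exc)
            outcomes.append(TargetOutcome(target=target, status="failed",
                                          detail=str(exc)))
            continue
        except GapfillTimeoutError as exc:
            logger.info("target %s timed out: %s", target, exc)
            outcomes.append(TargetOutcome(target=target, status="failed",
                                          detail=str(exc)))
            continue
        model = integrate_solution(model, solution,
                                   rxn_lik=costs.likelihoods,
                                   universal=universal)
        outcomes.append(TargetOutcome(target=target, status="filled",
                                      solution=solution))
    return model, outcomes


# ---------------------------------------------------------------------------
# Sensitivity analysis and pruning
# ---------------------------------------------------------------------------

@dataclass
class ReactionSensitivity:
    reaction_id: str
    essential_for_biomass: bool
    activated_reactions: list[str]     # reactions inactive once it is removed

    @property
    def non_contributing(self) -> bool:
        return not self.essential_for_biomass and not self.activated_reactions


@dataclass
class SensitivityReport:
    entries: list[ReactionSensitivity] = field(default_factory=list)
    processing_order: list[str] = field(default_factory=list)

    def entry(self, rxn_id: str) -> ReactionSensitivity:
        for e in self.entries:
            if e.reaction_id == rxn_id:
                return e
        raise KeyError(rxn_id)

    def non_contributing_ids(self) -> list[str]:
        return [e.reaction_id for e in self.entries if e.non_contributing]

    def to_dict(self) -> dict:
        return {
            "processing_order": list(self.processing_order),
            "entries": [
                {"reaction_id": e.reaction_id,
                 "essential_for_biomass": e.essential_for_biomass,
                 "activated_reactions": list(e.activated_reactions),
                 "non_contributing": e.non_contributing}
                for e in self.entries
            ],
        }


def sensitivity_order(gapfilled: list[tuple[str, float, int]],
                      mode: str) -> list[str]:
    """Parsimony: reverse order of addition (last added tested first).
    Likelihood: ascending likelihood (weakest evidence tested first)."""
    if mode == "parsimony":
        ranked = sorted(gapfilled, key=lambda t: -t[2])
    else:
        ranked = sorted(gapfilled, key=lambda t: (t[1], t[2]))
    return [rxn_id for rxn_id, _, _ in ranked]


def _inactive_set(model: MetabolicModel, media: Media,
                  tol: float) -> set[str]:
    return set(find_inactive_reactions(model, media, tol=tol))


def _assess(model: MetabolicModel, media: Media, rxn_id: str,
            baseline_inactive: set[str], tol: float,
            threshold: float) -> ReactionSensitivity:
    removed = model.copy()
    removed.remove_reaction(rxn_id)
    growth = run_fba(apply_media(removed, media))
    essential = (not growth.ok) or growth.objective_value < threshold
    now_inactive = _inactive_set(removed, media, tol)
    activated = sorted(now_inactive - baseline_inactive)
    return ReactionSensitivity(reaction_id=rxn_id,
                               essential_for_biomass=essential,
                               activated_reactions=activated)


def reaction_sensitivity(model: MetabolicModel,
                         gapfilled: list[tuple[str, float, int]],
                         mode: str, media: Media,
                         threshold: float = GROWTH_THRESHOLD,
                         tol: float = INACTIVITY_TOL) -> SensitivityReport:
    """For each gap-filled reaction (id, likelihood, addition order): does
    removing it kill biomass, and which reactions does it keep active?"""
    report = SensitivityReport()
    baseline_inactive = _inactive_set(model, media, tol)
    for rxn_id in sensitivity_order(gapfilled, mode):
        if not model.has_reaction(rxn_id):
            continue
        report.processing_order.append(rxn_id)
        report.entries.append(_assess(model, media, rxn_id,
                                      baseline_inactive, tol, threshold))
    return report


def prune_noncontributing(model: MetabolicModel, report: SensitivityReport,
                          media: Optional[Media] = None,
                          threshold: float = GROWTH_THRESHOLD,
                          tol: float = INACTIVITY_TOL) -> MetabolicModel:
    """Greedily remove non-contributing reactions in the report's processing
    order, re-assessing after every removal so that mutually redundant
    additions are not both removed.

    ``media`` must be supplied for re-assessment; when omitted the report is
    applied as-is (no re-evaluation), which is only safe for a single flag.
    """
    out = model.copy()
    flagged = [e.reaction_id for e in report.entries if e.non_contributing]
    if not flagged:
        return out
    if media is None:
        raise ValueError("media required to re-assess during pruning")

    for rxn_id in flagged:
        if not out.has_reaction(rxn_id):
            continue
        baseline_inactive = _inactive_set(out, media, tol)
        verdict = _assess(out, media, rxn_id, baseline_inactive, tol,
                          threshold)
        if verdict.non_contributing:
            out.remove_reaction(rxn_id)

    growth = run_fba(apply_media(out, media))
    if (not growth.ok) or growth.objective_value < threshold:
        raise RuntimeError("internal consistency error: biomass lost after "
                           "pruning despite essentiality checks")
    return out
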
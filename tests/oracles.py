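"""Independent brute-force implementations used to cross-check the package.

Nothing here imports the code paths under test: the likelihood oracle is
plain-loop arithmetic over raw rows, and the gap-filling oracle enumerates
candidate subsets with direct ``scipy.optimize.linprog`` feasibility checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog

# ---------------------------------------------------------------------------
# Likelihood chain, by direct summation
# ---------------------------------------------------------------------------


def brute_force_likelihoods(hits, reference, annotation_roles, complex_roles,
                            complex_reactions, k=1e-200, pseudocount=40.0,
                            retain_fraction=0.8, e_cutoff=1e-5):
    """Recompute every level of the likelihood chain with naive loops.

    hits: iterable of (query, target, evalue) raw rows (pre-filter).
    reference: dict target -> annotation.
    annotation_roles: dict annotation -> set of roles.
    complex_roles: dict complex -> set of roles.
    complex_reactions: dict complex -> set of reactions.

    Returns (annotation_p, role_p_per_gene, role_p_org, complex_p, reaction_p).
    """
    best = {}
    for q, t, e in hits:
        if e > e_cutoff:
            continue
        if (q, t) not in best or e < best[(q, t)]:
            best[(q, t)] = e

    by_query = {}
    for (q, t), e in best.items():
        by_query.setdefault(q, []).append((t, -math.log10(e + k)))

    annotation_p = {}
    for q, rows in by_query.items():
        s_max = max(s for _, s in rows)
        denom = pseudocount * s_max + sum(s * s for _, s in rows)
        for t, s in rows:
            a = " ".join(reference[t].split())
            key = (q, a)
            annotation_p[key] = annotation_p.get(key, 0.0) + s * s / denom

    role_p_per_gene = {}
    for (q, a), p in annotation_p.items():
        for r in annotation_roles.get(a, ()):
            key = (q, r)
            role_p_per_gene[key] = role_p_per_gene.get(key, 0.0) + p

    all_roles = set()
    for rs in annotation_roles.values():
        all_roles |= set(rs)
    for rs in complex_roles.values():
        all_roles |= set(rs)

    role_p_org = {}
    retained = {}
    for r in all_roles:
        vals = [(q, p) for (q, rr), p in role_p_per_gene.items() if rr == r]
        if not vals:
            role_p_org[r] = 0.0
            retained[r] = []
            continue
        p_org = max(p for _, p in vals)
        role_p_org[r] = p_org
        retained[r] = sorted(q for q, p in vals
                             if p >= retain_fraction * p_org)

    complex_p = {}
    for c, roles in complex_roles.items():
        complex_p[c] = min(role_p_org[r] for r in roles)

    reaction_p = {}
    all_reactions = set()
    for xs in complex_reactions.values():
        all_reactions |= set(xs)
    for x in all_reactions:
        linked = [c for c, xs in complex_reactions.items() if x in xs]
        linked = [c for c in linked if c in complex_p]
        reaction_p[x] = max((complex_p[c] for c in linked), default=0.0)

    return annotation_p, role_p_per_gene, role_p_org, complex_p, reaction_p


# ---------------------------------------------------------------------------
# Gap filling, by exhaustive subset enumeration
# ---------------------------------------------------------------------------

BIG_M = 1000.0
EPSILON = 1e-5


def _candidate_cost(rxn, direction, mode, p, transporter_pen=25.0,
                    lowdb_pen=5.0):
    base = 1.0
    if rxn.is_transporter:
        base += transporter_pen
    if rxn.source_confidence == "low":
        base += lowdb_pen
    if mode == "likelihood":
        base *= 1.0 - p
    g = rxn.delta_g
    if g is not None:
        opposing = g if direction == "forward" else -g
        if opposing > 0:
            base += (12.0 + 2.0 * opposing) / 10.0
    return base


def enumerate_gapfill(draft, universal, target, media, mode, likelihoods,
                      max_candidates=14):
    """Minimum-cost candidate subset activating the target, by enumeration.

    Candidates are every direction of every universal reaction absent from
    the draft (no reversal candidates: callers use drafts whose reactions are
    reversible or exchanges). Returns (best_cost, best_subset_ids) or
    (None, None) if no subset works. Supersets of feasible subsets are
    pruned: with nonnegative costs they cannot improve the optimum.
    """
    cand_rxns = [r for r in universal.reactions
                 if not draft.has_reaction(r.id)]
    candidates = []
    for rxn in cand_rxns:
        p = likelihoods.p(rxn.id) if likelihoods is not None else 0.0
        for direction in ("forward", "reverse"):
            cost = _candidate_cost(rxn, direction, mode, p)
            candidates.append((rxn, direction, cost))
    assert len(candidates) <= max_candidates

    base_reactions = []
    for rxn in draft.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if draft.is_exchange(rxn.id):
            (met,) = rxn.stoichiometry
            lb = -media.uptake_limits.get(met, 0.0)
            ub = max(ub, 0.0)
        if rxn.id == target:
            lb = max(lb, EPSILON)
        base_reactions.append((rxn, lb, ub))

    met_comp = {m.id: m.compartment for m in universal.metabolites}
    for m in draft.metabolites:
        met_comp.setdefault(m.id, m.compartment)

    def feasible(subset):
        met_ids = {}
        cols = []
        for rxn, lb, ub in base_reactions:
            cols.append((rxn.stoichiometry, lb, ub))
        for idx in subset:
            rxn, direction, _ = candidates[idx]
            if len(rxn.stoichiometry) == 1 and \
                    met_comp[next(iter(rxn.stoichiometry))] == "e":
                (met,) = rxn.stoichiometry
                rev_cap = media.uptake_limits.get(met, 0.0)
            else:
                rev_cap = BIG_M
            if direction == "forward":
                cols.append((rxn.stoichiometry, 0.0, BIG_M))
            else:
                flipped = {m: -c for m, c in rxn.stoichiometry.items()}
                cols.append((flipped, 0.0, rev_cap))
        for stoich, _, _ in cols:
            for m in stoich:
                met_ids.setdefault(m, len(met_ids))
        A = np.zeros((len(met_ids), len(cols)))
        bounds = []
        for j, (stoich, lb, ub) in enumerate(cols):
            bounds.append((lb, ub))
            for m, c in stoich.items():
                A[met_ids[m], j] += c
        res = linprog(np.zeros(len(cols)), A_eq=A,
                      b_eq=np.zeros(len(met_ids)), bounds=bounds,
                      method="highs")
        return res.status == 0

    best_cost, best_subset = None, None
    feasible_subsets: list[frozenset] = []
    indices = range(len(candidates))
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(indices, size):
            fs = frozenset(combo)
            if any(known <= fs for known in feasible_subsets):
                continue
            if feasible(combo):
                feasible_subsets.append(fs)
                cost = sum(candidates[i][2] for i in combo)
                if best_cost is None or cost < best_cost - 1e-12:
                    best_cost = cost
                    best_subset = sorted(
                        (candidates[i][0].id, candidates[i][1])
                        for i in combo)
    return best_cost, best_subset
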
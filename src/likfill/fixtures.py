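"""Seeded synthetic-data generators.

:func:`make_toy_universe` builds a deterministic small world containing every
input the rest of the package consumes: a universal reaction database, a
biochemistry template, a genome with planted homology evidence, a
high-confidence reference, a gold-standard model, media, and phenotypes.

The network embeds the two-pathway selection scenario: the precursor ``p_c``
can be made either through a 2-reaction path (S1, S2) with no gene evidence
or a 4-reaction path (L1..L4) whose genes carry planted evidence giving each
reaction a likelihood of 0.9. Parsimony-weighted gap filling picks the short
path; likelihood-weighted gap filling picks the long one.

Evidence is planted by inverting the scoring formula: a pair of hits at
log-score S to reference proteins sharing one annotation yields
``p = 2S/(PC + 2S)``, so S = 180 gives p = 0.9 exactly and S = 80 gives 0.8.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .likelihood import (BiochemTemplate, BlastHitTable, ReactionLikelihoods,
                         ReferenceDb, likelihood_chain)
from .model_core import (GprExpression, Media, MetabolicModel, Metabolite,
                         Reaction, write_model, write_sidecar)
from .phenotype import PhenotypeEntry, PhenotypeSet

PSEUDOCOUNT = 40.0


def _score_for_pair_hit(p: float, pseudocount: float = PSEUDOCOUNT) -> float:
    """Log-score such that two equal hits sharing one annotation give p."""
    return pseudocount * p / (2.0 * (1.0 - p))


def _score_for_single_hit(p: float, pseudocount: float = PSEUDOCOUNT) -> float:
    return pseudocount * p / (1.0 - p)


@dataclass
class ToyUniverse:
    seed: int
    universal: MetabolicModel
    gold_model: MetabolicModel
    template: BiochemTemplate
    genome: dict[str, str]                  # gene id -> annotation string
    reference: ReferenceDb
    blast: BlastHitTable
    media: dict[str, Media]
    phenotypes: PhenotypeSet
    planted_likelihoods: dict[str, float]   # reaction id -> target p
    long_path_ids: list[str] = field(default_factory=list)
    short_path_ids: list[str] = field(default_factory=list)
    growth_media_name: str = "glucose_minimal"

    @property
    def growth_media(self) -> Media:
        return self.media[self.growth_media_name]

    def reaction_likelihoods(self) -> ReactionLikelihoods:
        return likelihood_chain(self.blast, self.reference, self.template)


def _build_metabolites() -> list[Metabolite]:
    ext = ["glc_e", "nh4_e", "u_e", "x_e"]
    cyt = ["glc_c", "nh4_c", "u_c", "x_c", "a_c", "b_c", "p_c", "n_c",
           "s1_c", "l1_c", "l2_c", "l3_c", "w_c", "d1_c", "f1_c", "f2_c"]
    mets = [Metabolite(id=m, name=m, compartment="e") for m in ext]
    mets += [Metabolite(id=m, name=m, compartment="c") for m in cyt]
    return mets


def _rxn(rxn_id: str, stoich: dict[str, float], lb: float = 0.0,
         ub: float = 1000.0, gpr: str = "", delta_g=None,
         transporter: bool = False, confidence: str = "high",
         priority: str = "other") -> Reaction:
    return Reaction(id=rxn_id, stoichiometry=stoich, lower_bound=lb,
                    upper_bound=ub, gpr=GprExpression.parse(gpr),
                    delta_g=delta_g, is_transporter=transporter,
                    source_confidence=confidence, priority_class=priority)


def make_toy_universe(seed: int) -> ToyUniverse:
    """Deterministic synthetic world; identical output for identical seed."""
    rng = np.random.default_rng(seed)

    mets = _build_metabolites()

    # reaction id -> (gene spec, target likelihood). Gene spec is a list of
    # OR-groups; each group is AND-ed into the complex.
    evidence: dict[str, tuple[list[list[str]], float]] = {
        "T_glc": ([["gT1"]], 0.9),
        "T_nh4": ([["gT2"]], 0.9),
        "T_u": ([["gT3"]], 0.9),
        "R_core1": ([["g1"]], 0.9),
        "R_core2": ([["g2a", "g2b"]], 0.9),      # isozymes, p 0.9 / 0.8
        "R_nit": ([["g3a"], ["g3b"]], 0.9),      # two-subunit complex
        "R_u": ([["g4"]], 0.9),
        "L1": ([["gL1"]], 0.9),
        "L2": ([["gL2"]], 0.9),
        "L3": ([["gL3"]], 0.9),
        "L4": ([["gL4"]], 0.9),
    }

    gold_reactions = [
        _rxn("EX_glc_e", {"glc_e": -1.0}),
        _rxn("EX_nh4_e", {"nh4_e": -1.0}),
        _rxn("EX_u_e", {"u_e": -1.0}),
        _rxn("T_glc", {"glc_e": -1.0, "glc_c": 1.0}, gpr="gT1",
             transporter=True, priority="central"),
        _rxn("T_nh4", {"nh4_e": -1.0, "nh4_c": 1.0}, gpr="gT2",
             transporter=True, priority="central"),
        _rxn("T_u", {"u_e": -1.0, "u_c": 1.0}, gpr="gT3",
             transporter=True, priority="peripheral"),
        _rxn("R_core1", {"glc_c": -1.0, "a_c": 1.0}, gpr="g1",
             priority="central"),
        _rxn("R_core2", {"a_c": -1.0, "b_c": 1.0}, gpr="g2a or g2b",
             priority="central"),
        _rxn("R_nit", {"nh4_c": -1.0, "b_c": -1.0, "n_c": 1.0},
             gpr="g3a and g3b", priority="biosynthesis"),
        _rxn("L1", {"a_c": -1.0, "l1_c": 1.0}, gpr="gL1", delta_g=-5.0,
             priority="biosynthesis"),
        _rxn("L2", {"l1_c": -1.0, "l2_c": 1.0}, gpr="gL2", delta_g=-5.0,
             priority="biosynthesis"),
        _rxn("L3", {"l2_c": -1.0, "l3_c": 1.0}, gpr="gL3", delta_g=-5.0,
             priority="biosynthesis"),
        _rxn("L4", {"l3_c": -1.0, "p_c": 1.0}, gpr="gL4", delta_g=-5.0,
             priority="biosynthesis"),
        _rxn("R_u", {"u_c": -1.0, "a_c": 1.0}, gpr="g4",
             priority="peripheral"),
        _rxn("bio1", {"b_c": -1.0, "p_c": -1.0, "n_c": -1.0}),
    ]

    # Universal-only candidates: the short zero-evidence path, penalty
    # exercisers, decoys, and dead-end fillers.
    # keep decoy likelihoods >= 0.2 so their planted pair-hit scores stay
    # above the E-value ingest cutoff (S = 5 <=> p = 0.2)
    decoy_p1 = float(rng.uniform(0.22, 0.35))
    decoy_p2 = float(rng.uniform(0.22, 0.35))
    universal_only = [
        _rxn("S1", {"a_c": -1.0, "s1_c": 1.0}),
        _rxn("S2", {"s1_c": -1.0, "p_c": 1.0}),
        _rxn("R_unfav", {"b_c": -1.0, "a_c": 1.0}, delta_g=10.0),
        _rxn("EX_x_e", {"x_e": -1.0}),
        _rxn("T_x", {"x_e": -1.0, "x_c": 1.0}, transporter=True),
        _rxn("R_x", {"x_c": -1.0, "a_c": 1.0}),
        _rxn("R_lowconf", {"a_c": -1.0, "w_c": 1.0}, confidence="low"),
        _rxn("R_w2", {"w_c": -1.0, "b_c": 1.0}),
        _rxn("D1", {"a_c": -1.0, "d1_c": 1.0}),
        _rxn("D2", {"d1_c": -1.0, "b_c": 1.0}),
        _rxn("F1", {"b_c": -1.0, "f1_c": 1.0}, priority="peripheral"),
        _rxn("F2", {"f1_c": -1.0, "f2_c": 1.0}, priority="peripheral"),
    ]
    evidence["D1"] = ([["gD1"]], decoy_p1)
    evidence["D2"] = ([["gD2"]], decoy_p2)

    # The universal database carries no gene rules; rules are attached from
    # computed evidence (or curated ones live in the gold model only).
    universal_copies = []
    for r in gold_reactions:
        stripped = r.copy()
        stripped.gpr = GprExpression.empty()
        universal_copies.append(stripped)
    universal = MetabolicModel(
        id=f"toy_universal_seed{seed}",
        metabolites=mets,
        reactions=universal_copies + universal_only,
        biomass_reaction_id="bio1")

    gold = MetabolicModel(
        id=f"toy_gold_seed{seed}",
        metabolites=[m for m in mets if m.id not in
                     ("x_e", "x_c", "s1_c", "w_c", "d1_c", "f1_c", "f2_c")],
        reactions=gold_reactions,
        biomass_reaction_id="bio1")

    # ---- evidence plumbing: template, reference, genome, BLAST hits ------
    annotation_roles: dict[str, set[str]] = {}
    complex_roles: dict[str, set[str]] = {}
    complex_reactions: dict[str, set[str]] = {}
    reference: dict[str, str] = {}
    genome: dict[str, str] = {}
    blast_rows: list[tuple[str, str, float]] = []
    planted: dict[str, float] = {r.id: 0.0 for r in universal.reactions}

    for rxn_id in sorted(evidence):
        groups, target_p = evidence[rxn_id]
        cpx = f"cpx_{rxn_id}"
        complex_reactions[cpx] = {rxn_id}
        complex_roles[cpx] = set()
        planted[rxn_id] = target_p
        for gi, genes in enumerate(groups):
            role = f"role_{rxn_id}_{gi}"
            annotation = f"ann {rxn_id} {gi}"
            annotation_roles[annotation] = {role}
            complex_roles[cpx].add(role)
            ref_targets = [f"ref_{rxn_id}_{gi}_{t}" for t in (1, 2)]
            for tgt in ref_targets:
                reference[tgt] = annotation
            for gj, gene in enumerate(genes):
                # first gene in a group gets the full target likelihood;
                # later isozymes get 0.8 (still within the retention band).
                p = target_p if gj == 0 else 0.8
                score = _score_for_pair_hit(p)
                evalue = 10.0 ** (-score)
                genome[gene] = annotation
                for tgt in ref_targets:
                    blast_rows.append((gene, tgt, evalue))

    template = BiochemTemplate(annotation_roles, complex_roles,
                               complex_reactions)
    blast = BlastHitTable(blast_rows)
    ref_db = ReferenceDb(reference)

    media = {
        "glucose_minimal": Media("glucose_minimal",
                                 {"glc_e": 10.0, "nh4_e": 100.0}),
        "u_minimal": Media("u_minimal", {"u_e": 10.0, "nh4_e": 100.0}),
        "no_carbon": Media("no_carbon", {"nh4_e": 100.0}),
    }

    glc = media["glucose_minimal"]
    phenotypes = PhenotypeSet(entries=[
        PhenotypeEntry("knockout", "g1", observed_growth=False, media=glc),
        PhenotypeEntry("knockout", "gT2", observed_growth=False, media=glc),
        PhenotypeEntry("knockout", "gL1", observed_growth=False, media=glc),
        PhenotypeEntry("knockout", "g2a", observed_growth=True, media=glc),
        PhenotypeEntry("knockout", "g4", observed_growth=True, media=glc),
        PhenotypeEntry("biolog", "glucose_minimal", observed_growth=True),
        PhenotypeEntry("biolog", "u_minimal", observed_growth=True),
        PhenotypeEntry("biolog", "no_carbon", observed_growth=False),
    ])

    return ToyUniverse(
        seed=seed,
        universal=universal,
        gold_model=gold,
        template=template,
        genome=genome,
        reference=ref_db,
        blast=blast,
        media=media,
        phenotypes=phenotypes,
        planted_likelihoods=planted,
        long_path_ids=["L1", "L2", "L3", "L4"],
        short_path_ids=["S1", "S2"],
    )


# ---------------------------------------------------------------------------
# Draft construction and editing
# ---------------------------------------------------------------------------

def make_draft_model(genome: dict[str, str], template: BiochemTemplate,
                     universal: MetabolicModel,
                     rxn_lik: ReactionLikelihoods,
                     include_threshold: float) -> MetabolicModel:
    """Template draft: universal reactions with likelihood at or above the
    threshold (rules attached), plus exchanges for transported compounds and
    the biomass reaction."""
    if not 0.0 <= include_threshold <= 1.0:
        raise ValidationError(
            f"include_threshold must be in [0, 1], got {include_threshold}")
    selected: dict[str, Reaction] = {}
    for rxn in universal.reactions:
        if rxn_lik.p(rxn.id) >= include_threshold and rxn_lik.p(rxn.id) > 0:
            picked = rxn.copy()
            picked.gpr = rxn_lik.gpr(rxn.id)
            selected[rxn.id] = picked
    biomass = universal.reaction(universal.biomass_reaction_id).copy()
    selected.setdefault(biomass.id, biomass)
    # exchanges for every extracellular compound touched by a selected
    # transporter
    comp_of = {m.id: m.compartment for m in universal.metabolites}
    for rxn in list(selected.values()):
        if not rxn.is_transporter:
            continue
        for met_id in rxn.stoichiometry:
            if comp_of[met_id] != "e":
                continue
            exchange = universal.exchange_for(met_id)
            if exchange is not None and exchange.id not in selected:
                selected[exchange.id] = exchange.copy()
    met_ids = {m for rxn in selected.values() for m in rxn.stoichiometry}
    metabolites = [m for m in universal.metabolites if m.id in met_ids]
    return MetabolicModel(
        id=f"draft_{universal.id}",
        metabolites=metabolites,
        reactions=[selected[k] for k in sorted(selected)],
        biomass_reaction_id=universal.biomass_reaction_id)


def remove_reactions(model: MetabolicModel, ids: list[str]) -> MetabolicModel:
    """Copy of the model without the listed reactions (unknown id -> error)."""
    out = model.copy()
    for rxn_id in ids:
        out.remove_reaction(rxn_id)
    return out


# ---------------------------------------------------------------------------
# Small randomized gap-filling instances (for oracle comparisons)
# ---------------------------------------------------------------------------

@dataclass
class SmallGapfillInstance:
    seed: int
    draft: MetabolicModel
    universal: MetabolicModel
    likelihoods: ReactionLikelihoods
    media: Media
    target: str


def make_small_gapfill_instance(seed: int,
                                n_candidates: int = 5
                                ) -> SmallGapfillInstance:
    """Random chain network with a gap and a handful of candidate reactions
    (2 directions each), small enough for exhaustive subset enumeration."""
    rng = np.random.default_rng(seed)
    n_nodes = 5
    mets = [Metabolite(id="s_e", name="s_e", compartment="e")]
    mets += [Metabolite(id=f"m{i}_c", name=f"m{i}_c", compartment="c")
             for i in range(n_nodes)]

    draft_reactions = [
        _rxn("EX_s_e", {"s_e": -1.0}),
        _rxn("T_s", {"s_e": -1.0, "m0_c": 1.0}, lb=-1000.0, transporter=True),
        _rxn("tgt", {f"m{n_nodes - 1}_c": -1.0}),
    ]
    draft = MetabolicModel(id=f"small_draft_{seed}", metabolites=mets,
                           reactions=draft_reactions,
                           biomass_reaction_id="tgt")

    candidates = []
    lik_entries: dict[str, tuple[float, GprExpression]] = {}
    for k in range(n_candidates):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        stoich = {f"m{i}_c": -1.0, f"m{j}_c": 1.0}
        delta_g = None
        if rng.random() < 0.5:
            delta_g = float(np.round(rng.uniform(-15.0, 15.0), 3))
        confidence = "low" if rng.random() < 0.3 else "high"
        p = 0.0
        if rng.random() < 0.7:
            p = float(np.round(rng.uniform(0.0, 0.95), 4))
        rxn_id = f"c{k}"
        candidates.append(_rxn(rxn_id, stoich, delta_g=delta_g,
                               confidence=confidence))
        lik_entries[rxn_id] = (p, GprExpression.empty())

    universal = MetabolicModel(
        id=f"small_universal_{seed}", metabolites=mets,
        reactions=[r.copy() for r in draft_reactions] + candidates,
        biomass_reaction_id="tgt")
    media = Media(name="s_media", uptake_limits={"s_e": 10.0})
    return SmallGapfillInstance(
        seed=seed, draft=draft, universal=universal,
        likelihoods=ReactionLikelihoods(entries=lik_entries),
        media=media, target="tgt")


# ---------------------------------------------------------------------------
# Serialization of a whole universe
# ---------------------------------------------------------------------------

def write_universe(universe: ToyUniverse, out_dir: str,
                   model_format: str = "json") -> None:
    """Write every fixture input as plain-text files under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    ext = "json" if model_format == "json" else "xml"
    write_model(universe.universal, os.path.join(out_dir, f"universal.{ext}"),
                format=model_format)
    write_sidecar(universe.universal,
                  os.path.join(out_dir, "universal.attrs.tsv"))
    write_model(universe.gold_model, os.path.join(out_dir, f"gold.{ext}"),
                format=model_format)
    write_sidecar(universe.gold_model, os.path.join(out_dir, "gold.attrs.tsv"))
    universe.template.to_tsvs(
        os.path.join(out_dir, "annotation_to_role.tsv"),
        os.path.join(out_dir, "complex_roles.tsv"),
        os.path.join(out_dir, "complex_reactions.tsv"))
    universe.reference.to_tsv(os.path.join(out_dir, "reference.tsv"))
    with open(os.path.join(out_dir, "genome.tsv"), "w") as fh:
        fh.write("gene_id\tannotation\n")
        for gene in sorted(universe.genome):
            fh.write(f"{gene}\t{universe.genome[gene]}\n")
    with open(os.path.join(out_dir, "blast.tsv"), "w") as fh:
        fh.write("qseqid\tsseqid\tevalue\n")
        for query, target, evalue in universe.blast.rows:
            fh.write(f"{query}\t{target}\t{evalue:.6g}\n")
    for name, media in universe.media.items():
        media.to_tsv(os.path.join(out_dir, f"media_{name}.tsv"))
    universe.phenotypes.to_tsv(os.path.join(out_dir, "phenotypes.tsv"))
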
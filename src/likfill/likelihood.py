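"""Homology-evidence scoring: BLAST hits -> annotation -> role -> complex ->
reaction likelihoods, with Boolean gene-rule assembly.

The chain is:

1. log-score each retained hit, ``S = -log10(E + k)`` with ``k = 1e-200``;
2. annotation likelihood per gene with a pseudocount ``PC = 40``::

       p(i in A_a) = sum_{j in A_a} S_ij^2
                     ---------------------------------
                     PC * S_i,max + sum_{all j} S_ij^2

   calibrated so a lone hit at E = 1e-40 scores exactly 0.5;
3. role likelihood per gene = sum of its annotation likelihoods mapping to
   the role; organism role likelihood = max over genes, retaining genes
   within 80% of the max OR-linked;
4. complex likelihood = min over member roles (subunits AND-linked);
5. reaction likelihood = max over complexes, retaining complexes within 80%
   of the max OR-linked into the final gene rule.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .exceptions import ValidationError
from .model_core import GprExpression, MetabolicModel

E_VALUE_CUTOFF = 1e-5
LOG_SCORE_K = 1e-200
PSEUDOCOUNT = 40.0
RETAIN_FRACTION = 0.8


def _normalize_annotation(text: str) -> str:
    return " ".join(text.split())


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------

class BlastHitTable:
    """Filtered, deduplicated (query, target, e_value) rows.

    Ingest drops hits with E > cutoff and keeps the best (smallest) E-value
    per (query, target) pair.
    """

    def __init__(self, rows: Iterable[tuple[str, str, float]],
                 e_cutoff: float = E_VALUE_CUTOFF):
        best: dict[tuple[str, str], float] = {}
        for query, target, evalue in rows:
            evalue = float(evalue)
            if evalue < 0:
                raise ValidationError(
                    f"negative E-value {evalue} for ({query}, {target})")
            if evalue > e_cutoff:
                continue
            key = (query, target)
            if key not in best or evalue < best[key]:
                best[key] = evalue
        self.rows: list[tuple[str, str, float]] = [
            (q, t, e) for (q, t), e in sorted(best.items())
        ]

    def __len__(self) -> int:
        return len(self.rows)

    def queries(self) -> set[str]:
        return {q for q, _, _ in self.rows}

    @classmethod
    def from_tsv(cls, path: str,
                 e_cutoff: float = E_VALUE_CUTOFF) -> "BlastHitTable":
        """Read BLAST tabular output.

        Accepts either a 3+ column table with header containing qseqid,
        sseqid, evalue, or headerless outfmt-6 (12 columns: evalue is column
        11, 0-based 10) or a plain 3-column (query, target, evalue) table.
        """
        rows = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            table = [row for row in reader if row and row[0].strip()
                     and not row[0].startswith("#")]
        if not table:
            return cls([], e_cutoff=e_cutoff)
        header = [h.strip().lower() for h in table[0]]
        if "qseqid" in header and "evalue" in header:
            qi = header.index("qseqid")
            si = header.index("sseqid")
            ei = header.index("evalue")
            body = table[1:]
        elif len(table[0]) >= 12:
            qi, si, ei = 0, 1, 10
            body = table
        else:
            qi, si, ei = 0, 1, 2
            body = table
        for row in body:
            rows.append((row[qi], row[si], float(row[ei])))
        return cls(rows, e_cutoff=e_cutoff)


class ReferenceDb:
    """High-confidence reference: each target gene carries ONE annotation."""

    def __init__(self, annotations: dict[str, str]):
        self.annotations = {gene: _normalize_annotation(ann)
                            for gene, ann in annotations.items()}

    def __contains__(self, gene: str) -> bool:
        return gene in self.annotations

    def __getitem__(self, gene: str) -> str:
        return self.annotations[gene]

    def __len__(self) -> int:
        return len(self.annotations)

    @classmethod
    def from_tsv(cls, path: str) -> "ReferenceDb":
        annotations: dict[str, str] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0] == "gene_id":
                    continue
                gene, annotation = row[0], row[1]
                if gene in annotations:
                    raise ValidationError(
                        f"{path}: reference gene {gene} annotated twice")
                annotations[gene] = annotation
        return cls(annotations)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_id", "annotation"])
            for gene in sorted(self.annotations):
                writer.writerow([gene, self.annotations[gene]])


@dataclass
class LogScoreTable:
    rows: list[tuple[str, str, float]]   # (query, target, S)
    k: float = LOG_SCORE_K

    def by_query(self) -> dict[str, list[tuple[str, float]]]:
        out: dict[str, list[tuple[str, float]]] = {}
        for query, target, score in self.rows:
            out.setdefault(query, []).append((target, score))
        return out


@dataclass
class AnnotationLikelihoods:
    """p(gene has annotation) per (gene, annotation), plus per-gene S_max."""

    probabilities: dict[str, dict[str, float]]
    s_max: dict[str, float]
    pseudocount: float = PSEUDOCOUNT

    def p(self, gene: str, annotation: str) -> float:
        return self.probabilities.get(gene, {}).get(
            _normalize_annotation(annotation), 0.0)

    def genes(self) -> list[str]:
        return sorted(self.probabilities)


class BiochemTemplate:
    """annotation->roles, complex->roles, complex->reactions mappings."""

    def __init__(self,
                 annotation_roles: dict[str, set[str]],
                 complex_roles: dict[str, set[str]],
                 complex_reactions: dict[str, set[str]]):
        self.annotation_roles = {
            _normalize_annotation(a): set(rs)
            for a, rs in annotation_roles.items()
        }
        self.complex_roles = {c: set(rs) for c, rs in complex_roles.items()}
        self.complex_reactions = {c: set(xs)
                                  for c, xs in complex_reactions.items()}
        mapped_roles = set()
        for roles in self.annotation_roles.values():
            mapped_roles |= roles
        self.orphan_roles = set()
        for cpx, roles in self.complex_roles.items():
            self.orphan_roles |= roles - mapped_roles

    def roles(self) -> set[str]:
        out = set()
        for rs in self.annotation_roles.values():
            out |= rs
        for rs in self.complex_roles.values():
            out |= rs
        return out

    def reactions(self) -> set[str]:
        out = set()
        for xs in self.complex_reactions.values():
            out |= xs
        return out

    def complexes_for_reaction(self, reaction: str) -> list[str]:
        return sorted(c for c, xs in self.complex_reactions.items()
                      if reaction in xs)

    @classmethod
    def from_tsvs(cls, annotation_to_role: str, complex_roles: str,
                  complex_reactions: str) -> "BiochemTemplate":
        def read_pairs(path: str, header: tuple[str, str]) -> list[tuple[str, str]]:
            pairs = []
            with open(path, newline="") as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if not row or tuple(row[:2]) == header:
                        continue
                    pairs.append((row[0], row[1]))
            return pairs

        ann_roles: dict[str, set[str]] = {}
        for ann, role in read_pairs(annotation_to_role, ("annotation", "role")):
            ann_roles.setdefault(ann, set()).add(role)
        cpx_roles: dict[str, set[str]] = {}
        for cpx, role in read_pairs(complex_roles, ("complex", "role")):
            cpx_roles.setdefault(cpx, set()).add(role)
        cpx_rxns: dict[str, set[str]] = {}
        for cpx, rxn in read_pairs(complex_reactions, ("complex", "reaction")):
            cpx_rxns.setdefault(cpx, set()).add(rxn)
        return cls(ann_roles, cpx_roles, cpx_rxns)

    def to_tsvs(self, annotation_to_role: str, complex_roles: str,
                complex_reactions: str) -> None:
        def write_pairs(path: str, header: tuple[str, str],
                        mapping: dict[str, set[str]]) -> None:
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                writer.writerow(header)
                for key in sorted(mapping):
                    for value in sorted(mapping[key]):
                        writer.writerow([key, value])

        write_pairs(annotation_to_role, ("annotation", "role"),
                    self.annotation_roles)
        write_pairs(complex_roles, ("complex", "role"), self.complex_roles)
        write_pairs(complex_reactions, ("complex", "reaction"),
                    self.complex_reactions)


@dataclass
class RoleLikelihoods:
    per_gene: dict[str, dict[str, float]]          # gene -> role -> p
    organism: dict[str, float]                     # role -> max over genes
    retained_genes: dict[str, list[str]]           # role -> genes within 80%

    def p_org(self, role: str) -> float:
        return self.organism.get(role, 0.0)


@dataclass
class ComplexLikelihood:
    likelihood: float
    gpr: GprExpression


@dataclass
class ReactionLikelihoods:
    entries: dict[str, tuple[float, GprExpression]]
    complex_diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)

    def p(self, reaction: str) -> float:
        return self.entries.get(reaction, (0.0, None))[0]

    def gpr(self, reaction: str) -> GprExpression:
        if reaction in self.entries:
            return self.entries[reaction][1]
        return GprExpression.empty()

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["reaction_id", "likelihood", "gpr"])
            for rxn in sorted(self.entries):
                p, gpr = self.entries[rxn]
                writer.writerow([rxn, repr(p), gpr.to_string()])

    @classmethod
    def from_tsv(cls, path: str) -> "ReactionLikelihoods":
        entries: dict[str, tuple[float, GprExpression]] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0] == "reaction_id":
                    continue
                rxn, p, gpr = row[0], float(row[1]), row[2] if len(row) > 2 else ""
                entries[rxn] = (p, GprExpression.parse(gpr))
        return cls(entries=entries)


# ---------------------------------------------------------------------------
# The scoring chain
# ---------------------------------------------------------------------------

def compute_log_scores(hits: BlastHitTable,
                       k: float = LOG_SCORE_K) -> LogScoreTable:
    """S = -log10(E + k) per retained hit; k guards against E = 0."""
    rows = []
    for query, target, evalue in hits.rows:
        if evalue < 0:
            raise ValidationError(f"negative E-value for ({query}, {target})")
        rows.append((query, target, -math.log10(evalue + k)))
    return LogScoreTable(rows=rows, k=k)


def compute_annotation_likelihoods(scores: LogScoreTable, ref: ReferenceDb,
                                   pseudocount: float = PSEUDOCOUNT
                                   ) -> AnnotationLikelihoods:
    """Squared-score likelihood with pseudocount dilution.

    For gene i with hits j (scores S_ij), best score S_max::

        p(i in A_a) = sum_{j: ann(j)=a} S_ij^2
                      / (PC * S_max + sum_j S_ij^2)

    Genes with no hits get no entries. Every target must be in the reference.
    """
    missing = sorted({t for _, t, _ in scores.rows if t not in ref})
    if missing:
        raise ValidationError(
            f"targets absent from reference db: {missing}")
    probabilities: dict[str, dict[str, float]] = {}
    s_max: dict[str, float] = {}
    for query, hits in scores.by_query().items():
        best = max(score for _, score in hits)
        denominator = pseudocount * best + sum(s * s for _, s in hits)
        numerators: dict[str, float] = {}
        for target, score in hits:
            annotation = ref[target]
            numerators[annotation] = numerators.get(annotation, 0.0) + score * score
        probabilities[query] = {a: num / denominator
                                for a, num in numerators.items()}
        s_max[query] = best
    return AnnotationLikelihoods(probabilities=probabilities, s_max=s_max,
                                 pseudocount=pseudocount)


def compute_role_likelihoods(ann: AnnotationLikelihoods, tpl: BiochemTemplate,
                             retain_fraction: float = RETAIN_FRACTION
                             ) -> RoleLikelihoods:
    """Sum annotation likelihoods into roles; organism level takes the max
    over genes and retains genes within ``retain_fraction`` of it."""
    per_gene: dict[str, dict[str, float]] = {}
    for gene, anns in ann.probabilities.items():
        role_p: dict[str, float] = {}
        for annotation, p in anns.items():
            for role in tpl.annotation_roles.get(annotation, ()):
                role_p[role] = role_p.get(role, 0.0) + p
        if role_p:
            per_gene[gene] = role_p
    organism: dict[str, float] = {}
    retained: dict[str, list[str]] = {}
    for role in sorted(tpl.roles()):
        candidates = [(gene, ps[role]) for gene, ps in per_gene.items()
                      if role in ps]
        if not candidates:
            organism[role] = 0.0
            retained[role] = []
            continue
        p_org = max(p for _, p in candidates)
        organism[role] = p_org
        threshold = retain_fraction * p_org
        retained[role] = sorted(gene for gene, p in candidates
                                if p >= threshold and p > 0.0)
    return RoleLikelihoods(per_gene=per_gene, organism=organism,
                           retained_genes=retained)


def compute_complex_likelihoods(roles: RoleLikelihoods, tpl: BiochemTemplate
                                ) -> dict[str, ComplexLikelihood]:
    """Complex likelihood = min over member roles; subunits AND-linked."""
    known_roles = tpl.roles()
    out: dict[str, ComplexLikelihood] = {}
    for cpx in sorted(tpl.complex_roles):
        member_roles = sorted(tpl.complex_roles[cpx])
        unknown = [r for r in member_roles if r not in known_roles]
        if unknown:
            raise ValidationError(
                f"complex {cpx} references unknown roles {unknown}")
        p = min(roles.p_org(r) for r in member_roles)
        if p > 0.0:
            subunits = []
            for role in member_roles:
                genes = roles.retained_genes.get(role, [])
                if genes:
                    subunits.append(GprExpression.or_(
                        [GprExpression.leaf(g) for g in genes]))
            gpr = GprExpression.and_(subunits)
        else:
            gpr = GprExpression.empty()
        out[cpx] = ComplexLikelihood(likelihood=p, gpr=gpr)
    return out


def compute_reaction_likelihoods(complexes: dict[str, ComplexLikelihood],
                                 tpl: BiochemTemplate,
                                 retain_fraction: float = RETAIN_FRACTION
                                 ) -> ReactionLikelihoods:
    """Reaction likelihood = max over mapped complexes; complexes within
    ``retain_fraction`` of the max are OR-linked into the reaction rule."""
    entries: dict[str, tuple[float, GprExpression]] = {}
    diagnostics: dict[str, dict[str, float]] = {}
    for reaction in sorted(tpl.reactions()):
        linked = tpl.complexes_for_reaction(reaction)
        linked = [c for c in linked if c in complexes]
        if not linked:
            entries[reaction] = (0.0, GprExpression.empty())
            diagnostics[reaction] = {}
            continue
        diag = {c: complexes[c].likelihood for c in linked}
        diagnostics[reaction] = diag
        p = max(diag.values())
        if p <= 0.0:
            entries[reaction] = (0.0, GprExpression.empty())
            continue
        threshold = retain_fraction * p
        kept = [c for c in linked
                if diag[c] >= threshold and not complexes[c].gpr.is_empty()]
        gpr = GprExpression.or_([complexes[c].gpr for c in kept])
        entries[reaction] = (p, gpr)
    return ReactionLikelihoods(entries=entries,
                               complex_diagnostics=diagnostics)


def likelihood_chain(hits: BlastHitTable, ref: ReferenceDb,
                     tpl: BiochemTemplate,
                     k: float = LOG_SCORE_K,
                     pseudocount: float = PSEUDOCOUNT,
                     retain_fraction: float = RETAIN_FRACTION
                     ) -> ReactionLikelihoods:
    """Full pipeline from a hit table to reaction likelihoods."""
    scores = compute_log_scores(hits, k=k)
    ann = compute_annotation_likelihoods(scores, ref, pseudocount=pseudocount)
    roles = compute_role_likelihoods(ann, tpl, retain_fraction=retain_fraction)
    cplx = compute_complex_likelihoods(roles, tpl)
    return compute_reaction_likelihoods(cplx, tpl,
                                        retain_fraction=retain_fraction)


# ---------------------------------------------------------------------------
# ROC against a curated model
# ---------------------------------------------------------------------------

def roc_gene_reaction_links(rxn_lik: ReactionLikelihoods,
                            curated: MetabolicModel,
                            cutoffs: Iterable[float]
                            ) -> list[tuple[float, float, float]]:
    """Fraction of true / false computed gene-reaction links surviving each
    likelihood cutoff, as percentages.

    A computed link is every (gene, reaction) pair in the computed rules,
    scored with the reaction's likelihood; it is "true" iff the curated
    model's rule for that reaction contains the gene.
    """
    curated_links: dict[str, set[str]] = {}
    any_gpr = False
    for rxn in curated.reactions:
        genes = rxn.gpr.genes()
        if genes:
            any_gpr = True
        curated_links[rxn.id] = genes
    if not any_gpr:
        raise ValidationError("curated model has no gene rules; ROC undefined")

    links: list[tuple[float, bool]] = []   # (likelihood, is_true)
    for reaction, (p, gpr) in rxn_lik.entries.items():
        for gene in sorted(gpr.genes()):
            is_true = gene in curated_links.get(reaction, set())
            links.append((p, is_true))
    true_total = sum(1 for _, t in links if t)
    false_total = sum(1 for _, t in links if not t)

    out = []
    for cutoff in cutoffs:
        tp = sum(1 for p, t in links if t and p >= cutoff)
        fp = sum(1 for p, t in links if not t and p >= cutoff)
        tp_pct = 100.0 * tp / true_total if true_total else 0.0
        fp_pct = 100.0 * fp / false_total if false_total else 0.0
        out.append((cutoff, tp_pct, fp_pct))
    return out
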
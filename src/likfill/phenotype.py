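"""Knockout-lethality and single-substrate growth simulation with
confusion-matrix scoring against observed phenotype sets."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import ValidationError
from .fba import apply_media, run_fba
from .model_core import Media, MetabolicModel, Metabolite, Reaction

GROWTH_THRESHOLD = 1e-9
TRANSPORT_BOUND = 100.0


@dataclass
class PhenotypeEntry:
    kind: str                  # "knockout" | "biolog"
    key: str                   # gene id or media name
    observed_growth: bool
    media: Optional[Media] = None

    def __post_init__(self) -> None:
        if self.kind not in ("knockout", "biolog"):
            raise ValidationError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "knockout" and self.media is None:
            raise ValidationError(
                f"knockout entry {self.key} must carry a media")


@dataclass
class PhenotypeSet:
    entries: list[PhenotypeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for kind in ("knockout", "biolog"):
            keys = [e.key for e in self.entries if e.kind == kind]
            if len(keys) != len(set(keys)):
                raise ValidationError(f"duplicate {kind} phenotype keys")

    def of_kind(self, kind: str) -> list[PhenotypeEntry]:
        return [e for e in self.entries if e.kind == kind]

    @classmethod
    def from_tsv(cls, path: str,
                 media_by_name: dict[str, Media]) -> "PhenotypeSet":
        """Header: kind, key, media_name, observed_growth (0/1)."""
        entries = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0] == "kind":
                    continue
                kind, key, media_name, observed = row[:4]
                media = None
                if media_name:
                    if media_name not in media_by_name:
                        raise ValidationError(
                            f"{path}: unknown media {media_name!r}")
                    media = media_by_name[media_name]
                entries.append(PhenotypeEntry(
                    kind=kind, key=key,
                    observed_growth=observed.strip() in ("1", "true", "True"),
                    media=media))
        return cls(entries=entries)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["kind", "key", "media_name", "observed_growth"])
            for e in self.entries:
                writer.writerow([e.kind, e.key,
                                 e.media.name if e.media else "",
                                 "1" if e.observed_growth else "0"])


@dataclass
class PhenotypeResult:
    predicted: dict[str, bool]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def to_dict(self) -> dict:
        return {
            "predicted": dict(self.predicted),
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def knockout_model(model: MetabolicModel, genes: set[str]) -> MetabolicModel:
    """Zero both bounds of every reaction whose rule evaluates FALSE with the
    given genes removed. Reactions without gene rules are untouched."""
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.gpr.evaluate(genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def simulate_knockouts(model: MetabolicModel, media: Media,
                       genes: list[str],
                       threshold: float = GROWTH_THRESHOLD
                       ) -> dict[str, bool]:
    """Single-gene lethality: growth call per knocked-out gene."""
    constrained = apply_media(model, media)
    baseline = run_fba(constrained)
    if (not baseline.ok) or baseline.objective_value < threshold:
        raise ValidationError(
            f"model {model.id} does not grow on media {media.name} "
            f"(biomass {baseline.objective_value if baseline.ok else 'inf.'}); "
            f"gap fill to this media before simulating knockouts")
    predictions: dict[str, bool] = {}
    for gene in genes:
        ko = knockout_model(constrained, {gene})
        result = run_fba(ko)
        predictions[gene] = result.ok and result.objective_value >= threshold
    return predictions


def augment_with_transporters(model: MetabolicModel,
                              compounds: list[str],
                              bound: float = TRANSPORT_BOUND
                              ) -> MetabolicModel:
    """Ensure a reversible transporter and an exchange reaction exist for
    every listed extracellular compound (done once per assay batch)."""
    out = model.copy()
    for met_e in sorted(compounds):
        if not out.has_metabolite(met_e):
            out.metabolites.append(Metabolite(id=met_e, name=met_e,
                                              compartment="e"))
            out._met_index[met_e] = out.metabolites[-1]
        met_c = met_e[:-2] + "_c" if met_e.endswith("_e") else met_e + "_c"
        new_mets = []
        if not out.has_metabolite(met_c):
            new_mets.append(Metabolite(id=met_c, name=met_c, compartment="c"))
        t_id = f"T_assay_{met_e}"
        if not out.has_reaction(t_id):
            out.add_reaction(Reaction(
                id=t_id, stoichiometry={met_e: -1.0, met_c: 1.0},
                lower_bound=-bound, upper_bound=bound, is_transporter=True),
                metabolites=new_mets)
        if out.exchange_for(met_e) is None:
            out.add_reaction(Reaction(
                id=f"EX_assay_{met_e}", stoichiometry={met_e: -1.0},
                lower_bound=0.0, upper_bound=1000.0))
    return out


def simulate_biolog(model: MetabolicModel, media_list: list[Media],
                    threshold: float = GROWTH_THRESHOLD
                    ) -> dict[str, bool]:
    """Growth call per media after a one-time transporter augmentation
    covering every compound named in any media in the batch."""
    if not media_list:
        return {}
    compounds = sorted({c for media in media_list
                        for c in media.uptake_limits})
    augmented = augment_with_transporters(model, compounds)
    predictions: dict[str, bool] = {}
    for media in media_list:
        constrained = apply_media(augmented, media)
        result = run_fba(constrained)
        predictions[media.name] = (result.ok
                                   and result.objective_value >= threshold)
    return predictions


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def score_predictions(predicted: dict[str, bool],
                      observed: PhenotypeSet) -> PhenotypeResult:
    """2x2 confusion statistics; growth is the positive class. Metrics with a
    zero denominator are reported as None, never as 0."""
    keys = [e.key for e in observed.entries]
    missing = sorted(set(keys) - set(predicted))
    if missing:
        raise ValidationError(f"predictions missing for keys: {missing}")
    tp = fp = tn = fn = 0
    for entry in observed.entries:
        pred = predicted[entry.key]
        if entry.observed_growth and pred:
            tp += 1
        elif entry.observed_growth and not pred:
            fn += 1
        elif not entry.observed_growth and pred:
            fp += 1
        else:
            tn += 1
    return PhenotypeResult(
        predicted={k: predicted[k] for k in keys},
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )
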
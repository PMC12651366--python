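"""Typing- and zygosity-accuracy evaluation against gold-standard genotypes.

Following the conventions of Szolek et al. (2014): typing accuracy is the
fraction of correctly predicted alleles at 2- or 4-digit resolution (maximum
bipartite matching per locus, homozygous calls contributing their allele
twice, denominator fixed at 2 alleles per locus); zygosity accuracy is the
fraction of loci whose homozygous/heterozygous status is predicted correctly
irrespective of allele identity. Cohort summaries exclude derived (engineered)
lines so each genome is counted once, and report the unweighted mean of
per-model accuracies as the headline, with the pooled-allele fraction retained
as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .consensus import Genotype, _matched_alleles, is_homozygous

logger = logging.getLogger(__name__)


@dataclass
class ModelAccuracy:
    model_id: str
    alleles_correct_2d: int
    alleles_correct_4d: int
    alleles_total: int
    loci_zygosity_correct: int
    loci_total: int

    @property
    def accuracy_2d(self) -> float:
        return self.alleles_correct_2d / self.alleles_total

    @property
    def accuracy_4d(self) -> float:
        return self.alleles_correct_4d / self.alleles_total

    @property
    def zygosity(self) -> float:
        return self.loci_zygosity_correct / self.loci_total


@dataclass
class AccuracyReport:
    per_model: list[ModelAccuracy]
    excluded_models: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mean_accuracy_2d(self) -> float:
        return sum(m.accuracy_2d for m in self.per_model) / len(self.per_model)

    @property
    def mean_accuracy_4d(self) -> float:
        return sum(m.accuracy_4d for m in self.per_model) / len(self.per_model)

    @property
    def pooled_accuracy_2d(self) -> float:
        return sum(m.alleles_correct_2d for m in self.per_model) / sum(
            m.alleles_total for m in self.per_model
        )

    @property
    def pooled_accuracy_4d(self) -> float:
        return sum(m.alleles_correct_4d for m in self.per_model) / sum(
            m.alleles_total for m in self.per_model
        )

    @property
    def zygosity_accuracy(self) -> float:
        """Pooled over loci: correct loci / total loci across evaluated models."""
        return sum(m.loci_zygosity_correct for m in self.per_model) / sum(
            m.loci_total for m in self.per_model
        )


def round_pct(x: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up to `ndigits` decimals (report convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_UP))


def typing_accuracy(truth: Genotype, pred: Genotype, digits: int) -> float:
    """Fraction of correctly predicted alleles at the given resolution."""
    correct = total = 0
    for gene in sorted(truth):
        if gene not in pred:
            logger.info("gene %s missing from prediction; excluded", gene)
            continue
        correct += _matched_alleles(truth[gene], pred[gene], digits)
        total += 2
    if total == 0:
        raise ValueError("no loci shared between truth and prediction")
    return correct / total


def zygosity_accuracy(truth: Genotype, pred: Genotype) -> float:
    """Fraction of loci with correctly predicted hom/het status."""
    correct = total = 0
    for gene in sorted(truth):
        if gene not in pred:
            continue
        correct += is_homozygous(truth[gene]) == is_homozygous(pred[gene])
        total += 1
    if total == 0:
        raise ValueError("no loci shared between truth and prediction")
    return correct / total


def _model_accuracy(model_id: str, truth: Genotype, pred: Genotype) -> ModelAccuracy:
    genes = [g for g in sorted(truth) if g in pred]
    c2 = sum(_matched_alleles(truth[g], pred[g], 2) for g in genes)
    c4 = sum(_matched_alleles(truth[g], pred[g], 4) for g in genes)
    z = sum(is_homozygous(truth[g]) == is_homozygous(pred[g]) for g in genes)
    return ModelAccuracy(model_id, c2, c4, 2 * len(genes), z, len(genes))


def evaluate_cohort(
    truth_set: dict[str, Genotype],
    pred_set: dict[str, Genotype],
    derived_models: dict[str, str] | None = None,
) -> AccuracyReport:
    """Evaluate predictions for every model with gold-standard truth.

    ``derived_models`` maps an engineered/derivative line to its parental
    model; derivatives are excluded before averaging so isogenic families
    contribute one genome each. Models predicted but lacking truth are
    excluded and logged.
    """
    derived_models = derived_models or {}
    excluded: list[tuple[str, str]] = []
    per_model: list[ModelAccuracy] = []
    for model_id in sorted(truth_set):
        if model_id in derived_models:
            excluded.append((model_id, f"derived from {derived_models[model_id]}"))
            continue
        if model_id not in pred_set:
            excluded.append((model_id, "no prediction"))
            continue
        per_model.append(_model_accuracy(model_id, truth_set[model_id], pred_set[model_id]))
    for model_id in sorted(set(pred_set) - set(truth_set)):
        excluded.append((model_id, "no gold-standard truth"))
        logger.info("model %s has no truth genotype; excluded", model_id)
    if not per_model:
        raise ValueError("no overlap between truth and prediction sets")
    return AccuracyReport(per_model=per_model, excluded_models=excluded)
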
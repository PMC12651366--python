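"""Allele-specific expression (ASE) and homozygosity statistics.

At a heterozygous class I locus, allele-level RNA read counts give a raw
minor allele frequency MAF = min(c1, c2) / (c1 + c2) in [0, 0.5]. A balanced
locus sits near 0.5; transcriptional silencing of one allele drives the MAF
toward 0. An ASE-loss event is called when MAF < 0.25 (strict). MAF is
undefined for homozygous loci (no two distinguishable alleles) and when total
depth falls below a minimum (default 10 reads, to avoid zero-depth artifacts).

Cohort-level summaries: per-gene and per-cancer-type homozygosity frequency,
per-sample minimum MAF across the three class I genes, counts of samples with
at least one loss, and a case-vs-control comparison (Wilcoxon rank-sum on the
per-sample minimum MAF, Fisher's exact test on loss indicators, both
Benjamini-Hochberg adjusted when run across several strata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .consensus import GENES, ConsensusResult, is_homozygous
from .nomenclature import HLAAllele

MAF_LOSS_THRESHOLD = 0.25
MIN_DEPTH = 10


@dataclass
class ASERecord:
    """Per-sample per-gene allele read counts with derived MAF and loss call."""

    sample_id: str
    gene: str
    allele1: HLAAllele
    allele2: HLAAllele
    count1: int
    count2: int
    maf: float | None = None
    ase_loss: bool | None = None


def compute_maf(
    record: ASERecord,
    threshold: float = MAF_LOSS_THRESHOLD,
    min_depth: int = MIN_DEPTH,
) -> ASERecord:
    """Fill in MAF and the ASE-loss call for one record.

    MAF is undefined (None) for homozygous loci and for total depth below
    ``min_depth``; the loss call uses a strict inequality, so MAF exactly at
    the threshold is not a loss.
    """
    if record.count1 < 0 or record.count2 < 0:
        raise ValueError("read counts must be non-negative")
    total = record.count1 + record.count2
    if record.allele1.name == record.allele2.name or total < min_depth:
        record.maf, record.ase_loss = None, None
        return record
    record.maf = min(record.count1, record.count2) / total
    record.ase_loss = record.maf < threshold
    return record


def sample_min_maf(records: list[ASERecord]) -> float | None:
    """Minimum defined MAF across a sample's class I genes, or None."""
    mafs = [r.maf for r in records if r.maf is not None]
    return min(mafs) if mafs else None


def count_ase_loss_samples(records: list[ASERecord]) -> tuple[dict[str, int], int]:
    """Per-gene loss counts and the number of distinct samples with >=1 loss."""
    per_gene = {g: 0 for g in GENES}
    samples: set[str] = set()
    for r in records:
        if r.ase_loss:
            per_gene[r.gene] = per_gene.get(r.gene, 0) + 1
            samples.add(r.sample_id)
    return per_gene, len(samples)


@dataclass
class ZygositySummary:
    cancer_type: str
    gene: str
    n_models: int
    n_homozygous: int

    @property
    def frequency(self) -> float:
        return self.n_homozygous / self.n_models

    @property
    def percent(self) -> int:
        # displayed to the nearest integer
        return round(self.frequency * 100)


def homozygosity_frequency(
    results: list[ConsensusResult], cancer_types: dict[str, str]
) -> list[ZygositySummary]:
    """Per (cancer type, gene) homozygosity frequencies among typed models."""
    tallies: dict[tuple[str, str], list[int]] = {}
    for res in results:
        if res.genotype is None:
            continue
        ctype = cancer_types.get(res.model_id)
        if ctype is None:
            continue
        for gene in GENES:
            if gene not in res.genotype:
                continue
            n, h = tallies.setdefault((ctype, gene), [0, 0])
            tallies[(ctype, gene)][0] = n + 1
            tallies[(ctype, gene)][1] = h + is_homozygous(res.genotype[gene])
    return [
        ZygositySummary(ct, g, n, h)
        for (ct, g), (n, h) in sorted(tallies.items())
    ]


@dataclass
class ASEGroupComparison:
    n_case: int
    n_control: int
    rank_sum_statistic: float
    rank_sum_p: float
    fisher_odds_ratio: float
    fisher_p: float


def compare_ase_groups(
    case_min_maf: list[float],
    control_min_maf: list[float],
    case_loss: list[bool] | None = None,
    control_loss: list[bool] | None = None,
) -> ASEGroupComparison:
    """Case-vs-control ASE comparison.

    Primary: two-sided Wilcoxon rank-sum (Mann-Whitney U) on the per-sample
    minimum MAF. Secondary: Fisher's exact test on binary loss indicators
    (derived from the MAF threshold when not given).
    """
    if len(case_min_maf) < 2 or len(control_min_maf) < 2:
        raise ValueError("each group needs at least 2 samples")
    u = stats.mannwhitneyu(case_min_maf, control_min_maf, alternative="two-sided")
    if case_loss is None:
        case_loss = [m < MAF_LOSS_THRESHOLD for m in case_min_maf]
    if control_loss is None:
        control_loss = [m < MAF_LOSS_THRESHOLD for m in control_min_maf]
    table = [
        [sum(case_loss), len(case_loss) - sum(case_loss)],
        [sum(control_loss), len(control_loss) - sum(control_loss)],
    ]
    odds, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return ASEGroupComparison(
        n_case=len(case_min_maf),
        n_control=len(control_min_maf),
        rank_sum_statistic=float(u.statistic),
        rank_sum_p=float(u.pvalue),
        fisher_odds_ratio=float(odds) if math.isfinite(odds) else float("inf"),
        fisher_p=float(fisher_p),
    )
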